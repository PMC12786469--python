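"""Default 19-channel 10-20 montage and its grouping into 10 topographic regions.

Channels are grouped into frontal, central, parietal, occipital and temporal
regions, split by hemisphere.  Midline channels (Fz, Cz, Pz) contribute with
weight 1/2 to the left and right region of their lobe; the 19-channel clinical
montage used here carries no Oz, so the occipital regions contain O1/O2 only.
"""

from __future__ import annotations

#: Canonical 19-channel 10-20 labels, in conventional order.
CHANNELS_1020 = (
    "Fp1", "Fp2", "F3", "F4", "C3", "C4", "P3", "P4", "O1", "O2",
    "F7", "F8", "T3", "T4", "T5", "T6", "Fz", "Cz", "Pz",
)

#: The 10 topographic region codes, fixed order.
REGIONS = ("F-L", "F-R", "C-L", "C-R", "P-L", "P-R", "O-L", "O-R", "T-L", "T-R")

#: Default montage: region -> {channel: weight}.  Per-channel weights across
#: regions sum to 1 (midline channels split 0.5/0.5 between hemispheres).
DEFAULT_MONTAGE: dict[str, dict[str, float]] = {
    "F-L": {"Fp1": 1.0, "F3": 1.0, "F7": 1.0, "Fz": 0.5},
    "F-R": {"Fp2": 1.0, "F4": 1.0, "F8": 1.0, "Fz": 0.5},
    "C-L": {"C3": 1.0, "Cz": 0.5},
    "C-R": {"C4": 1.0, "Cz": 0.5},
    "P-L": {"P3": 1.0, "Pz": 0.5},
    "P-R": {"P4": 1.0, "Pz": 0.5},
    "O-L": {"O1": 1.0},
    "O-R": {"O2": 1.0},
    "T-L": {"T3": 1.0, "T5": 1.0},
    "T-R": {"T4": 1.0, "T6": 1.0},
}

_CANONICAL = {name.lower(): name for name in CHANNELS_1020}


def normalize_channel_name(raw: str) -> str | None:
    """Map a raw channel label to its canonical 10-20 name.

    Tolerates case, surrounding whitespace, an ``EEG `` prefix and a
    reference suffix (``Fp1-A1`` -> ``Fp1``).  Returns None when the label
    does not correspond to a montage channel.
    """
    name = raw.strip()
    if name.upper().startswith("EEG "):
        name = name[4:].strip()
    name = name.split("-")[0].strip()
    return _CANONICAL.get(name.lower())


def validate_montage(montage: dict[str, dict[str, float]]) -> None:
    """Check region codes, positive per-region weight, channel weights summing to 1."""
    if set(montage) != set(REGIONS):
        raise ValueError(f"montage regions must be exactly {REGIONS}")
    per_channel: dict[str, float] = {}
    for region, members in montage.items():
        if not members or sum(members.values()) <= 0:
            raise ValueError(f"region {region!r} has no assigned weight")
        for ch, w in members.items():
            if w <= 0:
                raise ValueError(f"non-positive weight for {ch!r} in {region!r}")
            per_channel[ch] = per_channel.get(ch, 0.0) + w
    bad = {ch: s for ch, s in per_channel.items() if abs(s - 1.0) > 1e-9}
    if bad:
        raise ValueError(f"per-channel weights must sum to 1, got {bad}")


def montage_channels(montage: dict[str, dict[str, float]]) -> set[str]:
    """All channel names referenced by a montage."""
    return {ch for members in montage.values() for ch in members}
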