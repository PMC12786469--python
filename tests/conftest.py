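import numpy as np
import pytest

from eegsonify.spectral import BAND_NAMES, WindowedFeatures


def make_features(P: dict, H: float, n_windows: int = 8) -> WindowedFeatures:
    """Constant-feature time series for synthesis tests."""
    rel = {b: np.full(n_windows, float(P.get(b, 0.0))) for b in BAND_NAMES}
    return WindowedFeatures(
        np.arange(n_windows, dtype=float), rel, np.full(n_windows, float(H))
    )


@pytest.fixture(scope="session")
def equal_weight_recording():
    from eegsonify.synthetic import SpectralProfile, generate_recording

    profile = SpectralProfile(
        {b: 0.2 for b in BAND_NAMES}, 0.9, "control"
    )
    return generate_recording(profile, duration_s=60.0, fs=500.0, seed=11)


@pytest.fixture(scope="session")
def equal_weight_features(equal_weight_recording):
    from eegsonify.spectral import extract_subject

    return extract_subject(equal_weight_recording)
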