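"""Statistics for the blind listener-classification panel.

Covers per-evaluator confusion metrics, exact two-tailed binomial tests
against a probability-matching chance level with Holm correction, a
group-level permutation test on mean accuracy, Fleiss' kappa with a
nonparametric bootstrap CI, Monte-Carlo power estimation, and panel summary
statistics.

The chance level is the expected accuracy of a guesser who labels classes in
proportion to their base rates (probability matching): with class fraction p,
chance = p^2 + (1-p)^2 — e.g. 50.58% for a 36/29 split — which is a more
conservative baseline than the uniform 50%.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.inter_rater import fleiss_kappa as _sm_fleiss_kappa
from statsmodels.stats.multitest import multipletests

POSITIVE = "AD"
NEGATIVE = "control"


@dataclass
class RatingMatrix:
    """Binary diagnosis ratings: subjects x evaluators, plus ground truth.

    ``ratings`` holds class labels; missing ratings are NaN/None.  The index
    gives subject ids, the columns evaluator ids.
    """

    truth: list[str]
    ratings: pd.DataFrame

    def __post_init__(self):
        if self.ratings.shape[1] < 1:
            raise ValueError("need at least one evaluator")
        if len(self.truth) != len(self.ratings):
            raise ValueError("truth length must match the number of subjects")

    @property
    def n_subjects(self) -> int:
        return len(self.truth)

    @property
    def evaluators(self) -> list[str]:
        return list(self.ratings.columns)

    def correctness(self) -> tuple[np.ndarray, np.ndarray]:
        """(correct, observed) boolean masks, subjects x evaluators."""
        truth = np.asarray(self.truth, object)[:, None]
        vals = self.ratings.to_numpy(object)
        observed = ~pd.isna(vals)
        correct = observed & (vals == truth)
        return correct, observed


@dataclass
class EvaluatorMetrics:
    evaluator: str
    accuracy: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    n_evaluated: int
    k_correct: int
    p_raw: float | None = None
    p_holm: float | None = None


@dataclass
class AgreementResult:
    kappa: float
    ci_low: float | None
    ci_high: float | None
    n_items_used: int


def _ratio(num: int, den: int) -> float:
    # undefined ratios are reported as NaN, never silently as 0
    return num / den if den > 0 else float("nan")


def confusion_metrics(
    ratings_one_evaluator: pd.Series,
    truth: list[str],
    positive_class: str = POSITIVE,
    evaluator: str = "",
) -> EvaluatorMetrics:
    """Accuracy/sensitivity/specificity/PPV/NPV from one evaluator's ratings.

    Missing ratings are excluded from this evaluator's denominator.
    """
    vals = ratings_one_evaluator.to_numpy(object)
    truth_arr = np.asarray(truth, object)
    mask = ~pd.isna(vals)
    if mask.sum() < 1:
        raise ValueError("evaluator has no non-missing ratings")
    vals, truth_arr = vals[mask], truth_arr[mask]
    pos_pred = vals == positive_class
    pos_true = truth_arr == positive_class
    tp = int(np.sum(pos_pred & pos_true))
    tn = int(np.sum(~pos_pred & ~pos_true))
    fp = int(np.sum(pos_pred & ~pos_true))
    fn = int(np.sum(~pos_pred & pos_true))
    n = tp + tn + fp + fn
    return EvaluatorMetrics(
        evaluator=evaluator or str(ratings_one_evaluator.name),
        accuracy=_ratio(tp + tn, n),
        sensitivity=_ratio(tp, tp + fn),
        specificity=_ratio(tn, tn + fp),
        ppv=_ratio(tp, tp + fp),
        npv=_ratio(tn, tn + fn),
        n_evaluated=n,
        k_correct=tp + tn,
    )


def chance_level(n_pos: int, n_neg: int) -> float:
    """Probability-matching chance accuracy p^2 + (1-p)^2 with p = n_pos/(n_pos+n_neg)."""
    if n_pos < 1 or n_neg < 1:
        if n_pos < 0 or n_neg < 0 or n_pos + n_neg == 0:
            raise ValueError("need non-negative counts with at least one subject")
    p = n_pos / (n_pos + n_neg)
    return p ** 2 + (1.0 - p) ** 2


def binomial_vs_chance(k_correct: int, n: int, p0: float) -> float:
    """Exact two-tailed binomial p-value (minimum-likelihood method)."""
    if not 0 <= k_correct <= n:
        raise ValueError("need 0 <= k <= n")
    if not 0 < p0 < 1:
        raise ValueError("p0 must be in (0, 1)")
    return float(stats.binomtest(k_correct, n, p0, alternative="two-sided").pvalue)


def holm_adjust(p_values) -> np.ndarray:
    """Step-down Holm adjustment, returned in input order and capped at 1."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p
    return multipletests(p, method="holm")[1]


def evaluate_panel(
    matrix: RatingMatrix,
    positive_class: str = POSITIVE,
    p0: float | None = None,
) -> list[EvaluatorMetrics]:
    """Confusion metrics plus binomial-vs-chance p-values (Holm corrected) per evaluator.

    The chance level defaults to the probability-matching level implied by the
    truth vector's class counts; each evaluator's n is their own number of
    non-missing ratings.
    """
    if p0 is None:
        n_pos = sum(t == positive_class for t in matrix.truth)
        p0 = chance_level(n_pos, matrix.n_subjects - n_pos)
    metrics = [
        confusion_metrics(matrix.ratings[e], matrix.truth, positive_class, evaluator=e)
        for e in matrix.evaluators
    ]
    raw = [binomial_vs_chance(m.k_correct, m.n_evaluated, p0) for m in metrics]
    adj = holm_adjust(raw)
    for m, pr, ph in zip(metrics, raw, adj):
        m.p_raw = float(pr)
        m.p_holm = float(ph)
    return metrics


def mean_accuracy(matrix: RatingMatrix) -> float:
    """Panel mean of per-evaluator accuracies (missing ratings excluded per evaluator)."""
    correct, observed = matrix.correctness()
    return float((correct.sum(axis=0) / observed.sum(axis=0)).mean())


def permutation_test_mean_accuracy(
    matrix: RatingMatrix, n_perm: int = 10_000, seed: int = 0
) -> tuple[float, float]:
    """Group-level permutation test on the panel's mean accuracy.

    Diagnostic labels are permuted across subjects while the rating structure
    stays fixed; the p-value is the fraction of permutations with mean
    accuracy >= observed.  Returns (p_conservative, p_naive): the primary
    estimate is (1 + B) / (1 + n_perm); the naive B / n_perm is also given.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    classes = set(matrix.truth)
    if len(classes) < 2:
        raise ValueError("truth must contain both classes")
    vals = matrix.ratings.to_numpy(object)
    observed_mask = ~pd.isna(vals)
    truth = np.asarray(matrix.truth, object)
    n_per_eval = observed_mask.sum(axis=0)
    # numeric encoding for fast permutation loops; missing -> -1 never matches
    cats = sorted(classes)
    code = {c: i for i, c in enumerate(cats)}
    vals_num = np.array(
        [[code.get(v, -1) if not pd.isna(v) else -1 for v in row] for row in vals],
        dtype=np.int8,
    )
    truth_num = np.array([code[t] for t in truth], dtype=np.int8)

    def stat(t: np.ndarray) -> float:
        correct = vals_num == t[:, None]
        return float((correct.sum(axis=0) / n_per_eval).mean())

    obs = stat(truth_num)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        count += stat(rng.permutation(truth_num)) >= obs - 1e-12
    return (1 + count) / (1 + n_perm), count / n_perm


def _complete_items(matrix: RatingMatrix) -> pd.DataFrame:
    vals = matrix.ratings
    return vals[~vals.isna().any(axis=1)]


def _kappa_from_counts(counts: np.ndarray) -> float:
    """Fleiss' 1971 kappa from an items x categories count table."""
    counts = np.asarray(counts, float)
    n_raters = counts.sum(axis=1)
    if np.any(n_raters != n_raters[0]):
        raise ValueError("all items must have the same number of ratings")
    r = n_raters[0]
    p_i = ((counts ** 2).sum(axis=1) - r) / (r * (r - 1))
    p_bar = p_i.mean()
    p_j = counts.sum(axis=0) / counts.sum()
    pe = (p_j ** 2).sum()
    if 1.0 - pe < 1e-12:
        # all ratings in a single category: perfect trivial agreement
        return 1.0 if p_bar > 1.0 - 1e-12 else float("nan")
    return float((p_bar - pe) / (1.0 - pe))


def _count_table(ratings: pd.DataFrame, categories: list[str]) -> np.ndarray:
    vals = ratings.to_numpy(object)
    return np.stack([(vals == c).sum(axis=1) for c in categories], axis=1)


def fleiss_kappa(matrix: RatingMatrix) -> AgreementResult:
    """Fleiss' kappa on the complete-item submatrix (listwise missing exclusion)."""
    if len(matrix.evaluators) < 2:
        raise ValueError("need at least 2 evaluators")
    complete = _complete_items(matrix)
    if len(complete) < 1:
        raise ValueError("no complete items")
    categories = sorted({v for v in complete.to_numpy(object).ravel()})
    counts = _count_table(complete, categories)
    if len(categories) == 1:
        kappa = _kappa_from_counts(counts)
    else:
        kappa = float(_sm_fleiss_kappa(counts, method="fleiss"))
    return AgreementResult(kappa=kappa, ci_low=None, ci_high=None, n_items_used=len(complete))


def bootstrap_kappa_ci(
    matrix: RatingMatrix, n_boot: int = 1000, seed: int = 0
) -> tuple[float, float]:
    """Percentile 95% CI for Fleiss' kappa by resampling items with replacement."""
    complete = _complete_items(matrix)
    categories = sorted({v for v in complete.to_numpy(object).ravel()})
    counts = _count_table(complete, categories)
    rng = np.random.default_rng(seed)
    n = counts.shape[0]
    kappas = np.empty(n_boot)
    for b in range(n_boot):
        kappas[b] = _kappa_from_counts(counts[rng.integers(0, n, n)])
    kappas = kappas[~np.isnan(kappas)]
    lo, hi = np.percentile(kappas, [2.5, 97.5])
    return float(lo), float(hi)


def agreement(matrix: RatingMatrix, n_boot: int = 1000, seed: int = 0) -> AgreementResult:
    """Fleiss' kappa with bootstrap CI."""
    point = fleiss_kappa(matrix)
    lo, hi = bootstrap_kappa_ci(matrix, n_boot=n_boot, seed=seed)
    return AgreementResult(point.kappa, lo, hi, point.n_items_used)


def power_simulation(
    n_subjects: int = 65,
    n_evaluators: int = 8,
    effect_mean_accuracy: float = 0.7612,
    effect_sd: float = 0.1795,
    alpha: float = 0.05,
    n_sims: int = 500,
    seed: int = 0,
    n_pos: int | None = None,
    n_perm: int = 500,
) -> float:
    """Monte-Carlo power of the group permutation test under the alternative.

    Each simulation draws evaluator accuracies from a normal distribution
    truncated to [0, 1], samples each evaluator's ratings Bernoulli-correct at
    their accuracy, and applies the permutation test at level ``alpha``.
    Power is the rejection fraction.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if n_sims < 100:
        raise ValueError("n_sims must be >= 100")
    n_pos = n_pos if n_pos is not None else round(n_subjects * 36 / 65)
    truth = np.array([POSITIVE] * n_pos + [NEGATIVE] * (n_subjects - n_pos), object)
    rng = np.random.default_rng(seed)
    a, b = (0.0 - effect_mean_accuracy) / effect_sd, (1.0 - effect_mean_accuracy) / effect_sd
    rejections = 0
    truth_num = (truth == POSITIVE).astype(np.int8)
    for _ in range(n_sims):
        accs = stats.truncnorm.rvs(
            a, b, loc=effect_mean_accuracy, scale=effect_sd,
            size=n_evaluators, random_state=rng,
        )
        correct = rng.random((n_subjects, n_evaluators)) < accs[None, :]
        # numeric ratings: agree with truth where correct, flipped otherwise
        ratings_num = np.where(correct, truth_num[:, None], 1 - truth_num[:, None])
        obs = correct.mean()
        count = 0
        for _ in range(n_perm):
            t = rng.permutation(truth_num)
            count += (ratings_num == t[:, None]).mean() >= obs - 1e-12
        p = (1 + count) / (1 + n_perm)
        rejections += p <= alpha
    return rejections / n_sims


def summarize_panel(metrics: list[EvaluatorMetrics]) -> pd.DataFrame:
    """Mean, sample SD, min and max of each metric across evaluators.

    With a single evaluator the SD is undefined and reported as NaN.
    """
    table = pd.DataFrame(
        {
            "accuracy": [m.accuracy for m in metrics],
            "sensitivity": [m.sensitivity for m in metrics],
            "specificity": [m.specificity for m in metrics],
            "ppv": [m.ppv for m in metrics],
            "npv": [m.npv for m in metrics],
        }
    )
    return pd.DataFrame(
        {
            "mean": table.mean(),
            "sd": table.std(ddof=1),
            "min": table.min(),
            "max": table.max(),
        }
    )


def summarize_values(values) -> dict[str, float]:
    """Mean/SD/min/max of a plain list of metric values (e.g. accuracies in %)."""
    arr = np.asarray(values, float)
    sd = float(arr.std(ddof=1)) if arr.size > 1 else float("nan")
    return {
        "mean": float(arr.mean()),
        "sd": sd,
        "min": float(arr.min()),
        "max": float(arr.max()),
    }
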