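"""Discrimination and calibration measurements for probabilistic classifiers.

A clinical risk model is judged on two axes: *discrimination* (does it rank
events above non-events — summarized by the AUC / c-index) and *calibration*
(do predicted probabilities match observed event frequencies — summarized by
the Brier decomposition and Hosmer–Lemeshow tests).  This module implements
both families of measurements plus the theoretical bounds that connect them:
a refinement-based lower bound on the AUC and a hinge-loss upper bound on the
rank loss, which together justify training a classifier on a joint
hinge + squared loss objective.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "ScoredPredictions",
    "ROCCurve",
    "BrierDecomposition",
    "HLTestResult",
    "ReliabilityBins",
    "ThresholdMetrics",
    "AUCComparison",
    "auc_mann_whitney",
    "roc_curve",
    "auc_trapezoidal",
    "brier_score",
    "brier_decomposition",
    "hosmer_lemeshow",
    "reliability_bins",
    "refinement_auc_bound",
    "hinge_rank_bound",
    "threshold_metrics",
    "compare_auc_z",
]

# Scores are grouped by value after rounding to this many decimals; the
# calibration/refinement decomposition is defined over discrete score values
# and exact float grouping would make every continuous score a singleton.
GROUP_DECIMALS = 12


class SingleClassError(ValueError):
    """Raised when a metric is undefined because only one class is present."""


@dataclass(frozen=True)
class ScoredPredictions:
    """Paired prediction scores and binary outcomes.

    Parameters
    ----------
    scores
        One real prediction per observation.  Calibration metrics require the
        probability scale [0, 1]; ranking-only metrics accept any real scale.
    labels
        Binary outcomes coded 0 (negative) / 1 (positive).
    """

    scores: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        labels = np.asarray(self.labels)
        if scores.ndim != 1 or labels.ndim != 1:
            raise ValueError("scores and labels must be one-dimensional")
        if scores.shape != labels.shape:
            raise ValueError(
                f"length mismatch: {scores.shape[0]} scores vs "
                f"{labels.shape[0]} labels"
            )
        if scores.shape[0] < 1:
            raise ValueError("at least one observation required")
        if not np.isfinite(scores).all():
            raise ValueError("scores must be finite")
        uniq = np.unique(labels)
        if not np.isin(uniq, [0, 1]).all():
            raise ValueError(f"labels must be coded 0/1, got values {uniq}")
        object.__setattr__(self, "scores", scores)
        object.__setattr__(self, "labels", labels.astype(np.int64))

    @property
    def n(self) -> int:
        return self.labels.shape[0]

    @property
    def n_pos(self) -> int:
        return int(self.labels.sum())

    @property
    def n_neg(self) -> int:
        return self.n - self.n_pos

    def require_both_classes(self, what: str) -> None:
        if self.n_pos == 0 or self.n_neg == 0:
            raise SingleClassError(
                f"{what} undefined: input contains a single class "
                f"({self.n_pos} positives, {self.n_neg} negatives)"
            )

    def require_probability_scale(self) -> None:
        if (self.scores < 0).any() or (self.scores > 1).any():
            bad = self.scores[(self.scores < 0) | (self.scores > 1)]
            raise ValueError(
                "calibration metrics require scores in [0, 1]; "
                f"found values such as {bad[:3]}"
            )


@dataclass(frozen=True)
class ROCCurve:
    """ROC curve as (FPR, TPR) step points, one per distinct threshold.

    ``thresholds`` holds the descending distinct score values preceded by an
    +inf sentinel for the (0, 0) corner; tied scores collapse into a single
    step, which is what produces the trapezoid under the tie convention.
    """

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray

    def __post_init__(self) -> None:
        for name in ("thresholds", "fpr", "tpr"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (len(self.thresholds) == len(self.fpr) == len(self.tpr)):
            raise ValueError("thresholds, fpr, tpr must have equal lengths")
        if (np.diff(self.fpr) < 0).any() or (np.diff(self.tpr) < 0).any():
            raise ValueError("fpr and tpr must be non-decreasing")
        if not (self.fpr[0] == 0 and self.tpr[0] == 0):
            raise ValueError("curve must start at (0, 0)")
        if not (self.fpr[-1] == 1 and self.tpr[-1] == 1):
            raise ValueError("curve must end at (1, 1)")


@dataclass(frozen=True)
class BrierDecomposition:
    """Brier score split into dis-calibration (CAL) and refinement (REF).

    Grouping predictions by score value s with group size n_s and observed
    positive fraction rho_s:

        CAL = (1/N) sum_s n_s (s - rho_s)^2      (calibration gap)
        REF = (1/N) sum_s n_s rho_s (1 - rho_s)  (group impurity)
        Brier = CAL + REF

    ``groups`` is a (n_groups, 3) array of (s, n_s, rho_s) rows.
    """

    brier: float
    cal: float
    ref: float
    groups: np.ndarray


@dataclass(frozen=True)
class HLTestResult:
    """Hosmer–Lemeshow goodness-of-fit test result.

    ``bins`` is a (g, 3) array of (O_g observed positives, n_g bin size,
    E_g sum of predicted scores) rows for the retained bins.  The statistic is
    referred to a chi-square distribution with ``df = g - 2`` degrees of
    freedom where g counts retained bins.
    """

    statistic: float
    scheme: str
    g: int
    df: int
    p_value: float
    bins: np.ndarray

    @property
    def fits_at_10pct(self) -> bool:
        """Whether the model fits at the 0.1 significance level."""
        return self.p_value > 0.1


@dataclass(frozen=True)
class ReliabilityBins:
    """Binned reliability-diagram table: mean prediction vs observed fraction."""

    edges: np.ndarray
    mean_pred: np.ndarray
    obs_frac: np.ndarray
    counts: np.ndarray


@dataclass(frozen=True)
class ThresholdMetrics:
    sensitivity: float
    specificity: float
    precision: float
    f_score: float
    tp: int
    fp: int
    tn: int
    fn: int
    f_undefined: bool = False


@dataclass(frozen=True)
class AUCComparison:
    auc_a: float
    auc_b: float
    z: float
    p_value: float


def auc_mann_whitney(preds: ScoredPredictions) -> float:
    """AUC as the concordant-pair fraction (c-index), ties counted 1/2.

    Returns (#{positive scored above negative} + 0.5 * #{ties}) / (N+ * N-),
    computed through midranks so ties contribute exactly one half.
    """
    preds.require_both_classes("AUC")
    ranks = stats.rankdata(preds.scores, method="average")
    pos = preds.labels == 1
    n_pos, n_neg = preds.n_pos, preds.n_neg
    rank_sum = ranks[pos].sum()
    return float((rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def roc_curve(preds: ScoredPredictions) -> ROCCurve:
    """ROC curve with one point per distinct score threshold plus endpoints.

    A point at threshold t classifies score >= t as positive.  Tied scores
    collapse into a single diagonal step.
    """
    preds.require_both_classes("ROC")
    order = np.argsort(-preds.scores, kind="stable")
    scores = preds.scores[order]
    labels = preds.labels[order]
    # last index of each run of tied scores
    distinct = np.nonzero(np.diff(scores))[0]
    last_of_run = np.r_[distinct, scores.size - 1]
    tp_cum = np.cumsum(labels)[last_of_run]
    fp_cum = np.cumsum(1 - labels)[last_of_run]
    tpr = np.r_[0.0, tp_cum / preds.n_pos]
    fpr = np.r_[0.0, fp_cum / preds.n_neg]
    thresholds = np.r_[np.inf, scores[last_of_run]]
    return ROCCurve(thresholds=thresholds, fpr=fpr, tpr=tpr)


def auc_trapezoidal(curve: ROCCurve) -> float:
    """Area under an ROC curve by the trapezoidal rule.

    Agrees with :func:`auc_mann_whitney` on the same data to 1e-12; the
    trapezoid over a tie step is exactly the half credit the rank form gives.
    """
    return float(np.trapezoid(curve.tpr, curve.fpr))


def brier_score(preds: ScoredPredictions) -> float:
    """Mean squared error between probability scores and 0/1 outcomes."""
    preds.require_probability_scale()
    return float(np.mean((preds.scores - preds.labels) ** 2))


def brier_decomposition(preds: ScoredPredictions) -> BrierDecomposition:
    """Two-component Brier decomposition over distinct score values.

    Scores are grouped by exact value after rounding to 12 decimals; for each
    group the calibration gap (s - rho_s)^2 and the impurity rho_s(1 - rho_s)
    are n_s-weighted and averaged.  CAL + REF reproduces the Brier score to
    machine precision.
    """
    preds.require_probability_scale()
    rounded = np.round(preds.scores, GROUP_DECIMALS)
    values, inverse, counts = np.unique(rounded, return_inverse=True, return_counts=True)
    pos_per_group = np.bincount(inverse, weights=preds.labels, minlength=values.size)
    rho = pos_per_group / counts
    n = preds.n
    cal = float(np.sum(counts * (values - rho) ** 2) / n)
    ref = float(np.sum(counts * rho * (1.0 - rho)) / n)
    groups = np.column_stack([values, counts.astype(float), rho])
    return BrierDecomposition(brier=cal + ref, cal=cal, ref=ref, groups=groups)


def _hl_bin_assignment(scores: np.ndarray, scheme: str, g: int) -> np.ndarray:
    if scheme == "H":
        # equal-width deciles [0, 0.1), ..., [0.9, 1]
        edges = np.linspace(0.0, 1.0, g + 1)
        idx = np.searchsorted(edges, scores, side="right") - 1
        return np.clip(idx, 0, g - 1)
    if scheme == "C":
        # quantile edges on the score distribution; duplicate edges are
        # dropped so tied scores always land in the same bin
        qs = np.quantile(scores, np.linspace(0, 1, g + 1))
        edges = np.unique(qs)
        idx = np.searchsorted(edges[1:-1], scores, side="right")
        return idx
    raise ValueError(f"unknown Hosmer-Lemeshow scheme {scheme!r}; use 'H' or 'C'")


def hosmer_lemeshow(preds: ScoredPredictions, scheme: str = "C", g: int = 10) -> HLTestResult:
    """Hosmer–Lemeshow chi-square goodness-of-fit test.

    Observations are binned by predicted score — scheme ``"H"`` uses g
    equal-width probability intervals, scheme ``"C"`` uses g (approximately)
    equal-count groups of the sorted scores.  Per retained bin the statistic
    accumulates (O_g - E_g)^2 / (E_g (1 - E_g / n_g)) where O_g is the count
    of observed positives, n_g the bin size and E_g the sum of predicted
    scores.  The p-value is the upper tail of chi-square with g - 2 degrees
    of freedom, g counting the retained bins.

    Degenerate bins (E_g = 0 or E_g = n_g): a bin whose numerator is also 0
    contributes 0 and is retained; otherwise it is merged with its neighbor
    toward the center.
    """
    preds.require_probability_scale()
    if g < 3:
        raise ValueError("need at least 3 bins (df = g - 2 must be >= 1)")
    if scheme == "C" and preds.n < g:
        raise ValueError(f"scheme C with g={g} requires at least {g} observations")

    idx = _hl_bin_assignment(preds.scores, scheme, g)
    n_assigned = int(idx.max()) + 1
    n_g = np.bincount(idx, minlength=n_assigned).astype(float)
    o_g = np.bincount(idx, weights=preds.labels, minlength=n_assigned)
    e_g = np.bincount(idx, weights=preds.scores, minlength=n_assigned)
    keep = n_g > 0
    bins = [list(t) for t in zip(o_g[keep], n_g[keep], e_g[keep])]

    # merge degenerate bins (denominator zero, numerator nonzero) toward center
    def degenerate(b: list[float]) -> bool:
        o, n, e = b
        denom_zero = e <= 0.0 or e >= n
        return denom_zero and (o - e) ** 2 > 0.0

    while len(bins) > 1:
        center = (len(bins) - 1) / 2.0
        bad = [i for i, b in enumerate(bins) if degenerate(b)]
        if not bad:
            break
        # merge the degenerate bin farthest from the center first
        i = max(bad, key=lambda i: (abs(i - center), i))
        j = i + 1 if i < center else i - 1
        merged = [bins[i][0] + bins[j][0], bins[i][1] + bins[j][1], bins[i][2] + bins[j][2]]
        lo, hi = min(i, j), max(i, j)
        bins = bins[:lo] + [merged] + bins[hi + 1 :]

    if len(bins) == 1 and degenerate(bins[0]):
        raise ValueError("HL undefined: all bins degenerate")

    table = np.asarray(bins, dtype=float)
    o, n, e = table[:, 0], table[:, 1], table[:, 2]
    denom = e * (1.0 - e / n)
    num = (o - e) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        contrib = np.where(num == 0.0, 0.0, num / denom)
    statistic = float(contrib.sum())
    g_used = len(bins)
    df = g_used - 2
    # fewer than 3 retained bins leaves no degrees of freedom for the
    # chi-square reference; the statistic is still reported
    p_value = float(stats.chi2.sf(statistic, df)) if df >= 1 else float("nan")
    return HLTestResult(
        statistic=statistic, scheme=scheme, g=g_used, df=df, p_value=p_value, bins=table
    )


def reliability_bins(preds: ScoredPredictions, n_bins: int = 10) -> ReliabilityBins:
    """Reliability-diagram table over equal-width probability bins.

    Bins are half-open [a, b) except the last, which is closed.  Empty bins
    are reported with count 0 and omitted from ``mean_pred``/``obs_frac``.
    """
    preds.require_probability_scale()
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.searchsorted(edges, preds.scores, side="right") - 1, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=preds.scores, minlength=n_bins)
    pos = np.bincount(idx, weights=preds.labels, minlength=n_bins)
    nonempty = counts > 0
    mean_pred = sums[nonempty] / counts[nonempty]
    obs_frac = pos[nonempty] / counts[nonempty]
    return ReliabilityBins(edges=edges, mean_pred=mean_pred, obs_frac=obs_frac, counts=counts)


def refinement_auc_bound(preds: ScoredPredictions) -> float:
    """Refinement-based lower bound on the AUC.

    Low refinement (confident, near-dichotomous scores) forces high
    concordance: the AUC is at least

        1 - (N^2 / (2 N+ N-)) * REF.

    The bound is tight for the all-0.5 balanced sample and holds whenever the
    between-group ordering of scores is concordant with the outcome rates.
    """
    preds.require_both_classes("refinement AUC bound")
    dec = brier_decomposition(preds)
    n = preds.n
    return 1.0 - (n * n / (2.0 * preds.n_pos * preds.n_neg)) * dec.ref


def hinge_rank_bound(raw_scores: np.ndarray, labels: np.ndarray) -> float:
    """Hinge-loss upper bound on the rank loss (1 - AUC).

    With class prior pi = N+/N and the mean hinge loss
    mean_i max(0, 1 - y~_i s_i) over signed labels y~ in {-1, +1}, the rank
    loss never exceeds mean-hinge / (pi (1 - pi)).  Minimizing the hinge loss
    therefore drives the AUC toward 1 — a loose but directional guarantee.
    """
    raw_scores = np.asarray(raw_scores, dtype=float)
    preds = ScoredPredictions(scores=raw_scores, labels=np.asarray(labels))
    preds.require_both_classes("hinge rank bound")
    signed = 2.0 * preds.labels - 1.0
    hinge = np.maximum(0.0, 1.0 - signed * raw_scores)
    pi = preds.n_pos / preds.n
    return float(hinge.mean() / (pi * (1.0 - pi)))


def threshold_metrics(preds: ScoredPredictions, threshold: float = 0.5) -> ThresholdMetrics:
    """Confusion-matrix metrics at a decision threshold (positive iff >=).

    F-score is the harmonic mean of precision and recall; when both the
    predicted-positive and actual-positive sets are empty it is reported as 0
    with ``f_undefined`` set.
    """
    pred_pos = preds.scores >= threshold
    actual_pos = preds.labels == 1
    tp = int(np.sum(pred_pos & actual_pos))
    fp = int(np.sum(pred_pos & ~actual_pos))
    fn = int(np.sum(~pred_pos & actual_pos))
    tn = int(np.sum(~pred_pos & ~actual_pos))
    sensitivity = tp / (tp + fn) if (tp + fn) > 0 else float("nan")
    specificity = tn / (tn + fp) if (tn + fp) > 0 else float("nan")
    f_undefined = (tp + fp) == 0 and (tp + fn) == 0
    precision = tp / (tp + fp) if (tp + fp) > 0 else 0.0
    recall = tp / (tp + fn) if (tp + fn) > 0 else 0.0
    if f_undefined:
        warnings.warn("F-score undefined: no predicted and no actual positives")
        f = 0.0
    elif precision + recall == 0:
        f = 0.0
    else:
        f = 2.0 * precision * recall / (precision + recall)
    return ThresholdMetrics(
        sensitivity=float(sensitivity),
        specificity=float(specificity),
        precision=float(precision),
        f_score=float(f),
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        f_undefined=f_undefined,
    )


def _delong_placements(scores: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC plus DeLong structural components V10 (per positive), V01 (per negative)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = pos.size, neg.size
    all_ranks = stats.rankdata(np.r_[pos, neg], method="average")
    pos_ranks = stats.rankdata(pos, method="average")
    neg_ranks = stats.rankdata(neg, method="average")
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    auc = float(v10.mean())
    return auc, v10, v01


def compare_auc_z(preds_a: ScoredPredictions, preds_b: ScoredPredictions) -> AUCComparison:
    """DeLong z-test for the difference of two correlated AUCs.

    Both score vectors must be evaluated on the same labeled observations in
    the same order; the covariance of the paired placement values accounts for
    the correlation.  Returns the z statistic and its two-sided p-value.  When
    the estimated variance of the difference is 0 (e.g. identical rankings)
    z = 0 and p = 1 by convention.
    """
    if preds_a.n != preds_b.n or not np.array_equal(preds_a.labels, preds_b.labels):
        raise ValueError("compare_auc_z requires the same labels under both predictions")
    preds_a.require_both_classes("AUC comparison")
    auc_a, v10_a, v01_a = _delong_placements(preds_a.scores, preds_a.labels)
    auc_b, v10_b, v01_b = _delong_placements(preds_b.scores, preds_b.labels)
    m, n = v10_a.size, v01_a.size
    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1]
    diff = auc_a - auc_b
    if var_diff <= 0 or diff == 0.0:
        z = 0.0
    else:
        z = diff / np.sqrt(var_diff)
    p = float(2.0 * stats.norm.sf(abs(z))) if z != 0.0 else 1.0
    return AUCComparison(auc_a=auc_a, auc_b=auc_b, z=float(z), p_value=p)
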