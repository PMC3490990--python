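"""Synthetic score and feature generators for calibration/discrimination studies.

Three families of samples, each with the generating truth recorded so recovery
tests can compare against closed forms:

* complementary triangular-beta scores — the unique non-trivial perfectly
  calibrated score population, whose AUC cannot exceed 5/6 (~0.83), the
  classical ceiling on discrimination under perfect calibration;
* class-conditional spherical Gaussians — training fixtures whose Bayes
  posterior is logistic in the first coordinate, with analytic AUC
  Phi(delta / sqrt(2));
* grouped-bin scores — a few discrete score values, each perfectly calibrated
  but impure, forcing discordant pairs (calibration without discrimination).

Plus the score-shrinkage transform (scores / 10) that leaves every ranking
quantity untouched while wrecking calibration, and the penalty-sweep
experiment that traces the discrimination/calibration tradeoff of the
DOC-SVM as the squared-loss penalty grows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import train_test_split

from .metrics import ScoredPredictions, auc_mann_whitney, brier_score, hosmer_lemeshow
from .models import LabeledDataset, TrainConfig, predict_proba, train

__all__ = [
    "SimulatedSample",
    "gen_triangular_beta",
    "shrink_scores",
    "gen_gaussian_classes",
    "gen_grouped_bins",
    "tradeoff_sweep",
    "TRIANGULAR_BETA_AUC",
]

# Closed-form concordance P(S+ > S-) of the complementary triangular pair:
# with f+(s) = 2s and F-(s) = 2s - s^2, the integral of f+ * F- over [0, 1]
# is 4/3 - 1/2 = 5/6.
TRIANGULAR_BETA_AUC = 5.0 / 6.0


@dataclass(frozen=True)
class SimulatedSample:
    """A generated sample with its generating parameters recorded in ``truth``."""

    labels: np.ndarray
    scores: Optional[np.ndarray] = None
    features: Optional[np.ndarray] = None
    truth: dict = field(default_factory=dict)

    def as_predictions(self) -> ScoredPredictions:
        if self.scores is None:
            raise ValueError("sample has no scores")
        return ScoredPredictions(scores=self.scores, labels=self.labels)

    def as_dataset(self) -> LabeledDataset:
        if self.features is None:
            raise ValueError("sample has no features")
        return LabeledDataset(features=self.features, labels=self.labels)


def gen_triangular_beta(n: int, prior: float = 0.5, seed: int = 0) -> SimulatedSample:
    """Scores from the complementary pair of triangular beta densities.

    Labels are Bernoulli(prior); positive scores have density 2s (Beta(2,1)),
    negative scores density 2(1-s) (Beta(1,2)).  The pair is realized as the
    two order statistics of a uniform pair: max for positives, min for
    negatives.  With prior 0.5 the marginal score is uniform and
    P(y=1 | s) = s — the sample is perfectly calibrated in expectation —
    while the population AUC is exactly 5/6.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 < prior < 1.0:
        raise ValueError("prior must be in (0, 1)")
    rng = np.random.default_rng(seed)
    labels = (rng.random(n) < prior).astype(np.int64)
    u = rng.random((n, 2))
    scores = np.where(labels == 1, u.max(axis=1), u.min(axis=1))
    return SimulatedSample(
        labels=labels,
        scores=scores,
        truth={
            "generator": "triangular_beta",
            "prior": prior,
            "seed": seed,
            "population_auc": TRIANGULAR_BETA_AUC,
        },
    )


def shrink_scores(scores: np.ndarray, factor: float = 10.0) -> np.ndarray:
    """Divide probability scores by ``factor`` (>= 1).

    A strictly monotone shrinkage: the ROC curve and AUC are unchanged but
    the scores no longer sit on the probability scale of the outcomes, so
    calibration (Brier, Hosmer–Lemeshow) degrades.
    """
    scores = np.asarray(scores, dtype=float)
    if (scores < 0).any() or (scores > 1).any():
        raise ValueError("scores must be in [0, 1]")
    if factor < 1:
        raise ValueError("shrink factor must be >= 1")
    return scores / factor


def gen_gaussian_classes(
    n: int, d: int, delta: float, prior: float = 0.5, seed: int = 0
) -> SimulatedSample:
    """Class-conditional spherical Gaussian features.

    Class means sit at ±delta/2 along the first axis with unit spherical
    covariance; the Bayes posterior is logistic,
    P(y=1 | x) = expit(delta * x1 + logit(prior)), and the AUC of the Bayes
    score is Phi(delta / sqrt(2)).  ``truth`` records delta, prior and the
    Bayes-calibrated scores of the drawn sample.
    """
    if n < 2 or d < 1 or delta < 0:
        raise ValueError("need n >= 2, d >= 1, delta >= 0")
    if not 0.0 < prior < 1.0:
        raise ValueError("prior must be in (0, 1)")
    rng = np.random.default_rng(seed)
    labels = (rng.random(n) < prior).astype(np.int64)
    x = rng.standard_normal((n, d))
    x[:, 0] += np.where(labels == 1, delta / 2.0, -delta / 2.0)
    bayes_scores = 1.0 / (1.0 + np.exp(-(delta * x[:, 0] + np.log(prior / (1 - prior)))))
    return SimulatedSample(
        labels=labels,
        features=x,
        scores=bayes_scores,
        truth={
            "generator": "gaussian_classes",
            "delta": delta,
            "prior": prior,
            "seed": seed,
            "bayes_auc": float(stats.norm.cdf(delta / np.sqrt(2.0))),
        },
    )


def gen_grouped_bins(
    group_sizes: Sequence[int], group_probs: Sequence[float], seed: int = 0
) -> SimulatedSample:
    """Discrete score groups, each calibrated to its own positive rate.

    Every member of group g receives the identical score ``group_probs[g]``
    and a Bernoulli(group_probs[g]) label, so the sample is perfectly
    calibrated by construction while mixed groups force discordant pairs —
    discrimination is capped by group impurity.
    """
    sizes = np.asarray(group_sizes, dtype=int)
    probs = np.asarray(group_probs, dtype=float)
    if sizes.shape != probs.shape:
        raise ValueError("group_sizes and group_probs must have equal lengths")
    if (probs < 0).any() or (probs > 1).any():
        raise ValueError("group_probs must be in [0, 1]")
    rng = np.random.default_rng(seed)
    scores = np.repeat(probs, sizes)
    labels = (rng.random(scores.size) < scores).astype(np.int64)
    return SimulatedSample(
        labels=labels,
        scores=scores,
        truth={
            "generator": "grouped_bins",
            "group_sizes": sizes.tolist(),
            "group_probs": probs.tolist(),
            "seed": seed,
        },
    )


def tradeoff_sweep(
    base_data: SimulatedSample,
    c2_grid: Sequence[float],
    c1: float = 1.0,
    config: TrainConfig = TrainConfig(),
    test_fraction: float = 0.5,
) -> pd.DataFrame:
    """Trace the discrimination/calibration tradeoff over the C2 penalty.

    Splits ``base_data`` (which must carry features) into stratified train and
    test halves, trains a DOC-SVM at fixed C1 for every C2 in the grid, and
    evaluates held-out AUC, Hosmer–Lemeshow C statistic and p-value, and Brier
    score.  Returns a table sorted by c2; a grid point whose training fails is
    kept as a flagged row so the sweep continues.
    """
    if base_data.features is None:
        raise ValueError("tradeoff_sweep needs a sample with features")
    if len(c2_grid) == 0:
        raise ValueError("c2_grid must be non-empty")
    data = base_data.as_dataset()
    idx_train, idx_test = train_test_split(
        np.arange(data.n),
        test_size=test_fraction,
        stratify=data.labels,
        random_state=config.seed,
    )
    d_train = LabeledDataset(features=data.features[idx_train], labels=data.labels[idx_train])
    x_test, y_test = data.features[idx_test], data.labels[idx_test]

    rows = []
    for c2 in sorted(c2_grid):
        row: dict = {"c2": float(c2), "failed": False}
        try:
            model = train(d_train, "docsvm", c_hinge=c1, c_squared=float(c2), config=config)
            proba = predict_proba(model, x_test)
            preds = ScoredPredictions(scores=proba, labels=y_test)
            hl = hosmer_lemeshow(preds, scheme="C", g=10)
            row.update(
                auc=auc_mann_whitney(preds),
                hlc_stat=hl.statistic,
                hlc_p=hl.p_value,
                brier=brier_score(preds),
            )
        except Exception as exc:  # keep sweeping past a bad grid point
            row.update(
                failed=True, auc=np.nan, hlc_stat=np.nan, hlc_p=np.nan, brier=np.nan,
                error=str(exc),
            )
        rows.append(row)
    return pd.DataFrame(rows)
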