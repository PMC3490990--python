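"""Hyperparameter tuning and the repeated-split model-comparison protocol.

Penalties are tuned by stratified k-fold cross-validation over a log-spaced
grid; model families are compared over repeated stratified train/test splits
with one-tailed paired t-tests on the per-split metrics, matching the common
benchmarking protocol for small clinical datasets (30 random splits).
Feature screening keeps the top-k features by absolute Welch t statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold, train_test_split

from .metrics import (
    ScoredPredictions,
    auc_mann_whitney,
    brier_score,
    hosmer_lemeshow,
    threshold_metrics,
)
from .models import LabeledDataset, LinearModel, TrainConfig, platt_fit, predict_proba, predict_raw, train

__all__ = [
    "CVResult",
    "SplitPlan",
    "default_grid",
    "kfold_cv",
    "repeated_splits_eval",
    "paired_ttest_one_tailed",
    "ttest_feature_rank",
]

_MINIMIZED = {"brier"}  # other criteria (auc, hlc_p) are maximized


@dataclass(frozen=True)
class CVResult:
    """Grid-search result: per-point fold metrics and the selected point."""

    grid: list[tuple[float, ...]]
    per_point: pd.DataFrame
    best: tuple[float, ...]
    criterion: str
    seed: int


@dataclass(frozen=True)
class SplitPlan:
    """Repeated stratified train/test split protocol (default 30 splits)."""

    n_splits: int = 30
    train_size: Optional[int] = None
    test_size: Optional[int] = None
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_splits < 1:
            raise ValueError("n_splits must be >= 1")


def default_grid(model_kind: str) -> list[tuple[float, ...]]:
    """Log-spaced penalty grid: 7 points in 10^-3..10^3 per penalty."""
    points = np.logspace(-3, 3, 7)
    if model_kind == "docsvm":
        return [(float(c1), float(c2)) for c1 in points for c2 in points]
    return [(float(c),) for c in points]


def _fit_spec(
    d_train: LabeledDataset, model_kind: str, point: tuple[float, ...], config: TrainConfig
) -> LinearModel:
    if model_kind == "docsvm":
        c1, c2 = point
        return train(d_train, "docsvm", c_hinge=c1, c_squared=c2, config=config)
    if model_kind == "svm":
        (c,) = point
        model = train(d_train, "svm", c_hinge=c, c_squared=0.0, config=config)
        raw = predict_raw(model, d_train.features)
        model.platt = platt_fit(raw, d_train.labels)
        return model
    if model_kind == "logreg":
        (c,) = point
        return train(d_train, "logreg", c_hinge=c, config=config)
    raise ValueError(f"unknown model_kind {model_kind!r}")


def _eval_metrics(model: LinearModel, x: np.ndarray, y: np.ndarray) -> dict:
    proba = predict_proba(model, x)
    preds = ScoredPredictions(scores=proba, labels=y)
    out = {"brier": brier_score(preds)}
    try:
        out["auc"] = auc_mann_whitney(preds)
    except ValueError:
        out["auc"] = np.nan
    try:
        hl = hosmer_lemeshow(preds, scheme="C", g=min(10, preds.n))
        out["hlc_p"] = hl.p_value
        out["hlc_stat"] = hl.statistic
    except ValueError:
        out["hlc_p"] = np.nan
        out["hlc_stat"] = np.nan
    tm = threshold_metrics(preds)
    out.update(
        f_score=tm.f_score, sensitivity=tm.sensitivity, specificity=tm.specificity
    )
    return out


def _stratified_folds(
    labels: np.ndarray, k: int, seed: int, max_attempts: int = 10
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified fold index pairs; re-drawn if any training side is single-class."""
    for attempt in range(max_attempts):
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed + attempt)
        folds = list(skf.split(np.zeros_like(labels), labels))
        ok = all(
            len(np.unique(labels[tr])) == 2 and len(labels[te]) > 0 for tr, te in folds
        )
        if ok:
            return folds
    raise ValueError("could not form folds with both classes in every training set")


def kfold_cv(
    data: LabeledDataset,
    model_kind: str = "docsvm",
    grid: Optional[Sequence[tuple[float, ...]]] = None,
    k: int = 10,
    criterion: str = "brier",
    seed: int = 0,
    config: TrainConfig = TrainConfig(),
) -> CVResult:
    """Stratified k-fold cross-validated grid search.

    Every grid point is trained on each of the k-1 training folds and scored
    on the held-out fold; the selected point maximizes (or, for "brier",
    minimizes) the mean criterion with ties broken toward the smaller C2 then
    the smaller C1.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if data.n < k:
        raise ValueError("need at least k observations")
    grid = list(grid) if grid is not None else default_grid(model_kind)
    if not grid:
        raise ValueError("grid must be non-empty")
    if criterion not in ("brier", "auc", "hlc_p"):
        raise ValueError(f"unknown criterion {criterion!r}")

    folds = _stratified_folds(data.labels, k, seed)
    records = []
    for point in grid:
        for fold_idx, (tr, te) in enumerate(folds):
            d_train = LabeledDataset(features=data.features[tr], labels=data.labels[tr])
            model = _fit_spec(d_train, model_kind, tuple(point), config)
            m = _eval_metrics(model, data.features[te], data.labels[te])
            records.append({"point": tuple(point), "fold": fold_idx, **m})
    per_point = pd.DataFrame(records)

    means = per_point.groupby("point")[criterion].mean()
    sign = 1.0 if criterion in _MINIMIZED else -1.0

    def sort_key(point: tuple[float, ...]) -> tuple:
        # tie-break: smaller c_squared, then smaller c_hinge
        c2 = point[1] if len(point) > 1 else 0.0
        c1 = point[0]
        return (sign * means[point], c2, c1)

    best = min(means.index, key=sort_key)
    return CVResult(
        grid=[tuple(p) for p in grid],
        per_point=per_point,
        best=tuple(best),
        criterion=criterion,
        seed=seed,
    )


def repeated_splits_eval(
    data: LabeledDataset,
    plan: SplitPlan,
    model_specs: Sequence[dict],
    config: TrainConfig = TrainConfig(),
) -> pd.DataFrame:
    """Evaluate model specs over repeated stratified train/test splits.

    ``model_specs`` entries are dicts with keys ``name``, ``model_kind`` and
    the penalties (``c_hinge``/``c_squared`` as applicable).  Each split draws
    a fresh stratified partition from (seed, split index); the returned table
    has one row per (split, model) with AUC, F-score, sensitivity,
    specificity, Brier score and the HL-C p-value.  A degenerate split is
    recorded as a missing row with its reason and the run continues.
    """
    n = data.n
    train_size = plan.train_size if plan.train_size is not None else int(round(0.6 * n))
    test_size = plan.test_size if plan.test_size is not None else n - train_size
    if train_size + test_size > n:
        raise ValueError("train_size + test_size exceeds the dataset size")

    rows = []
    for s in range(plan.n_splits):
        try:
            idx_train, idx_test = train_test_split(
                np.arange(n),
                train_size=train_size,
                test_size=test_size,
                stratify=data.labels if plan.stratified else None,
                random_state=plan.seed + s,
            )
            d_train = LabeledDataset(
                features=data.features[idx_train], labels=data.labels[idx_train]
            )
            d_train.require_both_classes()
        except Exception as exc:
            for spec in model_specs:
                rows.append({"split": s, "model": spec.get("name"), "missing": str(exc)})
            continue
        for spec in model_specs:
            name = spec.get("name", spec["model_kind"])
            try:
                kind = spec["model_kind"]
                if kind == "docsvm":
                    point = (spec.get("c_hinge", 1.0), spec.get("c_squared", 1.0))
                else:
                    point = (spec.get("c_hinge", 1.0),)
                model = _fit_spec(d_train, kind, point, config)
                m = _eval_metrics(model, data.features[idx_test], data.labels[idx_test])
                rows.append({"split": s, "model": name, "missing": None, **m})
            except Exception as exc:
                rows.append({"split": s, "model": name, "missing": str(exc)})
    return pd.DataFrame(rows)


def paired_ttest_one_tailed(a: np.ndarray, b: np.ndarray) -> dict:
    """One-tailed paired t-test of mean(a) > mean(b).

    Degenerate cases: identical vectors give t = 0, p = 0.5 (with a warning);
    a constant nonzero difference gives p = 0 or 1 by its sign.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("a and b must be equal-length vectors with >= 2 entries")
    diff = a - b
    if np.ptp(diff) == 0.0:
        if diff[0] == 0.0:
            warnings.warn("zero differences everywhere: p = 0.5 by convention")
            return {"t": 0.0, "p": 0.5}
        return {"t": np.inf if diff[0] > 0 else -np.inf, "p": 0.0 if diff[0] > 0 else 1.0}
    res = stats.ttest_rel(a, b, alternative="greater")
    return {"t": float(res.statistic), "p": float(res.pvalue)}


def ttest_feature_rank(data: LabeledDataset, top_k: int = 15) -> np.ndarray:
    """Rank features by |Welch two-sample t| between classes; return top-k indices.

    Zero within-class variances are floored at 1e-12 so constant features get
    a finite (extreme) statistic rather than NaN; ties break toward the
    smaller feature index.
    """
    data.require_both_classes()
    if data.d < top_k:
        raise ValueError(f"top_k={top_k} exceeds feature count {data.d}")
    pos = data.features[data.labels == 1]
    neg = data.features[data.labels == 0]
    m1, m0 = pos.mean(axis=0), neg.mean(axis=0)
    v1 = pos.var(axis=0, ddof=1) if pos.shape[0] > 1 else np.zeros(data.d)
    v0 = neg.var(axis=0, ddof=1) if neg.shape[0] > 1 else np.zeros(data.d)
    se = np.sqrt(np.maximum(v1 / pos.shape[0] + v0 / neg.shape[0], 1e-12))
    t = np.abs((m1 - m0) / se)
    order = np.lexsort((np.arange(data.d), -t))
    return order[:top_k]
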