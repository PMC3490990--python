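"""Linear classifiers trained on a joint hinge + squared loss objective.

The DOC-SVM (Doubly Optimized Calibrated SVM) minimizes

    1/2 ||w||^2 + C1 * sum_i max(0, 1 - y~_i (w.x_i + b))
                + C2 * sum_i (w.x_i + b - y_i)^2

with hinge targets y~ in {-1, +1} and squared-loss targets y in {0, 1}.  The
hinge term pushes the decision boundary apart (discrimination); the squared
term pulls the raw score toward the 0/1 outcome, i.e. toward the probability
scale (calibration).  C2 = 0 recovers the plain soft-margin linear SVM.
Probabilities are read off a DOC-SVM by clipping the raw score to [0, 1]; an
SVM needs Platt's sigmoid rescaling; a logistic-regression baseline applies
its own link.  All three are fit by deterministic full-batch (sub)gradient
descent.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import optimize, special

from .metrics import SingleClassError

__all__ = [
    "LabeledDataset",
    "TrainConfig",
    "LinearModel",
    "hinge_loss_vector",
    "docsvm_objective",
    "train",
    "predict_raw",
    "predict_proba",
    "platt_fit",
    "logreg_train",
]

MODEL_KINDS = ("docsvm", "svm", "logreg")


@dataclass(frozen=True)
class LabeledDataset:
    """An N x d feature matrix with binary {0, 1} labels."""

    features: np.ndarray
    labels: np.ndarray
    feature_names: Optional[list[str]] = None

    def __post_init__(self) -> None:
        x = np.asarray(self.features, dtype=float)
        y = np.asarray(self.labels)
        if x.ndim != 2:
            raise ValueError("features must be a 2-D matrix")
        if y.ndim != 1 or y.shape[0] != x.shape[0]:
            raise ValueError("labels must be a vector matching the feature rows")
        if not np.isfinite(x).all():
            raise ValueError("features contain missing or non-finite values")
        if x.shape[0] < 2:
            raise ValueError("need at least 2 observations")
        uniq = np.unique(y)
        if not np.isin(uniq, [0, 1]).all():
            raise ValueError(f"labels must be coded 0/1, got {uniq}")
        if self.feature_names is not None and len(self.feature_names) != x.shape[1]:
            raise ValueError("feature_names length must match feature columns")
        object.__setattr__(self, "features", x)
        object.__setattr__(self, "labels", y.astype(np.int64))

    @property
    def n(self) -> int:
        return self.features.shape[0]

    @property
    def d(self) -> int:
        return self.features.shape[1]

    def require_both_classes(self) -> None:
        if len(np.unique(self.labels)) < 2:
            raise SingleClassError("training requires both classes present")


@dataclass(frozen=True)
class TrainConfig:
    """Optimizer settings for the subgradient-descent trainers.

    The step at iteration t is eta0 / (L * (1 + t * decay)) where L is a
    data-dependent curvature scale (see ``train``); tol is the relative
    objective-change stopping tolerance.
    """

    max_iters: int = 2000
    eta0: float = 0.1
    decay: float = 0.01
    tol: float = 1e-8
    seed: int = 0
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.max_iters < 1:
            raise ValueError("max_iters must be >= 1")
        if self.tol < 0:
            raise ValueError("tol must be >= 0")


@dataclass
class LinearModel:
    """A trained linear scorer: raw score = w . x + b.

    ``c_hinge`` (C1) and ``c_squared`` (C2) are the hinge- and squared-loss
    penalties; ``trace`` records the objective value at every iteration;
    ``platt`` holds optional (A, B) sigmoid parameters for SVM probability
    read-out; ``standardizer`` holds the (mean, scale) used to z-score
    features at training time, reapplied at prediction time.
    """

    weights: np.ndarray
    bias: float
    c_hinge: float
    c_squared: float
    model_kind: str
    trace: list[float] = field(default_factory=list)
    platt: Optional[tuple[float, float]] = None
    standardizer: Optional[tuple[np.ndarray, np.ndarray]] = None
    converged: bool = True
    warning: Optional[str] = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if not np.isfinite(self.weights).all() or not np.isfinite(self.bias):
            raise ValueError("model parameters must be finite")
        if self.model_kind not in MODEL_KINDS:
            raise ValueError(f"model_kind must be one of {MODEL_KINDS}")
        if self.model_kind == "svm" and self.c_squared != 0:
            raise ValueError("svm models must have c_squared = 0")

    # -- serialization ----------------------------------------------------
    def to_json(self) -> str:
        payload = {
            "model_kind": self.model_kind,
            "weights": self.weights.tolist(),
            "bias": self.bias,
            "c_hinge": self.c_hinge,
            "c_squared": self.c_squared,
            "platt": list(self.platt) if self.platt is not None else None,
            "standardizer": (
                [self.standardizer[0].tolist(), self.standardizer[1].tolist()]
                if self.standardizer is not None
                else None
            ),
            "converged": self.converged,
            "warning": self.warning,
            "trace_summary": {
                "n_iters": len(self.trace),
                "initial": self.trace[0] if self.trace else None,
                "final": self.trace[-1] if self.trace else None,
                "best": min(self.trace) if self.trace else None,
            },
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "LinearModel":
        d = json.loads(text)
        std = d.get("standardizer")
        model = cls(
            weights=np.asarray(d["weights"], dtype=float),
            bias=float(d["bias"]),
            c_hinge=float(d["c_hinge"]),
            c_squared=float(d["c_squared"]),
            model_kind=d["model_kind"],
            trace=[d["trace_summary"]["best"]] if d["trace_summary"]["best"] is not None else [],
            platt=tuple(d["platt"]) if d.get("platt") is not None else None,
            standardizer=(
                (np.asarray(std[0], dtype=float), np.asarray(std[1], dtype=float))
                if std is not None
                else None
            ),
            converged=bool(d.get("converged", True)),
            warning=d.get("warning"),
        )
        return model

    def _transform(self, features: np.ndarray) -> np.ndarray:
        x = np.asarray(features, dtype=float)
        if x.ndim == 1:
            x = x[None, :]
        if x.shape[1] != self.weights.shape[0]:
            raise ValueError(
                f"feature dimension {x.shape[1]} does not match model dimension "
                f"{self.weights.shape[0]}"
            )
        if self.standardizer is not None:
            mean, scale = self.standardizer
            x = (x - mean) / scale
        return x


def hinge_loss_vector(model: LinearModel, data: LabeledDataset) -> np.ndarray:
    """Per-example hinge loss max(0, 1 - y~_i (w.x_i + b)), y~ in {-1, +1}."""
    raw = predict_raw(model, data.features)
    signed = 2.0 * data.labels - 1.0
    return np.maximum(0.0, 1.0 - signed * raw)


def docsvm_objective(model: LinearModel, data: LabeledDataset) -> float:
    """The joint objective 1/2||w||^2 + C1*sum hinge + C2*sum squared error."""
    if model.c_hinge < 0 or model.c_squared < 0:
        raise ValueError("penalties must be non-negative")
    raw = predict_raw(model, data.features)
    signed = 2.0 * data.labels - 1.0
    hinge = np.maximum(0.0, 1.0 - signed * raw).sum()
    squared = ((raw - data.labels) ** 2).sum()
    return float(
        0.5 * model.weights @ model.weights
        + model.c_hinge * hinge
        + model.c_squared * squared
    )


def _objective_and_grad(
    w: np.ndarray,
    b: float,
    x: np.ndarray,
    y01: np.ndarray,
    signed: np.ndarray,
    c1: float,
    c2: float,
) -> tuple[float, np.ndarray, float]:
    raw = x @ w + b
    margin = signed * raw
    active = margin < 1.0
    hinge = np.maximum(0.0, 1.0 - margin)
    resid = raw - y01
    obj = 0.5 * w @ w + c1 * hinge.sum() + c2 * (resid**2).sum()
    grad_w = w.copy()
    grad_b = 0.0
    if c1 > 0 and active.any():
        grad_w -= c1 * (signed[active] @ x[active])
        grad_b -= c1 * signed[active].sum()
    if c2 > 0:
        grad_w += 2.0 * c2 * (resid @ x)
        grad_b += 2.0 * c2 * resid.sum()
    return float(obj), grad_w, float(grad_b)


def train(
    data: LabeledDataset,
    model_kind: str = "docsvm",
    c_hinge: float = 1.0,
    c_squared: float = 1.0,
    config: TrainConfig = TrainConfig(),
) -> LinearModel:
    """Fit a DOC-SVM or linear SVM by deterministic full-batch subgradient descent.

    The parameters start at zero and follow the subgradient of the joint
    objective with step eta0 / (L * (1 + t * decay)); L = 1 + C1*R + 2*C2*(R^2+1)
    with R the mean row norm of the (optionally z-scored) features, which keeps
    the step commensurate with the objective's curvature across penalty scales.
    The best iterate (lowest objective) is returned.  Non-convergence within
    ``max_iters`` returns the best iterate with a warning flag rather than
    raising.  ``model_kind="svm"`` forces C2 = 0; ``model_kind="logreg"`` is
    served by :func:`logreg_train` with l2 = 1 / c_hinge (the usual C <-> 1/l2
    correspondence).
    """
    data.require_both_classes()
    if model_kind == "logreg":
        return logreg_train(data, l2=1.0 / max(c_hinge, 1e-12), config=config)
    if model_kind not in ("docsvm", "svm"):
        raise ValueError(f"unknown model_kind {model_kind!r}")
    if model_kind == "svm":
        c_squared = 0.0
    if c_hinge < 0 or c_squared < 0:
        raise ValueError("penalties must be non-negative")

    x = data.features
    standardizer = None
    if config.standardize:
        mean = x.mean(axis=0)
        scale = x.std(axis=0)
        scale = np.where(scale > 0, scale, 1.0)
        x = (x - mean) / scale
        standardizer = (mean, scale)

    y01 = data.labels.astype(float)
    signed = 2.0 * y01 - 1.0
    n, d = x.shape
    row_norm = float(np.linalg.norm(x, axis=1).mean())
    curvature = 1.0 + c_hinge * row_norm + 2.0 * c_squared * (row_norm**2 + 1.0)

    w = np.zeros(d)
    b = 0.0
    trace: list[float] = []
    best_obj = np.inf
    best_w, best_b = w.copy(), b
    converged = False
    prev_obj = None
    for t in range(config.max_iters):
        obj, grad_w, grad_b = _objective_and_grad(w, b, x, y01, signed, c_hinge, c_squared)
        trace.append(obj)
        if obj < best_obj:
            best_obj, best_w, best_b = obj, w.copy(), b
        if prev_obj is not None and config.tol > 0:
            rel = abs(prev_obj - obj) / max(abs(prev_obj), 1.0)
            if rel < config.tol:
                converged = True
                break
        prev_obj = obj
        # subgradients are per-example sums; normalize by n so the step
        # scale is independent of sample size
        eta = config.eta0 / (curvature * (1.0 + t * config.decay))
        w = w - eta * grad_w / n
        b = b - eta * grad_b / n

    warning = None
    if not converged:
        warning = f"did not converge within {config.max_iters} iterations"
        warnings.warn(warning)
    return LinearModel(
        weights=best_w,
        bias=float(best_b),
        c_hinge=c_hinge,
        c_squared=c_squared,
        model_kind=model_kind,
        trace=trace,
        standardizer=standardizer,
        converged=converged,
        warning=warning,
    )


def predict_raw(model: LinearModel, features: np.ndarray) -> np.ndarray:
    """Raw linear score w . x + b per row (after the stored standardization)."""
    x = model._transform(features)
    return x @ model.weights + model.bias


def predict_proba(model: LinearModel, features: np.ndarray) -> np.ndarray:
    """Probability read-out appropriate to the model kind.

    docsvm: clip(w.x + b, 0, 1) — the squared-loss term trains the raw score
    on the probability scale.  logreg: logistic link.  svm: Platt sigmoid of
    the raw score (requires :func:`platt_fit` parameters on the model).
    """
    raw = predict_raw(model, features)
    if model.model_kind == "docsvm":
        return np.clip(raw, 0.0, 1.0)
    if model.model_kind == "logreg":
        return special.expit(raw)
    if model.model_kind == "svm":
        if model.platt is None:
            raise ValueError("svm model has no Platt parameters: calibrate first")
        a, b = model.platt
        return special.expit(-(a * raw + b))
    raise ValueError(f"unknown model_kind {model.model_kind!r}")


def platt_fit(raw_scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """Platt's sigmoid calibration of raw classifier scores.

    Fits (A, B) maximizing the Bernoulli likelihood of
    P(y=1 | f) = 1 / (1 + exp(A f + B)) with the smoothed targets
    t+ = (N+ + 1)/(N+ + 2) and t- = 1/(N- + 2) that regularize the MLE.
    A <= 0 when scores are positively associated with the positive class.
    Constant scores yield A = 0 with B set by the smoothed prevalence and a
    warning.
    """
    f = np.asarray(raw_scores, dtype=float)
    y = np.asarray(labels)
    if f.shape != y.shape or f.ndim != 1:
        raise ValueError("raw_scores and labels must be matching vectors")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise SingleClassError("Platt fit requires both classes")
    t = np.where(y == 1, (n_pos + 1.0) / (n_pos + 2.0), 1.0 / (n_neg + 2.0))
    if np.ptp(f) == 0.0:
        warnings.warn("constant scores: Platt slope set to 0")
        p = (n_pos + 1.0) / (n_pos + n_neg + 2.0)
        return 0.0, float(np.log((1.0 - p) / p))

    def nll(ab: np.ndarray) -> float:
        z = ab[0] * f + ab[1]
        # -log p = log(1+e^z) for target 1; stable via logaddexp
        return float(np.sum(t * np.logaddexp(0.0, z) + (1.0 - t) * np.logaddexp(0.0, -z)))

    def grad(ab: np.ndarray) -> np.ndarray:
        z = ab[0] * f + ab[1]
        p1 = special.expit(-z)  # model's P(y=1)
        g = t - p1
        return np.array([np.sum(g * f), np.sum(g)])

    res = optimize.minimize(nll, x0=np.zeros(2), jac=grad, method="BFGS")
    a, b = res.x
    return float(a), float(b)


def logreg_train(
    data: LabeledDataset, l2: float = 1.0, config: TrainConfig = TrainConfig()
) -> LinearModel:
    """L2-regularized logistic regression via deterministic gradient descent.

    Minimizes sum_i log(1 + exp(-y~_i (w.x_i + b))) + (l2/2)||w||^2 with an
    unregularized bias, by L-BFGS from a zero start (deterministic).  With
    l2 = 0 on separable data the optimum is at infinity; the fit then stops
    at the iteration cap with large but finite weights and a warning.
    """
    data.require_both_classes()
    if l2 < 0:
        raise ValueError("l2 must be non-negative")
    x = data.features
    standardizer = None
    if config.standardize:
        mean = x.mean(axis=0)
        scale = x.std(axis=0)
        scale = np.where(scale > 0, scale, 1.0)
        x = (x - mean) / scale
        standardizer = (mean, scale)
    signed = 2.0 * data.labels.astype(float) - 1.0
    d = x.shape[1]

    def objective(theta: np.ndarray) -> tuple[float, np.ndarray]:
        w, b = theta[:d], theta[d]
        z = signed * (x @ w + b)
        obj = np.logaddexp(0.0, -z).sum() + 0.5 * l2 * w @ w
        s = -special.expit(-z) * signed
        grad_w = s @ x + l2 * w
        grad_b = s.sum()
        return float(obj), np.r_[grad_w, grad_b]

    res = optimize.minimize(
        objective,
        x0=np.zeros(d + 1),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": config.max_iters, "ftol": config.tol, "gtol": 1e-10},
    )
    warning = None
    if not res.success:
        warning = f"logistic fit stopped early: {res.message}"
        warnings.warn(warning)
    trace = [float(objective(np.zeros(d + 1))[0]), float(res.fun)]
    return LinearModel(
        weights=res.x[:d],
        bias=float(res.x[d]),
        c_hinge=0.0,
        c_squared=0.0,
        model_kind="logreg",
        trace=trace,
        standardizer=standardizer,
        converged=bool(res.success),
        warning=warning,
    )
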