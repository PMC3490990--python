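"""Delimited-text dataset IO, metric reports and run manifests.

Datasets are delimited text (tab default, comma accepted) with a header row,
numeric feature columns and one binary label column; '#' lines are comments.
Metric reports are emitted as nested JSON (discrimination / calibration /
bounds) validated by a pydantic schema, or as flat TSV carrying the same
numbers.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel

from .metrics import (
    ScoredPredictions,
    auc_mann_whitney,
    brier_decomposition,
    brier_score,
    hinge_rank_bound,
    hosmer_lemeshow,
    refinement_auc_bound,
    reliability_bins,
    threshold_metrics,
)
from .models import LabeledDataset

__all__ = [
    "DatasetFile",
    "read_dataset",
    "write_dataset",
    "read_predictions",
    "MetricReport",
    "evaluate_predictions",
    "report_to_tsv",
    "reliability_table",
    "file_sha256",
    "write_manifest",
]


@dataclass(frozen=True)
class DatasetFile:
    """Location and parsing conventions of a delimited dataset file."""

    path: Path
    delimiter: str = "\t"
    label_column: str = "label"

    def __post_init__(self) -> None:
        object.__setattr__(self, "path", Path(self.path))


def _coerce_labels(raw: pd.Series) -> np.ndarray:
    values = raw.to_numpy()
    uniq = sorted(pd.unique(raw).tolist(), key=str)
    as_set = set(str(u) for u in uniq)
    if as_set <= {"0", "1", "0.0", "1.0"}:
        return raw.astype(float).astype(np.int64).to_numpy()
    if as_set <= {"-1", "1", "-1.0", "1.0"}:
        return (raw.astype(float).to_numpy() > 0).astype(np.int64)
    if len(uniq) == 2:
        # two string levels: map by sorted order
        mapping = {uniq[0]: 0, uniq[1]: 1}
        return np.array([mapping[v] for v in values], dtype=np.int64)
    raise ValueError(
        f"label column must have two levels codable to 0/1; found {uniq}"
    )


def read_dataset(file: DatasetFile) -> LabeledDataset:
    """Parse a delimited file into a LabeledDataset.

    Labels coded {0,1} are used as-is; {-1,+1} map to {0,1}; any two string
    levels map by sorted order.  Missing values and malformed numeric cells
    raise with the offending row and column named.  A single-class file loads
    (training will refuse it later).
    """
    df = pd.read_csv(file.path, sep=file.delimiter, comment="#")
    if file.label_column not in df.columns:
        raise ValueError(
            f"label column {file.label_column!r} not found in {file.path} "
            f"(columns: {list(df.columns)})"
        )
    labels = _coerce_labels(df[file.label_column].astype(str).str.strip())
    feat = df.drop(columns=[file.label_column])
    bad_cells = []
    numeric = {}
    for col in feat.columns:
        coerced = pd.to_numeric(feat[col], errors="coerce")
        bad = coerced.isna() & feat[col].notna()
        for row in np.nonzero(bad.to_numpy())[0]:
            bad_cells.append((int(row), col, feat[col].iloc[row]))
        missing = feat[col].isna()
        for row in np.nonzero(missing.to_numpy())[0]:
            bad_cells.append((int(row), col, "<missing>"))
        numeric[col] = coerced
    if bad_cells:
        listing = "; ".join(f"row {r}, column {c!r}: {v!r}" for r, c, v in bad_cells[:10])
        raise ValueError(f"non-numeric or missing feature cells: {listing}")
    features = pd.DataFrame(numeric).to_numpy(dtype=float)
    return LabeledDataset(
        features=features, labels=labels, feature_names=list(feat.columns)
    )


def write_dataset(
    data: LabeledDataset, path: Path, delimiter: str = "\t", label_column: str = "label"
) -> None:
    names = data.feature_names or [f"x{i}" for i in range(data.d)]
    df = pd.DataFrame(data.features, columns=names)
    df[label_column] = data.labels
    df.to_csv(path, sep=delimiter, index=False)


def read_predictions(path: Path, delimiter: str = "\t") -> ScoredPredictions:
    """Read a two-column (score, label) delimited file with a header."""
    df = pd.read_csv(path, sep=delimiter, comment="#")
    if not {"score", "label"} <= set(df.columns):
        raise ValueError(f"prediction file needs 'score' and 'label' columns, got {list(df.columns)}")
    return ScoredPredictions(
        scores=df["score"].to_numpy(dtype=float),
        labels=df["label"].to_numpy(),
    )


class DiscriminationReport(BaseModel):
    auc: float
    sensitivity: float
    specificity: float
    f_score: float
    threshold: float


class CalibrationReport(BaseModel):
    brier: float
    cal: float
    ref: float
    hl_h_statistic: Optional[float]
    hl_h_p: Optional[float]
    hl_c_statistic: Optional[float]
    hl_c_p: Optional[float]


class BoundsReport(BaseModel):
    refinement_auc_lower_bound: float
    hinge_rank_upper_bound: Optional[float]


class MetricReport(BaseModel):
    """Nested discrimination / calibration / bounds metric report."""

    n: int
    n_pos: int
    n_neg: int
    discrimination: DiscriminationReport
    calibration: CalibrationReport
    bounds: BoundsReport


def evaluate_predictions(
    preds: ScoredPredictions, threshold: float = 0.5, hl_bins: int = 10
) -> MetricReport:
    """Full metric panel for a set of probability predictions."""
    dec = brier_decomposition(preds)
    tm = threshold_metrics(preds, threshold=threshold)

    def hl_or_none(scheme: str) -> tuple[Optional[float], Optional[float]]:
        try:
            hl = hosmer_lemeshow(preds, scheme=scheme, g=hl_bins)
            p = None if np.isnan(hl.p_value) else hl.p_value
            return hl.statistic, p
        except ValueError:
            return None, None

    hlh_stat, hlh_p = hl_or_none("H")
    hlc_stat, hlc_p = hl_or_none("C")
    signed_scale = 2.0 * preds.scores - 1.0  # probability scores to margin scale
    try:
        hinge_bound = hinge_rank_bound(signed_scale, preds.labels)
    except ValueError:
        hinge_bound = None
    return MetricReport(
        n=preds.n,
        n_pos=preds.n_pos,
        n_neg=preds.n_neg,
        discrimination=DiscriminationReport(
            auc=auc_mann_whitney(preds),
            sensitivity=tm.sensitivity,
            specificity=tm.specificity,
            f_score=tm.f_score,
            threshold=threshold,
        ),
        calibration=CalibrationReport(
            brier=dec.brier,
            cal=dec.cal,
            ref=dec.ref,
            hl_h_statistic=hlh_stat,
            hl_h_p=hlh_p,
            hl_c_statistic=hlc_stat,
            hl_c_p=hlc_p,
        ),
        bounds=BoundsReport(
            refinement_auc_lower_bound=refinement_auc_bound(preds),
            hinge_rank_upper_bound=hinge_bound,
        ),
    )


def report_to_tsv(report: MetricReport) -> str:
    """Flatten a nested report to two-column TSV with identical numbers."""
    flat: dict[str, object] = {}

    def walk(prefix: str, obj: dict) -> None:
        for key, value in obj.items():
            name = f"{prefix}.{key}" if prefix else key
            if isinstance(value, dict):
                walk(name, value)
            else:
                flat[name] = value

    walk("", report.model_dump())
    lines = ["metric\tvalue"]
    for key, value in flat.items():
        lines.append(f"{key}\t{value}")
    return "\n".join(lines) + "\n"


def reliability_table(preds: ScoredPredictions, n_bins: int = 10) -> pd.DataFrame:
    """Reliability bins as a table: bin_lo, bin_hi, n, mean_pred, obs_frac."""
    rb = reliability_bins(preds, n_bins=n_bins)
    rows = []
    j = 0
    for i in range(n_bins):
        row = {
            "bin_lo": rb.edges[i],
            "bin_hi": rb.edges[i + 1],
            "n": int(rb.counts[i]),
            "mean_pred": np.nan,
            "obs_frac": np.nan,
        }
        if rb.counts[i] > 0:
            row["mean_pred"] = rb.mean_pred[j]
            row["obs_frac"] = rb.obs_frac[j]
            j += 1
        rows.append(row)
    return pd.DataFrame(rows)


def file_sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(path: Path, command: str, params: dict, seed: Optional[int], inputs: list[Path]) -> None:
    """Record the command, parameters, seed and input hashes of a run."""
    from . import __version__

    manifest = {
        "version": __version__,
        "command": command,
        "params": params,
        "seed": seed,
        "inputs": {str(p): file_sha256(p) for p in inputs if Path(p).exists()},
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")
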