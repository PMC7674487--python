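"""Mutual-information voxel selection.

Each voxel's continuous density column is quantile-binned and scored by the
plug-in mutual information with the binary diagnosis label,

    I(X, Y) = sum_x sum_y p(x, y) log p(y | x)  -  sum_y p(y) log p(y),

in nats.  Voxels are ranked by I(X, Y) and the top-k become the classifier's
input features; ties break deterministically toward the lower column index.

The estimator is the empirical ("plug-in") one: probabilities are cell
frequencies of the joint contingency table, and 0 * log 0 := 0.  For binary
labels I(X, Y) <= H(Y) <= ln 2.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .vbm_io import CohortMatrix


@dataclass
class MIScores:
    """Per-column mutual information (nats) plus the estimator settings used."""

    score: np.ndarray
    n_bins: int
    estimator: str = "plugin-quantile"

    def __post_init__(self) -> None:
        self.score = np.asarray(self.score, dtype=np.float64)

    def __len__(self) -> int:
        return self.score.shape[0]


@dataclass
class SelectedFeatures:
    """Top-k voxel columns in strictly descending MI order (ties: lower index)."""

    columns: np.ndarray
    scores: np.ndarray
    voxel_coords: np.ndarray | None = None  # (k, 3) grid coordinates, if known

    def __post_init__(self) -> None:
        self.columns = np.asarray(self.columns, dtype=np.int64)
        self.scores = np.asarray(self.scores, dtype=np.float64)

    @property
    def k(self) -> int:
        return self.columns.shape[0]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "k": self.k,
            "columns": self.columns.tolist(),
            "mi_nats": self.scores.tolist(),
        }
        if self.voxel_coords is not None:
            payload["voxel_coords"] = self.voxel_coords.tolist()
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SelectedFeatures":
        payload = json.loads(Path(path).read_text())
        coords = payload.get("voxel_coords")
        return cls(
            columns=np.asarray(payload["columns"]),
            scores=np.asarray(payload["mi_nats"]),
            voxel_coords=None if coords is None else np.asarray(coords),
        )


def discretize_column(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-frequency (quantile) binning into codes {0..n_bins-1}.

    A value equal to a cut point goes to the lower bin; a constant column
    yields a single code 0 (its MI will be 0), not an error.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        raise ValueError("empty column")
    cuts = np.quantile(values, np.arange(1, n_bins) / n_bins)
    codes = (values[:, None] > cuts[None, :]).sum(axis=1)
    return codes.astype(np.int64)


def mutual_information(x: np.ndarray, y: np.ndarray) -> float:
    """Plug-in mutual information (nats) between discrete codes and binary labels.

    Tiny negative values from floating-point rounding are clipped to 0.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size == 0:
        raise ValueError("empty input")
    if not np.isin(y, [0, 1]).all():
        raise ValueError("labels must be binary")
    xs, xcodes = np.unique(x, return_inverse=True)
    joint = np.zeros((xs.size, 2), dtype=np.float64)
    np.add.at(joint, (xcodes, y.astype(np.int64)), 1.0)
    n = x.size
    p = joint / n
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * (np.log(p) - np.log(px) - np.log(py))
    mi = float(np.nansum(terms))
    return max(mi, 0.0)


def mi_scores(X: np.ndarray, y: np.ndarray, n_bins: int = 4) -> MIScores:
    """Mutual information of every column of X (binned) with the labels.

    Vectorized across columns: all columns are quantile-binned at once and
    the per-column joint tables accumulated with one bincount.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.int64)
    n, m = X.shape
    cuts = np.quantile(X, np.arange(1, n_bins) / n_bins, axis=0)  # (n_bins-1, m)
    codes = (X[None, :, :] > cuts[:, None, :]).sum(axis=0)  # (n, m)

    # joint[b, c, col] = #subjects with code b and label c at column col
    flat = (np.arange(m)[None, :] * (2 * n_bins)) + codes * 2 + y[:, None]
    counts = np.bincount(flat.ravel(), minlength=m * 2 * n_bins).reshape(m, n_bins, 2)
    p = counts / n
    px = p.sum(axis=2, keepdims=True)
    py = p.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * (np.log(p) - np.log(px) - np.log(py))
    scores = np.nansum(terms, axis=(1, 2))
    return MIScores(score=np.maximum(scores, 0.0), n_bins=n_bins)


def rank_and_select(
    scores: MIScores, k: int, voxel_index: np.ndarray | None = None
) -> SelectedFeatures:
    """Top-k columns by MI, descending; ties broken by ascending column index."""
    m = len(scores)
    if not 1 <= k <= m:
        raise ValueError(f"k={k} out of range [1, {m}]")
    order = np.lexsort((np.arange(m), -scores.score))
    cols = order[:k]
    return SelectedFeatures(
        columns=cols,
        scores=scores.score[cols],
        voxel_coords=None if voxel_index is None else voxel_index[cols],
    )


def select_features(
    cohort: CohortMatrix, k: int, n_bins: int = 4
) -> tuple[MIScores, SelectedFeatures]:
    """Score every voxel of a cohort matrix and keep the top-k.

    Call this on the *training* rows only; the frozen columns are then
    applied unchanged to held-out subjects.
    """
    scores = mi_scores(cohort.X, cohort.y, n_bins=n_bins)
    return scores, rank_and_select(scores, k, voxel_index=cohort.voxel_index)


def export_scores_tsv(
    scores: MIScores, voxel_index: np.ndarray, path: str | Path
) -> None:
    """Write per-voxel MI as TSV (column, i, j, k, mi_nats)."""
    df = pd.DataFrame(
        {
            "column": np.arange(len(scores)),
            "i": voxel_index[:, 0],
            "j": voxel_index[:, 1],
            "k": voxel_index[:, 2],
            "mi_nats": scores.score,
        }
    )
    df.to_csv(path, sep="\t", index=False)
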