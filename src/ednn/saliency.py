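"""Individual-level z-score saliency maps over the model's selected voxels.

A subject's density at each selected voxel is standardized twice, against
the healthy-control and the patient reference distributions of the training
cohort:

    zscore_HC  = (v - mean_HC)  / sd_HC
    zscore_SCZ = (v - mean_SCZ) / sd_SCZ
    combined   = zscore_SCZ / (zscore_SCZ + zscore_HC)

The combined score is computed exactly as defined: it is 0 where the voxel
sits on the patient mean, 0.5 where both standardizations agree, and is
*unbounded* in general — whenever |zscore_SCZ + zscore_HC| falls below a
small tolerance the voxel is flagged undefined (NaN in the rendered map)
rather than allowed to blow up.  Zero-variance reference voxels are flagged
and excluded up front.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import DegenerateClassError, GridMismatchError
from .features import SelectedFeatures
from .model import TrainedEDNN
from .vbm_io import CohortMatrix, VolumeImage, VoxelMask

DENOM_TOL = 1e-8


@dataclass
class GroupStats:
    """Per-voxel reference mean/SD for HC and SCZ, from a training cohort."""

    mean_hc: np.ndarray
    sd_hc: np.ndarray
    mean_scz: np.ndarray
    sd_scz: np.ndarray
    n_hc: int
    n_scz: int
    tissue: str
    flagged: np.ndarray  # True where either group SD is 0 (voxel excluded)

    @property
    def n_voxels(self) -> int:
        return self.mean_hc.shape[0]


@dataclass
class SaliencyMap:
    """Combined z-scores rendered on the grid for one subject."""

    volume: VolumeImage
    subject_id: str
    n_defined: int
    n_undefined: int

    def sidecar(self, path: str | Path) -> None:
        defined = self.volume.data[np.isfinite(self.volume.data)]
        payload = {
            "subject_id": self.subject_id,
            "n_defined": self.n_defined,
            "n_undefined": self.n_undefined,
            "combined_min": float(defined.min()) if defined.size else None,
            "combined_max": float(defined.max()) if defined.size else None,
            "combined_mean": float(defined.mean()) if defined.size else None,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def group_stats(cohort: CohortMatrix) -> GroupStats:
    """Per-voxel sample mean and SD (ddof=1) for each diagnostic group."""
    hc = cohort.X[cohort.y == 0]
    scz = cohort.X[cohort.y == 1]
    if hc.shape[0] < 2 or scz.shape[0] < 2:
        raise DegenerateClassError("group_stats needs >=2 subjects per class")
    sd_hc = hc.std(axis=0, ddof=1)
    sd_scz = scz.std(axis=0, ddof=1)
    return GroupStats(
        mean_hc=hc.mean(axis=0),
        sd_hc=sd_hc,
        mean_scz=scz.mean(axis=0),
        sd_scz=sd_scz,
        n_hc=hc.shape[0],
        n_scz=scz.shape[0],
        tissue=cohort.tissue,
        flagged=(sd_hc == 0.0) | (sd_scz == 0.0),
    )


def subject_zscores(
    v: np.ndarray, stats: GroupStats, columns: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(zscore_HC, zscore_SCZ, combined, undefined) at the given columns.

    ``v`` holds the subject's densities at those columns.  ``undefined`` is
    True where |zscore_SCZ + zscore_HC| < tolerance (combined left NaN) —
    flagged reference voxels must not be passed in.
    """
    cols = np.arange(stats.n_voxels) if columns is None else np.asarray(columns)
    if np.any(stats.flagged[cols]):
        raise ValueError("zscores requested at flagged (zero-SD) voxels")
    v = np.asarray(v, dtype=np.float64)
    z_hc = (v - stats.mean_hc[cols]) / stats.sd_hc[cols]
    z_scz = (v - stats.mean_scz[cols]) / stats.sd_scz[cols]
    denom = z_scz + z_hc
    undefined = np.abs(denom) < DENOM_TOL
    combined = np.full_like(z_hc, np.nan)
    np.divide(z_scz, denom, out=combined, where=~undefined)
    return z_hc, z_scz, combined, undefined


def render_saliency(
    model: TrainedEDNN | SelectedFeatures,
    subject_values: np.ndarray,
    stats: GroupStats,
    mask: VoxelMask,
    subject_id: str = "",
) -> SaliencyMap:
    """Combined z-score map at the model's selected voxels, 0 elsewhere.

    ``subject_values`` is the subject's full masked-voxel vector (one value
    per mask column, same ordering as the cohort matrix).  Selected voxels
    whose reference SD is zero, or whose combined denominator vanishes, are
    written as NaN and counted.
    """
    if isinstance(model, SelectedFeatures):
        columns = model.columns
    else:
        columns = model.feature_columns
    subject_values = np.asarray(subject_values, dtype=np.float64)
    if subject_values.shape[0] != mask.n_voxels:
        raise GridMismatchError("subject vector does not match mask voxel count")
    if stats.n_voxels != mask.n_voxels:
        raise GridMismatchError("reference stats do not match mask voxel count")

    out = np.zeros(mask.n_voxels, dtype=np.float64)
    n_defined = 0
    n_undefined = 0
    if columns.size:
        ok = ~stats.flagged[columns]
        good_cols = columns[ok]
        _, _, combined, undefined = subject_zscores(
            subject_values[good_cols], stats, good_cols
        )
        out[good_cols] = np.where(undefined, np.nan, combined)
        out[columns[~ok]] = np.nan
        n_undefined = int(undefined.sum() + (~ok).sum())
        n_defined = int(columns.size - n_undefined)

    grid = np.zeros(mask.grid_shape, dtype=np.float32)
    grid[mask.mask] = out.astype(np.float32)
    return SaliencyMap(
        volume=VolumeImage(grid, mask.affine),
        subject_id=subject_id,
        n_defined=n_defined,
        n_undefined=n_undefined,
    )
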