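"""NIfTI volume and cohort-manifest I/O for voxel-based morphometry.

Volumes are spatially normalized tissue-density maps (gray or white matter),
one per subject per tissue, all living on a shared voxel grid.  This module
loads them, builds an analysis mask from across-subject mean/variance
thresholds, and stacks the masked voxels into the subjects x voxels matrix
that every downstream stage (feature selection, classification, saliency)
operates on.

Voxel indices are 0-based ``(i, j, k)`` array coordinates; world coordinates
come only from the affine and no axis flips are ever applied.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import (
    EmptyMaskError,
    GridMismatchError,
    ManifestError,
    NaNVolumeError,
    NonVolumeError,
    VolumeFileMissingError,
    VolumeHeaderError,
)

MANIFEST_COLUMNS = ["subject_id", "gm_path", "wm_path", "label", "cohort"]
Tissue = Literal["GM", "WM"]


@dataclass
class VolumeImage:
    """A 3-D scalar grid of tissue density with its voxel-to-world affine."""

    data: np.ndarray
    affine: np.ndarray

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape)  # type: ignore[return-value]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise NonVolumeError(f"expected a 3-D volume, got ndim={self.data.ndim}")
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.affine.shape != (4, 4):
            raise VolumeHeaderError("affine must be 4x4")


@dataclass
class VoxelMask:
    """Boolean analysis mask on the shared grid; True cells define matrix columns."""

    mask: np.ndarray
    affine: np.ndarray

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return tuple(self.mask.shape)  # type: ignore[return-value]

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise NonVolumeError("mask must be 3-D")
        if self.n_voxels < 1:
            raise EmptyMaskError("mask retains zero voxels")

    def voxel_index(self) -> np.ndarray:
        """(n_voxels, 3) array of (i, j, k) coordinates, C-order, one per column."""
        return np.argwhere(self.mask)


@dataclass
class CohortManifest:
    """Roster of subjects: id, per-tissue volume paths, binary label, cohort tag."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in MANIFEST_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ManifestError(f"manifest missing columns: {missing}")
        self.frame = self.frame.reset_index(drop=True)
        ids = self.frame["subject_id"].astype(str)
        if ids.duplicated().any():
            raise ManifestError("duplicate subject_id in manifest")
        labels = self.frame["label"].to_numpy()
        if not np.isin(labels, [0, 1]).all():
            raise ManifestError("labels must be binary 0 (HC) / 1 (SCZ)")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def subject_ids(self) -> list[str]:
        return self.frame["subject_id"].astype(str).tolist()

    @property
    def labels(self) -> np.ndarray:
        return self.frame["label"].to_numpy(dtype=np.int64)

    def paths(self, tissue: Tissue) -> list[str]:
        col = "gm_path" if tissue == "GM" else "wm_path"
        return self.frame[col].astype(str).tolist()

    def subset(self, subject_ids: Sequence[str]) -> "CohortManifest":
        """Rows for the given subjects, in the given order."""
        idx = self.frame.set_index(self.frame["subject_id"].astype(str))
        missing = [s for s in subject_ids if s not in idx.index]
        if missing:
            raise ManifestError(f"unknown subject ids: {missing[:5]}")
        return CohortManifest(idx.loc[list(subject_ids)].reset_index(drop=True))

    def save(self, path: str | os.PathLike) -> None:
        self.frame[MANIFEST_COLUMNS].to_csv(path, index=False)


def load_manifest(path: str | os.PathLike, check_files: bool = True) -> CohortManifest:
    """Read a cohort CSV (header ``subject_id,gm_path,wm_path,label,cohort``)."""
    path = Path(path)
    if not path.exists():
        raise VolumeFileMissingError(f"manifest not found: {path}")
    frame = pd.read_csv(path, dtype={"subject_id": str}, keep_default_na=False)
    m = CohortManifest(frame)
    if check_files:
        for col in ("gm_path", "wm_path"):
            for p in m.frame[col].astype(str):
                if p and not Path(p).exists():
                    raise VolumeFileMissingError(f"manifest references missing file: {p}")
    return m


@dataclass
class CohortMatrix:
    """Subjects x masked-voxels density matrix with binary diagnosis labels.

    Column ``c`` of ``X`` holds the density at grid coordinate
    ``voxel_index[c]`` for every subject (row order = manifest order).
    """

    X: np.ndarray
    y: np.ndarray
    voxel_index: np.ndarray
    tissue: Tissue
    mask: VoxelMask
    subject_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.int64)
        if self.X.shape[0] != self.y.shape[0]:
            raise ManifestError("X rows and labels disagree")
        if self.X.shape[1] != self.voxel_index.shape[0]:
            raise GridMismatchError("X columns and voxel_index disagree")

    @property
    def n_subjects(self) -> int:
        return self.X.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.X.shape[1]

    def subset_subjects(self, rows: Sequence[int]) -> "CohortMatrix":
        rows = list(rows)
        return CohortMatrix(
            X=self.X[rows],
            y=self.y[rows],
            voxel_index=self.voxel_index,
            tissue=self.tissue,
            mask=self.mask,
            subject_ids=[self.subject_ids[r] for r in rows] if self.subject_ids else [],
        )


def load_volume(path: str | os.PathLike, nan_policy: str = "error") -> VolumeImage:
    """Load a NIfTI-1 volume (.nii/.nii.gz).

    On-disk integer data are rescaled through ``scl_slope``/``scl_inter``
    (nibabel's ``get_fdata``).  ``nan_policy`` is ``"error"`` (default) or
    ``"zero"`` (replace NaN with 0).
    """
    path = Path(path)
    if not path.exists():
        raise VolumeFileMissingError(f"no such volume: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises a zoo of header errors
        raise VolumeHeaderError(f"unreadable NIfTI header: {path}: {exc}") from exc
    if len(img.shape) != 3:
        raise NonVolumeError(f"{path}: expected 3-D image, got shape {img.shape}")
    data = np.asarray(img.get_fdata(dtype=np.float32))
    if np.isnan(data).any():
        if nan_policy == "zero":
            data = np.nan_to_num(data, nan=0.0)
        else:
            raise NaNVolumeError(f"{path}: volume contains NaN (nan_policy='error')")
    return VolumeImage(data=data, affine=np.asarray(img.affine))


def save_volume(v: VolumeImage, path: str | os.PathLike) -> Path:
    """Write a VolumeImage as float32 NIfTI-1; the affine is preserved bit-exact."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(np.asarray(v.data, dtype=np.float32), v.affine)
    nib.save(img, str(path))
    return path


def _check_same_grid(volumes: Iterable[VolumeImage]) -> tuple[tuple[int, ...], np.ndarray]:
    volumes = list(volumes)
    shape, affine = volumes[0].grid_shape, volumes[0].affine
    for v in volumes[1:]:
        if v.grid_shape != shape:
            raise GridMismatchError(f"grid mismatch: {v.grid_shape} vs {shape}")
        if not np.allclose(v.affine, affine, atol=1e-6):
            raise GridMismatchError("affine mismatch between volumes")
    return shape, affine


def build_mask(
    volumes: Sequence[VolumeImage],
    min_mean: float = 0.05,
    min_variance: float = 0.0,
) -> VoxelMask:
    """Across-subject mask: keep voxels with mean >= ``min_mean`` and
    variance strictly > ``min_variance``.

    Raising either threshold can only remove voxels (monotone).  Raises
    :class:`EmptyMaskError` if nothing survives.
    """
    if len(volumes) < 2:
        raise ManifestError("need >=2 volumes to build a mask")
    if min_mean < 0 or min_variance < 0:
        raise ValueError("thresholds must be >= 0")
    _, affine = _check_same_grid(volumes)
    stack = np.stack([v.data for v in volumes]).astype(np.float64)
    mean = stack.mean(axis=0)
    var = stack.var(axis=0)
    mask = (mean >= min_mean) & (var > min_variance)
    if not mask.any():
        raise EmptyMaskError(
            f"no voxel passes mean>={min_mean} and variance>{min_variance}"
        )
    return VoxelMask(mask=mask, affine=affine)


def save_mask(mask: VoxelMask, path: str | os.PathLike) -> Path:
    return save_volume(VolumeImage(mask.mask.astype(np.float32), mask.affine), path)


def load_mask(path: str | os.PathLike) -> VoxelMask:
    v = load_volume(path)
    return VoxelMask(mask=v.data > 0.5, affine=v.affine)


def stack_cohort(
    manifest: CohortManifest,
    tissue: Tissue,
    mask: VoxelMask,
    nan_policy: str = "error",
) -> CohortMatrix:
    """Assemble the subjects x voxels matrix for one tissue.

    Row order follows the manifest; ``X[s, c]`` is subject ``s``'s density at
    ``mask.voxel_index()[c]``.
    """
    vidx = mask.voxel_index()
    flat = np.flatnonzero(mask.mask.ravel())
    rows = []
    for p in manifest.paths(tissue):
        if not p:
            raise VolumeFileMissingError(
                f"manifest has no {tissue} path for some subject"
            )
        v = load_volume(p, nan_policy=nan_policy)
        if v.grid_shape != mask.grid_shape:
            raise GridMismatchError(
                f"{p}: grid {v.grid_shape} does not match mask {mask.grid_shape}"
            )
        rows.append(v.data.ravel()[flat])
    X = np.stack(rows).astype(np.float64)
    return CohortMatrix(
        X=X,
        y=manifest.labels,
        voxel_index=vidx,
        tissue=tissue,
        mask=mask,
        subject_ids=manifest.subject_ids,
    )


def matrix_row_to_volume(
    values: np.ndarray, mask: VoxelMask, background: float = 0.0
) -> VolumeImage:
    """Scatter a length-``n_voxels`` vector back onto the 3-D grid."""
    if values.shape[0] != mask.n_voxels:
        raise GridMismatchError("vector length does not match mask voxel count")
    grid = np.full(mask.grid_shape, background, dtype=np.float32)
    grid[mask.mask] = values
    return VolumeImage(data=grid, affine=mask.affine)
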