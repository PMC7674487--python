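"""Synthetic two-group VBM phantom cohorts with known discriminative voxels.

The generator emulates the study design of a case-control voxel-based
morphometry dataset: two groups (healthy controls, HC = 0; patients,
SCZ = 1), a constant tissue-density baseline, spatially smooth Gaussian
noise, and a group-specific density *reduction* inside spherical "atrophy"
blobs for the patient group.  The effect is injected before smoothing so
blob edges blur the way partial-volume effects do in real VBM maps, and
every voxel is clipped to [0, 1] because tissue densities are proportions.

Because the blobs are known exactly, the phantom doubles as the ground-truth
oracle for feature-recovery and saliency tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import GridMismatchError
from .vbm_io import CohortManifest, VoxelMask, VolumeImage, save_volume

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class Blob:
    """A spherical patient-group density reduction.

    ``effect`` is expressed in units of the baseline noise SD: inside the
    sphere, patient volumes lose ``effect * noise_sd`` density before
    smoothing.
    """

    center: tuple[int, int, int]
    radius: float
    effect: float

    def __post_init__(self) -> None:
        if self.effect < 0:
            raise ValueError("blob effect must be >= 0")
        if self.radius <= 0:
            raise ValueError("blob radius must be > 0")


@dataclass
class PhantomSpec:
    """Full parameterization of a synthetic two-group VBM cohort."""

    grid_shape: tuple[int, int, int] = (24, 24, 24)
    n_per_group: int = 30
    blobs: list[Blob] = field(default_factory=list)
    baseline_mean: float = 0.5
    noise_sd: float = 0.1
    smooth_fwhm: float = 2.0
    seed: int = 0
    tissue: str = "GM"
    cohort: str = "phantom"

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("need at least 2 subjects per group")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        for b in self.blobs:
            if not all(0 <= c < s for c, s in zip(b.center, self.grid_shape)):
                raise ValueError(f"blob center {b.center} outside grid {self.grid_shape}")


@dataclass
class GroundTruth:
    """Oracle for which voxels carry the group difference."""

    discriminative_mask: np.ndarray  # 3-D bool
    effect_map: np.ndarray  # per-voxel nominal effect (SD units), pre-smoothing

    @property
    def n_voxels(self) -> int:
        return int(self.discriminative_mask.sum())


def _effect_map(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """(per-voxel nominal effect, blob-membership mask); membership is
    geometric, so zero-effect blobs still appear in the ground truth."""
    grid = np.zeros(spec.grid_shape, dtype=np.float64)
    member = np.zeros(spec.grid_shape, dtype=bool)
    coords = np.indices(spec.grid_shape)
    for b in spec.blobs:
        d2 = sum((coords[a] - b.center[a]) ** 2 for a in range(3))
        inside = d2 <= b.radius**2
        member |= inside
        grid[inside] = np.maximum(grid[inside], b.effect)
    return grid, member


def _simulate_volume(
    spec: PhantomSpec, rng: np.random.Generator, effect_map: np.ndarray, patient: bool
) -> np.ndarray:
    raw = spec.baseline_mean + rng.normal(0.0, spec.noise_sd, size=spec.grid_shape)
    if patient:
        raw = raw - effect_map * spec.noise_sd
    if spec.smooth_fwhm > 0:
        raw = ndimage.gaussian_filter(raw, sigma=spec.smooth_fwhm * _FWHM_TO_SIGMA)
    return np.clip(raw, 0.0, 1.0)


def generate_phantom_cohort(
    spec: PhantomSpec, out_dir: str | Path
) -> tuple[CohortManifest, GroundTruth]:
    """Write ``2 * n_per_group`` NIfTI volumes plus a cohort manifest.

    HC subjects are baseline + smoothed noise; patients additionally lose
    ``effect * noise_sd`` density inside each blob (injected before
    smoothing).  Generation is bit-reproducible given ``spec.seed``.  Only
    ``spec.tissue`` volumes are written; the manifest's other tissue column
    is left empty.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    emap, member = _effect_map(spec)
    affine = np.diag([2.0, 2.0, 2.0, 1.0])  # 2 mm isotropic grid

    rows = []
    tissue_col = "gm_path" if spec.tissue == "GM" else "wm_path"
    other_col = "wm_path" if spec.tissue == "GM" else "gm_path"
    for label, group in ((0, "HC"), (1, "SCZ")):
        for i in range(spec.n_per_group):
            sid = f"{spec.cohort}-{group}{i:03d}"
            data = _simulate_volume(spec, rng, emap, patient=(label == 1))
            path = out_dir / f"{sid}_{spec.tissue}.nii.gz"
            save_volume(VolumeImage(data.astype(np.float32), affine), path)
            rows.append(
                {
                    "subject_id": sid,
                    tissue_col: str(path),
                    other_col: "",
                    "label": label,
                    "cohort": spec.cohort,
                }
            )
    manifest = CohortManifest(pd.DataFrame(rows))
    manifest.save(out_dir / "manifest.csv")

    gt = GroundTruth(discriminative_mask=member, effect_map=emap)
    save_volume(
        VolumeImage(gt.discriminative_mask.astype(np.float32), affine),
        out_dir / "ground_truth.nii.gz",
    )
    with open(out_dir / "phantom_spec.json", "w") as fh:
        json.dump(asdict(spec), fh, indent=2, default=list)
    return manifest, gt


def generate_phantom_study(
    spec: PhantomSpec, out_dir: str | Path
) -> tuple[CohortManifest, GroundTruth]:
    """Generate matched GM and WM volumes for every subject (one manifest).

    Both tissues share the blob layout; WM noise is an independent stream
    (seed offset by 1).
    """
    out_dir = Path(out_dir)
    gm_spec = PhantomSpec(**{**asdict(spec), "tissue": "GM", "blobs": spec.blobs})
    wm_spec = PhantomSpec(
        **{**asdict(spec), "tissue": "WM", "blobs": spec.blobs, "seed": spec.seed + 1}
    )
    gm_manifest, gt = generate_phantom_cohort(gm_spec, out_dir / "gm")
    wm_manifest, _ = generate_phantom_cohort(wm_spec, out_dir / "wm")
    frame = gm_manifest.frame.copy()
    frame["wm_path"] = wm_manifest.frame["wm_path"].to_numpy()
    merged = CohortManifest(frame)
    merged.save(out_dir / "manifest.csv")
    return merged, gt


def ground_truth_columns(
    gt: GroundTruth, mask: VoxelMask, voxel_index: np.ndarray
) -> set[int]:
    """Columns of a CohortMatrix whose voxels fall inside a discriminative blob."""
    if gt.discriminative_mask.shape != mask.grid_shape:
        raise GridMismatchError(
            f"ground truth grid {gt.discriminative_mask.shape} "
            f"!= mask grid {mask.grid_shape}"
        )
    i, j, k = voxel_index.T
    inside = gt.discriminative_mask[i, j, k]
    return set(np.flatnonzero(inside).tolist())
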