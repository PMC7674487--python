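"""Shared fixtures: tiny NIfTI volumes and a session-scoped phantom cohort.

The "study phantom" mirrors the conditions used throughout the validation
suite: 24^3 grid, one radius-3 atrophy blob at the grid center with effect
size 2.0 (in noise-SD units), 30 subjects per group, seed 7.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from ednn import (
    Blob,
    PhantomSpec,
    VolumeImage,
    build_mask,
    generate_phantom_cohort,
    stack_cohort,
)

STUDY_SPEC = dict(
    grid_shape=(24, 24, 24),
    n_per_group=30,
    blobs=[Blob(center=(12, 12, 12), radius=3.0, effect=2.0)],
    seed=7,
)


def make_volume(data: np.ndarray, spacing: float = 2.0) -> VolumeImage:
    return VolumeImage(
        data=np.asarray(data, dtype=np.float32),
        affine=np.diag([spacing, spacing, spacing, 1.0]),
    )


def mi_bruteforce(x, y) -> float:
    """Independent plug-in MI oracle: explicit double sum over the joint table."""
    x, y = list(x), list(y)
    n = len(x)
    mi = 0.0
    for a in set(x):
        for b in set(y):
            pxy = sum(1 for xi, yi in zip(x, y) if xi == a and yi == b) / n
            px = sum(1 for xi in x if xi == a) / n
            py = sum(1 for yi in y if yi == b) / n
            if pxy > 0:
                mi += pxy * math.log(pxy / (px * py))
    return mi


def auc_pairwise(scores, labels) -> float:
    """Independent AUC oracle: concordant pos/neg pairs, ties counted 1/2."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))


def bernoulli_kl(p: float, eps: float) -> float:
    """Closed-form Bernoulli KL oracle."""
    return p * math.log(p / eps) + (1 - p) * math.log((1 - p) / (1 - eps))


@pytest.fixture(scope="session")
def study_phantom(tmp_path_factory):
    """(manifest, ground_truth, out_dir) for the standard GM phantom cohort."""
    out = tmp_path_factory.mktemp("study_phantom")
    spec = PhantomSpec(**STUDY_SPEC)
    manifest, gt = generate_phantom_cohort(spec, out)
    return manifest, gt, out


@pytest.fixture(scope="session")
def study_matrix(study_phantom):
    """Full-cohort matrix for the standard phantom (mask over all subjects)."""
    manifest, gt, _ = study_phantom
    from ednn import load_volume

    vols = [load_volume(p) for p in manifest.paths("GM")]
    mask = build_mask(vols, min_mean=0.05, min_variance=0.0)
    return stack_cohort(manifest, "GM", mask), gt
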