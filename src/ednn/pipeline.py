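"""End-to-end orchestration: mask -> stack -> select -> train -> evaluate -> saliency.

``run_pipeline`` consumes a plain config dict (or YAML/JSON file) and runs
the whole diagnostic workflow per tissue, treating GM and WM as independent
models whose test-set probabilities are fused post hoc by arithmetic mean.
All randomness flows from a single top-level seed; rerunning the same
config yields byte-identical reports.

To keep held-out subjects honest, the analysis mask, the voxel MI ranking
and the reference statistics for saliency are all computed on the training
split only.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import vbm_io
from .errors import EDNNError
from .evaluate import EvalReport, evaluate_model, split_cohort
from .features import export_scores_tsv, select_features
from .model import EDNNConfig, combine_tissues, predict_proba, train_ednn
from .phantom import Blob, PhantomSpec, generate_phantom_study
from .saliency import group_stats, render_saliency

logger = logging.getLogger("ednn")

DEFAULTS: dict[str, Any] = {
    "tissues": ["GM"],
    "mask": {"min_mean": 0.05, "min_variance": 0.0},
    "features": {"k": 200, "n_bins": 4},
    "model": {},
    "split": {"train_fraction": 0.875},
    "eval": {"n_boot": 500},
    "saliency": True,
    "nan_policy": "error",
}


def load_config(path: str | Path) -> dict:
    """Read a YAML or JSON pipeline config."""
    text = Path(path).read_text()
    return yaml.safe_load(text)


def _phantom_spec_from_config(cfg: dict, seed: int) -> PhantomSpec:
    blobs = [
        Blob(center=tuple(b["center"]), radius=b["radius"], effect=b["effect"])
        for b in cfg.get("blobs", [])
    ]
    return PhantomSpec(
        grid_shape=tuple(cfg.get("grid_shape", (24, 24, 24))),
        n_per_group=cfg.get("n_per_group", 30),
        blobs=blobs,
        baseline_mean=cfg.get("baseline_mean", 0.5),
        noise_sd=cfg.get("noise_sd", 0.1),
        smooth_fwhm=cfg.get("smooth_fwhm", 2.0),
        seed=cfg.get("seed", seed),
        cohort=cfg.get("cohort", "phantom"),
    )


def run_pipeline(config: dict | str | Path, out_dir: str | Path | None = None) -> dict:
    """Execute the full workflow described by ``config``.

    Returns a summary dict with one :class:`EvalReport` per tissue plus the
    combined-tissue verdicts for the test subjects; all artifacts (mask, MI
    scores, model archives, reports, saliency maps) are written under
    ``out_dir``.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    cfg = {**DEFAULTS, **config}
    for section, defaults in DEFAULTS.items():  # section-level deep merge
        if isinstance(defaults, dict) and section in config:
            cfg[section] = {**defaults, **config[section]}
    seed = int(cfg.get("seed", 0))
    out = Path(out_dir or cfg.get("out_dir", "ednn_run"))
    out.mkdir(parents=True, exist_ok=True)

    t0 = time.perf_counter()
    if "phantom" in cfg:
        manifest, _ = generate_phantom_study(
            _phantom_spec_from_config(cfg["phantom"], seed), out / "phantom"
        )
        logger.info("phantom cohort generated: %d subjects", len(manifest))
    elif "manifest" in cfg:
        manifest = vbm_io.load_manifest(cfg["manifest"])
    else:
        raise EDNNError("config needs either a 'phantom' or a 'manifest' section")

    split = split_cohort(manifest, cfg["split"]["train_fraction"], seed)
    logger.info(
        "split: %d train / %d test (%s)", split.n_train, split.n_test, split.counts
    )
    train_manifest = manifest.subset(split.train_ids)
    test_manifest = manifest.subset(split.test_ids)

    reports: dict[str, EvalReport] = {}
    test_probs: dict[str, np.ndarray] = {}
    for tissue in cfg["tissues"]:
        stage = f"[{tissue}]"
        t_stage = time.perf_counter()

        train_vols = [
            vbm_io.load_volume(p, cfg["nan_policy"]) for p in train_manifest.paths(tissue)
        ]
        mask = vbm_io.build_mask(
            train_vols, cfg["mask"]["min_mean"], cfg["mask"]["min_variance"]
        )
        vbm_io.save_mask(mask, out / f"mask_{tissue}.nii.gz")
        logger.info("%s mask: %d voxels", stage, mask.n_voxels)

        train_mat = vbm_io.stack_cohort(train_manifest, tissue, mask, cfg["nan_policy"])
        test_mat = vbm_io.stack_cohort(test_manifest, tissue, mask, cfg["nan_policy"])

        k = min(cfg["features"]["k"], mask.n_voxels)
        scores, selected = select_features(train_mat, k, cfg["features"]["n_bins"])
        export_scores_tsv(scores, train_mat.voxel_index, out / f"mi_{tissue}.tsv")
        selected.to_json(out / f"selected_{tissue}.json")
        logger.info("%s selected %d voxels (max MI %.4f nats)", stage, k, selected.scores[0])

        mcfg = EDNNConfig(**{**cfg["model"], "seed": seed})
        model = train_ednn(
            train_mat.X[:, selected.columns],
            train_mat.y,
            mcfg,
            feature_columns=selected.columns,
        )
        model.save(out / f"model_{tissue}.npz")
        logger.info(
            "%s trained: final train accuracy %.4f (%d epochs)",
            stage,
            model.history["accuracy"][-1],
            len(model.history["accuracy"]),
        )

        report = evaluate_model(
            model, test_mat, n_boot=cfg["eval"]["n_boot"], seed=seed, cohort_tag=tissue
        )
        report.to_json(out / f"report_{tissue}.json")
        reports[tissue] = report
        test_probs[tissue] = predict_proba(model, test_mat.X[:, selected.columns])

        if cfg["saliency"]:
            stats = group_stats(train_mat)
            sal_dir = out / f"saliency_{tissue}"
            sal_dir.mkdir(exist_ok=True)
            for row, sid in enumerate(test_mat.subject_ids):
                smap = render_saliency(model, test_mat.X[row], stats, mask, sid)
                vbm_io.save_volume(smap.volume, sal_dir / f"{sid}_saliency.nii.gz")
                smap.sidecar(sal_dir / f"{sid}_saliency.json")
        logger.info("%s done in %.1fs", stage, time.perf_counter() - t_stage)

    combined = None
    if len(cfg["tissues"]) == 2 and set(cfg["tissues"]) == {"GM", "WM"}:
        combined = []
        y_test = test_manifest.labels
        for row, sid in enumerate(test_manifest.subject_ids):
            p, label = combine_tissues(
                float(test_probs["GM"][row]), float(test_probs["WM"][row])
            )
            combined.append(
                {"subject_id": sid, "probability": p, "label": label, "true": int(y_test[row])}
            )
        acc = float(np.mean([c["label"] == c["true"] for c in combined]))
        combined = {"subjects": combined, "accuracy": acc}
        (out / "combined_report.json").write_text(json.dumps(combined, indent=2))

    summary = {
        "out_dir": str(out),
        "seed": seed,
        "split": {"n_train": split.n_train, "n_test": split.n_test, "counts": split.counts},
        "reports": {t: asdict(r) for t, r in reports.items()},
        "combined": combined,
        "elapsed_s": time.perf_counter() - t0,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=float))
    return {"reports": reports, "combined": combined, "split": split, "out_dir": out}
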