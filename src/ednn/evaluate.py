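"""Evaluation protocol: stratified splits, diagnostic metrics, transfer retraining.

Six quantities summarize a binary diagnostic classifier here: accuracy,
sensitivity, specificity, PPV, NPV, and the Number Needed to Predict

    NNP = 1 / (PPV + NPV - 1),

the reciprocal of the predictive summary index — the expected number of
patients one must classify to obtain one more correct prediction than
chance.  NNP is undefined (flagged, not infinite) when PPV + NPV <= 1.

Confidence intervals are subject-level percentile bootstraps; ROC/AUC use a
threshold sweep with trapezoidal integration.  ``transfer_retrain``
implements the two-cohort protocol: evaluate the frozen model on the whole
unseen cohort, then warm-start retraining on the new cohort's training
split and re-evaluate on its test split.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from sklearn.metrics import roc_curve

from .errors import DegenerateClassError
from .model import EDNNConfig, TrainedEDNN, predict_label, predict_proba, train_ednn
from .vbm_io import CohortManifest, CohortMatrix


@dataclass
class SplitPlan:
    """A stratified train/test partition of a cohort (by subject id)."""

    train_ids: list[str]
    test_ids: list[str]
    train_fraction: float
    seed: int
    counts: dict[str, dict[int, int]] = field(default_factory=dict)

    @property
    def n_train(self) -> int:
        return len(self.train_ids)

    @property
    def n_test(self) -> int:
        return len(self.test_ids)


def split_cohort(
    manifest: CohortManifest, train_fraction: float, seed: int
) -> SplitPlan:
    """Stratified random split, deterministic given the seed.

    The training set size is ``round(train_fraction * n)``, allocated
    across classes by largest remainder so class proportions stay within
    one subject of the stratified target (400 subjects at 0.875 -> 350/50;
    132 at 92/132 -> 92/40).
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie in (0, 1)")
    y = manifest.labels
    ids = np.asarray(manifest.subject_ids)
    classes = np.unique(y)
    if classes.size < 2:
        raise DegenerateClassError("both classes must be present to stratify")

    n_train_total = int(round(train_fraction * len(y)))
    per_class_exact = {c: train_fraction * int((y == c).sum()) for c in classes}
    n_train = {c: int(np.floor(per_class_exact[c])) for c in classes}
    leftover = n_train_total - sum(n_train.values())
    by_remainder = sorted(
        classes, key=lambda c: (-(per_class_exact[c] - n_train[c]), c)
    )
    for c in by_remainder[: max(leftover, 0)]:
        n_train[c] += 1
    for c in classes:
        n_c = int((y == c).sum())
        if not 1 <= n_train[c] <= n_c - 1:
            raise DegenerateClassError(
                f"class {c} too small to stratify at fraction {train_fraction}"
            )

    rng = np.random.default_rng(seed)
    train_ids: list[str] = []
    test_ids: list[str] = []
    for c in classes:
        members = ids[y == c]
        perm = rng.permutation(len(members))
        train_ids += members[perm[: n_train[c]]].tolist()
        test_ids += members[perm[n_train[c] :]].tolist()
    counts = {
        "train": {int(c): int(n_train[c]) for c in classes},
        "test": {int(c): int((y == c).sum() - n_train[c]) for c in classes},
    }
    return SplitPlan(
        train_ids=train_ids,
        test_ids=test_ids,
        train_fraction=train_fraction,
        seed=seed,
        counts=counts,
    )


def nnp(ppv: float, npv: float) -> float | None:
    """Number Needed to Predict, 1/(PPV + NPV - 1); None when PSI <= 0."""
    psi = ppv + npv - 1.0
    if psi <= 0.0:
        return None
    return 1.0 / psi


@dataclass
class EvalReport:
    """Confusion counts, the six diagnostic quantities, CIs, ROC and AUC."""

    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    nnp: float | None
    auc: float | None = None
    roc_points: list[tuple[float, float]] | None = None  # (FPR, TPR)
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    cohort: str = ""
    tissue: str = ""
    config: dict = field(default_factory=dict)

    @property
    def n_test(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=float))


def confusion_metrics(tp: int, fp: int, tn: int, fn: int) -> EvalReport:
    """The six diagnostic quantities from raw confusion counts.

    Any quantity with a zero denominator (or NNP with PPV+NPV <= 1) comes
    back as None rather than raising.
    """
    if min(tp, fp, tn, fn) < 0:
        raise ValueError("confusion counts must be >= 0")
    n = tp + fp + tn + fn
    if n == 0:
        raise ValueError("all-zero confusion table")

    def ratio(num: int, den: int) -> float | None:
        return num / den if den > 0 else None

    sens = ratio(tp, tp + fn)
    spec = ratio(tn, tn + fp)
    ppv = ratio(tp, tp + fp)
    npv = ratio(tn, tn + fn)
    return EvalReport(
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        accuracy=(tp + tn) / n,
        sensitivity=sens,
        specificity=spec,
        ppv=ppv,
        npv=npv,
        nnp=nnp(ppv, npv) if ppv is not None and npv is not None else None,
    )


def roc_auc(
    scores: np.ndarray, labels: np.ndarray
) -> tuple[list[tuple[float, float]], float]:
    """ROC points (FPR, TPR) from a threshold sweep and the trapezoidal AUC.

    Tied scores enter the curve simultaneously, which makes the trapezoidal
    area equal to the pairwise-concordance (Mann-Whitney) estimator with
    ties counted 1/2.
    """
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise DegenerateClassError("ROC needs both classes present")
    fpr, tpr, _ = roc_curve(labels, np.asarray(scores, dtype=np.float64))
    auc = float(np.trapezoid(tpr, fpr))
    return list(zip(fpr.tolist(), tpr.tolist())), auc


def bootstrap_ci(
    metric: Callable[[np.ndarray, np.ndarray], float],
    y_true: np.ndarray,
    y_score: np.ndarray,
    n_boot: int = 2000,
    seed: int = 0,
    alpha: float = 0.05,
    require_both_classes: bool = False,
    max_redraws: int = 1000,
) -> tuple[float, float]:
    """Subject-level percentile bootstrap CI for any metric(y_true, y_score).

    A resample that degenerates to a single class is redrawn (and counted)
    when the metric needs both classes.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    y_true = np.asarray(y_true)
    y_score = np.asarray(y_score)
    n = len(y_true)
    rng = np.random.default_rng(seed)
    stats = np.empty(n_boot)
    redraws = 0
    for b in range(n_boot):
        while True:
            idx = rng.integers(0, n, size=n)
            if not require_both_classes or np.unique(y_true[idx]).size == 2:
                break
            redraws += 1
            if redraws > max_redraws:
                raise DegenerateClassError("bootstrap cannot find two-class resamples")
        stats[b] = metric(y_true[idx], y_score[idx])
    lo, hi = np.percentile(stats, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def _accuracy(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    return float((y_true == y_pred).mean())


def evaluate_model(
    model: TrainedEDNN,
    cohort: CohortMatrix,
    n_boot: int = 2000,
    seed: int = 0,
    with_roc: bool = True,
    cohort_tag: str = "",
) -> EvalReport:
    """Full report (counts, six metrics, bootstrap CIs, ROC/AUC) on a cohort.

    The cohort matrix is restricted to the model's selected columns here.
    """
    X = cohort.X[:, model.feature_columns]
    y = cohort.y
    prob = predict_proba(model, X)
    pred = (prob >= 0.5).astype(np.int64)
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    report = confusion_metrics(tp, fp, tn, fn)
    report.cohort = cohort_tag
    report.tissue = cohort.tissue
    report.config = asdict(model.config)

    if with_roc and np.unique(y).size == 2:
        report.roc_points, report.auc = roc_auc(prob, y)

    ss = np.random.SeedSequence(seed)
    metric_defs: list[tuple[str, Callable[[np.ndarray, np.ndarray], float], bool]] = [
        ("accuracy", _accuracy, False),
        (
            "sensitivity",
            lambda yt, yp: float((yp[yt == 1] == 1).mean()) if (yt == 1).any() else np.nan,
            True,
        ),
        (
            "specificity",
            lambda yt, yp: float((yp[yt == 0] == 0).mean()) if (yt == 0).any() else np.nan,
            True,
        ),
    ]
    for (name, fn_m, both), child in zip(metric_defs, ss.spawn(len(metric_defs))):
        report.ci[name] = bootstrap_ci(
            fn_m,
            y,
            pred,
            n_boot=n_boot,
            seed=int(child.generate_state(1)[0] % (2**31)),
            require_both_classes=both,
        )
    return report


def transfer_retrain(
    model: TrainedEDNN,
    new_cohort: CohortMatrix,
    split: SplitPlan,
    config: EDNNConfig | None = None,
    n_boot: int = 2000,
    seed: int = 0,
    cohort_tag: str = "",
) -> tuple[EvalReport, TrainedEDNN, EvalReport]:
    """Two-cohort transfer protocol.

    1. The frozen model is evaluated on the *entire* new cohort (the
       "unseen" report).
    2. The model is warm-started from the frozen weights and retrained on
       the new cohort's training split (same selected voxels), then
       evaluated on the new test split.

    Returns (unseen_report, retrained_model, retrained_report).
    """
    config = config or model.config
    unseen = evaluate_model(
        model, new_cohort, n_boot=n_boot, seed=seed,
        cohort_tag=f"{cohort_tag}-unseen" if cohort_tag else "unseen",
    )

    id_to_row = {s: r for r, s in enumerate(new_cohort.subject_ids)}
    train_rows = [id_to_row[s] for s in split.train_ids]
    test_rows = [id_to_row[s] for s in split.test_ids]
    train = new_cohort.subset_subjects(train_rows)
    test = new_cohort.subset_subjects(test_rows)

    retrained = train_ednn(
        train.X[:, model.feature_columns],
        train.y,
        config,
        feature_columns=model.feature_columns,
        warm_start=model,
    )
    retrained_report = evaluate_model(
        retrained, test, n_boot=n_boot, seed=seed + 1, cohort_tag=cohort_tag
    )
    return unseen, retrained, retrained_report
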