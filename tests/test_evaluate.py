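"""Splits, diagnostic metrics, ROC/AUC, bootstrap CIs and transfer retraining."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ednn import (
    EDNNConfig,
    bootstrap_ci,
    confusion_metrics,
    evaluate_model,
    nnp,
    roc_auc,
    split_cohort,
    train_ednn,
    transfer_retrain,
)
from ednn.errors import DegenerateClassError
from ednn.vbm_io import CohortManifest, CohortMatrix, VoxelMask

from conftest import auc_pairwise

import pandas as pd


def _manifest(n_hc, n_scz, cohort="c"):
    rows = [
        {"subject_id": f"{cohort}{i}", "gm_path": "", "wm_path": "",
         "label": 0 if i < n_hc else 1, "cohort": cohort}
        for i in range(n_hc + n_scz)
    ]
    return CohortManifest(pd.DataFrame(rows))


class TestSplitCohort:
    def test_balanced_400_at_87_5_percent(self):
        plan = split_cohort(_manifest(200, 200), 0.875, seed=0)
        assert plan.n_train == 350 and plan.n_test == 50
        assert plan.counts["train"] == {0: 175, 1: 175}

    def test_132_subjects_92_40(self):
        plan = split_cohort(_manifest(44, 88), 92 / 132, seed=0)
        assert plan.n_train == 92 and plan.n_test == 40
        # largest-remainder allocation keeps both classes within one subject
        assert plan.counts["train"] in ({0: 31, 1: 61}, {0: 30, 1: 62})

    def test_deterministic_given_seed(self):
        a = split_cohort(_manifest(30, 30), 0.8, seed=42)
        b = split_cohort(_manifest(30, 30), 0.8, seed=42)
        assert a.train_ids == b.train_ids and a.test_ids == b.test_ids
        c = split_cohort(_manifest(30, 30), 0.8, seed=43)
        assert a.train_ids != c.train_ids

    def test_partition_is_disjoint_and_complete(self):
        m = _manifest(25, 17)
        plan = split_cohort(m, 0.7, seed=1)
        assert set(plan.train_ids) | set(plan.test_ids) == set(m.subject_ids)
        assert set(plan.train_ids) & set(plan.test_ids) == set()

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        n_hc=st.integers(5, 120),
        n_scz=st.integers(5, 120),
        frac=st.floats(0.2, 0.9),
    )
    def test_stratification_within_one_subject(self, n_hc, n_scz, frac):
        plan = split_cohort(_manifest(n_hc, n_scz), frac, seed=0)
        for c, n_c in ((0, n_hc), (1, n_scz)):
            assert abs(plan.counts["train"][c] - frac * n_c) < 1.0

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateClassError):
            split_cohort(_manifest(10, 0), 0.8, seed=0)


class TestConfusionMetrics:
    def test_hand_computed_table(self):
        r = confusion_metrics(tp=3, fp=1, tn=2, fn=2)
        assert r.sensitivity == pytest.approx(0.6)
        assert r.specificity == pytest.approx(2 / 3)
        assert r.ppv == pytest.approx(0.75)
        assert r.npv == pytest.approx(0.5)
        assert r.accuracy == pytest.approx(0.625)
        assert r.nnp == pytest.approx(4.0)

    def test_perfect_classifier(self):
        r = confusion_metrics(tp=10, fp=0, tn=10, fn=0)
        assert (r.accuracy, r.sensitivity, r.specificity, r.ppv, r.npv) == (1, 1, 1, 1, 1)
        assert r.nnp == pytest.approx(1.0)

    def test_undefined_metrics_flagged_as_none(self):
        r = confusion_metrics(tp=0, fp=0, tn=5, fn=5)
        assert r.ppv is None and r.nnp is None
        assert nnp(0.5, 0.5) is None  # PSI = 0

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics(0, 0, 0, 0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(tp=st.integers(0, 30), fp=st.integers(0, 30),
           tn=st.integers(0, 30), fn=st.integers(0, 30))
    def test_identities_on_random_tables(self, tp, fp, tn, fn):
        n = tp + fp + tn + fn
        if n == 0:
            return
        r = confusion_metrics(tp, fp, tn, fn)
        assert r.accuracy == pytest.approx((tp + tn) / n)
        if r.sensitivity is not None:
            assert r.sensitivity == pytest.approx(tp / (tp + fn))
        if r.ppv is not None and r.npv is not None and r.ppv + r.npv > 1:
            assert r.nnp >= 1.0 - 1e-12


class TestRocAuc:
    def test_perfect_separation(self):
        _, auc = roc_auc(np.array([0.1, 0.2, 0.8, 0.9]), np.array([0, 0, 1, 1]))
        assert auc == pytest.approx(1.0)

    def test_worked_example(self):
        _, auc = roc_auc(np.array([0.1, 0.4, 0.35, 0.8]), np.array([0, 0, 1, 1]))
        assert auc == pytest.approx(0.75)

    def test_null_scores_near_half(self):
        rng = np.random.default_rng(0)
        scores = rng.uniform(size=2000)
        labels = rng.integers(0, 2, 2000)
        _, auc = roc_auc(scores, labels)
        assert auc == pytest.approx(0.5, abs=0.05)

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateClassError):
            roc_auc(np.array([0.1, 0.9]), np.array([1, 1]))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.randoms(use_true_random=False))
    def test_matches_pairwise_concordance_oracle(self, rnd):
        rng = np.random.default_rng(rnd.randrange(2**31))
        n = rng.integers(4, 30)
        labels = rng.integers(0, 2, n)
        if np.unique(labels).size < 2:
            labels[0], labels[1] = 0, 1
        # quantized scores force ties through both code paths
        scores = np.round(rng.uniform(size=n), 1)
        _, auc = roc_auc(scores, labels)
        assert auc == pytest.approx(auc_pairwise(scores, labels), abs=1e-12)


class TestBootstrapCI:
    @staticmethod
    def _acc(yt, yp):
        return float((yt == yp).mean())

    def test_constant_metric_degenerates_to_point(self):
        y = np.array([0, 1] * 10)
        lo, hi = bootstrap_ci(self._acc, y, y.copy(), n_boot=200, seed=0)
        assert (lo, hi) == (1.0, 1.0)

    def test_brackets_point_estimate(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 60)
        pred = np.where(rng.uniform(size=60) < 0.85, y, 1 - y)
        lo, hi = bootstrap_ci(self._acc, y, pred, n_boot=500, seed=2)
        assert lo <= self._acc(y, pred) <= hi

    def test_n_boot_floor(self):
        with pytest.raises(ValueError):
            bootstrap_ci(self._acc, np.array([0, 1]), np.array([0, 1]), n_boot=10)


def _matrix_from_arrays(X, y):
    n_vox = X.shape[1]
    side = int(np.ceil(n_vox ** (1 / 3)))
    grid = np.zeros((side, side, side), bool)
    grid.ravel()[:n_vox] = True
    mask = VoxelMask(grid, np.eye(4))
    return CohortMatrix(X, y, mask.voxel_index(), "GM", mask,
                        [f"s{i}" for i in range(len(y))])


def _cohort(n_per_group, k=12, gap=2.0, seed=0, shift=0.0):
    rng = np.random.default_rng(seed)
    y = np.repeat([0, 1], n_per_group)
    X = rng.normal(0.5 + shift, 0.1, size=(2 * n_per_group, k))
    X[y == 1, : k // 2] -= gap * 0.1
    return _matrix_from_arrays(X, y)


class TestTransferRetrain:
    def _model(self, cohort):
        cfg = EDNNConfig(n_hidden=8, max_epochs=100, batch_size=8, seed=0)
        return train_ednn(cohort.X, cohort.y, cfg)

    def test_zero_epoch_retrain_reduces_to_frozen_model(self):
        src = _cohort(20, seed=0)
        model = self._model(src)
        new = _cohort(15, seed=1)
        split = split_cohort(_manifest(15, 15, cohort="s"), 0.7, seed=0)
        # align split ids with the matrix subject ids, stratified by hand
        test_rows = list(range(10, 15)) + list(range(25, 30))
        split.train_ids = [f"s{i}" for i in range(30) if i not in set(test_rows)]
        split.test_ids = [f"s{i}" for i in test_rows]
        cfg = EDNNConfig(n_hidden=8, max_epochs=0, batch_size=8, seed=0)
        unseen, retrained, report = transfer_retrain(
            model, new, split, config=cfg, n_boot=100
        )
        np.testing.assert_array_equal(retrained.W1, model.W1)
        test = new.subset_subjects(test_rows)
        frozen_report = evaluate_model(model, test, n_boot=100)
        assert report.accuracy == frozen_report.accuracy
        assert (report.tp, report.fp, report.tn, report.fn) == (
            frozen_report.tp, frozen_report.fp, frozen_report.tn, frozen_report.fn
        )

    def test_no_drift_keeps_accuracy_close(self):
        gaps = []
        for seed in range(3):
            src = _cohort(25, seed=seed)
            model = self._model(src)
            new = _cohort(20, seed=100 + seed)  # same distribution
            split = split_cohort(_manifest(20, 20, cohort="s"), 0.7, seed=seed)
            unseen, _, retrained_rep = transfer_retrain(
                model, new, split, n_boot=100, seed=seed
            )
            gaps.append(abs(unseen.accuracy - retrained_rep.accuracy))
        assert np.mean(gaps) < 0.10

    def test_retraining_recovers_from_covariate_shift(self):
        deltas = []
        for seed in range(3):
            src = _cohort(25, seed=seed)
            model = self._model(src)
            new = _cohort(20, seed=200 + seed, shift=0.8)  # shifted baseline
            split = split_cohort(_manifest(20, 20, cohort="s"), 0.7, seed=seed)
            unseen, _, retrained_rep = transfer_retrain(
                model, new, split, n_boot=100, seed=seed
            )
            deltas.append(retrained_rep.accuracy - unseen.accuracy)
        assert np.mean(deltas) >= 0.0
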