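import json
import math

import numpy as np
import pytest

from ptmsvm.evaluation import (
    ConfusionCounts,
    confusion_metrics,
    evaluate_fold,
    fit_predictor,
    load_predictor,
    rank_candidates,
    roc_auc,
    run_cv,
    save_predictor,
    score_candidates,
    threshold_at_specificity,
    top_fraction,
)
from ptmsvm.kernels import (
    InteractionProfileMatrix,
    KernelConfig,
    mask_profiles,
    seq_similarity_matrix,
)
from ptmsvm.model import LabeledDataset, ModelParams
from ptmsvm.windows import blosum62


def concordance_auc(scores, labels):
    """O(n^2) Mann-Whitney oracle with ties counted 1/2."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == -1]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestConfusionMetrics:
    def test_perfect_classifier(self):
        report = confusion_metrics(ConfusionCounts(5, 5, 0, 0))
        assert (report.sn, report.sp, report.pre, report.acc, report.mcc) == (
            1.0, 1.0, 1.0, 1.0, 1.0,
        )
        assert not report.undefined

    def test_chance_level_symmetry(self):
        report = confusion_metrics(ConfusionCounts(25, 25, 25, 25))
        assert (report.sn, report.sp, report.pre, report.acc) == (0.5,) * 4
        assert report.mcc == pytest.approx(0.0)

    def test_worked_confusion_table(self):
        report = confusion_metrics(ConfusionCounts(tp=8, tn=7, fp=3, fn=2))
        assert report.sn == pytest.approx(0.8)
        assert report.sp == pytest.approx(0.7)
        assert report.pre == pytest.approx(8 / 11)
        assert report.acc == pytest.approx(0.75)
        assert report.mcc == pytest.approx((8 * 7 - 3 * 2) / math.sqrt(10 * 11 * 9 * 10))

    def test_zero_denominators_flagged_not_coerced(self):
        report = confusion_metrics(ConfusionCounts(tp=0, tn=4, fp=0, fn=0))
        assert report.sn is None and report.pre is None and report.mcc is None
        assert {"sn", "pre", "mcc"} <= report.undefined
        assert report.sp == 1.0 and report.acc == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(-1, 0, 0, 0)


class TestRocAuc:
    def test_perfect_separation(self):
        scores = np.array([0.9, 0.8, 0.2, 0.1])
        labels = np.array([1, 1, -1, -1])
        points, auc = roc_auc(scores, labels)
        assert auc == 1.0
        assert points[0] == (0.0, 0.0) and points[-1] == (1.0, 1.0)

    def test_random_labels_near_half(self):
        rng = np.random.default_rng(30)
        scores = rng.random(4000)
        labels = np.where(rng.random(4000) < 0.5, 1, -1)
        _, auc = roc_auc(scores, labels)
        assert auc == pytest.approx(0.5, abs=0.05)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_concordance_oracle_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.integers(0, 12, 200).astype(float)  # heavy ties
        labels = np.where(rng.random(200) < 0.4, 1, -1)
        points, auc = roc_auc(scores, labels)
        assert auc == pytest.approx(concordance_auc(scores, labels), abs=1e-12)
        fpr = [p[0] for p in points]
        tpr = [p[1] for p in points]
        assert fpr == sorted(fpr) and tpr == sorted(tpr)
        # ties grouped: one vertex per distinct score plus the origin
        assert len(points) == len(np.unique(scores)) + 1

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc(np.array([0.1, 0.2]), np.array([1, 1]))


class TestThresholdAtSpecificity:
    def test_separable_case(self):
        scores = np.array([0.1, 0.2, 0.8, 0.9])
        labels = np.array([-1, -1, 1, 1])
        result = threshold_at_specificity(scores, labels, 0.95)
        assert result.threshold == pytest.approx(0.8)
        assert result.reachable and result.specificity == 1.0

    def test_zero_target_returns_minimum_score(self):
        scores = np.array([0.5, 0.3, 0.9])
        labels = np.array([1, -1, -1])
        result = threshold_at_specificity(scores, labels, 0.0)
        assert result.threshold == 0.3

    @pytest.mark.parametrize("sp_target", [0.95, 0.99])
    def test_exhaustive_scan_oracle(self, sp_target):
        rng = np.random.default_rng(31)
        scores = np.round(rng.normal(size=1000), 2)  # rounding forces ties
        labels = np.where(rng.random(1000) < 0.3, 1, -1)
        neg = scores[labels == -1]
        result = threshold_at_specificity(scores, labels, sp_target)
        t = result.threshold
        assert (neg < t).mean() >= sp_target
        lower = np.unique(scores)[np.unique(scores) < t]
        if lower.size:
            assert (neg < lower[-1]).mean() < sp_target

    def test_unreachable_target_flagged(self):
        scores = np.array([0.7, 0.7, 0.7])
        labels = np.array([1, -1, -1])
        result = threshold_at_specificity(scores, labels, 0.95)
        assert math.isinf(result.threshold) and not result.reachable

    def test_no_negatives_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            threshold_at_specificity(np.array([0.1]), np.array([1]), 0.5)


class TestTopFraction:
    def test_perfect_ranking_recovers_all_positives(self):
        scores = np.array([0.9, 0.8, 0.7, 0.2, 0.1])
        labels = np.array([1, 1, 1, -1, -1])
        assert top_fraction(scores, labels, 60.0) == 1.0

    def test_partial_retrieval(self):
        # 10 samples, 4 positive; top 20% = 2 samples, 1 of them positive
        scores = np.arange(10, 0, -1).astype(float)
        labels = np.array([1, -1, 1, 1, 1, -1, -1, -1, -1, -1])
        assert top_fraction(scores, labels, 20.0) == pytest.approx(0.25)

    def test_whole_list_is_unity(self):
        rng = np.random.default_rng(32)
        scores = rng.random(50)
        labels = np.where(rng.random(50) < 0.5, 1, -1)
        labels[0] = 1
        assert top_fraction(scores, labels, 100.0) == 1.0

    def test_no_positives_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            top_fraction(np.array([0.1]), np.array([-1]), 50.0)


class TestRunCV:
    def test_every_sample_scored_once_per_repeat(self, strong_dataset):
        ds = strong_dataset
        result = run_cv(
            ds.windows, ds.profiles, ds.data, KernelConfig(), ModelParams(),
            folds=5, repeats=2, seed=7,
        )
        for r in range(2):
            assert set(result.fold_assignments[r]) == set(range(5))
            counts = np.bincount(result.fold_assignments[r], minlength=5)
            assert counts.sum() == ds.data.n

    def test_same_seed_bit_identical(self, strong_dataset):
        ds = strong_dataset
        kwargs = dict(folds=5, repeats=2, seed=3)
        r1 = run_cv(ds.windows, ds.profiles, ds.data, KernelConfig(), ModelParams(), **kwargs)
        r2 = run_cv(ds.windows, ds.profiles, ds.data, KernelConfig(), ModelParams(), **kwargs)
        np.testing.assert_array_equal(r1.scores, r2.scores)
        np.testing.assert_array_equal(r1.fold_assignments, r2.fold_assignments)
        assert r1.to_json() == r2.to_json()

    def test_averaged_metrics_within_repeat_range(self, strong_dataset):
        ds = strong_dataset
        result = run_cv(
            ds.windows, ds.profiles, ds.data, KernelConfig(), ModelParams(),
            folds=5, repeats=3, seed=5,
        )
        for name in ("sn", "sp", "auc", "mcc"):
            vals = [getattr(r, name) for r in result.per_repeat]
            avg = getattr(result.averaged, name)
            assert min(vals) - 1e-12 <= avg <= max(vals) + 1e-12

    def test_specificity_sensitivity_tradeoff_monotone(self, strong_dataset):
        ds = strong_dataset
        result = run_cv(
            ds.windows, ds.profiles, ds.data, KernelConfig(), ModelParams(),
            folds=5, repeats=1, seed=9,
        )
        scores, labels = result.scores[0], result.labels
        sn = {}
        for target in (0.95, 0.99):
            t = threshold_at_specificity(scores, labels, target).threshold
            sn[target] = (scores[labels == 1] >= t).mean()
        assert sn[0.99] <= sn[0.95]

    def test_too_few_samples_rejected(self, strong_dataset):
        ds = strong_dataset
        tiny = LabeledDataset(
            ds.data.site_ids[:4], ds.data.labels[:4], ds.data.target_ptm
        )
        with pytest.raises(ValueError, match="folds"):
            run_cv(
                ds.windows[:4], ds.profiles, tiny, KernelConfig(), ModelParams(),
                folds=10, repeats=1, seed=0,
            )

    def test_per_fold_metrics_available(self, strong_dataset):
        ds = strong_dataset
        result = run_cv(
            ds.windows, ds.profiles, ds.data, KernelConfig(), ModelParams(),
            folds=4, repeats=1, seed=2, per_fold_metrics=True,
        )
        assert len(result.per_fold) == 1 and len(result.per_fold[0]) == 4

    def test_exports_write_expected_files(self, strong_dataset, tmp_path):
        ds = strong_dataset
        result = run_cv(
            ds.windows, ds.profiles, ds.data, KernelConfig(), ModelParams(),
            folds=4, repeats=1, seed=2,
        )
        result.to_json(tmp_path / "metrics.json")
        result.scores_tsv(tmp_path / "scores.tsv")
        result.roc_tsv(tmp_path / "roc.tsv")
        doc = json.loads((tmp_path / "metrics.json").read_text())
        assert "averaged" in doc and doc["config"]["folds"] == 4
        lines = (tmp_path / "scores.tsv").read_text().splitlines()
        assert len(lines) == 1 + ds.data.n


class TestLeakageGuard:
    def test_test_fold_target_labels_cannot_influence_fold(self, strong_dataset):
        """Randomizing held-out target annotations/labels changes nothing."""
        ds = strong_dataset
        n = ds.data.n
        rng = np.random.default_rng(40)
        test_idx = np.sort(rng.choice(n, size=n // 5, replace=False))
        train_idx = np.setdiff1d(np.arange(n), test_idx)

        target_col = ds.profiles.ptm_names.index(ds.data.target_ptm)
        A_perturbed = ds.profiles.A.copy()
        A_perturbed[test_idx, target_col] = rng.integers(0, 2, size=len(test_idx))
        profiles_perturbed = InteractionProfileMatrix(
            list(ds.profiles.site_ids), list(ds.profiles.ptm_names), A_perturbed
        )
        labels_perturbed = ds.data.labels.copy()
        labels_perturbed[test_idx] = rng.choice([-1, 1], size=len(test_idx))
        data_perturbed = LabeledDataset(
            list(ds.data.site_ids), labels_perturbed, ds.data.target_ptm
        )

        S_seq = seq_similarity_matrix(ds.windows, blosum62())
        config, params = KernelConfig(), ModelParams()
        fold_a = evaluate_fold(S_seq, ds.profiles, ds.data, train_idx, test_idx, config, params)
        fold_b = evaluate_fold(
            S_seq, profiles_perturbed, data_perturbed, train_idx, test_idx, config, params
        )
        np.testing.assert_array_equal(fold_a.K_train.values, fold_b.K_train.values)
        np.testing.assert_array_equal(fold_a.K_cross, fold_b.K_cross)
        np.testing.assert_array_equal(fold_a.scores, fold_b.scores)

    def test_masking_is_applied_to_test_rows(self, strong_dataset):
        ds = strong_dataset
        test_ids = ds.data.site_ids[:5]
        masked = mask_profiles(ds.profiles, test_ids, ds.data.target_ptm)
        col = ds.profiles.ptm_names.index(ds.data.target_ptm)
        assert (masked.A[:5, col] == 0).all()


class TestRanking:
    @pytest.fixture
    def predictor(self, strong_dataset):
        ds = strong_dataset
        return fit_predictor(
            ds.windows, ds.profiles, ds.data, KernelConfig(),
            ModelParams(probability=True, seed=1),
        )

    def _clone_candidates(self, ds, indices):
        windows = []
        rows = []
        for rank, i in enumerate(indices):
            w = ds.windows[i]
            windows.append(type(w)(f"cand{rank}:11", w.residues))
            rows.append(ds.profiles.A[i])
        profiles = InteractionProfileMatrix(
            [w.site_id for w in windows], list(ds.profiles.ptm_names), np.array(rows)
        )
        return windows, profiles

    def test_positive_lookalike_outranks_negative_lookalike(self, strong_dataset, predictor):
        ds = strong_dataset
        pos_idx = int(np.argmax(ds.data.labels == 1))
        neg_idx = int(np.argmax(ds.data.labels == -1))
        windows, profiles = self._clone_candidates(ds, [pos_idx, neg_idx])
        ranked = rank_candidates(predictor, windows, profiles)
        assert ranked[0][0] == "cand0:11"

    def test_output_sorted_descending_with_id_tiebreak(self, strong_dataset, predictor):
        ds = strong_dataset
        windows, profiles = self._clone_candidates(ds, range(10))
        ranked = rank_candidates(predictor, windows, profiles)
        probs = [p for _, p in ranked]
        assert probs == sorted(probs, reverse=True)
        assert all(0 < p < 1 for p in probs)

    def test_empty_candidate_set(self, predictor, strong_dataset):
        ds = strong_dataset
        empty = InteractionProfileMatrix([], list(ds.profiles.ptm_names),
                                         np.zeros((0, len(ds.profiles.ptm_names))))
        assert rank_candidates(predictor, [], empty) == []

    def test_predictor_round_trip_preserves_scores(self, strong_dataset, predictor, tmp_path):
        ds = strong_dataset
        windows, profiles = self._clone_candidates(ds, range(6))
        path = tmp_path / "predictor.json"
        save_predictor(predictor, path)
        back = load_predictor(path)
        np.testing.assert_array_equal(
            score_candidates(predictor, windows, profiles),
            score_candidates(back, windows, profiles),
        )
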