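"""Classification metrics and cross-validation contracts: rank AUROC vs
pair counting, DeLong behaviour, controls, star codes, bootstrap test."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from metabosig import classify, simcohort, splits, preprocess


def brute_force_auroc(scores, labels):
    """All-pairs counting oracle: P(score_case > score_control) + 0.5 ties."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    pos, neg = s[y == 1], s[y == 0]
    wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


class TestAuroc:
    @pytest.mark.parametrize("scores,labels,expected", [
        ([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0], 1.0),
        ([0.9, 0.8, 0.2, 0.1], [0, 0, 1, 1], 0.0),
        ([0.5, 0.5, 0.5, 0.5], [1, 0, 1, 0], 0.5),
    ])
    def test_known_values(self, scores, labels, expected):
        assert classify.auroc(scores, labels) == expected

    def test_matches_pair_counting_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(4, 60))
            y = rng.integers(0, 2, n)
            if y.sum() in (0, n):
                continue
            s = np.round(rng.random(n), 2)  # coarse grid forces ties
            assert classify.auroc(s, y) == pytest.approx(brute_force_auroc(s, y), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            classify.auroc([0.1, 0.2], [1, 1])


def test_auprc_perfect_and_single_class():
    assert classify.auprc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0
    with pytest.raises(ValueError):
        classify.auprc([0.1, 0.2], [0, 0])


class TestStarCode:
    @pytest.mark.parametrize("p,code", [
        (0.03, "*"), (0.05, "*"), (0.005, "***"), (0.01, "***"),
        (0.001, "****"), (1e-9, "****"), (0.5, ""), (0.051, ""),
    ])
    def test_bands(self, p, code):
        assert classify.star_code(p) == code

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            classify.star_code(1.5)


class TestDeLong:
    def test_identical_scores_degenerate(self):
        rng = np.random.default_rng(1)
        s = rng.random(40)
        y = rng.integers(0, 2, 40)
        y[:2] = [0, 1]
        res = classify.delong_compare(s, s, y)
        assert res.degenerate and res.statistic == 0.0 and res.p_value == 1.0

    def test_antisymmetric(self):
        rng = np.random.default_rng(2)
        y = np.array([1] * 20 + [0] * 20)
        a = rng.random(40) + 0.3 * y
        b = rng.random(40)
        ab = classify.delong_compare(a, b, y)
        ba = classify.delong_compare(b, a, y)
        assert ab.statistic == pytest.approx(-ba.statistic)
        assert ab.p_value == pytest.approx(1 - stats.norm.cdf(ab.statistic))

    def test_separating_vs_random_agrees_with_permutation_oracle(self):
        rng = np.random.default_rng(3)
        y = np.array([1] * 50 + [0] * 50)
        a = y + 0.01 * rng.random(100)  # perfectly separating
        b = rng.random(100)
        res = classify.delong_compare(a, b, y)
        assert res.p_value < 0.01
        # permutation oracle: swap a/b per sample, difference of AUCs
        obs = classify.auroc(a, y) - classify.auroc(b, y)
        diffs = []
        for _ in range(500):
            swap = rng.random(100) < 0.5
            aa = np.where(swap, b, a)
            bb = np.where(swap, a, b)
            diffs.append(classify.auroc(aa, y) - classify.auroc(bb, y))
        p_perm = np.mean(np.asarray(diffs) >= obs - 1e-12)
        assert p_perm < 0.01

    def test_mismatched_lengths(self):
        with pytest.raises(ValueError):
            classify.delong_compare([0.1], [0.1, 0.2], [1, 0])

    def test_null_pvalues_roughly_uniform(self):
        rng = np.random.default_rng(4)
        y = np.array([1] * 30 + [0] * 30)
        ps = []
        for _ in range(300):
            ps.append(classify.delong_compare(rng.random(60), rng.random(60), y).p_value)
        assert stats.kstest(ps, "uniform").pvalue > 0.01


@pytest.fixture(scope="module")
def fitted(small_rf_data):
    matrix, labels, folds, subjects = small_rf_data
    model = classify.RandomForestCV(matrix, labels, folds, n_trees=100, seed=5)
    return model, model.fit()


@pytest.fixture(scope="module")
def small_rf_data():
    spec = simcohort.CohortSpec(n_subjects=120, n_features=200, n_planted=40,
                                planted_log2fc=2.0, case_prevalence=0.4,
                                missing_rate_base=0.05, seed=31)
    meta = simcohort.generate_cohort(spec)
    table, _ = simcohort.generate_peak_table(meta, spec)
    norm, _ = preprocess.run_default_pipeline(table, meta)
    folds = splits.grouped_stratified_kfold(meta, "class_label", 5, seed=1)
    per = meta.drop_duplicates("sample_id").set_index("sample_id")
    return norm.data, per["class_label"], folds, per["subject_id"]


class TestRandomForestCV:
    def test_mtry_floor_sqrt(self, small_rf_data):
        matrix, labels, folds, _ = small_rf_data
        m = classify.RandomForestCV(matrix.iloc[:, :100], labels, folds)
        assert m.mtry == 10
        m2 = classify.RandomForestCV(matrix.iloc[:, :120], labels, folds)
        assert m2.mtry == 10  # floor(sqrt(120)) = 10

    def test_every_ml_sample_scored_once(self, fitted):
        model, ev = fitted
        assert len(ev.scores) == len(model.folds)
        assert ev.scores.index.is_unique
        # each sample scored by the model of its own fold
        assert (ev.scores["fold"] == model.folds.loc[ev.scores.index]).all()

    def test_planted_signal_detected(self, fitted):
        _, ev = fitted
        assert ev.auroc >= 0.9
        assert 0.0 <= ev.auprc <= 1.0

    def test_deterministic_under_seed(self, small_rf_data):
        matrix, labels, folds, _ = small_rf_data
        e1 = classify.RandomForestCV(matrix, labels, folds, n_trees=30, seed=9).fit()
        e2 = classify.RandomForestCV(matrix, labels, folds, n_trees=30, seed=9).fit()
        pd.testing.assert_frame_equal(e1.scores, e2.scores)

    def test_control_near_chance_and_compare(self, small_rf_data, fitted):
        matrix, labels, folds, subjects = small_rf_data
        _, ev = fitted
        ctrl = classify.permuted_label_control(matrix, labels, folds, subjects,
                                               n_trees=100, seed=6)
        assert 0.3 <= ctrl.auroc <= 0.7
        ev.control = ctrl
        cmp = ev.compare_to_control()
        assert cmp.p_value < 0.001
        assert "AUROC" in ev.summary()

    def test_single_class_fold_raises(self, small_rf_data):
        matrix, labels, folds, _ = small_rf_data
        broken = labels.copy()
        broken[:] = 0
        broken[folds.index[folds == 0]] = 1  # all cases inside fold 0
        with pytest.raises(classify.FoldError, match="fold 0"):
            classify.RandomForestCV(matrix, broken, folds, n_trees=10).fit()


class TestPermuteLabels:
    def test_counts_and_concordance_preserved(self, small_rf_data):
        _, labels, folds, subjects = small_rf_data
        perm = classify.permute_labels_by_subject(labels, subjects, seed=3)
        # subject-level class counts are preserved exactly
        subj = subjects.reindex(labels.index)
        assert perm.groupby(subj).first().sum() == labels.groupby(subj).first().sum()
        grouped = perm.groupby(subj).nunique()
        assert (grouped == 1).all()

    def test_deterministic(self, small_rf_data):
        _, labels, folds, subjects = small_rf_data
        p1 = classify.permute_labels_by_subject(labels, subjects, seed=8)
        p2 = classify.permute_labels_by_subject(labels, subjects, seed=8)
        pd.testing.assert_series_equal(p1, p2)


class TestBootstrapSubset:
    def _eval(self, rng, n=200, auc_strength=1.0):
        y = rng.integers(0, 2, n)
        y[:2] = [0, 1]
        s = np.clip(rng.random(n) * 0.8 + auc_strength * 0.25 * y, 0, 1)
        scores = pd.DataFrame({"y_true": y, "score": s, "fold": 0},
                              index=[f"s{i}" for i in range(n)])
        return classify.ModelEvaluation(scores=scores,
                                        auroc=classify.auroc(s, y),
                                        auprc=classify.auprc(s, y))

    def test_p_value_consistent_with_t_statistic(self):
        rng = np.random.default_rng(5)
        ev = self._eval(rng)
        res = classify.bootstrap_subset_test(ev, ev.scores.index[:60], n_boot=300, seed=1)
        _, p_ref = stats.ttest_1samp(res.bootstrap_aucs, res.observed_auc)
        assert res.p_value == pytest.approx(p_ref)
        # an observed value at the bootstrap mean would give t ~ 0, p ~ 1
        _, p_at_mean = stats.ttest_1samp(res.bootstrap_aucs, res.bootstrap_aucs.mean())
        assert p_at_mean > 0.999

    def test_degraded_subset_detected(self):
        rng = np.random.default_rng(6)
        ev = self._eval(rng, auc_strength=1.0)
        # corrupt a subset: shuffle its scores so its AUC drops
        sub = ev.scores.index[:60]
        ev.scores.loc[sub, "score"] = rng.permutation(ev.scores.loc[sub, "score"].to_numpy())
        res = classify.bootstrap_subset_test(ev, sub, n_boot=500, seed=2)
        assert res.observed_auc < np.mean(res.bootstrap_aucs) - 0.05
        assert res.p_value < 0.001

    def test_deterministic_and_sized(self):
        rng = np.random.default_rng(7)
        ev = self._eval(rng)
        r1 = classify.bootstrap_subset_test(ev, ev.scores.index[:40], n_boot=100, seed=3)
        r2 = classify.bootstrap_subset_test(ev, ev.scores.index[:40], n_boot=100, seed=3)
        np.testing.assert_array_equal(r1.bootstrap_aucs, r2.bootstrap_aucs)
        assert r1.subset_size == 40 and len(r1.bootstrap_aucs) == 100

    def test_single_class_subset_rejected(self):
        rng = np.random.default_rng(8)
        ev = self._eval(rng)
        ids = ev.scores.index[ev.scores["y_true"] == 1][:10]
        with pytest.raises(ValueError):
            classify.bootstrap_subset_test(ev, ids, n_boot=10)
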