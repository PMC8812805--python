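import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from globinscreen import screenmodels as sm
from globinscreen.globin_features import FEATURE_NAMES

from conftest import make_truth_feature_table


def pairwise_auc_oracle(values, y):
    """Exhaustive (positive, negative) pair counting with half-credit ties."""
    pos = [v for v, label in zip(values, y) if label == 1]
    neg = [v for v, label in zip(values, y) if label == 0]
    wins = sum(
        1.0 if p > n else (0.5 if p == n else 0.0)
        for p, n in itertools.product(pos, neg)
    )
    return wins / (len(pos) * len(neg))


class TestSingleFeatureAuc:
    def test_perfect_separation(self):
        assert sm.single_feature_auc([1, 2, 3, 4], [0, 0, 1, 1], positive_label=1) == 1.0

    def test_interleaved(self):
        # brute force over the 4 (pos, neg) pairs: 3 wins / 4
        assert sm.single_feature_auc([1, 2, 3, 4], [0, 1, 0, 1], positive_label=1) == 0.75

    def test_all_tied(self):
        assert sm.single_feature_auc([5, 5, 5, 5], [0, 1, 0, 1], positive_label=1) == 0.5

    def test_single_class_errors(self):
        with pytest.raises(sm.SingleClassError):
            sm.single_feature_auc([1, 2], ["thalassaemia", "thalassaemia"])

    @settings(max_examples=200, deadline=None)
    @given(
        values=st.lists(st.integers(0, 5), min_size=2, max_size=12),
        data=st.data(),
    )
    def test_matches_pairwise_oracle(self, values, data):
        n = len(values)
        y = data.draw(
            st.lists(st.integers(0, 1), min_size=n, max_size=n).filter(
                lambda l: 0 < sum(l) < n
            )
        )
        auc = sm.single_feature_auc(values, y, positive_label=1)
        assert auc == pytest.approx(pairwise_auc_oracle(values, y), abs=1e-12)

    @settings(max_examples=100, deadline=None)
    @given(data=st.data())
    def test_symmetry_without_ties(self, data):
        n = data.draw(st.integers(4, 12))
        values = data.draw(
            st.lists(st.floats(0, 1), min_size=n, max_size=n, unique=True)
        )
        y = data.draw(
            st.lists(st.integers(0, 1), min_size=n, max_size=n).filter(
                lambda l: 0 < sum(l) < n
            )
        )
        a = sm.single_feature_auc(values, y, positive_label=1)
        b = sm.single_feature_auc([-v for v in values], y, positive_label=1)
        assert a + b == pytest.approx(1.0, abs=1e-12)


class TestSelectFeatures:
    @pytest.fixture(scope="class")
    def table(self):
        return make_truth_feature_table({"control": 40, "beta_thal": 40}, seed=1)

    def test_beta_ranks_top(self):
        # pure beta deficit with no gamma response: beta itself must dominate
        from globinscreen import synthcohort

        profiles = synthcohort.default_profiles()
        profiles["beta_thal"] = synthcohort.DiseaseProfile(
            "beta_thal", {"alpha": 1.0, "beta": 0.6, "gamma": 0.02},
            between_sample_cv=0.15, gamma_beta_coupling=0.0,
        )
        table = make_truth_feature_table(
            {"control": 40, "beta_thal": 40}, profiles=profiles, seed=1
        )
        ranked = sm.rank_features(table, table["class_label"])
        assert "beta_1p" in list(ranked.index[:2])

    def test_top_k_exact_count(self, table):
        chosen = sm.select_features(table, table["class_label"], {"top_k": 5})
        assert len(chosen) == 5

    def test_top_k_too_large_errors(self, table):
        with pytest.raises(ValueError, match="top_k"):
            sm.select_features(table, table["class_label"], {"top_k": 99})

    def test_impossible_auc_min_warns_empty(self, table):
        with pytest.warns(UserWarning, match="empty"):
            chosen = sm.select_features(table, table["class_label"], {"auc_min": 1.01})
        assert chosen == []

    def test_low_completeness_feature_excluded(self, table):
        broken = table.copy()
        broken.loc[broken.index[:60], "gamma_1p"] = np.nan
        with pytest.warns(UserWarning, match="completeness"):
            chosen = sm.select_features(broken, broken["class_label"], {"top_k": 5})
        assert "gamma_1p" not in chosen

    def test_tie_break_canonical_order(self):
        table = pd.DataFrame(
            {
                "sample_id": ["a", "b", "c", "d"],
                "class_label": ["control", "control", "thalassaemia", "thalassaemia"],
            }
        )
        for name in FEATURE_NAMES:
            table[name] = [1.0, 2.0, 3.0, 4.0]  # every feature ties at AUC 1
        chosen = sm.select_features(table, table["class_label"], {"top_k": 3})
        assert chosen == list(FEATURE_NAMES[:3])


def split_manifest(n_pos, n_neg):
    return pd.DataFrame(
        {
            "sample_id": [f"p{i}" for i in range(n_pos)] + [f"n{i}" for i in range(n_neg)],
            "class_label": ["thalassaemia"] * n_pos + ["control"] * n_neg,
        }
    )


class TestStratifiedSplit:
    def test_published_cohort_arithmetic(self):
        plan = sm.stratified_split(split_manifest(203, 106), seed=0)
        assert len(plan.train_ids) == 206
        assert len(plan.test_ids) == 103
        train_pos = sum(i.startswith("p") for i in plan.train_ids)
        assert train_pos == 135
        assert sum(i.startswith("n") for i in plan.train_ids) == 71
        assert sum(i.startswith("p") for i in plan.test_ids) == 68
        assert sum(i.startswith("n") for i in plan.test_ids) == 35

    def test_tiny_cohort_allocation(self):
        plan = sm.stratified_split(split_manifest(3, 3), seed=0)
        assert len(plan.train_ids) == 4 and len(plan.test_ids) == 2

    def test_seed_determinism(self):
        manifest = split_manifest(30, 20)
        assert sm.stratified_split(manifest, seed=5) == sm.stratified_split(manifest, seed=5)

    def test_disjoint_and_covering(self):
        manifest = split_manifest(31, 17)
        plan = sm.stratified_split(manifest, seed=2)
        train, test = set(plan.train_ids), set(plan.test_ids)
        assert not train & test
        assert train | test == set(manifest["sample_id"])

    def test_small_class_errors(self):
        with pytest.raises(ValueError, match="at least 3"):
            sm.stratified_split(split_manifest(2, 10), seed=0)

    @settings(max_examples=40, deadline=None)
    @given(n_pos=st.integers(3, 60), n_neg=st.integers(3, 60), seed=st.integers(0, 99))
    def test_per_class_counts_property(self, n_pos, n_neg, seed):
        plan = sm.stratified_split(split_manifest(n_pos, n_neg), seed=seed)
        train_pos = sum(i.startswith("p") for i in plan.train_ids)
        train_neg = len(plan.train_ids) - train_pos
        assert train_pos == int(np.floor(2 / 3 * n_pos + 0.5))
        assert train_neg == int(np.floor(2 / 3 * n_neg + 0.5))
        assert len(plan.train_ids) + len(plan.test_ids) == n_pos + n_neg


def toy_table(n=40, seed=0, sep=3.0):
    rng = np.random.default_rng(seed)
    half = n // 2
    x1 = np.concatenate([rng.normal(0, 1, half), rng.normal(sep, 1, half)])
    x2 = rng.normal(0, 1, n)
    return pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(n)],
            "class_label": ["control"] * half + ["thalassaemia"] * half,
            "f1": x1,
            "f2": x2,
        }
    )


class TestTrainClassifier:
    def test_lr_separable_training_auc_one(self):
        table = toy_table(sep=10.0)
        model = sm.train_classifier("LR", table, ["f1", "f2"], table["class_label"])
        scores = sm.score_samples(model, table, ["f1", "f2"])
        auc, _, _ = sm.roc_auc_ci(scores, table["class_label"].eq("thalassaemia").astype(int))
        assert auc == 1.0

    @pytest.mark.parametrize("method", sm.METHOD_NAMES)
    def test_all_methods_orientation(self, method):
        table = toy_table(sep=3.0)
        model = sm.train_classifier(method, table, ["f1", "f2"], table["class_label"], seed=1)
        scores = sm.score_samples(model, table, ["f1", "f2"])
        y = table["class_label"].eq("thalassaemia").astype(int)
        auc, _, _ = sm.roc_auc_ci(scores, y)
        assert auc >= 0.5

    def test_rf_deterministic_under_seed(self):
        table = toy_table()
        m1 = sm.train_classifier("RF", table, ["f1", "f2"], table["class_label"], seed=3)
        m2 = sm.train_classifier("RF", table, ["f1", "f2"], table["class_label"], seed=3)
        np.testing.assert_array_equal(
            sm.score_samples(m1, table, ["f1", "f2"]),
            sm.score_samples(m2, table, ["f1", "f2"]),
        )

    def test_unknown_method_errors(self):
        table = toy_table()
        with pytest.raises(ValueError, match="unknown method"):
            sm.train_classifier("XGB", table, ["f1"], table["class_label"])

    def test_nan_features_rejected(self):
        table = toy_table()
        table.loc[0, "f1"] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            sm.train_classifier("LR", table, ["f1", "f2"], table["class_label"])


class TestRocAucCi:
    def test_perfect_scores_degenerate_ci(self):
        y = np.array([0] * 50 + [1] * 50)
        scores = y.astype(float)
        auc, lo, hi = sm.roc_auc_ci(scores, y)
        assert auc == 1.0 and hi == 1.0
        assert lo <= auc <= hi

    def test_random_scores_near_half(self):
        """MC over seeds: AUC within 0.5 +/- 0.06 for >= 95% of seeds."""
        y = np.array([0] * 500 + [1] * 500)
        hits = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            auc, _, _ = sm.roc_auc_ci(rng.uniform(size=1000), y)
            hits += abs(auc - 0.5) <= 0.06
        assert hits >= 38

    def test_delong_width_close_to_bootstrap(self):
        """Bootstrap oracle (2000 resamples): CI widths agree within 20%."""
        rng = np.random.default_rng(7)
        y = np.array([0] * 80 + [1] * 80)
        scores = np.concatenate([rng.normal(0, 1, 80), rng.normal(1.0, 1, 80)])
        auc, lo, hi = sm.roc_auc_ci(scores, y)
        boot = []
        for _ in range(2000):
            idx_n = rng.integers(0, 80, 80)
            idx_p = 80 + rng.integers(0, 80, 80)
            b_scores = np.concatenate([scores[idx_n], scores[idx_p]])
            boot.append(sm.single_feature_auc(b_scores, y, positive_label=1))
        b_lo, b_hi = np.quantile(boot, [0.025, 0.975])
        assert (hi - lo) == pytest.approx(b_hi - b_lo, rel=0.20)

    def test_single_class_errors(self):
        with pytest.raises(sm.SingleClassError):
            sm.roc_auc_ci([0.1, 0.9], [1, 1])


class TestMetrics:
    def test_published_confusion_sensitivity_specificity(self):
        m = sm.confusion_metrics(tp=230, fn=3, tn=126, fp=6)
        assert sm.to_percent(m["sensitivity"]) == 98.7
        assert sm.to_percent(m["specificity"]) == 95.5

    def test_published_confusion_accuracy_precision(self):
        # 356/365 and 230/236 computed by hand
        m = sm.confusion_metrics(tp=230, fn=3, tn=126, fp=6)
        assert sm.to_percent(m["accuracy"]) == 97.5
        assert sm.to_percent(m["precision"]) == 97.5

    def test_all_correct_is_100(self):
        m = sm.confusion_metrics(tp=10, fn=0, tn=10, fp=0)
        assert sm.to_percent(m["sensitivity"]) == 100.0
        assert sm.to_percent(m["specificity"]) == 100.0
        assert sm.to_percent(m["accuracy"]) == 100.0
        assert sm.to_percent(m["precision"]) == 100.0

    def test_precision_masked_without_positive_calls(self):
        m = sm.confusion_metrics(tp=0, fn=5, tn=5, fp=0)
        assert m["precision"] is None

    def test_threshold_application(self):
        scores = [0.1, 0.4, 0.6, 0.9]
        y = [0, 0, 1, 1]
        m = sm.classification_metrics(scores, y, threshold=0.5)
        assert m["confusion"] == {"tp": 2, "fn": 0, "tn": 2, "fp": 0}

    @settings(max_examples=100, deadline=None)
    @given(
        tp=st.integers(0, 50), fn=st.integers(0, 50),
        tn=st.integers(0, 50), fp=st.integers(0, 50),
    )
    def test_metric_identities_property(self, tp, fn, tn, fp):
        if tp + fn + tn + fp == 0:
            return
        m = sm.confusion_metrics(tp, fn, tn, fp)
        n = tp + fn + tn + fp
        assert m["accuracy"] == pytest.approx((tp + tn) / n)
        if tp + fn:
            assert 0.0 <= m["sensitivity"] <= 1.0
            assert m["sensitivity"] == pytest.approx(tp / (tp + fn))
        if tn + fp:
            assert m["specificity"] == pytest.approx(tn / (tn + fp))
        if tp + fp:
            assert m["precision"] == pytest.approx(tp / (tp + fp))


class TestRunModelSuite:
    @pytest.fixture(scope="class")
    def study(self):
        discovery = make_truth_feature_table({"control": 60, "beta_thal": 60}, seed=11)
        validation = make_truth_feature_table({"control": 70, "beta_thal": 70}, seed=12)
        plan = sm.stratified_split(discovery, seed=1)
        train = discovery[discovery["sample_id"].isin(plan.train_ids)]
        test = discovery[discovery["sample_id"].isin(plan.test_ids)]
        return train, test, validation

    def test_lr_validation_auc_high(self, study):
        train, test, validation = study
        reports, _ = sm.run_model_suite(train, test, validation, methods=["LR"], seed=0)
        lr_val = next(r for r in reports if r.eval_set == "validation")
        assert lr_val.auc >= 0.95

    def test_permuted_labels_null(self, study):
        train, test, validation = study
        rng = np.random.default_rng(0)
        permuted = [t.copy() for t in (train, test, validation)]
        for t in permuted:
            t["class_label"] = rng.permutation(t["class_label"].to_numpy())
        reports, _ = sm.run_model_suite(*permuted, methods=["LR"], seed=0)
        val = next(r for r in reports if r.eval_set == "validation")
        assert abs(val.auc - 0.5) <= 0.1

    def test_single_method_report_count(self, study):
        train, test, validation = study
        reports, best = sm.run_model_suite(train, test, validation, methods=["LR"], seed=0)
        assert len(reports) == 3  # one per evaluation set
        assert best == "LR"
        assert {r.eval_set for r in reports} == {"train", "test", "validation"}

    def test_leakage_guard(self, study):
        train, test, _ = study
        with pytest.raises(sm.LeakageError):
            sm.run_model_suite(train, train, test)

    def test_effect_size_monotonicity(self):
        """Stronger beta deficit => higher LR validation AUC (seeded)."""
        from globinscreen import synthcohort

        aucs = []
        for beta_mean in (1.0, 0.85, 0.6):
            profiles = synthcohort.default_profiles()
            profiles["beta_thal"] = synthcohort.DiseaseProfile(
                "beta_thal", {"alpha": 1.0, "beta": beta_mean, "gamma": 0.02},
                between_sample_cv=0.2, gamma_beta_coupling=0.0,
            )
            discovery = make_truth_feature_table(
                {"control": 45, "beta_thal": 45}, profiles=profiles, seed=21
            )
            validation = make_truth_feature_table(
                {"control": 60, "beta_thal": 60}, profiles=profiles, seed=22
            )
            plan = sm.stratified_split(discovery, seed=2)
            train = discovery[discovery["sample_id"].isin(plan.train_ids)]
            test = discovery[discovery["sample_id"].isin(plan.test_ids)]
            reports, _ = sm.run_model_suite(train, test, validation, methods=["LR"], seed=2)
            aucs.append(next(r.auc for r in reports if r.eval_set == "validation"))
        assert aucs[0] < aucs[1] < aucs[2]

    def test_youden_threshold_mode(self, study):
        train, test, validation = study
        reports, _ = sm.run_model_suite(
            train, test, validation, methods=["LR"], seed=0, threshold="youden"
        )
        assert all(0.0 <= r.threshold <= 1.0 for r in reports)


class TestModelReportInvariants:
    def test_ci_must_bracket_auc(self):
        with pytest.raises(ValueError, match="bracket"):
            sm.ModelReport(
                method="LR", eval_set="test", auc=0.9, ci_low=0.95, ci_high=1.0,
                sensitivity=1.0, specificity=1.0, accuracy=1.0, precision=1.0,
                confusion={"tp": 1, "fn": 0, "tn": 1, "fp": 0}, threshold=0.5,
                selected_features=("f1",), n=2,
            )

    def test_confusion_must_sum_to_n(self):
        with pytest.raises(ValueError, match="sum"):
            sm.ModelReport(
                method="LR", eval_set="test", auc=0.9, ci_low=0.8, ci_high=1.0,
                sensitivity=1.0, specificity=1.0, accuracy=1.0, precision=1.0,
                confusion={"tp": 1, "fn": 0, "tn": 1, "fp": 0}, threshold=0.5,
                selected_features=("f1",), n=5,
            )
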