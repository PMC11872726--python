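import numpy as np
import pandas as pd
import pytest

from bcrpipe import stats as gs


def _usage_two_groups(case_values, control_values, gene="IGHV3-30"):
    index = [f"c{i}" for i in range(len(case_values))] + [
        f"h{i}" for i in range(len(control_values))
    ]
    usage = pd.DataFrame({gene: list(case_values) + list(control_values)}, index=index)
    groups = pd.Series(
        ["ME_mm"] * len(case_values) + ["HC"] * len(control_values), index=index
    )
    return usage, groups


class TestMultipleTesting:
    def test_bonferroni_arithmetic(self):
        adjusted = gs.bonferroni([0.02, 0.9], m=2)
        assert adjusted[0] == pytest.approx(0.04)
        assert adjusted[1] == 1.0  # capped

    def test_holm_sidak_hand_value(self):
        # smallest of three: q1 = 1 - (1 - 0.01)^3
        q = gs.holm_sidak([0.01, 0.2, 0.8])
        assert q[0] == pytest.approx(1 - 0.99**3, abs=1e-10)
        order = np.argsort([0.01, 0.2, 0.8])
        assert (np.diff(q[order]) >= -1e-12).all()  # step-down monotone
        assert (q <= 1).all() and (q >= [0.01, 0.2, 0.8]).all()


class TestMannWhitneyUsage:
    def test_identical_groups_give_p_one(self):
        usage, groups = _usage_two_groups([0.1, 0.2, 0.3], [0.1, 0.2, 0.3])
        result = gs.mannwhitney_usage(usage, groups, [("ME_mm", "HC")])
        assert result["p_raw"].iloc[0] == pytest.approx(1.0)

    def test_adjusted_at_least_raw_and_family_default(self):
        rng = np.random.default_rng(0)
        usage = pd.DataFrame(
            rng.dirichlet(np.ones(4), size=10),
            columns=list("abcd"),
            index=[f"s{i}" for i in range(10)],
        )
        groups = pd.Series(["ME_mm"] * 5 + ["HC"] * 5, index=usage.index)
        result = gs.mannwhitney_usage(usage, groups, [("ME_mm", "HC")])
        assert (result["p_adjusted"] >= result["p_raw"] - 1e-15).all()
        assert result["adjustment"].iloc[0] == "bonferroni(m=4)"

    def test_small_group_raises(self):
        usage, groups = _usage_two_groups([0.1], [0.2, 0.3])
        with pytest.raises(ValueError):
            gs.mannwhitney_usage(usage, groups, [("ME_mm", "HC")])


class TestKruskalDunn:
    def test_shifted_group_is_found(self):
        rng = np.random.default_rng(2)
        values = {
            "HC": rng.normal(0, 1, 20),
            "ME_mm": rng.normal(3, 1, 20),  # 3 SD shift
            "MS": rng.normal(0, 1, 20),
        }
        omnibus, pairwise = gs.kruskal_dunn(values)
        assert omnibus.p_raw < 1e-3
        hits = pairwise[pairwise["p_adjusted"] < 0.01]["comparison"].tolist()
        assert "HC_vs_ME_mm" in hits and "ME_mm_vs_MS" in hits
        assert (pairwise["p_adjusted"] >= pairwise["p_raw"] - 1e-15).all()

    def test_null_omnibus_statistic_near_mean(self):
        rng = np.random.default_rng(3)
        stats_h = []
        for _ in range(300):
            values = {g: rng.normal(0, 1, 15) for g in ("a", "b", "c", "d")}
            omnibus, _ = gs.kruskal_dunn(values)
            stats_h.append(omnibus.statistic)
        # H is asymptotically chi-square with k-1 = 3 dof
        assert np.mean(stats_h) == pytest.approx(3.0, abs=0.4)

    def test_two_groups_rejected(self):
        with pytest.raises(ValueError, match="mannwhitney"):
            gs.kruskal_dunn({"a": [1, 2], "b": [3, 4]})


class TestCohensD:
    def test_unit_difference_unit_sd(self):
        assert gs.cohens_d([0, 1, 2], [-1, 0, 1]) == pytest.approx(1.0)

    def test_identical_samples_zero(self):
        assert gs.cohens_d([1, 2, 3], [1, 2, 3]) == 0.0

    def test_zero_pooled_sd_raises(self):
        with pytest.raises(ValueError):
            gs.cohens_d([1, 1], [1, 1])

    def test_sign_convention(self):
        assert gs.cohens_d([0, 0, 0.1], [1, 1, 1.1]) < 0


class TestMedianUsageCorrelation:
    def _usage(self, a_medians, b_medians):
        rows = {}
        for i, (a, b) in enumerate(zip(a_medians, b_medians)):
            rows[f"gene{i}"] = [a, a, a, b, b, b]
        usage = pd.DataFrame(rows, index=["a1", "a2", "a3", "b1", "b2", "b3"])
        groups = pd.Series(["A"] * 3 + ["B"] * 3, index=usage.index)
        return usage, groups

    def test_identical_medians_give_one(self):
        usage, groups = self._usage([0.1, 0.3, 0.6], [0.1, 0.3, 0.6])
        assert gs.median_usage_correlation(usage, groups, "A", "B") == pytest.approx(1.0)

    def test_independent_vectors_give_low_r2(self):
        rng = np.random.default_rng(4)
        low = [
            gs.median_usage_correlation(
                *self._usage(rng.random(50), rng.random(50)), "A", "B"
            )
            for _ in range(20)
        ]
        assert np.mean(np.array(low) < 0.2) >= 0.9

    def test_zero_variance_raises(self):
        usage, groups = self._usage([0.2, 0.2, 0.2], [0.1, 0.5, 0.9])
        with pytest.raises(ValueError):
            gs.median_usage_correlation(usage, groups, "A", "B")


class TestPCA:
    def test_perfectly_correlated_pair(self):
        x = np.arange(10.0)
        features = pd.DataFrame({"f1": x, "f2": 2 * x + 1})
        _, explained, _ = gs.pca_features(features)
        assert explained[0] == pytest.approx(1.0)

    def test_matches_eigendecomposition(self):
        rng = np.random.default_rng(6)
        X = pd.DataFrame(rng.normal(size=(20, 6)), columns=list("abcdef"))
        _, explained, _ = gs.pca_features(X)
        Z = (X - X.mean()) / X.std(ddof=0)
        eigvals = np.sort(np.linalg.eigvalsh(np.corrcoef(Z.T)))[::-1]
        np.testing.assert_allclose(explained, eigvals / eigvals.sum(), atol=1e-8)

    def test_constant_feature_dropped_with_warning(self):
        X = pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [0, 1, 2], "c": [2, 1, 0]})
        with pytest.warns(UserWarning, match="constant"):
            scores, _, loadings = gs.pca_features(X)
        assert "a" not in loadings.columns


class TestStratifiedSplit:
    def test_ten_ten_splits_six_six(self):
        subjects = [f"c{i}" for i in range(10)] + [f"h{i}" for i in range(10)]
        labels = ["case"] * 10 + ["ctrl"] * 10
        train, test = gs.stratified_split(subjects, labels, rng=np.random.default_rng(0))
        assert sum(s.startswith("c") for s in train) == 6
        assert sum(s.startswith("h") for s in train) == 6
        assert len(test) == 8

    @pytest.mark.parametrize("n1,n2", [(4, 5), (7, 8), (10, 21), (21, 25), (25, 36), (36, 50)])
    def test_partition_and_proportions(self, n1, n2):
        subjects = [f"a{i}" for i in range(n1)] + [f"b{i}" for i in range(n2)]
        labels = ["A"] * n1 + ["B"] * n2
        train, test = gs.stratified_split(subjects, labels, rng=np.random.default_rng(1))
        assert set(train) | set(test) == set(subjects)
        assert not set(train) & set(test)
        for label, n in (("a", n1), ("b", n2)):
            got = sum(s.startswith(label) for s in train)
            assert abs(got - 0.6 * n) <= 1.0

    def test_tiny_label_raises(self):
        with pytest.raises(ValueError):
            gs.stratified_split(["a", "b", "c"], ["x", "x", "y"])


def _irls_logistic(X, y, iterations=200):
    """Independent Newton-Raphson ML fit (intercept prepended)."""
    design = np.column_stack([np.ones(len(y)), X])
    beta = np.zeros(design.shape[1])
    for _ in range(iterations):
        eta = design @ beta
        p = 1 / (1 + np.exp(-eta))
        W = p * (1 - p)
        hessian = design.T @ (design * W[:, None])
        gradient = design.T @ (y - p)
        step = np.linalg.solve(hessian, gradient)
        beta = beta + step
        if np.abs(step).max() < 1e-12:
            break
    return beta


class TestLogistic:
    def test_matches_irls_oracle(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(30, 3))
        eta = 0.5 + X @ np.array([1.0, -0.5, 0.2])
        y = (rng.random(30) < 1 / (1 + np.exp(-eta))).astype(int)
        features = pd.DataFrame(X, columns=["a", "b", "c"])
        coef, used_ridge = gs.fit_logistic(features, y)
        assert not used_ridge
        expected = _irls_logistic(X, y)
        np.testing.assert_allclose(coef, expected, atol=1e-6)

    def test_separable_direction_recovered(self):
        X = pd.DataFrame({"f": np.arange(20.0)})
        y = (X["f"] >= 10).astype(int)
        coef, _ = gs.fit_logistic(X, y)
        scores = gs.logistic_scores(X, coef)
        auc, _ = gs.roc_auc(scores, y)
        assert coef[1] > 0 and auc == 1.0

    def test_constant_feature_raises(self):
        X = pd.DataFrame({"f": np.ones(10), "g": np.arange(10.0)})
        with pytest.raises(ValueError):
            gs.fit_logistic(X, np.repeat([0, 1], 5))


class TestRocAuc:
    def test_perfect_separation(self):
        auc, curve = gs.roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert auc == 1.0
        assert {"fpr", "tpr"} <= set(curve.columns)

    def test_all_ties_give_half(self):
        auc, _ = gs.roc_auc([0.5] * 6, [0, 1, 0, 1, 0, 1])
        assert auc == pytest.approx(0.5)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(8)
        scores = rng.normal(size=40)
        labels = (rng.random(40) < 0.5).astype(int)
        a1, _ = gs.roc_auc(scores, labels)
        a2, _ = gs.roc_auc(np.exp(3 * scores), labels)
        assert a1 == pytest.approx(a2)

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            gs.roc_auc([0.1, 0.9], [1, 1])


class TestClassifierExperiment:
    def _usage(self, seed, shift=0.0):
        rng = np.random.default_rng(seed)
        genes = list(gs.DEFAULT_CLASSIFIER_FEATURES)
        index = [f"c{i}" for i in range(20)] + [f"h{i}" for i in range(20)]
        X = rng.normal(0.05, 0.01, size=(40, 6)).clip(0.001)
        X[:20] += shift
        usage = pd.DataFrame(X, columns=genes, index=index)
        groups = pd.Series(["ME_mm"] * 20 + ["HC"] * 20, index=index)
        return usage, groups

    def test_fixed_seed_reproduces_split(self):
        usage, groups = self._usage(1)
        r1 = gs.run_classifier_experiment(usage, groups, "ME_mm", "HC", seed=5)
        r2 = gs.run_classifier_experiment(usage, groups, "ME_mm", "HC", seed=5)
        assert r1.train_subjects == r2.train_subjects
        assert r1.test_subjects == r2.test_subjects
        assert r1.auc_test == r2.auc_test
        assert not set(r1.train_subjects) & set(r1.test_subjects)

    def test_strong_multigene_effect_is_learnable(self):
        # every feature shifted by ~2 SD: near-perfect test AUC expected
        hits = 0
        for seed in range(10):
            usage, groups = self._usage(seed, shift=0.02)
            report = gs.run_classifier_experiment(usage, groups, "ME_mm", "HC", seed=seed)
            hits += report.auc_test > 0.9
        assert hits >= 9

    def test_null_features_give_chance_auc(self):
        aucs = []
        for seed in range(20):
            usage, groups = self._usage(100 + seed, shift=0.0)
            report = gs.run_classifier_experiment(usage, groups, "ME_mm", "HC", seed=seed)
            aucs.append(report.auc_test)
        assert 0.35 < np.mean(aucs) < 0.65
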