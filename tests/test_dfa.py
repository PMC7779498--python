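"""Stepwise DFA, classification and pairwise-F tests against independent oracles."""

import numpy as np
import pytest

from convergekit import (
    FeatureSimConfig,
    build_structure,
    classify,
    dissimilarity_from_f,
    fit_model,
    pairwise_f_matrix,
    simulate_features,
    stepwise_select,
)
from convergekit.core import DyadicMatrix

from conftest import make_feature_table


def _two_group_table(rng, n1=12, n2=15, p=4, shift=0.8):
    X = np.vstack([rng.normal(0, 1, (n1, p)), rng.normal(shift, 1, (n2, p))])
    return make_feature_table(X, ["a"] * n1 + ["b"] * n2), X, n1, n2, p


class TestStepwiseSelect:
    def test_zero_within_variance_feature_enters_alone(self, rng):
        # f1 separates groups perfectly with zero within-group variance:
        # infinite partial F, enters at step 1, lambda hits 0, selection stops
        n = 10
        f1 = np.array([0.0] * n + [1.0] * n)
        noise = rng.normal(size=(2 * n, 3))
        table = make_feature_table(np.column_stack([f1, noise]), ["a"] * n + ["b"] * n)
        model = stepwise_select(table)
        assert model.selected_features == ["f1"]
        assert model.trace[0].p_value == 0.0

    def test_false_entry_rate_near_nominal_on_pure_noise(self):
        # with K independent noise features, P(any entry) ~ 1 - (1 - p_in)^K
        K, reps, hits = 5, 200, 0
        for k in range(reps):
            r = np.random.default_rng(500 + k)
            table = make_feature_table(r.normal(size=(24, K)), ["a"] * 12 + ["b"] * 12)
            hits += not stepwise_select(table, p_in=0.05, p_out=0.10).is_empty
        expected = 1 - 0.95 ** K  # 0.226
        assert abs(hits / reps - expected) < 0.09

    def test_wilks_lambda_non_increasing_along_entries(self, study_structure):
        cfg = FeatureSimConfig(n_features=15, calls_range=(5, 15), seed=21)
        table = simulate_features(study_structure, cfg)
        model = stepwise_select(table)
        lams = [r.wilks_lambda for r in model.trace if r.action == "enter"]
        assert len(lams) >= 1
        assert all(b <= a + 1e-12 for a, b in zip(lams, lams[1:]))

    def test_p_in_greater_than_p_out_rejected(self, rng):
        table, *_ = _two_group_table(rng)
        with pytest.raises(ValueError):
            stepwise_select(table, p_in=0.2, p_out=0.1)


class TestClassify:
    def test_perfect_separation_classifies_all(self, rng):
        n = 8
        f1 = np.repeat([0.0, 5.0, 10.0], n)
        table = make_feature_table(f1[:, None], np.repeat(list("abc"), n))
        model = stepwise_select(table)
        for mode in ("resubstitution", "leave_one_out"):
            res = classify(model, table, mode)
            assert res.percent_correct == 100.0

    def test_chance_level_for_27_groups(self, study_structure):
        cfg = FeatureSimConfig(n_features=3, calls_range=(4, 6), seed=2)
        table = simulate_features(study_structure, cfg)
        model = stepwise_select(table, p_in=0.9999, p_out=1.0)
        res = classify(model, table)
        assert res.chance_percent == pytest.approx(100.0 / 27)
        assert round(res.chance_percent, 1) == 3.7

    def test_shuffled_labels_recover_chance_rate(self):
        # with all group structure removed, the correct rate ~ 100/g %
        g, per = 5, 200  # 1000 calls
        r = np.random.default_rng(77)
        X = r.normal(size=(g * per, 3))
        labels = r.permutation(np.repeat([f"m{j}" for j in range(g)], per))
        table = make_feature_table(X, labels)
        res = classify(fit_model(table), table)
        assert abs(res.percent_correct - 100.0 / g) < 2.0

    def test_loo_excludes_singleton_individuals(self, rng):
        X = rng.normal(size=(9, 2))
        table = make_feature_table(X, ["a"] * 4 + ["b"] * 4 + ["c"])
        model = stepwise_select(table, p_in=0.9999, p_out=1.0)
        res = classify(model, table, mode="leave_one_out")
        assert res.n_classified == 8
        assert len(res.excluded_calls) == 1


class TestPairwiseF:
    def test_identical_group_means_give_zero_f(self, rng):
        base = rng.normal(size=(10, 3))
        X = np.vstack([base, base])  # identical groups -> identical means
        table = make_feature_table(X, ["a"] * 10 + ["b"] * 10)
        F = pairwise_f_matrix(fit_model(table))
        assert F.values[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_two_groups_equal_hotelling_t2_f(self, rng):
        table, X, n1, n2, p = _two_group_table(rng)
        model = stepwise_select(table, p_in=0.9999, p_out=1.0)
        assert model.p == p
        F = pairwise_f_matrix(model).values[0, 1]
        # independent Hotelling oracle
        x, y = X[:n1], X[n1:]
        S = (np.cov(x.T) * (n1 - 1) + np.cov(y.T) * (n2 - 1)) / (n1 + n2 - 2)
        d = x.mean(0) - y.mean(0)
        T2 = n1 * n2 / (n1 + n2) * d @ np.linalg.solve(S, d)
        F_hot = (n1 + n2 - p - 1) / (p * (n1 + n2 - 2)) * T2
        assert F == pytest.approx(F_hot, rel=1e-8)

    def test_three_groups_match_bruteforce_mahalanobis(self):
        # small integer table, D^2 by explicit matrix inversion
        X = np.array(
            [[0, 1], [1, 0], [1, 2], [4, 4], [5, 5], [4, 6], [9, 0], [8, 1], [10, 1]],
            dtype=float,
        )
        labels = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        table = make_feature_table(X, labels)
        model = stepwise_select(table, p_in=0.9999, p_out=1.0)
        F = pairwise_f_matrix(model)
        N, g, p = 9, 3, 2
        means = {l: X[np.array(labels) == l].mean(0) for l in "abc"}
        W = sum(
            (X[np.array(labels) == l] - means[l]).T @ (X[np.array(labels) == l] - means[l])
            for l in "abc"
        )
        Sp_inv = np.linalg.inv(W / (N - g))
        for i, a in enumerate("abc"):
            for j, b in enumerate("abc"):
                if i >= j:
                    continue
                diff = means[a] - means[b]
                d2 = diff @ Sp_inv @ diff
                expect = (N - g - p + 1) / (p * (N - g)) * (3 * 3 / 6) * d2
                assert F.values[i, j] == pytest.approx(expect, rel=1e-10)

    def test_invariant_to_feature_rescaling(self, rng):
        table, X, n1, n2, p = _two_group_table(rng)
        model = stepwise_select(table, p_in=0.9999, p_out=1.0)
        F1 = pairwise_f_matrix(model).values
        X2 = X.copy()
        X2[:, 0] = 7.5 * X2[:, 0] - 3.0  # affine rescale of one feature
        table2 = make_feature_table(X2, ["a"] * n1 + ["b"] * n2)
        model2 = stepwise_select(table2, p_in=0.9999, p_out=1.0)
        F2 = pairwise_f_matrix(model2).values
        assert np.allclose(F1, F2, rtol=1e-8)


class TestDissimilarity:
    def test_closed_form_values(self):
        ids = ("a", "b", "c")
        F = np.array([[0, 0, np.e - 1], [0, 0, 0], [np.e - 1, 0, 0]])
        mat = DyadicMatrix(ids, F, kind="pairwise_F")
        D = dissimilarity_from_f(mat)
        assert D.values[0, 1] == 0.0
        assert D.values[0, 2] == pytest.approx(1.0)
        assert D.kind == "dissimilarity_lnF"

    def test_monotone_in_f(self, rng):
        f = np.abs(rng.normal(size=100))
        g = np.log1p(f)
        order = np.argsort(f)
        assert np.all(np.diff(g[order]) >= 0)

    def test_negative_f_rejected(self):
        ids = ("a", "b")
        F = np.array([[0.0, -0.1], [-0.1, 0.0]])
        with pytest.raises(ValueError, match="negative"):
            dissimilarity_from_f(DyadicMatrix(ids, F, kind="pairwise_F"))
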