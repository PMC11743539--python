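import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fctopo import (
    bh_adjust,
    build_design,
    edgewise_glm,
    summary_t,
)
from fctopo.inference import (
    AUCGroupTest,
    EdgewisePermutationFDR,
    NetworkBasedStatistic,
    perm_pvalues,
    upper_triangle,
)


def make_cov(y, age=None, fd=None):
    n = len(y)
    rng = np.random.default_rng(0)
    return pd.DataFrame({
        "subject_id": [f"s{i}" for i in range(n)],
        "group": np.where(np.asarray(y) == 1, "treatment", "control"),
        "age": age if age is not None else rng.normal(22, 2, n),
        "mean_fd": fd if fd is not None else np.abs(rng.normal(0, 0.15, n)),
    })


def stack_from_edges(Y, n_nodes):
    """Rebuild symmetric matrices from upper-triangle edge values."""
    iu, ju = np.triu_indices(n_nodes, k=1)
    out = np.zeros((Y.shape[0], n_nodes, n_nodes))
    out[:, iu, ju] = Y
    out += np.swapaxes(out, 1, 2)
    return out


class TestDesign:
    def test_design_columns(self):
        cov = make_cov([1, 1, 0, 0])
        X, y, names = build_design(cov)
        assert names == ["intercept", "group", "age", "mean_fd"]
        np.testing.assert_array_equal(X[:, 1], [1, 1, 0, 0])

    def test_collinear_column_named(self):
        cov = make_cov([1, 1, 0, 0, 1, 0], age=[1, 1, 0, 0, 1, 0])  # age == group
        with pytest.raises(ValueError, match="age"):
            build_design(cov)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            build_design(make_cov([1, 1, 1]))


class TestEdgewiseGLM:
    def test_equal_group_means_give_zero_t(self):
        y = np.array([1, 1, 0, 0])
        Y = np.array([[1.0], [2.0], [1.0], [2.0]])  # same means in both groups
        X = np.column_stack([np.ones(4), y])
        z = stack_from_edges(Y, 2)
        t, eff = edgewise_glm(z, X)
        assert t[0] == pytest.approx(0.0, abs=1e-12)
        assert eff[0] == pytest.approx(0.0, abs=1e-12)

    def test_matches_pooled_two_sample_t_without_covariates(self, rng):
        g = np.random.default_rng(42)
        y = np.repeat([1, 0], [8, 9])
        Y = g.normal(size=(17, 10))
        X = np.column_stack([np.ones(17), y])
        t, _ = edgewise_glm(stack_from_edges(Y, 5), X)
        ref = stats.ttest_ind(Y[y == 1], Y[y == 0], equal_var=True).statistic
        np.testing.assert_allclose(t, ref, atol=1e-10)

    def test_planted_effect_concentrates_t(self):
        g = np.random.default_rng(7)
        y = np.repeat([1, 0], 30)
        Y = g.normal(size=(60, 45))
        Y[y == 1, 3] += 2.0
        X = np.column_stack([np.ones(60), y])
        t, _ = edgewise_glm(stack_from_edges(Y, 10), X)
        assert np.argmax(np.abs(t)) == 3
        assert abs(t[3]) > 5


class TestBH:
    def test_hand_worked_example(self):
        p = np.array([0.001, 0.02, 0.04, 0.2])
        reject, _ = bh_adjust(p, q=0.05)
        np.testing.assert_array_equal(reject, [True, True, False, False])

    def test_all_ones_no_rejections(self):
        reject, _ = bh_adjust(np.ones(6), q=0.05)
        assert not reject.any()

    def test_all_floor_all_rejected(self):
        reject, _ = bh_adjust(np.full(6, 1e-6), q=0.05)
        assert reject.all()


class TestSummaryT:
    def test_printed_group_summaries_reproduce_printed_t(self):
        # depression and autism-quotient rows of the cohort demographics table
        assert summary_t(6.15, 5.55, 67, 5.18, 5.59, 72) == pytest.approx(1.025, abs=0.01)
        assert summary_t(21.54, 8.87, 67, 20.21, 7.42, 72) == pytest.approx(0.954, abs=0.01)

    def test_equal_means_zero(self):
        assert summary_t(5.0, 1.0, 10, 5.0, 2.0, 12) == 0.0

    def test_doubling_sample_sizes_scales_t_by_sqrt2(self):
        t1 = summary_t(1.0, 2.0, 20, 0.5, 2.0, 20)
        t2 = summary_t(1.0, 2.0, 40, 0.5, 2.0, 40)
        assert t2 == pytest.approx(np.sqrt(2) * t1, rel=1e-9)

    def test_pooled_variant_close_to_welch_here(self):
        w = summary_t(6.15, 5.55, 67, 5.18, 5.59, 72)
        p = summary_t(6.15, 5.55, 67, 5.18, 5.59, 72, equal_var=True)
        assert w == pytest.approx(p, abs=0.005)

    def test_degenerate_zero_sds(self):
        assert np.isnan(summary_t(3.0, 0.0, 5, 3.0, 0.0, 5))


class TestPermutationMachinery:
    def test_perm_p_floor(self):
        null = np.zeros((99, 1))
        p = perm_pvalues(np.array([10.0]), null)
        assert p[0] == pytest.approx(1.0 / 100.0)

    def test_shuffles_reproducible_across_runs(self, small_study):
        _, panels, cov = small_study
        import fctopo
        z = fctopo.PearsonConnectivity().fit(panels).transform(panels)
        e1 = EdgewisePermutationFDR(n_perm=30, seed=3).fit(z, cov)
        e2 = EdgewisePermutationFDR(n_perm=30, seed=3).fit(z, cov)
        np.testing.assert_array_equal(e1.p_perm_, e2.p_perm_)

    def test_null_pvalues_superuniform(self):
        # exchangeable null data: rejection rate at alpha should not exceed it
        g = np.random.default_rng(11)
        rates = []
        for rep in range(40):
            y = np.repeat([1, 0], 10)
            Y = g.normal(size=(20, 28))
            z = stack_from_edges(Y, 8)
            cov = make_cov(y)
            est = EdgewisePermutationFDR(n_perm=99, seed=rep).fit(
                z, cov, covariate_cols=())
            rates.append((est.p_perm_ <= 0.10).mean())
        assert np.mean(rates) < 0.10 + 0.03


class TestNBS:
    def test_planted_component_found(self):
        g = np.random.default_rng(3)
        y = np.repeat([1, 0], 25)
        Y = g.normal(scale=0.2, size=(50, 45))
        iu, ju = np.triu_indices(10, k=1)
        planted = {(0, 1), (1, 2), (2, 3), (3, 4)}
        for e, (i, j) in enumerate(zip(iu, ju)):
            if (int(i), int(j)) in planted:
                Y[y == 1, e] += 1.0
        est = NetworkBasedStatistic(primary_p=0.001, n_perm=200, seed=1).fit(
            stack_from_edges(Y, 10), make_cov(y), covariate_cols=())
        assert est.components_
        top = est.components_[0]
        assert set(top.edges) == planted
        assert top.p_fwe == pytest.approx(1.0 / 201.0)

    def test_no_suprathreshold_edges_empty_result(self):
        g = np.random.default_rng(4)
        y = np.repeat([1, 0], 6)
        Y = g.normal(scale=0.1, size=(12, 10))
        est = NetworkBasedStatistic(primary_p=1e-6, n_perm=100, seed=0).fit(
            stack_from_edges(Y, 5), make_cov(y), covariate_cols=())
        assert est.components_ == []

    def test_result_table_schema(self, small_study):
        _, panels, cov = small_study
        import fctopo
        z = fctopo.PearsonConnectivity().fit(panels).transform(panels)
        est = NetworkBasedStatistic(primary_p=0.2, n_perm=100, seed=2).fit(z, cov)
        table = est.result_table(panels[0].region_names)
        assert list(table.columns) == ["component", "edges", "size", "p_fwe",
                                       "significant"]


class TestAUCGroupTest:
    def test_identical_groups_give_zero_t_and_p_near_one(self):
        y = np.repeat([1, 0], 6)
        base = np.arange(6, dtype=float)
        V = pd.DataFrame({"m|a": np.concatenate([base, base]),
                          "m|b": np.concatenate([base * 2, base * 2])})
        est = AUCGroupTest(n_perm=99, seed=0).fit(V, make_cov(y))
        np.testing.assert_allclose(est.t_, 0.0, atol=1e-12)
        assert (est.p_perm_ > 0.9).all()

    def test_zero_variance_feature_excluded_from_family(self):
        g = np.random.default_rng(1)
        y = np.repeat([1, 0], 8)
        V = pd.DataFrame({"m|a": g.normal(size=16), "m|b": np.ones(16)})
        est = AUCGroupTest(n_perm=49, seed=0).fit(V, make_cov(y))
        assert np.isnan(est.t_[1]) and np.isnan(est.p_fdr_[1])
        assert est.n_excluded_ == 1
        assert np.isfinite(est.p_fdr_[0])

    def test_planted_nodal_effect_flagged(self):
        g = np.random.default_rng(5)
        y = np.repeat([1, 0], 20)
        V = pd.DataFrame(g.normal(size=(40, 12)),
                         columns=[f"m|n{i}" for i in range(12)])
        V["m|n0"] += y * 3.0
        est = AUCGroupTest(n_perm=499, seed=2).fit(V, make_cov(y))
        assert est.reject_[0]
        assert est.reject_[1:].sum() <= 2

    def test_welch_t_matches_scipy(self):
        g = np.random.default_rng(8)
        y = np.repeat([1, 0], [9, 11])
        V = pd.DataFrame({"m|a": g.normal(size=20)})
        est = AUCGroupTest(n_perm=19, seed=0).fit(V, make_cov(y))
        ref = stats.ttest_ind(V.iloc[:9, 0], V.iloc[9:, 0], equal_var=False).statistic
        assert est.t_[0] == pytest.approx(ref, abs=1e-10)


def test_upper_triangle_roundtrip():
    g = np.random.default_rng(0)
    z = g.normal(size=(3, 6, 6))
    z = (z + np.swapaxes(z, 1, 2)) / 2
    for k in range(3):
        np.fill_diagonal(z[k], 0.0)
    Y, iu, ju = upper_triangle(z)
    assert Y.shape == (3, 15)
    np.testing.assert_array_equal(Y[1], z[1][iu, ju])
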