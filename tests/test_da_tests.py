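import numpy as np
import pytest
import scipy.stats as sps

from micronorm.core_io import CountTable, GroupDesign
from micronorm.da_tests import (
    ancom_test,
    bh_adjust,
    mann_whitney_test,
    nb_glm_test,
    run_da,
    voom_test,
    welch_t_test,
    zig_test,
)
from micronorm.normalization import NormalizedTable
from micronorm.simulate import make_synthetic_template, simulate_da_dataset, split_null

from conftest import brute_force_bh


def table_from(counts, **kw):
    counts = np.asarray(counts)
    return CountTable([f"t{i}" for i in range(counts.shape[0])],
                      [f"s{j}" for j in range(counts.shape[1])], counts, **kw)


def design_for(n1, n2):
    groups = {f"s{j}": ("a" if j < n1 else "b") for j in range(n1 + n2)}
    return GroupDesign(groups)


def values_table(mat):
    mat = np.asarray(mat, dtype=float)
    return NormalizedTable([f"t{i}" for i in range(mat.shape[0])],
                           [f"s{j}" for j in range(mat.shape[1])], mat, "none")


class TestBH:
    def test_worked_example(self):
        np.testing.assert_allclose(bh_adjust(np.array([0.01, 0.02, 0.03])),
                                   [0.03, 0.03, 0.03])

    def test_single_and_boundary(self):
        assert bh_adjust(np.array([0.2]))[0] == pytest.approx(0.2)
        np.testing.assert_allclose(bh_adjust(np.ones(5)), 1.0)

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            p = rng.uniform(size=rng.integers(1, 20))
            np.testing.assert_allclose(bh_adjust(p), brute_force_bh(p), atol=1e-12)

    def test_nan_propagates_and_is_excluded_from_ranking(self):
        p = np.array([0.01, np.nan, 0.02])
        q = bh_adjust(p)
        assert np.isnan(q[1])
        np.testing.assert_allclose(q[[0, 2]], bh_adjust(np.array([0.01, 0.02])))

    def test_q_at_least_p(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=50)
        assert np.all(bh_adjust(p) >= p - 1e-12)


class TestMannWhitney:
    def test_exact_small_sample_example(self):
        res = mann_whitney_test(values_table([[1, 2, 3, 4, 5, 6]]), design_for(3, 3))
        # all low ranks in one group: U=0, exact two-sided p = 2/C(6,3) = 0.1
        assert res.table["p"].iloc[0] == pytest.approx(0.1)

    def test_identical_groups_and_constant_taxon(self):
        res = mann_whitney_test(values_table([[1, 2, 3, 1, 2, 3], [7, 7, 7, 7, 7, 7]]),
                                design_for(3, 3))
        assert np.all(res.table["p"] == 1.0)

    def test_matches_enumeration_oracle(self):
        # exact p by enumerating all assignments of values to groups
        import itertools
        vals = np.array([3.0, 1.0, 4.0, 1.5, 9.0, 2.6])
        res = mann_whitney_test(values_table([vals]), design_for(3, 3))
        obs_u = res.table["statistic"].iloc[0]

        def u_stat(a, b):
            return sum((x > y) + 0.5 * (x == y) for x in a for y in b)

        us = [u_stat(vals[list(c)], vals[[i for i in range(6) if i not in c]])
              for c in itertools.combinations(range(6), 3)]
        extreme = np.mean([min(u, 9 - u) <= min(obs_u, 9 - obs_u) for u in us])
        assert res.table["p"].iloc[0] == pytest.approx(extreme)


class TestWelch:
    def test_null_calibration(self):
        rng = np.random.default_rng(2)
        mat = rng.normal(size=(2000, 30))
        res = welch_t_test(values_table(mat), design_for(15, 15))
        rate = np.mean(res.table["p"] <= 0.05)
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / 2000)

    def test_strong_separation(self):
        rng = np.random.default_rng(3)
        mat = np.concatenate([rng.normal(0, 1, (1, 10)), rng.normal(5, 1, (1, 10))], axis=1)
        res = welch_t_test(values_table(mat), design_for(10, 10))
        assert res.table["p"].iloc[0] < 1e-4

    def test_one_group_constant_still_finite(self):
        res = welch_t_test(values_table([[2, 2, 2, 1.0, 3.0, 5.0]]), design_for(3, 3))
        assert np.isfinite(res.table["statistic"].iloc[0])

    def test_both_groups_constant(self):
        res = welch_t_test(values_table([[2, 2, 2, 2, 2, 2], [1, 1, 1, 3, 3, 3]]),
                           design_for(3, 3))
        assert res.table["p"].iloc[0] == 1.0
        assert res.table["p"].iloc[1] == 0.0


from conftest import brute_force_ancom_w


class TestANCOM:
    def test_two_taxa_symmetry(self):
        rng = np.random.default_rng(4)
        t = table_from(rng.poisson(10, size=(2, 12)))
        res = ancom_test(t, design_for(6, 6))
        w = res.table["statistic"].to_numpy()
        assert w[0] == w[1] and w[0] in (0.0, 1.0)

    def test_w_matches_brute_force_all_pairs(self):
        rng = np.random.default_rng(5)
        counts = rng.poisson(6, size=(15, 20))
        counts[0, :10] *= 6  # one shifted taxon
        t = table_from(counts)
        design = design_for(10, 10)
        res = ancom_test(t, design)
        oracle = brute_force_ancom_w(t, design)
        np.testing.assert_array_equal(res.table["statistic"].to_numpy(), oracle)

    def test_w_bounds_and_default_pseudocount(self):
        rng = np.random.default_rng(6)
        t = table_from(rng.poisson(3, size=(10, 16)))
        res = ancom_test(t, design_for(8, 8))
        w = res.table["statistic"].to_numpy()
        assert np.all((w >= 0) & (w <= t.n_taxa - 1))
        assert res.params["pseudocount"] == 0.001

    def test_inflated_taxon_attains_max_w(self):
        tpl = make_synthetic_template(30, 0.5, seed=7, reference_depth=500)
        rng = np.random.default_rng(8)
        pi = tpl.proportions
        counts = np.column_stack([rng.multinomial(500, pi) for _ in range(50)])
        counts[1, :25] *= 8  # taxon 1 up 8x in group a
        t = table_from(counts)
        res = ancom_test(t, design_for(25, 25))
        w = res.table["statistic"].to_numpy()
        assert w[1] == w.max() and w[1] > 0

    def test_contracts(self):
        t = table_from([[1, 2], [3, 4]])
        with pytest.raises(ValueError):
            ancom_test(t, design_for(1, 1), pseudocount=-1)
        with pytest.raises(ValueError):
            ancom_test(table_from([[1, 2, 3, 4]]), design_for(2, 2))


class TestNBGLM:
    def _nb_null(self, m=600, n=20, seed=9):
        rng = np.random.default_rng(seed)
        means = rng.lognormal(2.0, 1.5, size=m)
        disp = 0.4
        counts = rng.negative_binomial(1 / disp, 1 / (1 + disp * means[:, None]),
                                       size=(m, 2 * n))
        return table_from(counts), design_for(n, n)

    def test_type_one_error_on_nb_null(self):
        t, design = self._nb_null()
        res = nb_glm_test(t, design, mode="wald", shrink_lfc=False)
        p = res.table["p"].dropna()
        rate = np.mean(p <= 0.05)
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / len(p))

    def test_sign_recovery_under_true_fold_change(self):
        rng = np.random.default_rng(10)
        hits = 0
        reps = 200
        for _ in range(reps):
            mean_b = 20.0
            disp = 0.3
            counts = np.concatenate([
                rng.negative_binomial(1 / disp, 1 / (1 + disp * 4 * mean_b), size=10),
                rng.negative_binomial(1 / disp, 1 / (1 + disp * mean_b), size=10),
            ])[None, :]
            filler = rng.poisson(15, size=(20, 20))
            t = table_from(np.vstack([counts, filler]))
            res = nb_glm_test(t, design_for(10, 10), mode="wald", shrink_lfc=False,
                              size_factors=np.ones(20))
            hits += res.table["lfc"].iloc[0] > 0
        assert hits / reps >= 0.95

    def test_shrinkage_pulls_low_count_lfc_toward_zero(self):
        rng = np.random.default_rng(11)
        counts = rng.poisson(2, size=(100, 16))
        counts[:5] = rng.poisson(1, size=(5, 16))
        t = table_from(counts + (counts.sum(axis=1) == 0).astype(int)[:, None])
        shrunk = nb_glm_test(t, design_for(8, 8), mode="wald", shrink_lfc=True)
        raw = nb_glm_test(t, design_for(8, 8), mode="wald", shrink_lfc=False)
        a = shrunk.table["lfc"].abs().to_numpy()
        b = raw.table["lfc"].abs().to_numpy()
        ok = np.isfinite(a) & np.isfinite(b)
        assert np.all(a[ok] <= b[ok] + 1e-9)

    def test_exact_mode_null_calibration(self):
        t, design = self._nb_null(m=400, seed=12)
        res = nb_glm_test(t, design, mode="exact")
        p = res.table["p"].dropna()
        rate = np.mean(p <= 0.05)
        # conditional test is conservative-to-nominal on null NB data
        assert rate < 0.05 + 3 * np.sqrt(0.05 * 0.95 / len(p))

    def test_all_zero_taxon_gets_nan(self):
        counts = np.vstack([np.zeros(12, dtype=int), np.ones(12, dtype=int) * 5])
        res = nb_glm_test(table_from(counts), design_for(6, 6))
        assert np.isnan(res.table["p"].iloc[0])

    def test_pseudocount_inflates_type_one_on_uneven_null(self):
        # adding +1 to every cell before an NB test on depth-uneven null data
        # raises the false-positive rate relative to the raw pipeline
        tpl = make_synthetic_template(300, 0.85, seed=13)
        rng = np.random.default_rng(14)
        depths = np.concatenate([rng.integers(1500, 2500, 20),
                                 rng.integers(15000, 25000, 20)])
        counts = np.column_stack([rng.multinomial(d, tpl.proportions) for d in depths])
        raw = table_from(counts)
        plus1 = table_from(counts + 1)
        design = design_for(20, 20)
        r_raw = nb_glm_test(raw, design, mode="wald", shrink_lfc=False)
        r_ps = nb_glm_test(plus1, design, mode="wald", shrink_lfc=False)
        rate_raw = np.mean(r_raw.table["q"].dropna() <= 0.05)
        rate_ps = np.mean(r_ps.table["q"].dropna() <= 0.05)
        assert rate_ps > rate_raw


class TestVoom:
    def test_null_calibration(self):
        rng = np.random.default_rng(15)
        counts = rng.poisson(rng.lognormal(3, 1, size=(500, 1)), size=(500, 24))
        res = voom_test(table_from(counts), design_for(12, 12))
        p = res.table["p"].dropna()
        rate = np.mean(p <= 0.05)
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / len(p)) + 0.01

    def test_flat_trend_weights_near_constant(self):
        rng = np.random.default_rng(16)
        counts = rng.poisson(1000, size=(200, 12))  # homoskedastic log-counts
        res = voom_test(table_from(counts), design_for(6, 6))
        t_mod = res.table["statistic"].to_numpy()
        y = np.log2((counts + 0.5) / (counts.sum(0) + 1)[None, :] * 1e6)
        t_ord = sps.ttest_ind(y[:, :6], y[:, 6:], axis=1).statistic
        r = np.corrcoef(t_mod, t_ord)[0, 1]
        assert r > 0.95

    def test_all_zero_taxon_nan(self):
        counts = np.vstack([np.zeros(12, dtype=int), np.full(12, 40)])
        res = voom_test(table_from(counts), design_for(6, 6))
        assert np.isnan(res.table["p"].iloc[0])

    def test_needs_three_per_group(self):
        with pytest.raises(ValueError):
            voom_test(table_from(np.ones((3, 4), dtype=int)), design_for(2, 2))


class TestZIG:
    def test_no_zeros_reduces_to_moderated_t(self):
        rng = np.random.default_rng(17)
        counts = rng.poisson(300, size=(100, 16)) + 1
        t = table_from(counts)
        res = zig_test(t, design_for(8, 8))
        # no zero cells -> no zero-inflation: weights are 1 and the statistic
        # correlates essentially perfectly with an ordinary t on log values
        from micronorm.normalization import css_normalize
        yv = np.log2(css_normalize(t).values + 1)
        t_ord = sps.ttest_ind(yv[:, :8], yv[:, 8:], axis=1).statistic
        r = np.corrcoef(res.table["statistic"], t_ord)[0, 1]
        assert r > 0.97

    def test_em_loglik_non_decreasing(self, sparse_table, two_group_design):
        res = zig_test(sparse_table, two_group_design)
        ll = np.array(res.params["log_likelihood"])
        assert np.all(np.diff(ll) >= -1e-6 * np.abs(ll[:-1]))

    def test_zero_model_tracks_library_size(self):
        # the point-mass probability must decrease with log library size:
        # that dependence is the model's whole account of depth-driven zeros
        tpl = make_synthetic_template(250, 0.9, seed=18)
        rng = np.random.default_rng(200)
        depths = rng.permutation(np.concatenate([rng.integers(400, 700, 15),
                                                 rng.integers(8000, 12000, 15)]))
        counts = np.column_stack([rng.multinomial(d, tpl.proportions) for d in depths])
        res = zig_test(table_from(counts), design_for(15, 15))
        assert res.params["zero_model"][1] < 0

    def test_type_one_inflates_when_groups_confound_depth(self):
        # library-size dependence cuts both ways: on an even-depth random
        # null the test is near nominal, but when the two groups differ 10x
        # in depth the zero model attributes depth artifacts to the group
        # effect and the false-positive rate blows up
        tpl = make_synthetic_template(250, 0.9, seed=18)
        rates = {}
        for confounded in (False, True):
            rs = []
            for seed in (300, 301, 302):
                rng = np.random.default_rng(seed)
                base = np.concatenate([rng.integers(400, 700, 15),
                                       rng.integers(8000, 12000, 15)])
                depths = base if confounded else rng.permutation(base)
                counts = np.column_stack([rng.multinomial(d, tpl.proportions)
                                          for d in base * 0 + depths])
                res = zig_test(table_from(counts), design_for(15, 15))
                rs.append(np.mean(res.table["p"].dropna() <= 0.05))
            rates[confounded] = np.mean(rs)
        assert rates[False] < 0.12
        assert rates[True] > 2 * rates[False]


class TestRunDA:
    def test_rarefy_then_mann_whitney_pipeline(self, sparse_table, two_group_design):
        res = run_da(sparse_table, two_group_design, "mann_whitney",
                     normalization="rarefy",
                     norm_params={"depth": int(sparse_table.library_sizes().min()),
                                  "seed": 0})
        assert res.params["normalization"] == "rarefy"
        assert len(res.table) == sparse_table.n_taxa

    @pytest.mark.parametrize("norm", ["none", "proportion"])
    def test_t_test_routings(self, sparse_table, two_group_design, norm):
        res = run_da(sparse_table, two_group_design, "welch_t", normalization=norm)
        assert res.method == "welch_t"

    def test_count_models_reject_transformed_input(self, sparse_table, two_group_design):
        with pytest.raises(ValueError):
            run_da(sparse_table, two_group_design, "ancom", normalization="proportion")

    def test_zig_on_rarefied_is_flagged(self, sparse_table, two_group_design):
        res = run_da(sparse_table, two_group_design, "zig", normalization="rarefy",
                     norm_params={"depth": int(sparse_table.library_sizes().min()),
                                  "seed": 0})
        assert "library_size_warning" in res.params

    def test_unknown_method_rejected(self, sparse_table, two_group_design):
        with pytest.raises(ValueError):
            run_da(sparse_table, two_group_design, "kruskal")
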