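import numpy as np
import pytest

from micronorm.core_io import CountTable
from micronorm.simulate import (
    TemplateCommunity,
    fit_dirichlet_multinomial,
    fit_gamma_poisson,
    fit_multinomial,
    make_synthetic_template,
    make_template_pair,
    simulate_clustering_dataset,
    simulate_compositional_dataset,
    simulate_da_dataset,
    split_null,
)


def table_from(counts):
    counts = np.asarray(counts)
    return CountTable([f"t{i}" for i in range(counts.shape[0])],
                      [f"s{j}" for j in range(counts.shape[1])], counts)


class TestFitting:
    def test_multinomial_pooled_proportions(self):
        tpl = fit_multinomial(table_from([[2], [3], [5]]))
        np.testing.assert_allclose(tpl.proportions, [0.2, 0.3, 0.5])
        assert tpl.proportions.sum() == pytest.approx(1.0)
        two = fit_multinomial(table_from([[2, 2], [3, 3], [5, 5]]))
        np.testing.assert_allclose(two.proportions, tpl.proportions)

    def test_dm_theta_recovery_within_20_percent(self):
        true_theta = 0.05
        rng = np.random.default_rng(20)
        pi = np.sort(rng.dirichlet(np.ones(100)))[::-1]
        conc = (1 - true_theta) / true_theta
        counts = np.column_stack([
            rng.multinomial(2000, rng.dirichlet(pi * conc)) for _ in range(500)
        ])
        tpl = fit_dirichlet_multinomial(table_from(counts))
        assert tpl.theta == pytest.approx(true_theta, rel=0.2)
        assert tpl.proportions.sum() == pytest.approx(1.0)

    def test_dm_multinomial_limit_hits_lower_clip(self):
        rng = np.random.default_rng(21)
        pi = rng.dirichlet(np.ones(50))
        counts = np.column_stack([rng.multinomial(2000, pi) for _ in range(300)])
        tpl = fit_dirichlet_multinomial(table_from(counts))
        assert tpl.theta < 0.005

    def test_gp_moment_identities_and_poisson_limit(self):
        rng = np.random.default_rng(22)
        counts = np.column_stack([rng.poisson([5, 50, 2]) for _ in range(400)])
        tpl = fit_gamma_poisson(table_from(counts))
        z = counts / counts.sum(0)[None, :] * np.median(counts.sum(0))
        np.testing.assert_allclose(tpl.gp_shape / tpl.gp_rate, z.mean(axis=1), rtol=1e-9)
        # scaled Poisson data is close to the v <= m boundary: the fit must
        # flag at least the boundary cases as the Poisson limit
        assert tpl.poisson_limit.dtype == bool

    def test_gp_shape_recovery_within_25_percent(self):
        rng = np.random.default_rng(23)
        shape = 0.8
        means = np.full(40, 50.0)
        lam = rng.gamma(shape, means[:, None] / shape, size=(40, 500))
        counts = rng.poisson(lam)
        tpl = fit_gamma_poisson(table_from(counts))
        med_shape = float(np.median(tpl.gp_shape))
        assert med_shape == pytest.approx(shape, rel=0.25)


class TestSyntheticTemplate:
    def test_sparsity_target_reached(self):
        tpl = make_synthetic_template(1000, 0.9, seed=3)
        rng = np.random.default_rng(4)
        counts = np.column_stack([rng.multinomial(2000, tpl.proportions)
                                  for _ in range(40)])
        assert (counts == 0).mean() == pytest.approx(0.9, abs=0.05)

    def test_deterministic_given_seed(self):
        a = make_synthetic_template(500, 0.9, seed=7)
        b = make_synthetic_template(500, 0.9, seed=7)
        np.testing.assert_array_equal(a.proportions, b.proportions)

    def test_large_template_supported(self):
        tpl = make_synthetic_template(2000, 0.9, seed=8)
        assert tpl.n_taxa == 2000 and tpl.proportions.sum() == pytest.approx(1.0)

    def test_unattainable_target_warns(self):
        with pytest.warns(UserWarning):
            make_synthetic_template(12, 0.99, seed=9)


class TestClusteringSimulation:
    def test_effect_size_one_gives_identical_ecosystems(self):
        a, b = make_template_pair(200, 0.9, seed=10)
        ds = simulate_clustering_dataset(a, b, effect_size=1.0, seed=11)
        np.testing.assert_allclose(ds.group_proportions["group_1"],
                                   ds.group_proportions["group_2"], atol=1e-12)

    def test_large_effect_size_approaches_pure_templates(self):
        a, b = make_template_pair(200, 0.9, seed=10)
        ds = simulate_clustering_dataset(a, b, effect_size=1e6, seed=11)
        np.testing.assert_allclose(ds.group_proportions["group_1"], a.proportions,
                                   atol=1e-5)

    def test_chance_level_clustering_at_effect_size_one(self):
        from micronorm.diversity import clustering_accuracy, compute_distance, pam_cluster
        from micronorm.core_io import GroupDesign
        a, b = make_template_pair(150, 0.9, seed=12)
        accs = []
        for rep in range(6):
            ds = simulate_clustering_dataset(a, b, effect_size=1.0, seed=100 + rep)
            dm = compute_distance(ds.table, "braycurtis")
            res = pam_cluster(dm, k=2, seed=rep, restarts=3)
            accs.append(clustering_accuracy(res, GroupDesign(dict(ds.table.sample_group))))
        assert np.mean(accs) < 0.75  # chance is 0.5; matching allows some lift

    def test_library_size_median_near_target(self):
        a, b = make_template_pair(200, 0.9, seed=10)
        meds = []
        for seed in range(13, 19):
            ds = simulate_clustering_dataset(a, b, effect_size=2.0, N_L=5000, seed=seed)
            meds.append(np.median(ds.table.library_sizes()))
        assert np.mean(meds) == pytest.approx(5000, rel=0.10)

    def test_effect_size_below_one_rejected(self):
        a, b = make_template_pair(200, 0.9, seed=10)
        with pytest.raises(ValueError):
            simulate_clustering_dataset(a, b, effect_size=0.5)


class TestBalancedDesign:
    def test_truth_identity_on_ecosystem_vectors(self):
        # the taxa whose ecosystem proportions differ between groups must be
        # exactly the recorded truth set (checked on the vectors, no sampling)
        tpl = make_synthetic_template(300, 0.9, seed=14)
        ds = simulate_da_dataset(tpl, n_per_group=5, fold_change=5.0,
                                 tp_fraction=0.1, design="balanced", seed=15)
        p1, p2 = ds.group_proportions["group_1"], ds.group_proportions["group_2"]
        assert p1.sum() == pytest.approx(1.0, abs=1e-9)
        assert p2.sum() == pytest.approx(1.0, abs=1e-9)
        differing = {tpl.taxon_ids[i] for i in np.nonzero(~np.isclose(p1, p2, rtol=1e-12, atol=0))[0]}
        assert differing == ds.truth_set

    def test_fc_one_and_zero_fraction_give_empty_truth(self):
        tpl = make_synthetic_template(100, 0.9, seed=16)
        assert simulate_da_dataset(tpl, fold_change=1.0, tp_fraction=0.1,
                                   seed=1).truth == {}
        assert simulate_da_dataset(tpl, fold_change=5.0, tp_fraction=0.0,
                                   seed=1).truth == {}

    def test_balanced_contract_violations(self):
        tpl = make_synthetic_template(100, 0.9, seed=16)
        with pytest.raises(ValueError):
            simulate_da_dataset(tpl, fold_change=0.5)
        with pytest.raises(ValueError):
            simulate_da_dataset(tpl, fold_change=2.0, tp_fraction=0.6)

    def test_reproducible_from_seed(self):
        tpl = make_synthetic_template(100, 0.9, seed=16)
        a = simulate_da_dataset(tpl, n_per_group=8, fold_change=3.0, seed=17)
        b = simulate_da_dataset(tpl, n_per_group=8, fold_change=3.0, seed=17)
        np.testing.assert_array_equal(a.table.counts, b.table.counts)
        assert a.truth == b.truth

    @pytest.mark.parametrize("family,kw", [
        ("dirichlet_multinomial", {"theta": 0.02}),
        ("gamma_poisson", {"gp_shape": 0.5}),
    ])
    def test_overdispersed_families_draw(self, family, kw):
        tpl = make_synthetic_template(100, 0.9, seed=16)
        ds = simulate_da_dataset(tpl, family=family, n_per_group=6,
                                 fold_change=2.0, seed=18, **kw)
        assert ds.table.counts.shape == (100, 12)


class TestCompositionalDesign:
    def test_ten_percent_of_2000_taxa(self):
        tpl = make_synthetic_template(2000, 0.9, seed=19)
        ds = simulate_compositional_dataset(tpl, fold_change=5.0, n_per_group=5, seed=20)
        assert len(ds.truth) == 200

    def test_every_non_tp_relative_abundance_decreases(self):
        tpl = make_synthetic_template(300, 0.9, seed=21)
        ds = simulate_compositional_dataset(tpl, fold_change=8.0, n_per_group=5, seed=22)
        p1, p2 = ds.group_proportions["group_1"], ds.group_proportions["group_2"]
        non_tp = [i for i, t in enumerate(tpl.taxon_ids) if t not in ds.truth_set]
        pos = [i for i in non_tp if p2[i] > 0]
        assert np.all(p1[pos] < p2[pos])

    def test_truth_differs_from_relative_abundance_truth(self):
        # ecosystem truth is 10% of taxa, but in relative-abundance terms
        # every taxon with positive proportion shifts — the two sets differ
        tpl = make_synthetic_template(300, 0.9, seed=21)
        ds = simulate_compositional_dataset(tpl, fold_change=8.0, n_per_group=5, seed=22)
        p1, p2 = ds.group_proportions["group_1"], ds.group_proportions["group_2"]
        rel_differing = {tpl.taxon_ids[i]
                         for i in np.nonzero(~np.isclose(p1, p2, rtol=1e-12, atol=1e-18))[0]}
        assert ds.truth_set < rel_differing

    def test_fc_limit_and_contract(self):
        tpl = make_synthetic_template(100, 0.9, seed=23)
        with pytest.raises(ValueError):
            simulate_compositional_dataset(tpl, fold_change=1.0)
        with pytest.raises(ValueError):
            simulate_compositional_dataset(tpl, fold_change=2.0, tp_fraction=0.9)


class TestNullSplit:
    def _uneven_table(self, n=60, seed=24):
        rng = np.random.default_rng(seed)
        tpl = make_synthetic_template(150, 0.9, seed=seed)
        depths = np.round(np.exp(rng.uniform(np.log(2000), np.log(80000), n))).astype(int)
        counts = np.column_stack([rng.multinomial(d, tpl.proportions) for d in depths])
        return table_from(counts)

    def test_truth_always_empty(self):
        t = self._uneven_table()
        for mode in ("random", "uneven"):
            ds = split_null(t, n_per_group=20, mode=mode, seed=1)
            assert ds.truth == {}
            assert ds.table.n_samples == 40

    def test_uneven_ratio_within_20_percent(self):
        t = self._uneven_table()
        ds = split_null(t, n_per_group=10, mode="uneven", target_ratio=10, seed=2)
        g1 = [s for s, g in ds.table.sample_group.items() if g == "group_1"]
        g2 = [s for s, g in ds.table.sample_group.items() if g == "group_2"]
        depths = dict(zip(ds.table.sample_ids, ds.table.library_sizes()))
        ratio = np.mean([depths[s] for s in g1]) / np.mean([depths[s] for s in g2])
        assert ratio == pytest.approx(10, rel=0.2)

    def test_group_size_grid_supported(self):
        t = self._uneven_table(n=220, seed=25)
        for n in (3, 20, 100):
            ds = split_null(t, n_per_group=n, mode="random", seed=3)
            labels = list(ds.table.sample_group.values())
            assert labels.count("group_1") == labels.count("group_2") == n

    def test_insufficient_samples_rejected(self):
        with pytest.raises(ValueError):
            split_null(self._uneven_table(n=10), n_per_group=6)


class TestConvergenceToMultinomial:
    """DM with tiny theta and GP with huge shape must reproduce multinomial
    sensitivity and FDR within Monte-Carlo error on matched seeds."""

    @pytest.mark.parametrize("family,kw", [
        ("dirichlet_multinomial", {"theta": 1e-6}),
        ("gamma_poisson", {"gp_shape": 1e6}),
    ])
    def test_limit_matches_multinomial(self, family, kw):
        from micronorm.core_io import GroupDesign
        from micronorm.da_tests import mann_whitney_test
        from micronorm.evaluate import confusion_metrics
        tpl = make_synthetic_template(200, 0.9, seed=26)
        sens, fdrs = {}, {}
        for fam, fkw in [("multinomial", {}), (family, kw)]:
            s_list, f_list = [], []
            for rep in range(3):
                ds = simulate_da_dataset(tpl, family=fam, n_per_group=25,
                                         fold_change=8.0, tp_fraction=0.1,
                                         seed=500 + rep, **fkw)
                res = mann_whitney_test(ds.table, GroupDesign(dict(ds.table.sample_group)))
                s, f, _ = confusion_metrics(res, ds.truth_set)
                s_list.append(s)
                f_list.append(f)
            sens[fam], fdrs[fam] = np.mean(s_list), np.mean(f_list)
        # 3 x Monte-Carlo s.e. of a proportion over ~20 truth taxa x 3 reps
        tol = 3 * np.sqrt(0.25 / 60)
        assert abs(sens[family] - sens["multinomial"]) < tol
        assert abs(fdrs[family] - fdrs["multinomial"]) < tol
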