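"""Family-aware splits, internal CV, model selection and both protocols."""

import numpy as np
import pytest

from l1l2pheno import (
    CohortSpec,
    GridPoint,
    L1L2Hyperparams,
    RidgePlugin,
    SolverSettings,
    impute_missing,
    make_grid,
    make_interfamily_splits,
    run_bootstrap_dap,
    run_internal_cv,
    run_l1l2_dap,
    select_model,
    shuffle_phenotype,
    simulate_cohort,
    squared_correlation,
    tau_max,
)
from l1l2pheno.genotype_data import PhenotypeVector

SETTINGS = SolverSettings(tolerance=1e-5)


def _grid_for(g, ph, n_tau=3):
    tmax = tau_max(g.values, ph.values)
    return make_grid([1e-2, 1e-1], tmax * np.array([0.3, 0.12, 0.05])[:n_tau], [1.0, 10.0])


class TestInterfamilySplits:
    def test_equal_families_get_exact_fraction(self):
        fams = [f"f{i}" for i in range(10) for _ in range(4)]
        plan = make_interfamily_splits(fams, n_resamplings=5, dev_fraction=0.7, k_folds=3, seed=0)
        for r in range(5):
            assert len(plan.dev_families[r]) == 7
            assert len(plan.val_families[r]) == 3

    def test_partition_and_no_overlap(self, small_cohort):
        g, _, _ = small_cohort
        plan = make_interfamily_splits(g.family_ids, n_resamplings=4, k_folds=5, seed=3)
        for r in range(4):
            assert not (set(plan.dev_families[r]) & set(plan.val_families[r]))
            dev, val, folds = plan.indices(g.family_ids, r)
            assert np.intersect1d(dev, val).size == 0
            assert dev.size + val.size == g.n_samples
            # folds partition the development set
            assert folds.size == dev.size
            # no family straddles folds
            fam = np.asarray(g.family_ids)[dev]
            for f in np.unique(fam):
                assert np.unique(folds[fam == f]).size == 1

    def test_determinism(self, small_cohort):
        g, _, _ = small_cohort
        a = make_interfamily_splits(g.family_ids, n_resamplings=3, seed=9)
        b = make_interfamily_splits(g.family_ids, n_resamplings=3, seed=9)
        assert a.dev_families == b.dev_families
        assert a.fold_of_family == b.fold_of_family

    def test_single_giant_family_errors(self):
        fams = ["big"] * 30 + ["small"] * 2
        with pytest.raises(ValueError, match="big"):
            make_interfamily_splits(fams, dev_fraction=0.7)


class TestSquaredCorrelation:
    def test_perfect_and_sign_flip(self, rng):
        y = rng.standard_normal(50)
        assert squared_correlation(y, y) == pytest.approx(1.0)
        assert squared_correlation(y, -y + 3.0) == pytest.approx(1.0)

    def test_constant_prediction_scores_zero(self, rng):
        y = rng.standard_normal(20)
        assert squared_correlation(y, np.full(20, 2.5)) == 0.0

    def test_short_input_rejected(self):
        with pytest.raises(ValueError):
            squared_correlation(np.array([1.0]), np.array([2.0]))


class TestInternalCV:
    def test_single_point_mse_matches_manual_loop(self, small_cohort):
        from l1l2pheno.l1l2 import fit_l1l2, predict

        g, ph, _ = small_cohort
        plan = make_interfamily_splits(g.family_ids, n_resamplings=1, k_folds=4, seed=2)
        dev, _, folds = plan.indices(g.family_ids, 0)
        X, y = g.values[dev], ph.values[dev]
        h = L1L2Hyperparams(0.1, 0.4 * tau_max(X, y), 1.0)
        [gp] = run_internal_cv(X, y, g.snp_names, folds, [h], SETTINGS)
        manual = []
        for k in np.unique(folds):
            m = fit_l1l2(X[folds != k], y[folds != k], h, SETTINGS, feature_names=g.snp_names)
            manual.append(np.mean((y[folds == k] - predict(m, X[folds == k])) ** 2))
        assert gp.cv_mse == pytest.approx(np.mean(manual), rel=1e-6)

    def test_support_recovery_on_strong_signal(self):
        # noiseless 2-sparse trait: the best-MSE grid point finds the true
        # SNPs in nearly every fold
        spec = CohortSpec(n_families=40, samples_per_family=4, n_snps=60, n_chromosomes=2,
                          ld_block_size=6, n_causal=2, heritability=0.95,
                          missing_rate=0.0, seed=5)
        g, ph, truth = simulate_cohort(spec)
        plan = make_interfamily_splits(g.family_ids, n_resamplings=1, k_folds=10, seed=5)
        dev, _, folds = plan.indices(g.family_ids, 0)
        X, y = g.values[dev], ph.values[dev]
        grid = make_grid([1e-2], tau_max(X, y) * np.array([0.5, 0.2, 0.05]), [1e-2])
        points = run_internal_cv(X, y, g.snp_names, folds, grid, SETTINGS)
        best = min(points, key=lambda p: p.cv_mse)
        # refit per fold at the winning point and count truth recovery
        from l1l2pheno.l1l2 import fit_l1l2

        causal_names = {g.snp_names[j] for j in truth.causal_indices}
        causal_blocks = set(truth.block_of_snp[truth.causal_indices])
        hits = 0
        for k in np.unique(folds):
            m = fit_l1l2(X[folds != k], y[folds != k], best.hyperparams, SETTINGS,
                         feature_names=g.snp_names)
            sel_blocks = set(truth.block_of_snp[m.support])
            if causal_blocks <= sel_blocks:
                hits += 1
        assert hits >= 9

    def test_empty_grid_rejected(self, small_cohort):
        g, ph, _ = small_cohort
        with pytest.raises(ValueError):
            run_internal_cv(g.values, ph.values, g.snp_names, np.zeros(g.n_samples), [])


class TestSelectModel:
    def _gp(self, mu, tau, lam, mse, stab):
        return GridPoint(L1L2Hyperparams(mu, tau, lam), mse, stab)

    def test_single_point(self):
        gp = self._gp(0.1, 1.0, 1.0, 2.0, 0.5)
        assert select_model([gp]) == gp.hyperparams

    def test_stability_breaks_near_ties(self):
        a = self._gp(0.1, 1.0, 1.0, 2.00, 0.5)
        b = self._gp(0.1, 2.0, 1.0, 2.00, 0.2)
        assert select_model([a, b]) == b.hyperparams

    def test_zero_tolerance_is_pure_argmin(self):
        a = self._gp(0.1, 1.0, 1.0, 1.0, 0.9)
        b = self._gp(0.1, 2.0, 1.0, 1.04, 0.1)
        assert select_model([a, b], mse_tolerance_fraction=0.0) == a.hyperparams

    def test_invariant_to_input_order(self, rng):
        pts = [
            self._gp(float(m), float(t), float(l), float(mse), float(s))
            for m, t, l, mse, s in rng.random((12, 5)) + 0.01
        ]
        picks = set()
        for _ in range(6):
            order = rng.permutation(len(pts))
            picks.add(select_model([pts[i] for i in order]))
        assert len(picks) == 1


@pytest.fixture(scope="module")
def dap_cohort():
    spec = CohortSpec(n_families=60, samples_per_family=3, n_snps=250, n_chromosomes=3,
                      ld_block_size=10, n_causal=4, heritability=0.55,
                      maf_range=(0.2, 0.5), effect_size_range=(0.5, 2.0), seed=17)
    g, ph, truth = simulate_cohort(spec)
    return impute_missing(g, seed=17), ph, truth


class TestL1L2Dap:
    def test_heritable_trait_beats_shuffled_control(self, dap_cohort):
        g, ph, _ = dap_cohort
        plan = make_interfamily_splits(g.family_ids, n_resamplings=3, k_folds=4, seed=1)
        res = run_l1l2_dap(g, ph, plan, _grid_for(g, ph), SETTINGS)
        assert all(0.0 <= r <= 1.0 for r in res.r2)
        shuf = shuffle_phenotype(ph, seed=2)
        res0 = run_l1l2_dap(g, shuf, plan, _grid_for(g, shuf), SETTINGS)
        assert res.mean_r2 > res0.mean_r2 + 0.05
        assert res.accuracy_stability.shape[0] == 3 * 12

    def test_end_to_end_determinism(self, dap_cohort):
        g, ph, _ = dap_cohort
        plan = make_interfamily_splits(g.family_ids, n_resamplings=2, k_folds=3, seed=4)
        grid = _grid_for(g, ph, n_tau=2)
        a = run_l1l2_dap(g, ph, plan, grid, SETTINGS)
        b = run_l1l2_dap(g, ph, plan, grid, SETTINGS)
        assert a.r2 == b.r2
        assert a.selected == b.selected
        for wa, wb in zip(a.weight_vectors, b.weight_vectors):
            np.testing.assert_array_equal(wa, wb)

    def test_family_leakage_inflates_accuracy(self, dap_cohort):
        # deliberately corrupt the split: clone validation families into
        # development -> relatives on both sides must inflate r^2
        g, ph, _ = dap_cohort
        plan = make_interfamily_splits(g.family_ids, n_resamplings=3, k_folds=4, seed=6)
        clean = run_l1l2_dap(g, ph, plan, _grid_for(g, ph, n_tau=2), SETTINGS)
        leaky_r2 = []
        from l1l2pheno.l1l2 import fit_l1l2, predict

        for r in range(3):
            dev, val, _ = plan.indices(g.family_ids, r)
            corrupt_dev = np.concatenate([dev, val])  # every val sample leaks
            h = clean.selected[r]
            m = fit_l1l2(g.values[corrupt_dev], ph.values[corrupt_dev], h, SETTINGS,
                         feature_names=g.snp_names)
            leaky_r2.append(squared_correlation(ph.values[val], predict(m, g.values[val])))
        assert np.mean(leaky_r2) > clean.mean_r2

    def test_missing_calls_rejected(self, small_cohort):
        spec = CohortSpec(n_families=10, samples_per_family=3, n_snps=40, n_causal=3,
                          missing_rate=0.05, seed=3)
        g, ph, _ = simulate_cohort(spec)
        plan = make_interfamily_splits(g.family_ids, n_resamplings=1, k_folds=2, seed=0)
        with pytest.raises(ValueError, match="impute"):
            run_l1l2_dap(g, ph, plan, [L1L2Hyperparams(0.1, 0.5, 1.0)], SETTINGS)


class TestBootstrapDap:
    def test_linear_plugin_recovers_sparse_noiseless_trait(self):
        spec = CohortSpec(n_families=50, samples_per_family=3, n_snps=40, n_chromosomes=2,
                          ld_block_size=5, n_causal=2, heritability=0.99,
                          missing_rate=0.0, seed=8)
        g, ph, _ = simulate_cohort(spec)
        res = run_bootstrap_dap(g, ph, RidgePlugin(), [{"alpha": 0.1}, {"alpha": 10.0}],
                                n_grid_bootstraps=3, n_eval_bootstraps=5, seed=0)
        assert res.mean_r2 > 0.95
        assert res.selection_bias_prone
        assert len(res.r2) == 5

    def test_single_param_grid_trivial_selection(self, dap_cohort):
        g, ph, _ = dap_cohort
        res = run_bootstrap_dap(g, ph, RidgePlugin(), [{"alpha": 5.0}],
                                n_grid_bootstraps=2, n_eval_bootstraps=4, seed=1)
        assert res.selected == [{"alpha": 5.0}] * 4
        assert len(res.r2) == 4

    def test_same_seed_identical(self, dap_cohort):
        g, ph, _ = dap_cohort
        args = dict(n_grid_bootstraps=2, n_eval_bootstraps=3, seed=11)
        a = run_bootstrap_dap(g, ph, RidgePlugin(), [{"alpha": 1.0}], **args)
        b = run_bootstrap_dap(g, ph, RidgePlugin(), [{"alpha": 1.0}], **args)
        assert a.r2 == b.r2
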