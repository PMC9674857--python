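import numpy as np
import pytest
from scipy.linalg import eigh

from kinstack.genotypes import simulate_genotypes, filter_by_maf
from kinstack.gblup import fit_gblup, predict_gblup, select_kernels
from kinstack.kinship import KinshipMatrix, additive_kinship, build_kinship_set, dominance_kinship
from kinstack.simulate import scenario_preset, simulate_scenario


def _identity_kernel(n):
    return KinshipMatrix(np.eye(n), "A", [f"s{i}" for i in range(n)], "gt5pct")


@pytest.fixture(scope="module")
def kinships(small_panel):
    return [k for k in build_kinship_set(small_panel) if k.maf_tag == "gt5pct"]


class TestSelectKernels:
    @pytest.mark.parametrize(
        "scenario,expected",
        [
            ("S1", ["A"]),
            ("S3", ["A", "D"]),
            ("S5", ["D"]),
            ("S8", ["A", "D", "DD"]),
            ("S9", ["A", "D", "AA", "AD", "DD"]),
        ],
    )
    def test_active_effects_pick_matching_kernels(self, kinships, scenario, expected):
        cfg = scenario_preset(scenario, qtn=10)
        assert [k.rel_type for k in select_kernels(cfg, kinships)] == expected

    def test_missing_kernel_type_rejected(self, kinships):
        cfg = scenario_preset("S9", qtn=10)
        with pytest.raises(ValueError, match="lacks"):
            select_kernels(cfg, [k for k in kinships if k.rel_type == "A"])


class TestFitGblup:
    def test_identity_kernel_predicts_observed_mean(self):
        rng = np.random.default_rng(0)
        n = 60
        y = rng.normal(2.0, 1.0, n)
        ymiss = y.copy()
        ymiss[:10] = np.nan
        fit = fit_gblup(ymiss, [_identity_kernel(n)], n_iter=3000, burn_in=500, seed=1)
        preds = predict_gblup(fit, [f"s{i}" for i in range(10)])
        obs_mean = y[10:].mean()
        # exchangeable samples carry no information: predictions ~ the mean
        assert np.abs(preds - obs_mean).max() < 0.35

    def test_prediction_for_observed_sample_is_usage_error(self):
        y = np.random.default_rng(1).normal(size=20)
        fit = fit_gblup(y, [_identity_kernel(20)], n_iter=200, burn_in=50, seed=0)
        with pytest.raises(ValueError, match="observed"):
            predict_gblup(fit, ["s0"])

    def test_prediction_vector_length(self):
        y = np.random.default_rng(2).normal(size=30)
        y[:7] = np.nan
        fit = fit_gblup(y, [_identity_kernel(30)], n_iter=300, burn_in=50, seed=0)
        assert predict_gblup(fit, [f"s{i}" for i in range(7)]).shape == (7,)

    def test_duplicated_genotype_test_samples_predicted_alike(self):
        g = simulate_genotypes(40, 300, (0.1, 0.5), seed=3)
        g.calls[1] = g.calls[0]  # make samples 0 and 1 genotype-identical
        ka = additive_kinship(g)
        sim = simulate_scenario(g, scenario_preset("S1", qtn=100, seed=1))
        y = sim.phenotype.copy()
        y[:2] = np.nan
        fit = fit_gblup(y, [ka], n_iter=4000, burn_in=500, seed=2)
        p = predict_gblup(fit, [g.samples[0], g.samples[1]])
        assert abs(p[0] - p[1]) < 0.15  # identical kernel rows, MC noise only

    def test_non_psd_kernel_rejected(self):
        vals = np.eye(10)
        vals[0, 1] = vals[1, 0] = 2.0  # eigenvalue 1 - 2 < 0
        k = KinshipMatrix(vals, "A", [f"s{i}" for i in range(10)], None)
        with pytest.raises(ValueError, match="PSD"):
            fit_gblup(np.zeros(10) + np.random.default_rng(0).normal(size=10), [k], 100, 10)

    def test_sample_order_mismatch_rejected(self):
        k1 = _identity_kernel(10)
        k2 = KinshipMatrix(np.eye(10), "D", [f"t{i}" for i in range(10)], None)
        with pytest.raises(ValueError, match="sample order"):
            fit_gblup(np.random.default_rng(0).normal(size=10), [k1, k2], 100, 10)


class TestClosedFormAgreement:
    def test_fixed_variance_posterior_mean_equals_blup_solve(self):
        """With variances and mean fixed, the sampler's posterior mean of u
        must equal the direct mixed-model solve (independent dense oracle)."""
        rng = np.random.default_rng(7)
        g = simulate_genotypes(40, 120, (0.1, 0.5), seed=7)
        ka = additive_kinship(g)
        y = rng.normal(size=40)
        s2u, s2e = 0.6, 0.4
        fit = fit_gblup(
            y, [ka], n_iter=50, burn_in=10, seed=1,
            fixed_variances={"A": s2u, "e": s2e}, fixed_mu=0.0,
        )
        # oracle: u = s2u K (s2u K + s2e I)^{-1} y, floored eigenvalues
        d, u_mat = eigh(ka.values)
        k_floored = (u_mat * np.maximum(d, 1e-8)) @ u_mat.T
        oracle = s2u * k_floored @ np.linalg.solve(s2u * k_floored + s2e * np.eye(40), y)
        np.testing.assert_allclose(fit.u_hat["A"], oracle, atol=1e-6)


class TestParameterRecovery:
    def test_two_kernels_on_additive_data_rank_variances(self):
        """On purely additive phenotypes the dominance variance component
        should come out smaller than the additive one."""
        wins = 0
        for seed in range(5):
            g = simulate_genotypes(200, 800, (0.05, 0.5), seed=40 + seed)
            sub = filter_by_maf(g, "gt5pct")
            ka, kd = additive_kinship(sub), dominance_kinship(sub)
            sim = simulate_scenario(g, scenario_preset("S1", qtn=200, h2=0.8, seed=seed))
            fit = fit_gblup(sim.phenotype, [ka, kd], n_iter=2500, burn_in=400, seed=seed)
            if fit.var_components["D"] < fit.var_components["A"]:
                wins += 1
        assert wins >= 4

    def test_additive_signal_dominates_heritability_estimate(self):
        """Posterior genetic-variance fraction is substantial for a strongly
        heritable additive trait and grows with the simulated heritability."""
        g = simulate_genotypes(300, 1000, (0.01, 0.5), seed=11)
        ka = additive_kinship(filter_by_maf(g, "gt5pct"))
        ests = {}
        for h2 in (0.3, 0.9):
            vals = []
            for seed in range(3):
                sim = simulate_scenario(g, scenario_preset("S1", qtn=300, h2=h2, seed=seed))
                fit = fit_gblup(sim.phenotype, [ka], n_iter=3000, burn_in=500, seed=seed)
                vals.append(fit.heritability)
            ests[h2] = np.mean(vals)
        assert ests[0.9] > ests[0.3]
        assert ests[0.9] > 0.5
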