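import numpy as np
import pandas as pd
import pytest

import noisecorr as nc
from noisecorr.scm import ScmSampler


def _noiseless_dataset(n=80, rho=0.8, seed=0):
    """Two exact replicates per molecule type sharing correlated latents."""
    rng = np.random.default_rng(seed)
    lat = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], n)
    vals = np.column_stack([lat[:, 0], lat[:, 0], lat[:, 1], lat[:, 1]])
    # one experiment/technology per replicate: stratum effects then act as
    # per-column noise, so the cross-replicate shared signal identifies L
    meta = nc.ReplicateMeta(pd.DataFrame({
        "replicate_id": ["p1", "p2", "m1", "m2"],
        "experiment_id": ["pe1", "pe2", "me1", "me2"],
        "technology_id": ["pt1", "pt2", "mt1", "mt2"],
        "molecule_type": ["protein", "protein", "mRNA", "mRNA"],
    }))
    mat = nc.ExpressionMatrix([f"g{i}" for i in range(n)], meta.replicate_ids,
                              vals, np.ones_like(vals, bool), True)
    return mat, meta, lat


class TestInitState:
    def test_initialization_is_deterministic(self):
        truth = nc.default_scm_truth(seed=1)
        mat, _ = nc.simulate_scm_dataset(truth, n_genes=100, seed=2)
        cfg = nc.McmcConfig(n_iterations=10, n_burnin=5)
        a = nc.init_state(mat, truth.layout, cfg)
        b = nc.init_state(mat, truth.layout, cfg)
        np.testing.assert_array_equal(a.L, b.L)
        np.testing.assert_array_equal(a.X_full, b.X_full)
        assert a.psi12 == b.psi12

    def test_noiseless_init_psi_matches_sample_correlation(self):
        mat, meta, lat = _noiseless_dataset()
        state = nc.init_state(mat, meta, nc.McmcConfig(n_iterations=2, n_burnin=1))
        expected = np.corrcoef(lat[:, 0], lat[:, 1])[0, 1]
        assert state.psi12 == pytest.approx(expected, abs=1e-6)

    def test_fully_observed_data_has_no_imputation_slots(self):
        mat, meta, _ = _noiseless_dataset()
        state = nc.init_state(mat, meta, nc.McmcConfig(n_iterations=2, n_burnin=1))
        np.testing.assert_array_equal(state.X_full, mat.values)

    def test_single_type_layout_rejected(self):
        meta = nc.ReplicateMeta(pd.DataFrame({
            "replicate_id": ["m1", "m2"], "experiment_id": ["e", "e"],
            "technology_id": ["t", "t"], "molecule_type": ["mRNA", "mRNA"],
        }))
        vals = np.random.default_rng(0).normal(size=(10, 2))
        mat = nc.ExpressionMatrix([f"g{i}" for i in range(10)],
                                  meta.replicate_ids, vals,
                                  np.ones_like(vals, bool), True)
        with pytest.raises(ValueError, match="molecule type"):
            nc.init_state(mat, meta, nc.McmcConfig(n_iterations=2, n_burnin=1))

    def test_unobserved_genes_excluded_with_warning(self):
        truth = nc.default_scm_truth(seed=1)
        mat, _ = nc.simulate_scm_dataset(truth, n_genes=100, seed=2)
        mat.observed[0, :] = False
        mat.values[0, :] = np.nan
        mat = nc.ExpressionMatrix(mat.gene_ids, mat.replicate_ids, mat.values,
                                  mat.observed, True)
        with pytest.warns(UserWarning, match="excluding 1 genes"):
            sampler = ScmSampler(mat, truth.layout, nc.McmcConfig(n_iterations=2, n_burnin=1))
        assert sampler.n == 99


class TestGibbs:
    def test_low_noise_chain_concentrates_at_sample_correlation(self):
        mat, meta, lat = _noiseless_dataset(n=200, rho=0.7, seed=1)
        cfg = nc.McmcConfig(n_iterations=400, n_burnin=200, thin=1, n_chains=1,
                            seed=0, nmar=False, psi_proposal_scale=0.2)
        samples, summ = nc.fit_scm(mat, meta, cfg)
        target = np.corrcoef(lat[:, 0], lat[:, 1])[0, 1]
        assert summ.psi12_mean == pytest.approx(target, abs=0.05)

    def test_parameter_recovery_on_scm_simulated_data(self):
        truth = nc.default_scm_truth(
            n_experiments_per_type=4, technologies_per_type=2, seed=1000)
        mat, _ = nc.simulate_scm_dataset(truth, n_genes=500, seed=2000)
        cfg = nc.McmcConfig(n_iterations=800, n_burnin=400, thin=2,
                            n_chains=2, seed=3000)
        samples, summ = nc.fit_scm(mat, truth.layout, cfg)
        assert abs(summ.psi12_mean - truth.psi12) < 3 * summ.psi12_sd
        amp = nc.amplification_estimate(samples)
        true_A = truth.G[0] / truth.G[1]
        assert abs(amp.mean() - true_A) < 3 * amp.std(ddof=1)
        assert summ.rhat_psi12 < 1.2

    def test_gene_permutation_leaves_posterior_unchanged_within_mcmc_error(self):
        truth = nc.default_scm_truth(seed=4)
        mat, _ = nc.simulate_scm_dataset(truth, n_genes=300, seed=5)
        perm = np.random.default_rng(0).permutation(mat.n_genes)
        shuffled = nc.ExpressionMatrix(mat.gene_ids[perm], mat.replicate_ids,
                                       mat.values[perm], mat.observed[perm], True)
        cfg = nc.McmcConfig(n_iterations=500, n_burnin=250, thin=2, n_chains=1, seed=9)
        _, a = nc.fit_scm(mat, truth.layout, cfg)
        _, b = nc.fit_scm(shuffled, truth.layout, cfg)
        assert a.psi12_mean == pytest.approx(
            b.psi12_mean, abs=3 * (a.psi12_sd + b.psi12_sd))

    def test_mar_masking_with_nmar_machinery_unbiased(self):
        """Robustness: modeling missingness as NMAR does not bias psi12 on MAR data."""
        truth = nc.default_scm_truth(seed=6)
        truth.eta0_k[:] = 50.0  # generate fully observed ...
        mat, _ = nc.simulate_scm_dataset(truth, n_genes=400, seed=7)
        rng = np.random.default_rng(8)
        drop = rng.random(mat.values.shape) < 0.3  # ... then mask at random
        mat = nc.ExpressionMatrix(mat.gene_ids, mat.replicate_ids,
                                  np.where(drop, np.nan, mat.values),
                                  mat.observed & ~drop, True)
        cfg = nc.McmcConfig(n_iterations=600, n_burnin=300, thin=2, n_chains=1, seed=9)
        _, summ = nc.fit_scm(mat, truth.layout, cfg)
        assert abs(summ.psi12_mean - truth.psi12) < max(3 * summ.psi12_sd, 0.05)

    def test_ignoring_detection_bias_attenuates_psi12(self):
        truth = nc.default_scm_truth(n_experiments_per_type=2,
                                     technologies_per_type=1, seed=3)
        is_prot = np.array([e.startswith("protein")
                            for e in truth.layout.experiment_ids])
        truth.eta0_k[:] = np.where(is_prot, -0.5, 2.0)  # strong detection bias
        mat, _ = nc.simulate_scm_dataset(truth, n_genes=600, seed=7)
        base = nc.McmcConfig(n_iterations=600, n_burnin=300, thin=2,
                             n_chains=1, seed=5, nmar=True)
        ignore = nc.McmcConfig(n_iterations=600, n_burnin=300, thin=2,
                               n_chains=1, seed=5, nmar=False)
        _, with_model = nc.fit_scm(mat, truth.layout, base)
        _, without = nc.fit_scm(mat, truth.layout, ignore)
        assert without.psi12_mean < with_model.psi12_mean
        assert abs(with_model.psi12_mean - truth.psi12) < 3 * with_model.psi12_sd


class TestPosteriorProducts:
    @pytest.fixture(scope="class")
    @staticmethod
    def fitted():
        truth = nc.default_scm_truth(seed=11)
        mat, _ = nc.simulate_scm_dataset(truth, n_genes=300, seed=12)
        cfg = nc.McmcConfig(n_iterations=600, n_burnin=300, thin=2,
                            n_chains=1, seed=13)
        samples, summ = nc.fit_scm(mat, truth.layout, cfg)
        return truth, samples, summ

    def test_amplification_of_equal_scales_is_one(self, fitted):
        _, samples, _ = fitted
        forced = samples.G.copy()
        forced[:, 0] = forced[:, 1]
        equal = nc.ScmSamples(**{**samples.__dict__, "G": forced})
        np.testing.assert_allclose(nc.amplification_estimate(equal), 1.0)

    def test_amplification_recovers_scale_ratio(self, fitted):
        truth, samples, _ = fitted
        amp = nc.amplification_estimate(samples)
        assert amp.mean() == pytest.approx(truth.G[0] / truth.G[1],
                                           abs=4 * amp.std(ddof=1) + 0.05)

    def test_detection_curve_monotone_and_crosses_half(self, fitted):
        truth, samples, _ = fitted
        exp = samples.experiment_ids[0]
        curve = nc.detection_curve(samples, exp, grid=np.linspace(-8, 8, 401))
        assert (np.diff(curve.p_detect_mean) >= 0).all()
        k = samples.experiment_ids.index(exp)
        x_half = -samples.eta0_k[:, k].mean() / samples.eta1_k[:, k].mean()
        crossing = curve.x[np.argmin(np.abs(curve.p_detect_mean - 0.5))]
        assert crossing == pytest.approx(x_half, abs=0.3)

    def test_representative_sample_consistent_with_posterior(self, fitted):
        _, samples, summ = fitted
        draw = nc.sample_representative_expression(samples, seed=0)
        r = np.corrcoef(draw.log_mrna, draw.log_protein)[0, 1]
        assert r == pytest.approx(summ.psi12_mean, abs=0.1)
        # many draws reproduce the stored per-gene moments
        draws = np.stack([
            nc.sample_representative_expression(samples, seed=s).log_mrna
            for s in range(200)
        ])
        np.testing.assert_allclose(draws.mean(0), samples.gene_mean[:, 1], atol=0.1)
        np.testing.assert_allclose(draws.std(0), samples.gene_sd[:, 1], atol=0.1)

    def test_zero_posterior_sd_draw_equals_mean(self, fitted):
        _, samples, _ = fitted
        frozen = nc.ScmSamples(**{**samples.__dict__,
                                  "gene_sd": np.zeros_like(samples.gene_sd)})
        draw = nc.sample_representative_expression(frozen, seed=1)
        np.testing.assert_allclose(draw.log_protein, samples.gene_mean[:, 0])
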