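import numpy as np
import pytest
from scipy import stats

import bayspar as bp
from bayspar.calibration import (
    McmcSettings,
    PriorSpec,
    fit_bayspar,
    load_ensemble,
    posterior_prediction_uncertainty,
    sample_truncnorm_lower,
    save_ensemble,
    summarize_field,
)
from bayspar.gdgt import CoreTopRecord, build_calibration_dataset
from bayspar.synthetic import make_truth, simulate_coretops

from conftest import make_point_mass_ensemble

FAST = McmcSettings(n_chains=1, n_iter=800, n_warmup=300, thin=1)


def records_from_arrays(lats, lons, temps, tex):
    return [
        CoreTopRecord(core_id=str(i), lat=float(la), lon=float(lo), tex86=float(t),
                      sst_woa_C=float(c))
        for i, (la, lo, c, t) in enumerate(zip(lats, lons, temps, tex))
    ]


class TestTruncatedNormalSampler:
    @pytest.mark.parametrize("mean,sd", [(2.0, 1.0), (0.0, 1.0), (-1.0, 0.5),
                                         (-5.0, 1.0), (-9.0, 1.0), (0.02, 0.003)])
    def test_moments_match_scipy(self, mean, sd):
        """Inverse-CDF + tail sampler against scipy's truncated normal moments."""
        rng = np.random.default_rng(42)
        draws = np.array([sample_truncnorm_lower(mean, sd, rng) for _ in range(40_000)])
        assert np.all(draws >= 0)
        a = (0.0 - mean) / sd
        m_true, v_true = stats.truncnorm.stats(a, np.inf, loc=mean, scale=sd, moments="mv")
        se = np.sqrt(v_true / len(draws))
        assert draws.mean() == pytest.approx(float(m_true), abs=4 * se + 1e-12)
        assert draws.std() == pytest.approx(float(np.sqrt(v_true)), rel=0.05)

    def test_far_tail_finite(self):
        rng = np.random.default_rng(0)
        x = [sample_truncnorm_lower(-30.0, 1.0, rng) for _ in range(200)]
        assert np.all(np.isfinite(x)) and np.all(np.asarray(x) >= 0)


class TestPriorValidation:
    def test_improper_prior_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            PriorSpec(tau2_scale=-1.0)

    def test_phi_grid_defaults(self):
        p = PriorSpec()
        assert p.phi_grid is not None and len(p.phi_grid) == 20
        assert np.all(np.diff(np.log(p.phi_grid)) > 0)

    def test_mcmc_validation(self):
        with pytest.raises(ValueError):
            McmcSettings(n_iter=100, n_warmup=100)
        with pytest.raises(ValueError):
            McmcSettings(thin=0)


class TestFitBayspar:
    def test_noise_free_limit_recovers_exactly(self):
        """Noise-free data + tau2 prior pinned near zero collapses alpha, beta."""
        rng = np.random.default_rng(3)
        n = 150
        lats = rng.uniform(-9, 9, n)
        lons = rng.uniform(0.5, 19.5, n)  # single box
        temps = rng.uniform(0, 30, n)
        a_true, b_true = 0.12, 0.021
        tex = a_true + b_true * temps
        ds = build_calibration_dataset(records_from_arrays(lats, lons, temps, tex), "SST")
        priors = PriorSpec(phi_fixed=5e-4, tau2_shape=2000.0, tau2_scale=2000.0 * 1e-9)
        ens = fit_bayspar(ds, priors=priors, mcmc=FAST, seed=11)
        assert ens.alpha.mean() == pytest.approx(a_true, abs=1e-3)
        assert ens.beta.mean() == pytest.approx(b_true, abs=1e-3)

    def test_beta_always_positive(self):
        rng = np.random.default_rng(5)
        n = 80
        lats = rng.uniform(-9, 9, n)
        temps = rng.uniform(0, 5, n)
        tex = 0.3 + 0.001 * temps + 0.05 * rng.standard_normal(n)  # nearly flat slope
        ds = build_calibration_dataset(
            records_from_arrays(lats, rng.uniform(0.5, 19.5, n), temps, np.clip(tex, 0, 1)),
            "SST")
        ens = fit_bayspar(ds, priors=PriorSpec(phi_fixed=5e-4), mcmc=FAST, seed=2)
        assert np.all(ens.beta > 0)

    def test_bit_reproducible_for_fixed_seed(self):
        rng = np.random.default_rng(8)
        n = 60
        recs = records_from_arrays(
            rng.uniform(-30, 30, n), rng.uniform(-60, 60, n),
            t := rng.uniform(0, 28, n), np.clip(0.2 + 0.02 * t, 0, 1))
        ds = build_calibration_dataset(recs, "SST")
        mc = McmcSettings(n_chains=2, n_iter=200, n_warmup=50, thin=2)
        e1 = fit_bayspar(ds, priors=PriorSpec(phi_fixed=1e-3), mcmc=mc, seed=99)
        e2 = fit_bayspar(ds, priors=PriorSpec(phi_fixed=1e-3), mcmc=mc, seed=99)
        assert np.array_equal(e1.alpha, e2.alpha)
        assert np.array_equal(e1.beta, e2.beta)
        assert np.array_equal(e1.tau2, e2.tau2)
        assert np.array_equal(e1.phi, e2.phi)

    def test_draw_count_accounting(self):
        rng = np.random.default_rng(8)
        n = 40
        recs = records_from_arrays(
            rng.uniform(-9, 9, n), rng.uniform(0.5, 19.5, n),
            t := rng.uniform(0, 28, n), np.clip(0.2 + 0.02 * t, 0, 1))
        ds = build_calibration_dataset(recs, "SST")
        mc = McmcSettings(n_chains=2, n_iter=110, n_warmup=10, thin=4)
        ens = fit_bayspar(ds, priors=PriorSpec(phi_fixed=1e-3), mcmc=mc, seed=1)
        assert ens.n_draws == mc.n_kept == 2 * (100 // 4)

    def test_phi_grid_sampling_stays_on_grid(self):
        rng = np.random.default_rng(12)
        n = 100
        recs = records_from_arrays(
            rng.uniform(-50, 50, n), rng.uniform(-170, 170, n),
            t := rng.uniform(0, 28, n),
            np.clip(0.2 + 0.018 * t + 0.03 * rng.standard_normal(n), 0, 1))
        ds = build_calibration_dataset(recs, "SST")
        priors = PriorSpec()
        ens = fit_bayspar(ds, priors=priors, mcmc=FAST, seed=4)
        assert np.all(np.isin(ens.phi, priors.phi_grid))
        assert len(np.unique(ens.phi)) > 1  # the update actually moves

    def test_empty_dataset_rejected(self, grid):
        ds = build_calibration_dataset(
            [CoreTopRecord(core_id="a", lat=0, lon=0, tex86=0.5, sst_woa_C=20.0)], "SST")
        ds.records, ds.P, ds.C_diag, ds.box_index = [], ds.P[:0], ds.C_diag[:0], ds.box_index[:0]
        with pytest.raises(ValueError, match="empty"):
            fit_bayspar(ds)

    def test_data_poor_box_matches_gp_conditional(self):
        """A box with no data shrinks to the process conditional on its neighbors.

        Hyperparameters are pinned by near-degenerate priors and the data
        boxes carry abundant low-noise data, so the empty box's marginal
        should match a direct Gaussian-conditional computation (slope
        truncation imposed by rejection).
        """
        rng = np.random.default_rng(21)
        grid = bp.GridSpec()
        mu_a, mu_b, s2a, s2b, phi = 0.25, 0.018, 4e-3, 4e-5, 5e-4
        data_boxes = [76, 77]  # centroids (0,-90), (0,-70)
        empty_box = 78  # centroid (0,-50)
        a_field = {76: 0.22, 77: 0.30}
        b_field = {76: 0.016, 77: 0.022}
        recs = []
        tau = 0.005
        for b in data_boxes:
            cla, clo = grid.centroid(b)
            n = 400
            temps = rng.uniform(0, 30, n)
            tex = a_field[b] + b_field[b] * temps + tau * rng.standard_normal(n)
            recs += records_from_arrays(
                np.full(n, cla), np.full(n, clo), temps, np.clip(tex, 0, 1))
        ds = build_calibration_dataset(recs, "SST", grid=grid)
        pin = 4e4
        priors = PriorSpec(
            mu_alpha_mean=mu_a, mu_alpha_sd=1e-5, mu_beta_mean=mu_b, mu_beta_sd=1e-6,
            sigma2_alpha_shape=pin, sigma2_alpha_scale=(pin - 1) * s2a,
            sigma2_beta_shape=pin, sigma2_beta_scale=(pin - 1) * s2b,
            phi_fixed=phi,
        )
        mc = McmcSettings(n_chains=2, n_iter=3000, n_warmup=500, thin=1)
        ens = fit_bayspar(ds, grid=grid, priors=priors, mcmc=mc, seed=33,
                          extra_boxes=[empty_box])
        col = ens.box_column(empty_box)

        # direct conditional: empty box given the posterior-mean data boxes
        cents = grid.centroids[[76, 77, 78]]
        R = bp.build_correlation_matrix(cents, bp.CorrelationModel(phi=phi))
        r12 = R[2, :2]
        R11 = R[:2, :2]
        sol = np.linalg.solve(R11, r12)
        var_c = 1.0 - r12 @ sol
        a_obs = ens.alpha[:, [ens.box_column(76), ens.box_column(77)]].mean(axis=0)
        b_obs = ens.beta[:, [ens.box_column(76), ens.box_column(77)]].mean(axis=0)
        mean_a = mu_a + sol @ (a_obs - mu_a)
        mean_b = mu_b + sol @ (b_obs - mu_b)
        sd_a = np.sqrt(s2a * var_c)
        sd_b = np.sqrt(s2b * var_c)
        # slope conditional with positivity by rejection
        g = np.random.default_rng(0)
        bs = mean_b + sd_b * g.standard_normal(200_000)
        bs = bs[bs > 0]
        assert ens.alpha[:, col].mean() == pytest.approx(mean_a, abs=4 * sd_a / 30)
        assert ens.alpha[:, col].std() == pytest.approx(sd_a, rel=0.12)
        assert ens.beta[:, col].mean() == pytest.approx(bs.mean(), abs=4 * sd_b / 30)
        assert ens.beta[:, col].std() == pytest.approx(bs.std(), rel=0.12)


class TestPosteriorSummaries:
    def test_point_mass_uncertainty_near_zero(self):
        ens = make_point_mass_ensemble([40], alpha=0.2, beta=0.02, tau2=1e-16)
        assert posterior_prediction_uncertainty(ens, 40) < 1e-4

    def test_two_draw_mixture_matches_enumeration(self):
        ens = make_point_mass_ensemble([40], alpha=0.2, beta=0.02, tau2=4e-4, n_draws=2)
        ens.alpha = np.array([[0.18], [0.24]])
        ens.beta = np.array([[0.016], [0.022]])
        ens.tau2 = np.array([4e-4, 9e-4])
        tex = 0.5
        means = (tex - ens.alpha[:, 0]) / ens.beta[:, 0]
        variances = ens.tau2 / ens.beta[:, 0] ** 2
        expected = np.sqrt(variances.mean() + means.var())  # hand-computed mixture SD
        assert posterior_prediction_uncertainty(ens, 40, tex86=tex) == pytest.approx(expected)

    def test_smaller_beta_larger_uncertainty(self):
        big = make_point_mass_ensemble([40], alpha=0.2, beta=0.03, tau2=4e-4,
                                       n_draws=50, jitter_sd=1e-4, seed=5)
        small = make_point_mass_ensemble([40], alpha=0.2, beta=0.01, tau2=4e-4,
                                         n_draws=50, jitter_sd=1e-4, seed=5)
        assert (posterior_prediction_uncertainty(small, 40)
                > posterior_prediction_uncertainty(big, 40))

    def test_inactive_box_raises(self):
        ens = make_point_mass_ensemble([40], alpha=0.2, beta=0.02)
        with pytest.raises(KeyError, match="41"):
            posterior_prediction_uncertainty(ens, 41)

    def test_constant_field_relative_range_zero(self):
        ens = make_point_mass_ensemble([1, 2, 3], alpha=0.2, beta=0.02, n_draws=10)
        assert summarize_field(ens, "beta")["relative_range"] == 0.0

    def test_single_draw_median_equals_draw(self):
        ens = make_point_mass_ensemble([1, 2], alpha=[0.1, 0.3], beta=[0.01, 0.03])
        s = summarize_field(ens, "alpha")
        assert np.allclose(s["median"], [0.1, 0.3])

    def test_quantiles_match_sort_oracle(self, rng):
        ens = make_point_mass_ensemble([7], alpha=0.2, beta=0.02, n_draws=100,
                                       jitter_sd=0.01, seed=9)
        s = summarize_field(ens, "beta", level=0.90)
        x = np.sort(ens.beta[:, 0])
        # sort-based linear-interpolation quantile oracle
        def q(p):
            h = p * (len(x) - 1)
            lo = int(np.floor(h))
            return x[lo] + (h - lo) * (x[min(lo + 1, len(x) - 1)] - x[lo])
        assert s["median"][0] == pytest.approx(q(0.5))
        assert s["lower"][0] == pytest.approx(q(0.05))
        assert s["upper"][0] == pytest.approx(q(0.95))

    def test_which_validated(self):
        ens = make_point_mass_ensemble([1], alpha=0.2, beta=0.02)
        with pytest.raises(ValueError):
            summarize_field(ens, "tau")


class TestPersistence:
    def test_netcdf_roundtrip(self, tmp_path):
        box_ids = np.arange(60, 90, 3)
        truth = make_truth(box_ids=box_ids, seed=1)
        recs = simulate_coretops(120, truth, seed=2, box_ids=box_ids)
        ds = build_calibration_dataset(recs, "SST")
        ens = fit_bayspar(ds, priors=PriorSpec(phi_fixed=5e-4),
                          mcmc=McmcSettings(n_chains=1, n_iter=120, n_warmup=20, thin=2),
                          seed=7)
        path = tmp_path / "posterior.nc"
        save_ensemble(ens, path)
        back = load_ensemble(path)
        assert np.allclose(back.alpha, ens.alpha)
        assert np.allclose(back.beta, ens.beta)
        assert np.array_equal(back.box_ids, ens.box_ids)
        assert back.target_kind == ens.target_kind
        assert back.settings.n_iter == ens.settings.n_iter
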