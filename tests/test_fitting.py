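import warnings

import numpy as np
import pytest

import renalmri as rm
from renalmri.fitting import PriorSpec, _estimate_sigma, segmented_init

from _oracles import brute_force_posterior_medians


class TestAdc:
    def test_noiseless_monoexp_exact_recovery(self):
        params = rm.MonoexpParams(s0=500, adc=1.1e-3)
        curve = rm.DecayCurve.dwi(rm.monoexp_signal(params, np.asarray(rm.DWI_B_VALUES)))
        result = rm.fit_adc(curve)
        assert result.converged
        assert result.params.adc == pytest.approx(1.1e-3, rel=1e-8)
        assert result.params.s0 == pytest.approx(500, rel=1e-8)

    def test_two_point_closed_form(self):
        curve = rm.DecayCurve([200.0, 800.0], [100.0, 50.0], kind="dwi")
        result = rm.fit_adc(curve)
        assert result.params.adc == pytest.approx(np.log(2) / 600, rel=1e-10)

    def test_ivim_curve_high_b_recovers_d(self, noiseless_ivim_curve, kidney_truth):
        # above b=200 the fast compartment is < exp(-8) of its b=0 amplitude
        result = rm.fit_adc(noiseless_ivim_curve)
        assert abs(result.params.adc - kidney_truth.d) / kidney_truth.d < 0.005

    def test_nonpositive_signals_nonconverged(self):
        curve = rm.DecayCurve([200.0, 400.0, 800.0], [-5.0, -1.0, 0.0], kind="dwi")
        result = rm.fit_adc(curve)
        assert not result.converged and result.params is None

    def test_too_few_high_b_points_rejected(self):
        curve = rm.DecayCurve([0.0, 100.0, 800.0], [10.0, 9.0, 5.0], kind="dwi")
        with pytest.raises(ValueError, match="at least 2"):
            rm.fit_adc(curve)


class TestT2Star:
    def test_noiseless_exact_recovery(self):
        params = rm.T2StarParams(s0=200, t2_star=33)
        curve = rm.DecayCurve.bold(rm.t2star_signal(params, np.asarray(rm.BOLD_ECHO_TIMES)))
        result = rm.fit_t2star(curve)
        assert result.params.t2_star == pytest.approx(33, rel=1e-8)

    def test_two_echo_closed_form(self):
        s5, s40 = 200 * np.exp(-5 / 33), 200 * np.exp(-40 / 33)
        curve = rm.DecayCurve([5.0, 40.0], [s5, s40], kind="bold")
        result = rm.fit_t2star(curve)
        assert result.params.t2_star == pytest.approx(35 / np.log(s5 / s40), rel=1e-8)
        assert result.params.t2_star == pytest.approx(33, rel=1e-8)

    def test_constant_signal_flagged(self):
        curve = rm.DecayCurve.bold(np.full(5, 100.0))
        result = rm.fit_t2star(curve)
        assert not result.converged


class TestSegmentedInit:
    def test_noiseless_init_close_to_truth(self):
        truth = rm.IvimParams(s0=1000, f=0.20, d=1.2e-3, d_star=4e-2)
        curve = rm.DecayCurve.dwi(rm.ivim_signal(truth, np.asarray(rm.DWI_B_VALUES)))
        result = segmented_init(curve)
        assert 0.195 <= result.params.f <= 0.205
        assert abs(result.params.d - truth.d) / truth.d < 0.01

    def test_pure_monoexp_gives_zero_f(self):
        curve = rm.DecayCurve.dwi(
            rm.monoexp_signal(rm.MonoexpParams(s0=800, adc=1.3e-3), np.asarray(rm.DWI_B_VALUES))
        )
        result = segmented_init(curve)
        assert result.params.f == 0.0

    def test_intercept_above_s0_clamped_not_negative(self):
        # drop the measured b=0 signal below the back-projected intercept
        truth = rm.MonoexpParams(s0=800, adc=1.3e-3)
        signal = rm.monoexp_signal(truth, np.asarray(rm.DWI_B_VALUES))
        signal[0] = 700.0
        result = segmented_init(rm.DecayCurve.dwi(signal))
        assert result.params.f == 0.0
        assert "flags" in result.diagnostics


class TestBayesianIvim:
    def test_noiseless_recovery_within_tolerance(self, noiseless_ivim_curve, kidney_truth):
        result = rm.fit_ivim_bayesian(noiseless_ivim_curve)
        assert result.converged
        assert result.params.f == pytest.approx(kidney_truth.f, rel=0.01)
        assert result.params.d == pytest.approx(kidney_truth.d, rel=0.01)
        assert result.params.d_star == pytest.approx(kidney_truth.d_star, rel=0.05)

    def test_zero_perfusion_d_recovered_d_star_unidentified(self):
        curve = rm.DecayCurve.dwi(
            rm.monoexp_signal(rm.MonoexpParams(s0=1000, adc=1.245e-3), np.asarray(rm.DWI_B_VALUES))
        )
        result = rm.fit_ivim_bayesian(curve)
        assert result.params.d == pytest.approx(1.245e-3, rel=0.01)
        priors = PriorSpec()
        span = priors.d_star_bounds[1] - priors.d_star_bounds[0]
        assert result.diagnostics["ci95_width"]["d_star"] >= 0.5 * span

    def test_seeded_noisy_fit_deterministic(self, noiseless_ivim_curve):
        rng = np.random.default_rng(42)
        signal = noiseless_ivim_curve.signal + rng.normal(0, 50, 9)
        curve = rm.DecayCurve.dwi(signal)
        a = rm.fit_ivim_bayesian(curve, seed=1)
        b = rm.fit_ivim_bayesian(curve, seed=1)
        assert a.params == b.params
        assert a.diagnostics["ci95_width"] == b.diagnostics["ci95_width"]

    def test_degenerate_curve_nonconverged(self):
        result = rm.fit_ivim_bayesian(rm.DecayCurve.dwi(np.full(9, 250.0)))
        assert not result.converged and result.params is None

    def test_grid_matches_brute_force_oracle(self, kidney_truth):
        """Marginal medians agree with a dense independent 4-D grid posterior."""
        priors = PriorSpec()
        ranges = {
            "f": priors.f_bounds[1] - priors.f_bounds[0],
            "d": priors.d_bounds[1] - priors.d_bounds[0],
            "d_star": priors.d_star_bounds[1] - priors.d_star_bounds[0],
        }
        b = np.asarray(rm.DWI_B_VALUES)
        clean = rm.ivim_signal(kidney_truth, b)
        rng = np.random.default_rng(0)
        for _ in range(3):
            curve = rm.DecayCurve.dwi(clean + rng.normal(0, 50, 9))
            sigma = 50.0
            fit = rm.fit_ivim_bayesian(curve, priors=priors, sigma=sigma)
            oracle = brute_force_posterior_medians(curve, priors, sigma, n=100)
            s0_range = priors.resolve_s0_max(curve)
            for k in ("f", "d", "d_star"):
                assert abs(fit.params.__getattribute__(k) - oracle[k]) < 0.02 * ranges[k]
            assert abs(fit.params.s0 - oracle["s0"]) < 0.02 * s0_range

    def test_mcmc_engine_agrees_with_grid(self, kidney_truth):
        b = np.asarray(rm.DWI_B_VALUES)
        rng = np.random.default_rng(5)
        curve = rm.DecayCurve.dwi(rm.ivim_signal(kidney_truth, b) + rng.normal(0, 50, 9))
        priors = PriorSpec()
        grid = rm.fit_ivim_bayesian(curve, priors=priors, sigma=50.0, engine="grid")
        mcmc = rm.fit_ivim_bayesian(curve, priors=priors, sigma=50.0, engine="mcmc", seed=3)
        assert abs(mcmc.params.f - grid.params.f) < 0.02
        assert abs(mcmc.params.d - grid.params.d) < 0.02 * (priors.d_bounds[1] - priors.d_bounds[0])
        assert abs(mcmc.params.d_star - grid.params.d_star) < 0.02 * (
            priors.d_star_bounds[1] - priors.d_star_bounds[0]
        )

    def test_compartment_swap_flagged(self):
        # Force the posterior towards d* < d by a curve whose only decay is slow
        priors = PriorSpec(d_bounds=(2e-4, 5e-3), d_star_bounds=(5e-3, 0.3))
        truth = rm.IvimParams(s0=1000, f=0.65, d=4.5e-3, d_star=6e-3)
        curve = rm.DecayCurve.dwi(rm.ivim_signal(truth, np.asarray(rm.DWI_B_VALUES)))
        result = rm.fit_ivim_bayesian(curve, priors=priors)
        if result.params.d_star < result.params.d:
            assert not result.converged
            assert "compartment_swapped" in result.diagnostics["flags"]


class TestRecoveryStatistics:
    def test_bias_over_noisy_replicates(self, kidney_truth):
        """f and D nearly unbiased at SNR 20; D* allowed a much larger bias."""
        b = np.asarray(rm.DWI_B_VALUES)
        clean = rm.ivim_signal(kidney_truth, b)
        rng = np.random.default_rng(12)
        estimates = []
        for _ in range(100):
            curve = rm.DecayCurve.dwi(clean + rng.normal(0, 50, 9))
            fit = rm.fit_ivim_bayesian(curve)
            estimates.append([fit.params.f, fit.params.d, fit.params.d_star])
        med = np.median(np.asarray(estimates), axis=0)
        assert abs(med[0] / kidney_truth.f - 1) < 0.05
        assert abs(med[1] / kidney_truth.d - 1) < 0.05
        assert abs(med[2] / kidney_truth.d_star - 1) < 0.20

    def test_adc_tracks_d_across_cohort(self):
        """Pearson r(ADC, D) > 0.9 over ROI-mean curves spanning renal values."""
        rng = np.random.default_rng(8)
        adcs, ds = [], []
        for i in range(15):
            f = rng.uniform(0.08, 0.28)
            d = rng.uniform(0.95e-3, 1.45e-3)
            truth = rm.IvimParams(s0=1000, f=f, d=d, d_star=4e-2)
            clean = rm.ivim_signal(truth, np.asarray(rm.DWI_B_VALUES))
            # ROI-mean curve over ~90 voxels: noise reduced by sqrt(n)
            signal = clean + rng.normal(0, 50 / np.sqrt(90), 9)
            curve = rm.DecayCurve.dwi(signal)
            adcs.append(rm.fit_adc(curve).params.adc)
            ds.append(rm.fit_ivim_bayesian(curve).params.d)
        r = rm.correlate_adc_d(adcs, ds)
        assert r.r > 0.9

    def test_model_comparison_residuals(self, kidney_truth):
        """IVIM beats the all-b monoexponential on biexponential data."""
        b = np.asarray(rm.DWI_B_VALUES)
        clean = rm.ivim_signal(kidney_truth, b)
        rng = np.random.default_rng(3)
        wins = 0
        n = 30
        for _ in range(n):
            curve = rm.DecayCurve.dwi(clean + rng.normal(0, 50, 9))
            ivim = rm.fit_ivim_bayesian(curve)
            mono = rm.fit_adc(curve, b_min=0.0)
            if ivim.residual_norm < mono.residual_norm:
                wins += 1
        assert wins >= 0.9 * n


class TestFitMap:
    def test_noiseless_map_recovers_truth(self, uniform_phantom, kidney_truth):
        stack = rm.simulate_dwi(uniform_phantom, noise_sigma=0.0)
        mask = uniform_phantom.regions.whole_kidney_mask
        pmap = rm.fit_map(stack, mask, "adc")
        assert pmap.n_nonconverged == 0
        np.testing.assert_allclose(pmap.params["adc"][mask], kidney_truth.d, rtol=5e-3)
        np.testing.assert_allclose(pmap.params["s0"][mask], pmap.params["s0"][mask][0], rtol=1e-10)

    def test_empty_mask_warns(self, uniform_phantom):
        stack = rm.simulate_dwi(uniform_phantom, noise_sigma=0.0)
        with pytest.warns(UserWarning, match="empty mask"):
            pmap = rm.fit_map(stack, np.zeros(stack.shape[1:], dtype=bool), "adc")
        assert pmap.n_fitted == 0

    def test_grid_mismatch_rejected(self, uniform_phantom):
        stack = rm.simulate_dwi(uniform_phantom, noise_sigma=0.0)
        with pytest.raises(ValueError, match="grid mismatch"):
            rm.fit_map(stack, np.zeros((5, 5), dtype=bool), "adc")

    def test_noisy_map_nonconverged_fraction_small(self, uniform_phantom):
        stack = rm.simulate_dwi(uniform_phantom, seed=0)
        mask = uniform_phantom.regions.whole_kidney_mask
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pmap = rm.fit_map(stack, mask, "ivim")
        assert pmap.n_nonconverged / pmap.n_fitted < 0.05


def test_sigma_estimate_floor(noiseless_ivim_curve):
    seg = segmented_init(noiseless_ivim_curve)
    sigma = _estimate_sigma(noiseless_ivim_curve, seg)
    assert sigma >= 1e-4 * np.max(noiseless_ivim_curve.signal) * 0.999
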