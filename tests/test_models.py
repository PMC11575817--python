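"""Bayesian mixed-model fitting and derived validity statistics."""

import warnings

import numpy as np
import pytest

from vbtval.models import (PriorSpec, SamplerSpec, compute_r2, compute_rmse,
                           compute_smb, fit_model1, fit_model2, hdi)

from conftest import make_paired


class TestHdi:
    def test_normal_draws_match_central_interval(self):
        rng = np.random.default_rng(0)
        lo, hi = hdi(rng.standard_normal(1_000_000))
        assert lo == pytest.approx(-1.96, abs=0.02)
        assert hi == pytest.approx(1.96, abs=0.02)

    def test_uniform_draws_interval_length(self):
        rng = np.random.default_rng(1)
        lo, hi = hdi(rng.uniform(0, 1, 200_000))
        assert hi - lo == pytest.approx(0.95, abs=0.01)

    def test_constant_draws_zero_width(self):
        lo, hi = hdi(np.full(500, 3.14))
        assert lo == hi == 3.14

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError, match="100"):
            hdi(np.zeros(50))

    def test_invalid_mass_rejected(self):
        with pytest.raises(ValueError, match="mass"):
            hdi(np.zeros(500), mass=1.0)

    def test_skewed_hdi_shorter_than_central_interval(self):
        rng = np.random.default_rng(2)
        draws = rng.exponential(1.0, 200_000)
        lo, hi = hdi(draws)
        central = np.quantile(draws, [0.025, 0.975])
        assert (hi - lo) < (central[1] - central[0])
        assert lo == pytest.approx(0.0, abs=0.01)


class TestModel1:
    def test_identity_device_near_noiseless(self, fast_sampler):
        data = make_paired(seed=1, sigma=0.001)
        fit = fit_model1(data, sampler=fast_sampler)
        assert fit.converged
        assert 0.99 <= fit.summary("slope").mean <= 1.01
        assert -0.005 <= fit.summary("intercept").mean <= 0.005

    def test_pooled_ols_agreement_without_random_effects(self, fast_sampler):
        data = make_paired(seed=2, alpha=0.03, beta=0.95, sigma=0.04)
        fit = fit_model1(data, sampler=fast_sampler)
        x = data.frame.criterion_mv.to_numpy()
        y = data.frame.practical_mv.to_numpy()
        X = np.column_stack([np.ones_like(x), x])
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        s = fit.summary("slope")
        mc_se = s.draws.std() / np.sqrt(max(fit.ess_min, 1.0))
        assert abs(s.mean - ols[1]) < max(3 * mc_se, 0.01)

    def test_back_transformation_consistency(self, fast_sampler):
        data = make_paired(seed=3, alpha=0.05, beta=0.9, sigma=0.03)
        fit_nat = fit_model1(data, sampler=fast_sampler)
        mu = data.frame.criterion_mv.mean()
        s = data.frame.criterion_mv.std(ddof=1)
        std_frame = data.frame.copy()
        std_frame["criterion_mv"] = (std_frame.criterion_mv - mu) / s
        std_frame["practical_mv"] = (std_frame.practical_mv - mu) / s
        data_std = type(data)(std_frame, "device", len(std_frame), 0, 0)
        fit_std = fit_model1(data_std, sampler=fast_sampler)
        b1 = fit_std.summary("slope").mean
        b0 = mu + s * fit_std.summary("intercept").mean - b1 * mu
        assert b1 == pytest.approx(fit_nat.summary("slope").mean, abs=0.01)
        assert b0 == pytest.approx(fit_nat.summary("intercept").mean, abs=0.01)

    def test_diagnostics_reported(self, fast_sampler):
        fit = fit_model1(make_paired(seed=4, sigma=0.03), sampler=fast_sampler)
        assert set(fit.rhat) == {"intercept", "slope", "sigma", "tau0", "tau1", "rho"}
        assert fit.ess_min > 100
        s = fit.summary("slope")
        assert s.rhat_max == fit.rhat_max and not s.flagged

    def test_determinism(self, fast_sampler):
        data = make_paired(seed=5, sigma=0.03)
        f1 = fit_model1(data, sampler=fast_sampler)
        f2 = fit_model1(data, sampler=fast_sampler)
        assert np.array_equal(f1.posterior["slope"], f2.posterior["slope"])
        assert np.array_equal(f1.u_std, f2.u_std)

    def test_too_few_subjects_rejected(self, fast_sampler):
        data = make_paired(seed=6, n_subjects=1, sigma=0.03)
        with pytest.raises(ValueError, match="subjects"):
            fit_model1(data, sampler=fast_sampler)


class TestModel2:
    def test_identity_concentrates_at_zero(self, fast_sampler):
        data = make_paired(seed=7, sigma=0.0005)
        fit = fit_model2(data, sampler=fast_sampler)
        assert abs(fit.summary("slope").mean) < 0.002

    def test_constant_offset_recovered(self, fast_sampler):
        data = make_paired(seed=8, alpha=0.05, beta=1.0, sigma=0.02)
        fit = fit_model2(data, sampler=fast_sampler)
        assert 0.045 <= fit.summary("slope").mean <= 0.055

    def test_smb_of_standardized_offset(self, fast_sampler):
        base = make_paired(seed=9, sigma=0.02)
        sd = float(base.frame.criterion_mv.std(ddof=1))
        frame = base.frame.copy()
        frame["practical_mv"] = frame.practical_mv + 0.3 * sd
        data = type(base)(frame, "device", len(frame), 0, 0)
        fit = fit_model2(data, sampler=fast_sampler)
        smb = compute_smb(fit, sd)
        assert 0.2 <= smb.mean <= 0.4

    def test_smb_delta_consistency(self, fast_sampler):
        data = make_paired(seed=10, alpha=0.02, sigma=0.03)
        fit = fit_model2(data, sampler=fast_sampler)
        sd = float(data.frame.criterion_mv.std(ddof=1))
        smb = compute_smb(fit, sd)
        assert np.allclose(smb.draws * sd, fit.draws("slope"), atol=1e-12)

    def test_smb_zero_when_delta_zero(self, fast_sampler):
        data = make_paired(seed=10, alpha=0.02, sigma=0.03)
        fit = fit_model2(data, sampler=fast_sampler)
        fit.posterior["slope"] = np.full_like(fit.posterior["slope"], 0.034)
        smb = compute_smb(fit, 0.17)
        assert smb.mean == pytest.approx(0.2, abs=1e-12)
        assert smb.hdi_low == smb.hdi_high == pytest.approx(0.2, abs=1e-12)

    def test_invalid_scale_rejected(self, fast_sampler):
        data = make_paired(seed=10, sigma=0.03)
        fit = fit_model2(data, sampler=fast_sampler)
        with pytest.raises(ValueError, match="scale_sd"):
            compute_smb(fit, 0.0)


class TestDerivedStatistics:
    def test_rmse_near_zero_for_noiseless_fit(self, fast_sampler):
        fit = fit_model1(make_paired(seed=11, sigma=0.0005), sampler=fast_sampler)
        assert compute_rmse(fit).mean < 0.003

    def test_rmse_recovers_residual_sd(self, fast_sampler):
        fit = fit_model1(make_paired(seed=12, sigma=0.05, n_subjects=20, n_reps=30),
                         sampler=fast_sampler)
        assert 0.045 <= compute_rmse(fit).mean <= 0.055

    def test_rmse_scales_with_sigma(self, fast_sampler):
        r1 = compute_rmse(fit_model1(make_paired(seed=13, sigma=0.03),
                                     sampler=fast_sampler)).mean
        r2 = compute_rmse(fit_model1(make_paired(seed=13, sigma=0.06),
                                     sampler=fast_sampler)).mean
        assert r2 / r1 == pytest.approx(2.0, rel=0.10)

    def test_r2_near_one_for_noiseless_identity(self, fast_sampler):
        fit = fit_model1(make_paired(seed=14, sigma=0.0005), sampler=fast_sampler)
        assert compute_r2(fit).mean > 0.999

    def test_r2_matches_variance_ratio(self, fast_sampler):
        # signal SD 0.17 (uniform width ~0.59), sigma 0.03 -> R2 ~ 0.970
        width = 0.17 * np.sqrt(12)
        fit = fit_model1(make_paired(seed=15, sigma=0.03, mv_low=0.4,
                                     mv_high=0.4 + width), sampler=fast_sampler)
        assert 0.94 <= compute_r2(fit).mean <= 0.99

    def test_r2_decreases_with_noise(self, fast_sampler):
        r2s = [compute_r2(fit_model1(make_paired(seed=16, sigma=s),
                                     sampler=fast_sampler)).mean
               for s in (0.01, 0.03, 0.09)]
        assert r2s[0] > r2s[1] > r2s[2]


class TestCalibration:
    def test_hdi_coverage_over_replicates(self, tiny_sampler):
        """95% HDIs for intercept, slope and delta cover truth at ~nominal rate."""
        alpha, beta, sigma = 0.04, 0.92, 0.04
        hits = {"intercept": 0, "slope": 0, "delta": 0}
        n_rep = 25
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for k in range(n_rep):
                data = make_paired(seed=100 + k, n_subjects=10, n_reps=12,
                                   alpha=alpha, beta=beta, sigma=sigma,
                                   tau0=0.01, tau1=0.02)
                fit = fit_model1(data, sampler=tiny_sampler)
                s0, s1 = fit.summary("intercept"), fit.summary("slope")
                hits["intercept"] += s0.hdi_low <= alpha <= s0.hdi_high
                hits["slope"] += s1.hdi_low <= beta <= s1.hdi_high
                fit2 = fit_model2(data, sampler=tiny_sampler)
                d = fit2.summary("slope")
                x = data.frame.criterion_mv
                true_delta = float(np.mean(alpha + (beta - 1) * x))
                hits["delta"] += d.hdi_low <= true_delta <= d.hdi_high
        for name, h in hits.items():
            assert 0.85 * n_rep <= h <= n_rep, f"{name} coverage {h}/{n_rep}"


class TestPriors:
    def test_invalid_priors_rejected(self):
        with pytest.raises(ValueError):
            PriorSpec(sigma_scale=0.0)
        with pytest.raises(ValueError):
            PriorSpec(lkj_eta=0.5)

    def test_sampler_contract_enforced(self):
        with pytest.raises(ValueError, match="1000"):
            SamplerSpec(n_walkers=8, n_keep=50)
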