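"""Linearized cosinor fits: exactness, oracle equivalence, calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from pmrhythm.circular import wrap_signed
from pmrhythm.cosinor import (
    DesignSpec,
    amp_phase,
    fit_cosinor,
    fit_matrix,
    nadir_from_acrophase,
    rhythm_f_tests,
)

TWO_PI = 2.0 * np.pi


def _meta_from_angles(theta, psi):
    """Minimal metadata table carrying pre-computed angles."""
    n = len(theta)
    return pd.DataFrame(
        {
            "sample_id": [f"S{i}" for i in range(n)],
            "theta_zt": theta,
            "theta_clock": theta,
            "theta_darkmid": theta,
            "psi_season": psi,
        }
    )


class TestFitCosinor:
    def test_exact_recovery_on_noiseless_cosine(self):
        theta = np.linspace(0, TWO_PI, 48, endpoint=False)
        psi = np.random.default_rng(0).uniform(0, TWO_PI, 48)
        y = 1.0 + 0.5 * np.cos(theta - np.pi / 3)
        fit = fit_cosinor(y, _meta_from_angles(theta, psi), DesignSpec(covariates=[]))
        assert fit.A_d == pytest.approx(0.5, abs=1e-8)
        assert fit.phi_d == pytest.approx(np.pi / 3, abs=1e-8)
        assert fit.mu == pytest.approx(1.0, abs=1e-8)

    def test_zero_coefficients_flagged_degenerate_with_phase_zero(self):
        amp, phi = amp_phase(0.0, 0.0)
        assert amp == 0.0 and phi == 0.0

    def test_constant_y_gives_f_zero_p_one(self):
        rng = np.random.default_rng(0)
        theta = rng.uniform(0, TWO_PI, 60)
        psi = rng.uniform(0, TWO_PI, 60)
        F_d, p_d, _, _ = rhythm_f_tests(
            np.full(60, 3.7), _meta_from_angles(theta, psi), DesignSpec(covariates=[])
        )
        assert F_d == 0.0 and p_d == 1.0

    def test_noise_free_rhythm_gives_infinite_f_zero_p(self):
        theta = np.linspace(0, TWO_PI, 60, endpoint=False)
        psi = (theta * 3.1) % TWO_PI
        y = 2.0 + 0.4 * np.cos(theta - 1.0)
        F_d, p_d, _, _ = rhythm_f_tests(
            y, _meta_from_angles(theta, psi), DesignSpec(covariates=[])
        )
        assert np.isinf(F_d) and p_d == 0.0

    def test_matches_nonlinear_cosinor_oracle(self):
        """Linearized OLS equals direct nonlinear least squares of
        mu + A_d*cos(theta-phi_d) + A_s*cos(psi-phi_s) on 50 random instances."""
        rng = np.random.default_rng(7)
        spec = DesignSpec(covariates=[])
        for _ in range(50):
            n = 80
            theta = rng.uniform(0, TWO_PI, n)
            psi = rng.uniform(0, TWO_PI, n)
            y = (
                rng.normal(2, 1)
                + rng.uniform(0.2, 1.0) * np.cos(theta - rng.uniform(0, TWO_PI))
                + rng.uniform(0.2, 1.0) * np.cos(psi - rng.uniform(0, TWO_PI))
                + 0.5 * rng.standard_normal(n)
            )
            fit = fit_cosinor(y, _meta_from_angles(theta, psi), spec)

            def model(x, mu, A_d, phi_d, A_s, phi_s):
                th, ps = x
                return mu + A_d * np.cos(th - phi_d) + A_s * np.cos(ps - phi_s)

            # multi-start over phase grid: the nonlinear surface has local
            # optima in (phi_d, phi_s); keep the best SSE solution
            best, best_sse = None, np.inf
            for pd0 in (0.5, 2.0, 3.5, 5.0):
                for ps0 in (0.5, 2.0, 3.5, 5.0):
                    try:
                        popt, _ = optimize.curve_fit(
                            model, (theta, psi), y,
                            p0=[y.mean(), 0.5, pd0, 0.5, ps0], maxfev=20000,
                        )
                    except RuntimeError:
                        continue
                    sse = np.sum((model((theta, psi), *popt) - y) ** 2)
                    if sse < best_sse:
                        best, best_sse = popt, sse
            fitted_nl = model((theta, psi), *best)
            fitted_lin = (
                fit.mu
                + fit.A_d * np.cos(theta - fit.phi_d)
                + fit.A_s * np.cos(psi - fit.phi_s)
            )
            np.testing.assert_allclose(fitted_lin, fitted_nl, atol=1e-8)

    def test_rank_deficient_design_reported(self):
        theta = np.linspace(0, TWO_PI, 40, endpoint=False)
        meta = _meta_from_angles(theta, theta.copy())  # seasonal == diurnal angle
        with pytest.raises(ValueError, match="rank"):
            fit_cosinor(np.ones(40), meta, DesignSpec(covariates=[]))


class TestFStatCalibration:
    def test_null_p_values_uniform(self):
        """Gaussian-null features yield Uniform(0,1) nested-F p-values."""
        rng = np.random.default_rng(11)
        n, m = 200, 2000
        theta = rng.uniform(0, TWO_PI, n)
        psi = rng.uniform(0, TWO_PI, n)
        meta = _meta_from_angles(theta, psi)
        Y = rng.standard_normal((m, n))
        mat = pd.DataFrame(Y, index=[f"F{i}" for i in range(m)], columns=meta["sample_id"])
        fits = fit_matrix(mat, meta, DesignSpec(covariates=[]))
        ks = stats.kstest(fits["p_d"], "uniform").statistic
        assert ks < 0.035

    def test_power_rises_with_amplitude(self):
        rng = np.random.default_rng(13)
        n = 150
        theta = rng.uniform(0, TWO_PI, n)
        psi = rng.uniform(0, TWO_PI, n)
        meta = _meta_from_angles(theta, psi)
        spec = DesignSpec(covariates=[])
        rates = []
        for amp in (0.1, 0.3, 0.6):
            Y = amp * np.cos(theta - 1.0) + rng.standard_normal((200, n))
            mat = pd.DataFrame(Y, index=[f"F{i}" for i in range(200)],
                               columns=meta["sample_id"])
            fits = fit_matrix(mat, meta, spec)
            rates.append((fits["p_d"] < 0.05).mean())
        assert rates[0] < rates[1] < rates[2]


class TestInvariants:
    def test_time_origin_equivariance(self):
        rng = np.random.default_rng(5)
        n = 100
        theta = rng.uniform(0, TWO_PI, n)
        psi = rng.uniform(0, TWO_PI, n)
        y = 1 + 0.5 * np.cos(theta - 2.0) + 0.3 * np.cos(psi - 1.0) + rng.standard_normal(n)
        spec = DesignSpec(covariates=[])
        delta = 1.234
        f0 = fit_cosinor(y, _meta_from_angles(theta, psi), spec)
        f1 = fit_cosinor(y, _meta_from_angles((theta + delta) % TWO_PI, psi), spec)
        assert abs(wrap_signed(f1.phi_d - f0.phi_d - delta)) < 1e-9
        assert f1.A_d == pytest.approx(f0.A_d, abs=1e-9)
        assert f1.F_d == pytest.approx(f0.F_d, abs=1e-9)
        assert f1.p_d == pytest.approx(f0.p_d, abs=1e-9)

    def test_rss_monotonicity(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            n = 60
            theta = rng.uniform(0, TWO_PI, n)
            psi = rng.uniform(0, TWO_PI, n)
            y = rng.standard_normal(n)
            fit = fit_cosinor(y, _meta_from_angles(theta, psi), DesignSpec(covariates=[]))
            assert fit.rss_reduced_d >= fit.rss_full - 1e-12
            assert fit.rss_reduced_s >= fit.rss_full - 1e-12

    @pytest.mark.parametrize("phi,expected", [(np.pi, 0.0), (0.0, np.pi), (1.5 * np.pi, 0.5 * np.pi)])
    def test_nadir_is_acrophase_shifted_by_pi(self, phi, expected):
        assert nadir_from_acrophase(phi) == pytest.approx(expected, abs=1e-12)


class TestFitMatrix:
    def test_identical_features_identical_fits(self, small_cohort, plain_spec):
        _, samples, _, matrix = small_cohort
        trip = pd.concat([matrix.iloc[[0]]] * 3)
        trip.index = ["a", "b", "c"]
        fits = fit_matrix(trip, samples, plain_spec)
        for col in ("A_d", "phi_d", "F_d", "p_d"):
            assert np.ptp(fits[col].to_numpy()) < 1e-10

    def test_alignment_invariance_under_column_permutation(self, small_cohort, plain_spec):
        _, samples, _, matrix = small_cohort
        rng = np.random.default_rng(1)
        perm = rng.permutation(matrix.shape[1])
        fits0 = fit_matrix(matrix, samples, plain_spec)
        fits1 = fit_matrix(matrix.iloc[:, perm], samples, plain_spec)
        np.testing.assert_allclose(fits0["F_d"], fits1["F_d"], atol=1e-9)
        np.testing.assert_allclose(fits0["phi_d"], fits1["phi_d"], atol=1e-9)

    def test_acrophase_recovery_under_noise(self):
        cfg_kwargs = dict(n_samples=500, n_features=400, frac_rhythmic=0.1,
                          amp_fixed=0.5, noise_sd=1.0, seed=17)
        from pmrhythm.synthetic import SimulationConfig, simulate_matrix, simulate_samples, simulate_truth

        cfg = SimulationConfig(**cfg_kwargs)
        s = simulate_samples(cfg)
        t = simulate_truth(cfg)
        m = simulate_matrix(s, t, cfg)
        fits = fit_matrix(m, s, DesignSpec.for_mode("rna"))
        detected = (fits["p_d"] < 0.05) & t["is_rhythmic_diurnal"].to_numpy()
        err = np.abs(wrap_signed(fits.loc[detected, "phi_d"].to_numpy()
                                 - t.loc[detected.to_numpy(), "phi_d"].to_numpy()))
        assert detected.sum() > 10
        assert err.mean() < 0.35

    def test_feature_with_missing_values_uses_listwise_deletion(self, small_cohort, plain_spec):
        _, samples, _, matrix = small_cohort
        mat = matrix.iloc[:5].copy()
        mat.iloc[0, :30] = np.nan
        fits = fit_matrix(mat, samples, plain_spec)
        assert fits.loc[0, "n"] == matrix.shape[1] - 30
        assert not fits.loc[0, "degenerate_flag"]

    def test_feature_with_too_few_samples_flagged(self, small_cohort, plain_spec):
        _, samples, _, matrix = small_cohort
        mat = matrix.iloc[:3].copy()
        mat.iloc[1, 5:] = np.nan
        fits = fit_matrix(mat, samples, plain_spec)
        assert bool(fits.loc[1, "degenerate_flag"])
        assert np.isnan(fits.loc[1, "F_d"])
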