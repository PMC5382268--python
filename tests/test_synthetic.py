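"""Synthetic cohort generator: determinism, marginals, model inversion."""

import numpy as np
import pandas as pd
import pytest

from pmrhythm.circular import wrap_signed
from pmrhythm.cosinor import fit_matrix
from pmrhythm.synthetic import (
    SimulationConfig,
    compute_ad_global_score,
    simulate_annotations,
    simulate_matrix,
    simulate_samples,
    simulate_truth,
)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_samples": 5},
            {"frac_rhythmic": 1.5},
            {"coupling": -0.1},
            {"noise_sd": 0.0},
            {"frac_female": 2.0},
        ],
    )
    def test_invalid_fields_rejected_by_name(self, kwargs):
        with pytest.raises(ValueError, match=next(iter(kwargs))):
            SimulationConfig(**kwargs)


class TestSimulateSamples:
    def test_seeded_determinism(self):
        cfg = SimulationConfig(n_samples=100, seed=1)
        pd.testing.assert_frame_equal(simulate_samples(cfg), simulate_samples(cfg))

    def test_times_and_dates_in_range(self):
        cfg = SimulationConfig(n_samples=500, seed=3)
        s = simulate_samples(cfg)
        assert ((s["clock_time_of_death"] >= 0) & (s["clock_time_of_death"] < 24)).all()
        dates = pd.to_datetime(s["date_of_death"])
        assert (dates.dt.year == cfg.year).all()

    def test_cohort_marginals_match_configuration(self):
        cfg = SimulationConfig(n_samples=5000, seed=5)
        s = simulate_samples(cfg)
        assert 1 - s["sex_male"].mean() == pytest.approx(0.63, abs=0.03)
        assert s["depression"].mean() == pytest.approx(0.61, abs=0.03)
        assert s["ad_reagan_dx"].mean() == pytest.approx(0.59, abs=0.03)
        assert np.median(s["age_death"]) == pytest.approx(88.7, abs=1.0)
        assert np.median(s["pmi_hours"]) == pytest.approx(5.7, rel=0.15)


class TestSimulateTruth:
    def test_full_coupling_makes_every_morning_feature_fall(self):
        cfg = SimulationConfig(n_features=500, coupling=1.0, seed=2)
        t = simulate_truth(cfg)
        morning = t["diurnal_class"] == "morning"
        assert (t.loc[morning, "seasonal_class"] == "fall").all()
        assert (t.loc[~morning, "seasonal_class"] == "spring").all()

    def test_no_rhythmic_features_means_zero_amplitudes(self):
        cfg = SimulationConfig(n_features=200, frac_rhythmic=0.0, seed=2)
        t = simulate_truth(cfg)
        assert (t["A_d"] == 0).all() and (t["A_s"] == 0).all()

    def test_half_coupling_classes_independent(self):
        cfg = SimulationConfig(n_features=2000, coupling=0.5, seed=4)
        t = simulate_truth(cfg)
        tab = pd.crosstab(t["diurnal_class"], t["seasonal_class"]).to_numpy()
        from scipy.stats import chi2_contingency

        _, p, _, _ = chi2_contingency(tab, correction=False)
        assert p > 0.05

    def test_phases_wrapped_and_amplitudes_nonnegative(self):
        t = simulate_truth(SimulationConfig(n_features=300, seed=9))
        assert ((t["phi_d"] >= 0) & (t["phi_d"] < 2 * np.pi)).all()
        assert ((t["phi_s"] >= 0) & (t["phi_s"] < 2 * np.pi)).all()
        assert (t[["A_d", "A_s"]] >= 0).all().all()


class TestSimulateMatrix:
    def test_zero_noise_cosinor_inversion(self, clean_cohort, plain_spec):
        _, samples, truth, matrix = clean_cohort
        fits = fit_matrix(matrix, samples, plain_spec)
        np.testing.assert_allclose(fits["A_d"], truth["A_d"], atol=1e-6)
        err = np.abs(wrap_signed(fits["phi_d"].to_numpy() - truth["phi_d"].to_numpy()))
        assert err.max() < 1e-6

    def test_seeded_write_is_byte_identical(self, tmp_path):
        cfg = SimulationConfig(n_samples=50, n_features=20, seed=11)
        out = []
        for rep in range(2):
            s = simulate_samples(cfg)
            m = simulate_matrix(s, simulate_truth(cfg), cfg)
            p = tmp_path / f"m{rep}.tsv"
            m.to_csv(p, sep="\t")
            out.append(p.read_bytes())
        assert out[0] == out[1]

    def test_methylation_mode_stays_in_unit_interval(self):
        cfg = SimulationConfig(n_samples=50, n_features=30, seed=12)
        s = simulate_samples(cfg)
        m = simulate_matrix(s, simulate_truth(cfg), cfg, mode="meth")
        assert ((m > 0) & (m < 1)).all().all()

    def test_null_ad_effect_leaves_group_means_close(self):
        cfg = SimulationConfig(
            n_samples=2000, n_features=20, frac_rhythmic=1.0, amp_fixed=0.3,
            ad_phase_shift_h=0.0, ad_seasonal_shift_d=0.0, ad_amp_ratio=1.0,
            covariate_effect_sd=0.0, noise_sd=0.5, seed=13,
        )
        s = simulate_samples(cfg)
        m = simulate_matrix(s, simulate_truth(cfg), cfg)
        ad = s["ad_reagan_dx"].to_numpy().astype(bool)  # aligned with matrix columns
        diff = m.loc[:, ad].mean(axis=1) - m.loc[:, ~ad].mean(axis=1)
        assert np.abs(diff).mean() < 0.1


class TestSimulateAnnotations:
    def test_bed_outputs_sorted_half_open_nonnegative(self):
        cfg = SimulationConfig(n_features=200, seed=6)
        truth = simulate_truth(cfg)
        _, peaks, tf_sites = simulate_annotations(truth, cfg)
        for bed in (peaks, tf_sites):
            assert (bed["start"] >= 0).all()
            assert (bed["start"] < bed["end"]).all()
            grouped = bed.groupby("chrom")["start"]
            assert all(g.is_monotonic_increasing for _, g in grouped)

    def test_point_mass_at_zero_distance_makes_all_proximal(self):
        cfg = SimulationConfig(n_features=100, frac_tss_proximal=1.0,
                               tss_proximal_max_bp=0, seed=6)
        truth = simulate_truth(cfg)
        assert (truth["tss_distance"] == 0).all()

    def test_tf_indicator_rates_follow_class_probs(self):
        cfg = SimulationConfig(
            n_features=3000, seed=8,
            tf_site_class_probs={"TFX": (0.8, 0.2), "TFY": (0.3, 0.3)},
        )
        t = simulate_truth(cfg)
        morning = t["diurnal_class"] == "morning"
        assert t.loc[morning, "tf_TFX"].mean() == pytest.approx(0.8, abs=0.05)
        assert t.loc[~morning, "tf_TFX"].mean() == pytest.approx(0.2, abs=0.05)


class TestAdGlobalScore:
    def test_identical_participants_score_zero(self):
        df = pd.DataFrame(np.ones((5, 12)))
        with pytest.raises(ValueError, match="zero-variance"):
            compute_ad_global_score(df)

    def test_matches_two_step_zscore_oracle(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.gamma(2.0, 1.5, size=(40, 12)))
        expected = np.zeros(40)
        for c in df.columns:
            col = df[c].to_numpy()
            expected += (col - col.mean()) / col.std(ddof=1)
        expected /= 12
        np.testing.assert_allclose(compute_ad_global_score(df), expected, atol=1e-12)

    def test_uniform_one_sd_participant_scores_one(self):
        rng = np.random.default_rng(4)
        base = rng.normal(10, 2, size=(30, 6))
        df = pd.DataFrame(base)
        mean, sd = df.mean(), df.std(ddof=1)
        df.loc[30] = (mean + sd).to_numpy()
        scores = compute_ad_global_score(df)
        # the appended participant sits ~1 s.d. above the mean in every column
        assert scores.iloc[-1] == pytest.approx(1.0, abs=0.05)
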