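"""Shared fixtures: small seeded synthetic cohorts reused across tests."""

import pytest

from pmrhythm.cosinor import DesignSpec
from pmrhythm.synthetic import (
    SimulationConfig,
    simulate_matrix,
    simulate_samples,
    simulate_truth,
)


@pytest.fixture(scope="session")
def small_cohort():
    """200 subjects, 300 features, 20% rhythmic at A=0.5, unit noise."""
    cfg = SimulationConfig(
        n_samples=200, n_features=300, frac_rhythmic=0.2, amp_fixed=0.5, noise_sd=1.0, seed=42
    )
    samples = simulate_samples(cfg)
    truth = simulate_truth(cfg)
    matrix = simulate_matrix(samples, truth, cfg)
    return cfg, samples, truth, matrix


@pytest.fixture(scope="session")
def clean_cohort():
    """Essentially noise-free cohort: every feature rhythmic, no covariates."""
    cfg = SimulationConfig(
        n_samples=150,
        n_features=40,
        frac_rhythmic=1.0,
        amp_fixed=0.5,
        noise_sd=1e-9,
        covariate_effect_sd=0.0,
        ad_phase_shift_h=0.0,
        ad_seasonal_shift_d=0.0,
        ad_amp_ratio=1.0,
        seed=7,
    )
    samples = simulate_samples(cfg)
    truth = simulate_truth(cfg)
    matrix = simulate_matrix(samples, truth, cfg)
    return cfg, samples, truth, matrix


@pytest.fixture(scope="session")
def plain_spec():
    return DesignSpec(diurnal_angle="zt", covariates=[])


@pytest.fixture(scope="session")
def rna_spec():
    return DesignSpec.for_mode("rna")
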