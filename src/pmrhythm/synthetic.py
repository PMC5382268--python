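"""Synthetic cohorts with known diurnal/seasonal rhythm structure.

The generator emulates the statistical structure of a post-mortem brain
cohort: one death timestamp per subject spread over the 24-h day and the
365-day year; covariate marginals typical of an old, community-based
autopsy cohort (median age near 89, about 63% female, 61% with at least
one depressive symptom, median post-mortem interval near 5.7 h, 59% with
a pathological Alzheimer's diagnosis); bimodal diurnal acrophases near
ZT0 and ZT12 and bimodal seasonal acrophases near spring and fall, with a
configurable morning-fall coupling; additive covariate effects; AD-linked
phase shifts and amplitude attenuation; TSS-proximity structure for
epigenomic features; and class-dependent transcription-factor site
placement.

The expression model is the exact inverse of the analysis model:

    y = mu + A_d*cos(theta - phi_d) + A_s*cos(psi - phi_s)
           + sum_k gamma_k x_k + eps,  eps ~ N(0, noise_sd)

so at zero noise the downstream cosinor fit recovers the planted
parameters to machine precision.  Methylation-mode output passes the
linear predictor through a logistic squash so beta values stay in (0, 1).

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import timeref
from .circular import wrap_angle

TWO_PI = 2.0 * np.pi

#: Chicago — the cohort's default site
DEFAULT_SITE = {"latitude": 41.88, "longitude": -87.63, "utc_offset": -6.0}

#: default seasonal acrophase centers: mid-April (spring) and mid-October (fall)
SPRING_CENTER = TWO_PI * 104.0 / 365.0
FALL_CENTER = (SPRING_CENTER + np.pi) % TWO_PI


@dataclass
class SimulationConfig:
    """All knobs of the synthetic cohort generator.

    Defaults encode the emulated study conditions: cohort marginals from
    an aged autopsy cohort, acrophase clusters at ZT0/ZT12 and
    spring/fall, strong (0.9) morning-fall coupling, a -1.5 h diurnal
    phase advance and +15 d seasonal delay with 20% amplitude attenuation
    in pathological AD.  Per-feature amplitudes are log-normal with median
    ``amp_median`` (log2-expression units); rhythm effect sizes in real
    cortex are unreported, so the default (0.1) is simply small relative
    to the unit noise.
    """

    n_samples: int = 400
    n_features: int = 1000
    frac_rhythmic: float = 0.2
    diurnal_centers: tuple[float, float] = (0.0, np.pi)  # ZT0, ZT12
    seasonal_centers: tuple[float, float] = (SPRING_CENTER, FALL_CENTER)
    vonmises_kappa: float = 8.0
    coupling: float = 0.9  # P(fall seasonal class | morning diurnal class)
    amp_median: float = 0.1
    amp_log_sd: float = 0.5
    amp_fixed: float | None = None  # overrides the log-normal law when set
    noise_sd: float = 1.0
    covariate_effect_sd: float = 0.05
    mean_level: float = 5.0
    mean_level_sd: float = 1.0
    # cohort marginals
    age_median: float = 88.7
    age_sd: float = 6.0
    frac_female: float = 0.63
    frac_depression: float = 0.61
    pmi_median_h: float = 5.7
    frac_ad: float = 0.59
    # AD rhythm modification
    ad_phase_shift_h: float = -1.5
    ad_seasonal_shift_d: float = 15.0
    ad_amp_ratio: float = 0.8
    # annotation structure
    frac_tss_proximal: float = 0.5
    tss_proximal_max_bp: int = 2000
    tss_distal_range_bp: tuple[int, int] = (5000, 40000)
    peak_width_bp: int = 500
    n_tfs: int = 10
    tf_site_class_probs: dict[str, tuple[float, float]] = field(default_factory=dict)
    tf_background_prob: float = 0.2
    site: dict = field(default_factory=lambda: dict(DEFAULT_SITE))
    year: int = 2015
    n_batches: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 10:
            raise ValueError(f"n_samples must be >= 10, got {self.n_samples}")
        if self.n_features < 1:
            raise ValueError("n_features must be positive")
        if not (0.0 <= self.frac_rhythmic <= 1.0):
            raise ValueError(f"frac_rhythmic must be in [0,1], got {self.frac_rhythmic}")
        if not (0.0 <= self.coupling <= 1.0):
            raise ValueError(f"coupling must be in [0,1], got {self.coupling}")
        if self.noise_sd <= 0:
            raise ValueError(f"noise_sd must be > 0, got {self.noise_sd}")
        for name in ("frac_female", "frac_depression", "frac_ad", "frac_tss_proximal"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0,1], got {v}")

    def tf_names(self) -> list[str]:
        if self.tf_site_class_probs:
            return sorted(self.tf_site_class_probs)
        return [f"TF{i + 1}" for i in range(self.n_tfs)]

    def tf_probs(self, tf: str) -> tuple[float, float]:
        """(P(site | morning feature), P(site | evening feature))."""
        return self.tf_site_class_probs.get(tf, (self.tf_background_prob, self.tf_background_prob))


def _rng(cfg: SimulationConfig, stream: str) -> np.random.Generator:
    streams = {"samples": 1, "truth": 2, "matrix": 3, "annotations": 4}
    return np.random.default_rng(np.random.SeedSequence([int(cfg.seed), streams[stream]]))


def simulate_samples(cfg: SimulationConfig) -> pd.DataFrame:
    """Sample-metadata table: death timestamps, site, covariates.

    Death dates are uniform over one (non-leap by default) year and clock
    times uniform over the 24-h day; covariates follow the configured
    cohort marginals.  Output carries the standard metadata schema plus
    sun-event and angle columns.
    """
    rng = _rng(cfg, "samples")
    n = cfg.n_samples
    day = rng.integers(0, 365, size=n)
    dates = pd.to_datetime(f"{cfg.year}-01-01") + pd.to_timedelta(day, unit="D")
    clock = rng.uniform(0.0, 24.0, size=n)
    age = cfg.age_median + cfg.age_sd * rng.standard_normal(n)
    meta = pd.DataFrame(
        {
            "sample_id": [f"S{i:04d}" for i in range(n)],
            "date_of_death": dates.strftime("%Y-%m-%d"),
            "clock_time_of_death": clock,
            "latitude": cfg.site["latitude"],
            "longitude": cfg.site["longitude"],
            "utc_offset": cfg.site["utc_offset"],
            "age_death": np.clip(age, 65.0, 110.0),
            "sex_male": (rng.uniform(size=n) > cfg.frac_female).astype(int),
            "pmi_hours": cfg.pmi_median_h * np.exp(0.45 * rng.standard_normal(n)),
            "depression": (rng.uniform(size=n) < cfg.frac_depression).astype(int),
            "ad_reagan_dx": (rng.uniform(size=n) < cfg.frac_ad).astype(int),
            "batch": [f"B{rng.integers(1, cfg.n_batches + 1)}" for _ in range(n)],
            "rin": np.clip(7.0 + 0.7 * rng.standard_normal(n), 5.1, 10.0),
            "chip_crosscorr": np.clip(0.08 + 0.02 * rng.standard_normal(n), 0.03, 0.2),
        }
    )
    # pathology burden: log-normal, shifted upward for NIA-Reagan positives
    meta["ad_global_score"] = np.exp(
        np.log(0.35) + 0.6 * rng.standard_normal(n)
    ) + 0.4 * meta["ad_reagan_dx"]
    return timeref.add_time_columns(meta)


def simulate_truth(cfg: SimulationConfig) -> pd.DataFrame:
    """Per-feature ground truth: rhythm flags, amplitudes, phases, classes.

    Rhythmic features draw diurnal acrophases from a two-component von
    Mises mixture at the configured centers; the seasonal class is coupled
    to the diurnal class (morning -> fall with probability ``coupling``)
    and seasonal acrophases are drawn around the class center.  AD phase
    shifts and the amplitude ratio apply to rhythmic features only.
    """
    rng = _rng(cfg, "truth")
    m = cfg.n_features
    rhythmic = rng.uniform(size=m) < cfg.frac_rhythmic
    morning = rng.uniform(size=m) < 0.5
    fall = np.where(
        morning,
        rng.uniform(size=m) < cfg.coupling,
        rng.uniform(size=m) >= cfg.coupling,
    )
    phi_d = np.where(
        morning,
        rng.vonmises(cfg.diurnal_centers[0], cfg.vonmises_kappa, size=m),
        rng.vonmises(cfg.diurnal_centers[1], cfg.vonmises_kappa, size=m),
    )
    spring_c, fall_c = cfg.seasonal_centers
    phi_s = np.where(
        fall,
        rng.vonmises(fall_c, cfg.vonmises_kappa, size=m),
        rng.vonmises(spring_c, cfg.vonmises_kappa, size=m),
    )
    if cfg.amp_fixed is not None:
        amp_d = np.full(m, float(cfg.amp_fixed))
        amp_s = np.full(m, float(cfg.amp_fixed))
    else:
        amp_d = cfg.amp_median * np.exp(cfg.amp_log_sd * rng.standard_normal(m))
        amp_s = cfg.amp_median * np.exp(cfg.amp_log_sd * rng.standard_normal(m))

    proximal = rng.uniform(size=m) < cfg.frac_tss_proximal
    lo, hi = cfg.tss_distal_range_bp
    tss_distance = np.where(
        proximal,
        rng.integers(0, cfg.tss_proximal_max_bp + 1, size=m),
        rng.integers(lo, hi, size=m),
    )

    truth = pd.DataFrame(
        {
            "feature_id": [f"F{i:05d}" for i in range(m)],
            "is_rhythmic_diurnal": rhythmic,
            "is_rhythmic_seasonal": rhythmic,
            "A_d": np.where(rhythmic, amp_d, 0.0),
            "A_s": np.where(rhythmic, amp_s, 0.0),
            "phi_d": wrap_angle(phi_d),
            "phi_s": wrap_angle(phi_s),
            "diurnal_class": np.where(morning, "morning", "evening"),
            "seasonal_class": np.where(fall, "fall", "spring"),
            "ad_delta_phi_d": np.where(rhythmic, cfg.ad_phase_shift_h * TWO_PI / 24.0, 0.0),
            "ad_delta_phi_s": np.where(rhythmic, cfg.ad_seasonal_shift_d * TWO_PI / 365.0, 0.0),
            "ad_amp_ratio": np.where(rhythmic, cfg.ad_amp_ratio, 1.0),
            "tss_distance": tss_distance,
        }
    )
    for tf in cfg.tf_names():
        p_morning, p_evening = cfg.tf_probs(tf)
        p = np.where(morning, p_morning, p_evening)
        truth[f"tf_{tf}"] = (rng.uniform(size=m) < p).astype(int)
    return truth


#: covariates with additive effects on expression in the generator
EFFECT_COVARIATES = ["age_death", "sex_male", "pmi_hours", "depression", "ad_global_score", "rin"]


def simulate_matrix(
    samples: pd.DataFrame,
    truth: pd.DataFrame,
    cfg: SimulationConfig,
    mode: str = "rna",
) -> pd.DataFrame:
    """Feature-by-sample measurement matrix from cohort + truth tables.

    Applies the cosinor generative model with the subject's zeitgeber
    diurnal angle and seasonal angle, per-feature covariate effects (drawn
    once per feature with scale ``covariate_effect_sd``; the batch
    covariate acts through a per-batch offset), AD-specific phase shifts
    and amplitude attenuation, and Gaussian noise.  ``mode='meth'``
    squashes the linear predictor through a logistic link so values lie
    in (0, 1).
    """
    if mode not in ("rna", "h3k9ac", "meth"):
        raise ValueError(f"mode must be rna/h3k9ac/meth, got {mode!r}")
    needed = {"theta_zt", "psi_season"}
    if not needed <= set(samples.columns):
        raise ValueError("samples table lacks angle columns; run timeref.add_time_columns")
    rng = _rng(cfg, "matrix")
    n, m = len(samples), len(truth)

    theta = samples["theta_zt"].to_numpy()
    psi = samples["psi_season"].to_numpy()
    ad = samples["ad_reagan_dx"].to_numpy(dtype=float)

    # feature x sample phase/amplitude with AD modification
    phi_d = truth["phi_d"].to_numpy()[:, None] + truth["ad_delta_phi_d"].to_numpy()[:, None] * ad
    phi_s = truth["phi_s"].to_numpy()[:, None] + truth["ad_delta_phi_s"].to_numpy()[:, None] * ad
    ratio = 1.0 + (truth["ad_amp_ratio"].to_numpy()[:, None] - 1.0) * ad
    A_d = truth["A_d"].to_numpy()[:, None] * ratio
    A_s = truth["A_s"].to_numpy()[:, None] * ratio

    mu = cfg.mean_level + cfg.mean_level_sd * rng.standard_normal(m)
    if mode == "meth":
        mu = rng.uniform(-2.0, 2.0, size=m)  # logit-scale baseline

    lp = mu[:, None] + A_d * np.cos(theta[None, :] - phi_d) + A_s * np.cos(psi[None, :] - phi_s)

    # covariate effects, standardized so effect scales are comparable
    gammas = cfg.covariate_effect_sd * rng.standard_normal((m, len(EFFECT_COVARIATES)))
    for k, cov in enumerate(EFFECT_COVARIATES):
        x = samples[cov].to_numpy(dtype=float)
        x = (x - x.mean()) / (x.std() if x.std() > 0 else 1.0)
        lp += gammas[:, [k]] * x[None, :]
    batch_codes = pd.Categorical(samples["batch"]).codes
    batch_offsets = cfg.covariate_effect_sd * rng.standard_normal((m, batch_codes.max() + 1))
    lp += batch_offsets[:, batch_codes]

    lp = lp + cfg.noise_sd * rng.standard_normal((m, n))
    if mode == "meth":
        lp = 1.0 / (1.0 + np.exp(-lp))
    return pd.DataFrame(lp, index=truth["feature_id"], columns=samples["sample_id"])


def simulate_annotations(truth: pd.DataFrame, cfg: SimulationConfig):
    """Synthetic genome annotations consistent with the truth table.

    Places each feature's transcript TSS on a synthetic genome (two
    chromosomes, fixed spacing), derives an epigenomic interval (peak) for
    the feature at its planted TSS distance, and scatters TF binding sites
    near features according to their per-class indicators.

    Returns ``(tss, peaks, tf_sites)``: a TSS table (feature_id, chrom,
    tss_pos, strand, active) and two BED-like DataFrames (chrom, start,
    end, name, score, strand), sorted, 0-based half-open.
    """
    rng = _rng(cfg, "annotations")
    m = len(truth)
    spacing = 100_000
    half = (m + 1) // 2
    chrom = np.where(np.arange(m) < half, "chr1", "chr2")
    pos_in_chrom = np.where(np.arange(m) < half, np.arange(m), np.arange(m) - half)
    tss_pos = (pos_in_chrom + 1) * spacing
    strand = np.where(rng.uniform(size=m) < 0.5, "+", "-")
    tss = pd.DataFrame(
        {
            "feature_id": truth["feature_id"],
            "chrom": chrom,
            "tss_pos": tss_pos,
            "strand": strand,
            "active": True,
        }
    )

    dist = truth["tss_distance"].to_numpy()
    sign = np.where(rng.uniform(size=m) < 0.5, -1, 1)
    # place the interval so its nearest edge sits at the planted distance
    start = np.where(sign > 0, tss_pos + dist, np.maximum(tss_pos - dist - cfg.peak_width_bp, 0))
    peaks = pd.DataFrame(
        {
            "chrom": chrom,
            "start": start,
            "end": start + cfg.peak_width_bp,
            "name": [f"peak_{fid}" for fid in truth["feature_id"]],
            "score": 0,
            "strand": ".",
        }
    )

    rows = []
    for tf in cfg.tf_names():
        ind = truth[f"tf_{tf}"].to_numpy().astype(bool)
        for j in np.nonzero(ind)[0]:
            offset = int(rng.integers(-1500, 1500))
            s = max(tss_pos[j] + offset, 0)
            rows.append((chrom[j], s, s + 15, tf, 0, "."))
        # background sites far from any TSS
        n_bg = int(rng.integers(1, 4))
        for _ in range(n_bg):
            c = "chr1" if rng.uniform() < 0.5 else "chr2"
            s = int(rng.integers(0, (half + 1) * spacing))
            s = s - (s % spacing) + spacing // 2  # midway between TSSs
            rows.append((c, s, s + 15, tf, 0, "."))
    tf_sites = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])
    peaks = peaks.sort_values(["chrom", "start", "end"]).reset_index(drop=True)
    tf_sites = tf_sites.sort_values(["chrom", "start", "end"]).reset_index(drop=True)
    return tss, peaks, tf_sites


def compute_ad_global_score(densities: pd.DataFrame) -> pd.Series:
    """Pathology summary score from region x pathology density counts.

    ``densities`` has one row per participant and one column per
    (region, pathology) density per mm^2.  Each column is z-scaled across
    participants and the z-scores are averaged across all columns.
    """
    if len(densities) < 2:
        raise ValueError("need at least 2 participants to standardize densities")
    sd = densities.std(ddof=1)
    zero = sd[sd == 0]
    if len(zero):
        raise ValueError(f"zero-variance density columns: {list(zero.index)}")
    z = (densities - densities.mean()) / sd
    return z.mean(axis=1)
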