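"""Alzheimer's disease and the amplitude/timing of molecular rhythms.

The base cosinor design is augmented with interactions between each
cosine/sine term and three modifiers — pathological AD diagnosis, age at
death and male sex — so that AD-specific rhythm parameters are estimated
while the age and sex effects on those parameters are adjusted for:

    y = mu + sum_m in {AD, age, sex} and base:
        (a_d + sum_m a_dm x_m) cos(theta) + (b_d + sum_m b_dm x_m) sin(theta)
      + (a_s + sum_m a_sm x_m) cos(psi)  + (b_s + sum_m b_sm x_m) sin(psi)
      + main effects of AD, age, sex + eps

Group-specific parameters are read off at AD in {0, 1} with age and sex
fixed at their cohort means: e.g.  a_d(g) = a_d + a_dAD*g +
a_dage*mean(age) + a_dsex*mean(sex), then A(g), phi(g) via the standard
amplitude/phase identities.  The relative amplitude is the amplitude
divided by the model-predicted mean level of that group (covariates at
cohort means), a standard cosinor normalization; raw amplitudes are also
returned.

Cohort-level AD effects are summarized as the median across features of
the circular difference (AD minus non-AD) in acrophase — wrapped to
(-12, 12] hours diurnally and (-182.5, 182.5] days seasonally — and of
the difference in relative amplitude.  Permutation p-values shuffle times
of death (diurnal metrics) or dates (seasonal metrics) and recompute the
whole procedure; AD labels are never shuffled, so the AD-covariate
structure is preserved under the null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .circular import wrap_signed
from .clustering import classify_features
from .cosinor import DIURNAL_ANGLE_COLUMN, DesignSpec, amp_phase
from .permutation import _aligned_arrays, child_rng, permutation_p, permute_metadata

TWO_PI = 2.0 * np.pi

#: rhythm-parameter modifiers, in design order
MODIFIERS = ["ad_reagan_dx", "age_death", "sex_male"]

AD_FIT_COLUMNS = [
    "feature_id",
    "phi_d_ad",
    "phi_d_nonad",
    "delta_phi_d_h",
    "A_d_ad",
    "A_d_nonad",
    "A_rel_d_ad",
    "A_rel_d_nonad",
    "phi_s_ad",
    "phi_s_nonad",
    "delta_phi_s_d",
    "A_s_ad",
    "A_s_nonad",
    "A_rel_s_ad",
    "A_rel_s_nonad",
]


def _ad_design(meta: pd.DataFrame, spec: DesignSpec):
    """Base cosinor design augmented with modifier x (cos, sin) interactions.

    Modifier main effects are included through the covariate set (AD
    enters via ad_reagan_dx if present in the covariates, else appended).
    Returns (X, names, rhythm_ix) where rhythm_ix maps each of the four
    rhythm columns to the indices of its interaction columns.
    """
    theta = meta[DIURNAL_ANGLE_COLUMN[spec.diurnal_angle]].to_numpy(dtype=float)
    psi = meta["psi_season"].to_numpy(dtype=float)
    base = [np.ones_like(theta), np.cos(theta), np.sin(theta), np.cos(psi), np.sin(psi)]
    names = ["intercept", "cos_d", "sin_d", "cos_s", "sin_s"]

    cov = spec.covariate_frame(meta)
    for mod in MODIFIERS:
        if mod not in cov.columns:
            cov[mod] = meta[mod].astype(float)
    for c in cov.columns:
        base.append(cov[c].to_numpy(dtype=float))
        names.append(c)

    rhythm_ix: dict[str, dict[str, int]] = {k: {} for k in ("cos_d", "sin_d", "cos_s", "sin_s")}
    for mod in MODIFIERS:
        x = meta[mod].to_numpy(dtype=float)
        for k, col in zip(("cos_d", "sin_d", "cos_s", "sin_s"), (base[1], base[2], base[3], base[4])):
            base.append(x * col)
            rhythm_ix[k][mod] = len(base) - 1
            names.append(f"{k}:{mod}")
    X = np.column_stack(base)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(
            f"AD-augmented design is rank-deficient (rank {rank} < {X.shape[1]}); columns: {names}"
        )
    return X, names, rhythm_ix, cov


def fit_ad_matrix(matrix: pd.DataFrame, meta: pd.DataFrame, spec: DesignSpec) -> pd.DataFrame:
    """Group-specific rhythm parameters per feature under the AD model.

    Returns one row per complete feature with AD and non-AD amplitudes,
    relative amplitudes, acrophases, and wrapped acrophase differences in
    hours (diurnal) and days (seasonal).
    """
    Y, meta_aligned = _aligned_arrays(matrix, meta)
    finite = np.all(np.isfinite(Y), axis=0)
    if not finite.all():
        Y = Y[:, finite]
    ids = matrix.index.to_numpy()[finite]
    if meta_aligned["ad_reagan_dx"].nunique() < 2:
        raise ValueError("both AD and non-AD subjects are required")
    return _fit_ad_arrays(Y, meta_aligned, spec, ids)


def _fit_ad_arrays(Y: np.ndarray, meta: pd.DataFrame, spec: DesignSpec, ids) -> pd.DataFrame:
    X, names, rhythm_ix, cov = _ad_design(meta, spec)
    n, p = X.shape
    if n <= p + 2:
        raise ValueError(f"too few samples ({n}) for {p} design columns")
    coef, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)

    mods_mean = {m: float(meta[m].astype(float).mean()) for m in MODIFIERS}
    name_ix = {nm: i for i, nm in enumerate(names)}

    def group_coef(term: str, g: int) -> np.ndarray:
        c = coef[name_ix[term]].copy()
        for mod in MODIFIERS:
            x = float(g) if mod == "ad_reagan_dx" else mods_mean[mod]
            c = c + coef[rhythm_ix[term][mod]] * x
        return c

    # model-predicted mean level per group: covariates at cohort means, AD at g
    cov_means = cov.mean(axis=0)
    out = {}
    for g, tag in ((1, "ad"), (0, "nonad")):
        level = coef[name_ix["intercept"]].copy()
        for c in cov.columns:
            x = float(g) if c == "ad_reagan_dx" else float(cov_means[c])
            level = level + coef[name_ix[c]] * x
        A_d, phi_d = amp_phase(group_coef("cos_d", g), group_coef("sin_d", g))
        A_s, phi_s = amp_phase(group_coef("cos_s", g), group_coef("sin_s", g))
        with np.errstate(divide="ignore", invalid="ignore"):
            out[f"A_rel_d_{tag}"] = np.where(level != 0, A_d / level, np.nan)
            out[f"A_rel_s_{tag}"] = np.where(level != 0, A_s / level, np.nan)
        out[f"A_d_{tag}"] = A_d
        out[f"A_s_{tag}"] = A_s
        out[f"phi_d_{tag}"] = phi_d
        out[f"phi_s_{tag}"] = phi_s

    delta_d = wrap_signed(out["phi_d_ad"] - out["phi_d_nonad"]) * 24.0 / TWO_PI
    delta_s = wrap_signed(out["phi_s_ad"] - out["phi_s_nonad"]) * 365.0 / TWO_PI
    frame = pd.DataFrame({"feature_id": ids})
    for k in AD_FIT_COLUMNS[1:]:
        if k == "delta_phi_d_h":
            frame[k] = delta_d
        elif k == "delta_phi_s_d":
            frame[k] = delta_s
        else:
            frame[k] = out[k]
    return frame


def fit_ad_cosinor(y, meta: pd.DataFrame, spec: DesignSpec, feature_id: str = "feature"):
    """Single-feature convenience wrapper around :func:`fit_ad_matrix`."""
    mat = pd.DataFrame([np.asarray(y, dtype=float)], index=[feature_id], columns=meta["sample_id"])
    return fit_ad_matrix(mat, meta, spec).iloc[0]


def classify_by_nonad_phase(ad_fits: pd.DataFrame, seed: int = 0, use_nadir: bool = False):
    """Temporal classification from the non-AD-group acrophases.

    The classes are defined on the unaffected group so AD-group phases can
    be summarized against fixed class boundaries.
    """
    return classify_features(
        ad_fits["phi_d_nonad"].to_numpy(),
        ad_fits["phi_s_nonad"].to_numpy(),
        seed=seed,
        feature_ids=ad_fits["feature_id"].tolist(),
        use_nadir=use_nadir,
    )


@dataclass
class AdDifferenceSummary:
    """Median AD-vs-non-AD rhythm differences with permutation p-values."""

    scope: str
    n_features: int
    median_delta_phi_d_h: float
    median_delta_phi_s_d: float
    median_delta_arel_d: float
    median_delta_arel_s: float
    p_phi_d: float
    p_phi_s: float
    p_arel_d: float
    p_arel_s: float
    B: int
    seed: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _median_deltas(fits: pd.DataFrame) -> tuple[float, float, float, float]:
    return (
        float(np.median(fits["delta_phi_d_h"])),
        float(np.median(fits["delta_phi_s_d"])),
        float(np.median(fits["A_rel_d_ad"] - fits["A_rel_d_nonad"])),
        float(np.median(fits["A_rel_s_ad"] - fits["A_rel_s_nonad"])),
    )


def ad_median_differences(
    matrix: pd.DataFrame,
    meta: pd.DataFrame,
    spec: DesignSpec,
    B: int = 200,
    seed: int = 0,
    feature_subset=None,
    scope: str = "all",
    recompute_sun: bool = False,
) -> AdDifferenceSummary:
    """Median AD phase/amplitude differences and their permutation tests.

    Diurnal metrics (acrophase difference in hours, relative-amplitude
    difference) are tested against nulls that shuffle times of death;
    seasonal metrics against nulls that shuffle dates.  Two-sided
    empirical p-values (|null median| >= |observed median|).
    ``feature_subset`` restricts to a feature-ID collection (e.g. one
    temporal class, or rhythmic features only).
    """
    if feature_subset is not None:
        matrix = matrix.loc[matrix.index.isin(set(feature_subset))]
    if len(matrix) < 20:
        raise ValueError(f"need >= 20 features in scope, got {len(matrix)}")

    Y, meta_aligned = _aligned_arrays(matrix, meta)
    finite = np.all(np.isfinite(Y), axis=0)
    Y = Y[:, finite]
    ids = matrix.index.to_numpy()[finite]

    obs = _median_deltas(_fit_ad_arrays(Y, meta_aligned, spec, ids))
    null = np.empty((B, 4))
    for b in range(B):
        meta_t = permute_metadata(meta_aligned, "times", child_rng(seed, b), recompute_sun)
        d = _median_deltas(_fit_ad_arrays(Y, meta_t, spec, ids))
        null[b, 0], null[b, 2] = d[0], d[2]
        meta_d = permute_metadata(meta_aligned, "dates", child_rng(seed, B + b), recompute_sun)
        d = _median_deltas(_fit_ad_arrays(Y, meta_d, spec, ids))
        null[b, 1], null[b, 3] = d[1], d[3]

    p = [permutation_p(obs[k], null[:, k], tail="two_sided") for k in range(4)]
    return AdDifferenceSummary(
        scope=scope,
        n_features=int(ids.size),
        median_delta_phi_d_h=obs[0],
        median_delta_phi_s_d=obs[1],
        median_delta_arel_d=obs[2],
        median_delta_arel_s=obs[3],
        p_phi_d=p[0],
        p_phi_s=p[1],
        p_arel_d=p[2],
        p_arel_s=p[3],
        B=B,
        seed=seed,
    )
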