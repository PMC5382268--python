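"""Joint diurnal + seasonal cosinor regression, fit by linearized OLS.

Model per feature, with one observation per subject:

    y = mu + A_d * cos(theta - phi_d) + A_s * cos(psi - phi_s)
           + sum_k gamma_k * x_k + eps

where theta is the diurnal angle (24-h period) and psi the seasonal angle
(365-day period) of the subject's death, and x_k are clinical/technical
covariates.  Both periods are fixed — each subject contributes a single
time point, so period estimation is impossible by design.  The model is
linearized via

    A*cos(t - phi) = a*cos(t) + b*sin(t),  A = sqrt(a^2 + b^2),
    phi = atan2(b, a)

and fit by ordinary least squares on the design
[1, cos(theta), sin(theta), cos(psi), sin(psi), covariates].

Rhythmicity per period is assessed with a nested F test: the full model's
residual sum of squares against a reduced model omitting that period's
cosine/sine pair, F with (2, n - p_full) degrees of freedom.

Fitting is vectorized across features: all features share the sample
design matrix, so a whole matrix is fit with a single least-squares solve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

TWO_PI = 2.0 * np.pi

DIURNAL_ANGLE_COLUMN = {"zt": "theta_zt", "clock": "theta_clock", "darkmid": "theta_darkmid"}

#: default covariate adjustment sets per data modality
MODE_COVARIATES = {
    "rna": ["age_death", "sex_male", "pmi_hours", "depression", "ad_global_score", "batch", "rin"],
    "h3k9ac": [
        "age_death",
        "sex_male",
        "pmi_hours",
        "depression",
        "ad_global_score",
        "batch",
        "chip_crosscorr",
    ],
    "meth": ["age_death", "sex_male", "pmi_hours", "depression", "ad_global_score", "batch"],
}

#: amplitudes below this are treated as degenerate (phase undefined)
DEGENERATE_AMPLITUDE = 1e-12

FIT_COLUMNS = [
    "feature_id",
    "n",
    "mu",
    "a_d",
    "b_d",
    "a_s",
    "b_s",
    "A_d",
    "phi_d",
    "A_s",
    "phi_s",
    "F_d",
    "p_d",
    "F_s",
    "p_s",
    "degenerate_flag",
]


@dataclass
class DesignSpec:
    """Which diurnal reference and which covariates enter the design.

    ``diurnal_angle`` is one of ``zt`` (0 = sunrise), ``clock``
    (0 = midnight) or ``darkmid`` (0 = dark-period midpoint).  String
    covariates (e.g. ``batch``) are expanded to treatment-coded dummies.
    """

    diurnal_angle: str = "zt"
    covariates: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.diurnal_angle not in DIURNAL_ANGLE_COLUMN:
            raise ValueError(
                f"diurnal_angle must be one of {sorted(DIURNAL_ANGLE_COLUMN)}, "
                f"got {self.diurnal_angle!r}"
            )

    @classmethod
    def for_mode(cls, mode: str, diurnal_angle: str = "zt") -> "DesignSpec":
        if mode not in MODE_COVARIATES:
            raise ValueError(f"mode must be one of {sorted(MODE_COVARIATES)}, got {mode!r}")
        return cls(diurnal_angle=diurnal_angle, covariates=list(MODE_COVARIATES[mode]))

    def covariate_frame(self, meta: pd.DataFrame) -> pd.DataFrame:
        """Numeric covariate columns, with categorical columns dummy-coded."""
        missing = [c for c in self.covariates if c not in meta.columns]
        if missing:
            raise ValueError(f"metadata lacks covariate columns: {missing}")
        parts = []
        for c in self.covariates:
            col = meta[c]
            if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
                dummies = pd.get_dummies(col, prefix=c, drop_first=True, dtype=float)
                parts.append(dummies)
            else:
                parts.append(col.astype(float).to_frame(c))
        if not parts:
            return pd.DataFrame(index=meta.index)
        return pd.concat(parts, axis=1)

    def design(self, meta: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
        """Full design matrix [1, cos t, sin t, cos psi, sin psi, covariates]."""
        theta = meta[DIURNAL_ANGLE_COLUMN[self.diurnal_angle]].to_numpy(dtype=float)
        psi = meta["psi_season"].to_numpy(dtype=float)
        cov = self.covariate_frame(meta)
        names = ["intercept", "cos_d", "sin_d", "cos_s", "sin_s", *cov.columns]
        X = np.column_stack(
            [
                np.ones_like(theta),
                np.cos(theta),
                np.sin(theta),
                np.cos(psi),
                np.sin(psi),
                *(cov[c].to_numpy(dtype=float) for c in cov.columns),
            ]
        )
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            raise ValueError(
                f"design matrix is rank-deficient (rank {rank} < {X.shape[1]} columns); "
                f"columns: {names}"
            )
        return X, names


@dataclass
class CosinorFit:
    """Fitted rhythm parameters for one feature."""

    feature_id: str
    n: int
    mu: float
    a_d: float
    b_d: float
    a_s: float
    b_s: float
    A_d: float
    phi_d: float
    A_s: float
    phi_s: float
    F_d: float
    p_d: float
    F_s: float
    p_s: float
    covariate_coefs: dict[str, float]
    rss_full: float
    rss_reduced_d: float
    rss_reduced_s: float
    degenerate_flag: bool


def amp_phase(a, b):
    """Amplitude/acrophase from linear cosine/sine coefficients.

    A = sqrt(a^2 + b^2); phi = atan2(b, a) wrapped to [0, 2*pi), so that
    a*cos(t) + b*sin(t) = A*cos(t - phi).  A degenerate pair (a = b = 0)
    gets the conventional phase 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    amp = np.hypot(a, b)
    phi = np.where(amp < DEGENERATE_AMPLITUDE, 0.0, np.arctan2(b, a) % TWO_PI)
    return amp, phi


def nadir_from_acrophase(phi):
    """Trough angle of a cosine curve: the acrophase shifted by pi."""
    return (np.asarray(phi, dtype=float) - np.pi) % TWO_PI


def _rss(X: np.ndarray, Y: np.ndarray):
    """Least-squares coefficients and residual sums of squares, per column of Y."""
    coef, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ coef
    return coef, np.einsum("ij,ij->j", resid, resid)


def fit_matrix_arrays(Y: np.ndarray, X: np.ndarray):
    """Vectorized cosinor statistics for features sharing one design matrix.

    Parameters
    ----------
    Y : (n_samples, n_features) array without missing values.
    X : (n_samples, p) full design with the cosine/sine pairs in columns
        1:3 (diurnal) and 3:5 (seasonal).

    Returns a dict of per-feature arrays (coefficients, amplitudes, phases,
    F statistics, p-values, residual sums of squares).
    """
    n, p_full = X.shape
    if n <= p_full + 2:
        raise ValueError(f"too few samples ({n}) for {p_full} design columns")
    coef, rss_full = _rss(X, Y)
    keep_d = [i for i in range(p_full) if i not in (1, 2)]
    keep_s = [i for i in range(p_full) if i not in (3, 4)]
    _, rss_red_d = _rss(X[:, keep_d], Y)
    _, rss_red_s = _rss(X[:, keep_s], Y)

    df2 = n - p_full
    scale = 1e-12 * np.maximum(1.0, np.einsum("ij,ij->j", Y, Y))
    perfect = rss_full <= scale  # zero residual variance

    def _f_and_p(rss_red):
        with np.errstate(divide="ignore", invalid="ignore"):
            F = ((rss_red - rss_full) / 2.0) / (rss_full / df2)
        # perfect full fit: F is +inf (p=0) if the rhythm terms carry signal,
        # 0 (p=1) if the reduced model is equally perfect (e.g. constant y)
        F = np.where(perfect, np.where(rss_red - rss_full <= scale, 0.0, np.inf), np.maximum(F, 0.0))
        p = np.where(np.isinf(F), 0.0, stats.f.sf(np.where(np.isinf(F), 1.0, F), 2, df2))
        return F, p

    F_d, p_d = _f_and_p(rss_red_d)
    F_s, p_s = _f_and_p(rss_red_s)

    A_d, phi_d = amp_phase(coef[1], coef[2])
    A_s, phi_s = amp_phase(coef[3], coef[4])
    return {
        "n": np.full(Y.shape[1], n),
        "mu": coef[0],
        "a_d": coef[1],
        "b_d": coef[2],
        "a_s": coef[3],
        "b_s": coef[4],
        "A_d": A_d,
        "phi_d": phi_d,
        "A_s": A_s,
        "phi_s": phi_s,
        "F_d": F_d,
        "p_d": p_d,
        "F_s": F_s,
        "p_s": p_s,
        "rss_full": rss_full,
        "rss_reduced_d": rss_red_d,
        "rss_reduced_s": rss_red_s,
        "degenerate_flag": (A_d < DEGENERATE_AMPLITUDE) | (A_s < DEGENERATE_AMPLITUDE) | perfect,
        "coef": coef,
    }


def fit_cosinor(y, meta: pd.DataFrame, spec: DesignSpec, feature_id: str = "feature") -> CosinorFit:
    """Fit the joint cosinor model for a single feature.

    ``meta`` must carry angle columns (see :func:`pmrhythm.timeref.add_time_columns`)
    aligned with ``y``.  Rows where ``y`` is missing are dropped.
    """
    y = np.asarray(y, dtype=float)
    if y.shape[0] != len(meta):
        raise ValueError("y and metadata lengths differ")
    ok = np.isfinite(y)
    y = y[ok]
    meta = meta.loc[ok]
    X, names = spec.design(meta)
    out = fit_matrix_arrays(y[:, None], X)
    cov_names = names[5:]
    return CosinorFit(
        feature_id=feature_id,
        n=int(out["n"][0]),
        mu=float(out["mu"][0]),
        a_d=float(out["a_d"][0]),
        b_d=float(out["b_d"][0]),
        a_s=float(out["a_s"][0]),
        b_s=float(out["b_s"][0]),
        A_d=float(out["A_d"][0]),
        phi_d=float(out["phi_d"][0]),
        A_s=float(out["A_s"][0]),
        phi_s=float(out["phi_s"][0]),
        F_d=float(out["F_d"][0]),
        p_d=float(out["p_d"][0]),
        F_s=float(out["F_s"][0]),
        p_s=float(out["p_s"][0]),
        covariate_coefs={nm: float(v) for nm, v in zip(cov_names, out["coef"][5:, 0])},
        rss_full=float(out["rss_full"][0]),
        rss_reduced_d=float(out["rss_reduced_d"][0]),
        rss_reduced_s=float(out["rss_reduced_s"][0]),
        degenerate_flag=bool(out["degenerate_flag"][0]),
    )


def rhythm_f_tests(y, meta: pd.DataFrame, spec: DesignSpec):
    """Nested-F statistics and p-values for diurnal and seasonal rhythmicity."""
    fit = fit_cosinor(y, meta, spec)
    return fit.F_d, fit.p_d, fit.F_s, fit.p_s


def fit_matrix(
    matrix: pd.DataFrame,
    meta: pd.DataFrame,
    spec: DesignSpec,
    min_samples: int = 10,
) -> pd.DataFrame:
    """Fit the cosinor model to every feature of a features x samples matrix.

    ``matrix`` has features as rows (index = feature IDs) and samples as
    columns; ``meta`` is indexed or keyed by ``sample_id`` and must carry
    angle columns.  Sample IDs are aligned by name; complete features are
    fit in one vectorized solve, features with missing values fall back to
    per-feature listwise deletion.  Features with fewer than
    ``min_samples`` usable samples are flagged degenerate with NaN
    statistics and excluded from downstream summaries.

    Returns a DataFrame with one row per input feature, in input order.
    """
    meta = meta.set_index("sample_id") if "sample_id" in meta.columns else meta
    common = [s for s in matrix.columns if s in meta.index]
    if not common:
        raise ValueError("no overlapping sample IDs between matrix and metadata")
    matrix = matrix[common]
    meta = meta.loc[common]
    X, names = spec.design(meta)

    Y = matrix.to_numpy(dtype=float).T  # samples x features
    complete = np.all(np.isfinite(Y), axis=0)
    result = pd.DataFrame(index=matrix.index, columns=FIT_COLUMNS[1:], dtype=object)

    if complete.any():
        out = fit_matrix_arrays(Y[:, complete], X)
        idx = matrix.index[complete]
        for key in FIT_COLUMNS[1:-1]:
            result.loc[idx, key] = out[key]
        result.loc[idx, "degenerate_flag"] = out["degenerate_flag"]

    for j in np.nonzero(~complete)[0]:
        fid = matrix.index[j]
        ok = np.isfinite(Y[:, j])
        if ok.sum() < min_samples:
            result.loc[fid, "degenerate_flag"] = True
            result.loc[fid, "n"] = int(ok.sum())
            continue
        sub = fit_matrix_arrays(Y[ok, j][:, None], X[ok])
        for key in FIT_COLUMNS[1:-1]:
            result.loc[fid, key] = sub[key][0]
        result.loc[fid, "degenerate_flag"] = bool(sub["degenerate_flag"][0])

    for col in FIT_COLUMNS[1:-1]:
        result[col] = pd.to_numeric(result[col], errors="coerce")
    result["degenerate_flag"] = (
        result["degenerate_flag"].apply(lambda v: bool(v) if v == v and v is not None else True)
    )
    result.insert(0, "feature_id", result.index)
    return result.reset_index(drop=True)
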