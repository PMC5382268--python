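"""Seeded permutation engine and the genome-wide median-F rhythmicity test.

With one death time per subject, the natural genome-wide null is obtained
by shuffling times of death (for diurnal rhythms) or dates of death (for
seasonal rhythms) across subjects while leaving expression and covariates
in place.  The observed median nested-F statistic across all features is
compared to its distribution over B such null data sets; the empirical
p-value is the proportion of null medians at least as large.

Two shuffling styles are provided:

- ``recompute_sun=True`` (faithful): the raw clock time (or date) label
  moves between subjects and the diurnal angle is re-derived using the
  *recipient* subject's own date/site sun events, so the marginal
  distribution of recorded times is preserved exactly.
- ``recompute_sun=False`` (fast): the angle columns themselves are
  permuted.  When all subjects share one site the two styles differ only
  through day-to-day sunrise drift.

Replicate seeds are derived from the master seed by counter
(``SeedSequence([master, replicate])``), so results are bit-identical
regardless of evaluation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import timeref
from .cosinor import DesignSpec, fit_matrix_arrays

TWO_PI = 2.0 * np.pi

SHUFFLE_MODES = ("times", "dates", "both")


def child_rng(master_seed: int, index: int) -> np.random.Generator:
    """Independent per-replicate generator derived from the master seed."""
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), int(index)]))


@dataclass
class PermutationResult:
    """An observed statistic with its permutation null sample.

    ``empirical_p`` uses the inclusive convention #{null >= observed}/B
    (ties count as exceedances, the conservative choice); when no null
    value reaches the observed statistic the label reports "<1/B" rather
    than zero.
    """

    observed: float
    null_values: np.ndarray
    B: int
    shuffle_mode: str
    seed: int
    tail: str = "greater"
    tie_tol: float = 0.0
    empirical_p: float = field(init=False)

    def __post_init__(self) -> None:
        self.null_values = np.asarray(self.null_values, dtype=float)
        if self.null_values.size != self.B:
            raise ValueError("null_values length must equal B")
        self.empirical_p = permutation_p(
            self.observed, self.null_values, tail=self.tail, tie_tol=self.tie_tol
        )

    @property
    def p_label(self) -> str:
        if self.empirical_p == 0.0:
            return f"<{1.0 / self.B:g}"
        return f"{self.empirical_p:g}"

    def to_dict(self) -> dict:
        return {
            "observed": self.observed,
            "empirical_p": self.empirical_p,
            "p_label": self.p_label,
            "B": self.B,
            "shuffle_mode": self.shuffle_mode,
            "seed": self.seed,
            "tail": self.tail,
            "null_mean": float(np.mean(self.null_values)),
            "null_sd": float(np.std(self.null_values)),
        }


def permutation_p(observed: float, null_values, tail: str = "greater", tie_tol: float = 0.0) -> float:
    """Empirical p-value: proportion of null values as extreme as observed.

    ``tie_tol`` treats null values within that margin of the observed
    statistic as ties (counted as exceedances); useful for statistics with
    exact ties recomputed through floating-point arithmetic.
    """
    null_values = np.asarray(null_values, dtype=float)
    if null_values.size == 0:
        raise ValueError("empty null sample")
    if tail == "greater":
        return float(np.mean(null_values >= observed - tie_tol))
    if tail == "two_sided":
        return float(np.mean(np.abs(null_values) >= abs(observed) - tie_tol))
    raise ValueError(f"tail must be 'greater' or 'two_sided', got {tail!r}")


def permute_metadata(
    meta: pd.DataFrame,
    shuffle_mode: str,
    rng: np.random.Generator,
    recompute_sun: bool = True,
) -> pd.DataFrame:
    """Return metadata with death times and/or dates shuffled across samples.

    All other columns, covariates included, stay fixed.  With
    ``recompute_sun`` the permuted raw labels are re-converted to angles
    against each recipient row's own date and site; otherwise the relevant
    angle columns are permuted directly.  Modes: ``times`` (clock time of
    death), ``dates`` (date of death), ``both`` (each with its own
    independent permutation, breaking the time-date pairing too).
    """
    if shuffle_mode not in SHUFFLE_MODES:
        raise ValueError(f"shuffle_mode must be one of {SHUFFLE_MODES}, got {shuffle_mode!r}")
    meta = meta.copy()
    n = len(meta)
    if recompute_sun:
        if shuffle_mode in ("times", "both"):
            perm = rng.permutation(n)
            meta["clock_time_of_death"] = meta["clock_time_of_death"].to_numpy()[perm]
        if shuffle_mode in ("dates", "both"):
            perm = rng.permutation(n)
            meta["date_of_death"] = meta["date_of_death"].to_numpy()[perm]
        return timeref.add_time_columns(meta.drop(columns=timeref.ANGLE_COLUMNS + timeref.SUN_COLUMNS, errors="ignore"))
    if shuffle_mode in ("times", "both"):
        perm = rng.permutation(n)
        for col in ("theta_zt", "theta_clock", "theta_darkmid", "clock_time_of_death"):
            if col in meta:
                meta[col] = meta[col].to_numpy()[perm]
    if shuffle_mode in ("dates", "both"):
        perm = rng.permutation(n)
        for col in ("psi_season", "date_of_death"):
            if col in meta:
                meta[col] = meta[col].to_numpy()[perm]
    return meta


def _aligned_arrays(matrix: pd.DataFrame, meta: pd.DataFrame):
    meta = meta.set_index("sample_id") if "sample_id" in meta.columns else meta
    common = [s for s in matrix.columns if s in meta.index]
    if not common:
        raise ValueError("no overlapping sample IDs between matrix and metadata")
    return matrix[common].to_numpy(dtype=float).T, meta.loc[common].reset_index()


def median_f_test(
    matrix: pd.DataFrame,
    meta: pd.DataFrame,
    spec: DesignSpec,
    period: str = "diurnal",
    B: int = 1000,
    seed: int = 0,
    shuffle_mode: str | None = None,
    recompute_sun: bool = False,
) -> PermutationResult:
    """Genome-wide rhythmicity: observed median F vs shuffled-time nulls.

    ``period`` selects the diurnal or seasonal nested-F statistic; the
    default shuffle follows it (times for diurnal, dates for seasonal).
    Every replicate re-fits all features on the permuted metadata.
    """
    if period not in ("diurnal", "seasonal"):
        raise ValueError(f"period must be 'diurnal' or 'seasonal', got {period!r}")
    if B < 1:
        raise ValueError("B must be >= 1")
    key = "F_d" if period == "diurnal" else "F_s"
    if shuffle_mode is None:
        shuffle_mode = "times" if period == "diurnal" else "dates"

    Y, meta_aligned = _aligned_arrays(matrix, meta)
    finite = np.all(np.isfinite(Y), axis=0)
    Y = Y[:, finite]

    X, _ = spec.design(meta_aligned)
    observed = float(np.median(fit_matrix_arrays(Y, X)[key]))

    null = np.empty(B)
    for b in range(B):
        rng = child_rng(seed, b)
        meta_b = permute_metadata(meta_aligned, shuffle_mode, rng, recompute_sun=recompute_sun)
        Xb, _ = spec.design(meta_b)
        null[b] = np.median(fit_matrix_arrays(Y, Xb)[key])

    return PermutationResult(
        observed=observed, null_values=null, B=B, shuffle_mode=shuffle_mode, seed=seed
    )
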