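"""Transcription-factor binding sites as predictors of temporal class.

The local transcription-factor environment shapes circadian transcription
in model systems.  Here each feature (transcript TSS, acetylation peak,
or CpG site) gets a binary indicator per TF: 1 if the feature's anchor
overlaps an annotated binding site of that TF or lies within 2,000 bp of
one.  A single joint logistic regression of temporal class (morning vs
evening, or fall vs spring) on *all* TF indicators then estimates each
TF's association adjusted for the others — the "independent impact" of
each TF's local presence.

Inference is permutation-based: null data sets shuffle times (or dates)
of death, re-fit the cosinor model, re-cluster the phases, and re-fit the
logistic model.  Per-TF uncorrected p-values compare |beta| to that TF's
null betas; the analysis-wide FDR at threshold t is the expected number
of null coefficients with |beta| >= t (averaged over replicates, pooled
across TFs) divided by the observed count, evaluated at each observed
|beta| and monotonized.

A small ridge penalty (default 1e-4 on standardized indicators) guards
against complete separation from sparse TF columns; set ``ridge=0`` for
pure maximum likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats
from sklearn.linear_model import LogisticRegression

from .clustering import classify_features
from .cosinor import DesignSpec, fit_matrix_arrays
from .permutation import _aligned_arrays, child_rng, permute_metadata

#: outcome coding: positive beta favours the first-named class
OUTCOME_POSITIVE = {"morning_vs_evening": "morning", "fall_vs_spring": "fall"}


def annotate_tf_sites(
    anchors: pd.DataFrame,
    tf_sites: pd.DataFrame,
    window_bp: int = 2000,
) -> pd.DataFrame:
    """Binary feature x TF indicator matrix from anchor/site proximity.

    ``anchors`` has columns feature_id, chrom, start, end (a TSS or CpG is
    a width-1 interval); ``tf_sites`` is BED-like with the TF name in the
    ``name`` column.  The indicator is 1 when the anchor interval expanded
    by ``window_bp`` on both sides overlaps any site of the TF (idempotent
    under duplicated sites).  TFs with zero sites yield all-zero columns.
    """
    tf_names = sorted(tf_sites["name"].unique())
    trees: dict[tuple[str, str], IntervalTree] = {}
    for (tf, chrom), grp in tf_sites.groupby(["name", "chrom"]):
        trees[(tf, chrom)] = IntervalTree.from_tuples(
            (int(s), max(int(e), int(s) + 1)) for s, e in zip(grp["start"], grp["end"])
        )
    out = np.zeros((len(anchors), len(tf_names)), dtype=int)
    chroms = anchors["chrom"].to_numpy()
    starts = anchors["start"].to_numpy()
    ends = anchors["end"].to_numpy()
    for j, tf in enumerate(tf_names):
        for i in range(len(anchors)):
            tree = trees.get((tf, chroms[i]))
            if tree is None:
                continue
            # inclusive <= window_bp gap on either side (gap measured from
            # the interval edges, matching the TSS-distance convention)
            lo = int(starts[i]) - window_bp - 1
            hi = int(ends[i]) + window_bp + 1
            if tree.overlaps(lo, hi):
                out[i, j] = 1
    return pd.DataFrame(out, index=anchors["feature_id"].to_numpy(), columns=tf_names)


@dataclass
class TfEffects:
    """Per-TF log-odds (optionally with permutation p-values and FDR)."""

    table: pd.DataFrame  # columns: tf_name, beta [, p_uncorrected, fdr]
    outcome: str
    layer: str = "rna"


def fit_tf_logistic(
    labels,
    tf_matrix: pd.DataFrame,
    ridge: float = 1e-4,
    positive_label: str | None = None,
) -> pd.DataFrame:
    """One joint logistic model: temporal class on all TF indicators.

    ``labels`` holds two class labels per feature; ``positive_label``
    names the class coded 1 (defaults to the lexicographically smaller
    one in spirit of morning/fall coding — pass it explicitly in pipeline
    use).  Indicators are standardized for the ridge penalty and the
    coefficients mapped back to the 0/1 indicator scale.  Constant
    (all-zero or all-one) TF columns get beta 0.

    Returns a DataFrame with columns tf_name, beta.
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError(f"need exactly 2 classes, got {list(classes)}")
    if positive_label is None:
        positive_label = sorted(classes)[0]
    y = (labels == positive_label).astype(int)
    X = tf_matrix.to_numpy(dtype=float)
    sd = X.std(axis=0)
    varying = sd > 0
    betas = np.zeros(X.shape[1])
    if varying.any():
        Xs = (X[:, varying] - X[:, varying].mean(axis=0)) / sd[varying]
        C = 1.0 / ridge if ridge > 0 else np.inf
        clf = LogisticRegression(C=C, max_iter=2000, solver="lbfgs")
        clf.fit(Xs, y)
        betas[varying] = clf.coef_[0] / sd[varying]
    return pd.DataFrame({"tf_name": tf_matrix.columns, "beta": betas})


def _fdr_from_nulls(obs_abs: np.ndarray, null_abs: np.ndarray) -> np.ndarray:
    """Plug-in permutation FDR at each observed |beta|, monotonized.

    ``null_abs`` has shape (B, n_tf).  FDR(t) = mean_b #{|null_b| >= t} /
    #{|obs| >= t}; enforced non-increasing in t and clipped to [0, 1].
    """
    B = null_abs.shape[0]
    flat = np.sort(null_abs.ravel())
    order = np.argsort(-obs_abs, kind="stable")  # descending |beta|
    ranks = np.arange(1, obs_abs.size + 1)  # observed count at each threshold
    exp_null = (flat.size - np.searchsorted(flat, obs_abs[order], side="left")) / B
    raw = exp_null / ranks
    # step-up: each threshold gets the smallest raw estimate at or below it
    fdr_sorted = np.minimum(np.minimum.accumulate(raw[::-1])[::-1], 1.0)
    fdr = np.empty_like(obs_abs)
    fdr[order] = fdr_sorted
    return fdr


def tf_permutation_fdr(
    matrix: pd.DataFrame,
    meta: pd.DataFrame,
    spec: DesignSpec,
    tf_matrix: pd.DataFrame,
    outcome: str = "morning_vs_evening",
    B: int = 200,
    seed: int = 0,
    ridge: float = 1e-4,
    use_nadir: bool = False,
    cluster_seed: int = 0,
    recompute_sun: bool = False,
) -> TfEffects:
    """TF effects with permutation p-values and analysis-wide FDR.

    Observed: fit cosinor to all features, cluster acrophases, regress the
    chosen class on all TF indicators.  Null replicates shuffle times of
    death (diurnal outcome) or dates (seasonal), then repeat the full
    fit -> cluster -> logistic procedure.
    """
    if outcome not in OUTCOME_POSITIVE:
        raise ValueError(f"outcome must be one of {sorted(OUTCOME_POSITIVE)}, got {outcome!r}")
    axis = "diurnal" if outcome == "morning_vs_evening" else "seasonal"
    shuffle_mode = "times" if axis == "diurnal" else "dates"
    class_col = f"{axis}_class"
    positive = OUTCOME_POSITIVE[outcome]

    Y, meta_aligned = _aligned_arrays(matrix, meta)
    finite = np.all(np.isfinite(Y), axis=0)
    Y = Y[:, finite]
    feature_ids = matrix.index.to_numpy()[finite]
    tf_sub = tf_matrix.loc[feature_ids]

    def betas_for(meta_x) -> np.ndarray:
        X, _ = spec.design(meta_x)
        out = fit_matrix_arrays(Y, X)
        cls = classify_features(
            out["phi_d"], out["phi_s"], seed=cluster_seed, use_nadir=use_nadir
        )
        return fit_tf_logistic(
            cls[class_col].to_numpy(), tf_sub, ridge=ridge, positive_label=positive
        )["beta"].to_numpy()

    obs = betas_for(meta_aligned)
    null = np.empty((B, obs.size))
    for b in range(B):
        meta_b = permute_metadata(meta_aligned, shuffle_mode, child_rng(seed, b), recompute_sun)
        null[b] = betas_for(meta_b)

    obs_abs = np.abs(obs)
    null_abs = np.abs(null)
    p_unc = np.mean(null_abs >= obs_abs[None, :], axis=0)
    fdr = _fdr_from_nulls(obs_abs, null_abs)
    table = pd.DataFrame(
        {"tf_name": tf_sub.columns, "beta": obs, "p_uncorrected": p_unc, "fdr": fdr}
    )
    return TfEffects(table=table, outcome=outcome)


def coefficient_correlation(effects_a: pd.DataFrame, effects_b: pd.DataFrame):
    """Spearman correlation of two analyses' TF log-odds vectors.

    Aligns on tf_name; requires at least 3 shared TFs.  Returns (rho, p).
    """
    merged = effects_a.merge(effects_b, on="tf_name", suffixes=("_a", "_b"))
    if len(merged) < 3:
        raise ValueError(f"need >=3 shared TFs, got {len(merged)}")
    rho, p = stats.spearmanr(merged["beta_a"], merged["beta_b"])
    return float(rho), float(p)
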