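"""Circular statistics shared across the rhythm analyses.

Acrophases live on a circle, so group comparisons and correlations use
circular methods: the Mardia–Watson–Wheeler (MWW) uniform-scores test for
two-sample differences in angular distribution, the
Jammalamadaka–SenGupta circular correlation coefficient for angle–angle
association, and a plain 2x2 chi-square for set enrichment against
external gene lists.

Ties in the MWW ranking are resolved by midranks from a stable sort, so
results are deterministic even on degenerate inputs.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats

TWO_PI = 2.0 * np.pi


def wrap_angle(a):
    """Wrap angles to [0, 2*pi)."""
    return np.asarray(a, dtype=float) % TWO_PI


def wrap_signed(a):
    """Wrap angle differences to (-pi, pi]."""
    a = np.asarray(a, dtype=float)
    return np.pi - (np.pi - a) % TWO_PI


def circ_mean(angles) -> float:
    """Circular mean via atan2 of mean sine and cosine, in [0, 2*pi)."""
    a = np.asarray(angles, dtype=float)
    return float(np.arctan2(np.mean(np.sin(a)), np.mean(np.cos(a))) % TWO_PI)


def circ_dist(a, b):
    """Absolute circular distance between angles, in [0, pi]."""
    return np.abs(wrap_signed(np.asarray(a, dtype=float) - np.asarray(b, dtype=float)))


def circ_resultant(angles) -> float:
    """Mean resultant length R in [0, 1]; near 0 for dispersed angles."""
    a = np.asarray(angles, dtype=float)
    return float(np.hypot(np.mean(np.sin(a)), np.mean(np.cos(a))))


def mww_w(group_a, group_b) -> float:
    """Mardia–Watson–Wheeler W statistic for two angular samples.

    The combined sample is ranked around the circle (midranks for ties),
    each observation is mapped to the uniform score beta_i = 2*pi*r_i/N,
    and W = 2 * sum_g (C_g^2 + S_g^2) / n_g where C_g, S_g are the sums of
    cosines and sines of the scores within group g.  Large W indicates the
    two angular distributions differ.
    """
    a = wrap_angle(group_a)
    b = wrap_angle(group_b)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 angles for the MWW test")
    combined = np.concatenate([a, b])
    n = combined.size
    ranks = stats.rankdata(combined, method="average")
    # Canonical rank origin: measure ranks relative to the first observation.
    # A joint rotation of all angles cyclically shifts the rank vector; this
    # (exact half-integer) re-origin makes W numerically identical, not just
    # mathematically invariant, under joint rotation.
    beta = TWO_PI * ((ranks - ranks[0]) % n) / n
    w = 0.0
    for g in (slice(0, a.size), slice(a.size, n)):
        c = math.fsum(np.cos(beta[g]))
        s = math.fsum(np.sin(beta[g]))
        n_g = beta[g].size
        w += (c * c + s * s) / n_g
    return float(2.0 * w)


def mww_perm_test(group_a, group_b, B: int = 1000, seed: int = 0):
    """Label-permutation test on the MWW W statistic.

    Standalone mode: the null reassigns group labels uniformly at random,
    holding the pooled angles fixed.  (In the pipeline, nulls for W are
    instead built by shuffling death times and re-fitting; see
    :mod:`pmrhythm.permutation`.)

    Returns a :class:`pmrhythm.permutation.PermutationResult`.
    """
    from .permutation import PermutationResult, child_rng

    a = wrap_angle(group_a)
    b = wrap_angle(group_b)
    observed = mww_w(a, b)
    pooled = np.concatenate([a, b])
    n_a = a.size
    null = np.empty(B)
    for i in range(B):
        rng = child_rng(seed, i)
        perm = rng.permutation(pooled.size)
        null[i] = mww_w(pooled[perm[:n_a]], pooled[perm[n_a:]])
    return PermutationResult(
        observed=observed,
        null_values=null,
        B=B,
        shuffle_mode="labels",
        seed=seed,
        tie_tol=1e-9 * max(1.0, abs(observed)),
    )


def mww_exact_p(group_a, group_b) -> float:
    """Exact label-permutation p-value for the MWW W on small samples.

    Enumerates every assignment of the pooled angles into groups of the
    observed sizes; p = proportion of assignments with W >= observed
    (ties inclusive).  Feasible for pooled sizes up to ~12.
    """
    from itertools import combinations

    a = wrap_angle(group_a)
    b = wrap_angle(group_b)
    observed = mww_w(a, b)
    pooled = np.concatenate([a, b])
    n = pooled.size
    idx = range(n)
    count = total = 0
    for pick in combinations(idx, a.size):
        rest = [i for i in idx if i not in pick]
        total += 1
        if mww_w(pooled[list(pick)], pooled[rest]) >= observed - 1e-12:
            count += 1
    return count / total


def circ_corr(alpha, beta) -> float:
    """Jammalamadaka–SenGupta circular correlation coefficient.

    rho = sum sin(a - abar) sin(b - bbar) /
          sqrt(sum sin^2(a - abar) * sum sin^2(b - bbar))

    with abar, bbar the circular means.  Invariant to rotating either
    input; equals 1 when beta = alpha + const and -1 when beta = -alpha
    + const.
    """
    a = wrap_angle(alpha)
    b = wrap_angle(beta)
    if a.size != b.size:
        raise ValueError("alpha and beta must have equal length")
    if a.size < 3:
        raise ValueError("need at least 3 angle pairs")
    sa = np.sin(a - circ_mean(a))
    sb = np.sin(b - circ_mean(b))
    denom = np.sqrt(np.sum(sa**2) * np.sum(sb**2))
    if denom == 0.0:
        raise ValueError("degenerate input: one sample has no angular dispersion")
    return float(np.sum(sa * sb) / denom)


def chi2_contingency(table: np.ndarray):
    """Pearson chi-square without continuity correction; (chi2, p, dof).

    The cell terms are accumulated with an exactly rounded sum, so the
    statistic does not depend on row/column ordering — permuting class
    labels permutes the terms but leaves the result bit-identical.
    """
    table = np.asarray(table, dtype=float)
    if table.sum() == 0 or np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError(f"chi-square undefined for table with empty margin:\n{table}")
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    expected = row * col / table.sum()
    chi2 = math.fsum(((table - expected) ** 2 / expected).ravel())
    dof = (table.shape[0] - 1) * (table.shape[1] - 1)
    return float(chi2), float(stats.chi2.sf(chi2, dof)), int(dof)


def enrichment_chi2(hits_a, hits_b, universe):
    """2x2 chi-square for overlap of two feature sets within a universe.

    Builds the (in/out of A) x (in/out of B) table over ``universe`` and
    returns (chi2, p) from the 1-df Pearson test without continuity
    correction.  Suitable for testing whether a rhythmic-gene list is
    enriched for an external gene list.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    a = set(hits_a) & universe
    b = set(hits_b) & universe
    n11 = len(a & b)
    n10 = len(a - b)
    n01 = len(b - a)
    n00 = len(universe) - n11 - n10 - n01
    chi2, p, _ = chi2_contingency(np.array([[n11, n10], [n01, n00]]))
    return chi2, p
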