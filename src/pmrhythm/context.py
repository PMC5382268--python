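"""Rhythm timing versus genomic position.

Epigenomic features (histone-acetylation peaks, CpG sites) are related to
transcription start sites in two ways:

- a proximity split: features within 2,000 bp of an *active* TSS (one
  whose transcript is expressed in >90% of samples) versus features
  farther away, compared by the Mardia–Watson–Wheeler W on their diurnal
  and seasonal acrophase distributions and by a 4x2 chi-square of the
  four temporal classes against the two proximity groups;
- transcript-class proximity groups: epigenomic features within a window
  of the TSS of morning- versus evening-classified transcripts, whose
  acrophase distributions are again compared by W and chi-square.
  Features near TSSs of both classes are ambiguous and excluded (keeping
  the two groups disjoint), with a count of exclusions reported.

All coordinates are 0-based half-open (BED convention).  Distances are
edge-to-point gaps: zero when the TSS falls inside the feature interval.
The 2,000 bp boundary is inclusive ("within" reads as <=).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .circular import chi2_contingency, mww_w
from .clustering import classify_features
from .cosinor import DesignSpec, fit_matrix_arrays
from .permutation import PermutationResult, _aligned_arrays, child_rng, permute_metadata

TWO_PI = 2.0 * np.pi

COMBINED_CLASSES = ["morning/fall", "morning/spring", "evening/fall", "evening/spring"]


def tss_distance(features: pd.DataFrame, tss: pd.DataFrame, active_only: bool = True):
    """Distance from each feature interval to the nearest (active) TSS.

    ``features`` needs columns chrom/start/end (0-based half-open);
    ``tss`` needs chrom/tss_pos and optionally an ``active`` flag.
    Returns (distances, nearest_ids): the gap in bp (0 if a TSS lies
    inside the interval) and the feature_id of the nearest TSS.  Features
    on chromosomes absent from the TSS table get distance +inf and id
    None.
    """
    if active_only and "active" in tss.columns:
        tss = tss[tss["active"]]
    dist = np.full(len(features), np.inf)
    nearest = np.full(len(features), None, dtype=object)
    for chrom, idx in features.groupby("chrom").groups.items():
        sub = tss[tss["chrom"] == chrom]
        if sub.empty:
            continue
        pos = np.sort(sub["tss_pos"].to_numpy())
        order = np.argsort(sub["tss_pos"].to_numpy(), kind="stable")
        ids = sub["feature_id"].to_numpy()[order]
        start = features.loc[idx, "start"].to_numpy()
        end = features.loc[idx, "end"].to_numpy()
        # last TSS strictly left of `end`, first TSS at or beyond `end`
        left_i = np.searchsorted(pos, end, side="left") - 1
        right_i = left_i + 1
        left_pos = pos[np.clip(left_i, 0, None)]
        inside = (left_i >= 0) & (left_pos >= start)
        d_left = np.where(left_i >= 0, np.where(inside, 0.0, start - left_pos), np.inf)
        d_right = np.where(
            right_i < pos.size, pos[np.clip(right_i, None, pos.size - 1)] - end, np.inf
        )
        use_left = d_left <= d_right
        dist[idx] = np.where(use_left, d_left, d_right)
        chosen = np.where(use_left, np.clip(left_i, 0, None), np.clip(right_i, None, pos.size - 1))
        nearest[idx] = ids[chosen]
    return dist, nearest


def split_by_proximity(features: pd.DataFrame, tss: pd.DataFrame, threshold_bp: int = 2000):
    """Partition feature names into TSS-proximal and TSS-distal sets.

    Proximal means distance <= threshold (inclusive boundary).  The two
    sets are disjoint and exhaust the input.
    """
    dist, _ = tss_distance(features, tss)
    names = features["name"].to_numpy()
    proximal = set(names[dist <= threshold_bp])
    distal = set(names[dist > threshold_bp])
    return proximal, distal


@dataclass
class ContextComparison:
    """W and chi-square comparisons of two feature groups' rhythm timing."""

    w_diurnal: PermutationResult
    w_seasonal: PermutationResult
    chi2_classes: PermutationResult
    n_group_a: int
    n_group_b: int

    def to_dict(self) -> dict:
        return {
            "w_diurnal": self.w_diurnal.to_dict(),
            "w_seasonal": self.w_seasonal.to_dict(),
            "chi2_classes": self.chi2_classes.to_dict(),
            "n_group_a": self.n_group_a,
            "n_group_b": self.n_group_b,
        }


def _class_by_group_table(classification: pd.DataFrame, in_a: np.ndarray) -> np.ndarray:
    """4x2 table: combined temporal class x group membership."""
    tab = np.zeros((4, 2))
    for i, cls in enumerate(COMBINED_CLASSES):
        mask = classification["combined_class"].to_numpy() == cls
        tab[i, 0] = np.sum(mask & in_a)
        tab[i, 1] = np.sum(mask & ~in_a)
    return tab


def context_comparison(
    matrix: pd.DataFrame,
    meta: pd.DataFrame,
    spec: DesignSpec,
    group_a: set,
    group_b: set,
    B: int = 1000,
    seed: int = 0,
    use_nadir: bool = False,
    chi2_table: str = "4x2",
    recompute_sun: bool = False,
) -> ContextComparison:
    """Compare rhythm timing between two fixed feature groups.

    Observed statistics: MWW W on the diurnal acrophases of group A versus
    group B, the same on seasonal acrophases, and the chi-square of the
    temporal-class x group table (4x2 over combined classes by default,
    "2x2" uses the single-axis class).  Null replicates shuffle times of
    death (diurnal W), dates (seasonal W) or both (chi-square), re-fit all
    features and recompute; the group partition is a function of genomic
    coordinates only and never changes under permutation.
    """
    Y, meta_aligned = _aligned_arrays(matrix, meta)
    finite = np.all(np.isfinite(Y), axis=0)
    Y = Y[:, finite]
    feature_ids = matrix.index.to_numpy()[finite]
    in_a = np.isin(feature_ids, list(group_a))
    in_b = np.isin(feature_ids, list(group_b))
    if in_a.sum() < 2 or in_b.sum() < 2:
        raise ValueError(
            f"both groups need >=2 features with data (got {in_a.sum()}, {in_b.sum()})"
        )

    def fit_phases(meta_x):
        X, _ = spec.design(meta_x)
        out = fit_matrix_arrays(Y, X)
        return out["phi_d"], out["phi_s"]

    def chi2_stat(meta_x):
        phi_d, phi_s = fit_phases(meta_x)
        cls = classify_features(phi_d, phi_s, seed=seed, use_nadir=use_nadir)
        if chi2_table == "4x2":
            tab = _class_by_group_table(cls, in_a)
        else:
            tab = np.zeros((2, 2))
            dc = cls["diurnal_class"].to_numpy()
            for i, lab in enumerate(("morning", "evening")):
                tab[i, 0] = np.sum((dc == lab) & in_a)
                tab[i, 1] = np.sum((dc == lab) & in_b)
        # drop empty classes: chi-square needs non-zero margins
        tab = tab[tab.sum(axis=1) > 0]
        chi2, _, _ = chi2_contingency(tab)
        return chi2

    phi_d0, phi_s0 = fit_phases(meta_aligned)
    obs_wd = mww_w(phi_d0[in_a], phi_d0[in_b])
    obs_ws = mww_w(phi_s0[in_a], phi_s0[in_b])
    obs_chi2 = chi2_stat(meta_aligned)

    null_wd = np.empty(B)
    null_ws = np.empty(B)
    null_chi2 = np.empty(B)
    for b in range(B):
        meta_t = permute_metadata(meta_aligned, "times", child_rng(seed, b), recompute_sun)
        phi_d, _ = fit_phases(meta_t)
        null_wd[b] = mww_w(phi_d[in_a], phi_d[in_b])
        meta_d = permute_metadata(meta_aligned, "dates", child_rng(seed, B + b), recompute_sun)
        _, phi_s = fit_phases(meta_d)
        null_ws[b] = mww_w(phi_s[in_a], phi_s[in_b])
        meta_b = permute_metadata(meta_aligned, "both", child_rng(seed, 2 * B + b), recompute_sun)
        null_chi2[b] = chi2_stat(meta_b)

    return ContextComparison(
        w_diurnal=PermutationResult(obs_wd, null_wd, B, "times", seed),
        w_seasonal=PermutationResult(obs_ws, null_ws, B, "dates", seed),
        chi2_classes=PermutationResult(obs_chi2, null_chi2, B, "both", seed),
        n_group_a=int(in_a.sum()),
        n_group_b=int(in_b.sum()),
    )


def transcript_proximity_groups(
    features: pd.DataFrame,
    transcript_classes: pd.DataFrame,
    tss: pd.DataFrame,
    window_bp: int = 2000,
    axis: str = "diurnal",
):
    """Group epigenomic features by the temporal class of nearby transcripts.

    Each feature is assigned the class(es) of transcripts whose TSS lies
    within ``window_bp`` of its interval (edge-inclusive).  Features near
    both a morning- and an evening-class TSS (or both fall and spring for
    ``axis='seasonal'``) are ambiguous: excluded and counted.

    Returns ``(groups, n_ambiguous)`` where groups maps class label ->
    set of feature names.
    """
    col = "diurnal_class" if axis == "diurnal" else "seasonal_class"
    class_of = dict(zip(transcript_classes["feature_id"], transcript_classes[col]))
    labels = sorted(set(class_of.values()))
    groups: dict[str, set] = {lab: set() for lab in labels}
    n_ambiguous = 0
    tss_use = tss[tss["feature_id"].isin(class_of)]
    for chrom, fidx in features.groupby("chrom").groups.items():
        sub = tss_use[tss_use["chrom"] == chrom]
        if sub.empty:
            continue
        pos = sub["tss_pos"].to_numpy()
        order = np.argsort(pos, kind="stable")
        pos = pos[order]
        tids = sub["feature_id"].to_numpy()[order]
        for i in fidx:
            start = features.at[i, "start"]
            end = features.at[i, "end"]
            lo = np.searchsorted(pos, start - window_bp, side="left")
            hi = np.searchsorted(pos, end + window_bp, side="right")
            near = {class_of[t] for t in tids[lo:hi]}
            if len(near) > 1:
                n_ambiguous += 1
            elif len(near) == 1:
                groups[near.pop()].add(features.at[i, "name"])
    return groups, n_ambiguous
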