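"""Acrophase clustering on the circle and the diurnal-seasonal coupling test.

Acrophase distributions in cortical omics are bimodal on both the 24-h and
the 365-day circle.  A one-dimensional self-organizing map whose node grid
is a ring (the 1-D torus, so the topology respects circular data) is
trained on the acrophases presented as unit vectors (cos phi, sin phi);
the trained codebook is then cut into exactly two contiguous arcs at the
two largest circular gaps between occupied nodes, giving two clusters per
axis: morning/evening for the diurnal acrophases and spring/fall for the
seasonal ones.

Coupling between the two classifications (e.g. morning-acrophase features
tending to have fall seasonal acrophases) is tested with the chi-square
statistic of the 2x2 diurnal x seasonal class table, compared to null
tables obtained by shuffling both times and dates of death and re-running
the whole fit + cluster + tabulate procedure.

Training uses the batch-SOM update (all points assigned to their best
matching node, then every node moved to the neighborhood-weighted circular
mean of its assignees) with a Gaussian ring neighborhood whose radius
decays linearly over epochs.  The downstream object is only a two-way cut
of a circular density, which is insensitive to these hyperparameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .circular import chi2_contingency, circ_dist, wrap_angle
from .cosinor import DesignSpec, fit_matrix_arrays
from .permutation import PermutationResult, child_rng, permute_metadata

TWO_PI = 2.0 * np.pi

DIURNAL_LABELS = ("morning", "evening")
SEASONAL_LABELS = ("fall", "spring")


@dataclass
class SomCodebook:
    """A trained ring SOM over one circular axis.

    ``node_angles`` are in ring order; ``node_cluster`` assigns each node
    to cluster 0 or 1 (two contiguous arcs).  ``node_counts`` holds the
    number of training points mapped to each node (the data-density
    weights used when cutting the ring).  A degenerate codebook (all
    training angles essentially identical) has a single cluster.
    """

    node_angles: np.ndarray
    node_cluster: np.ndarray
    node_counts: np.ndarray
    seed: int
    degenerate: bool = False

    def cluster_means(self) -> dict[int, float]:
        out = {}
        for c in np.unique(self.node_cluster):
            w = self.node_counts[self.node_cluster == c].astype(float)
            a = self.node_angles[self.node_cluster == c]
            if w.sum() == 0:
                w = np.ones_like(w)
            out[int(c)] = float(
                np.arctan2(np.sum(w * np.sin(a)), np.sum(w * np.cos(a))) % TWO_PI
            )
        return out


def som_fit_ring(
    angles,
    n_nodes: int = 24,
    seed: int = 0,
    n_epochs: int = 10,
    radius_start: float = 6.0,
    radius_end: float = 1.0,
) -> SomCodebook:
    """Train a ring SOM on circular data and cut it into two clusters.

    The codebook is initialized at evenly spaced angles with a seeded
    random rotation, trained with batch updates, and cut at the two
    largest circular gaps between *occupied* nodes (nodes with zero
    assigned points carry no data density and never separate clusters).
    """
    angles = wrap_angle(angles)
    if angles.size < 2 * n_nodes:
        raise ValueError(f"need at least {2 * n_nodes} points to train {n_nodes} nodes")
    if not np.all(np.isfinite(angles)):
        raise ValueError("angles must be finite")

    # all-identical input: no second cluster exists
    if np.max(circ_dist(angles, angles[0])) < 1e-9:
        node_angles = np.full(n_nodes, float(angles[0]))
        counts = np.zeros(n_nodes, dtype=int)
        counts[0] = angles.size
        return SomCodebook(node_angles, np.zeros(n_nodes, dtype=int), counts, seed, degenerate=True)

    rng = np.random.default_rng(seed)
    offset = rng.uniform(0.0, TWO_PI)
    node_angles = (np.arange(n_nodes) * TWO_PI / n_nodes + offset) % TWO_PI
    ring_pos = np.arange(n_nodes)

    u = np.column_stack([np.cos(angles), np.sin(angles)])
    for epoch in range(n_epochs):
        frac = epoch / max(n_epochs - 1, 1)
        sigma = radius_start + (radius_end - radius_start) * frac
        # best matching node per point, by circular distance
        d = circ_dist(angles[:, None], node_angles[None, :])
        bmu = np.argmin(d, axis=1)
        # ring distance between every node and every BMU
        ring_d = np.abs(ring_pos[:, None] - ring_pos[None, bmu])
        ring_d = np.minimum(ring_d, n_nodes - ring_d)
        h = np.exp(-(ring_d**2) / (2.0 * sigma**2))  # n_nodes x n_points
        num = h @ u
        norm = np.linalg.norm(num, axis=1)
        ok = norm > 1e-12
        node_angles[ok] = np.arctan2(num[ok, 1], num[ok, 0]) % TWO_PI

    d = circ_dist(angles[:, None], node_angles[None, :])
    bmu = np.argmin(d, axis=1)
    counts = np.bincount(bmu, minlength=n_nodes)

    occupied = np.nonzero(counts > 0)[0]
    if occupied.size < 2:
        return SomCodebook(node_angles, np.zeros(n_nodes, dtype=int), counts, seed, degenerate=True)

    # cut the circle at the two largest gaps between occupied node angles
    occ_angles = node_angles[occupied]
    order = np.argsort(occ_angles)
    sorted_angles = occ_angles[order]
    gaps = np.diff(np.append(sorted_angles, sorted_angles[0] + TWO_PI))
    cut1, cut2 = np.sort(np.argsort(gaps)[-2:])
    occ_cluster = np.zeros(occupied.size, dtype=int)
    # nodes strictly after cut1 and up to cut2 (in sorted order) form cluster 1
    occ_cluster[order[cut1 + 1 : cut2 + 1]] = 1

    # unoccupied nodes inherit the cluster of the nearest occupied node
    node_cluster = np.zeros(n_nodes, dtype=int)
    nearest = np.argmin(circ_dist(node_angles[:, None], occ_angles[None, :]), axis=1)
    node_cluster[:] = occ_cluster[nearest]
    node_cluster[occupied] = occ_cluster

    return SomCodebook(node_angles, node_cluster, counts, seed, degenerate=False)


def classify(angles, codebook: SomCodebook) -> np.ndarray:
    """Cluster index (0/1) of each angle: the cluster of its nearest node."""
    angles = wrap_angle(angles)
    d = circ_dist(angles[:, None], codebook.node_angles[None, :])
    return codebook.node_cluster[np.argmin(d, axis=1)]


def _label_clusters(codebook: SomCodebook, axis: str, use_nadir: bool = False) -> dict[int, str]:
    """Map cluster indices to interpretable labels.

    Diurnal: the cluster whose density-weighted circular mean is nearer
    angle 0 (ZT0 / sunrise) is "morning".  Seasonal: the cluster whose
    mean lies in the Jul-Dec half-year [pi, 2*pi) is "fall"; if both or
    neither do, the cluster with the smaller circular mean is "fall"
    (deterministic tie-break).

    With ``use_nadir`` the codebook was trained on acrophases but the
    temporal semantics follow the curve troughs: cluster means are rotated
    by pi before labelling.
    """
    means = codebook.cluster_means()
    if use_nadir:
        means = {c: (m - np.pi) % TWO_PI for c, m in means.items()}
    if codebook.degenerate or len(means) == 1:
        only = next(iter(means))
        return {only: DIURNAL_LABELS[0] if axis == "diurnal" else SEASONAL_LABELS[0]}
    (c0, m0), (c1, m1) = sorted(means.items())
    if axis == "diurnal":
        if circ_dist(m0, 0.0) <= circ_dist(m1, 0.0):
            return {c0: "morning", c1: "evening"}
        return {c0: "evening", c1: "morning"}
    in0, in1 = np.pi <= m0 < TWO_PI, np.pi <= m1 < TWO_PI
    if in0 and not in1:
        return {c0: "fall", c1: "spring"}
    if in1 and not in0:
        return {c0: "spring", c1: "fall"}
    if m0 <= m1:
        return {c0: "fall", c1: "spring"}
    return {c0: "spring", c1: "fall"}


def classify_features(
    phi_d,
    phi_s,
    seed: int = 0,
    n_nodes: int = 24,
    feature_ids=None,
    use_nadir: bool = False,
) -> pd.DataFrame:
    """Two-axis temporal classification of features from their acrophases.

    Trains one ring SOM per axis, cuts each into two clusters, and labels
    them morning/evening (diurnal) and fall/spring (seasonal).

    For methylation the temporal semantics follow the nadir (trough)
    rather than the acrophase, since hypomethylation associates with
    transcription.  Because the nadirs are the acrophases rotated by
    exactly pi, clustering nadirs yields the identical feature partition;
    ``use_nadir=True`` therefore clusters the given acrophases and
    relabels the clusters by their nadir-side means, which is both
    mathematically equivalent and numerically exact.

    Returns a DataFrame with columns feature_id, diurnal_class,
    seasonal_class, combined_class, phase_used.
    """
    phi_d = wrap_angle(phi_d)
    phi_s = wrap_angle(phi_s)
    if phi_d.size != phi_s.size:
        raise ValueError("phi_d and phi_s must have equal length")
    if feature_ids is None:
        feature_ids = [f"feature_{i}" for i in range(phi_d.size)]

    cb_d = som_fit_ring(phi_d, n_nodes=n_nodes, seed=seed)
    cb_s = som_fit_ring(phi_s, n_nodes=n_nodes, seed=seed + 1)
    lab_d = _label_clusters(cb_d, "diurnal", use_nadir=use_nadir)
    lab_s = _label_clusters(cb_s, "seasonal", use_nadir=use_nadir)
    d_class = np.array([lab_d[c] for c in classify(phi_d, cb_d)])
    s_class = np.array([lab_s[c] for c in classify(phi_s, cb_s)])
    return pd.DataFrame(
        {
            "feature_id": list(feature_ids),
            "diurnal_class": d_class,
            "seasonal_class": s_class,
            "combined_class": [f"{d}/{s}" for d, s in zip(d_class, s_class)],
            "phase_used": "nadir" if use_nadir else "acrophase",
        }
    )


def class_table(classification: pd.DataFrame) -> np.ndarray:
    """2x2 contingency table of diurnal class x seasonal class counts."""
    tab = pd.crosstab(classification["diurnal_class"], classification["seasonal_class"])
    tab = tab.reindex(index=list(DIURNAL_LABELS), columns=list(SEASONAL_LABELS), fill_value=0)
    return tab.to_numpy()


def coupling_chi2(
    matrix: pd.DataFrame,
    meta: pd.DataFrame,
    spec: DesignSpec,
    B: int = 1000,
    seed: int = 0,
    use_nadir: bool = False,
    p_threshold: float | None = None,
    recompute_sun: bool = False,
) -> PermutationResult:
    """Diurnal-seasonal coupling chi-square with a shuffled-time/date null.

    Observed: fit all features, cluster diurnal and seasonal phases,
    tabulate the 2x2 class table and compute its chi-square.  Null
    replicates shuffle both times and dates of death and repeat the whole
    procedure (fit, cluster, tabulate).  ``use_nadir`` shifts both phase
    sets by pi (the methylation convention); ``p_threshold`` restricts to
    features rhythmic at that level on both axes (sensitivity analysis).
    """

    def statistic(meta_x: pd.DataFrame, rep_seed: int) -> float:
        X, _ = spec.design(meta_x)
        out = fit_matrix_arrays(Y, X)
        keep = ~out["degenerate_flag"]
        if p_threshold is not None:
            keep &= (out["p_d"] < p_threshold) & (out["p_s"] < p_threshold)
        cls = classify_features(
            out["phi_d"][keep], out["phi_s"][keep], seed=rep_seed, use_nadir=use_nadir
        )
        chi2, _, _ = chi2_contingency(class_table(cls))
        return chi2

    from .permutation import _aligned_arrays

    Y, meta_aligned = _aligned_arrays(matrix, meta)
    finite = np.all(np.isfinite(Y), axis=0)
    Y = Y[:, finite]

    observed = statistic(meta_aligned, seed)
    null = np.empty(B)
    for b in range(B):
        rng = child_rng(seed, b)
        meta_b = permute_metadata(meta_aligned, "both", rng, recompute_sun=recompute_sun)
        null[b] = statistic(meta_b, seed)

    return PermutationResult(observed=observed, null_values=null, B=B, shuffle_mode="both", seed=seed)
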