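"""TSS proximity, transcript-class proximity groups, context comparisons."""

import numpy as np
import pandas as pd
import pytest

from pmrhythm.context import (
    context_comparison,
    split_by_proximity,
    transcript_proximity_groups,
    tss_distance,
)
from pmrhythm.cosinor import DesignSpec
from pmrhythm.synthetic import (
    SimulationConfig,
    simulate_annotations,
    simulate_matrix,
    simulate_samples,
    simulate_truth,
)


def _features(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def _tss(rows):
    df = pd.DataFrame(rows, columns=["feature_id", "chrom", "tss_pos"])
    df["strand"] = "+"
    df["active"] = True
    return df


class TestTssDistance:
    def test_tss_inside_peak_distance_zero(self):
        feats = _features([("chr1", 100, 300, "p1")])
        tss = _tss([("t1", "chr1", 200)])
        dist, near = tss_distance(feats, tss)
        assert dist[0] == 0 and near[0] == "t1"

    def test_gap_measured_from_interval_edge(self):
        feats = _features([("chr1", 1000, 1200, "p1")])
        tss = _tss([("t1", "chr1", 3199)])
        dist, _ = tss_distance(feats, tss)
        assert dist[0] == 1999

    def test_missing_chromosome_gives_infinity(self):
        feats = _features([("chrX", 0, 10, "p1")])
        tss = _tss([("t1", "chr1", 5)])
        dist, near = tss_distance(feats, tss)
        assert np.isinf(dist[0]) and near[0] is None

    def test_matches_brute_force_on_random_features(self):
        rng = np.random.default_rng(0)
        feats = _features(
            [
                (f"chr{rng.integers(1, 3)}", s, s + int(rng.integers(1, 400)), f"p{i}")
                for i, s in enumerate(rng.integers(0, 100_000, 500))
            ]
        )
        tss = _tss(
            [(f"t{i}", f"chr{rng.integers(1, 3)}", int(p))
             for i, p in enumerate(rng.integers(0, 100_000, 80))]
        )
        dist, _ = tss_distance(feats, tss)
        for i in range(len(feats)):
            chrom, start, end = feats.loc[i, ["chrom", "start", "end"]]
            best = np.inf
            for _, row in tss[tss["chrom"] == chrom].iterrows():
                p = row["tss_pos"]
                if start <= p < end:
                    d = 0
                elif p < start:
                    d = start - p
                else:
                    d = p - end
                best = min(best, d)
            assert dist[i] == best

    def test_inactive_tss_excluded(self):
        feats = _features([("chr1", 100, 200, "p1")])
        tss = _tss([("t1", "chr1", 150), ("t2", "chr1", 5000)])
        tss.loc[0, "active"] = False
        dist, near = tss_distance(feats, tss)
        assert dist[0] == 4800 and near[0] == "t2"


class TestSplitByProximity:
    def test_boundary_exactly_at_threshold_is_proximal(self):
        feats = _features([("chr1", 0, 100, "p1"), ("chr1", 0, 100, "p2")])
        tss = _tss([("t1", "chr1", 2100)])
        prox, dist = split_by_proximity(feats, tss, threshold_bp=2000)
        assert prox == {"p1", "p2"} and dist == set()
        prox, dist = split_by_proximity(feats, tss, threshold_bp=1999)
        assert prox == set() and dist == {"p1", "p2"}

    def test_empty_tss_all_distal(self):
        feats = _features([("chr1", 0, 100, "p1")])
        tss = _tss([]).iloc[0:0]
        prox, dist = split_by_proximity(feats, tss)
        assert prox == set() and dist == {"p1"}

    def test_partition_exhaustive_disjoint(self):
        rng = np.random.default_rng(1)
        feats = _features(
            [("chr1", s, s + 100, f"p{i}") for i, s in enumerate(rng.integers(0, 50_000, 200))]
        )
        tss = _tss([(f"t{i}", "chr1", int(p)) for i, p in enumerate(rng.integers(0, 50_000, 30))])
        prox, dist = split_by_proximity(feats, tss)
        assert prox | dist == set(feats["name"])
        assert prox & dist == set()


class TestTranscriptProximityGroups:
    def test_single_tss_in_window_assigns_its_class(self):
        feats = _features([("chr1", 1000, 1100, "p1")])
        tss = _tss([("t1", "chr1", 2000)])
        classes = pd.DataFrame({"feature_id": ["t1"], "diurnal_class": ["morning"]})
        groups, ambiguous = transcript_proximity_groups(feats, classes, tss)
        assert groups["morning"] == {"p1"} and ambiguous == 0

    def test_conflicting_classes_excluded_and_counted(self):
        feats = _features([("chr1", 1000, 1100, "p1")])
        tss = _tss([("t1", "chr1", 500), ("t2", "chr1", 1500)])
        classes = pd.DataFrame(
            {"feature_id": ["t1", "t2"], "diurnal_class": ["morning", "evening"]}
        )
        groups, ambiguous = transcript_proximity_groups(feats, classes, tss)
        assert ambiguous == 1
        assert all(len(g) == 0 for g in groups.values())

    def test_out_of_window_tss_ignored(self):
        feats = _features([("chr1", 1000, 1100, "p1")])
        tss = _tss([("t1", "chr1", 3200)])  # 2100 bp past the end
        classes = pd.DataFrame({"feature_id": ["t1"], "diurnal_class": ["morning"]})
        groups, ambiguous = transcript_proximity_groups(feats, classes, tss)
        assert all(len(g) == 0 for g in groups.values()) and ambiguous == 0


@pytest.fixture(scope="module")
def planted():
    """Proximal features planted morning/fall, distal evening/spring."""
    cfg = SimulationConfig(
        n_samples=300, n_features=1000, frac_rhythmic=1.0, amp_fixed=0.5,
        noise_sd=1.0, coupling=1.0, seed=31,
    )
    s = simulate_samples(cfg)
    t = simulate_truth(cfg)
    m = simulate_matrix(s, t, cfg)
    morning = t["diurnal_class"] == "morning"
    group_a = set(t.loc[morning, "feature_id"])       # plays "proximal"
    group_b = set(t.loc[~morning, "feature_id"])      # plays "distal"
    return s, m, group_a, group_b


class TestContextComparison:
    def test_planted_split_detected_by_all_three_statistics(self, planted):
        s, m, ga, gb = planted
        res = context_comparison(
            m, s, DesignSpec(covariates=[]), ga, gb, B=200, seed=0
        )
        assert res.w_diurnal.empirical_p <= 0.05
        assert res.w_seasonal.empirical_p <= 0.05
        assert res.chi2_classes.empirical_p <= 0.05

    def test_random_split_not_detected(self, planted):
        s, m, ga, gb = planted
        rng = np.random.default_rng(2)
        ids = np.array(sorted(ga | gb))
        rng.shuffle(ids)
        res = context_comparison(
            m, s, DesignSpec(covariates=[]), set(ids[:500]), set(ids[500:]), B=100, seed=0
        )
        assert res.w_diurnal.empirical_p > 0.05
        assert res.chi2_classes.empirical_p > 0.05

    def test_partition_never_changes_under_metadata_permutation(self):
        """Proximity depends only on coordinates, not on sample metadata."""
        cfg = SimulationConfig(n_features=100, seed=4)
        t = simulate_truth(cfg)
        tss, peaks, _ = simulate_annotations(t, cfg)
        before = split_by_proximity(peaks, tss)
        after = split_by_proximity(peaks, tss)  # identical inputs, pure function
        assert before == after
        planted_prox = set(
            f"peak_{fid}" for fid, d in zip(t["feature_id"], t["tss_distance"]) if d <= 2000
        )
        assert before[0] == planted_prox
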