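"""Trajectory clustering and flight/traverse similarity distributions.

Flights are spatially downsampled to seven points at equal arc-length
fractions (endpoints exact), and the Euclidean distance between the
7x3 = 21-dimensional downsampled shapes is the flight-similarity metric for
agglomerative hierarchical clustering, cut at a linkage distance of 1.3 m
(configurable within the 1.2-1.4 m range; single linkage by default).

Pairwise flight similarity within a cluster is the Pearson correlation of
the concatenated x, y, z coordinates after resampling each flight to a
common number of equal-time points; traverse similarity uses concatenated
x, y only.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import pearsonr

logger = logging.getLogger("batmap")


def downsample_flight(xyz, n_points: int = 7) -> np.ndarray:
    """Points at equal cumulative arc-length fractions along a flight path.

    The first and last points are exactly the take-off and landing
    positions.  A degenerate zero-length path yields n copies of its point.
    """
    xyz = np.asarray(xyz, float)
    seg = np.linalg.norm(np.diff(xyz, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if s[-1] <= 0:
        return np.repeat(xyz[:1], n_points, axis=0)
    frac = np.linspace(0.0, s[-1], n_points)
    pts = np.column_stack([np.interp(frac, s, xyz[:, k]) for k in range(3)])
    pts[0], pts[-1] = xyz[0], xyz[-1]
    return pts


@dataclass
class TrajectoryCluster:
    cluster_id: int
    member_ids: list
    template: np.ndarray                    # (7, 3) mean downsampled shape
    n_flights_per_human: dict = field(default_factory=dict)

    @property
    def n_flights(self) -> int:
        return len(self.member_ids)


def cluster_flights(flight_paths, linkage_distance: float = 1.3,
                    method: str = "single", human_labels=None) -> list:
    """Agglomerative clustering of flights on downsampled-shape distance.

    Returns clusters sorted by descending membership (ties by smallest
    member id, which makes the result independent of input ordering up to
    relabeling).
    """
    n = len(flight_paths)
    if n == 0:
        raise ValueError("need at least one flight")
    shapes = np.stack([downsample_flight(p).ravel() for p in flight_paths])
    if n == 1:
        labels = np.array([1])
    else:
        Z = linkage(shapes, method=method, metric="euclidean")
        labels = fcluster(Z, t=linkage_distance, criterion="distance")
    clusters = []
    for lab in np.unique(labels):
        members = sorted(np.flatnonzero(labels == lab).tolist())
        template = shapes[members].mean(axis=0).reshape(-1, 3)
        per_human = {}
        if human_labels is not None:
            for m in members:
                h = human_labels[m]
                if h is not None:
                    per_human[h] = per_human.get(h, 0) + 1
        clusters.append(TrajectoryCluster(0, members, template, per_human))
    clusters.sort(key=lambda c: (-c.n_flights, c.member_ids[0]))
    for i, c in enumerate(clusters):
        c.cluster_id = i
    return clusters


def resample_equal_time(t, coords, n: int = 100) -> np.ndarray:
    """Resample a path to n equal-time points, (n, d)."""
    t = np.asarray(t, float)
    coords = np.asarray(coords, float)
    ti = np.linspace(t[0], t[-1], n)
    return np.column_stack([np.interp(ti, t, coords[:, k])
                            for k in range(coords.shape[1])])


@dataclass
class SimilarityDistributions:
    within_r: np.ndarray
    across_r: np.ndarray

    @property
    def n_within(self) -> int:
        return self.within_r.size

    @property
    def n_across(self) -> int:
        return self.across_r.size


def _pairwise_r(vectors_a, vectors_b=None):
    """Pearson r of concatenated-coordinate vectors: all within-a pairs, or
    all cross pairs if vectors_b is given."""
    out = []
    if vectors_b is None:
        for i, j in combinations(range(len(vectors_a)), 2):
            out.append(pearsonr(vectors_a[i], vectors_a[j]).statistic)
    else:
        for va in vectors_a:
            for vb in vectors_b:
                out.append(pearsonr(va, vb).statistic)
    return out


def flight_pair_correlations(clusters, flights_data, human_labels,
                             min_per_human: int = 4,
                             n_resample: int = 100) -> SimilarityDistributions:
    """Within- vs across-human flight-pair correlations, pooled over clusters.

    ``flights_data`` maps flight id -> (t, xyz).  Only clusters with at
    least ``min_per_human`` flights to each human contribute; others are
    skipped with a log entry.
    """
    within, across = [], []
    for c in clusters:
        by_human = {}
        for m in c.member_ids:
            h = human_labels[m]
            if h is not None:
                by_human.setdefault(h, []).append(m)
        if len(by_human) < 2 or any(len(v) < min_per_human
                                    for v in by_human.values()):
            logger.info("cluster %d skipped for pair correlations "
                        "(needs >=%d flights per human)", c.cluster_id,
                        min_per_human)
            continue
        vecs = {h: [resample_equal_time(*flights_data[m], n_resample).ravel(order="F")
                    for m in ms] for h, ms in by_human.items()}
        humans = sorted(vecs)
        for h in humans:
            within.extend(_pairwise_r(vecs[h]))
        for ha, hb in combinations(humans, 2):
            across.extend(_pairwise_r(vecs[ha], vecs[hb]))
    return SimilarityDistributions(np.asarray(within), np.asarray(across))


def traverse_correlations(traverse_paths_by_human,
                          n_resample: int = 100) -> SimilarityDistributions:
    """Within- vs across-human traverse correlations on concatenated x, y.

    ``traverse_paths_by_human`` maps human id -> list of (t, xy) paths.
    """
    vecs = {h: [resample_equal_time(t, xy[:, :2], n_resample).ravel(order="F")
                for t, xy in paths]
            for h, paths in traverse_paths_by_human.items()}
    humans = sorted(vecs)
    within, across = [], []
    for h in humans:
        within.extend(_pairwise_r(vecs[h]))
    for ha, hb in combinations(humans, 2):
        across.extend(_pairwise_r(vecs[ha], vecs[hb]))
    return SimilarityDistributions(np.asarray(within), np.asarray(across))
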