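"""Spatial clustering statistics for residue sets.

The degree of spatial clustering of a set of N_s residue positions is the
average inverse distance over all pairs,

    M_s = (1 / N_pairs) Σ_{i<j} 1 / r_ij,   N_pairs = N_s (N_s - 1) / 2,

with r_ij the distance between residue centers of mass (Å); M_s has units of
1/Å and is robust to a few outliers.  The clustering ratio

    ρ = M_s,cons / M_s,int

compares a subset (e.g. conserved residues) with the whole set (interface or
patch); ρ > 1 means the subset is clustered within the whole.

Significance is assessed empirically against random same-size subsets, and
conserved residues are partitioned into spatial sub-clusters by average-linkage
agglomerative clustering under a distance threshold (21 Å homodimers, 15 Å
complexes; the rule behind these defaults is half the mean maximum inter-atom
distance of conserved interface residues).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

from .structure import ResidueKey

#: Sub-cluster distance thresholds (Å) by analysis flavor.
LINKAGE_THRESHOLDS = {"homodimer": 21.0, "complex": 15.0}

DEFAULT_SEED = 20100527
_COINCIDENT_TOL = 1e-9


class TooFewPointsError(ValueError):
    """M_s is undefined for fewer than 2 points."""


class TooFewConservedError(TooFewPointsError):
    """The conserved subset has fewer than 2 members; ρ cannot be computed."""


@dataclass
class PointSet:
    """Residue keys with their 3-D positions (typically centers of mass)."""

    keys: list[ResidueKey]
    coords: np.ndarray

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if len(self.keys) != len(self.coords):
            raise ValueError("keys and coords must have the same length")
        if len(set(self.keys)) != len(self.keys):
            raise ValueError("duplicate residue keys in point set")

    @classmethod
    def from_centers(cls, centers: Mapping[ResidueKey, np.ndarray],
                     keys: Iterable[ResidueKey] | None = None) -> "PointSet":
        keys = sorted(centers) if keys is None else sorted(keys)
        return cls(keys=list(keys), coords=np.array([centers[k] for k in keys]))

    def __len__(self) -> int:
        return len(self.keys)

    def subset(self, keys: Iterable[ResidueKey]) -> "PointSet":
        wanted = set(keys)
        idx = [i for i, k in enumerate(self.keys) if k in wanted]
        missing = wanted - {self.keys[i] for i in idx}
        if missing:
            raise ValueError(f"keys not in point set: {sorted(missing)[:5]}")
        return PointSet(keys=[self.keys[i] for i in idx], coords=self.coords[idx])


def _as_coords(points) -> np.ndarray:
    if isinstance(points, PointSet):
        return points.coords
    return np.asarray(points, dtype=float).reshape(-1, 3)


def spatial_clustering_score(points) -> float:
    """M_s: mean inverse pairwise distance (1/Å) of a point set."""
    coords = _as_coords(points)
    if len(coords) < 2:
        raise TooFewPointsError(f"M_s needs at least 2 points, got {len(coords)}")
    d = pdist(coords)
    if d.min() < _COINCIDENT_TOL:
        raise ValueError("coincident points: pairwise distance is zero")
    return float(np.mean(1.0 / d))


@dataclass
class ClusteringResult:
    """M_s of the subset and the whole set, and their ratio ρ."""

    m_s_subset: float
    m_s_whole: float

    @property
    def rho(self) -> float:
        return self.m_s_subset / self.m_s_whole


def clustering_ratio(subset: PointSet, whole: PointSet) -> ClusteringResult:
    """ρ = M_s(subset) / M_s(whole); the subset must be contained in the whole."""
    if not set(subset.keys) <= set(whole.keys):
        raise ValueError("subset keys are not all contained in the whole set")
    if len(subset) < 2:
        raise TooFewConservedError(
            f"conserved subset has {len(subset)} point(s); at least 2 required"
        )
    if len(whole) < 2:
        raise TooFewPointsError("whole set needs at least 2 points")
    return ClusteringResult(
        m_s_subset=spatial_clustering_score(subset),
        m_s_whole=spatial_clustering_score(whole),
    )


@dataclass
class RandomSubsetTest:
    """Null distribution of M_s over uniform same-size subsets of the whole set."""

    n_trials: int
    mean_random: float
    sd_random: float
    p_empirical: float
    seed: int
    observed: float


def random_subset_test(
    whole: PointSet,
    subset_size: int,
    observed_m_s: float,
    n_trials: int = 1000,
    seed: int = DEFAULT_SEED,
) -> RandomSubsetTest:
    """Compare an observed M_s against random same-size subsets of the whole set.

    Draws ``n_trials`` uniform subsets without replacement, computes each M_s,
    and reports their mean, SD, and the empirical p-value
    p = (1 + #{M_s,random ≥ observed}) / (n_trials + 1).
    """
    n = len(whole)
    if subset_size > n:
        raise ValueError(f"subset_size {subset_size} exceeds set size {n}")
    if subset_size < 2:
        raise TooFewPointsError("subset_size must be at least 2")
    if n_trials < 1:
        raise ValueError("n_trials must be at least 1")
    d = pdist(whole.coords)
    if d.min() < _COINCIDENT_TOL:
        raise ValueError("coincident points: pairwise distance is zero")
    inv = squareform(1.0 / d)
    rng = np.random.default_rng(seed)
    npairs2 = subset_size * (subset_size - 1)  # off-diagonal sum counts each pair twice
    values = np.empty(n_trials)
    for t in range(n_trials):
        idx = rng.choice(n, size=subset_size, replace=False)
        values[t] = inv[np.ix_(idx, idx)].sum() / npairs2
    k = int(np.sum(values >= observed_m_s))
    return RandomSubsetTest(
        n_trials=n_trials,
        mean_random=float(values.mean()),
        sd_random=float(values.std(ddof=0)),
        p_empirical=(1 + k) / (n_trials + 1),
        seed=seed,
        observed=float(observed_m_s),
    )


@dataclass
class SubclusterPartition:
    """Disjoint spatial sub-clusters (singletons allowed) of a residue set."""

    clusters: list[frozenset[ResidueKey]]
    threshold: float

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def members(self, include_singletons: bool = True) -> set[ResidueKey]:
        out: set[ResidueKey] = set()
        for c in self.clusters:
            if include_singletons or len(c) > 1:
                out |= c
        return out

    def sizes(self) -> list[int]:
        return sorted((len(c) for c in self.clusters), reverse=True)


def average_linkage_subclusters(points: PointSet, threshold: float) -> SubclusterPartition:
    """Partition points by average-linkage agglomerative clustering.

    Clusters are merged while the minimum average inter-cluster distance is at
    or below ``threshold`` (average of all inter-point distances between the
    two clusters, UPGMA); since average linkage is monotone this equals cutting
    the dendrogram at that height.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    n = len(points)
    if n == 0:
        raise ValueError("cannot cluster an empty point set")
    if n == 1:
        return SubclusterPartition(clusters=[frozenset(points.keys)], threshold=threshold)
    z = linkage(pdist(points.coords), method="average")
    labels = fcluster(z, t=threshold, criterion="distance")
    groups: dict[int, set[ResidueKey]] = {}
    for key, lab in zip(points.keys, labels):
        groups.setdefault(int(lab), set()).add(key)
    clusters = [frozenset(g) for _, g in sorted(groups.items())]
    return SubclusterPartition(clusters=clusters, threshold=threshold)


def derive_linkage_threshold(interfaces: Iterable[np.ndarray]) -> float:
    """Half the mean, over interfaces, of the maximum inter-atom distance among
    atoms of conserved interface residues (the rule behind the 21/15 Å defaults)."""
    maxima = []
    for coords in interfaces:
        coords = np.asarray(coords, dtype=float).reshape(-1, 3)
        if len(coords) < 2:
            raise ValueError("each interface needs at least 2 atoms")
        maxima.append(pdist(coords).max())
    if not maxima:
        raise ValueError("empty collection of interfaces")
    return 0.5 * float(np.mean(maxima))


def subcluster_report_frame(partition: SubclusterPartition, centers: Mapping[ResidueKey, np.ndarray]):
    """Cluster report: cluster id, size, members, intra-cluster M_s (NaN for singletons)."""
    import pandas as pd

    rows = []
    for cid, cluster in enumerate(
        sorted(partition.clusters, key=lambda c: (-len(c), sorted(c))), start=1
    ):
        members = sorted(cluster)
        if len(members) >= 2:
            m_s = spatial_clustering_score(np.array([centers[k] for k in members]))
        else:
            m_s = float("nan")
        rows.append(
            {
                "cluster": cid,
                "size": len(members),
                "members": ";".join(f"{k.chain_id}{k.residue_number}{k.insertion_code}" for k in members),
                "m_s": m_s,
            }
        )
    return pd.DataFrame(rows, columns=["cluster", "size", "members", "m_s"])
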