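"""Collapse SOM clusters into annotated phenotypes.

Mean expression profiles per SOM cluster are z-scored per marker and capped,
then merged by consensus hierarchical clustering (repeated subsampled
average-linkage runs tallied into a consensus matrix, itself hierarchically
clustered). A remap table — machine-generated here, optionally hand-edited —
carries the cluster -> metacluster -> annotation mapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .image_io import RemapTable
from .preprocessing import PixelTable

__all__ = [
    "ClusterProfile",
    "ConsensusConfig",
    "compute_profiles",
    "zscore_cap",
    "consensus_metacluster",
    "apply_remap",
    "mapping_to_remap",
]


@dataclass
class ClusterProfile:
    """Per-SOM-cluster mean expression and member counts.

    Rows cover ids ``1..n_clusters``; empty clusters have count 0 and are
    excluded from metaclustering.
    """

    cluster_ids: np.ndarray
    mean_expression: np.ndarray = field(repr=False)
    counts: np.ndarray
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.cluster_ids = np.asarray(self.cluster_ids, dtype=np.int64)
        self.mean_expression = np.asarray(self.mean_expression, dtype=np.float64)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if not (len(self.cluster_ids) == len(self.counts) == self.mean_expression.shape[0]):
            raise ValueError("profile fields must have one row per cluster")

    @property
    def nonempty(self) -> np.ndarray:
        return self.counts > 0

    @property
    def nonempty_ids(self) -> np.ndarray:
        return self.cluster_ids[self.nonempty]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.mean_expression, columns=self.feature_names or None)
        df.insert(0, "cluster", self.cluster_ids)
        df["count"] = self.counts
        return df


@dataclass
class ConsensusConfig:
    k: int = 15
    iterations: int = 100
    item_subsample: float = 0.8
    linkage: str = "average"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if not 0 < self.item_subsample <= 1:
            raise ValueError("item_subsample must be in (0, 1]")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


def compute_profiles(
    table: PixelTable | np.ndarray,
    assignments: np.ndarray,
    n_clusters: int | None = None,
    feature_names: list[str] | None = None,
) -> ClusterProfile:
    """Arithmetic mean of each cluster's rows, plus member counts."""
    if isinstance(table, PixelTable):
        values = table.values
        feature_names = feature_names or list(table.marker_names)
    else:
        values = np.asarray(table, dtype=np.float64)
    assignments = np.asarray(assignments, dtype=np.int64)
    if len(assignments) != values.shape[0]:
        raise ValueError("assignments length must match table rows")
    if n_clusters is None:
        n_clusters = int(assignments.max(initial=0))
    counts = np.bincount(assignments, minlength=n_clusters + 1)[1:]
    sums = np.zeros((n_clusters, values.shape[1]))
    np.add.at(sums, assignments - 1, values)
    means = np.divide(
        sums, counts[:, None], out=np.zeros_like(sums), where=counts[:, None] > 0
    )
    return ClusterProfile(
        cluster_ids=np.arange(1, n_clusters + 1),
        mean_expression=means,
        counts=counts,
        feature_names=feature_names or [],
    )


def zscore_cap(
    profile: ClusterProfile, cap: float = 3.0, symmetric: bool = False
) -> np.ndarray:
    """Z-score each marker across nonempty clusters; cap large values.

    Sample standard deviation (ddof=1); zero-variance markers map to 0. The
    cap is upper-only by default; ``symmetric=True`` also floors at ``-cap``.
    Returns a matrix over the nonempty clusters only (``profile.nonempty_ids``).
    """
    x = profile.mean_expression[profile.nonempty]
    if x.shape[0] < 2:
        raise ValueError("need at least 2 nonempty clusters to z-score")
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    z = np.divide(x - mean, sd, out=np.zeros_like(x), where=sd > 0)
    z = np.minimum(z, cap)
    if symmetric:
        z = np.maximum(z, -cap)
    return z


def consensus_metacluster(
    capped: np.ndarray,
    config: ConsensusConfig,
    cluster_ids: np.ndarray | None = None,
    return_matrix: bool = False,
):
    """Consensus hierarchical clustering of (capped z-scored) profile rows.

    Each iteration subsamples ceil(item_subsample * n) rows, clusters them
    hierarchically (Euclidean, average linkage) cut at k, and tallies
    co-assignments. The consensus matrix (co-clustered / co-sampled pairs) is
    converted to distances (1 - consensus) and clustered once more, cut at k.
    Returns a mapping ``cluster_id -> metacluster`` (ids 1..k).
    """
    capped = np.asarray(capped, dtype=np.float64)
    n = capped.shape[0]
    if cluster_ids is None:
        cluster_ids = np.arange(1, n + 1)
    cluster_ids = np.asarray(cluster_ids, dtype=np.int64)
    if len(cluster_ids) != n:
        raise ValueError("cluster_ids length must match capped rows")
    if config.k > n:
        raise ValueError(f"k={config.k} exceeds {n} nonempty clusters")
    if config.k == n:
        mapping = {int(c): i + 1 for i, c in enumerate(cluster_ids)}
        return (mapping, np.eye(n)) if return_matrix else mapping

    rng = np.random.default_rng(config.seed)
    # subsampling k or fewer rows makes every iteration trivial (each row its
    # own cluster) and the consensus matrix uninformative; keep n_sub > k
    n_sub = min(n, max(int(np.ceil(config.item_subsample * n)), config.k + 1))
    co_clustered = np.zeros((n, n))
    co_sampled = np.zeros((n, n))
    for _ in range(config.iterations):
        idx = rng.choice(n, size=n_sub, replace=False)
        z = linkage(capped[idx], method=config.linkage, metric="euclidean")
        labels = fcluster(z, t=config.k, criterion="maxclust")
        same = labels[:, None] == labels[None, :]
        co_sampled[np.ix_(idx, idx)] += 1
        co_clustered[np.ix_(idx, idx)] += same
    consensus = np.divide(
        co_clustered, co_sampled, out=np.zeros_like(co_clustered), where=co_sampled > 0
    )
    np.fill_diagonal(consensus, 1.0)
    dist = 1.0 - consensus
    dist = (dist + dist.T) / 2.0
    np.fill_diagonal(dist, 0.0)
    z = linkage(squareform(dist, checks=False), method=config.linkage)
    meta = fcluster(z, t=config.k, criterion="maxclust")
    mapping = {int(c): int(m) for c, m in zip(cluster_ids, meta)}
    return (mapping, consensus) if return_matrix else mapping


def apply_remap(
    assignments: np.ndarray, remap: RemapTable
) -> tuple[np.ndarray, np.ndarray]:
    """Relabel SOM assignments to metaclusters with per-element annotations."""
    assignments = np.asarray(assignments, dtype=np.int64)
    remap.validate_covers(assignments)
    max_id = int(
        max(assignments.max(initial=0), remap.frame["som_cluster"].max())
    )
    lut_meta = np.zeros(max_id + 1, dtype=np.int64)
    lut_meta[remap.frame["som_cluster"].to_numpy()] = remap.frame[
        "metacluster"
    ].to_numpy()
    meta = lut_meta[assignments]
    annotations = remap.meta_annotations
    lut_ann = np.empty(int(remap.frame["metacluster"].max()) + 1, dtype=object)
    for m, a in annotations.items():
        lut_ann[m] = a
    return meta, lut_ann[meta]


def mapping_to_remap(
    mapping: dict[int, int], annotations: dict[int, str] | None = None
) -> RemapTable:
    """Build a RemapTable from a consensus mapping, with placeholder names."""
    rows = []
    for som_id in sorted(mapping):
        meta = mapping[som_id]
        name = (annotations or {}).get(meta, f"metacluster_{meta}")
        rows.append({"som_cluster": som_id, "metacluster": meta, "annotation": name})
    return RemapTable(pd.DataFrame(rows))
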