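"""Cluster consistency score: replicate orchestration and the statistic.

The score asks, for each cluster in each replicate run, how many clusters of
every other replicate are needed (taking them in decreasing-overlap order) to
cover 95% of its members; those pairwise counts are averaged per cluster and
then mapped back onto the observations, giving one score per observation.
A score of 1 means the replicates group the observations identically (up to
relabeling); larger values mean a cluster's members are scattered across
several clusters of other runs. The metric is clustering-agnostic — it only
consumes aligned label vectors — so it applies equally to pixel, cell, or
external clusterings.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pixel_pipeline import PixelRunConfig, run_pixel_clustering

__all__ = [
    "ReplicateSet",
    "ConsistencyResult",
    "run_replicates",
    "coverage_target",
    "min_clusters_to_cover",
    "cluster_consistency",
    "coverage_sweep",
]


@dataclass
class ReplicateSet:
    """Aligned cluster-assignment vectors from replicate runs (same pixels)."""

    assignments: np.ndarray = field(repr=False)  # (n_replicates, n_observations)
    seeds: list[int] = field(default_factory=list)
    coords: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.assignments = np.asarray(self.assignments, dtype=np.int64)
        if self.assignments.ndim != 2:
            raise ValueError("assignments must be 2-D (replicates x observations)")

    @property
    def n_replicates(self) -> int:
        return self.assignments.shape[0]

    @property
    def n_observations(self) -> int:
        return self.assignments.shape[1]


@dataclass
class ConsistencyResult:
    per_cluster_scores: dict[tuple[int, int], float]
    per_observation_scores: np.ndarray
    coverage: float

    @property
    def mean(self) -> float:
        return float(np.mean(self.per_observation_scores))

    @property
    def sd(self) -> float:
        return float(np.std(self.per_observation_scores, ddof=1))

    def summary(self) -> dict[str, float]:
        return {"mean": self.mean, "sd": self.sd, "coverage": self.coverage}


def run_replicates(
    config: PixelRunConfig,
    n: int = 5,
    base_seed: int = 0,
    level: str = "meta",
    images=None,
) -> ReplicateSet:
    """Run the pixel pipeline ``n`` times, differing only in seed.

    Exclusion filters are deterministic, so every replicate retains the
    identical pixel list and the assignment vectors align element-wise.
    ``level`` selects metacluster (default) or raw SOM-cluster assignments.
    """
    if level not in ("meta", "som"):
        raise ValueError("level must be 'meta' or 'som'")
    vectors = []
    seeds = []
    coords = None
    for i in range(n):
        seed = base_seed + i
        try:
            result = run_pixel_clustering(
                dataclasses.replace(config, seed=seed, output_dir=None), images=images
            )
        except Exception as exc:  # noqa: BLE001 - annotate which replicate failed
            raise RuntimeError(f"replicate {i + 1}/{n} (seed {seed}) failed") from exc
        if coords is None:
            coords = result.table.coords
        vectors.append(
            result.meta_assignments if level == "meta" else result.som_assignments
        )
        seeds.append(seed)
    return ReplicateSet(np.stack(vectors), seeds=seeds, coords=coords)


def coverage_target(n_pixels: int, coverage: float = 0.95) -> float:
    """Cumulative member count that must be reached: coverage x n (no rounding)."""
    if not 0 < coverage <= 1:
        raise ValueError("coverage must be in (0, 1]")
    if n_pixels < 1:
        raise ValueError("n_pixels must be >= 1")
    return coverage * n_pixels


def min_clusters_to_cover(
    overlap_counts: np.ndarray, n_pixels: int, coverage: float = 0.95
) -> int:
    """Minimum number of clusters whose summed overlap reaches the target.

    ``overlap_counts[j]`` is how many of a cluster's ``n_pixels`` members fall
    in cluster j of the other replicate. Counts are taken in descending order
    (ties broken by ascending cluster index) until their cumulative sum
    reaches ``coverage * n_pixels``.
    """
    counts = np.asarray(overlap_counts, dtype=np.int64)
    if counts.sum() != n_pixels:
        raise ValueError(
            f"overlap counts sum to {counts.sum()}, expected n_pixels={n_pixels}"
        )
    target = coverage_target(n_pixels, coverage)
    order = np.lexsort((np.arange(len(counts)), -counts))
    cumulative = np.cumsum(counts[order])
    return int(np.searchsorted(cumulative, target) + 1)


def _pairwise_scores(labels_a: np.ndarray, labels_b: np.ndarray, coverage: float):
    """For each cluster of A: clusters of B needed to cover its members."""
    a_ids, a_codes = np.unique(labels_a, return_inverse=True)
    b_ids, b_codes = np.unique(labels_b, return_inverse=True)
    contingency = np.zeros((len(a_ids), len(b_ids)), dtype=np.int64)
    np.add.at(contingency, (a_codes, b_codes), 1)
    out = {}
    for i, a_id in enumerate(a_ids):
        row = contingency[i]
        out[int(a_id)] = min_clusters_to_cover(row, int(row.sum()), coverage)
    return out


def cluster_consistency(reps: ReplicateSet, coverage: float = 0.95) -> ConsistencyResult:
    """Per-cluster and per-observation consistency scores across replicates.

    score(r, c) = mean over the other replicates of the cover count for
    cluster c of replicate r; each observation's score is the mean over
    replicates of the score of the cluster it sits in.
    """
    n_rep = reps.n_replicates
    if n_rep < 2:
        raise ValueError("need at least 2 replicates")
    labels = reps.assignments
    per_cluster: dict[tuple[int, int], float] = {}
    for r in range(n_rep):
        sums: dict[int, float] = {}
        for s in range(n_rep):
            if s == r:
                continue
            pair = _pairwise_scores(labels[r], labels[s], coverage)
            for cid, value in pair.items():
                sums[cid] = sums.get(cid, 0.0) + value
        for cid, total in sums.items():
            per_cluster[(r, cid)] = total / (n_rep - 1)

    per_obs = np.zeros(reps.n_observations)
    for r in range(n_rep):
        ids = np.unique(labels[r])
        lut = np.zeros(int(ids.max()) + 1)
        for cid in ids:
            lut[cid] = per_cluster[(r, int(cid))]
        per_obs += lut[labels[r]]
    per_obs /= n_rep
    return ConsistencyResult(per_cluster, per_obs, coverage)


def coverage_sweep(reps: ReplicateSet, coverages: list[float]) -> pd.DataFrame:
    """Mean per-observation score at each coverage (monotone non-decreasing)."""
    rows = []
    for cov in coverages:
        if not 0 < cov <= 1:
            raise ValueError(f"invalid coverage {cov}")
        rows.append(
            {"coverage": cov, "mean_score": cluster_consistency(reps, cov).mean}
        )
    return pd.DataFrame(rows)
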