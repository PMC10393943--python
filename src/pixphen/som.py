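"""Self-organizing map: the overclustering engine for pixels and cells.

Online (stochastic) training with a linearly decaying learning rate between
the configured start and end rates, a Gaussian neighborhood over grid
Chebyshev distance whose radius decays linearly from half the grid diagonal
to 1, Euclidean best-matching-unit selection, and data-sampled node
initialization. Everything is deterministic given the seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

__all__ = ["SOMConfig", "SOMModel", "train_som", "assign_som"]

try:  # pragma: no cover - exercised indirectly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap(args[0]) if args and callable(args[0]) else wrap


@dataclass
class SOMConfig:
    grid_rows: int = 10
    grid_cols: int = 10
    alpha_start: float = 0.05
    alpha_end: float = 0.01
    passes: int = 10
    distance: str = "euclidean"
    init: str = "random"
    radius_start: float | None = None  # default: half the grid diagonal
    radius_end: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_rows * self.grid_cols < 2:
            raise ValueError("grid must have at least 2 nodes")
        if not 0 < self.alpha_end <= self.alpha_start < 1:
            raise ValueError("need 0 < alpha_end <= alpha_start < 1")
        if self.passes < 1:
            raise ValueError("passes must be >= 1")
        if self.distance != "euclidean":
            raise ValueError("only the Euclidean distance is supported")
        if self.init != "random":
            raise ValueError("only random (data-sampled) initialization is supported")

    @property
    def n_nodes(self) -> int:
        return self.grid_rows * self.grid_cols

    def resolved_radius_start(self) -> float:
        if self.radius_start is not None:
            return self.radius_start
        half_diag = 0.5 * math.hypot(self.grid_rows - 1, self.grid_cols - 1)
        return max(half_diag, self.radius_end)


@dataclass
class SOMModel:
    config: SOMConfig
    weights: np.ndarray = field(repr=False)
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if self.weights.shape[0] != self.config.n_nodes:
            raise ValueError("weights row count must equal grid size")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("weights must be finite")
        if self.feature_names and len(self.feature_names) != self.weights.shape[1]:
            raise ValueError("feature_names length must match weight columns")

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(
            json.dumps(
                {
                    "config": asdict(self.config),
                    "feature_names": self.feature_names,
                    "weights": self.weights.tolist(),
                },
            )
        )
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "SOMModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            config=SOMConfig(**payload["config"]),
            weights=np.array(payload["weights"]),
            feature_names=payload["feature_names"],
        )


@njit(cache=False)
def _train_loop(weights, data, order, alphas, radii, grid_cols):  # pragma: no cover
    n_nodes, n_feat = weights.shape
    for step in range(order.size):
        x = data[order[step]]
        best = 0
        best_d = np.inf
        for j in range(n_nodes):
            d = 0.0
            for f in range(n_feat):
                t = weights[j, f] - x[f]
                d += t * t
            if d < best_d:
                best_d = d
                best = j
        br = best // grid_cols
        bc = best % grid_cols
        alpha = alphas[step]
        denom = 2.0 * radii[step] * radii[step]
        for j in range(n_nodes):
            dr = abs(j // grid_cols - br)
            dc = abs(j % grid_cols - bc)
            cheb = dr if dr > dc else dc
            aj = alpha * math.exp(-(cheb * cheb) / denom)
            for f in range(n_feat):
                weights[j, f] += aj * (x[f] - weights[j, f])


def _train_loop_numpy(weights, data, order, alphas, radii, grid_cols):
    """Pure-numpy fallback, identical arithmetic to the jitted loop."""
    n_nodes = weights.shape[0]
    node_r = np.arange(n_nodes) // grid_cols
    node_c = np.arange(n_nodes) % grid_cols
    for step in range(order.size):
        x = data[order[step]]
        diffs = weights - x
        best = int(np.argmin(np.einsum("ij,ij->i", diffs, diffs)))
        cheb = np.maximum(
            np.abs(node_r - node_r[best]), np.abs(node_c - node_c[best])
        )
        h = alphas[step] * np.exp(-(cheb**2) / (2.0 * radii[step] ** 2))
        weights += h[:, None] * (x - weights)


def train_som(
    data: np.ndarray, config: SOMConfig, feature_names: list[str] | None = None
) -> SOMModel:
    """Train a SOM on ``data`` (n_observations x n_features)."""
    data = np.ascontiguousarray(data, dtype=np.float64)
    if data.ndim != 2 or data.shape[1] < 1:
        raise ValueError("data must be 2-D with at least one feature")
    if not np.all(np.isfinite(data)):
        raise ValueError("data contains non-finite values")
    n, m = data.shape
    if n < config.n_nodes:
        raise ValueError(
            f"{n} observations < {config.n_nodes} SOM nodes; use a smaller grid"
        )
    if feature_names is not None and len(feature_names) != m:
        raise ValueError("feature_names length must match data columns")

    rng = np.random.default_rng(config.seed)
    # data-sampled init: n_nodes distinct training rows
    init_idx = rng.choice(n, size=config.n_nodes, replace=False)
    weights = data[init_idx].copy()

    total_steps = config.passes * n
    alphas = np.linspace(config.alpha_start, config.alpha_end, total_steps)
    radii = np.linspace(config.resolved_radius_start(), config.radius_end, total_steps)
    order = np.concatenate([rng.permutation(n) for _ in range(config.passes)])

    loop = _train_loop if _HAVE_NUMBA else _train_loop_numpy
    loop(weights, data, order.astype(np.int64), alphas, radii, config.grid_cols)
    return SOMModel(config=config, weights=weights, feature_names=feature_names or [])


def assign_som(model: SOMModel, data: np.ndarray, chunk: int = 8192) -> np.ndarray:
    """Map each row to its best-matching unit; returns 1-based node ids.

    Pure function of (model, data): row i's id does not depend on other rows.
    Ties are broken toward the lowest node id.
    """
    data = np.asarray(data, dtype=np.float64)
    if data.ndim != 2 or data.shape[1] != model.weights.shape[1]:
        raise ValueError(
            f"data has {data.shape[-1] if data.ndim == 2 else '?'} features, "
            f"model expects {model.weights.shape[1]}"
        )
    w = model.weights
    out = np.empty(data.shape[0], dtype=np.int64)
    for start in range(0, data.shape[0], chunk):
        block = data[start : start + chunk]
        # explicit differences keep exact ties exact; argmin ties -> lowest id
        d = np.square(block[:, None, :] - w[None, :, :]).sum(axis=2)
        out[start : start + chunk] = np.argmin(d, axis=1) + 1
    return out
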