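"""Cell phenotyping from pixel-cluster composition within segmentation masks.

The primary route tallies, for every segmented cell, the fraction of its
pixels assigned to each pixel (meta)cluster and clusters cells on those
composition vectors. The integrated-expression baseline (per-cell mean
marker intensity, optionally after the smoothing/pixel-normalization
cascade) is provided for comparison. Both feed the same SOM ->
consensus-metaclustering machinery as the pixel stage.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .image_io import LabelMap, MultiChannelImage, RemapTable
from .metaclustering import (
    ConsensusConfig,
    apply_remap,
    compute_profiles,
    consensus_metacluster,
    mapping_to_remap,
    zscore_cap,
)
from .preprocessing import smooth_channels
from .som import SOMConfig, SOMModel, assign_som, train_som

__all__ = [
    "CellFeatureTable",
    "CellClusterResult",
    "cell_pixel_composition",
    "normalize_cell_features",
    "integrated_expression_features",
    "cluster_cells",
]


@dataclass
class CellFeatureTable:
    """Per-cell feature vectors with provenance of the feature kind."""

    cells: pd.DataFrame = field(repr=False)  # columns: fov, cell_id, cell_size
    features: np.ndarray = field(repr=False)
    feature_names: list[str] = field(default_factory=list)
    feature_kind: str = "pixel_composition"

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=np.float64)
        if len(self.cells) != self.features.shape[0]:
            raise ValueError("cells and features row counts differ")
        if self.features.shape[1] != len(self.feature_names):
            raise ValueError("feature_names length must match feature columns")
        if self.feature_kind not in ("pixel_composition", "integrated_expression"):
            raise ValueError(f"unknown feature_kind {self.feature_kind!r}")
        if (self.cells["cell_size"] < 1).any():
            raise ValueError("cell_size must be >= 1")
        if self.cells.duplicated(["fov", "cell_id"]).any():
            raise ValueError("cell ids must be unique per FOV")

    def to_frame(self) -> pd.DataFrame:
        df = self.cells.reset_index(drop=True).copy()
        for i, name in enumerate(self.feature_names):
            df[name] = self.features[:, i]
        return df


def _as_array(obj) -> np.ndarray:
    return obj.data if isinstance(obj, LabelMap) else np.asarray(obj)


def cell_pixel_composition(
    assignment_maps: dict[str, LabelMap | np.ndarray],
    masks: dict[str, LabelMap | np.ndarray],
    n_clusters: int | None = None,
    prefix: str = "cluster_",
) -> CellFeatureTable:
    """Per-cell pixel-cluster counts divided by total cell size.

    ``assignment_maps`` hold the per-pixel (meta)cluster id images (0 =
    unassigned); unassigned in-cell pixels contribute to the denominator
    only. Cell size is the full geometric mask area.
    """
    if set(assignment_maps) != set(masks):
        raise ValueError(
            f"FOV mismatch: assignments {sorted(assignment_maps)} vs masks {sorted(masks)}"
        )
    if n_clusters is None:
        n_clusters = max(int(_as_array(m).max(initial=0)) for m in assignment_maps.values())
    rows = []
    feats = []
    for fov in sorted(assignment_maps):
        assign = _as_array(assignment_maps[fov]).astype(np.int64)
        mask = _as_array(masks[fov]).astype(np.int64)
        if assign.shape != mask.shape:
            raise ValueError(f"FOV {fov!r}: assignment/mask shape mismatch")
        max_cell = int(mask.max(initial=0))
        if max_cell == 0:
            continue
        counts = np.zeros((max_cell + 1, n_clusters + 1), dtype=np.int64)
        np.add.at(counts, (mask.ravel(), assign.ravel()), 1)
        sizes = counts.sum(axis=1)
        present = np.nonzero(sizes[1:])[0] + 1
        rows.append(
            pd.DataFrame(
                {"fov": fov, "cell_id": present, "cell_size": sizes[present]}
            )
        )
        feats.append(counts[present, 1:] / sizes[present, None])
    if not rows:
        raise ValueError("no cells found in any mask")
    return CellFeatureTable(
        cells=pd.concat(rows, ignore_index=True),
        features=np.vstack(feats),
        feature_names=[f"{prefix}{k}" for k in range(1, n_clusters + 1)],
        feature_kind="pixel_composition",
    )


def _percentile_normalize(
    table: CellFeatureTable, quantile: float
) -> CellFeatureTable:
    divisors = np.quantile(table.features, quantile, axis=0)
    keep = divisors > 0
    if not keep.all():
        dropped = [n for n, k in zip(table.feature_names, keep) if not k]
        warnings.warn(
            f"dropping features with zero {quantile:g}-quantile: {dropped}",
            stacklevel=3,
        )
    features = table.features[:, keep] / divisors[keep][None, :]
    return CellFeatureTable(
        cells=table.cells,
        features=features,
        feature_names=[n for n, k in zip(table.feature_names, keep) if k],
        feature_kind=table.feature_kind,
    )


def normalize_cell_features(
    table: CellFeatureTable, quantile: float = 0.999
) -> CellFeatureTable:
    """Divide each composition feature by its percentile over cells."""
    if table.feature_kind != "pixel_composition":
        raise ValueError("normalize_cell_features expects pixel_composition features")
    if len(table.cells) == 0:
        raise ValueError("empty feature table")
    return _percentile_normalize(table, quantile)


def integrated_expression_features(
    images: dict[str, MultiChannelImage],
    masks: dict[str, LabelMap | np.ndarray],
    preprocess: bool = False,
    sigma: float = 2.0,
    normalize: bool = True,
    quantile: float = 0.999,
) -> CellFeatureTable:
    """Classical baseline: per-cell summed marker expression / cell size.

    With ``preprocess=True`` the images first pass through the smoothing and
    per-pixel sum-to-1 normalization cascade. With ``normalize=True`` the
    resulting columns get the percentile normalization.
    """
    if set(images) != set(masks):
        raise ValueError("FOV mismatch between images and masks")
    rows = []
    feats = []
    marker_names = None
    for fov in sorted(images):
        image = images[fov]
        if marker_names is None:
            marker_names = list(image.marker_names)
        elif list(image.marker_names) != marker_names:
            raise ValueError("marker sets differ between FOVs")
        data = image.data
        if preprocess:
            data = smooth_channels(image, sigma).data
            sums = data.sum(axis=0)
            data = np.divide(data, sums[None], out=np.zeros_like(data), where=sums > 0)
        mask = _as_array(masks[fov]).astype(np.int64)
        if mask.shape != image.shape:
            raise ValueError(f"FOV {fov!r}: image/mask shape mismatch")
        max_cell = int(mask.max(initial=0))
        if max_cell == 0:
            continue
        sizes = np.bincount(mask.ravel(), minlength=max_cell + 1)
        sums = np.zeros((max_cell + 1, data.shape[0]))
        np.add.at(sums, mask.ravel(), data.reshape(data.shape[0], -1).T)
        present = np.nonzero(sizes[1:])[0] + 1
        rows.append(
            pd.DataFrame({"fov": fov, "cell_id": present, "cell_size": sizes[present]})
        )
        feats.append(sums[present] / sizes[present, None])
    if not rows:
        raise ValueError("no cells found in any mask")
    table = CellFeatureTable(
        cells=pd.concat(rows, ignore_index=True),
        features=np.vstack(feats),
        feature_names=marker_names,
        feature_kind="integrated_expression",
    )
    return _percentile_normalize(table, quantile) if normalize else table


@dataclass
class CellClusterResult:
    table: CellFeatureTable
    som_model: SOMModel
    som_assignments: np.ndarray
    remap: RemapTable
    meta_assignments: np.ndarray
    annotations: np.ndarray
    maps: dict[str, LabelMap]

    def labels_frame(self) -> pd.DataFrame:
        df = self.table.cells[["fov", "cell_id"]].copy()
        df["som_cluster"] = self.som_assignments
        df["metacluster"] = self.meta_assignments
        df["annotation"] = self.annotations
        return df


def cluster_cells(
    table: CellFeatureTable,
    som: SOMConfig,
    consensus: ConsensusConfig,
    remap: RemapTable | None = None,
    masks: dict[str, LabelMap | np.ndarray] | None = None,
    seed: int = 0,
) -> CellClusterResult:
    """SOM -> profiles -> capped z-scores -> consensus -> remap, over cells.

    Mirrors the pixel stage exactly, with cells as observations. When masks
    are given, per-FOV cell phenotype maps are rendered by painting each
    cell's region with its metacluster id.
    """
    state = np.random.SeedSequence(seed).generate_state(2)
    som = dataclasses.replace(som, seed=int(state[0]))
    consensus = dataclasses.replace(consensus, seed=int(state[1]))
    if len(table.cells) < som.n_nodes:
        raise ValueError(
            f"{len(table.cells)} cells < {som.n_nodes} SOM nodes; "
            "configure a smaller grid"
        )
    model = train_som(table.features, som, list(table.feature_names))
    som_assignments = assign_som(model, table.features)
    profile = compute_profiles(
        table.features, som_assignments, n_clusters=som.n_nodes,
        feature_names=list(table.feature_names),
    )
    if int(profile.nonempty.sum()) == 1:
        # degenerate: every cell in one SOM node -> single phenotype
        mapping = {int(profile.nonempty_ids[0]): 1}
    else:
        capped = zscore_cap(profile)
        mapping = consensus_metacluster(
            capped, consensus, cluster_ids=profile.nonempty_ids
        )
    if remap is None:
        remap = mapping_to_remap(mapping)
    meta_assignments, annotations = apply_remap(som_assignments, remap)

    maps: dict[str, LabelMap] = {}
    if masks is not None:
        legend = remap.meta_annotations
        cells = table.cells
        for fov in sorted(masks):
            mask = _as_array(masks[fov]).astype(np.int64)
            in_fov = (cells["fov"] == fov).to_numpy()
            lut = np.zeros(int(mask.max(initial=0)) + 1, dtype=np.int64)
            lut[cells.loc[in_fov, "cell_id"].to_numpy()] = meta_assignments[in_fov]
            maps[fov] = LabelMap(fov, lut[mask], legend)
    return CellClusterResult(
        table=table,
        som_model=model,
        som_assignments=som_assignments,
        remap=remap,
        meta_assignments=meta_assignments,
        annotations=annotations,
        maps=maps,
    )
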