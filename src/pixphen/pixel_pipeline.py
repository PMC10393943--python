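"""End-to-end pixel clustering: preprocessing -> SOM -> metaclustering -> maps.

All FOVs in a dataset are processed in aggregate: smoothing and extraction
run per FOV, the retained pixels are pooled, normalized, overclustered by the
SOM (optionally trained on a subsample), collapsed to metaclusters by
consensus, optionally remapped/annotated from a hand-edited table, and
rendered back into per-FOV pixel phenotype maps.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import image_io
from .image_io import LabelMap, MultiChannelImage, RemapTable
from .metaclustering import (
    ClusterProfile,
    ConsensusConfig,
    apply_remap,
    compute_profiles,
    consensus_metacluster,
    mapping_to_remap,
    zscore_cap,
)
from .preprocessing import (
    NormalizationParams,
    PixelTable,
    apply_percentile_norm,
    concat_tables,
    extract_pixels,
    fit_percentile_norm,
    normalize_pixels,
    smooth_channels,
    subsample_pixels,
)
from .som import SOMConfig, SOMModel, assign_som, train_som

__all__ = [
    "PixelRunConfig",
    "PixelRunResult",
    "run_pixel_clustering",
    "render_phenotype_map",
    "cluster_composition",
]


@dataclass
class PixelRunConfig:
    """Everything one pixel-clustering run needs; the unit of replication.

    ``seed`` is the single entry point for randomness: per-stage seeds for
    subsampling, SOM training, and consensus are derived from it, so two runs
    with equal configs are bit-identical and replicates differ only by seed.
    """

    dataset_dir: str | Path | None
    markers: list[str]
    fovs: list[str] | None = None
    sigma: float = 2.0
    quantile: float = 0.999
    subsample_fraction: float = 1.0
    pixel_norm: bool = True
    percentile_norm: bool = True
    region_mask_name: str | None = None
    positivity_filter: tuple[str, float] | None = None
    som: SOMConfig = field(default_factory=SOMConfig)
    consensus: ConsensusConfig = field(default_factory=ConsensusConfig)
    remap_path: str | Path | None = None
    output_dir: str | Path | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.markers:
            raise ValueError("marker set must be nonempty")

    def stage_seeds(self) -> dict[str, int]:
        state = np.random.SeedSequence(self.seed).generate_state(3)
        return {
            "subsample": int(state[0]),
            "som": int(state[1]),
            "consensus": int(state[2]),
        }


@dataclass
class PixelRunResult:
    config: PixelRunConfig
    table: PixelTable
    norm_params: NormalizationParams | None
    som_model: SOMModel
    som_assignments: np.ndarray
    profile: ClusterProfile
    capped_zscores: np.ndarray
    remap: RemapTable
    meta_assignments: np.ndarray
    annotations: np.ndarray
    consensus_matrix: np.ndarray
    maps: dict[str, LabelMap]

    def assignments_frame(self) -> pd.DataFrame:
        df = self.table.coords.copy()
        df["som_cluster"] = self.som_assignments
        df["metacluster"] = self.meta_assignments
        df["annotation"] = self.annotations
        return df


def _load_images(config: PixelRunConfig) -> dict[str, MultiChannelImage]:
    if config.dataset_dir is None:
        raise ValueError("config.dataset_dir is not set and no images were supplied")
    root = Path(config.dataset_dir)
    fovs = config.fovs
    if fovs is None:
        # only subdirectories that actually hold the panel's images are FOVs
        first = config.markers[0]
        fovs = [
            f
            for f in image_io.list_fovs(root)
            if any((root / f / f"{first}{ext}").exists() for ext in (".tiff", ".tif"))
        ]
    if not fovs:
        raise ValueError(f"no FOV directories found under {root}")
    return {fov: image_io.load_fov(root / fov, config.markers, fov) for fov in fovs}


def run_pixel_clustering(
    config: PixelRunConfig,
    images: dict[str, MultiChannelImage] | None = None,
) -> PixelRunResult:
    """Execute the full pixel-clustering cascade and return all artifacts.

    ``images`` may be supplied to bypass disk loading (tests, simulations);
    otherwise FOVs are read from ``config.dataset_dir``.
    """
    seeds = config.stage_seeds()
    if images is None:
        images = _load_images(config)
    else:
        images = {f: img.select_markers(config.markers) for f, img in images.items()}

    tables = []
    shapes: dict[str, tuple[int, int]] = {}
    for fov_id, image in images.items():
        shapes[fov_id] = image.shape
        smoothed = smooth_channels(image, config.sigma)
        region_mask = None
        if config.region_mask_name is not None:
            mask_path = Path(config.dataset_dir) / fov_id / config.region_mask_name
            region_mask = image_io.load_label_map(mask_path).data > 0
        tables.append(
            extract_pixels(
                smoothed,
                region_mask=region_mask,
                positivity_filter=config.positivity_filter,
                stage="smoothed",
            )
        )
    table = concat_tables(tables)
    if table.n_pixels == 0:
        raise ValueError("no pixels retained after exclusion filters")

    if config.pixel_norm:
        table = normalize_pixels(table)
    norm_params = None
    if config.percentile_norm:
        norm_params = fit_percentile_norm(table, config.quantile)
        table = apply_percentile_norm(table, norm_params)

    train_table = subsample_pixels(table, config.subsample_fraction, seeds["subsample"])
    som_config = dataclasses.replace(config.som, seed=seeds["som"])
    som_model = train_som(train_table.values, som_config, list(config.markers))
    som_assignments = assign_som(som_model, table.values)

    profile = compute_profiles(table, som_assignments, n_clusters=som_config.n_nodes)
    consensus_config = dataclasses.replace(config.consensus, seed=seeds["consensus"])
    if int(profile.nonempty.sum()) == 1:
        # degenerate: every pixel in one SOM node -> single phenotype
        capped = np.zeros((1, len(config.markers)))
        mapping, consensus_matrix = {int(profile.nonempty_ids[0]): 1}, np.ones((1, 1))
    else:
        capped = zscore_cap(profile)
        mapping, consensus_matrix = consensus_metacluster(
            capped, consensus_config, cluster_ids=profile.nonempty_ids, return_matrix=True
        )
    if config.remap_path is not None:
        remap = image_io.read_remap(config.remap_path)
    else:
        remap = mapping_to_remap(mapping)
    meta_assignments, annotations = apply_remap(som_assignments, remap)

    legend = remap.meta_annotations
    maps = {}
    coords = table.coords
    for fov_id, shape in shapes.items():
        in_fov = (coords["fov"] == fov_id).to_numpy()
        maps[fov_id] = render_phenotype_map(
            fov_id, coords[in_fov], meta_assignments[in_fov], shape, legend
        )

    result = PixelRunResult(
        config=config,
        table=table,
        norm_params=norm_params,
        som_model=som_model,
        som_assignments=som_assignments,
        profile=profile,
        capped_zscores=capped,
        remap=remap,
        meta_assignments=meta_assignments,
        annotations=annotations,
        consensus_matrix=consensus_matrix,
        maps=maps,
    )
    if config.output_dir is not None:
        _write_artifacts(result, Path(config.output_dir), seeds)
    return result


def _write_artifacts(result: PixelRunResult, out: Path, seeds: dict[str, int]) -> None:
    for sub in ("models", "assignments", "profiles", "maps", "logs"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    result.som_model.to_json(out / "models" / "som.json")
    if result.norm_params is not None:
        result.norm_params.to_json(out / "models" / "norm_params.json")
    result.assignments_frame().to_csv(out / "assignments" / "pixels.csv", index=False)
    result.profile.to_frame().to_csv(out / "profiles" / "cluster_profiles.csv", index=False)
    capped_df = pd.DataFrame(
        result.capped_zscores,
        index=result.profile.nonempty_ids,
        columns=result.profile.feature_names or None,
    )
    capped_df.to_csv(out / "profiles" / "capped_zscores.csv")
    pd.DataFrame(
        result.consensus_matrix,
        index=result.profile.nonempty_ids,
        columns=result.profile.nonempty_ids,
    ).to_csv(out / "profiles" / "consensus_matrix.csv")
    image_io.write_remap(result.remap, out / "profiles" / "remap.csv")
    for fov_id, label_map in result.maps.items():
        image_io.save_label_map(
            label_map, out / "maps" / f"{fov_id}_phenotype_map.tiff", png=True
        )
    cfg = dataclasses.asdict(result.config)
    cfg = {k: (str(v) if isinstance(v, Path) else v) for k, v in cfg.items()}
    (out / "logs" / "run_log.json").write_text(
        json.dumps({"config": cfg, "stage_seeds": seeds}, indent=1, default=str)
    )


def render_phenotype_map(
    fov_id: str,
    coords: pd.DataFrame,
    ids: np.ndarray,
    shape: tuple[int, int],
    legend: dict[int, str] | None = None,
) -> LabelMap:
    """Paint metacluster ids at (row, col) coords; 0 everywhere else."""
    ids = np.asarray(ids, dtype=np.int64)
    rows = coords["row"].to_numpy(dtype=np.int64)
    cols = coords["col"].to_numpy(dtype=np.int64)
    if len(rows) != len(ids):
        raise ValueError("coords and ids lengths differ")
    h, w = shape
    if len(rows) and (
        rows.min() < 0 or rows.max() >= h or cols.min() < 0 or cols.max() >= w
    ):
        raise ValueError("coordinate out of image bounds")
    data = np.zeros(shape, dtype=np.int64)
    data[rows, cols] = ids
    return LabelMap(fov_id, data, legend)


def cluster_composition(
    label_map: LabelMap,
    region_mask: np.ndarray | None = None,
    denominator: str = "all",
) -> pd.Series:
    """Fraction of region pixels in each metacluster.

    ``denominator="all"`` divides by every pixel in the region (fractions sum
    to <= 1, with equality iff nothing was excluded); ``"assigned"`` divides
    by assigned (nonzero) pixels only (fractions sum to 1).
    """
    if denominator not in ("all", "assigned"):
        raise ValueError("denominator must be 'all' or 'assigned'")
    data = label_map.data
    if region_mask is not None:
        region_mask = np.asarray(region_mask).astype(bool)
        if region_mask.shape != data.shape:
            raise ValueError("region mask shape mismatch")
        data = data[region_mask]
    data = data.ravel()
    if data.size == 0:
        raise ValueError("empty region")
    counts = np.bincount(data)
    assigned = data[data > 0]
    if denominator == "assigned" and assigned.size == 0:
        raise ValueError("no assigned pixels in region")
    denom = data.size if denominator == "all" else assigned.size
    ids = np.arange(1, len(counts))
    return pd.Series(counts[1:] / denom, index=ids, name="fraction")
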