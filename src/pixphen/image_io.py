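"""Reading and writing of on-disk artifacts.

All raster data are single-channel TIFFs: one grayscale intensity image per
marker, and unsigned-integer label images for segmentation masks, phenotype
maps, and ground truth. Tables are CSV, parameters and legends JSON.

Coordinate convention: 0-based (row, col), pixel (0, 0) at top-left.
Dataset layout: ``dataset_root/<fov_id>/<marker>.tiff`` with the optional
segmentation mask at ``dataset_root/<fov_id>/segmentation.tiff``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "MultiChannelImage",
    "LabelMap",
    "RemapTable",
    "load_fov",
    "save_fov",
    "save_label_map",
    "load_label_map",
    "read_remap",
    "write_remap",
    "label_palette",
    "render_label_png",
    "list_fovs",
]

_TIFF_EXTS = (".tiff", ".tif")


@dataclass
class MultiChannelImage:
    """Per-FOV stack of marker channels with aligned geometry.

    ``data`` has shape ``(n_markers, height, width)`` with nonnegative real
    intensities in arbitrary units.
    """

    fov_id: str
    marker_names: list[str]
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("data must be 3-D (n_markers, height, width)")
        if len(self.marker_names) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.marker_names)} marker names for "
                f"{self.data.shape[0]} channels"
            )
        if len(set(self.marker_names)) != len(self.marker_names):
            raise ValueError("marker names must be unique")
        if np.any(self.data < 0):
            raise ValueError("intensities must be nonnegative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[1], self.data.shape[2]

    def select_markers(self, markers: list[str]) -> "MultiChannelImage":
        """Return a new image with channels reordered/subset to ``markers``."""
        missing = [m for m in markers if m not in self.marker_names]
        if missing:
            raise KeyError(f"markers not present in image: {missing}")
        idx = [self.marker_names.index(m) for m in markers]
        return MultiChannelImage(self.fov_id, list(markers), self.data[idx])


@dataclass
class LabelMap:
    """2-D nonnegative integer image; 0 is background/excluded."""

    fov_id: str
    data: np.ndarray
    legend: dict[int, str] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("label map must be 2-D")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("label map must be integer-valued")
        if self.data.min(initial=0) < 0:
            raise ValueError("label ids must be >= 0")


@dataclass
class RemapTable:
    """SOM cluster -> metacluster -> annotation mapping.

    The human-in-the-loop artifact: produced automatically by consensus
    metaclustering and optionally hand-edited before being re-applied.
    """

    frame: pd.DataFrame = field(repr=False)

    COLUMNS = ("som_cluster", "metacluster", "annotation")

    def __post_init__(self) -> None:
        df = self.frame
        missing = set(self.COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"remap table missing columns: {sorted(missing)}")
        for col in ("som_cluster", "metacluster"):
            vals = df[col]
            as_num = pd.to_numeric(vals, errors="coerce")
            if as_num.isna().any() or not np.allclose(as_num, as_num.round()):
                raise ValueError(f"column {col!r} must contain integer ids")
            df[col] = as_num.astype(np.int64)
        if df["som_cluster"].duplicated().any():
            dups = sorted(df.loc[df["som_cluster"].duplicated(), "som_cluster"])
            raise ValueError(f"duplicate som_cluster ids: {dups}")
        if (df["som_cluster"] < 1).any() or (df["metacluster"] < 1).any():
            raise ValueError("cluster ids must be >= 1")
        ann = df["annotation"].astype(str)
        if (ann.str.len() == 0).any():
            raise ValueError("annotations must be non-empty")
        df["annotation"] = ann
        self.frame = df.reset_index(drop=True)

    @property
    def som_to_meta(self) -> dict[int, int]:
        return dict(zip(self.frame["som_cluster"], self.frame["metacluster"]))

    @property
    def meta_annotations(self) -> dict[int, str]:
        return dict(zip(self.frame["metacluster"], self.frame["annotation"]))

    def validate_covers(self, som_ids) -> None:
        """Raise if any id in ``som_ids`` is absent from the table."""
        have = set(self.frame["som_cluster"])
        missing = sorted(set(int(i) for i in np.unique(som_ids)) - have)
        if missing:
            raise ValueError(f"remap table missing SOM clusters: {missing}")


def _marker_path(fov_dir: Path, marker: str) -> Path:
    for ext in _TIFF_EXTS:
        p = fov_dir / f"{marker}{ext}"
        if p.exists():
            return p
    raise FileNotFoundError(
        f"no image for marker {marker!r} in {fov_dir} "
        f"(looked for {marker}.tiff / {marker}.tif)"
    )


def load_fov(fov_dir: str | Path, markers: list[str], fov_id: str | None = None) -> MultiChannelImage:
    """Load one FOV, stacking channels in the requested marker order.

    Channel order is wholly determined by ``markers``, never by directory
    listing order.
    """
    fov_dir = Path(fov_dir)
    if not markers:
        raise ValueError("marker list must be nonempty")
    channels = []
    shape = None
    for marker in markers:
        arr = tifffile.imread(_marker_path(fov_dir, marker))
        if arr.ndim != 2:
            raise ValueError(f"marker {marker!r} image is not single-channel 2-D")
        if shape is None:
            shape = arr.shape
        elif arr.shape != shape:
            raise ValueError(
                f"dimension mismatch for marker {marker!r}: "
                f"{arr.shape} vs {shape}"
            )
        channels.append(np.asarray(arr, dtype=np.float64))
    return MultiChannelImage(fov_id or fov_dir.name, list(markers), np.stack(channels))


def save_fov(image: MultiChannelImage, fov_dir: str | Path) -> list[Path]:
    """Write one single-channel TIFF per marker; returns written paths."""
    fov_dir = Path(fov_dir)
    fov_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, marker in enumerate(image.marker_names):
        p = fov_dir / f"{marker}.tiff"
        tifffile.imwrite(p, image.data[i].astype(np.float32))
        paths.append(p)
    return paths


def save_label_map(label_map: LabelMap, path: str | Path, png: bool = False) -> Path:
    """Write a label map as 32-bit unsigned TIFF (lossless round trip).

    With ``png=True`` a color-rendered companion ``<path>.png`` is written
    using the deterministic id palette.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = label_map.data
    if data.max(initial=0) > np.iinfo(np.uint32).max:
        raise ValueError("label ids exceed uint32 capacity")
    tifffile.imwrite(path, data.astype(np.uint32))
    if label_map.legend is not None:
        legend_path = path.with_suffix(path.suffix + ".legend.json")
        legend_path.write_text(
            json.dumps({str(k): v for k, v in label_map.legend.items()}, indent=1)
        )
    if png:
        render_label_png(label_map, path.with_suffix(".png"))
    return path


def load_label_map(path: str | Path, fov_id: str | None = None) -> LabelMap:
    path = Path(path)
    data = tifffile.imread(path)
    legend = None
    legend_path = path.with_suffix(path.suffix + ".legend.json")
    if legend_path.exists():
        legend = {int(k): v for k, v in json.loads(legend_path.read_text()).items()}
    return LabelMap(fov_id or path.stem, np.asarray(data).astype(np.int64), legend)


def read_remap(path: str | Path) -> RemapTable:
    """Read and validate a remap CSV (header som_cluster,metacluster,annotation)."""
    df = pd.read_csv(path)
    return RemapTable(df)


def write_remap(table: RemapTable, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.frame.to_csv(path, index=False)
    return path


def label_palette(max_id: int) -> np.ndarray:
    """Deterministic id -> RGB palette, shape (max_id + 1, 3) uint8; id 0 black."""
    import matplotlib

    base = (np.asarray(matplotlib.colormaps["tab20"].colors) * 255).astype(np.uint8)
    pal = np.zeros((max_id + 1, 3), dtype=np.uint8)
    for i in range(1, max_id + 1):
        pal[i] = base[(i - 1) % len(base)]
    return pal


def render_label_png(label_map: LabelMap, path: str | Path) -> Path:
    from PIL import Image

    pal = label_palette(int(label_map.data.max(initial=0)))
    rgb = pal[label_map.data]
    Image.fromarray(rgb).save(Path(path))
    return Path(path)


def list_fovs(dataset_root: str | Path) -> list[str]:
    """Sorted FOV ids = subdirectory names of the dataset root."""
    root = Path(dataset_root)
    return sorted(p.name for p in root.iterdir() if p.is_dir())
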