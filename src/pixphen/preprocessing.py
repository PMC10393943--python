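"""Normalization cascade for pixel-level clustering.

The fixed pipeline order is: Gaussian smoothing -> pixel extraction with
exclusion of all-zero pixels (and optional region mask / marker-positivity
filter) -> per-pixel sum-to-1 normalization -> per-marker division by the
pooled 99.9th-percentile value. Either normalization step can be switched
off for ablation experiments. Percentiles are fitted once over the full
retained pixel set (all FOVs pooled) before any subsampling; the subsample
is used only for SOM training.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .image_io import MultiChannelImage

__all__ = [
    "PixelTable",
    "NormalizationParams",
    "smooth_channels",
    "extract_pixels",
    "concat_tables",
    "normalize_pixels",
    "fit_percentile_norm",
    "apply_percentile_norm",
    "subsample_pixels",
]

STAGES = ("raw", "smoothed", "pixel_normalized", "fully_normalized")


@dataclass
class PixelTable:
    """Flat table of retained pixels: coords (fov, row, col) x marker values."""

    coords: pd.DataFrame = field(repr=False)
    values: np.ndarray = field(repr=False)
    marker_names: list[str] = field(default_factory=list)
    stage: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (n_pixels, n_markers)")
        if len(self.coords) != self.values.shape[0]:
            raise ValueError("coords and values row counts differ")
        if self.values.shape[1] != len(self.marker_names):
            raise ValueError("marker_names length must match value columns")
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")

    @property
    def n_pixels(self) -> int:
        return self.values.shape[0]

    def __len__(self) -> int:
        return self.n_pixels


@dataclass
class NormalizationParams:
    """Per-marker percentile divisors fitted on pooled pixel-normalized data."""

    marker_names: list[str]
    per_marker_divisor: np.ndarray
    quantile: float = 0.999

    def __post_init__(self) -> None:
        self.per_marker_divisor = np.asarray(self.per_marker_divisor, dtype=np.float64)
        if len(self.per_marker_divisor) != len(self.marker_names):
            raise ValueError("one divisor per marker required")
        if np.any(self.per_marker_divisor <= 0):
            raise ValueError("all divisors must be > 0")

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(
            json.dumps(
                {
                    "quantile": self.quantile,
                    "per_marker_divisor": dict(
                        zip(self.marker_names, self.per_marker_divisor.tolist())
                    ),
                },
                indent=1,
            )
        )
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "NormalizationParams":
        payload = json.loads(Path(path).read_text())
        divisors = payload["per_marker_divisor"]
        return cls(
            marker_names=list(divisors),
            per_marker_divisor=np.array(list(divisors.values())),
            quantile=payload["quantile"],
        )


def smooth_channels(image: MultiChannelImage, sigma: float) -> MultiChannelImage:
    """Gaussian-blur each channel independently (reflect boundary, 4-sigma kernel)."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return image
    smoothed = np.stack(
        [
            ndimage.gaussian_filter(ch, sigma=sigma, mode="reflect", truncate=4.0)
            for ch in image.data
        ]
    )
    return MultiChannelImage(image.fov_id, list(image.marker_names), np.clip(smoothed, 0, None))


def extract_pixels(
    image: MultiChannelImage,
    region_mask: np.ndarray | None = None,
    positivity_filter: tuple[str, float] | None = None,
    stage: str = "raw",
) -> PixelTable:
    """Flatten an image into a pixel table, dropping excluded pixels.

    A pixel is retained iff it lies inside ``region_mask`` (when given),
    strictly exceeds the positivity threshold on the filter marker (when
    given), and is not zero across all markers in the image.
    """
    h, w = image.shape
    keep = np.any(image.data > 0, axis=0)
    if region_mask is not None:
        region_mask = np.asarray(region_mask)
        if region_mask.shape != (h, w):
            raise ValueError(
                f"region mask shape {region_mask.shape} != image shape {(h, w)}"
            )
        keep &= region_mask.astype(bool)
    if positivity_filter is not None:
        marker, threshold = positivity_filter
        if marker not in image.marker_names:
            raise KeyError(f"positivity marker {marker!r} not in image")
        keep &= image.data[image.marker_names.index(marker)] > threshold
    rows, cols = np.nonzero(keep)
    coords = pd.DataFrame(
        {"fov": image.fov_id, "row": rows.astype(np.int64), "col": cols.astype(np.int64)}
    )
    values = image.data[:, rows, cols].T.copy()
    return PixelTable(coords, values, list(image.marker_names), stage=stage)


def concat_tables(tables: list[PixelTable]) -> PixelTable:
    """Pool pixel tables from multiple FOVs (same markers, same stage)."""
    if not tables:
        raise ValueError("need at least one table")
    first = tables[0]
    for t in tables[1:]:
        if t.marker_names != first.marker_names:
            raise ValueError("marker sets differ between tables")
        if t.stage != first.stage:
            raise ValueError("stages differ between tables")
    coords = pd.concat([t.coords for t in tables], ignore_index=True)
    values = np.vstack([t.values for t in tables])
    return PixelTable(coords, values, list(first.marker_names), stage=first.stage)


def normalize_pixels(table: PixelTable) -> PixelTable:
    """Divide each pixel row by its total so every row sums to 1."""
    if table.stage not in ("raw", "smoothed"):
        raise ValueError(f"cannot pixel-normalize a table at stage {table.stage!r}")
    sums = table.values.sum(axis=1)
    if np.any(sums == 0):
        n = int((sums == 0).sum())
        raise ValueError(
            f"{n} all-zero pixel rows present; they must be excluded before "
            "pixel normalization"
        )
    values = table.values / sums[:, None]
    return PixelTable(table.coords, values, list(table.marker_names), stage="pixel_normalized")


def fit_percentile_norm(table: PixelTable, quantile: float = 0.999) -> NormalizationParams:
    """Fit per-marker divisors: the ``quantile`` of each marker over all pixels.

    Uses the linear-interpolation quantile definition. Raises if any marker's
    quantile is zero (such a marker should be excluded from the panel).
    """
    if not 0 < quantile <= 1:
        raise ValueError("quantile must be in (0, 1]")
    divisors = np.quantile(table.values, quantile, axis=0)
    zero = [m for m, d in zip(table.marker_names, divisors) if d <= 0]
    if zero:
        raise ValueError(
            f"markers {zero} have a {quantile:g}-quantile of 0; exclude them "
            "from the clustering panel"
        )
    return NormalizationParams(list(table.marker_names), divisors, quantile)


def apply_percentile_norm(table: PixelTable, params: NormalizationParams) -> PixelTable:
    """Divide each marker column by its fitted divisor (no clipping)."""
    if list(params.marker_names) != list(table.marker_names):
        raise ValueError("params fitted on a different marker set")
    values = table.values / params.per_marker_divisor[None, :]
    return PixelTable(table.coords, values, list(table.marker_names), stage="fully_normalized")


def subsample_pixels(table: PixelTable, fraction: float, seed: int) -> PixelTable:
    """Uniform sample without replacement of floor(fraction * n) rows."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if table.n_pixels == 0:
        raise ValueError("cannot subsample an empty table")
    if fraction == 1:
        return table
    n_keep = int(np.floor(fraction * table.n_pixels))
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(table.n_pixels, size=n_keep, replace=False))
    return PixelTable(
        table.coords.iloc[idx].reset_index(drop=True),
        table.values[idx],
        list(table.marker_names),
        stage=table.stage,
    )
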