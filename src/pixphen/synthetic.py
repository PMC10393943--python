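"""Synthetic multiplexed-image datasets with known ground truth.

Cells are non-overlapping (optionally rotated) ellipses, each belonging to a
latent phenotype with a characteristic marker signature. Pixel intensities
are Poisson counts around gain x signature, with optional per-pixel dropout,
additive boundary spillover into adjacent cells, per-FOV gain factors (batch
effect), and zero background — so every pipeline stage, including zero-pixel
exclusion and the normalization cascade, is exercised on data where the true
phenotype of every pixel and cell is known.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage
from skimage.draw import ellipse as draw_ellipse

from .image_io import LabelMap, MultiChannelImage, save_fov

__all__ = [
    "SignatureMatrix",
    "GroundTruth",
    "NoiseConfig",
    "GenerationError",
    "make_signatures",
    "simulate_fov",
    "simulate_dataset",
]


class GenerationError(RuntimeError):
    """Raised when cell placement fails after bounded retries."""


@dataclass
class SignatureMatrix:
    """Mean marker intensities per latent phenotype (n_phenotypes x n_markers)."""

    phenotype_names: list[str]
    signatures: np.ndarray = field(repr=False)
    marker_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.signatures = np.asarray(self.signatures, dtype=np.float64)
        if self.signatures.ndim != 2:
            raise ValueError("signatures must be 2-D")
        if self.signatures.shape[0] != len(self.phenotype_names):
            raise ValueError("one row per phenotype required")
        if self.signatures.shape[1] != len(self.marker_names):
            raise ValueError("one column per marker required")
        if np.any(self.signatures < 0):
            raise ValueError("signatures must be nonnegative")
        if np.any(self.signatures.max(axis=1) <= 0):
            raise ValueError("every phenotype needs >= 1 strictly positive marker")

    @property
    def n_phenotypes(self) -> int:
        return self.signatures.shape[0]

    def covered_markers(self) -> list[str]:
        """Markers expressed by at least one phenotype."""
        pos = self.signatures.max(axis=0) > 0
        return [m for m, p in zip(self.marker_names, pos) if p]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.signatures, index=self.phenotype_names, columns=self.marker_names
        )


@dataclass
class GroundTruth:
    """Per-FOV latent labels: pixel phenotype image and per-cell phenotypes.

    ``pixel_labels`` uses 0 for background and k >= 1 for phenotype k;
    ``cell_labels`` has columns (fov, cell_id, phenotype) with 1-based
    phenotype indices matching the signature matrix rows.
    """

    pixel_labels: np.ndarray = field(repr=False)
    cell_labels: pd.DataFrame = field(repr=False)
    signatures: SignatureMatrix = None


@dataclass
class NoiseConfig:
    poisson_scale: float = 1.0  # 0 disables counting noise (exact means)
    dropout_prob: float = 0.0
    gain: float = 1.0

    def __post_init__(self) -> None:
        if not 0 <= self.dropout_prob < 1:
            raise ValueError("dropout_prob must be in [0, 1)")
        if self.poisson_scale < 0 or self.gain <= 0:
            raise ValueError("poisson_scale must be >= 0 and gain > 0")


def make_signatures(
    n_phenotypes: int,
    n_markers: int,
    markers_per_phenotype: int,
    seed: int,
    primary_range: tuple[float, float] = (8.0, 10.0),
    secondary_range: tuple[float, float] = (3.0, 6.0),
) -> SignatureMatrix:
    """Assign each phenotype a distinct random marker subset with high means.

    The first marker of each subset is the phenotype's dominant marker (drawn
    from ``primary_range``); the rest draw from ``secondary_range``.
    Off-support markers are exactly zero. Deterministic per seed.
    """
    if n_phenotypes < 1:
        raise ValueError("n_phenotypes must be >= 1")
    if not 1 <= markers_per_phenotype <= n_markers:
        raise ValueError("need 1 <= markers_per_phenotype <= n_markers")
    from math import comb

    if comb(n_markers, markers_per_phenotype) < n_phenotypes:
        raise ValueError("not enough distinct marker subsets for the phenotypes")
    rng = np.random.default_rng(seed)
    supports: list[frozenset[int]] = []
    sig = np.zeros((n_phenotypes, n_markers))
    for p in range(n_phenotypes):
        for _ in range(10_000):
            subset = rng.choice(n_markers, size=markers_per_phenotype, replace=False)
            if frozenset(subset) not in supports:
                break
        else:  # pragma: no cover - astronomically unlikely given the comb check
            raise GenerationError("could not draw a distinct marker subset")
        supports.append(frozenset(subset))
        sig[p, subset[0]] = rng.uniform(*primary_range)
        if markers_per_phenotype > 1:
            sig[p, subset[1:]] = rng.uniform(
                *secondary_range, size=markers_per_phenotype - 1
            )
    return SignatureMatrix(
        phenotype_names=[f"phenotype_{p + 1}" for p in range(n_phenotypes)],
        signatures=sig,
        marker_names=[f"marker_{m + 1}" for m in range(n_markers)],
    )


def _place_cells(
    rng: np.random.Generator,
    height: int,
    width: int,
    n_cells: int,
    radius_range: tuple[float, float],
    max_retries: int,
) -> np.ndarray:
    """Rejection-sample non-overlapping ellipses; returns a cell label image."""
    labels = np.zeros((height, width), dtype=np.int64)
    r_lo, r_hi = radius_range
    for cell_id in range(1, n_cells + 1):
        for _ in range(max_retries):
            a = rng.uniform(r_lo, r_hi)
            b = rng.uniform(r_lo, r_hi)
            cr = rng.uniform(r_hi, height - r_hi)
            cc = rng.uniform(r_hi, width - r_hi)
            angle = rng.uniform(0, np.pi)
            rr, cc_idx = draw_ellipse(cr, cc, a, b, shape=(height, width), rotation=angle)
            if rr.size < 3 or np.any(labels[rr, cc_idx] != 0):
                continue
            labels[rr, cc_idx] = cell_id
            break
        else:
            raise GenerationError(
                f"failed to place cell {cell_id}/{n_cells} after {max_retries} tries; "
                "reduce n_cells or enlarge the image"
            )
    return labels


def simulate_fov(
    signatures: SignatureMatrix,
    height: int,
    width: int,
    n_cells: int,
    noise: NoiseConfig | None = None,
    spillover_width: int = 0,
    spillover_fraction: float = 0.5,
    seed: int = 0,
    fov_id: str = "fov0",
    radius_range: tuple[float, float] = (4.0, 9.0),
    max_retries: int = 500,
) -> tuple[MultiChannelImage, LabelMap, GroundTruth]:
    """Simulate one FOV: image stack, segmentation mask, and ground truth.

    Noise-free limit (poisson_scale=0, dropout 0, spillover 0): every in-cell
    pixel equals gain x its phenotype's signature exactly; background is 0.
    Spillover adds ``spillover_fraction`` of a cell's mean boundary intensity
    to pixels of neighboring cells within ``spillover_width`` of its border.
    """
    noise = noise or NoiseConfig()
    rng = np.random.default_rng(seed)
    cell_labels_img = _place_cells(rng, height, width, n_cells, radius_range, max_retries)

    # round-robin phenotypes in shuffled cell order: all phenotypes represented
    phen_of_cell = np.arange(n_cells) % signatures.n_phenotypes + 1
    rng.shuffle(phen_of_cell)

    pixel_phen = np.zeros((height, width), dtype=np.int64)
    in_cell = cell_labels_img > 0
    pixel_phen[in_cell] = phen_of_cell[cell_labels_img[in_cell] - 1]

    n_markers = len(signatures.marker_names)
    expected = np.zeros((n_markers, height, width))
    sig = noise.gain * signatures.signatures  # (n_phen, n_markers)
    expected[:, in_cell] = sig[pixel_phen[in_cell] - 1].T

    if spillover_width > 0:
        struct = ndimage.generate_binary_structure(2, 2)
        for cell_id in range(1, n_cells + 1):
            footprint = cell_labels_img == cell_id
            halo = (
                ndimage.binary_dilation(footprint, structure=struct, iterations=spillover_width)
                & in_cell
                & ~footprint
            )
            if halo.any():
                donor = spillover_fraction * sig[phen_of_cell[cell_id - 1] - 1]
                expected[:, halo] += donor[:, None]

    if noise.poisson_scale > 0:
        data = rng.poisson(expected * noise.poisson_scale) / noise.poisson_scale
    else:
        data = expected
    if noise.dropout_prob > 0:
        drop = rng.random(data.shape) < noise.dropout_prob
        data = np.where(drop, 0.0, data)

    image = MultiChannelImage(fov_id, list(signatures.marker_names), data)
    mask = LabelMap(fov_id, cell_labels_img)
    truth = GroundTruth(
        pixel_labels=pixel_phen,
        cell_labels=pd.DataFrame(
            {
                "fov": fov_id,
                "cell_id": np.arange(1, n_cells + 1),
                "phenotype": phen_of_cell,
            }
        ),
        signatures=signatures,
    )
    return image, mask, truth


def simulate_dataset(
    signatures: SignatureMatrix,
    n_fovs: int,
    per_fov_gain: list[float],
    out_dir: str | Path | None,
    height: int = 256,
    width: int = 256,
    n_cells: int = 60,
    noise: NoiseConfig | None = None,
    spillover_width: int = 0,
    spillover_fraction: float = 0.5,
    seed: int = 0,
    shared_layout: bool = False,
    radius_range: tuple[float, float] = (4.0, 9.0),
) -> dict[str, tuple[MultiChannelImage, LabelMap, GroundTruth]]:
    """Simulate ``n_fovs`` FOVs and (optionally) write the dataset layout.

    ``per_fov_gain[i]`` multiplies all channels of FOV i, emulating per-run
    sensitivity drift. With ``shared_layout=True`` every FOV reuses the same
    geometry sub-seed, so FOVs differ only by gain (and noise draws).
    Layout written: ``out/<fov>/<marker>.tiff``, ``segmentation.tiff``,
    ``ground_truth.tiff``, plus ``cell_phenotypes.csv``, ``signatures.csv``
    and ``panel.json`` at the root.
    """
    if len(per_fov_gain) != n_fovs:
        raise ValueError("per_fov_gain must have one entry per FOV")
    noise = noise or NoiseConfig()
    sub_seeds = np.random.SeedSequence(seed).generate_state(n_fovs)
    if shared_layout:
        sub_seeds = np.full(n_fovs, sub_seeds[0])

    out: dict[str, tuple[MultiChannelImage, LabelMap, GroundTruth]] = {}
    for i in range(n_fovs):
        fov_id = f"fov{i}"
        fov_noise = NoiseConfig(
            poisson_scale=noise.poisson_scale,
            dropout_prob=noise.dropout_prob,
            gain=noise.gain * per_fov_gain[i],
        )
        out[fov_id] = simulate_fov(
            signatures,
            height,
            width,
            n_cells,
            noise=fov_noise,
            spillover_width=spillover_width,
            spillover_fraction=spillover_fraction,
            seed=int(sub_seeds[i]),
            fov_id=fov_id,
            radius_range=radius_range,
        )

    if out_dir is not None:
        root = Path(out_dir)
        root.mkdir(parents=True, exist_ok=True)
        cell_rows = []
        for fov_id, (image, mask, truth) in out.items():
            fov_dir = root / fov_id
            save_fov(image, fov_dir)
            tifffile.imwrite(fov_dir / "segmentation.tiff", mask.data.astype(np.uint32))
            tifffile.imwrite(
                fov_dir / "ground_truth.tiff", truth.pixel_labels.astype(np.uint32)
            )
            cell_rows.append(truth.cell_labels)
        pd.concat(cell_rows, ignore_index=True).to_csv(
            root / "cell_phenotypes.csv", index=False
        )
        signatures.to_frame().to_csv(root / "signatures.csv")
        (root / "panel.json").write_text(
            json.dumps({"markers": signatures.marker_names}, indent=1)
        )
    return out
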