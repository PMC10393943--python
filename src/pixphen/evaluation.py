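"""Metrics and baselines for clustering comparisons.

Adjusted Rand index for partition agreement, silhouette for cluster
definition, per-phenotype F1 against labeled references, an Otsu
marker-positivity baseline (with the combinatorial pattern count that
motivates clustering over thresholding), and paired Spearman correlation of
composition vectors across replicate samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skimage.filters import threshold_otsu
from sklearn import metrics as skmetrics

from .preprocessing import PixelTable

__all__ = [
    "LabeledComparison",
    "adjusted_rand",
    "silhouette",
    "phenotype_f1",
    "majority_mapping",
    "otsu_positivity",
    "combo_counts",
    "replicate_correlation",
]


@dataclass
class LabeledComparison:
    """Predicted vs reference labels, with an optional rename of predictions."""

    predicted: np.ndarray
    reference: np.ndarray
    mapping: dict | None = None

    def __post_init__(self) -> None:
        self.predicted = np.asarray(self.predicted)
        self.reference = np.asarray(self.reference)
        if len(self.predicted) != len(self.reference):
            raise ValueError("predicted and reference lengths differ")
        if len(self.predicted) == 0:
            raise ValueError("empty comparison")
        if self.mapping is not None:
            unmapped = sorted(
                set(np.unique(self.predicted)) - set(self.mapping), key=str
            )
            if unmapped:
                raise ValueError(f"unmapped predicted phenotypes: {unmapped}")

    def resolved_predictions(self) -> np.ndarray:
        if self.mapping is None:
            return self.predicted
        return np.array([self.mapping[p] for p in self.predicted])


def adjusted_rand(a, b) -> float:
    """Adjusted Rand index between two labelings of the same observations."""
    a = np.asarray(a)
    b = np.asarray(b)
    if len(a) != len(b):
        raise ValueError("label vectors must have equal length")
    if len(a) == 0:
        raise ValueError("label vectors must be nonempty")
    return float(skmetrics.adjusted_rand_score(a, b))


def silhouette(
    features: np.ndarray, labels, subsample: int | None = None, seed: int = 0
) -> float:
    """Mean silhouette (Euclidean) over a seeded subsample of observations."""
    features = np.asarray(features, dtype=np.float64)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette requires at least 2 distinct labels")
    if subsample is not None and subsample < len(labels):
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(labels), size=subsample, replace=False)
        features, labels = features[idx], labels[idx]
        if len(np.unique(labels)) < 2:
            raise ValueError("subsample retained a single label; increase subsample")
    return float(skmetrics.silhouette_score(features, labels, metric="euclidean"))


def phenotype_f1(cmp: LabeledComparison) -> dict:
    """Per-class precision/recall/F1 plus macro and weighted averages."""
    pred = cmp.resolved_predictions()
    ref = cmp.reference
    classes = sorted(set(map(str, np.unique(ref))) | set(map(str, np.unique(pred))))
    pred = pred.astype(str)
    ref = ref.astype(str)
    precision, recall, f1, support = skmetrics.precision_recall_fscore_support(
        ref, pred, labels=classes, zero_division=0
    )
    per_class = pd.DataFrame(
        {
            "phenotype": classes,
            "precision": precision,
            "recall": recall,
            "f1": f1,
            "support": support,
        }
    )
    return {
        "per_class": per_class,
        "macro_f1": float(f1.mean()),
        "weighted_f1": float(skmetrics.f1_score(ref, pred, average="weighted", zero_division=0)),
    }


def majority_mapping(predicted, reference) -> dict:
    """Map each predicted cluster to its majority reference label.

    The standard device for scoring an unsupervised clustering against
    labeled data; ties resolve to the smallest reference label.
    """
    predicted = np.asarray(predicted)
    reference = np.asarray(reference)
    out = {}
    for p in np.unique(predicted):
        refs, counts = np.unique(reference[predicted == p], return_counts=True)
        out[p] = refs[np.argmax(counts)]
    return out


def otsu_positivity(table: PixelTable, nbins: int = 256) -> np.ndarray:
    """Binary positivity per pixel x marker via per-marker Otsu thresholds.

    Thresholds come from 256-bin histograms of each marker's nonzero values;
    positive means strictly above the threshold.
    """
    values = table.values
    positive = np.zeros(values.shape, dtype=bool)
    for j, marker in enumerate(table.marker_names):
        col = values[:, j]
        nz = col[col > 0]
        if nz.size == 0 or np.ptp(nz) == 0:
            raise ValueError(
                f"marker {marker!r} has no intensity variation; cannot threshold"
            )
        thresh = threshold_otsu(nz, nbins=nbins)
        positive[:, j] = col > thresh
    return positive


def combo_counts(binary: np.ndarray, n_positive: int) -> int:
    """Number of distinct observed positivity patterns with exactly n positives."""
    binary = np.asarray(binary, dtype=bool)
    rows = binary[binary.sum(axis=1) == n_positive]
    if rows.size == 0:
        return 0
    return len(np.unique(rows, axis=0))


def replicate_correlation(
    compositions: list[np.ndarray], pairing: list[tuple[int, int]]
) -> dict:
    """Spearman rank correlation of paired composition vectors.

    Reports per-pair rho (and rho^2, since published 'R^2' summaries may be
    either) with mean +/- SD summaries.
    """
    rows = []
    for i, j in pairing:
        a = np.asarray(compositions[i], dtype=np.float64)
        b = np.asarray(compositions[j], dtype=np.float64)
        if a.shape != b.shape:
            raise ValueError(f"pair ({i}, {j}): composition lengths differ")
        rho = float(stats.spearmanr(a, b).statistic)
        rows.append({"pair": (i, j), "spearman_rho": rho, "rho_squared": rho**2})
    frame = pd.DataFrame(rows)
    return {
        "per_pair": frame,
        "mean_rho": float(frame["spearman_rho"].mean()),
        "sd_rho": float(frame["spearman_rho"].std(ddof=1)) if len(frame) > 1 else 0.0,
        "mean_rho_squared": float(frame["rho_squared"].mean()),
    }
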