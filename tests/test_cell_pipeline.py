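import numpy as np
import pandas as pd
import pytest

from pixphen.cell_pipeline import (
    CellFeatureTable,
    cell_pixel_composition,
    cluster_cells,
    integrated_expression_features,
    normalize_cell_features,
)
from pixphen.image_io import LabelMap, MultiChannelImage
from pixphen.metaclustering import ConsensusConfig
from pixphen.som import SOMConfig


def _maps(assign, mask):
    return {"fov0": LabelMap("fov0", assign)}, {"fov0": LabelMap("fov0", mask)}


class TestCellPixelComposition:
    def test_pure_cell(self):
        mask = np.zeros((5, 5), dtype=np.int64)
        mask[0:2, :] = 1  # 10 pixels
        assign = np.where(mask > 0, 3, 0)
        maps, masks = _maps(assign, mask)
        table = cell_pixel_composition(maps, masks)
        assert table.cells["cell_size"].tolist() == [10]
        feats = dict(zip(table.feature_names, table.features[0]))
        assert feats["cluster_3"] == 1.0
        assert sum(feats.values()) == 1.0

    def test_excluded_pixels_count_in_denominator(self):
        mask = np.zeros((4, 4), dtype=np.int64)
        mask[0:2, 0:4] = 1  # 8 pixels
        assign = np.zeros((4, 4), dtype=np.int64)
        assign[0, 0:4] = 2
        assign[1, 0:2] = 2  # 6 assigned to cluster 2, 2 excluded
        maps, masks = _maps(assign, mask)
        table = cell_pixel_composition(maps, masks)
        feats = dict(zip(table.feature_names, table.features[0]))
        assert feats["cluster_2"] == 0.75

    def test_matches_exhaustive_tally(self):
        rng = np.random.default_rng(0)
        mask = rng.integers(0, 6, (40, 40))
        assign = rng.integers(0, 4, (40, 40))
        maps, masks = _maps(assign, mask)
        table = cell_pixel_composition(maps, masks)
        for i, (_, row) in enumerate(table.cells.iterrows()):
            cell_px = mask == row["cell_id"]
            assert row["cell_size"] == cell_px.sum()
            for k in range(1, 4):
                expected = np.sum(assign[cell_px] == k) / cell_px.sum()
                assert table.features[i, k - 1] == pytest.approx(expected)

    def test_fov_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            cell_pixel_composition(
                {"fovA": np.zeros((2, 2), int)}, {"fovB": np.zeros((2, 2), int)}
            )


class TestNormalizeCellFeatures:
    def _table(self, features, names=None):
        n = len(features)
        return CellFeatureTable(
            pd.DataFrame({"fov": "f", "cell_id": np.arange(1, n + 1), "cell_size": 5}),
            np.asarray(features, dtype=float),
            names or [f"cluster_{i+1}" for i in range(np.shape(features)[1])],
            feature_kind="pixel_composition",
        )

    def test_constant_feature_becomes_one(self):
        out = normalize_cell_features(self._table(np.full((20, 1), 0.5)))
        assert np.allclose(out.features, 1.0)

    def test_post_normalization_quantiles_are_one(self):
        rng = np.random.default_rng(1)
        out = normalize_cell_features(self._table(rng.uniform(0.1, 1, (500, 4))))
        assert np.allclose(np.quantile(out.features, 0.999, axis=0), 1.0, atol=1e-6)

    def test_zero_column_dropped_with_warning(self):
        features = np.ones((10, 2))
        features[:, 1] = 0.0
        with pytest.warns(UserWarning, match="cluster_2"):
            out = normalize_cell_features(self._table(features))
        assert out.feature_names == ["cluster_1"]

    def test_wrong_kind_rejected(self):
        table = self._table(np.ones((5, 1)))
        table.feature_kind = "integrated_expression"
        with pytest.raises(ValueError, match="pixel_composition"):
            normalize_cell_features(table)


class TestIntegratedExpression:
    def test_one_pixel_cell_raw_values(self):
        mask = np.zeros((3, 3), dtype=np.int64)
        mask[1, 1] = 1
        data = np.zeros((2, 3, 3))
        data[0, 1, 1] = 2.0
        data[1, 1, 1] = 4.0
        images = {"fov0": MultiChannelImage("fov0", ["a", "b"], data)}
        table = integrated_expression_features(
            images, {"fov0": mask}, normalize=False
        )
        assert table.features[0].tolist() == [2.0, 4.0]

    def test_scaling_behavior(self):
        rng = np.random.default_rng(2)
        mask = np.zeros((20, 20), dtype=np.int64)
        mask[2:6, 2:6] = 1
        mask[10:15, 10:15] = 2
        data = rng.uniform(0.5, 2, (3, 20, 20))
        images = {"fov0": MultiChannelImage("fov0", ["a", "b", "c"], data)}
        doubled = {"fov0": MultiChannelImage("fov0", ["a", "b", "c"], 2 * data)}
        raw = integrated_expression_features(images, {"fov0": mask}, normalize=False)
        raw2 = integrated_expression_features(doubled, {"fov0": mask}, normalize=False)
        assert np.allclose(raw2.features, 2 * raw.features)
        norm = integrated_expression_features(images, {"fov0": mask})
        norm2 = integrated_expression_features(doubled, {"fov0": mask})
        assert np.allclose(norm.features, norm2.features)

    def test_matches_summation_oracle(self):
        rng = np.random.default_rng(3)
        mask = rng.integers(0, 4, (15, 15))
        data = rng.uniform(0, 5, (2, 15, 15))
        images = {"fov0": MultiChannelImage("fov0", ["a", "b"], data)}
        table = integrated_expression_features(images, {"fov0": mask}, normalize=False)
        for i, (_, row) in enumerate(table.cells.iterrows()):
            cell_px = mask == row["cell_id"]
            for j in range(2):
                expected = data[j][cell_px].sum() / cell_px.sum()
                assert table.features[i, j] == pytest.approx(expected)

    def test_preprocess_flag_pixel_normalizes(self):
        mask = np.zeros((11, 11), dtype=np.int64)
        mask[5, 5] = 1
        data = np.zeros((2, 11, 11))
        data[0, 5, 5] = 3.0
        data[1, 5, 5] = 1.0
        images = {"fov0": MultiChannelImage("fov0", ["a", "b"], data)}
        table = integrated_expression_features(
            images, {"fov0": mask}, preprocess=True, sigma=0.0, normalize=False
        )
        assert np.allclose(table.features[0], [0.75, 0.25])


class TestClusterCells:
    def _archetype_table(self, n_per=40, seed=4):
        rng = np.random.default_rng(seed)
        archetypes = np.eye(3)
        features = np.vstack(
            [rng.normal(a, 0.02, (n_per, 3)).clip(0) for a in archetypes]
        )
        labels = np.repeat([1, 2, 3], n_per)
        table = CellFeatureTable(
            pd.DataFrame(
                {
                    "fov": "f",
                    "cell_id": np.arange(1, 3 * n_per + 1),
                    "cell_size": 10,
                }
            ),
            features,
            ["cluster_1", "cluster_2", "cluster_3"],
            feature_kind="pixel_composition",
        )
        return table, labels

    def test_recovers_archetypes(self):
        from pixphen.evaluation import adjusted_rand

        table, labels = self._archetype_table()
        result = cluster_cells(
            table, SOMConfig(grid_rows=3, grid_cols=3), ConsensusConfig(k=3), seed=0
        )
        assert adjusted_rand(result.meta_assignments, labels) == 1.0

    def test_determinism(self):
        table, _ = self._archetype_table()
        a = cluster_cells(table, SOMConfig(grid_rows=3, grid_cols=3), ConsensusConfig(k=3), seed=1)
        b = cluster_cells(table, SOMConfig(grid_rows=3, grid_cols=3), ConsensusConfig(k=3), seed=1)
        assert np.array_equal(a.meta_assignments, b.meta_assignments)

    def test_constant_features_single_phenotype(self):
        table, _ = self._archetype_table()
        table.features = np.full_like(table.features, 0.5)
        result = cluster_cells(
            table, SOMConfig(grid_rows=3, grid_cols=3), ConsensusConfig(k=2), seed=2
        )
        # all cells land in one effective phenotype
        assert len(np.unique(result.meta_assignments)) == 1

    def test_too_few_cells_suggests_smaller_grid(self):
        table, _ = self._archetype_table(n_per=2)
        with pytest.raises(ValueError, match="smaller grid"):
            cluster_cells(table, SOMConfig(), ConsensusConfig(k=2), seed=0)

    def test_cell_phenotype_maps_painted(self):
        table, _ = self._archetype_table(n_per=5)
        mask = np.zeros((10, 15), dtype=np.int64)
        for cid in range(1, 16):
            mask[(cid - 1) % 10, cid - 1] = cid
        result = cluster_cells(
            table, SOMConfig(grid_rows=2, grid_cols=2), ConsensusConfig(k=3),
            masks={"f": mask}, seed=3,
        )
        painted = result.maps["f"].data
        labels = result.labels_frame()
        for _, row in labels.iterrows():
            assert painted[mask == row["cell_id"]].item() == row["metacluster"]
        assert np.all(painted[mask == 0] == 0)


def test_composition_invariant_to_intensity_scaling(sig3, noisy_dataset):
    """Composition features depend only on pixel cluster identity."""
    from pixphen.pixel_pipeline import PixelRunConfig, run_pixel_clustering
    from pixphen.som import SOMConfig

    images = {f: v[0] for f, v in noisy_dataset.items()}
    masks = {f: v[1] for f, v in noisy_dataset.items()}
    config = PixelRunConfig(
        dataset_dir=None, markers=sig3.covered_markers(),
        som=SOMConfig(grid_rows=4, grid_cols=4), consensus=ConsensusConfig(k=3), seed=0,
    )
    base = run_pixel_clustering(config, images=images)
    scaled_images = {
        f: MultiChannelImage(f, img.marker_names, img.data * 3.0)
        for f, img in images.items()
    }
    scaled = run_pixel_clustering(config, images=scaled_images)
    a = cell_pixel_composition(base.maps, masks)
    b = cell_pixel_composition(scaled.maps, masks)
    assert np.allclose(a.features, b.features)
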