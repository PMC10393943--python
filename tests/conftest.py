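import numpy as np
import pandas as pd
import pytest

from pixphen import (
    NoiseConfig,
    make_signatures,
    simulate_dataset,
    simulate_fov,
)


@pytest.fixture(scope="session")
def sig3():
    return make_signatures(n_phenotypes=3, n_markers=6, markers_per_phenotype=2, seed=0)


@pytest.fixture(scope="session")
def noise_free_fov(sig3):
    """One FOV with exact intensities: gain x signature inside cells, 0 outside."""
    return simulate_fov(
        sig3, 96, 96, 20,
        noise=NoiseConfig(poisson_scale=0.0, dropout_prob=0.0),
        spillover_width=0, seed=4,
    )


@pytest.fixture(scope="session")
def noisy_dataset(sig3):
    """Two small FOVs with Poisson noise and dropout, in memory."""
    return simulate_dataset(
        sig3, 2, [1.0, 1.5], None, height=96, width=96, n_cells=20,
        noise=NoiseConfig(poisson_scale=1.0, dropout_prob=0.05), seed=9,
    )


def make_pixel_table(n_pixels=50, n_markers=4, seed=0, stage="smoothed"):
    from pixphen.preprocessing import PixelTable

    rng = np.random.default_rng(seed)
    values = rng.uniform(0.1, 5.0, size=(n_pixels, n_markers))
    coords = pd.DataFrame(
        {
            "fov": "fov0",
            "row": np.arange(n_pixels) // 100,
            "col": np.arange(n_pixels) % 100,
        }
    )
    return PixelTable(coords, values, [f"m{i}" for i in range(n_markers)], stage=stage)
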