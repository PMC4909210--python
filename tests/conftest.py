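"""Shared fixtures: phantoms, a cohort-scale pipeline run, and the
brute-force Niblack oracle."""

from __future__ import annotations

import numpy as np
import pytest

from chorobin.phantom import PhantomConfig, generate_phantom
from chorobin.pipeline import PipelineConfig, run_pipeline


@pytest.fixture(scope="session")
def phantom_clean():
    """Noise-free phantom (two-level image) with ground truth."""
    cfg = PhantomConfig(seed=4, speckle_looks=None)
    image, truth = generate_phantom(cfg)
    return cfg, image, truth


@pytest.fixture(scope="session")
def phantom_speckle():
    """Phantom with 100-frame-averaged speckle."""
    cfg = PhantomConfig(seed=4, speckle_looks=100)
    image, truth = generate_phantom(cfg)
    return cfg, image, truth


@pytest.fixture(scope="session")
def study_run():
    """Full pipeline on a 20-eyes-per-arm synthetic cohort."""
    return run_pipeline(PipelineConfig(seed=11, n_per_group=20))


@pytest.fixture(scope="session")
def niblack_bruteforce():
    """Independent windowed mean/SD threshold computation: explicit
    per-pixel loops over a symmetric-padded raster."""

    def brute(img_u8: np.ndarray, radius: int, k: float) -> np.ndarray:
        img = np.asarray(img_u8, dtype=float)
        padded = np.pad(img, radius, mode="symmetric")
        h, w = img.shape
        size = 2 * radius + 1
        out = np.empty((h, w))
        for y in range(h):
            for x in range(w):
                win = padded[y:y + size, x:x + size]
                out[y, x] = win.mean() + k * win.std()
        return out

    return brute
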