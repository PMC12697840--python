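"""Shared fixtures: small seeded datasets and the canonical benchmark."""

import numpy as np
import pandas as pd
import pytest

from nircal import SpectralDataset, simulate


@pytest.fixture(scope="session")
def small_lib():
    """Pure-spectrum library on a short grid for fast model tests."""
    grid = np.linspace(4000.0, 9000.0, 200)
    return simulate.gen_pure_spectra(11, grid=grid)


@pytest.fixture(scope="session")
def bench():
    """The canonical synthetic benchmark instance (fixed seed)."""
    return simulate.benchmark_suite(1)


@pytest.fixture
def toy_dataset():
    """Hand-sized dataset: 8 samples, 5 grid points, one component."""
    rng = np.random.default_rng(5)
    grid = np.array([4000.0, 4100.0, 4200.0, 4300.0, 4400.0])
    y = np.linspace(1.0, 8.0, 8)
    absorbance = np.outer(y, np.array([0.1, 0.2, 0.3, 0.2, 0.1]))
    absorbance = absorbance + 0.01 * rng.standard_normal(absorbance.shape)
    ids = [f"s{i}" for i in range(8)]
    comp = pd.DataFrame({"protein": y}, index=pd.Index(ids, name="id"))
    return SpectralDataset(ids, grid, absorbance, components=comp)
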