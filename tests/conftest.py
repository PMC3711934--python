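"""Shared fixtures: small simulated datasets with planted ground truth."""

import numpy as np
import pandas as pd
import pytest

import phenonoise as pn


@pytest.fixture(scope="session")
def small_cfg() -> pn.SimConfig:
    """Down-scaled study design with all planted effects on."""
    return pn.SimConfig(
        n_strains=12,
        n_reps=5,
        n_cells=60,
        n_base_traits=24,
        n_other=7,
        n_sites=400,
        n_subpopulations=3,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_ds(small_cfg):
    return pn.generate(small_cfg)


@pytest.fixture(scope="session")
def small_traits(small_ds):
    return pn.summarize_cells(small_ds.cells, small_ds.catalogue)


@pytest.fixture(scope="session")
def null_ds():
    cfg = pn.SimConfig.null(
        n_strains=12, n_reps=5, n_cells=60, n_base_traits=24, n_other=7,
        n_sites=400, n_subpopulations=3, seed=12,
    )
    return pn.generate(cfg)


@pytest.fixture(scope="session")
def null_traits(null_ds):
    return pn.summarize_cells(null_ds.cells, null_ds.catalogue)


@pytest.fixture(scope="session")
def wide_null_traits():
    """Null dataset at the study's 37-strain x 5-replicate geometry."""
    cfg = pn.SimConfig.null(
        n_strains=37, n_reps=5, n_cells=50, n_base_traits=60, n_other=7,
        n_sites=200, seed=7,
    )
    ds = pn.generate(cfg)
    return pn.summarize_cells(ds.cells, ds.catalogue)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_noise_table(values: np.ndarray, columns=None, n_reps: int = 5):
    """Wrap an array as a NoiseTable with STRAIN.rep sample ids."""
    n = values.shape[0]
    assert n % n_reps == 0
    ids = [f"S{i // n_reps + 1:02d}.{i % n_reps + 1}" for i in range(n)]
    cols = columns if columns is not None else [f"CCV{j}_A" for j in range(values.shape[1])]
    return pn.noise.NoiseTable(
        pd.DataFrame(values, index=pd.Index(ids, name="sample"), columns=cols), 0.4, 3
    )
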