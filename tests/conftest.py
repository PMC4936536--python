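"""Shared fixtures: small geographies, datasets, and the replicated
recovery/model-selection experiment used by several slow tests."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from scalemap import (
    MultiscaleData,
    MultiscaleGeography,
    SimulationTruth,
    make_lattice_geography,
    recovery_experiment,
    simulate_dataset,
)
from scalemap.data import LevelData


@pytest.fixture
def geog_6in2() -> MultiscaleGeography:
    """Six fine units (two rows of three, rook adjacency) in two coarse units."""
    fine = [f"c{i}" for i in range(6)]
    coarse = ["dA", "dB"]
    parent = {"c0": "dA", "c1": "dA", "c2": "dB", "c3": "dA", "c4": "dA", "c5": "dB"}
    # layout:  c0 c1 c2
    #          c3 c4 c5
    pairs = [("c0", "c1"), ("c1", "c2"), ("c3", "c4"), ("c4", "c5"),
             ("c0", "c3"), ("c1", "c4"), ("c2", "c5")]
    fadj = {u: set() for u in fine}
    for a, b in pairs:
        fadj[a].add(b)
        fadj[b].add(a)
    cadj = {"dA": {"dB"}, "dB": {"dA"}}
    return MultiscaleGeography(fine, coarse, parent, fadj, cadj)


@pytest.fixture
def data_6in2(geog_6in2) -> MultiscaleData:
    rng = np.random.default_rng(42)
    n = np.array([50, 60, 70, 80, 90, 100])
    y = rng.binomial(n, 0.12)
    x = rng.normal(40.0, 8.0, size=6)
    fine = pd.DataFrame({"unit_id": geog_6in2.fine_ids, "y": y, "n": n, "x": x})
    return MultiscaleData.from_frames(geog_6in2, fine)


@pytest.fixture
def lattice_data():
    """A small simulated lattice study (6x6 grid, four 3x3 blocks)."""
    geog = make_lattice_geography(6, 6, 3, 3)
    truth = SimulationTruth(n_trials=200, seed=7)
    data, state = simulate_dataset(geog, truth, 7)
    return geog, data, truth, state


def make_level(y, n, x) -> LevelData:
    """LevelData with the covariate taken as already standardized."""
    y = np.asarray(y, dtype=np.int64)
    n = np.asarray(n, dtype=np.int64)
    x = np.asarray(x, dtype=float)
    return LevelData(y=y, n=n, x_raw=x, x=x, x_mean=0.0, x_sd=1.0)


@pytest.fixture(scope="session")
def recovery_run():
    """The replicated simulate-fit-score experiment: 20 datasets from the
    shared model on the 12x12/9-block design with ~500 trials per unit,
    each fitted with both model variants (3 chains x 3000 iterations).

    Session-scoped: parameter recovery, convergence, model-selection
    direction and surface-smoothness checks all read from this one run.
    """
    return recovery_experiment(n_replicates=20, seed=101)
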