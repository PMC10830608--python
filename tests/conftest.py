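"""Shared fixtures.

The expensive session fixtures run the factorial experiments once at reduced
problem size (500-row corridor, 40 years, 3 replicates, 30-year spread
horizon) and are shared by the mechanism and acceptance tests; the kernel
runs use the full-size corridor because emergent dispersal distances are the
quantity under test there.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import pytest

from matewave.demography import DemographyParams, POLYGYNOUS
from matewave.dispersal import SettlementRule
from matewave.engine import (
    SimConfig,
    experiment1_design,
    experiment2_design,
    run_experiment,
    run_simulation,
)
from matewave.io import make_fixture
from matewave.landscape import InitSpec, generate_landscape

MASTER_SEED = 1


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_landscape():
    return generate_landscape(20, 100, 0.07, seed=7)


@pytest.fixture(scope="session")
def two_patch_pair():
    return make_fixture("two_patch_pair")


@pytest.fixture(scope="session")
def edge_ladder():
    return make_fixture("edge_ladder")


@pytest.fixture(scope="session")
def strip_costs():
    return make_fixture("strip_costs")


@pytest.fixture(scope="session")
def exp1_scaled():
    """Scaled-down full mating-system factorial (189 runs)."""
    design = dataclasses.replace(
        experiment1_design(years=40, replicates=3, n_rows=500),
        spread_horizon=30,
    )
    return run_experiment(design, master_seed=MASTER_SEED)


@pytest.fixture(scope="session")
def exp2_scaled():
    """Scaled-down settlement-strategy factorial, polygynous runs."""
    design = experiment2_design(
        years=40, replicates=3, n_rows=500, mating_systems=("polygynous",)
    )
    return run_experiment(design, master_seed=MASTER_SEED)


def _kernel_run(strategy: str, replicate: int):
    cfg = SimConfig(
        mating=POLYGYNOUS,
        demography=DemographyParams(fecundity=3.0, b=0.1),
        settlement=SettlementRule(strategy=strategy),
        years=50,
        master_seed=MASTER_SEED,
        scenario_id=f"kernel_{strategy}",
    )
    return run_simulation(
        cfg, replicate, record_dispersal=True, record_neighbourhoods=True
    )


@pytest.fixture(scope="session")
def kernel_runs():
    """Full-size runs at habitat quality 10, fecundity 3: emergent kernels.

    Returns {strategy: (dispersal table, neighbourhood table)} pooled over
    3 replicates each for the habitat-only, mate-search and
    density-dependent settlement rules.
    """
    out = {}
    for strategy in ("habitat_only", "mate_search", "density_dependent"):
        disp, nbhd = [], []
        for rep in range(3):
            res = _kernel_run(strategy, rep)
            disp.append(res.dispersal)
            nbhd.append(res.neighbourhoods)
        out[strategy] = (
            pd.concat(disp, ignore_index=True),
            pd.concat(nbhd, ignore_index=True),
        )
    return out


def female_kernel_mean(dispersal: pd.DataFrame) -> float:
    """Mean rows displaced by settled females, averaged over replicates."""
    fem = dispersal[(dispersal.sex == "F") & (dispersal.fate == "settled")]
    return float(fem.groupby("replicate").rows_displaced.mean().mean())
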