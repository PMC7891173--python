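"""Shared simulation fixtures.

The stochastic runs are session-scoped because several test modules read
the same replicate sets (gene-flow agreement, parallel gain, passive-mean
reconstruction, the pooled validation study).  All seeds are fixed.
"""

from __future__ import annotations

import pandas as pd
import pytest

from beegeneflow import (
    MatingSystem,
    SimConfig,
    default_validation_grid,
    run,
    run_validation_study,
)


@pytest.fixture(scope="session")
def unc_config() -> SimConfig:
    return SimConfig(
        n_b=250, n_p=250, mating_system=MatingSystem.UNCONTROLLED,
        q=0.5, seed=7, replicates=10,
    )


@pytest.fixture(scope="session")
def unc_tables(unc_config) -> list[pd.DataFrame]:
    return run(unc_config)


@pytest.fixture(scope="session")
def con_config() -> SimConfig:
    return SimConfig(
        n_b=250, n_p=250, mating_system=MatingSystem.CONTROLLED,
        q=0.5, n_stations=10, seed=7, replicates=10,
    )


@pytest.fixture(scope="session")
def con_tables(con_config) -> list[pd.DataFrame]:
    return run(con_config)


@pytest.fixture(scope="session")
def recon_config() -> SimConfig:
    return SimConfig(
        n_b=200, n_p=200, mating_system=MatingSystem.UNCONTROLLED,
        q=0.5, seed=11, replicates=20,
    )


@pytest.fixture(scope="session")
def recon_tables(recon_config) -> list[pd.DataFrame]:
    return run(recon_config)


@pytest.fixture(scope="session")
def validation_report():
    """The reduced validation study used by the acceptance suite."""
    return run_validation_study(default_validation_grid(seed=1))
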