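import numpy as np
import pytest

from multistage import (
    CohortTable,
    Participant,
    SimulationParams,
    calibrate_rates,
    simulate_cohort,
)
from multistage.simulate import GeneticConfig


@pytest.fixture
def three_row_cohort() -> CohortTable:
    return CohortTable.from_participants(
        [
            Participant("a", 57.0, 63.5, True, ("e3", "e4"), {"rs1": 1.0, "rs2": 0.0}),
            Participant("b", 60.0, 65.0, False, ("e3", "e3"), {"rs1": 2.0, "rs2": 1.5}),
            Participant("c", 48.25, 80.125, False, None, {}),
        ]
    )


@pytest.fixture(scope="session")
def powerlaw_cohort() -> CohortTable:
    """A 6-step power-law cohort, large enough for a stable fit."""
    rates = calibrate_rates(6, 0.20, 100.0, mode="powerlaw")
    params = SimulationParams(
        n_true=6, step_rates=rates, sample_size=50_000, seed=7,
        mode="powerlaw", genetic=None,
    )
    return simulate_cohort(params)


@pytest.fixture(scope="session")
def genetic_cohort() -> CohortTable:
    """A cohort with APOE strata and 23 dosage columns."""
    rates = calibrate_rates(10, 0.20, 100.0, mode="powerlaw")
    params = SimulationParams(
        n_true=10, step_rates=rates, sample_size=30_000, seed=11,
        mode="powerlaw", genetic=GeneticConfig(),
    )
    return simulate_cohort(params)
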