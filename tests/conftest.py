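"""Shared fixtures.

The heavy stochastic checks all consume replicate simulations from a
small set of study conditions (overlap x escape scaling at 100% liganded
ErbB3).  Those runs are produced once per session, at the scaled protocol
(dt = 1e-5 with recalibrated binding radii), and shared across tests via
the ``cells`` fixture.
"""

from __future__ import annotations

import pytest

from erbbsim.engine import simulate_replicates
from erbbsim.landscape import build_empty_landscape, build_fixture_landscape
from erbbsim.observers import steady_state_summary
from erbbsim.parameters import ParameterSet

# scaled study protocol used throughout the suite
TEST_DT = 1e-5
TEST_DURATION = 60.0
TEST_WINDOW = 30.0
TEST_RUNS = 4
BASE_SEED = 10
LANDSCAPE_SEED = 100


@pytest.fixture(scope="session")
def params() -> ParameterSet:
    return ParameterSet()


def _landscape(overlap):
    if overlap == "none":
        return build_empty_landscape()
    return build_fixture_landscape(float(overlap), LANDSCAPE_SEED)


@pytest.fixture(scope="session")
def cells():
    """Memoised replicate runs per study condition.

    ``cells(overlap, scaling, ligand, duration, runs, dt)`` returns the
    list of per-run observation DataFrames, computing them on first use.
    """
    cache: dict = {}

    def get(
        overlap,
        scaling=1.0,
        ligand=1.0,
        duration=TEST_DURATION,
        runs=TEST_RUNS,
        dt=TEST_DT,
    ):
        key = (overlap, scaling, ligand, duration, runs, dt)
        if key not in cache:
            cache[key] = simulate_replicates(
                _landscape(overlap),
                ParameterSet(),
                n_runs=runs,
                base_seed=BASE_SEED,
                ligand_fraction=ligand,
                escape_scaling=scaling,
                duration=duration,
                dt=dt,
            )
        return cache[key]

    return get


def summarize(runs, window=TEST_WINDOW):
    return steady_state_summary(runs, window=window)


def pooled_sd(sd_a: float, sd_b: float) -> float:
    return ((sd_a**2 + sd_b**2) / 2.0) ** 0.5
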