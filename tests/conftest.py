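"""Shared fixtures: solved default model, simulated traces, smoke sweep.

Simulation-heavy fixtures are session-scoped so the triangular-ramp runs and
the attenuation-space smoke sweep are computed once and shared between the
behavioural unit tests and the acceptance tests.
"""

import numpy as np
import pytest

from dcacrm import sweep as sweep_mod
from dcacrm.dynamics import (
    DEFAULT_ACTIVE,
    simulate,
    switching_protocol,
    triangular_protocol,
)
from dcacrm.reduction import DEFAULT_PROPERTIES, solve_passive

AC_VARIANTS = (0.08, 0.49, 0.88)


@pytest.fixture(scope="session")
def props():
    return DEFAULT_PROPERTIES


@pytest.fixture(scope="session")
def passive(props):
    return solve_passive(props)


@pytest.fixture(scope="session")
def active():
    return DEFAULT_ACTIVE


@pytest.fixture(scope="session")
def variant_passive(props):
    """Solved parameter sets for the three representative AC attenuations."""
    return {va: solve_passive(props.replace(va_sd_ac=va)) for va in AC_VARIANTS}


@pytest.fixture(scope="session")
def triangular(props):
    return triangular_protocol()


@pytest.fixture(scope="session")
def variant_traces(variant_passive, props, active, triangular):
    """Triangular-ramp traces of the default model at the three AC levels."""
    return {
        va: simulate(pp, props.p, active, triangular, dt_out=0.1)
        for va, pp in variant_passive.items()
    }


@pytest.fixture(scope="session")
def default_trace(variant_traces):
    return variant_traces[0.49]


@pytest.fixture(scope="session")
def switching_trace(passive, props, active):
    proto = switching_protocol()
    return simulate(passive, props.p, active, proto, dt_out=0.1), proto


@pytest.fixture(scope="session")
def smoke_sweep(props, active):
    """Coarse attenuation-cube sweep whose grid contains the default cell."""
    grid = sweep_mod.SweepGrid(
        va_ds_dc=(0.26, 0.86, 4),   # 0.26, 0.46, 0.66, 0.86
        va_sd_dc=(0.29, 0.89, 4),   # 0.29, 0.49, 0.69, 0.89
        va_sd_ac=(0.09, 0.89, 3),   # 0.09, 0.49, 0.89
    )
    return sweep_mod.sweep(grid, props, active, dt_out=0.2)
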