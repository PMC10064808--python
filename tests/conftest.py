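import numpy as np
import pytest
from hypothesis import settings

from pyrocosm import (
    FireForcingParams,
    SimulationGrid,
    SoilComposition,
    ThermalProperties,
    build_forcing_curve,
    simulate_heat_transfer,
    summarize_exposure,
)

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def props():
    """Default soil thermal properties (loam-like composition, k = 0.03 W/cm/K)."""
    return ThermalProperties.from_composition(SoilComposition())


@pytest.fixture(scope="session")
def field_600(props):
    """Default high-severity (600 °C) simulation."""
    curve = build_forcing_curve(FireForcingParams(T_max=600.0))
    return simulate_heat_transfer(curve, props, SimulationGrid())


@pytest.fixture(scope="session")
def field_450(props):
    """Default low-severity (450 °C) simulation."""
    curve = build_forcing_curve(FireForcingParams(T_max=450.0))
    return simulate_heat_transfer(curve, props, SimulationGrid())


@pytest.fixture(scope="session")
def field_600_fine(props):
    """High-severity run at halved dz and output dt (grid-convergence check)."""
    curve = build_forcing_curve(FireForcingParams(T_max=600.0))
    grid = SimulationGrid(dz=0.05, depth_total=15.0, dt_out=0.5)
    return simulate_heat_transfer(curve, props, grid)


@pytest.fixture(scope="session")
def summary_600(field_600):
    return summarize_exposure(field_600)


@pytest.fixture(scope="session")
def summary_450(field_450):
    return summarize_exposure(field_450)


@pytest.fixture(scope="session")
def peaks_by_fire(summary_450, summary_600):
    """Per-depth peak temperatures per fire level, as the survival model uses."""
    return {"450": summary_450.peaks, "600": summary_600.peaks}
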