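"""pyrocosm: fire-driven soil heat transfer and depth-stratified microbial
survival statistics.

Simulates heat conduction into a soil column under a prescribed surface
fire forcing (ramp/hold/decay), derives per-depth heat-exposure metrics and
a microbial heat mortality zone, and runs the survival statistics of a
pyrocosm burn experiment (thermocouple treatment comparisons, CFU
presence/absence tests, thermotolerance midpoint recovery) on observed or
synthetic data.
"""

__version__ = "0.1.0"

from .cfu import (
    DesignSpec,
    chi_squared_presence,
    growth_summary,
    min_growth_depth,
    read_cfu_csv,
    write_cfu_csv,
)
from .config import RunConfig
from .errors import (
    DataError,
    DegenerateDataError,
    NumericalError,
    ParameterError,
    PyrocosmError,
)
from .exposure import ExposureConfig, ExposureSummary, MortalityZone, mortality_zone, summarize_exposure
from .forcing import FireForcingParams, ForcingCurve, build_forcing_curve, evaluate_forcing
from .soil import (
    SoilComposition,
    ThermalProperties,
    thermal_diffusivity,
    volumetric_heat_capacity,
)
from .solver import (
    SimulationGrid,
    TemperatureField,
    halfspace_step_oracle,
    simulate_heat_transfer,
)
from .synth import (
    NoiseModel,
    SurvivalModel,
    T50Fit,
    build_design,
    fit_lethal_midpoint,
    gen_cfu_grid,
    gen_thermocouple_traces,
)
from .thermo import (
    ThermocoupleTrace,
    compare_treatments,
    load_table1_reference,
    model_vs_observed,
    read_traces_csv,
    welch_t,
    write_traces_csv,
)

__all__ = [
    "__version__",
    "FireForcingParams", "ForcingCurve", "build_forcing_curve", "evaluate_forcing",
    "SoilComposition", "ThermalProperties", "volumetric_heat_capacity",
    "thermal_diffusivity",
    "SimulationGrid", "TemperatureField", "simulate_heat_transfer",
    "halfspace_step_oracle",
    "ExposureConfig", "ExposureSummary", "MortalityZone", "summarize_exposure",
    "mortality_zone",
    "ThermocoupleTrace", "welch_t", "compare_treatments", "model_vs_observed",
    "read_traces_csv", "write_traces_csv", "load_table1_reference",
    "DesignSpec", "growth_summary", "chi_squared_presence", "min_growth_depth",
    "read_cfu_csv", "write_cfu_csv",
    "SurvivalModel", "NoiseModel", "T50Fit", "build_design",
    "gen_thermocouple_traces", "gen_cfu_grid", "fit_lethal_midpoint",
    "RunConfig",
    "PyrocosmError", "ParameterError", "DataError", "DegenerateDataError",
    "NumericalError",
]


def run_full_pipeline(config: "RunConfig", plots: bool = True):
    """See :func:`pyrocosm.pipeline.run_full_pipeline` (imported lazily so
    that library use does not pull in matplotlib)."""
    from .pipeline import run_full_pipeline as _run

    return _run(config, plots=plots)
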