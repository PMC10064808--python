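"""YAML run configuration.

A single file describes a full pipeline run: fire forcing per treatment,
soil thermal properties, the simulation grid, the exposure analysis, and
the synthetic observation/survival models. Unknown keys are rejected so
typos fail loudly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import yaml

from .cfu import DesignSpec
from .errors import ParameterError
from .exposure import ExposureConfig
from .forcing import FireForcingParams
from .soil import SoilComposition, ThermalProperties
from .solver import SimulationGrid
from .synth import NoiseModel, SurvivalModel


def _take(section: dict, allowed: dict, where: str) -> dict:
    unknown = set(section) - set(allowed)
    if unknown:
        raise ParameterError(f"unknown key(s) {sorted(unknown)} in config section "
                             f"'{where}'")
    return {allowed[k]: v for k, v in section.items()}


@dataclass
class RunConfig:
    """Validated pipeline configuration with study defaults."""

    seed: int = 7
    output_dir: str = "pyrocosm_out"
    fire_treatments: Sequence[float] = (450.0, 600.0)
    fire_basal: float = 20.0
    fire_ramp: float = 600.0
    fire_hold: float = 60.0
    fire_decay: float = 1800.0
    fire_dt: float = 1.0
    soil: SoilComposition = field(default_factory=SoilComposition)
    conductivity: float = 0.03  # W cm^-1 K^-1
    latent_heat: bool = False
    grid: SimulationGrid = field(default_factory=SimulationGrid)
    bottom: str = "dirichlet"
    exposure: ExposureConfig = field(default_factory=ExposureConfig)
    survival: SurvivalModel = field(default_factory=SurvivalModel)
    noise: NoiseModel = field(default_factory=NoiseModel)
    design: DesignSpec = field(default_factory=DesignSpec)
    probe_depths: Sequence[float] = (2.0, 5.0, 8.0)
    probe_reps: int = 6
    biocrust_offset_C: float = -10.0

    def forcing_params(self, t_max: float) -> FireForcingParams:
        return FireForcingParams(
            T_basal=self.fire_basal, T_max=t_max, t_ramp=self.fire_ramp,
            t_hold=self.fire_hold, t_decay=self.fire_decay, dt=self.fire_dt,
        )

    def thermal_properties(self) -> ThermalProperties:
        return ThermalProperties.from_composition(self.soil, self.conductivity)

    @classmethod
    def from_dict(cls, raw: Optional[dict]) -> "RunConfig":
        raw = dict(raw or {})
        kw = {}

        top = _take(
            {k: v for k, v in raw.items()
             if k not in ("fire", "soil", "grid", "exposure", "synth")},
            {"seed": "seed", "output_dir": "output_dir", "bottom": "bottom",
             "latent_heat": "latent_heat"},
            "top level",
        )
        kw.update(top)

        fire = _take(raw.get("fire", {}), {
            "treatments": "fire_treatments", "basal_C": "fire_basal",
            "ramp_s": "fire_ramp", "hold_s": "fire_hold",
            "decay_s": "fire_decay", "dt_s": "fire_dt",
        }, "fire")
        kw.update(fire)

        soil_raw = dict(raw.get("soil", {}))
        cond = soil_raw.pop("conductivity_W_cmK", None)
        soil_kw = _take(soil_raw, {
            "bulk_density": "bulk_density", "theta": "theta",
            "x_mineral": "x_mineral", "x_organic": "x_organic",
        }, "soil")
        kw["soil"] = SoilComposition(**soil_kw)
        if cond is not None:
            kw["conductivity"] = float(cond)

        grid_kw = _take(raw.get("grid", {}), {
            "dz_cm": "dz", "depth_cm": "depth_total",
            "dt_out_s": "dt_out", "duration_s": "duration",
        }, "grid")
        kw["grid"] = SimulationGrid(**grid_kw)

        exp_kw = _take(raw.get("exposure", {}), {
            "window_s": "window", "thresholds_C": "thresholds",
            "lethal_peak_C": "lethal_peak_threshold",
        }, "exposure")
        kw["exposure"] = ExposureConfig(**exp_kw)

        synth_raw = dict(raw.get("synth", {}))
        synth_kw = _take(synth_raw, {
            "t50_C": "T50", "slope_C": "slope", "p_base": "p_base",
            "temp_sd_C": "temp_sd", "depth_jitter_sd_cm": "depth_jitter_sd",
            "replicates": "replicates", "biocrust_offset_C": "biocrust_offset_C",
            "probe_depths_cm": "probe_depths", "probe_reps": "probe_reps",
        }, "synth")
        surv_kw = {k: synth_kw.pop(k) for k in ("T50", "slope", "p_base")
                   if k in synth_kw}
        noise_kw = {k: synth_kw.pop(k) for k in ("temp_sd", "depth_jitter_sd")
                    if k in synth_kw}
        reps = synth_kw.pop("replicates", None)
        kw["survival"] = SurvivalModel(**surv_kw)
        seed = int(kw.get("seed", cls.seed))
        kw["noise"] = NoiseModel(seed=seed, **noise_kw)
        if reps is not None:
            kw["design"] = DesignSpec(replicates=int(reps))
        for k in ("biocrust_offset_C", "probe_depths", "probe_reps"):
            if k in synth_kw:
                kw[k] = synth_kw.pop(k)

        cfg = cls(**kw)
        for t in cfg.fire_treatments:
            cfg.forcing_params(float(t))  # validates
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if raw is not None and not isinstance(raw, dict):
            raise ParameterError("config file must contain a YAML mapping")
        return cls.from_dict(raw)
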