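"""Soil thermal parameterization.

Maps soil composition (mineral, organic, water volume fractions) to the
volumetric heat capacity via de Vries-style linear mixing, and bridges the
field's cm-based thermal conductivity to the SI diffusivity the solver uses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import ParameterError

# volumetric heat capacities of the constituents, MJ m^-3 K^-1
C_MINERAL = 1.92
C_ORGANIC = 2.51
C_WATER = 4.18


@dataclass(frozen=True)
class SoilComposition:
    """Volumetric soil composition (loam-like defaults).

    bulk_density is carried for provenance/reporting; the heat model only
    needs the volume fractions.
    """

    bulk_density: float = 1.40  # g cm^-3
    theta: float = 0.10  # volumetric water content, m^3 m^-3
    x_mineral: float = 0.45  # mineral volume fraction
    x_organic: float = 0.05  # organic-matter volume fraction

    def __post_init__(self) -> None:
        for name in ("bulk_density", "theta", "x_mineral", "x_organic"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ParameterError(f"{name} must be >= 0, got {v}")
        s = self.theta + self.x_mineral + self.x_organic
        if s > 1.0 + 1e-12:
            raise ParameterError(
                f"theta + x_mineral + x_organic = {s:.4f} exceeds 1"
            )


def volumetric_heat_capacity(comp: SoilComposition) -> float:
    """Volumetric heat capacity, MJ m⁻³ K⁻¹, by linear mixing of the
    mineral, organic and water constituents (air contributes negligibly)."""
    return C_MINERAL * comp.x_mineral + C_ORGANIC * comp.x_organic + C_WATER * comp.theta


@dataclass(frozen=True)
class ThermalProperties:
    """Bulk thermal properties of the column.

    conductivity is expressed in W cm⁻¹ K⁻¹ (the unit the field literature
    quotes for fire-heated soils; 0.03 W cm⁻¹ K⁻¹ = 3 W m⁻¹ K⁻¹);
    heat_capacity in MJ m⁻³ K⁻¹.
    """

    conductivity: float = 0.03  # W cm^-1 K^-1
    heat_capacity: float = 1.4075  # MJ m^-3 K^-1 (default composition)

    def __post_init__(self) -> None:
        if not math.isfinite(self.conductivity) or self.conductivity <= 0:
            raise ParameterError(f"conductivity must be > 0, got {self.conductivity}")
        if not math.isfinite(self.heat_capacity) or self.heat_capacity <= 0:
            raise ParameterError(f"heat_capacity must be > 0, got {self.heat_capacity}")

    @classmethod
    def from_composition(
        cls, comp: SoilComposition, conductivity: float = 0.03
    ) -> "ThermalProperties":
        return cls(conductivity=conductivity,
                   heat_capacity=volumetric_heat_capacity(comp))

    @property
    def diffusivity(self) -> float:
        """Thermal diffusivity α, m² s⁻¹."""
        return thermal_diffusivity(self)


def thermal_diffusivity(props: ThermalProperties) -> float:
    """α = k / C in SI units.

    conductivity (W cm⁻¹ K⁻¹) × 100 → W m⁻¹ K⁻¹;
    heat_capacity (MJ m⁻³ K⁻¹) × 10⁶ → J m⁻³ K⁻¹.
    """
    return (props.conductivity * 100.0) / (props.heat_capacity * 1.0e6)
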