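"""Culture-plate presence/absence statistics.

The survival readout of the burn experiment is whether colony-forming
units (CFUs) grew on a BG-11 plate inoculated from each centimetre of each
soil core: a grid of (cover × fire temperature × depth × replicate) binary
outcomes. This module summarizes growth fractions, runs the Pearson
chi-squared homogeneity tests (by fire temperature, by cover), and locates
the shallowest depth with any growth per treatment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, DegenerateDataError, ParameterError

GRID_COLUMNS = ["cover", "fire_temp", "depth_cm", "replicate", "growth"]

COVERS = ("bare", "biocrust")
FIRE_LEVELS = ("control", "450", "600")


@dataclass(frozen=True)
class DesignSpec:
    """Factorial design of the burn experiment: 2 covers × 3 fire levels ×
    10 depths × 6 replicates = 360 plates by default."""

    covers: Tuple[str, ...] = COVERS
    fire_levels: Tuple[str, ...] = FIRE_LEVELS
    depths: Tuple[int, ...] = tuple(range(1, 11))
    replicates: int = 6

    def __post_init__(self) -> None:
        if self.replicates < 0:
            raise ParameterError(f"replicates must be >= 0, got {self.replicates}")
        if any(int(d) != d or not (1 <= d <= 10) for d in self.depths):
            raise ParameterError("depths must be whole centimetres in 1..10")

    @property
    def total(self) -> int:
        return (len(self.covers) * len(self.fire_levels)
                * len(self.depths) * self.replicates)


def validate_grid(grid: pd.DataFrame) -> pd.DataFrame:
    """Check CFU grid structure; returns the frame with canonical dtypes."""
    missing = set(GRID_COLUMNS) - set(grid.columns)
    if missing:
        raise DataError(f"CFU grid missing columns: {sorted(missing)}")
    if grid.empty:
        raise DataError("CFU grid is empty")
    g = grid.copy()
    g["fire_temp"] = g["fire_temp"].astype(str)
    g["depth_cm"] = g["depth_cm"].astype(int)
    if not g["depth_cm"].between(1, 10).all():
        raise DataError("depth_cm must be integral in [1, 10]")
    if not g["growth"].isin([0, 1]).all():
        raise DataError("growth must be 0 or 1")
    keys = g[["cover", "fire_temp", "depth_cm", "replicate"]]
    if keys.duplicated().any():
        raise DataError("duplicate (cover, fire_temp, depth, replicate) keys")
    return g


def read_cfu_csv(path) -> pd.DataFrame:
    return validate_grid(pd.read_csv(path, dtype={"fire_temp": str}))


def write_cfu_csv(grid: pd.DataFrame, path) -> None:
    validate_grid(grid).to_csv(path, index=False)


def growth_summary(grid: pd.DataFrame) -> dict:
    """Growth fractions overall, per treatment (cover × fire level) and per
    depth. Percentages are reported to one decimal place."""
    g = validate_grid(grid)
    n_total = len(g)
    n_pos = int(g["growth"].sum())
    per_treatment = (
        g.groupby(["cover", "fire_temp"])["growth"].mean().to_dict()
    )
    per_depth = g.groupby("depth_cm")["growth"].mean().to_dict()
    return {
        "n_total": n_total,
        "n_positive": n_pos,
        "overall_fraction": n_pos / n_total,
        "overall_percent": round(100.0 * n_pos / n_total, 1),
        "per_treatment": {f"{c}:{f}": v for (c, f), v in per_treatment.items()},
        "per_depth": {int(d): v for d, v in per_depth.items()},
    }


def contingency_table(grid: pd.DataFrame, factor: str) -> pd.DataFrame:
    """factor levels × {growth, no growth} count table, pooled over the
    other design factors."""
    if factor not in ("fire_temp", "cover"):
        raise ParameterError(f"factor must be 'fire_temp' or 'cover', got {factor!r}")
    g = validate_grid(grid)
    tab = pd.crosstab(g[factor], g["growth"]).reindex(columns=[1, 0], fill_value=0)
    tab.columns = ["growth", "no_growth"]
    return tab


def chi_squared_presence(grid: pd.DataFrame, factor: str) -> dict:
    """Pearson chi-squared test (no continuity correction) of growth
    homogeneity across the levels of `factor`."""
    tab = contingency_table(grid, factor)
    arr = tab.to_numpy()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise DegenerateDataError(
            f"zero marginal total in the {factor} contingency table"
        )
    chi2, p, dof, _ = stats.chi2_contingency(arr, correction=False)
    return {"chi2": float(chi2), "dof": int(dof), "p": float(p),
            "table": tab.to_dict()}


def min_growth_depth(grid: pd.DataFrame, cover: str,
                     fire_temp: str) -> Optional[int]:
    """Shallowest depth with at least one positive replicate for the given
    treatment; None if the treatment grew nowhere."""
    g = validate_grid(grid)
    sub = g[(g["cover"] == cover) & (g["fire_temp"] == str(fire_temp))]
    if sub.empty:
        raise KeyError(f"treatment ({cover!r}, {fire_temp!r}) not in grid")
    pos = sub.loc[sub["growth"] == 1, "depth_cm"]
    return int(pos.min()) if not pos.empty else None
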