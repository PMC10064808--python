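"""Depth-wise heat-exposure metrics and mortality-zone classification.

Reduces a simulated temperature field to per-depth summaries (peak, time of
peak, windowed mean, time and degree-seconds above thresholds) and classifies
the heat mortality zone: the surface-anchored depth interval within which
peak temperature reaches a lethal threshold for microbial survival.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, ParameterError
from .solver import TemperatureField

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExposureConfig:
    """window: averaging window from t = 0, s (the study summarizes the
    first 30 min); thresholds: ascending list of exposure thresholds, °C;
    lethal_peak_threshold: peak temperature defining the mortality zone, °C.
    """

    window: float = 1800.0
    thresholds: Sequence[float] = (50.0, 60.0, 100.0)
    lethal_peak_threshold: float = 100.0

    def __post_init__(self) -> None:
        if not math.isfinite(self.window) or self.window <= 0:
            raise ParameterError(f"window must be > 0, got {self.window}")
        th = tuple(float(x) for x in self.thresholds)
        if list(th) != sorted(th):
            raise ParameterError(f"thresholds must be sorted ascending, got {th}")
        object.__setattr__(self, "thresholds", th)
        if self.lethal_peak_threshold <= 0:
            raise ParameterError("lethal_peak_threshold must be > 0")


@dataclass
class ExposureSummary:
    """Per-depth exposure metrics.

    per_depth: DataFrame indexed by depth_cm with columns peak_C, t_peak_s,
    mean_window_C, t_above_<θ>_s and degsec_above_<θ> for each threshold θ.
    per_node: same metrics on the full grid (optional).
    """

    per_depth: pd.DataFrame
    config: ExposureConfig
    window_used: float
    per_node: Optional[pd.DataFrame] = None

    def to_csv(self, path) -> None:
        self.per_depth.to_csv(path)

    @property
    def peaks(self) -> pd.Series:
        return self.per_depth["peak_C"]


def _metrics_at(series: np.ndarray, times: np.ndarray, window: float,
                thresholds: Sequence[float]) -> dict:
    dt = np.diff(times)
    # sample weights for time-integral metrics: trailing interval per sample
    w = np.concatenate((dt, dt[-1:])) if dt.size else np.array([1.0])
    i_peak = int(np.argmax(series))
    in_win = times <= window
    row = {
        "peak_C": float(series[i_peak]),
        "t_peak_s": float(times[i_peak]),
        "mean_window_C": float(series[in_win].mean()),
    }
    for th in thresholds:
        above = series > th
        key = f"{th:g}"
        row[f"t_above_{key}_s"] = float(w[above].sum())
        row[f"degsec_above_{key}"] = float((w[above] * (series[above] - th)).sum())
    return row


def summarize_exposure(
    field: TemperatureField,
    cfg: ExposureConfig = ExposureConfig(),
    depths_cm: Optional[Sequence[float]] = None,
    include_nodes: bool = False,
) -> ExposureSummary:
    """Compute per-depth exposure metrics.

    Metrics are computed at whole-centimetre grid nodes 1-10 cm by default
    (peak and threshold times over the full record; the mean over the
    configured window, truncated to the record length with a warning).
    """
    if field.temps.size == 0:
        raise DataError("empty temperature field")
    window = cfg.window
    if window > field.times[-1]:
        log.warning(
            "analysis window %.0f s exceeds the %.0f s record; truncating",
            window, field.times[-1],
        )
        window = float(field.times[-1])
    if depths_cm is None:
        dmax = int(math.floor(field.depths[-1] + 1e-9))
        depths_cm = [d for d in range(1, 11) if d <= dmax]

    rows = {}
    for d in depths_cm:
        series = field.temps[field.depth_index(d)]
        rows[float(d)] = _metrics_at(series, field.times, window, cfg.thresholds)
    per_depth = pd.DataFrame.from_dict(rows, orient="index")
    per_depth.index.name = "depth_cm"

    per_node = None
    if include_nodes:
        nrows = {
            float(z): _metrics_at(field.temps[i], field.times, window, cfg.thresholds)
            for i, z in enumerate(field.depths)
        }
        per_node = pd.DataFrame.from_dict(nrows, orient="index")
        per_node.index.name = "depth_cm"

    return ExposureSummary(per_depth=per_depth, config=cfg,
                           window_used=window, per_node=per_node)


@dataclass(frozen=True)
class MortalityZone:
    """Surface-anchored depth interval [0, deepest_cm] in which peak
    temperature reached the lethal threshold; empty if no depth qualified."""

    deepest_cm: Optional[float]
    threshold_C: float
    qualifying_depths: tuple = ()
    gaps: tuple = ()

    @property
    def empty(self) -> bool:
        return self.deepest_cm is None

    def contains(self, depth_cm: float) -> bool:
        return (not self.empty) and 0 <= depth_cm <= self.deepest_cm

    def as_dict(self) -> dict:
        return {
            "deepest_cm": self.deepest_cm,
            "threshold_C": self.threshold_C,
            "qualifying_depths_cm": list(self.qualifying_depths),
            "gaps_cm": list(self.gaps),
            "empty": self.empty,
        }


def mortality_zone(
    summary: ExposureSummary, lethal_peak_threshold: Optional[float] = None
) -> MortalityZone:
    """Classify the heat mortality zone from per-depth peak temperatures.

    The zone is [0, D] where D is the deepest reported depth whose peak
    temperature meets or exceeds the threshold. Sub-threshold depths lying
    above D (possible only under exotic forcings) are reported as gaps with
    a warning; they do not shrink the zone.
    """
    th = (summary.config.lethal_peak_threshold
          if lethal_peak_threshold is None else float(lethal_peak_threshold))
    peaks = summary.per_depth["peak_C"]
    qualifying = peaks.index[peaks >= th].tolist()
    if not qualifying:
        return MortalityZone(deepest_cm=None, threshold_C=th)
    deepest = max(qualifying)
    gaps = [d for d in peaks.index if d < deepest and d not in qualifying]
    if gaps:
        log.warning("non-contiguous mortality zone: sub-threshold depths %s "
                    "above the deepest qualifying depth %.1f cm", gaps, deepest)
    return MortalityZone(deepest_cm=float(deepest), threshold_C=th,
                         qualifying_depths=tuple(qualifying), gaps=tuple(gaps))
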