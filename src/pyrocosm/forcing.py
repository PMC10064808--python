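"""Surface fire forcing curve: the prescribed temperature time series used
as the top boundary condition of the soil heat model.

A burn is described by three phases — a linear ramp from the basal
temperature to the fire maximum, a hold at the maximum, and an exponential
decay back toward basal. The decay rate is fixed so that the residual rise
above basal is exactly 1% of the total rise at the end of the decay phase,
which yields the right-skewed shape typical of a surface fire (cooling is
much slower than ignition).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParameterError

#: Fraction of the rise above basal remaining at the end of the decay phase.
DECAY_RESIDUAL = 0.01


@dataclass(frozen=True)
class FireForcingParams:
    """Parameters of the ramp/hold/decay surface forcing.

    Parameters
    ----------
    T_basal : float
        Ambient (pre-fire) surface temperature, °C.
    T_max : float
        Fire maximum surface temperature, °C. The study's low- and
        high-severity burns use 450 and 600 °C.
    t_ramp, t_hold, t_decay : float
        Durations of the three phases, s.
    dt : float
        Sampling interval of the emitted curve, s.
    """

    T_basal: float = 20.0
    T_max: float = 600.0
    t_ramp: float = 600.0
    t_hold: float = 60.0
    t_decay: float = 1800.0
    dt: float = 1.0

    def __post_init__(self) -> None:
        if not math.isfinite(self.T_basal):
            raise ParameterError("T_basal must be finite")
        if not math.isfinite(self.T_max) or self.T_max < self.T_basal:
            raise ParameterError(
                f"T_max ({self.T_max}) must be finite and >= T_basal ({self.T_basal})"
            )
        for name in ("t_ramp", "t_hold", "t_decay"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ParameterError(f"{name} must be a non-negative duration, got {v}")
        if not math.isfinite(self.dt) or self.dt <= 0:
            raise ParameterError(f"dt must be > 0, got {self.dt}")

    @property
    def total_duration(self) -> float:
        """Total curve duration, s."""
        return self.t_ramp + self.t_hold + self.t_decay

    @property
    def decay_rate(self) -> float:
        """Exponential decay rate k (s⁻¹) with residual DECAY_RESIDUAL at t_decay."""
        if self.t_decay == 0:
            return math.inf
        return math.log(1.0 / DECAY_RESIDUAL) / self.t_decay


@dataclass(frozen=True)
class ForcingCurve:
    """Sampled surface forcing: uniformly spaced times (plus phase
    boundaries, if those are not sample points) and temperatures in °C."""

    times: np.ndarray
    temps: np.ndarray
    params: FireForcingParams = field(default=FireForcingParams())

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "temps", np.asarray(self.temps, dtype=float))
        if self.times.shape != self.temps.shape:
            raise ParameterError("times and temps must have equal length")

    @property
    def duration(self) -> float:
        return float(self.times[-1])

    def at(self, t) -> np.ndarray:
        """Forcing at arbitrary times; clamped to the final value past the end."""
        return np.interp(t, self.times, self.temps)

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_s": self.times, "temp_C": self.temps}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path) -> "ForcingCurve":
        df = pd.read_csv(path)
        return cls(df["time_s"].to_numpy(float), df["temp_C"].to_numpy(float))


def evaluate_forcing(params: FireForcingParams, t) -> np.ndarray:
    """Evaluate the piecewise ramp/hold/decay law at arbitrary times.

    The law is a pure function of t, so refining the sampling grid leaves
    values at shared time points bit-identical.
    """
    t = np.asarray(t, dtype=float)
    rise = params.T_max - params.T_basal
    out = np.full(t.shape, params.T_basal, dtype=float)

    ramp_end = params.t_ramp
    hold_end = params.t_ramp + params.t_hold

    in_ramp = t < ramp_end
    if params.t_ramp > 0:
        out[in_ramp] = params.T_basal + rise * t[in_ramp] / params.t_ramp
    in_hold = (t >= ramp_end) & (t <= hold_end)
    out[in_hold] = params.T_max
    in_decay = t > hold_end
    if np.any(in_decay):
        if params.t_decay == 0:
            out[in_decay] = params.T_basal
        else:
            out[in_decay] = params.T_basal + rise * np.exp(
                -params.decay_rate * (t[in_decay] - hold_end)
            )
    return out


def build_forcing_curve(params: FireForcingParams) -> ForcingCurve:
    """Sample the forcing law at dt spacing over the full burn.

    Samples are placed at every multiple of dt in [0, total]; the two phase
    boundaries and the end point are inserted when they are not already
    sample points, so the curve attains T_max exactly at t_ramp and holds
    it through t_ramp + t_hold.
    """
    total = params.total_duration
    base = np.arange(0.0, total + 0.5 * params.dt, params.dt)
    if base[-1] > total:  # guard float spill past the end
        base = base[:-1]
    anchors = np.array([params.t_ramp, params.t_ramp + params.t_hold, total])
    times = np.union1d(base, anchors)
    # collapse float near-duplicates introduced by union1d
    keep = np.concatenate(([True], np.diff(times) > 1e-9 * max(params.dt, 1.0)))
    times = times[keep]

    temps = evaluate_forcing(params, times)
    # pin the hold phase to T_max exactly (no float drift from the ramp)
    on_hold = (times >= params.t_ramp) & (times <= params.t_ramp + params.t_hold)
    temps[on_hold] = params.T_max
    return ForcingCurve(times=times, temps=temps, params=params)
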