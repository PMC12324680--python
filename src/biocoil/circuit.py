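"""Electrical behavior of the coil pair: RL step response, switching-rate
limit and impedance matching for AC drive.

The winding is modelled as a series RL branch.  The measured toggle time of
the physical supply (current up to target and back to zero) is treated as an
experimental input, not something derived from L/R — in practice it is
dominated by the power supply, not by the coil time constant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .coil_geometry import CoilPair

__all__ = [
    "ElectricalParams",
    "SwitchingAnalysis",
    "step_current",
    "time_to_fraction",
    "max_switch_frequency",
    "impedance",
    "voltage_for_current",
    "switching_analysis",
    "estimate_inductance",
]


@dataclass(frozen=True)
class ElectricalParams:
    """Series RL model: resistance R (ohm), inductance L (H), drive V (volt)."""

    R: float
    L: float
    V: float

    def __post_init__(self) -> None:
        if self.R <= 0:
            raise ValueError(f"R must be > 0, got {self.R}")
        if self.L < 0:
            raise ValueError(f"L must be >= 0, got {self.L}")

    @property
    def tau(self) -> float:
        """Time constant L/R, s."""
        return self.L / self.R

    @property
    def steady_current(self) -> float:
        """Asymptotic current V/R, A."""
        return self.V / self.R


@dataclass(frozen=True)
class SwitchingAnalysis:
    """Transient summary: tau = L/R, rise time to ``rise_fraction`` of V/R,
    the measured full on+off toggle time, and the largest integer switching
    frequency whose period still fits the toggle."""

    tau: float
    t_rise: float
    rise_fraction: float
    toggle_time: float
    f_max: int

    def to_dict(self) -> dict:
        return {
            "tau_us": self.tau * 1e6,
            "t_rise_ms": self.t_rise * 1e3,
            "rise_fraction": self.rise_fraction,
            "toggle_time_ms": self.toggle_time * 1e3,
            "f_max_hz": self.f_max,
        }


def step_current(params: ElectricalParams, t):
    """Current (A) at time t (s) after a voltage step: (V/R)(1 - e^{-tR/L}).

    Vectorized over t; t must be >= 0.  L = 0 gives the instantaneous V/R.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    if params.L == 0:
        out = np.full(t.shape, params.steady_current)
    else:
        out = params.steady_current * (1.0 - np.exp(-t / params.tau))
    return float(out) if out.ndim == 0 else out


def time_to_fraction(params: ElectricalParams, frac: float) -> float:
    """Time (s) for the step response to reach ``frac`` of V/R:
    -(L/R) ln(1 - frac), with frac strictly inside (0, 1)."""
    if not 0.0 < frac < 1.0:
        raise ValueError(f"frac must be in (0, 1), got {frac}")
    return -params.tau * math.log1p(-frac)


def max_switch_frequency(toggle_time: float) -> int:
    """Largest whole-number switching frequency (Hz) whose period is at
    least ``toggle_time`` (s): floor(1 / toggle_time)."""
    if toggle_time <= 0:
        raise ValueError(f"toggle_time must be > 0, got {toggle_time}")
    return int(math.floor(1.0 / toggle_time))


def impedance(params: ElectricalParams, f: float) -> float:
    """Series-RL impedance magnitude |Z| = sqrt(R^2 + (2 pi f L)^2), ohm."""
    if f < 0:
        raise ValueError(f"f must be >= 0, got {f}")
    return math.hypot(params.R, 2.0 * math.pi * f * params.L)


def voltage_for_current(params: ElectricalParams, i: float, f: float) -> float:
    """Drive voltage needed for current amplitude ``i`` at frequency ``f``
    (impedance matching): V = i |Z|."""
    return i * impedance(params, f)


def switching_analysis(
    params: ElectricalParams, toggle_time: float, rise_fraction: float = 0.99
) -> SwitchingAnalysis:
    """Assemble the transient summary for a measured toggle time."""
    return SwitchingAnalysis(
        tau=params.tau,
        t_rise=time_to_fraction(params, rise_fraction),
        rise_fraction=rise_fraction,
        toggle_time=toggle_time,
        f_max=max_switch_frequency(toggle_time),
    )


def _wheeler_multilayer(mean_radius: float, length: float, depth: float, n_turns: int) -> float:
    """Wheeler's multilayer air-core estimate, henry.

    L [uH] = 31.5 a^2 N^2 / (6a + 9l + 10b) with mean radius a, winding
    length l and depth b in meters (the 1928 inch formula rescaled).
    Accurate to a few percent for squat multilayer coils; advisory only.
    """
    return 31.5 * mean_radius**2 * n_turns**2 / (
        6.0 * mean_radius + 9.0 * length + 10.0 * depth
    ) * 1e-6


def _coaxial_loop_mutual(a: float, b: float, d: float) -> float:
    """Maxwell's mutual inductance of two coaxial loops (radii a, b,
    axial separation d), henry."""
    from scipy.special import ellipe, ellipk

    m = 4.0 * a * b / ((a + b) ** 2 + d**2)  # m = k^2
    k = math.sqrt(m)
    mu0 = 4e-7 * math.pi
    return mu0 * math.sqrt(a * b) * ((2.0 / k - k) * ellipk(m) - (2.0 / k) * ellipe(m))


def estimate_inductance(pair: CoilPair, configuration: str = "winding") -> float:
    """Advisory inductance estimate (H), good to tens of percent; never a
    substitute for a measured value.

    ``configuration="winding"`` returns Wheeler's multilayer estimate for one
    winding; ``"series"`` returns the series pair 2(L1 + M) with the mutual
    term from Maxwell's coaxial-loop formula at the mean radius and the
    centroid spacing.
    """
    w = pair.winding
    depth = w.n_layers * w.wire.diameter
    L1 = _wheeler_multilayer(w.mean_radius, w.axial_width, depth, w.n_turns)
    if configuration == "winding":
        return L1
    if configuration == "series":
        M = w.n_turns**2 * _coaxial_loop_mutual(w.mean_radius, w.mean_radius, pair.spacing)
        return 2.0 * (L1 + M)
    raise ValueError(f"configuration must be 'winding' or 'series', got {configuration!r}")
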