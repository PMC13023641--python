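"""Thermal SAR dosimetry from temperature–time curves.

Under a lumped heat balance ``m c dT/dt = P_abs`` (early exposure, before
conduction and boundary losses matter) the effective absorbed power per
unit mass follows directly from the initial temperature slope:

    SAR_eff = P_abs / m = c * dT/dt.

This module estimates that slope from sampled rise curves, propagates the
linear dependence on the assumed heat capacity (sensitivity analysis),
detects thermal stabilization (|dT/dt| < 1e-4 K/s sustained over a
continuous 10-minute window by default), and evaluates a conservative
bound on how far the internal temperature peak can exceed the measured
surface rise: for uniform volumetric heating rho*SAR in a wall of
half-thickness L and thermal conductivity k,

    dT_max - dT_s  <=  rho * SAR_eff * L^2 / (2 k),
    R_T = dT_max / dT_s  <=  1 + rho * SAR_eff * L^2 / (2 k dT_s),

the slab steady-state closed form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .bioheat import MaterialThermal

__all__ = [
    "SlopeFit",
    "SarEstimate",
    "SensitivityResult",
    "PeakSurfaceBound",
    "initial_slope",
    "estimate_sar_eff",
    "sensitivity",
    "stabilization_time",
    "peak_surface_bound",
    "round_sig",
]

#: Stabilization thresholds: sustained |dT/dt| below 1e-4 K/s over 600 s.
STABILIZATION_RATE_K_PER_S = 1e-4
STABILIZATION_WINDOW_S = 600.0

#: Default slope-fit window: the first 20 minutes of exposure, within
#: which the rise is approximately linear (short-time lumped limit).
DEFAULT_SLOPE_WINDOW_S = (0.0, 1200.0)


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (display convention)."""
    if x == 0:
        return 0.0
    return round(x, sig - 1 - int(math.floor(math.log10(abs(x)))))


@dataclass(frozen=True)
class SlopeFit:
    """Initial-rise slope with fit diagnostics."""

    slope: float            # K/s
    intercept: float        # K
    residual_rms: float     # K, RMS of fit residuals
    n_points: int
    window: tuple           # (t_start, t_end), s


def initial_slope(times, delta_t, window: tuple = DEFAULT_SLOPE_WINDOW_S,
                  mode: str = "ols") -> SlopeFit:
    """Temperature rise rate over the initial (approximately linear) window.

    Parameters
    ----------
    times, delta_t : array_like
        Sample times (s) and temperature rises (K).
    window : (t_start, t_end)
        Samples with t_start <= t <= t_end enter the fit.
    mode : {"ols", "two_point"}
        Ordinary least squares over the window (default), or the simple
        rise-over-run between the first and last sample in the window.

    Raises
    ------
    ValueError
        Fewer than two samples in the window, or zero time span.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(delta_t, dtype=float)
    if t.shape != y.shape:
        raise ValueError("times and delta_t must have matching shapes")
    sel = (t >= window[0]) & (t <= window[1])
    t_w, y_w = t[sel], y[sel]
    if len(t_w) < 2:
        raise ValueError(f"need >= 2 samples in window {window}, got {len(t_w)}")
    if t_w.max() == t_w.min():
        raise ValueError("zero time span in fit window")
    if mode == "two_point":
        slope = (y_w[-1] - y_w[0]) / (t_w[-1] - t_w[0])
        intercept = y_w[0] - slope * t_w[0]
    elif mode == "ols":
        slope, intercept = np.polyfit(t_w, y_w, 1)
    else:
        raise ValueError("mode must be 'ols' or 'two_point'")
    resid = y_w - (slope * t_w + intercept)
    return SlopeFit(slope=float(slope), intercept=float(intercept),
                    residual_rms=float(np.sqrt(np.mean(resid**2))),
                    n_points=len(t_w), window=(float(window[0]), float(window[1])))


@dataclass(frozen=True)
class SarEstimate:
    """Thermally inferred effective SAR with its provenance."""

    slope: float                        # K/s
    heat_capacity: float                # J/(kg K)
    sar_eff: float                      # W/kg, = heat_capacity * slope
    window: tuple | None = None         # (t_start, t_end) used for the slope
    sensitivity_range: tuple | None = None  # (low, high) W/kg
    cooling: bool = False               # slope was negative

    @property
    def display(self) -> float:
        """Two-significant-figure reporting form."""
        return round_sig(self.sar_eff, 2)


def estimate_sar_eff(slope: float, heat_capacity: float,
                     window: tuple | None = None) -> SarEstimate:
    """SAR_eff = c * dT/dt from the lumped heat balance.

    A negative slope yields a (negative) estimate flagged as cooling
    rather than an error: reference or control channels legitimately
    drift downwards.
    """
    if heat_capacity <= 0:
        raise ValueError("heat capacity must be positive")
    return SarEstimate(slope=float(slope), heat_capacity=float(heat_capacity),
                       sar_eff=float(heat_capacity * slope), window=window,
                       cooling=slope < 0)


@dataclass(frozen=True)
class SensitivityResult:
    """Linear propagation of heat-capacity uncertainty into SAR_eff."""

    percent_max_deviation: float
    sar_range: tuple        # (low, high) W/kg
    c_nominal: float
    c_interval: tuple


def sensitivity(slope: float, c_nominal: float,
                c_interval: tuple) -> SensitivityResult:
    """Maximum relative SAR_eff deviation over a heat-capacity interval.

    Because SAR_eff is exactly linear in c, the relative SAR deviation
    equals the relative capacity deviation:
    ``max(|hi - c|, |c - lo|) / c * 100``.
    """
    lo, hi = c_interval
    if not (lo <= c_nominal <= hi):
        raise ValueError(f"nominal capacity {c_nominal} outside interval {c_interval}")
    pct = max(hi - c_nominal, c_nominal - lo) / c_nominal * 100.0
    return SensitivityResult(percent_max_deviation=float(pct),
                             sar_range=(float(lo * slope), float(hi * slope)),
                             c_nominal=float(c_nominal),
                             c_interval=(float(lo), float(hi)))


def stabilization_time(times, delta_t,
                       rate_threshold: float = STABILIZATION_RATE_K_PER_S,
                       window: float = STABILIZATION_WINDOW_S) -> float | None:
    """Earliest time from which |dT/dt| stays below threshold for a window.

    Rates are forward differences between consecutive samples at the
    native sampling.  A window starting at ``t`` is satisfied when every
    sampling interval contained in ``[t, t + window]`` has
    ``|rate| < rate_threshold`` (strict; a rate exactly at the threshold
    does not count).  Returns ``None`` when no window qualifies.

    Raises
    ------
    ValueError
        If the series spans less than one window.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(delta_t, dtype=float)
    if t[-1] - t[0] < window:
        raise ValueError("series shorter than the stabilization window")
    rates = np.diff(y) / np.diff(t)
    ok = np.abs(rates) < rate_threshold
    for i in range(len(t)):
        j = np.searchsorted(t, t[i] + window)
        if j > len(t) - 1 and t[-1] - t[i] < window:
            break
        j = min(j, len(t) - 1)
        if t[j] - t[i] >= window and np.all(ok[i:j]):
            return float(t[i])
    return None


@dataclass(frozen=True)
class PeakSurfaceBound:
    """Conservative bound on internal peak vs IR-measured surface rise."""

    sar_eff: float          # W/kg
    half_thickness: float   # m
    surface_rise: float     # K
    excess_bound: float     # K, dT_max - dT_s upper bound
    ratio: float            # R_T upper bound

    def __post_init__(self) -> None:
        assert self.excess_bound >= 0


def peak_surface_bound(material: MaterialThermal, sar_eff: float,
                       half_thickness: float,
                       surface_rise: float) -> PeakSurfaceBound:
    """Slab steady-state bound on the internal temperature excess.

    ``excess = rho * SAR_eff * L^2 / (2 k)`` and
    ``R_T = 1 + excess / dT_s``.  The excess scales quadratically with
    the half-thickness and linearly with rho/k and SAR_eff.
    """
    if half_thickness <= 0:
        raise ValueError("half thickness must be positive")
    if surface_rise <= 0:
        raise ValueError("surface rise must be positive (ratio undefined)")
    if sar_eff < 0:
        raise ValueError("SAR_eff must be >= 0")
    excess = (material.density * sar_eff * half_thickness**2
              / (2.0 * material.thermal_conductivity))
    return PeakSurfaceBound(sar_eff=float(sar_eff),
                            half_thickness=float(half_thickness),
                            surface_rise=float(surface_rise),
                            excess_bound=float(excess),
                            ratio=float(1.0 + excess / surface_rise))
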