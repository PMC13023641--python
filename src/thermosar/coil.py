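"""Conical coil geometry and electrical excitation.

The stimulation coil is a conductor wound uniformly on the frustum of a
cone.  A point on the winding is addressed by its slant coordinate ``s``
(distance from the cone apex along the generatrix); the azimuthal phase
advances linearly with ``s`` at the winding rate ``k = 2*pi*N / L`` where
``L = s2 - s1`` is the slant extent of the wound region and ``N`` the
number of turns.  With the apex at the origin and the symmetry axis along
+z, the winding path is::

    r(s) = (s sin(a) cos(ks),  s sin(a) sin(ks),  s cos(a))

with ``a`` the cone half-angle.  The drive is a PWM current; for an ideal
unipolar square wave of duty ``D`` the peak current is ``I_rms / sqrt(D)``.
An idealized RL step response models the switching stage's current
transient.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "CoilGeometry",
    "ExcitationWaveform",
    "RLDrive",
    "helix_point",
    "winding_rate",
    "waveform_currents",
    "rl_step_current",
    "DEFAULT_COIL",
]


@dataclass(frozen=True)
class CoilGeometry:
    """Uniformly wound conical coil.

    Parameters
    ----------
    half_angle : float
        Cone half-angle between axis and generatrix, radians, in (0, pi/2].
    s1, s2 : float
        Slant-coordinate bounds of the wound region, metres, 0 <= s1 < s2.
    n_turns : int
        Number of turns distributed uniformly over [s1, s2].
    current : float
        Drive current (RMS) used for field computation, amperes.
    """

    half_angle: float
    s1: float
    s2: float
    n_turns: int
    current: float = 0.75

    def __post_init__(self) -> None:
        if not (0.0 < self.half_angle <= math.pi / 2):
            raise ValueError(f"half_angle must be in (0, pi/2], got {self.half_angle}")
        if not (0.0 <= self.s1 < self.s2):
            raise ValueError(f"need 0 <= s1 < s2, got s1={self.s1}, s2={self.s2}")
        if self.n_turns < 1:
            raise ValueError(f"n_turns must be >= 1, got {self.n_turns}")

    @property
    def slant_length(self) -> float:
        """Slant extent L = s2 - s1 of the wound region, metres."""
        return self.s2 - self.s1

    @property
    def winding_rate(self) -> float:
        """Azimuthal phase advance per unit slant length, rad/m."""
        return 2.0 * math.pi * self.n_turns / self.slant_length


#: Fixture geometry used by tests and examples.  The fabricated coil's
#: half-angle and slant bounds are not part of the public record (only the
#: turn count and drive are), so field magnitudes computed with it are
#: fixture-dependent.
DEFAULT_COIL = CoilGeometry(half_angle=math.pi / 4, s1=0.02, s2=0.12, n_turns=40,
                            current=0.75)


def winding_rate(geometry: CoilGeometry) -> float:
    """Angular winding rate k = 2*pi*N/L in rad/m."""
    return geometry.winding_rate


def helix_point(geometry: CoilGeometry, s):
    """Position of the winding at slant coordinate ``s``.

    Parameters
    ----------
    geometry : CoilGeometry
    s : float or array_like
        Slant coordinate(s), must lie within [s1, s2].

    Returns
    -------
    numpy.ndarray
        Position(s) in metres; shape ``(3,)`` for scalar ``s``, else
        ``s.shape + (3,)``.

    Raises
    ------
    ValueError
        If any ``s`` lies outside the wound region.
    """
    s_arr = np.asarray(s, dtype=float)
    if np.any(s_arr < geometry.s1) or np.any(s_arr > geometry.s2):
        raise ValueError(
            f"slant coordinate outside winding range [{geometry.s1}, {geometry.s2}]"
        )
    k = geometry.winding_rate
    sin_a = math.sin(geometry.half_angle)
    cos_a = math.cos(geometry.half_angle)
    phase = k * s_arr
    pts = np.stack(
        [s_arr * sin_a * np.cos(phase), s_arr * sin_a * np.sin(phase), s_arr * cos_a],
        axis=-1,
    )
    return pts if s_arr.ndim else pts.reshape(3)


@dataclass(frozen=True)
class ExcitationWaveform:
    """PWM current drive: repetition rate, duty cycle and RMS amplitude."""

    frequency: float
    duty: float
    rms_current: float
    rise_time: float = 0.0
    polarity: str = "unipolar"

    def __post_init__(self) -> None:
        if self.frequency <= 0:
            raise ValueError("frequency must be positive")
        if not (0.0 < self.duty < 1.0):
            raise ValueError("duty must lie in (0, 1)")
        if self.rms_current <= 0:
            raise ValueError("rms_current must be positive")
        if self.rise_time < 0:
            raise ValueError("rise_time must be >= 0")
        if self.polarity not in ("unipolar", "bipolar"):
            raise ValueError("polarity must be 'unipolar' or 'bipolar'")

    @property
    def period(self) -> float:
        return 1.0 / self.frequency


def waveform_currents(waveform: ExcitationWaveform) -> tuple[float, float]:
    """Peak and RMS current of an ideal square drive.

    For a unipolar square wave that is on a fraction ``D`` of each period,
    ``I_rms^2 = D * I_peak^2`` so ``I_peak = I_rms / sqrt(D)``.  A bipolar
    square wave conducts the whole period, hence peak equals RMS.
    """
    if waveform.polarity == "unipolar":
        peak = waveform.rms_current / math.sqrt(waveform.duty)
    else:
        peak = waveform.rms_current
    return peak, waveform.rms_current


@dataclass(frozen=True)
class RLDrive:
    """Idealized RL model of the switching stage (supply, coil L, series R)."""

    supply_voltage: float
    inductance: float
    series_resistance: float

    def __post_init__(self) -> None:
        if min(self.supply_voltage, self.inductance, self.series_resistance) <= 0:
            raise ValueError("RLDrive parameters must all be strictly positive")

    @property
    def time_constant(self) -> float:
        return self.inductance / self.series_resistance

    @property
    def steady_current(self) -> float:
        return self.supply_voltage / self.series_resistance


def rl_step_current(drive: RLDrive, t, branch: str = "rise", i0: float | None = None):
    """Current of the RL network after a step, at time(s) ``t`` >= 0.

    Rise branch: ``i(t) = (V/R) (1 - exp(-t R/L))``; decay branch:
    ``i(t) = i0 exp(-t R/L)`` with ``i0`` defaulting to the steady current.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time must be nonnegative")
    tau = drive.time_constant
    if branch == "rise":
        out = drive.steady_current * (1.0 - np.exp(-t_arr / tau))
    elif branch == "decay":
        start = drive.steady_current if i0 is None else i0
        out = start * np.exp(-t_arr / tau)
    else:
        raise ValueError("branch must be 'rise' or 'decay'")
    return out if t_arr.ndim else float(out)
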