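"""Bioheat transport with SAR-derived volumetric sources.

The governing model is the Pennes bioheat equation

    rho c dT/dt = div(k grad T) + rho_b c_b w_b (T_b - T) + Q_met + Q_ext,

with ``Q_ext = rho * SAR`` coupling the electromagnetic power absorption
(local SAR = sigma E_rms^2 / rho, W/kg) to the thermal problem.  For a
non-perfused phantom the perfusion and metabolic terms vanish and the
equation reduces to pure conduction with a volumetric source.  Two limits
are provided besides the 1-D PDE solver: a lumped-capacitance balance
``m c dT/dt = P_abs - hA (T - T_amb)`` (early-time linear rise, late-time
plateau) and a quasi-static eddy-current loss model for a conductive
cylindrical implant in an axial time-varying field.

The PDE solver uses a conservative finite-volume discretization on a slab
(half-thickness, symmetry plane at x=0) or a solid cylinder (axis at r=0),
with backward-Euler (default, unconditionally stable) or forward-Euler
stepping.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Callable

import numpy as np
from scipy.sparse import diags
from scipy.sparse.linalg import splu

from .field import MU_0

__all__ = [
    "MaterialThermal",
    "PerfusionSource",
    "ThermalDomain1D",
    "TemperatureField",
    "LumpedResponse",
    "EddyLossResult",
    "RESIN",
    "STAINLESS_STEEL",
    "SOFT_TISSUE",
    "local_sar",
    "sar_to_volumetric",
    "solve_transient",
    "solve_lumped",
    "eddy_loss",
    "square_wave_flux",
]


@dataclass(frozen=True)
class MaterialThermal:
    """Electrical and thermal properties of a homogeneous medium (SI)."""

    density: float                   # kg/m^3
    heat_capacity: float             # J/(kg K)
    thermal_conductivity: float      # W/(m K)
    electrical_conductivity: float = 0.0   # S/m
    rel_permittivity: float = 1.0
    rel_permeability: float = 1.0

    def __post_init__(self) -> None:
        if min(self.density, self.heat_capacity, self.thermal_conductivity) <= 0:
            raise ValueError("density, heat capacity and thermal conductivity "
                             "must be strictly positive")
        if self.electrical_conductivity < 0:
            raise ValueError("electrical conductivity must be >= 0")


#: Photopolymer printing resin of the tibia phantom.
RESIN = MaterialThermal(density=1150.0, heat_capacity=1300.0,
                        thermal_conductivity=0.25,
                        electrical_conductivity=1e-8, rel_permittivity=2.5)

#: Medical-grade stainless steel implant.  Conductivity and mu_r are the
#: reported implant values; density, heat capacity and thermal conductivity
#: are representative austenitic-steel figures.
STAINLESS_STEEL = MaterialThermal(density=7900.0, heat_capacity=500.0,
                                  thermal_conductivity=15.0,
                                  electrical_conductivity=1.4e6)

#: Generic soft tissue (muscle-like) for the tissue-vs-metal contrast runs.
SOFT_TISSUE = MaterialThermal(density=1050.0, heat_capacity=3600.0,
                              thermal_conductivity=0.5,
                              electrical_conductivity=0.5,
                              rel_permittivity=1e4)


@dataclass(frozen=True)
class PerfusionSource:
    """Blood-perfusion sink and metabolic source of the bioheat equation.

    Exactly one perfusion parameterization must be active: either the
    volumetric exchange rate ``perfusion_rate`` (w_b, 1/s, entering as
    rho_b c_b w_b) or a volumetric mass perfusion (kg/(m^3 s), i.e. the
    product rho_b * w_b) as cited for cortical bone.
    """

    blood_density: float = 1050.0        # kg/m^3
    blood_heat_capacity: float = 3617.0  # J/(kg K)
    perfusion_rate: float | None = None            # w_b, 1/s
    volumetric_mass_perfusion: float | None = None  # rho_b * w_b, kg/(m^3 s)
    arterial_temperature: float = 310.15  # K
    metabolic_rate: float = 0.0           # Q_met, W/m^3

    def __post_init__(self) -> None:
        active = (self.perfusion_rate is not None,
                  self.volumetric_mass_perfusion is not None)
        if sum(active) != 1:
            raise ValueError("exactly one of perfusion_rate and "
                             "volumetric_mass_perfusion must be given")
        if self.perfusion_rate is not None and self.perfusion_rate < 0:
            raise ValueError("perfusion_rate must be >= 0")
        if (self.volumetric_mass_perfusion is not None
                and self.volumetric_mass_perfusion < 0):
            raise ValueError("volumetric_mass_perfusion must be >= 0")
        if self.metabolic_rate < 0:
            raise ValueError("metabolic_rate must be >= 0")

    @property
    def sink_coefficient(self) -> float:
        """rho_b c_b w_b in W/(m^3 K)."""
        if self.perfusion_rate is not None:
            return self.blood_density * self.blood_heat_capacity * self.perfusion_rate
        return self.volumetric_mass_perfusion * self.blood_heat_capacity


@dataclass(frozen=True)
class ThermalDomain1D:
    """1-D half-domain: slab (0..half thickness) or cylinder (0..radius).

    Node 0 sits on the symmetry plane/axis (always zero-flux); the last
    node is the outer surface, whose condition is one of

    - ``("insulated",)``
    - ``("fixed", T_surface)``
    - ``("convective", h, T_ambient)``  with h in W/(m^2 K)
    """

    geometry_kind: str              # "slab" | "cylinder"
    extent: float                   # half-thickness or radius, m
    node_count: int
    boundary: tuple = ("insulated",)

    def __post_init__(self) -> None:
        if self.geometry_kind not in ("slab", "cylinder"):
            raise ValueError("geometry_kind must be 'slab' or 'cylinder'")
        if self.extent <= 0:
            raise ValueError("extent must be positive")
        if self.node_count < 3:
            raise ValueError("node_count must be >= 3")
        if self.boundary[0] not in ("insulated", "fixed", "convective"):
            raise ValueError(f"unknown boundary kind {self.boundary[0]!r}")

    @property
    def positions(self) -> np.ndarray:
        return np.linspace(0.0, self.extent, self.node_count)


def local_sar(material: MaterialThermal, erms) -> float:
    """Local specific absorption rate sigma * E_rms^2 / rho in W/kg."""
    erms = np.asarray(erms, dtype=float)
    if np.any(erms < 0):
        raise ValueError("E_rms must be >= 0")
    out = material.electrical_conductivity * erms**2 / material.density
    return float(out) if out.ndim == 0 else out


def sar_to_volumetric(material: MaterialThermal, sar) -> float:
    """Volumetric heat source Q_ext = rho * SAR in W/m^3."""
    sar = np.asarray(sar, dtype=float)
    if np.any(sar < 0):
        raise ValueError("SAR must be >= 0")
    out = material.density * sar
    return float(out) if out.ndim == 0 else out


@dataclass
class TemperatureField:
    """Node temperatures over time plus solver diagnostics."""

    positions: np.ndarray       # (n,), m
    times: np.ndarray           # (nt,), s
    temperature: np.ndarray     # (nt, n), K
    energy_residual: float = 0.0  # max relative per-step balance error (insulated)
    diagnostics: dict = dc_field(default_factory=dict)

    @property
    def delta(self) -> np.ndarray:
        """Temperature rise relative to the initial snapshot."""
        return self.temperature - self.temperature[0]


def _fv_geometry(domain: ThermalDomain1D):
    """Cell volumes and face areas (per unit depth/length) for the FV mesh."""
    x = domain.positions
    h = x[1] - x[0]
    faces = 0.5 * (x[:-1] + x[1:])
    if domain.geometry_kind == "slab":
        edges = np.concatenate([[x[0]], faces, [x[-1]]])
        vol = np.diff(edges)                  # per unit area
        area_int = np.ones(len(faces))        # internal face areas
        area_surf = 1.0
    else:  # cylinder, per unit axial length
        edges = np.concatenate([[0.0], faces, [x[-1]]])
        vol = math.pi * np.diff(edges**2)
        area_int = 2.0 * math.pi * faces
        area_surf = 2.0 * math.pi * x[-1]
    return h, vol, area_int, area_surf


def solve_transient(domain: ThermalDomain1D, material: MaterialThermal,
                    q_ext, t_end: float, dt: float,
                    perfusion: PerfusionSource | None = None,
                    t_initial: float = 296.15,
                    scheme: str = "implicit",
                    store_every: int = 1) -> TemperatureField:
    """Integrate the 1-D bioheat equation.

    Parameters
    ----------
    q_ext : float or array_like
        Volumetric source in W/m^3, scalar or per node (e.g. from
        :func:`sar_to_volumetric`).
    t_end, dt : float
        Final time and time step, seconds.
    perfusion : PerfusionSource, optional
        When given, adds the blood-perfusion sink and metabolic source;
        omitted for phantom (non-perfused) scenarios.
    scheme : {"implicit", "explicit"}
        Backward Euler (any dt) or forward Euler (raises if dt exceeds the
        stability bound, naming the maximum stable step).
    store_every : int
        Keep every ``store_every``-th step (plus the initial and final one).

    Returns
    -------
    TemperatureField
        With ``energy_residual`` the largest per-step relative violation of
        the global balance d/dt Int(rho c T) = Int(q) for insulated
        domains (diagnostic only otherwise).
    """
    if dt <= 0 or t_end <= 0:
        raise ValueError("dt and t_end must be positive")
    n = domain.node_count
    q = np.broadcast_to(np.asarray(q_ext, dtype=float), (n,)).copy()
    h, vol, area_int, area_surf = _fv_geometry(domain)
    k = material.thermal_conductivity
    rho_c = material.density * material.heat_capacity
    cap = rho_c * vol                                  # J/K per cell

    # conduction matrix K (W/K): K @ T gives net outflow per cell
    g = k * area_int / h                               # face conductances
    main = np.zeros(n)
    main[:-1] += g
    main[1:] += g
    K = diags([-g, main, -g], offsets=(-1, 0, 1), format="csc").tolil()

    sink = np.zeros(n)          # W/(m^3 K) distributed sink coefficient
    src = q * vol               # W per cell
    if perfusion is not None:
        sink[:] = perfusion.sink_coefficient
        src = src + (perfusion.sink_coefficient * perfusion.arterial_temperature
                     + perfusion.metabolic_rate) * vol

    bkind = domain.boundary[0]
    fixed_last = bkind == "fixed"
    if bkind == "convective":
        h_conv, t_amb = domain.boundary[1], domain.boundary[2]
        K[n - 1, n - 1] += h_conv * area_surf
        src[n - 1] += h_conv * area_surf * t_amb
    A = K.tocsc() + diags(sink * vol, format="csc")

    n_steps = int(math.ceil(t_end / dt - 1e-12))
    T = np.full(n, float(t_initial))
    if fixed_last:
        T[n - 1] = domain.boundary[1]

    if scheme == "explicit":
        row_abs = np.asarray(np.abs(A).sum(axis=1)).ravel()
        with np.errstate(divide="ignore"):
            dt_max = float(np.min(cap / np.maximum(row_abs, 1e-300)))
        if dt > dt_max:
            raise ValueError(
                f"explicit step dt={dt:g} s unstable; maximum stable dt is "
                f"{dt_max:g} s")
        lhs_solve = None
    elif scheme == "implicit":
        M = diags(cap / dt, format="csc")
        lhs = (M + A).tolil()
        if fixed_last:
            lhs[n - 1, :] = 0.0
            lhs[n - 1, n - 1] = 1.0
        lhs_solve = splu(lhs.tocsc()).solve
    else:
        raise ValueError("scheme must be 'implicit' or 'explicit'")

    times = [0.0]
    snaps = [T.copy()]
    max_resid = 0.0
    insulated = bkind == "insulated" and perfusion is None
    total_cap = cap.sum()
    t_now = 0.0
    for step in range(n_steps):
        step_dt = min(dt, t_end - t_now)
        if scheme == "explicit":
            T_new = T + step_dt * (src - A @ T) / cap
            if fixed_last:
                T_new[n - 1] = domain.boundary[1]
        else:
            if abs(step_dt - dt) > 1e-12 * dt:
                M = diags(cap / step_dt, format="csc")
                lhs = (M + A).tolil()
                if fixed_last:
                    lhs[n - 1, :] = 0.0
                    lhs[n - 1, n - 1] = 1.0
                solve = splu(lhs.tocsc()).solve
            else:
                solve = lhs_solve
            rhs = cap / step_dt * T + src
            if fixed_last:
                rhs[n - 1] = domain.boundary[1]
            T_new = solve(rhs)
        if insulated:
            dE = float(np.dot(cap, T_new - T))
            Ein = float(src.sum()) * step_dt
            if Ein != 0.0:
                max_resid = max(max_resid, abs(dE - Ein) / abs(Ein))
            else:
                max_resid = max(max_resid, abs(dE) / (total_cap * 1e-12 + 1.0))
        T = T_new
        t_now += step_dt
        if (step + 1) % store_every == 0 or step == n_steps - 1:
            times.append(t_now)
            snaps.append(T.copy())

    return TemperatureField(
        positions=domain.positions, times=np.asarray(times),
        temperature=np.asarray(snaps), energy_residual=max_resid,
        diagnostics={"scheme": scheme, "dt": dt,
                     "perfused": perfusion is not None,
                     "boundary": domain.boundary},
    )


@dataclass
class LumpedResponse:
    """Temperature rise of a lumped thermal mass over time."""

    times: np.ndarray
    delta_t: np.ndarray

    @property
    def initial_slope(self) -> float:
        return float((self.delta_t[1] - self.delta_t[0])
                     / (self.times[1] - self.times[0]))


def solve_lumped(mass: float, heat_capacity: float,
                 p_abs: float | Callable[[float], float],
                 loss_coefficient: float = 0.0,
                 t_end: float = 3600.0,
                 times=None) -> LumpedResponse:
    """Lumped-capacitance balance m c dT/dt = P_abs - hA * dT.

    With constant power and no loss the rise is the linear early-time law
    ``dT = P t / (m c)``; with a Newton-cooling loss ``hA`` (W/K) it
    saturates at the plateau ``P / hA``.  ``dT`` is the rise above the
    (constant) ambient; the body starts in equilibrium with it.

    Parameters
    ----------
    p_abs : float or callable
        Absorbed power in W, constant or a function of time.
    loss_coefficient : float
        Newton-cooling conductance hA in W/K, >= 0.
    times : array_like, optional
        Evaluation times; defaults to 601 points over [0, t_end].
    """
    if mass <= 0 or heat_capacity <= 0:
        raise ValueError("mass and heat capacity must be positive")
    if loss_coefficient < 0:
        raise ValueError("loss coefficient must be >= 0")
    t = (np.linspace(0.0, t_end, 601) if times is None
         else np.asarray(times, dtype=float))
    mc = mass * heat_capacity
    if callable(p_abs):
        from scipy.integrate import solve_ivp
        sol = solve_ivp(
            lambda tt, y: (p_abs(tt) - loss_coefficient * y[0]) / mc,
            (0.0, float(t[-1])), [0.0], t_eval=t, rtol=1e-9, atol=1e-12,
            max_step=(t[-1] - t[0]) / 200 if len(t) > 1 else np.inf)
        dT = sol.y[0]
    elif loss_coefficient == 0.0:
        dT = p_abs * t / mc
    else:
        tau = mc / loss_coefficient
        dT = (p_abs / loss_coefficient) * (1.0 - np.exp(-t / tau))
    return LumpedResponse(times=t, delta_t=dT)


@dataclass(frozen=True)
class EddyLossResult:
    """Eddy-current dissipation in a conductive cylinder (quasi-static)."""

    volumetric_loss: float   # W/m^3, cross-section averaged
    p_abs: float             # W
    sar: float               # W/kg
    skin_depth: float        # m, at the dominant frequency
    quasi_static_ok: bool    # skin depth >= radius; else loss is underestimated
    mean_square_dbdt: float  # <(dB/dt)^2>, T^2/s^2


def square_wave_flux(b0: float, frequency: float, duty: float = 0.5,
                     rise_fraction: float = 0.01,
                     n_samples: int = 4000) -> tuple[np.ndarray, np.ndarray]:
    """One period of a unipolar trapezoidal flux-density waveform.

    An ideal square wave has unbounded dB/dt, so a finite rise/fall time
    (default 1% of the period) is mandatory for the time-domain loss
    route.

    Returns
    -------
    (t, B) : arrays over one period [0, 1/f).
    """
    if rise_fraction <= 0:
        raise ValueError("rise_fraction must be positive: an ideal square "
                         "wave has unbounded dB/dt")
    period = 1.0 / frequency
    tr = rise_fraction * period
    t_on = duty * period
    t = np.linspace(0.0, period, n_samples, endpoint=False)
    b = np.zeros_like(t)
    ramp_up = t < tr
    b[ramp_up] = b0 * t[ramp_up] / tr
    flat = (t >= tr) & (t < t_on)
    b[flat] = b0
    ramp_dn = (t >= t_on) & (t < t_on + tr)
    b[ramp_dn] = b0 * (1.0 - (t[ramp_dn] - t_on) / tr)
    return t, b


def mean_square_dbdt_time(t: np.ndarray, b: np.ndarray) -> float:
    """Period-averaged (dB/dt)^2 from one period of samples.

    ``t`` must cover one period without repeating the endpoint (the
    waveform wraps around); the average is weighted by interval length.
    """
    t = np.asarray(t, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(t) < 3:
        raise ValueError("need at least 3 samples per period")
    dt_wrap = np.median(np.diff(t))
    dts = np.concatenate([np.diff(t), [dt_wrap]])
    dbs = np.concatenate([np.diff(b), [b[0] - b[-1]]])
    rates = dbs / dts
    return float(np.sum(rates**2 * dts) / np.sum(dts))


def mean_square_dbdt_spectrum(frequencies, amplitudes) -> float:
    """<(dB/dt)^2> = sum_n (w_n B_n)^2 / 2 for a harmonic series."""
    w = 2.0 * math.pi * np.asarray(frequencies, dtype=float)
    b = np.asarray(amplitudes, dtype=float)
    return float(np.sum((w * b) ** 2) / 2.0)


def square_wave_spectrum(b0: float, frequency: float,
                         n_harmonics: int = 15) -> tuple[np.ndarray, np.ndarray]:
    """Odd-harmonic truncation of a 50%-duty square flux waveform.

    The AC part of a unipolar square wave of amplitude ``b0`` has odd
    harmonics of amplitude ``2 b0 / (pi n)``; the series for dB/dt does
    not converge, so a truncation order (default 15 odd harmonics) must
    be chosen.
    """
    n = 2 * np.arange(n_harmonics) + 1
    return n * frequency, 2.0 * b0 / (math.pi * n)


def eddy_loss(radius: float, length: float, sigma: float, density: float,
              *, time_series: tuple | None = None,
              spectrum: tuple | None = None,
              fundamental_hz: float | None = None,
              mu_r: float = 1.0) -> EddyLossResult:
    """Eddy-current loss of a conductive cylinder in a uniform axial B(t).

    Quasi-static model: the induced azimuthal field at radius r is
    ``E = -(r/2) dB/dt``; averaging the Joule density ``sigma E^2`` over
    the cross-section gives a volumetric loss ``sigma a^2 <(dB/dt)^2>/8``.
    Validity requires the skin depth at the dominant frequency to exceed
    the radius; otherwise the field no longer penetrates the full cross
    section and the result carries ``quasi_static_ok=False``.

    Exactly one of ``time_series=(t, B)`` (one period of samples) or
    ``spectrum=(frequencies, amplitudes)`` must be given.
    """
    if (time_series is None) == (spectrum is None):
        raise ValueError("give exactly one of time_series or spectrum")
    if min(radius, length, density) <= 0 or sigma < 0:
        raise ValueError("radius, length, density must be positive; sigma >= 0")
    if time_series is not None:
        t, b = time_series
        msq = mean_square_dbdt_time(np.asarray(t), np.asarray(b))
        f_dom = fundamental_hz or 1.0 / (np.asarray(t)[-1] - np.asarray(t)[0])
    else:
        freqs, amps = spectrum
        msq = mean_square_dbdt_spectrum(freqs, amps)
        f_dom = fundamental_hz or float(np.min(freqs))
    vol_loss = sigma * radius**2 * msq / 8.0
    volume = math.pi * radius**2 * length
    p = vol_loss * volume
    sar = vol_loss / density
    omega = 2.0 * math.pi * f_dom
    delta = math.sqrt(2.0 / (omega * MU_0 * mu_r * sigma)) if sigma > 0 else math.inf
    return EddyLossResult(volumetric_loss=vol_loss, p_abs=p, sar=sar,
                          skin_depth=delta, quasi_static_ok=delta >= radius,
                          mean_square_dbdt=msq)
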