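"""Magnetic flux density of the conical winding.

On the symmetry axis the Biot–Savart integral over the helical path has a
closed integrand: with observation point (0, 0, z0),

    B_i(z0) = mu0 I / (4 pi) * Int_{s1}^{s2} C_i(s) / d(s)^{3/2} ds

where d(s) = s^2 - 2 s z0 cos(a) + z0^2 is the squared source-observer
distance and the auxiliary numerators are

    Cx = sin(a) [ -k s^2 cos(a) cos(ks) + k s z0 cos(ks) + z0 sin(ks) ]
    Cy = sin(a) [ -k s^2 cos(a) sin(ks) + k s z0 sin(ks) - z0 cos(ks) ]
    Cz = k s^2 sin^2(a)

These are exactly the components of dl x R for the helix tangent and the
axial displacement.  The integrals have no closed form and are evaluated
by adaptive quadrature.  Off the axis no such reduction exists; the field
is computed by summing straight current segments along the discretized
winding, which also serves as an independent oracle on the axis.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.integrate import quad

from .coil import CoilGeometry, helix_point

__all__ = [
    "MU_0",
    "AxialFieldSample",
    "FieldGrid",
    "NonuniformityMap",
    "SingularFieldError",
    "integrand_terms",
    "axial_field",
    "segment_field",
    "field_grid",
    "nonuniformity_map",
    "roi_field_range",
]

MU_0 = 4.0e-7 * math.pi  # vacuum permeability, T m / A


class SingularFieldError(ValueError):
    """Observation point coincides with (or touches) the winding path."""


def integrand_terms(geometry: CoilGeometry, s, z0):
    """Auxiliary numerators (Cx, Cy, Cz) of the on-axis Biot–Savart integrands.

    Vectorized over ``s``.  Equal to the components of dl/ds x R where
    dl/ds is the helix tangent and R the vector from the winding point to
    (0, 0, z0).
    """
    s = np.asarray(s, dtype=float)
    k = geometry.winding_rate
    sin_a = math.sin(geometry.half_angle)
    cos_a = math.cos(geometry.half_angle)
    ks = k * s
    cx = sin_a * (-k * s**2 * cos_a * np.cos(ks) + k * s * z0 * np.cos(ks)
                  + z0 * np.sin(ks))
    cy = sin_a * (-k * s**2 * cos_a * np.sin(ks) + k * s * z0 * np.sin(ks)
                  - z0 * np.cos(ks))
    cz = k * s**2 * sin_a**2
    return cx, cy, cz


def _min_denominator(geometry: CoilGeometry, z0: float) -> float:
    """Minimum of d(s) = s^2 - 2 s z0 cos(a) + z0^2 over the wound range."""
    cos_a = math.cos(geometry.half_angle)
    s_star = min(max(z0 * cos_a, geometry.s1), geometry.s2)
    return s_star**2 - 2.0 * s_star * z0 * cos_a + z0**2


@dataclass(frozen=True)
class AxialFieldSample:
    """Flux density at an on-axis observation point."""

    z0: float
    bx: float
    by: float
    bz: float

    @property
    def vector(self) -> np.ndarray:
        return np.array([self.bx, self.by, self.bz])

    @property
    def magnitude(self) -> float:
        return float(np.linalg.norm(self.vector))


def axial_field(geometry: CoilGeometry, z0: float,
                quadrature_tol: float = 1e-10) -> AxialFieldSample:
    """On-axis flux density by adaptive quadrature of the helix integrals.

    Parameters
    ----------
    geometry : CoilGeometry
    z0 : float
        Axial coordinate of the observation point, metres.
    quadrature_tol : float
        Relative tolerance passed to the adaptive quadrature.

    Raises
    ------
    SingularFieldError
        If the observation point lies on (or numerically touches) the
        winding path.
    """
    if _min_denominator(geometry, z0) <= 1e-18:
        raise SingularFieldError(
            f"observation point z0={z0} lies on the winding path")
    cos_a = math.cos(geometry.half_angle)
    pref = MU_0 * geometry.current / (4.0 * math.pi)
    # The integrand oscillates n_turns times over [s1, s2]; give the
    # adaptive rule enough subintervals to resolve every period.
    limit = max(200, 30 * geometry.n_turns)

    def make(component: int):
        def f(s: float) -> float:
            c = integrand_terms(geometry, s, z0)[component]
            d = s * s - 2.0 * s * z0 * cos_a + z0 * z0
            return float(c) / d**1.5
        return f

    vals = []
    with warnings.catch_warnings():
        # Bx/By integrate to near-zero by symmetry; the relative target is
        # then unreachable and quad emits a roundoff warning.  The small
        # absolute floor keeps those components accurate in absolute terms.
        warnings.simplefilter("ignore")
        for comp in range(3):
            v, _ = quad(make(comp), geometry.s1, geometry.s2,
                        epsabs=1e-13, epsrel=quadrature_tol, limit=limit)
            vals.append(pref * v)
    return AxialFieldSample(z0, *vals)


def segment_field(geometry: CoilGeometry, points,
                  segments_per_turn: int = 200) -> np.ndarray:
    """Flux density at arbitrary points by straight-segment summation.

    The winding is discretized into ``segments_per_turn * n_turns``
    straight segments; each contributes ``mu0 I/(4 pi) dl x R / |R|^3``
    evaluated at the segment midpoint (midpoint rule, second-order in the
    segment length).

    Parameters
    ----------
    points : array_like, shape (..., 3)
        Observation points, metres.

    Returns
    -------
    numpy.ndarray, shape (..., 3)
        Flux density vectors in tesla.
    """
    pts_in = np.asarray(points, dtype=float)
    pts = np.atleast_2d(pts_in)
    shape = pts_in.shape
    pts = pts.reshape(-1, 3)
    n_seg = segments_per_turn * geometry.n_turns
    s_edges = np.linspace(geometry.s1, geometry.s2, n_seg + 1)
    nodes = helix_point(geometry, s_edges)          # (n_seg+1, 3)
    dl = np.diff(nodes, axis=0)                     # (n_seg, 3)
    mid = 0.5 * (nodes[:-1] + nodes[1:])            # (n_seg, 3)
    pref = MU_0 * geometry.current / (4.0 * math.pi)
    out = np.empty_like(pts)
    # chunk over observation points to bound memory at ~n_seg*3 floats each
    for i, p in enumerate(pts):
        r = p[None, :] - mid
        r3 = np.sum(r * r, axis=1) ** 1.5
        if np.any(r3 == 0.0):
            raise SingularFieldError("observation point on the winding path")
        out[i] = pref * np.sum(np.cross(dl, r) / r3[:, None], axis=0)
    return out.reshape(shape)


@dataclass
class FieldGrid:
    """Flux density sampled on a regular 3-D lattice.

    Nodes closer to the winding than the guard distance are masked: their
    vectors are NaN and ``mask`` is True there.
    """

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    b: np.ndarray           # (nx, ny, nz, 3), tesla
    mask: np.ndarray        # (nx, ny, nz) bool, True = masked (near winding)
    provenance: dict = dc_field(default_factory=dict)

    @property
    def bmag(self) -> np.ndarray:
        """|B| per node (NaN on masked nodes)."""
        return np.linalg.norm(self.b, axis=-1)

    @property
    def n_masked(self) -> int:
        return int(self.mask.sum())


def field_grid(geometry: CoilGeometry, bounds, spacing,
               segments_per_turn: int = 200,
               guard_factor: float = 2.0) -> FieldGrid:
    """Flux density on a regular lattice inside/around the coil.

    Parameters
    ----------
    bounds : ((xmin, xmax), (ymin, ymax), (zmin, zmax))
        Lattice extent in metres.
    spacing : float or (dx, dy, dz)
        Lattice spacing, metres; must be positive.
    guard_factor : float
        Nodes within ``guard_factor * min(spacing)`` of the winding are
        masked rather than evaluated (the segment sum diverges there).
    """
    spacing = np.broadcast_to(np.asarray(spacing, dtype=float), (3,))
    if np.any(spacing <= 0):
        raise ValueError("grid spacing must be positive")
    axes = []
    for (lo, hi), h in zip(bounds, spacing):
        n = int(round((hi - lo) / h)) + 1
        axes.append(lo + h * np.arange(max(n, 1)))
    x, y, z = axes
    xx, yy, zz = np.meshgrid(x, y, z, indexing="ij")
    pts = np.stack([xx, yy, zz], axis=-1).reshape(-1, 3)

    # guard mask: distance to a densely sampled winding path
    s_dense = np.linspace(geometry.s1, geometry.s2,
                          segments_per_turn * geometry.n_turns + 1)
    path = helix_point(geometry, s_dense)
    guard = guard_factor * float(spacing.min())
    d2min = np.full(len(pts), np.inf)
    for chunk in np.array_split(path, max(1, len(path) // 2000)):
        d2 = np.sum((pts[:, None, :] - chunk[None, :, :]) ** 2, axis=-1)
        d2min = np.minimum(d2min, d2.min(axis=1))
    masked = d2min < guard**2

    b = np.full((len(pts), 3), np.nan)
    if np.any(~masked):
        b[~masked] = segment_field(geometry, pts[~masked], segments_per_turn)
    shape = (len(x), len(y), len(z))
    return FieldGrid(
        x=x, y=y, z=z,
        b=b.reshape(shape + (3,)),
        mask=masked.reshape(shape),
        provenance={
            "half_angle": geometry.half_angle, "s1": geometry.s1,
            "s2": geometry.s2, "n_turns": geometry.n_turns,
            "current": geometry.current,
            "segments_per_turn": segments_per_turn,
            "spacing": spacing.tolist(), "guard_distance": guard,
        },
    )


@dataclass
class NonuniformityMap:
    """Gradient of |B|^2 per node — geometric surrogate for the
    gradient-driven (dielectrophoretic) interaction strength."""

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    grad_b2: np.ndarray     # (nx, ny, nz, 3), T^2/m


def nonuniformity_map(grid: FieldGrid) -> NonuniformityMap:
    """Central-difference gradient of |B|^2 on the lattice.

    Interior nodes use central differences, boundaries one-sided ones.
    An axis with a single plane cannot be differentiated; its component
    is reported as zero with a warning.
    """
    b2 = grid.bmag ** 2
    grads = []
    axes = [grid.x, grid.y, grid.z]
    for ax_idx, coords in enumerate(axes):
        if len(coords) < 2:
            warnings.warn(
                f"axis {ax_idx} has a single plane; its gradient component "
                "is reported as zero", stacklevel=2)
            grads.append(np.zeros_like(b2))
        else:
            grads.append(np.gradient(b2, coords, axis=ax_idx))
    return NonuniformityMap(grid.x, grid.y, grid.z, np.stack(grads, axis=-1))


def roi_field_range(grid: FieldGrid, roi) -> tuple[float, float]:
    """(min |B|, max |B|) over unmasked nodes inside an axis-aligned box.

    Parameters
    ----------
    roi : ((xmin, xmax), (ymin, ymax), (zmin, zmax))

    Raises
    ------
    ValueError
        If the ROI contains no unmasked grid node.
    """
    (x0, x1), (y0, y1), (z0, z1) = roi
    sel_x = (grid.x >= x0) & (grid.x <= x1)
    sel_y = (grid.y >= y0) & (grid.y <= y1)
    sel_z = (grid.z >= z0) & (grid.z <= z1)
    sub = grid.bmag[np.ix_(sel_x, sel_y, sel_z)]
    sub_mask = grid.mask[np.ix_(sel_x, sel_y, sel_z)]
    vals = sub[~sub_mask]
    if vals.size == 0:
        raise ValueError("ROI contains no unmasked grid nodes")
    return float(vals.min()), float(vals.max())
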