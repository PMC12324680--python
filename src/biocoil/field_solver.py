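"""Semi-analytic magnetostatics of circular loops and coil pairs.

The off-axis field of a filamentary circular loop has a closed form in the
complete elliptic integrals K and E.  With the loop of radius ``a0`` in the
plane x = 0, and a field point at axial distance ``x`` and radial distance
``r`` from the axis, define

    alpha = r/a0,  beta = x/a0,  gamma = x/r,
    Q = (1 + alpha)^2 + beta^2,  k^2 = 4 alpha / Q,
    B0 = mu0 i / (2 a0)                      (center field of the loop),

then

    Ba = B0 / (pi sqrt(Q)) [ E(k) (1 - alpha^2 - beta^2)/(Q - 4 alpha) + K(k) ]
    Br = B0 gamma / (pi sqrt(Q)) [ E(k) (1 + alpha^2 + beta^2)/(Q - 4 alpha) - K(k) ]

(Q - 4 alpha = (1 - alpha)^2 + beta^2 vanishes only on the filament itself).
On the axis the exact closed form Ba = mu0 i a0^2 / (2 (a0^2 + x^2)^{3/2}),
Br = 0 is used instead.  A coil pair is the superposition over its
filamentary :class:`~biocoil.coil_geometry.LoopSet`, which makes every field
quantity exactly linear in the drive current.

Homogeneity over a sample region is summarized as the maximum deviation of
the axial component from its value at the region center ("axial divergence")
and the maximum magnitude of the radial component ("radial divergence").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize_scalar
from scipy.special import ellipe, ellipk

from .coil_geometry import CoilPair, LoopSet, SampleRegion, discretize_winding

__all__ = [
    "MU0",
    "FieldMap",
    "HomogeneityReport",
    "loop_field",
    "loopset_field",
    "pair_field",
    "field_map",
    "homogeneity",
    "helmholtz_spacing",
    "helmholtz_spacing_distributed",
    "current_for_field",
    "ideal_pair_center_field",
]

#: Vacuum permeability, N A^-2.
MU0 = 4e-7 * np.pi

# A field point closer to the filament than this fraction of the loop radius
# is treated as singular.
_SINGULAR_TOL = 1e-9
# Radial distances below this (m) take the exact on-axis branch.
_ON_AXIS_TOL = 1e-12


class SingularFieldPoint(ValueError):
    """Raised when a field point lies on (or numerically on) the filament."""


@dataclass(frozen=True)
class HomogeneityReport:
    """Uniformity summary of a sampled field map (all fields in tesla)."""

    Ba_center: float
    Ba_mean: float
    axial_divergence: float
    radial_divergence: float
    n_samples: int

    def to_dict(self) -> dict:
        return {
            "Ba_center_mT": self.Ba_center * 1e3,
            "Ba_mean_mT": self.Ba_mean * 1e3,
            "axial_divergence_uT": self.axial_divergence * 1e6,
            "radial_divergence_uT": self.radial_divergence * 1e6,
            "n_samples": self.n_samples,
        }


@dataclass(frozen=True)
class FieldMap:
    """Field sampled on a square lattice restricted to a :class:`SampleRegion`.

    ``x``/``r`` are the axial/radial coordinates (m) of every lattice point
    (points with equal r appear once per lattice position so that area
    averages are correct); ``Ba``/``Br`` the field components (T).
    """

    region: SampleRegion
    current: float
    x: np.ndarray
    r: np.ndarray
    Ba: np.ndarray
    Br: np.ndarray

    def __len__(self) -> int:
        return self.x.size

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "x_mm": self.x * 1e3,
                "r_mm": self.r * 1e3,
                "Ba_mT": self.Ba * 1e3,
                "Br_mT": self.Br * 1e3,
            }
        )


def loop_field(a0: float, i: float, x, r):
    """Axial and radial field (T) of one filamentary loop of radius ``a0``
    (m) carrying ``i`` (A), at axial/radial distances ``x``/``r`` (m) from
    the loop center.  Vectorized over ``x`` and ``r``.

    Raises :class:`SingularFieldPoint` if any point lies on the filament and
    ValueError for nonphysical geometry (a0 <= 0, r < 0).
    """
    if a0 <= 0:
        raise ValueError(f"loop radius must be > 0, got {a0}")
    x = np.asarray(x, dtype=float)
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("radial distance r must be >= 0")
    x, r = np.broadcast_arrays(x, r)

    # distance from the filament circle (in the meridional plane)
    filament_dist = np.hypot(r - a0, x)
    if np.any(filament_dist < _SINGULAR_TOL * a0):
        raise SingularFieldPoint("field point lies on the wire filament")

    on_axis = r < _ON_AXIS_TOL
    alpha = r / a0
    beta = x / a0
    Q = (1.0 + alpha) ** 2 + beta**2
    m = 4.0 * alpha / Q  # m = k^2 for scipy's ellipk/ellipe
    if np.any(m >= 1.0):
        raise SingularFieldPoint("elliptic parameter k^2 >= 1 (point on filament)")
    B0 = MU0 * i / (2.0 * a0)
    K = ellipk(m)
    E = ellipe(m)
    denom = Q - 4.0 * alpha  # (1 - alpha)^2 + beta^2
    pref = B0 / (np.pi * np.sqrt(Q))
    Ba = pref * (E * (1.0 - alpha**2 - beta**2) / denom + K)
    with np.errstate(divide="ignore", invalid="ignore"):
        gamma = np.where(on_axis, 0.0, x / np.where(on_axis, 1.0, r))
    Br = pref * gamma * (E * (1.0 + alpha**2 + beta**2) / denom - K)

    # exact on-axis closed form
    Ba_axis = MU0 * i * a0**2 / (2.0 * (a0**2 + x**2) ** 1.5)
    Ba = np.where(on_axis, Ba_axis, Ba)
    Br = np.where(on_axis, 0.0, Br)
    if Ba.ndim == 0:
        return float(Ba), float(Br)
    return Ba, Br


def loopset_field(loops: LoopSet, x, r):
    """Superposed field (T) of every loop in ``loops`` at points (x, r)
    measured from the pair midpoint."""
    x = np.asarray(x, dtype=float)
    r = np.asarray(r, dtype=float)
    x, r = np.broadcast_arrays(x, r)
    Ba = np.zeros(x.shape)
    Br = np.zeros(x.shape)
    for a0, x0, i in zip(loops.radius, loops.axial_offset, loops.current):
        ba, br = loop_field(a0, i, x - x0, r)
        Ba = Ba + ba
        Br = Br + br
    if Ba.ndim == 0:
        return float(Ba), float(Br)
    return Ba, Br


def _half_loopset(pair: CoilPair) -> LoopSet:
    """The winding centered at +spacing/2 only (the other is its mirror)."""
    loops = discretize_winding(pair)
    right = loops.axial_offset > 0
    return LoopSet(
        radius=loops.radius[right],
        axial_offset=loops.axial_offset[right],
        current=loops.current[right],
    )


def pair_field(pair: CoilPair, x, r):
    """Field (T) of the discretized coil pair at points (x, r) from the
    midpoint; exactly linear in ``pair.current``.

    The mirror winding's field is the +spacing/2 winding's field evaluated
    at -x with the radial component negated, so the pair is computed from a
    single winding.  This makes the midplane symmetries exact in floating
    point: Br(0, r) = 0, Ba even and Br odd in x.
    """
    x = np.asarray(x, dtype=float)
    half = _half_loopset(pair)
    ba_r, br_r = loopset_field(half, x, r)
    ba_l, br_l = loopset_field(half, -x, r)
    Ba = ba_r + ba_l
    Br = br_r - br_l
    if np.ndim(Ba) == 0:
        return float(Ba), float(Br)
    return Ba, Br


def _region_grid(region: SampleRegion):
    """Square-lattice sample points of a region as flat (x, r) arrays.

    The transverse lattice covers [-radius, radius]^2 at grid_step and keeps
    points with sqrt(px^2+py^2) <= radius; a cylinder additionally stacks
    axial planes at grid_step covering its height symmetrically.
    """
    step = region.grid_step
    n = int(np.floor(region.radius / step + 1e-9))
    g = np.arange(-n, n + 1) * step
    px, py = np.meshgrid(g, g)
    rr = np.hypot(px, py).ravel()
    rr = rr[rr <= region.radius * (1.0 + 1e-12)]
    if region.shape == "disk" or region.height == 0:
        zs = np.array([0.0])
    else:
        nz = int(np.floor(region.height / 2.0 / step + 1e-9))
        zs = np.arange(-nz, nz + 1) * step
    zs = zs + region.axial_center
    x = np.repeat(zs, rr.size)
    r = np.tile(rr, zs.size)
    return x, r


def field_map(pair: CoilPair, region: SampleRegion) -> FieldMap:
    """Sample the pair field over a region; deterministic point ordering.

    The region must fit inside the bore (region radius strictly below the
    winding inner radius).  Exploits axisymmetry: the field is evaluated once
    per unique (x, r) and scattered back onto the lattice.
    """
    if region.radius >= pair.winding.inner_radius:
        raise ValueError(
            f"sample region radius {region.radius} m does not fit inside the "
            f"bore (winding inner radius {pair.winding.inner_radius} m)"
        )
    x, r = _region_grid(region)
    pts = np.column_stack([x, r])
    uniq, inv = np.unique(pts, axis=0, return_inverse=True)
    Ba_u, Br_u = pair_field(pair, uniq[:, 0], uniq[:, 1])
    return FieldMap(
        region=region,
        current=pair.current,
        x=x,
        r=r,
        Ba=Ba_u[inv],
        Br=Br_u[inv],
    )


def homogeneity(fmap: FieldMap, Ba_center: float | None = None, Br_center: float | None = None,
                pair: CoilPair | None = None) -> HomogeneityReport:
    """Uniformity summary of a field map.

    The reference center value is the axial component at the region center
    (axial_center, r=0); it is taken from the map if that point was sampled,
    recomputed from ``pair`` if given, otherwise it must be passed in.
    """
    if len(fmap) == 0:
        raise ValueError("empty field map")
    if Ba_center is None:
        at_center = (fmap.r == 0) & (fmap.x == fmap.region.axial_center)
        if np.any(at_center):
            Ba_center = float(fmap.Ba[at_center][0])
        elif pair is not None:
            Ba_center, _ = pair_field(pair, fmap.region.axial_center, 0.0)
        else:
            raise ValueError(
                "center point not in map; pass Ba_center or the pair to recompute it"
            )
    return HomogeneityReport(
        Ba_center=float(Ba_center),
        Ba_mean=float(fmap.Ba.mean()),
        axial_divergence=float(np.abs(fmap.Ba - Ba_center).max()),
        radial_divergence=float(np.abs(fmap.Br).max()),
        n_samples=len(fmap),
    )


def _axial_curvature_at_midpoint(a0: float, spacing: float) -> float:
    """d^2 Ba / dx^2 at the midpoint of an ideal point-loop pair (per A turn).

    On-axis Ba of one loop offset by x0 is mu0 a0^2 / (2 (a0^2+u^2)^{3/2}),
    u = x - x0; its second derivative at the midpoint reduces to the closed
    form below (identical for both loops by symmetry).
    """
    u2 = (spacing / 2.0) ** 2
    s = a0**2 + u2
    return MU0 * a0**2 * (-1.5 * s**-2.5 + 7.5 * u2 * s**-3.5)


def helmholtz_spacing(a0: float) -> float:
    """Loop-pair spacing (m) that zeroes the second axial derivative of the
    on-axis field at the midpoint — the Helmholtz condition.  For ideal
    point loops the root is exactly the loop radius; it is found numerically
    (brentq on the analytic curvature) rather than asserted."""
    if a0 <= 0:
        raise ValueError(f"loop radius must be > 0, got {a0}")
    return float(brentq(lambda s: _axial_curvature_at_midpoint(a0, s),
                        0.2 * a0, 5.0 * a0, xtol=1e-12 * a0, rtol=8.9e-16))


def helmholtz_spacing_distributed(
    pair: CoilPair, region: SampleRegion, rel_bracket: tuple[float, float] = (0.6, 1.6)
) -> float:
    """Winding-centroid spacing (m) minimizing the axial divergence of the
    distributed pair over ``region``.  Slower than :func:`helmholtz_spacing`
    (each trial spacing maps the whole region); use a coarse grid_step."""
    a_mean = pair.winding.mean_radius

    def objective(spacing: float) -> float:
        trial = CoilPair(winding=pair.winding, spacing=spacing, current=pair.current)
        fmap = field_map(trial, region)
        return homogeneity(fmap, pair=trial).axial_divergence

    res = minimize_scalar(
        objective,
        bounds=(rel_bracket[0] * a_mean, rel_bracket[1] * a_mean),
        method="bounded",
        options={"xatol": 1e-6},
    )
    return float(res.x)


def current_for_field(pair: CoilPair, B_target: float) -> float:
    """Drive current (A) producing axial field ``B_target`` (T) at the pair
    center; exact by linearity."""
    if B_target < 0:
        raise ValueError("B_target must be >= 0")
    unit = CoilPair(winding=pair.winding, spacing=pair.spacing, current=1.0)
    Ba1, _ = pair_field(unit, 0.0, 0.0)
    return float(B_target / Ba1)


def ideal_pair_center_field(a0: float, n_turns: int, i: float) -> float:
    """Center field (T) of an ideal Helmholtz pair (two point loops of
    radius a0 = spacing, n_turns each): (4/5)^{3/2} mu0 N i / a0."""
    return (4.0 / 5.0) ** 1.5 * MU0 * n_turns * i / a0
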