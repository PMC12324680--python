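"""Physical description of the coil pair and its filamentary discretization.

A Helmholtz exposure system is built from two identical multilayer windings
mounted coaxially.  For field computation each turn of wire is collapsed onto
a filamentary circular loop at the wire center; the resulting
:class:`LoopSet` is the geometric input to :mod:`biocoil.field_solver`.

All lengths are SI meters internally; configuration files use explicit
unit-suffixed keys (``wire_diameter_mm`` ...) converted at the boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

__all__ = [
    "COPPER_RESISTIVITY",
    "WireSpec",
    "WindingSpec",
    "CoilPair",
    "LoopSet",
    "SampleRegion",
    "discretize_winding",
    "wire_length",
    "resistance_from_geometry",
]

#: Resistivity of annealed copper at 20 degC, ohm*m.
COPPER_RESISTIVITY = 1.68e-8


@dataclass(frozen=True)
class WireSpec:
    """Round magnet wire.

    ``diameter`` is the packing pitch (insulation included) used to lay out
    turns; ``conductor_diameter`` is the bare-copper diameter used for the
    conduction cross-section.  For enamelled wire the two differ by the
    insulation build (22 AWG: 0.644 mm bare inside a ~0.71 mm overall
    diameter); when only one number is known leave ``conductor_diameter``
    unset and it falls back to ``diameter``.
    """

    diameter: float
    resistivity: float = COPPER_RESISTIVITY
    conductor_diameter: float | None = None

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError(f"wire diameter must be > 0, got {self.diameter}")
        if self.resistivity <= 0:
            raise ValueError(f"resistivity must be > 0, got {self.resistivity}")
        if self.conductor_diameter is not None and not (
            0 < self.conductor_diameter <= self.diameter
        ):
            raise ValueError(
                "conductor_diameter must lie in (0, diameter], got "
                f"{self.conductor_diameter}"
            )

    @property
    def conduction_area(self) -> float:
        """Cross-sectional area of the conducting core, m^2."""
        d = self.conductor_diameter if self.conductor_diameter is not None else self.diameter
        return math.pi * (d / 2.0) ** 2


@dataclass(frozen=True)
class WindingSpec:
    """One multilayer winding: ``n_turns`` of wire on a holder of
    ``inner_radius``, laid in square packing across ``axial_width``."""

    inner_radius: float
    axial_width: float
    n_turns: int
    wire: WireSpec

    def __post_init__(self) -> None:
        if self.inner_radius <= 0:
            raise ValueError(f"inner_radius must be > 0, got {self.inner_radius}")
        if self.n_turns < 1:
            raise ValueError(f"n_turns must be >= 1, got {self.n_turns}")
        if self.axial_width < self.wire.diameter:
            raise ValueError(
                "axial_width must hold at least one wire diameter "
                f"({self.axial_width} < {self.wire.diameter})"
            )

    @property
    def turns_per_layer(self) -> int:
        return int(math.floor(self.axial_width / self.wire.diameter))

    @property
    def n_layers(self) -> int:
        return int(math.ceil(self.n_turns / self.turns_per_layer))

    @property
    def outer_radius(self) -> float:
        """Outer envelope of the wound coil, m."""
        return self.inner_radius + self.n_layers * self.wire.diameter

    @property
    def mean_radius(self) -> float:
        """Turn-count-weighted mean loop radius of the winding, m."""
        radii, _ = _layer_layout(self)
        return float(np.mean(radii))


@dataclass(frozen=True)
class CoilPair:
    """Mirror-symmetric coaxial pair carrying equal co-directed current.

    ``spacing`` is the centroid-to-centroid distance of the two windings
    along the shared axis; the pair midpoint is the coordinate origin.
    """

    winding: WindingSpec
    spacing: float
    current: float = 1.0

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError(f"spacing must be > 0, got {self.spacing}")


@dataclass(frozen=True)
class LoopSet:
    """Filamentary loops: arrays of radius (m), axial offset (m), current (A)."""

    radius: np.ndarray
    axial_offset: np.ndarray
    current: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.radius, float)
        x = np.asarray(self.axial_offset, float)
        i = np.asarray(self.current, float)
        if not (r.shape == x.shape == i.shape):
            raise ValueError("radius, axial_offset and current must have equal shape")
        object.__setattr__(self, "radius", r)
        object.__setattr__(self, "axial_offset", x)
        object.__setattr__(self, "current", i)

    def __len__(self) -> int:
        return self.radius.size


@dataclass(frozen=True)
class SampleRegion:
    """Region over which the field is mapped (the sample dish).

    ``disk`` is a flat circle in the plane perpendicular to the axis at
    ``axial_center``; ``cylinder`` extends ``height`` symmetrically about it.
    """

    shape: Literal["disk", "cylinder"] = "cylinder"
    radius: float = 17.5e-3
    height: float = 5.0e-3
    axial_center: float = 0.0
    grid_step: float = 0.5e-3

    def __post_init__(self) -> None:
        if self.shape not in ("disk", "cylinder"):
            raise ValueError(f"shape must be 'disk' or 'cylinder', got {self.shape!r}")
        if self.radius <= 0:
            raise ValueError(f"radius must be > 0, got {self.radius}")
        if self.grid_step <= 0:
            raise ValueError(f"grid_step must be > 0, got {self.grid_step}")
        if self.shape == "cylinder" and self.height < 0:
            raise ValueError(f"height must be >= 0, got {self.height}")


def _layer_layout(winding: WindingSpec, max_layers: int = 50):
    """Radii and axial offsets (relative to the winding centroid) of all turns.

    Square packing: layer j sits at inner_radius + (j + 1/2) * wire diameter;
    each layer holds ``turns_per_layer`` turns whose centers span the winding
    width symmetrically; a partial last layer fills from the axial start.
    """
    t = winding.wire.diameter
    tpl = winding.turns_per_layer
    if tpl < 1:
        raise ValueError("axial width too small for one turn")
    n_layers = winding.n_layers
    if n_layers > max_layers:
        raise ValueError(
            f"{winding.n_turns} turns need {n_layers} layers, exceeding the "
            f"configured maximum of {max_layers}; geometry looks inconsistent"
        )
    span = tpl * t
    radii = []
    offsets = []
    remaining = winding.n_turns
    for j in range(n_layers):
        a = winding.inner_radius + (j + 0.5) * t
        n_this = min(tpl, remaining)
        for m in range(n_this):
            radii.append(a)
            offsets.append(-span / 2.0 + (m + 0.5) * t)
        remaining -= n_this
    radii = np.array(radii)
    offsets = np.array(offsets)
    # a partial last layer pulls the turn centroid off the layout center;
    # re-center so "spacing" means centroid-to-centroid of the turns
    offsets -= offsets.mean()
    return radii, offsets


def discretize_winding(pair: CoilPair, max_layers: int = 50) -> LoopSet:
    """Collapse every turn of both windings onto a filamentary loop.

    The two windings' centroids sit at -spacing/2 and +spacing/2, and the
    second winding is the mirror image of the first about the midplane (only
    a partial last layer breaks the windings' own axial symmetry, and the
    mirrored assembly restores it for the pair).  Turn count is conserved
    exactly (``len(result) == 2 * n_turns``).
    """
    radii, offsets = _layer_layout(pair.winding, max_layers=max_layers)
    r = np.concatenate([radii, radii])
    x = np.concatenate([offsets - pair.spacing / 2.0, pair.spacing / 2.0 - offsets])
    i = np.full(r.shape, pair.current)
    return LoopSet(radius=r, axial_offset=x, current=i)


def wire_length(pair: CoilPair, lead_length: float = 0.0) -> float:
    """Total conductor length of the pair, m: sum of loop circumferences
    plus an optional lead allowance."""
    loops = discretize_winding(pair)
    return float(2.0 * np.pi * loops.radius.sum() + lead_length)


def resistance_from_geometry(pair: CoilPair, lead_length: float = 0.0) -> float:
    """DC resistance of the series-connected pair predicted from geometry,
    ohm: rho * L / A with the wire's conduction cross-section."""
    wire = pair.winding.wire
    return wire.resistivity * wire_length(pair, lead_length) / wire.conduction_area
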