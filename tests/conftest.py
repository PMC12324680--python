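import numpy as np
import pytest

from biocoil import CoilPair, WindingSpec, WireSpec
from biocoil.field_solver import MU0


@pytest.fixture(scope="session")
def table1_pair() -> CoilPair:
    """The reference 96-turn winding pair at the Helmholtz spacing, 1 A."""
    wire = WireSpec(diameter=0.71e-3, conductor_diameter=0.644e-3)
    winding = WindingSpec(
        inner_radius=40e-3, axial_width=16e-3, n_turns=96, wire=wire
    )
    return CoilPair(winding=winding, spacing=43.4e-3, current=1.0)


def biot_savart_segments(a0, i, x, r, nseg=100_000):
    """Brute-force Biot-Savart oracle: the loop approximated by ``nseg``
    straight segments (midpoint rule), summed directly.

    Independent of the elliptic-integral path: no special functions, no
    shared code.  Returns (Ba, Br) at the point (axial x, radial r).
    """
    phi = (np.arange(nseg) + 0.5) / nseg * 2.0 * np.pi
    dphi = 2.0 * np.pi / nseg
    px, py = a0 * np.cos(phi), a0 * np.sin(phi)
    dlx, dly = -a0 * np.sin(phi) * dphi, a0 * np.cos(phi) * dphi
    # field point at (r, 0, x); loop lies in the z = 0 plane
    rx, ry, rz = r - px, -py, x
    r3 = (rx**2 + ry**2 + rz**2) ** 1.5
    f = MU0 * i / (4.0 * np.pi)
    Bz = f * np.sum((dlx * ry - dly * rx) / r3)  # axial
    Bx = f * np.sum(dly * rz / r3)  # radial, toward the field point
    return Bz, Bx
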