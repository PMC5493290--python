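import numpy as np
import pytest

import avm
from avm import mechanics as mech


@pytest.fixture(scope="session")
def disk40():
    """Small packed disk tissue reused (read-only) across tests."""
    rng = np.random.default_rng(12345)
    return avm.init_packing(avm.ScenarioSpec(geometry="disk", N=40), rng)


@pytest.fixture()
def disk40_copy(disk40):
    t = disk40.copy()
    t.remesh()
    return t


def hex_lattice_tissue(nx=8, ny=8, spacing=1.0):
    """Triangular lattice of cell centres inside a snug rectangular ghost line.

    The ghost line hugs the lattice so that every perimeter cell is
    ghost-adjacent (no oversized orphan cells at the patch sides).
    """
    pts = []
    for j in range(ny):
        for i in range(nx):
            pts.append((i * spacing + (j % 2) * spacing / 2, j * spacing * np.sqrt(3) / 2))
    pts = np.asarray(pts)
    lo = pts.min(axis=0) - 0.8 * spacing
    hi = pts.max(axis=0) + 0.8 * spacing
    ring = []
    nxg = max(int((hi[0] - lo[0]) / spacing), 2)
    nyg = max(int((hi[1] - lo[1]) / spacing), 2)
    for k in range(nxg):
        ring.append((lo[0] + (hi[0] - lo[0]) * k / nxg, lo[1]))
    for k in range(nyg):
        ring.append((hi[0], lo[1] + (hi[1] - lo[1]) * k / nyg))
    for k in range(nxg):
        ring.append((hi[0] - (hi[0] - lo[0]) * k / nxg, hi[1]))
    for k in range(nyg):
        ring.append((lo[0], hi[1] - (hi[1] - lo[1]) * k / nyg))
    return avm.Tissue.build(pts, [np.asarray(ring)], A0=np.sqrt(3) / 2 * spacing**2)


@pytest.fixture(scope="session")
def hex_tissue():
    return hex_lattice_tissue()


def single_hexagon_tissue(p0=None, Gamma=1.0):
    """One interior cell whose Voronoi polygon is a regular hexagon.

    Ghost ring of 6 sites at distance d around the origin gives a regular
    hexagonal cell of area (sqrt(3)/2) d^2.  d is chosen so the cell area is
    pi (the standard target area).
    """
    d = np.sqrt(np.pi / (np.sqrt(3) / 2))
    ang = 2 * np.pi * np.arange(6) / 6
    ring = d * np.stack([np.cos(ang), np.sin(ang)], axis=1)
    return avm.Tissue.build(np.array([[0.0, 0.0]]), [ring], A0=np.pi)
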