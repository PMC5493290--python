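"""Initial-condition generation.

Cell centres are initialised from an energy-minimised packing of slightly
polydisperse soft disks confined to the requested geometry at packing
fraction phi = 1, so that cells start evenly spaced without sitting on a
grid and the mean Voronoi cell area equals the target area A0 (enforced
exactly by a final global rescale).  Boundary ghosts are strung along the
geometry's rim at spacing ~ l0.

Supported geometries: disk, annulus, rectangle strips (several separate
patches) and a disk inside a fixed circular confinement cavity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.spatial import cKDTree

from . import mechanics as mech
from .tissue import Tissue

__all__ = ["ScenarioSpec", "init_packing", "soft_disk_residual"]


@dataclass
class ScenarioSpec:
    """What tissue to build.

    geometry : disk | annulus | rectangle_strips | cavity
    N : number of cells (total, across strips for rectangle_strips)
    polydispersity : half-width of the uniform soft-disk radius distribution,
        as a fraction of the mean radius
    packing_fraction : area fraction of the soft disks in the region (phi)
    type_fractions : mapping type index -> fraction (must sum to 1)
    A0 : target cell area (pi by default, so the mean disk radius is 1)
    ghost_spacing : arc length between consecutive boundary ghosts
    hole_area_fraction : annulus only — hole area / outer disk area
    n_strips, strip_aspect : rectangle_strips only
    cavity_factor : cavity only — wall radius / initial tissue radius
    """

    geometry: str = "disk"
    N: int = 100
    polydispersity: float = 0.1
    packing_fraction: float = 1.0
    type_fractions: dict[int, float] = field(default_factory=lambda: {0: 1.0})
    A0: float = np.pi
    ghost_spacing: float = 1.0
    hole_area_fraction: float = 0.2
    n_strips: int = 3
    strip_aspect: float = 3.0
    strip_gap: float = 4.0
    cavity_factor: float = 1.6
    seed: int = 0

    def __post_init__(self):
        if self.N < 3:
            raise ValueError("need at least 3 cells")
        total = sum(self.type_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("type fractions must sum to 1")
        if self.geometry not in ("disk", "annulus", "rectangle_strips", "cavity"):
            raise ValueError(f"unknown geometry {self.geometry!r}")


# ---------------------------------------------------------------------------
# soft-disk packing minimisation
# ---------------------------------------------------------------------------

def _pack(points0, radii, wall_energy_grad, rng, gtol=1e-10):
    """Minimise harmonic disk-overlap + wall energy; returns positions."""
    n = len(points0)
    rmax = float(np.max(radii))

    def fg(x):
        p = x.reshape(n, 2)
        tree = cKDTree(p)
        pairs = np.asarray(list(tree.query_pairs(2.0 * rmax)), dtype=np.int64)
        e = 0.0
        g = np.zeros_like(p)
        if len(pairs):
            d = p[pairs[:, 0]] - p[pairs[:, 1]]
            r = np.linalg.norm(d, axis=1)
            sigma = radii[pairs[:, 0]] + radii[pairs[:, 1]]
            ov = sigma - r
            touch = ov > 0
            if np.any(touch):
                d, r, ov, pr = d[touch], r[touch], ov[touch], pairs[touch]
                e += 0.5 * float(np.sum(ov**2))
                gv = -(ov / r)[:, None] * d
                np.add.at(g, pr[:, 0], gv)
                np.add.at(g, pr[:, 1], -gv)
        ew, gw = wall_energy_grad(p)
        return e + ew, (g + gw).ravel()

    res = minimize(
        fg,
        np.asarray(points0, dtype=float).ravel(),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": 5000, "gtol": gtol, "ftol": 0.0},
    )
    return res.x.reshape(n, 2)


def soft_disk_residual(points, radii, wall_energy_grad) -> float:
    """Max residual force magnitude of the packed configuration (diagnostic)."""
    n = len(points)
    tree = cKDTree(points)
    pairs = np.asarray(list(tree.query_pairs(2.0 * float(np.max(radii)))), dtype=np.int64)
    g = np.zeros_like(points)
    if len(pairs):
        d = points[pairs[:, 0]] - points[pairs[:, 1]]
        r = np.linalg.norm(d, axis=1)
        ov = radii[pairs[:, 0]] + radii[pairs[:, 1]] - r
        touch = ov > 0
        d, r, ov, pr = d[touch], r[touch], ov[touch], pairs[touch]
        gv = -(ov / r)[:, None] * d
        np.add.at(g, pr[:, 0], gv)
        np.add.at(g, pr[:, 1], -gv)
    _, gw = wall_energy_grad(points)
    g += gw
    return float(np.max(np.linalg.norm(g, axis=1))) if len(g) else 0.0


def _disk_wall(R):
    def weg(p):
        r = np.linalg.norm(p, axis=1)
        pen = np.clip(r - R, 0.0, None)
        e = 0.5 * float(np.sum(pen**2))
        with np.errstate(invalid="ignore", divide="ignore"):
            g = np.where(r[:, None] > 1e-12, (pen / np.maximum(r, 1e-12))[:, None] * p, 0.0)
        return e, g

    return weg


def _annulus_wall(R_in, R_out):
    def weg(p):
        r = np.maximum(np.linalg.norm(p, axis=1), 1e-12)
        pen_out = np.clip(r - R_out, 0.0, None)
        pen_in = np.clip(R_in - r, 0.0, None)
        e = 0.5 * float(np.sum(pen_out**2 + pen_in**2))
        g = ((pen_out - pen_in) / r)[:, None] * p
        return e, g

    return weg


def _rect_wall(w, h):
    def weg(p):
        gx = np.clip(p[:, 0] - w / 2, 0.0, None) + np.clip(p[:, 0] + w / 2, None, 0.0)
        gy = np.clip(p[:, 1] - h / 2, 0.0, None) + np.clip(p[:, 1] + h / 2, None, 0.0)
        e = 0.5 * float(np.sum(gx**2 + gy**2))
        return e, np.stack([gx, gy], axis=1)

    return weg


def _ring(radius, spacing, center=(0.0, 0.0), phase=0.0):
    n = max(int(round(2.0 * np.pi * radius / spacing)), 8)
    ang = phase + np.arange(n) * (2.0 * np.pi / n)
    return np.stack([center[0] + radius * np.cos(ang), center[1] + radius * np.sin(ang)], axis=1)


def _rect_ring(w, h, spacing, center=(0.0, 0.0)):
    corners = np.array(
        [[-w / 2, -h / 2], [w / 2, -h / 2], [w / 2, h / 2], [-w / 2, h / 2]]
    )
    pts = []
    for k in range(4):
        a, b = corners[k], corners[(k + 1) % 4]
        seglen = np.linalg.norm(b - a)
        n = max(int(round(seglen / spacing)), 1)
        for t in np.arange(n) / n:
            pts.append(a + t * (b - a))
    return np.asarray(pts) + np.asarray(center)


# ---------------------------------------------------------------------------
# scenario assembly
# ---------------------------------------------------------------------------

def _assign_types(N, fractions, rng):
    types = np.zeros(N, dtype=np.int64)
    keys = sorted(fractions)
    counts = [int(round(fractions[k] * N)) for k in keys]
    counts[-1] = N - sum(counts[:-1])
    pool = np.concatenate([np.full(c, k, dtype=np.int64) for k, c in zip(keys, counts)])
    rng.shuffle(pool)
    types[:] = pool
    return types


def init_packing(spec: ScenarioSpec, rng: np.random.Generator | None = None) -> Tissue:
    """Build the initial tissue for a scenario (deterministic given the rng).

    Without an explicit generator, one is seeded from ``spec.seed``.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    mean_r = np.sqrt(spec.A0 / np.pi)
    radii = mean_r * (
        1.0 + spec.polydispersity * (2.0 * rng.random(spec.N) - 1.0)
    )
    disk_area = float(np.sum(np.pi * radii**2))
    margin = 0.5 * mean_r  # ghost ring offset from the packed region
    sp = spec.ghost_spacing

    if spec.geometry in ("disk", "cavity"):
        R = np.sqrt(disk_area / (np.pi * spec.packing_fraction))
        ang = 2.0 * np.pi * rng.random(spec.N)
        rad = R * np.sqrt(rng.random(spec.N))
        p0 = np.stack([rad * np.cos(ang), rad * np.sin(ang)], axis=1)
        pts = _pack(p0, radii, _disk_wall(R - mean_r), rng)
        loops_pos = [_ring(R + margin, sp)]
        wall_loops: list[int] = []
        if spec.geometry == "cavity":
            loops_pos.append(_ring(spec.cavity_factor * (R + margin), sp))
            wall_loops = [1]
    elif spec.geometry == "annulus":
        R_out = np.sqrt(
            disk_area / (np.pi * spec.packing_fraction * (1.0 - spec.hole_area_fraction))
        )
        R_in = R_out * np.sqrt(spec.hole_area_fraction)
        ang = 2.0 * np.pi * rng.random(spec.N)
        rad = np.sqrt(R_in**2 + (R_out**2 - R_in**2) * rng.random(spec.N))
        p0 = np.stack([rad * np.cos(ang), rad * np.sin(ang)], axis=1)
        pts = _pack(p0, radii, _annulus_wall(R_in + mean_r, R_out - mean_r), rng)
        loops_pos = [_ring(R_out + margin, sp), _ring(max(R_in - margin, sp), sp)]
        wall_loops = []
    else:  # rectangle_strips
        per = [spec.N // spec.n_strips] * spec.n_strips
        per[-1] += spec.N - sum(per)
        pts_list = []
        loops_pos = []
        wall_loops = []
        x0 = 0.0
        cursor = 0
        for npts in per:
            area = float(np.sum(np.pi * radii[cursor : cursor + npts] ** 2))
            h = np.sqrt(area / (spec.packing_fraction * spec.strip_aspect))
            w = spec.strip_aspect * h
            center = (x0 + w / 2.0, 0.0)
            p0 = np.stack(
                [
                    center[0] + (rng.random(npts) - 0.5) * (w - 2 * mean_r),
                    center[1] + (rng.random(npts) - 0.5) * (h - 2 * mean_r),
                ],
                axis=1,
            )
            local = _pack(
                p0 - center,
                radii[cursor : cursor + npts],
                _rect_wall(w - 2 * mean_r, h - 2 * mean_r),
                rng,
            )
            pts_list.append(local + center)
            loops_pos.append(_rect_ring(w + 2 * margin, h + 2 * margin, sp, center))
            cursor += npts
            x0 += w + spec.strip_gap
        pts = np.vstack(pts_list)

    types = _assign_types(spec.N, spec.type_fractions, rng)
    n_types = max(max(spec.type_fractions) + 1, 1)
    theta = 2.0 * np.pi * rng.random(spec.N)
    tissue = Tissue.build(
        pts,
        loops_pos,
        types=types,
        n_types=n_types,
        A0=spec.A0,
        theta=theta,
        wall_loops=wall_loops,
    )
    # enforce <A> = A0 exactly by a global rescale of all coordinates
    geo = mech.cell_geometry(tissue)
    scale = np.sqrt(spec.A0 / float(np.mean(geo["areas"])))
    tissue.pos *= scale
    tissue.remesh()
    return tissue
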