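"""Vertex-model energy on the dual Voronoi tessellation and cell-centre forces.

The tissue energy is

    E = sum_i K_i/2 (A_i - A0_i)^2  +  sum_i Gamma_i/2 P_i^2
        + sum_i sum_{edges e of cell i} Lambda_e l_e,

with A_i and P_i the Voronoi area and perimeter of interior cell i, and
Lambda_e the junction tension looked up from the cell-type pair across the
dual Delaunay edge (the reserved type "M" for cell-boundary contacts).
Accumulating the tension term per cell side double-counts interior-interior
junctions, which is exactly the conventional factor 2 that makes the uniform-
tension model identical to the preferred-perimeter form
Gamma/2 (P - P0)^2 with P0 = -Lambda/Gamma, up to the constant
Gamma P0^2 / 2 per cell.

Forces are the exact negative gradient of the energy with respect to cell
centre positions, assembled by the chain rule through the analytic
circumcenter Jacobians: the energy gradient with respect to every Voronoi
vertex is computed per cell polygon and then scattered onto the three
Delaunay sites of each vertex.  Boundary ghosts receive forces through the
triangles they share with interior cells but own no cell terms.

A soft repulsive core between cell centres (harmonic half-spring of range
``a``) stabilises the model in regimes where the Voronoi construction alone
becomes delicate (very high shape factor, divisions).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import triangle_circumcenters, triangle_jacobians
from .tissue import Tissue, FLAG_INTERIOR, FLAG_WALL

__all__ = [
    "MechanicalParams",
    "EnergyBreakdown",
    "effective_p0",
    "p0_to_lambda",
    "regular_polygon_p0",
    "boundary_tension_threshold",
    "cell_geometry",
    "vm_energy",
    "vm_forces",
    "soft_core_energy",
    "soft_core_forces",
]

_TERMS = ("area", "perimeter", "junction")


@dataclass
class MechanicalParams:
    """Mechanical parameters of the vertex-model energy.

    ``K`` and ``Gamma`` are scalars or per-type arrays (length ``n_types``).
    ``Lambda`` is a symmetric (n_types+1) x (n_types+1) matrix over cell
    types, the last row/column being the boundary type "M".  The native area
    ``A0`` lives on the tissue (mutable under growth), not here.

    Units: K = 1 and the soft-core range a = 1 set the energy and length
    scales; time is measured in gamma / (K a^2).
    """

    K: float | np.ndarray = 1.0
    Gamma: float | np.ndarray = 1.0
    Lambda: float | np.ndarray = 0.0
    k_core: float = 1.0
    a: float = 1.0

    def per_type(self, n_types: int):
        K = np.broadcast_to(np.asarray(self.K, dtype=float), (n_types,))
        G = np.broadcast_to(np.asarray(self.Gamma, dtype=float), (n_types,))
        lam = np.asarray(self.Lambda, dtype=float)
        if lam.ndim == 0:
            lam = np.full((n_types + 1, n_types + 1), float(lam))
        if lam.shape != (n_types + 1, n_types + 1):
            raise ValueError(
                f"Lambda must be scalar or ({n_types + 1}, {n_types + 1}) "
                "(cell types plus boundary type M)"
            )
        if not np.allclose(lam, lam.T):
            raise ValueError("Lambda matrix must be symmetric")
        return K, G, lam

    @classmethod
    def uniform_p0(cls, p0: float, Gamma: float = 1.0, A0: float = np.pi, **kw):
        """Parameters with uniform junction tension chosen to give shape factor p0."""
        return cls(K=1.0, Gamma=Gamma, Lambda=p0_to_lambda(p0, Gamma, A0), **kw)


@dataclass
class EnergyBreakdown:
    area_term: float = 0.0
    perimeter_term: float = 0.0
    junction_term: float = 0.0
    soft_core_term: float = 0.0
    boundary_line_term: float = 0.0
    boundary_bend_term: float = 0.0

    @property
    def total(self) -> float:
        return (
            self.area_term
            + self.perimeter_term
            + self.junction_term
            + self.soft_core_term
            + self.boundary_line_term
            + self.boundary_bend_term
        )


# ---------------------------------------------------------------------------
# shape-factor algebra
# ---------------------------------------------------------------------------

def effective_p0(Gamma: float, Lambda: float, A0: float = np.pi) -> float:
    """Dimensionless shape factor p0 = P0/sqrt(A0) with P0 = -Lambda/Gamma."""
    if Gamma <= 0:
        raise ValueError("Gamma must be positive (no preferred perimeter otherwise)")
    if A0 <= 0:
        raise ValueError("A0 must be positive")
    return (-Lambda / Gamma) / np.sqrt(A0)


def p0_to_lambda(p0: float, Gamma: float = 1.0, A0: float = np.pi) -> float:
    """Uniform junction tension realising a given shape factor (inverse map)."""
    return -p0 * Gamma * np.sqrt(A0)


def regular_polygon_p0(n: int) -> float:
    """Shape factor P/sqrt(A) of the regular n-gon: sqrt(4 n tan(pi/n)).

    3.722 for the hexagon, 3.812 for the pentagon (the solid-liquid critical
    value), 4.0 for the square, 4.559 for the equilateral triangle.
    """
    if n < 3:
        raise ValueError("a polygon needs at least 3 sides")
    return float(np.sqrt(4 * n * np.tan(np.pi / n)))


def boundary_tension_threshold(lam_rr: float, lam_bM: float, lam_rb: float) -> float:
    """Tension Lambda_rM below which red-boundary contacts become favourable.

    Replacing a blue-boundary plus a red-blue contact by a red-boundary plus
    a red-red contact lowers the energy when
    Lambda_rM < Lambda_rr + Lambda_bM - Lambda_rb.
    """
    return lam_rr + lam_bM - lam_rb


# ---------------------------------------------------------------------------
# geometry of the current tessellation
# ---------------------------------------------------------------------------

def cell_geometry(tissue: Tissue):
    """Areas, perimeters and polygon data of all interior cells.

    Returns a dict with per-cell ``areas`` and ``perimeters`` (ordered as
    ``mesh.cells().owners``) plus the flattened occurrence arrays used by the
    force assembly: vertex positions ``V``, edge vectors and lengths of the
    polygon edge occurrence -> next occurrence, and the circumcenters.
    """
    mesh = tissue.mesh
    cx = mesh.cells()
    # circumcenters only of triangles bordering interior cells: triangles made
    # of boundary ghosts alone (e.g. slivers outside a concave rim) may be
    # near-degenerate and never enter any cell polygon
    used = np.unique(cx.tri)
    cc = np.full((mesh.n_triangles, 2), np.nan)
    cc[used] = triangle_circumcenters(mesh.points, mesh.triangles[used])
    V = cc[cx.tri]
    Vn = V[cx.nxt]
    seg = Vn - V  # polygon edge from occurrence to its successor
    slen = np.linalg.norm(seg, axis=1)
    cross = V[:, 0] * Vn[:, 1] - V[:, 1] * Vn[:, 0]
    areas = 0.5 * np.add.reduceat(cross, cx.ptr[:-1])
    perims = np.add.reduceat(slen, cx.ptr[:-1])
    return {
        "cells": cx,
        "circumcenters": cc,
        "V": V,
        "seg": seg,
        "slen": slen,
        "areas": areas,
        "perimeters": perims,
    }


def _lambda_per_edge(tissue: Tissue, cx, lam_matrix: np.ndarray) -> np.ndarray:
    """Junction tension per polygon-edge occurrence from the type-pair matrix."""
    own_type = tissue.types[cx.site_of]
    nbr_type = tissue.types[cx.nbr]
    return lam_matrix[own_type, nbr_type]


# ---------------------------------------------------------------------------
# energy
# ---------------------------------------------------------------------------

def vm_energy(
    tissue: Tissue,
    params: MechanicalParams,
    terms: tuple[str, ...] = _TERMS,
    scaled: bool = False,
) -> EnergyBreakdown:
    """Vertex-model energy of the current tessellation.

    With ``scaled=True`` the perimeter and junction contributions are
    reported jointly as Gamma/2 (P - P0)^2 per cell with P0 = -Lambda/Gamma
    (requires uniform tension), which differs from the unscaled form by the
    constant Gamma P0^2 / 2 per cell.
    """
    geo = cell_geometry(tissue)
    cx = geo["cells"]
    K, G, lam = params.per_type(tissue.n_types)
    ctype = tissue.types[cx.owners]
    A0 = tissue.A0[cx.owners]
    out = EnergyBreakdown()
    if scaled:
        lam_vals = lam[:-1, :-1]
        if not np.allclose(lam_vals, lam_vals.flat[0]):
            raise ValueError("scaled form requires uniform junction tension")
        P0 = -lam_vals.flat[0] / G[ctype]
        out.area_term = float(np.sum(0.5 * K[ctype] * (geo["areas"] - A0) ** 2))
        out.perimeter_term = float(
            np.sum(0.5 * G[ctype] * (geo["perimeters"] - P0) ** 2)
        )
        return out
    if "area" in terms:
        out.area_term = float(np.sum(0.5 * K[ctype] * (geo["areas"] - A0) ** 2))
    if "perimeter" in terms:
        out.perimeter_term = float(np.sum(0.5 * G[ctype] * geo["perimeters"] ** 2))
    if "junction" in terms:
        lam_e = _lambda_per_edge(tissue, cx, lam)
        out.junction_term = float(np.sum(lam_e * geo["slen"]))
    return out


# ---------------------------------------------------------------------------
# forces
# ---------------------------------------------------------------------------

def vm_forces(
    tissue: Tissue,
    params: MechanicalParams,
    terms: tuple[str, ...] = _TERMS,
) -> np.ndarray:
    """Exact negative gradient of :func:`vm_energy` w.r.t. every site position.

    Raises if the mesh is stale (sites moved since the last equiangulation):
    forces evaluated on a non-Delaunay mesh are not the model's forces.
    """
    if tissue.mesh_stale:
        raise RuntimeError(
            "mesh is stale: call tissue.equiangulate() after moving sites "
            "and before evaluating forces"
        )
    mesh = tissue.mesh
    geo = cell_geometry(tissue)
    cx = geo["cells"]
    K, G, lam = params.per_type(tissue.n_types)
    ctype_occ = tissue.types[cx.site_of]
    A0_occ = tissue.A0[cx.site_of]
    areas_occ = geo["areas"][cx.cell_of]
    perims_occ = geo["perimeters"][cx.cell_of]
    V, seg, slen = geo["V"], geo["seg"], geo["slen"]
    nxt, prv = cx.nxt, cx.prv

    # unit edge vectors; degenerate (zero-length) junction edges carry no
    # well-defined direction — their contribution vanishes continuously
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = np.where(slen[:, None] > 1e-300, seg / slen[:, None], 0.0)

    g = np.zeros_like(V)  # dE/d r_nu per vertex occurrence
    if "area" in terms:
        pref = K[ctype_occ] * (areas_occ - A0_occ)
        diff = V[nxt] - V[prv]
        # dA/dr_nu = 0.5 * (y_{nu+1} - y_{nu-1}, x_{nu-1} - x_{nu+1})
        g[:, 0] += pref * 0.5 * diff[:, 1]
        g[:, 1] += pref * (-0.5) * diff[:, 0]
    if "perimeter" in terms:
        pref = G[ctype_occ] * perims_occ
        g += pref[:, None] * (unit[prv] - unit)
    if "junction" in terms:
        lam_e = _lambda_per_edge(tissue, cx, lam)
        g += lam_e[prv][:, None] * unit[prv] - lam_e[:, None] * unit

    used = np.unique(cx.tri)
    J = np.zeros((mesh.n_triangles, 3, 2, 2))
    J[used] = triangle_jacobians(mesh.points, mesh.triangles[used])
    Jocc = J[cx.tri]  # (L, 3, 2, 2)
    contrib = np.einsum("lb,lsba->lsa", g, Jocc)  # (L, 3, 2)
    F = np.zeros_like(tissue.pos)
    sites = mesh.triangles[cx.tri]  # (L, 3)
    np.add.at(F, sites.ravel(), -contrib.reshape(-1, 2))
    return F


# ---------------------------------------------------------------------------
# soft-core repulsion
# ---------------------------------------------------------------------------

def _core_pairs(tissue: Tissue) -> np.ndarray:
    """Delaunay-adjacent pairs subject to the soft core.

    Cell-centre pairs, plus cell-wall pairs so that immobile confinement
    walls exert contact forces on cells.
    """
    edges = tissue.mesh.edges()
    fi = tissue.flags[edges[:, 0]]
    fj = tissue.flags[edges[:, 1]]
    cc = (fi == FLAG_INTERIOR) & (fj == FLAG_INTERIOR)
    cw = ((fi == FLAG_INTERIOR) & (fj == FLAG_WALL)) | (
        (fi == FLAG_WALL) & (fj == FLAG_INTERIOR)
    )
    return edges[cc | cw]


def soft_core_energy(tissue: Tissue, params: MechanicalParams) -> float:
    pairs = _core_pairs(tissue)
    if len(pairs) == 0:
        return 0.0
    d = tissue.pos[pairs[:, 0]] - tissue.pos[pairs[:, 1]]
    r = np.linalg.norm(d, axis=1)
    overlap = np.clip(params.a - r, 0.0, None)
    return float(0.5 * params.k_core * np.sum(overlap**2))


def soft_core_forces(tissue: Tissue, params: MechanicalParams) -> np.ndarray:
    """Radial harmonic repulsion f = k_core (a - r) for r < a, zero beyond.

    Coincident centres get a capped force along a fixed direction with a
    warning (the configuration is pathological but must not produce NaNs).
    """
    F = np.zeros_like(tissue.pos)
    pairs = _core_pairs(tissue)
    if len(pairs) == 0:
        return F
    d = tissue.pos[pairs[:, 0]] - tissue.pos[pairs[:, 1]]
    r = np.linalg.norm(d, axis=1)
    touching = r < params.a
    if not np.any(touching):
        return F
    pairs, d, r = pairs[touching], d[touching], r[touching]
    tiny = r < 1e-9
    if np.any(tiny):
        import warnings

        warnings.warn("coincident cell centres: capping soft-core force")
        d[tiny] = np.array([1.0, 0.0])
        r[tiny] = 1e-9
    mag = params.k_core * (params.a - np.minimum(r, params.a))
    fvec = (mag / r)[:, None] * d
    np.add.at(F, pairs[:, 0], fvec)
    np.add.at(F, pairs[:, 1], -fvec)
    return F
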