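"""Measurements on tissues and trajectories.

Glassy dynamics is quantified by the self-intermediate scattering function
F(q, t) = < exp(i q . (r(t) - r(0))) > at the inverse cell size q = 2 pi / a
and its alpha-relaxation time tau_alpha (first drop of F below 1/2); a
diverging tau_alpha together with a vanishing T1 rate marks the solid
(glassy) phase.  Mechanical state is summarised by a per-cell virial stress
assembled from scalar edge tensions on the junction and triangulation edge
networks; its (negative half-)trace is the cell pressure, with compression
positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import mechanics as mech
from .tissue import Tissue

__all__ = [
    "ScatteringResult",
    "PhaseMetrics",
    "self_intermediate",
    "tau_alpha_from_F",
    "t1_statistics",
    "hardy_stress",
    "cell_pressures",
    "neighbour_distribution",
    "demixing_index",
    "classify_phase",
]

#: sentinel multiplier for a censored (never-crossing) tau_alpha
CENSOR_FACTOR = 10.0


@dataclass
class ScatteringResult:
    q: float
    t_grid: np.ndarray
    F: np.ndarray
    tau_alpha: float  # +inf when F never drops below 1/2

    @property
    def censored(self) -> bool:
        return not np.isfinite(self.tau_alpha)


@dataclass
class PhaseMetrics:
    t1_rate: float
    tau_alpha: float
    tau_inst: float
    classification: str  # solid | liquid | unstable


# ---------------------------------------------------------------------------
# self-intermediate scattering function
# ---------------------------------------------------------------------------

def self_intermediate(
    times: np.ndarray,
    positions: np.ndarray,
    q_magnitude: float = 2.0 * np.pi,
    n_directions: int = 8,
    n_time_origins: int = 10,
) -> ScatteringResult:
    """Isotropically averaged F(q, t) from a trajectory of tracked cells.

    ``positions`` has shape (n_frames, n_cells, 2) for cells present in every
    frame (cells created or destroyed mid-window must be excluded by the
    caller; :func:`aligned_positions` in :mod:`avm.trajio` does this).
    Averages over cells, ``n_directions`` equally spaced q directions and up
    to ``n_time_origins`` evenly spaced time origins; tau_alpha is the first
    crossing of 1/2, linearly interpolated, +inf if never reached.
    """
    times = np.asarray(times, dtype=float)
    positions = np.asarray(positions, dtype=float)
    n_frames = len(times)
    if n_frames < 2:
        raise ValueError("need at least two snapshots")
    angles = np.arange(n_directions) * (2.0 * np.pi / n_directions)
    qvecs = q_magnitude * np.stack([np.cos(angles), np.sin(angles)], axis=1)
    # lag grid = frame offsets relative to t[0]
    lags = np.arange(n_frames)
    origins = np.unique(
        np.linspace(0, n_frames - 2, min(n_time_origins, n_frames - 1)).astype(int)
    )
    F = np.zeros(n_frames)
    counts = np.zeros(n_frames)
    F[0] = 1.0
    counts[0] = 1.0
    for o in origins:
        disp = positions[o + 1 :] - positions[o]  # (n_lags, n_cells, 2)
        phase = np.einsum("lcx,dx->lcd", disp, qvecs)
        F_lag = np.cos(phase).mean(axis=(1, 2))
        lag_idx = lags[1 : n_frames - o]
        F[lag_idx] += F_lag
        counts[lag_idx] += 1.0
    valid = counts > 0
    Favg = np.full(n_frames, np.nan)
    Favg[valid] = F[valid] / counts[valid]
    t_grid = times - times[0]
    tau = tau_alpha_from_F(t_grid[valid], Favg[valid])
    return ScatteringResult(q=q_magnitude, t_grid=t_grid[valid], F=Favg[valid], tau_alpha=tau)


def tau_alpha_from_F(t: np.ndarray, F: np.ndarray) -> float:
    """First time F(t) crosses 1/2, linearly interpolated; +inf if never."""
    below = np.nonzero(F < 0.5)[0]
    if len(below) == 0:
        return np.inf
    k = int(below[0])
    if k == 0:
        return float(t[0])
    t0, t1 = t[k - 1], t[k]
    f0, f1 = F[k - 1], F[k]
    return float(t0 + (0.5 - f0) * (t1 - t0) / (f1 - f0))


# ---------------------------------------------------------------------------
# T1 statistics
# ---------------------------------------------------------------------------

def t1_statistics(events: list[dict], n_cells: int, duration: float):
    """T1 rate per cell per unit time, plus per-cell counts.

    ``events`` are event-log records (dicts with at least ``event`` and
    ``ids``); only records with ``event == "T1"`` count — flips involving
    boundary ghosts are never logged as T1 by the integrator.
    """
    counts: dict[int, int] = {}
    total = 0
    for ev in events:
        if ev.get("event") != "T1":
            continue
        total += 1
        for cid in ev["ids"]:
            counts[cid] = counts.get(cid, 0) + 1
    rate = total / (n_cells * duration) if n_cells > 0 and duration > 0 else 0.0
    return rate, counts


# ---------------------------------------------------------------------------
# per-cell virial (Hardy) stress and pressure
# ---------------------------------------------------------------------------

def hardy_stress(tissue: Tissue, params: mech.MechanicalParams) -> np.ndarray:
    """Per-cell 2x2 virial stress tensors, ordered as ``mesh.cells().owners``.

    The vertex-model energy is rewritten as a function of the scalar lengths
    of two edge networks: the Voronoi junctions (carrying the perimeter and
    tension derivatives) and the Delaunay edges (carrying the area-term
    derivative through the exact kite decomposition of a Voronoi cell,
    A_i = sum_e l_junction(e) * l_delaunay(e) / 4, each kite being the pair
    of triangles spanned by a junction and its dual Delaunay edge).  Each
    edge then carries the scalar tension t_e = dE/dl_e, and the stress
    attributed to cell i collects cell i's own contributions:

        sigma_i = (1 / A_i) sum_e t_e^{(i)} l_e  (e_hat x e_hat)

    so that the area-weighted mean equals the global virial stress.  Tensile
    edges produce positive (tensile) stress entries; the pressure convention
    is handled by :func:`cell_pressures`.
    """
    geo = mech.cell_geometry(tissue)
    cx = geo["cells"]
    K, G, lam = params.per_type(tissue.n_types)
    ctype = tissue.types[cx.site_of]
    A_occ = geo["areas"][cx.cell_of]
    A0_occ = tissue.A0[cx.site_of]
    P_occ = geo["perimeters"][cx.cell_of]
    lam_e = lam[ctype, tissue.types[cx.nbr]]

    # junction edge of the occurrence: Voronoi segment, dual Delaunay edge
    seg, slen = geo["seg"], geo["slen"]
    dvec = tissue.pos[cx.nbr] - tissue.pos[cx.site_of]
    dlen = np.linalg.norm(dvec, axis=1)

    # cell's own tension contributions on each of its junction edges:
    #   perimeter: Gamma_i P_i, tension: Lambda_e, area: K_i (A_i - A0_i) l_del / 4
    t_jct = G[ctype] * P_occ + lam_e + K[ctype] * (A_occ - A0_occ) * dlen / 4.0
    # and on the dual Delaunay edge: area term only
    t_del = K[ctype] * (A_occ - A0_occ) * slen / 4.0

    with np.errstate(invalid="ignore", divide="ignore"):
        jhat = np.where(slen[:, None] > 1e-300, seg / slen[:, None], 0.0)
        dhat = dvec / dlen[:, None]
    outer_j = jhat[:, :, None] * jhat[:, None, :]
    outer_d = dhat[:, :, None] * dhat[:, None, :]
    per_occ = t_jct[:, None, None] * slen[:, None, None] * outer_j
    per_occ = per_occ + t_del[:, None, None] * dlen[:, None, None] * outer_d

    n_cells = cx.n_cells
    sigma = np.zeros((n_cells, 2, 2))
    np.add.at(sigma, cx.cell_of, per_occ)
    sigma /= geo["areas"][:, None, None]
    return sigma


def cell_pressures(tissue: Tissue, params: mech.MechanicalParams) -> np.ndarray:
    """Per-cell pressure p = -(1/2) tr(sigma); compression is positive."""
    sigma = hardy_stress(tissue, params)
    return -0.5 * np.trace(sigma, axis1=1, axis2=2)


# ---------------------------------------------------------------------------
# structure
# ---------------------------------------------------------------------------

def neighbour_distribution(tissue: Tissue, bulk_only: bool = False):
    """Normalised histogram of interior-neighbour counts per cell.

    Boundary contacts are excluded from the count.  With ``bulk_only`` cells
    touching the boundary are dropped entirely (pure bulk statistics).
    Returns ``(values, frequencies)``.
    """
    cx = tissue.mesh.cells()
    interior = tissue.interior
    counts = []
    for ci in range(cx.n_cells):
        nbrs = cx.nbr[cx.ptr[ci] : cx.ptr[ci + 1]]
        is_int = interior[nbrs]
        if bulk_only and not np.all(is_int):
            continue
        counts.append(int(np.count_nonzero(is_int)))
    vals, freq = np.unique(np.asarray(counts), return_counts=True)
    return vals, freq / freq.sum()


def demixing_index(tissue: Tissue) -> float:
    """Fraction of cell-cell junction length joining same-type cells."""
    geo = mech.cell_geometry(tissue)
    cx = geo["cells"]
    interior = tissue.interior
    cellcell = interior[cx.nbr]
    own = tissue.types[cx.site_of[cellcell]]
    other = tissue.types[cx.nbr[cellcell]]
    l = geo["slen"][cellcell]
    total = float(np.sum(l))
    if total == 0.0:
        return 1.0
    return float(np.sum(l[own == other]) / total)


# ---------------------------------------------------------------------------
# phase classification
# ---------------------------------------------------------------------------

def classify_phase(
    t1_rate: float,
    tau_alpha: float,
    run_length: float,
    tau_inst: float = np.inf,
) -> PhaseMetrics:
    """Solid / liquid / unstable classification of one run.

    solid: zero T1 rate and tau_alpha beyond the run length; unstable: the
    boundary length exceeded 1.05x its reference within the run (finite
    tau_inst); liquid otherwise.  A censored tau_alpha is reported as
    run_length * CENSOR_FACTOR in tables; here it stays +inf.
    """
    if np.isfinite(tau_inst):
        cls = "unstable"
    elif t1_rate == 0.0 and (not np.isfinite(tau_alpha) or tau_alpha > run_length):
        cls = "solid"
    else:
        cls = "liquid"
    return PhaseMetrics(
        t1_rate=t1_rate, tau_alpha=tau_alpha, tau_inst=tau_inst, classification=cls
    )
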