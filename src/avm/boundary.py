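"""Flexible ghost-particle boundary of the cell sheet.

The tissue edge is a closed line (or several lines) of ghost particles, each
with exactly two boundary neighbours.  The line carries a harmonic tension
per edge, E_line = 1/2 sum lambda (l - l0)^2, and a bending stiffness per
site, E_bend = 1/2 sum zeta (theta - pi)^2 with theta the interior angle
between the two neighbouring edges.  The connectivity (number of loops and
their membership, up to refinement) is fixed for the whole run: the sheet
may grow fingers but can never split or develop holes.

Refinement keeps the boundary resolution commensurate with the cell size:
edges longer than ``l_max`` are split at their midpoint, edges shorter than
``l_min`` are contracted by merging their endpoints.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely.geometry import LinearRing

from .tissue import Tissue, FLAG_BOUNDARY

__all__ = [
    "BoundaryParams",
    "boundary_energy",
    "boundary_forces",
    "refine",
    "topology_guard",
    "TopologyViolation",
    "boundary_length",
]


class TopologyViolation(RuntimeError):
    """The boundary line lost simplicity, connectivity or loop count."""


@dataclass
class BoundaryParams:
    """Boundary line parameters.

    mode : "fixed" boundaries never move; "free" boundaries move under the
        vertex-model and line forces (never under activity or noise).
    lam : line tension stiffness (energy / length^2), uniform per run.
    l0 : native edge length; defaults to the cell-size unit a.
    zeta : bending stiffness (energy).
    l_max, l_min : refinement thresholds; default 2*l0 and l0/2.
    """

    mode: str = "free"
    lam: float = 0.0
    l0: float = 1.0
    zeta: float = 0.0
    l_max: float | None = None
    l_min: float | None = None

    def __post_init__(self):
        if self.mode not in ("fixed", "free"):
            raise ValueError("boundary mode must be 'fixed' or 'free'")
        if self.l_max is None:
            self.l_max = 2.0 * self.l0
        if self.l_min is None:
            self.l_min = 0.5 * self.l0


def _loop_edges(loop: np.ndarray):
    return loop, np.roll(loop, -1)


def boundary_length(tissue: Tissue, loop_index: int | None = None) -> float:
    """Total length of the boundary line (all loops, or one)."""
    total = 0.0
    loops = tissue.loops if loop_index is None else [tissue.loops[loop_index]]
    for loop in loops:
        i, j = _loop_edges(loop)
        total += float(np.sum(np.linalg.norm(tissue.pos[j] - tissue.pos[i], axis=1)))
    return total


def boundary_energy(tissue: Tissue, params: BoundaryParams) -> tuple[float, float]:
    """(line-tension term, bending term) of all boundary loops."""
    line = 0.0
    bend = 0.0
    for loop in tissue.loops:
        i, j = _loop_edges(loop)
        d = tissue.pos[j] - tissue.pos[i]
        l = np.linalg.norm(d, axis=1)
        if np.any(l < 1e-12):
            raise ValueError("coincident boundary neighbours: angle undefined")
        line += 0.5 * params.lam * float(np.sum((l - params.l0) ** 2))
        if params.zeta != 0.0:
            left = np.roll(loop, 1)
            right = np.roll(loop, -1)
            u = tissue.pos[left] - tissue.pos[loop]
            v = tissue.pos[right] - tissue.pos[loop]
            nu = np.linalg.norm(u, axis=1)
            nv = np.linalg.norm(v, axis=1)
            cosang = np.clip(
                np.einsum("ij,ij->i", u, v) / (nu * nv), -1.0, 1.0
            )
            theta = np.arccos(cosang)
            bend += 0.5 * params.zeta * float(np.sum((theta - np.pi) ** 2))
    return line, bend


def boundary_forces(tissue: Tissue, params: BoundaryParams) -> np.ndarray:
    """Negative gradient of :func:`boundary_energy` w.r.t. site positions."""
    F = np.zeros_like(tissue.pos)
    for loop in tissue.loops:
        i, j = _loop_edges(loop)
        d = tissue.pos[j] - tissue.pos[i]
        l = np.linalg.norm(d, axis=1)
        unit = d / l[:, None]
        # line tension: dE/dl = lam (l - l0), pulls edge ends together when l > l0
        t = params.lam * (l - params.l0)
        fvec = t[:, None] * unit
        np.add.at(F, i, fvec)
        np.add.at(F, j, -fvec)
        if params.zeta != 0.0:
            left = np.roll(loop, 1)
            right = np.roll(loop, -1)
            u = tissue.pos[left] - tissue.pos[loop]
            v = tissue.pos[right] - tissue.pos[loop]
            nu = np.linalg.norm(u, axis=1)
            nv = np.linalg.norm(v, axis=1)
            uh = u / nu[:, None]
            vh = v / nv[:, None]
            cosang = np.clip(np.einsum("ij,ij->i", uh, vh), -1.0, 1.0)
            theta = np.arccos(cosang)
            sin = np.sqrt(np.clip(1.0 - cosang * cosang, 0.0, None))
            # dE/dtheta * dtheta/dcos = -zeta (theta - pi) / sin(theta);
            # near the straight rest state theta -> pi the ratio tends to +zeta
            coef = np.where(sin > 1e-8, -params.zeta * (theta - np.pi) / np.maximum(sin, 1e-300), params.zeta)
            # gradients of cos(theta)
            dcos_dleft = (vh - cosang[:, None] * uh) / nu[:, None]
            dcos_dright = (uh - cosang[:, None] * vh) / nv[:, None]
            gl = coef[:, None] * dcos_dleft
            gr = coef[:, None] * dcos_dright
            np.add.at(F, left, -gl)
            np.add.at(F, right, -gr)
            np.add.at(F, loop, gl + gr)
    return F


def refine(tissue: Tissue, params: BoundaryParams):
    """Split over-long boundary edges and contract under-short ones.

    Returns a list of event tuples ``("boundary_add" | "boundary_remove",
    site_ids...)``.  A proposal that would make a loop self-intersect or drop
    below 3 sites is rejected.  The loop count never changes.
    """
    events = []
    for li in range(len(tissue.loops)):
        loop = tissue.loops[li]
        # split pass
        i, j = _loop_edges(loop)
        l = np.linalg.norm(tissue.pos[j] - tissue.pos[i], axis=1)
        long_edges = np.nonzero(l > params.l_max)[0]
        for k in reversed(long_edges.tolist()):
            a, b = loop[k], loop[(k + 1) % len(loop)]
            mid = 0.5 * (tissue.pos[a] + tissue.pos[b])
            proposal = np.insert(tissue.pos[loop], k + 1, mid, axis=0)
            if len(proposal) >= 4 and not LinearRing(proposal).is_simple:
                import warnings

                warnings.warn("boundary split rejected: would self-intersect")
                continue
            flag = tissue.flags[a]
            new = tissue.append_sites(
                pos=mid[None, :],
                flags=[flag],
                types=[tissue.boundary_type],
                A0=[np.nan],
                age=[0.0],
                theta=[0.0],
            )[0]
            loop = np.insert(loop, k + 1, new)
            tissue.loops[li] = loop
            events.append(("boundary_add", int(tissue.ids[new])))
        # merge pass
        merged = True
        while merged:
            merged = False
            loop = tissue.loops[li]
            if len(loop) <= 3:
                break
            i, j = _loop_edges(loop)
            l = np.linalg.norm(tissue.pos[j] - tissue.pos[i], axis=1)
            short = np.nonzero(l < params.l_min)[0]
            for k in short.tolist():
                loop = tissue.loops[li]
                if len(loop) <= 3:
                    break
                a, b = int(loop[k]), int(loop[(k + 1) % len(loop)])
                mid = 0.5 * (tissue.pos[a] + tissue.pos[b])
                keep_positions = tissue.pos[loop].copy()
                keep_positions[k] = mid
                proposal = np.delete(keep_positions, (k + 1) % len(loop), axis=0)
                if len(proposal) >= 4 and not LinearRing(proposal).is_simple:
                    import warnings

                    warnings.warn("boundary merge rejected: would self-intersect")
                    continue
                removed_id = int(tissue.ids[b])
                tissue.pos[a] = mid
                tissue.delete_sites([b])
                events.append(("boundary_remove", removed_id))
                merged = True
                break  # indices shifted: restart scan
    if events:
        tissue.remesh()
    return events


def topology_guard(tissue: Tissue, expected_loops: int | None = None) -> None:
    """Verify the boundary invariants; raise :class:`TopologyViolation` if broken.

    Checks: every boundary particle belongs to exactly one loop (two
    neighbours), every loop has >= 3 sites and is a simple polygon, and the
    loop count matches ``expected_loops`` when given.
    """
    seen: dict[int, int] = {}
    for li, loop in enumerate(tissue.loops):
        if len(loop) < 3:
            raise TopologyViolation(f"boundary loop {li} has fewer than 3 sites")
        for s in loop:
            if int(s) in seen:
                raise TopologyViolation(
                    f"site {int(s)} appears in loops {seen[int(s)]} and {li}: "
                    "a boundary particle must have exactly two neighbours"
                )
            seen[int(s)] = li
        if not LinearRing(tissue.pos[loop]).is_simple:
            raise TopologyViolation(f"boundary loop {li} self-intersects")
    flagged = set(np.nonzero(tissue.flags != 0)[0].tolist())
    if flagged != set(seen):
        raise TopologyViolation("boundary flags and loop membership disagree")
    if expected_loops is not None and len(tissue.loops) != expected_loops:
        raise TopologyViolation(
            f"loop count changed: expected {expected_loops}, found {len(tissue.loops)}"
        )
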