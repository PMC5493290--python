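"""Cell growth, division and death.

Growth compounds the native (target) area every step,
A0(t + dt) = (1 + eta dt) A0(t), and ages every cell by dt.  A cell whose
current Voronoi area exceeds the critical area A_c divides with rate
chi (A - A_c); divisions are checked every ``check_every`` steps with the
probability accumulated over the true elapsed interval, so chi is
independent of the time-step choice.  Daughters are placed symmetrically
about the mother along its polarity vector, inherit half of the mother's
native area each, and start at age zero.  Cells that reach ``max_age`` are
removed instantaneously.  The Delaunay triangulation is rebuilt after every
division or death event.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import mechanics as mech
from .tissue import Tissue, FLAG_INTERIOR

__all__ = [
    "PopulationParams",
    "grow",
    "division_probability",
    "divide",
    "remove",
    "population_update",
]


@dataclass
class PopulationParams:
    """Growth / division / death parameters.

    eta : native-area growth rate per unit time.
    A_c : critical division area (length^2).
    chi : division-rate constant (1 / (area * time)).
    max_age : removal age; ``inf`` disables death (the default — growth runs
        in the source study have no apoptosis).
    check_every : steps between division/death checks.
    daughter_offset : centre-to-centre separation of fresh daughters.
    """

    eta: float = 0.0
    A_c: float = 2.8
    chi: float = 0.0
    max_age: float = np.inf
    check_every: int = 25
    daughter_offset: float = 0.5
    enable_growth: bool = True
    enable_death: bool = False

    def __post_init__(self):
        if self.check_every < 1:
            raise ValueError("check_every must be >= 1")
        if min(self.eta, self.A_c, self.chi, self.daughter_offset) < 0:
            raise ValueError("population parameters must be non-negative")


def grow(tissue: Tissue, params: PopulationParams, dt: float) -> None:
    """Compound native areas by (1 + eta dt) and advance ages by dt, in place."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    interior = tissue.interior
    if params.enable_growth and params.eta != 0.0:
        tissue.A0[interior] *= 1.0 + params.eta * dt
    tissue.age[interior] += dt


def division_probability(area: float, params: PopulationParams, interval: float) -> float:
    """Probability that a cell of the given area divides within ``interval``.

    The rate is chi * max(A - A_c, 0); over a check interval the probability
    is rate * interval, capped at 1.
    """
    if interval <= 0:
        raise ValueError("interval must be positive")
    rate = params.chi * max(area - params.A_c, 0.0)
    return min(rate * interval, 1.0)


def divide(
    tissue: Tissue, cell_index: int, params: PopulationParams, rng: np.random.Generator
):
    """Replace one cell by two daughters along its polarity; rebuild the mesh.

    Returns the event record ``("division", mother_id, d1_id, d2_id)``.
    """
    if tissue.flags[cell_index] != FLAG_INTERIOR:
        raise ValueError("only interior cells divide")
    r = tissue.pos[cell_index].copy()
    n = np.array([np.cos(tissue.theta[cell_index]), np.sin(tissue.theta[cell_index])])
    off = 0.5 * params.daughter_offset * n
    p1, p2 = r + off, r - off
    # collision guard: jitter if a daughter lands on an existing site
    for p in (p1, p2):
        d = np.linalg.norm(tissue.pos - p, axis=1)
        d[cell_index] = np.inf
        if np.min(d) < 1e-6:
            import warnings

            warnings.warn("daughter collides with an existing site; jittering")
            p += rng.normal(scale=1e-4, size=2)
    mother_id = int(tissue.ids[cell_index])
    mother_type = int(tissue.types[cell_index])
    half_A0 = 0.5 * float(tissue.A0[cell_index])
    theta0 = float(tissue.theta[cell_index])
    tissue.delete_sites([cell_index])
    new = tissue.append_sites(
        pos=np.vstack([p1, p2]),
        flags=[FLAG_INTERIOR, FLAG_INTERIOR],
        types=[mother_type, mother_type],
        A0=[half_A0, half_A0],
        age=[0.0, 0.0],
        theta=[theta0, theta0],
    )
    tissue.remesh()
    return ("division", mother_id, int(tissue.ids[new[0]]), int(tissue.ids[new[1]]))


def remove(tissue: Tissue, cell_index: int):
    """Remove a cell instantaneously; neighbours tile the vacated area.

    Returns the event record ``("death", cell_id)``.
    """
    if tissue.flags[cell_index] != FLAG_INTERIOR:
        raise ValueError("only interior cells can be removed")
    if tissue.n_cells <= 1:
        raise RuntimeError("cannot remove the last interior cell")
    cell_id = int(tissue.ids[cell_index])
    tissue.delete_sites([cell_index])
    tissue.remesh()
    return ("death", cell_id)


def population_update(
    tissue: Tissue,
    params: PopulationParams,
    rng: np.random.Generator,
    interval: float,
):
    """Division and death sweep over all cells (called every check_every steps).

    ``interval`` is the elapsed simulation time since the previous sweep.
    Returns the list of event records.  Uses current Voronoi areas; the mesh
    is rebuilt after each topological event so later decisions in the same
    sweep see a consistent tessellation.
    """
    events = []
    if params.enable_death and np.isfinite(params.max_age):
        while True:
            idx = tissue.interior_idx
            old = idx[tissue.age[idx] >= params.max_age]
            if len(old) == 0 or tissue.n_cells <= 1:
                break
            events.append(remove(tissue, int(old[0])))
    if params.chi > 0.0:
        geo = mech.cell_geometry(tissue)
        owners = geo["cells"].owners
        areas = geo["areas"]
        probs = np.minimum(params.chi * np.clip(areas - params.A_c, 0.0, None) * interval, 1.0)
        draws = rng.random(len(probs))
        dividing_ids = tissue.ids[owners[draws < probs]]
        for cid in dividing_ids:
            idx = int(np.nonzero(tissue.ids == cid)[0][0])
            events.append(divide(tissue, idx, params, rng))
    return events
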