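"""Central tissue container: particles, flags, per-cell state and the mesh.

A tissue is a set of particles in the plane.  *Interior* particles are cell
centres and own a Voronoi cell; *boundary* particles are ghosts that mark the
tissue edge and are strung together into one or more closed boundary loops;
*wall* particles are immobile obstacles (e.g. a confinement cavity).

The Delaunay mesh is built lazily and kept current by equiangulation.  Moving
particles marks the mesh stale; force evaluation on a stale mesh is an error
(the caller must equiangulate first), which catches mis-ordered integration
loops early.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import TriMesh, build_triangulation

__all__ = ["Tissue", "FLAG_INTERIOR", "FLAG_BOUNDARY", "FLAG_WALL"]

FLAG_INTERIOR = 0
FLAG_BOUNDARY = 1
FLAG_WALL = 2

_FLAG_NAMES = {FLAG_INTERIOR: "interior", FLAG_BOUNDARY: "boundary", FLAG_WALL: "wall"}
_FLAG_CODES = {v: k for k, v in _FLAG_NAMES.items()}


@dataclass
class Tissue:
    """Particle arrays plus boundary connectivity.

    Attributes
    ----------
    pos : (M, 2) particle positions, units of the soft-core range ``a``.
    flags : (M,) int, one of FLAG_INTERIOR / FLAG_BOUNDARY / FLAG_WALL.
    types : (M,) int cell type; boundary and wall particles carry
        ``n_types`` (the reserved boundary type "M").
    A0 : (M,) native (target) cell area; NaN for non-interior particles.
    age : (M,) cell age in simulation time units.
    theta : (M,) polarity angle; meaningful for interior particles only.
    ids : (M,) stable integer identifiers, preserved across divisions and
        removals (used by event logs and trajectory tracking).
    loops : list of index arrays, each a closed boundary loop in cyclic
        order.  Loop membership and connectivity are fixed for the whole run
        except for boundary refinement (ghost insertion/merging).
    loop_fixed : per-loop flag; fixed loops never move (walls, clamped rims).
    n_types : number of distinct cell types (>= 1).
    """

    pos: np.ndarray
    flags: np.ndarray
    types: np.ndarray
    A0: np.ndarray
    age: np.ndarray
    theta: np.ndarray
    ids: np.ndarray
    loops: list[np.ndarray] = field(default_factory=list)
    loop_fixed: list[bool] = field(default_factory=list)
    n_types: int = 1

    _mesh: TriMesh | None = field(default=None, repr=False)
    _stale: bool = field(default=True, repr=False)
    _next_id: int = field(default=0, repr=False)

    def __post_init__(self):
        self.pos = np.ascontiguousarray(self.pos, dtype=float)
        self.flags = np.asarray(self.flags, dtype=np.int8)
        self.types = np.asarray(self.types, dtype=np.int64)
        self.A0 = np.asarray(self.A0, dtype=float)
        self.age = np.asarray(self.age, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        self.ids = np.asarray(self.ids, dtype=np.int64)
        if self._next_id <= (self.ids.max() if len(self.ids) else -1):
            self._next_id = int(self.ids.max()) + 1

    # -- constructors -------------------------------------------------------

    @classmethod
    def build(
        cls,
        interior_pos: np.ndarray,
        boundary_loops_pos: list[np.ndarray],
        *,
        types: np.ndarray | None = None,
        n_types: int = 1,
        A0: float | np.ndarray = np.pi,
        loop_fixed: list[bool] | None = None,
        theta: np.ndarray | None = None,
        wall_loops: list[int] | None = None,
    ) -> "Tissue":
        """Assemble a tissue from interior positions and ghost-loop positions."""
        n_int = len(interior_pos)
        pos = [np.asarray(interior_pos, dtype=float)]
        flags = [np.zeros(n_int, dtype=np.int8)]
        loops = []
        offset = n_int
        wall_loops = set(wall_loops or [])
        for li, lp in enumerate(boundary_loops_pos):
            m = len(lp)
            pos.append(np.asarray(lp, dtype=float))
            flag = FLAG_WALL if li in wall_loops else FLAG_BOUNDARY
            flags.append(np.full(m, flag, dtype=np.int8))
            loops.append(np.arange(offset, offset + m, dtype=np.int64))
            offset += m
        M = offset
        pos_arr = np.vstack(pos)
        flags_arr = np.concatenate(flags)
        types_arr = np.full(M, n_types, dtype=np.int64)
        if types is None:
            types_arr[:n_int] = 0
        else:
            types_arr[:n_int] = np.asarray(types, dtype=np.int64)
        A0_arr = np.full(M, np.nan)
        A0_arr[:n_int] = A0
        theta_arr = np.zeros(M)
        if theta is not None:
            theta_arr[:n_int] = theta
        if loop_fixed is None:
            loop_fixed = [li in wall_loops for li in range(len(loops))]
        return cls(
            pos=pos_arr,
            flags=flags_arr,
            types=types_arr,
            A0=A0_arr,
            age=np.zeros(M),
            theta=theta_arr,
            ids=np.arange(M, dtype=np.int64),
            loops=loops,
            loop_fixed=list(loop_fixed),
            n_types=n_types,
        )

    # -- views --------------------------------------------------------------

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def interior(self) -> np.ndarray:
        return self.flags == FLAG_INTERIOR

    @property
    def interior_idx(self) -> np.ndarray:
        return np.nonzero(self.interior)[0]

    @property
    def n_cells(self) -> int:
        return int(np.count_nonzero(self.interior))

    @property
    def boundary_type(self) -> int:
        """Reserved type index "M" for boundary/wall contacts."""
        return self.n_types

    # -- mesh management ----------------------------------------------------

    @property
    def mesh(self) -> TriMesh:
        if self._mesh is None:
            self.remesh()
        return self._mesh

    @property
    def mesh_stale(self) -> bool:
        # a not-yet-built mesh is fine (it will be built from scratch);
        # stale means sites moved since the last equiangulation/rebuild
        return self._mesh is not None and self._stale

    def remesh(self) -> TriMesh:
        """Full from-scratch Delaunay rebuild (after divisions, deaths, edits)."""
        self._mesh = build_triangulation(self.pos, self.interior, self.loops)
        self._stale = False
        return self._mesh

    def mark_moved(self) -> None:
        """Declare that positions changed; forces are invalid until equiangulation."""
        self._stale = True

    def equiangulate(self):
        """Restore the Delaunay property after motion; returns (flips, quads)."""
        if self._mesh is None:
            self.remesh()
            return 0, []
        try:
            result = self._mesh.equiangulate()
            # validate: a corrupted mesh (inverted triangles after too large
            # a move) can survive the flip pass but break the cell complex
            self._mesh.cells()
        except Exception:
            # rebuild from scratch; T1 bookkeeping for this step is lost,
            # which only happens in the pathological regime the rebuild fixes
            self.remesh()
            return 0, []
        self._stale = False
        return result

    # -- surgery ------------------------------------------------------------

    def append_sites(self, pos, flags, types, A0, age, theta) -> np.ndarray:
        """Append particles; returns their indices.  Invalidates the mesh."""
        k = len(pos)
        idx = np.arange(self.n_sites, self.n_sites + k, dtype=np.int64)
        self.pos = np.vstack([self.pos, np.asarray(pos, dtype=float)])
        self.flags = np.concatenate([self.flags, np.asarray(flags, dtype=np.int8)])
        self.types = np.concatenate([self.types, np.asarray(types, dtype=np.int64)])
        self.A0 = np.concatenate([self.A0, np.asarray(A0, dtype=float)])
        self.age = np.concatenate([self.age, np.asarray(age, dtype=float)])
        self.theta = np.concatenate([self.theta, np.asarray(theta, dtype=float)])
        new_ids = np.arange(self._next_id, self._next_id + k, dtype=np.int64)
        self._next_id += k
        self.ids = np.concatenate([self.ids, new_ids])
        self._mesh = None
        return idx

    def delete_sites(self, indices) -> None:
        """Remove particles by index, remapping boundary loops.  Invalidates mesh."""
        indices = np.atleast_1d(np.asarray(indices, dtype=np.int64))
        keep = np.ones(self.n_sites, dtype=bool)
        keep[indices] = False
        remap = np.cumsum(keep) - 1
        self.pos = self.pos[keep]
        self.flags = self.flags[keep]
        self.types = self.types[keep]
        self.A0 = self.A0[keep]
        self.age = self.age[keep]
        self.theta = self.theta[keep]
        self.ids = self.ids[keep]
        new_loops = []
        for loop in self.loops:
            kept = loop[keep[loop]]
            new_loops.append(remap[kept])
        self.loops = new_loops
        self._mesh = None

    def copy(self) -> "Tissue":
        return Tissue(
            pos=self.pos.copy(),
            flags=self.flags.copy(),
            types=self.types.copy(),
            A0=self.A0.copy(),
            age=self.age.copy(),
            theta=self.theta.copy(),
            ids=self.ids.copy(),
            loops=[lp.copy() for lp in self.loops],
            loop_fixed=list(self.loop_fixed),
            n_types=self.n_types,
        )
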