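"""Delaunay triangulation of cell centres and its dual Voronoi tessellation.

The tissue is represented by particles (cell centres plus boundary "ghosts")
whose Delaunay triangulation is maintained incrementally by *equiangulation*:
any interior edge whose opposite angles sum to more than 180 degrees is
flipped, and the procedure is repeated until no such edge remains.  A single
flip changes exactly one edge of the dual Voronoi tessellation and therefore
realises a T1 neighbour exchange between the four cells around the flipped
edge.

Voronoi vertices are circumcenters of Delaunay triangles; the analytic
Jacobian of a circumcenter with respect to its three sites is what turns
gradients of the vertex-model energy (a function of Voronoi vertices) into
forces on cell centres.

Only planar, non-periodic triangulations are supported.  Every interior site
must be fully surrounded by triangles, which in practice means the point set
must include a closed ring (or rings) of boundary ghosts enclosing all
interior sites.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay as _SciPyDelaunay
from scipy.spatial import QhullError

__all__ = [
    "DegenerateTriangleError",
    "MeshError",
    "TriMesh",
    "CellComplex",
    "VoronoiCell",
    "circumcenter",
    "triangle_circumcenters",
    "triangle_jacobians",
    "vertex_jacobian",
    "build_triangulation",
    "junction_length",
]

#: relative tolerance on the incircle determinant below which a cocircular
#: configuration is treated as a tie and NOT flipped (strict ">" trigger).
INCIRCLE_RTOL = 1e-12


class DegenerateTriangleError(ValueError):
    """Raised when a triangle is (near-)collinear and has no circumcenter."""


class MeshError(RuntimeError):
    """Raised when the triangulation is structurally invalid or corrupted."""


# ---------------------------------------------------------------------------
# circumcenters and their Jacobians
# ---------------------------------------------------------------------------

def triangle_circumcenters(points: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    """Circumcenters of a batch of triangles, shape (T, 2).

    Computed in coordinates relative to the first corner for numerical
    stability.  Raises :class:`DegenerateTriangleError` if any triangle is
    degenerate (collinear corners).
    """
    p1 = points[triangles[:, 0]]
    b = points[triangles[:, 1]] - p1
    c = points[triangles[:, 2]] - p1
    d = 2.0 * (b[:, 0] * c[:, 1] - b[:, 1] * c[:, 0])
    b2 = np.einsum("ij,ij->i", b, b)
    c2 = np.einsum("ij,ij->i", c, c)
    scale = np.maximum(b2, c2)
    bad = np.abs(d) <= 1e-12 * scale
    if np.any(bad):
        t = int(np.nonzero(bad)[0][0])
        raise DegenerateTriangleError(
            f"degenerate triangle between sites {tuple(int(s) for s in triangles[t])}"
        )
    ux = (c[:, 1] * b2 - b[:, 1] * c2) / d
    uy = (b[:, 0] * c2 - c[:, 0] * b2) / d
    return p1 + np.stack([ux, uy], axis=1)


def circumcenter(p1, p2, p3) -> np.ndarray:
    """Circumcenter of a single triangle (equidistant from all three corners)."""
    pts = np.asarray([p1, p2, p3], dtype=float)
    return triangle_circumcenters(pts, np.array([[0, 1, 2]]))[0]


def triangle_jacobians(points: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    """Analytic derivative of each circumcenter w.r.t. its three sites.

    Returns an array of shape (T, 3, 2, 2): ``J[t, s, a, b]`` is the partial
    derivative of component ``a`` of the circumcenter of triangle ``t`` with
    respect to component ``b`` of site ``s`` of that triangle.  The three
    per-site blocks of one triangle sum to the identity (a rigid translation
    of the sites translates the circumcenter).

    The computation is centred on the triangle centroid; the Jacobian itself
    is translation invariant.
    """
    tri_pts = points[triangles]  # (T, 3, 2)
    centred = tri_pts - tri_pts.mean(axis=1, keepdims=True)
    x = centred[..., 0]  # (T, 3)
    y = centred[..., 1]
    s = x * x + y * y
    x1, x2, x3 = x[:, 0], x[:, 1], x[:, 2]
    y1, y2, y3 = y[:, 0], y[:, 1], y[:, 2]
    s1, s2, s3 = s[:, 0], s[:, 1], s[:, 2]

    d = 2.0 * (x1 * (y2 - y3) + x2 * (y3 - y1) + x3 * (y1 - y2))
    scale = np.max(s, axis=1)
    bad = np.abs(d) <= 1e-12 * scale
    if np.any(bad):
        t = int(np.nonzero(bad)[0][0])
        area2 = d[t] / 2.0
        raise DegenerateTriangleError(
            f"degenerate triangle between sites {tuple(int(v) for v in triangles[t])}"
            f" (doubled signed area {area2:.3e})"
        )
    nx = s1 * (y2 - y3) + s2 * (y3 - y1) + s3 * (y1 - y2)
    ny = s1 * (x3 - x2) + s2 * (x1 - x3) + s3 * (x2 - x1)
    cx = nx / d
    cy = ny / d

    T = len(triangles)
    J = np.empty((T, 3, 2, 2))
    # cyclic permutations (1,2,3), (2,3,1), (3,1,2)
    corner = [
        (x1, y1, s2, s3, y2 - y3, x3 - x2),
        (x2, y2, s3, s1, y3 - y1, x1 - x3),
        (x3, y3, s1, s2, y1 - y2, x2 - x1),
    ]
    for i, (xi, yi, s_next, s_prev, dy, dx) in enumerate(corner):
        # dNx/dxi, dNx/dyi, dNy/dxi, dNy/dyi; dD/dxi = 2*dy, dD/dyi = 2*dx
        dnx_dx = 2.0 * xi * dy
        dnx_dy = 2.0 * yi * dy - s_next + s_prev
        dny_dx = 2.0 * xi * dx + s_next - s_prev
        dny_dy = 2.0 * yi * dx
        dd_dx = 2.0 * dy
        dd_dy = 2.0 * dx
        J[:, i, 0, 0] = (dnx_dx - cx * dd_dx) / d
        J[:, i, 0, 1] = (dnx_dy - cx * dd_dy) / d
        J[:, i, 1, 0] = (dny_dx - cy * dd_dx) / d
        J[:, i, 1, 1] = (dny_dy - cy * dd_dy) / d
    return J


def vertex_jacobian(mesh: "TriMesh", triangle_id: int, site_id: int) -> np.ndarray:
    """2x2 Jacobian of the Voronoi vertex dual to ``triangle_id`` w.r.t. one site.

    ``site_id`` must be one of the three corners of the triangle.  A
    near-degenerate triangle raises :class:`DegenerateTriangleError` with a
    condition diagnostic.
    """
    tri = mesh.triangles[triangle_id]
    local = np.nonzero(tri == site_id)[0]
    if len(local) == 0:
        raise ValueError(f"site {site_id} is not a corner of triangle {triangle_id}")
    J = triangle_jacobians(mesh.points, mesh.triangles[triangle_id : triangle_id + 1])
    return J[0, int(local[0])]


# ---------------------------------------------------------------------------
# incircle predicate
# ---------------------------------------------------------------------------

def _incircle(points, a, b, c, d):
    """Strictly positive when site d lies inside the circumcircle of CCW (a,b,c).

    Vectorised over arrays of indices.  Ties (cocircular within
    ``INCIRCLE_RTOL`` of the natural scale) return non-positive: no flip.
    """
    pa = points[a] - points[d]
    pb = points[b] - points[d]
    pc = points[c] - points[d]
    a2 = np.einsum("...i,...i->...", pa, pa)
    b2 = np.einsum("...i,...i->...", pb, pb)
    c2 = np.einsum("...i,...i->...", pc, pc)
    det = (
        pa[..., 0] * (pb[..., 1] * c2 - pc[..., 1] * b2)
        - pa[..., 1] * (pb[..., 0] * c2 - pc[..., 0] * b2)
        + a2 * (pb[..., 0] * pc[..., 1] - pb[..., 1] * pc[..., 0])
    )
    scale = np.maximum(np.maximum(a2, b2), c2)
    return det - INCIRCLE_RTOL * scale * scale


def _signed_area(points, a, b, c):
    u = points[b] - points[a]
    v = points[c] - points[a]
    return u[..., 0] * v[..., 1] - u[..., 1] * v[..., 0]


# ---------------------------------------------------------------------------
# cell complex: ordered Voronoi polygons of interior sites
# ---------------------------------------------------------------------------

@dataclass
class CellComplex:
    """Flattened, counter-clockwise ordered Voronoi polygons of interior sites.

    One "vertex occurrence" is one corner of one cell polygon; different cells
    sharing the same Voronoi vertex have distinct occurrences.

    Attributes
    ----------
    owners : (n_cells,) site index owning each cell.
    ptr : (n_cells + 1,) block boundaries into the occurrence arrays.
    tri : (L,) triangle index whose circumcenter is the occurrence's position.
    nbr : (L,) neighbouring site across the polygon edge occurrence -> next.
    nxt, prv : (L,) cyclic successor / predecessor occurrence indices.
    cell_of : (L,) owning cell index of each occurrence.
    """

    owners: np.ndarray
    ptr: np.ndarray
    tri: np.ndarray
    nbr: np.ndarray
    nxt: np.ndarray
    prv: np.ndarray
    cell_of: np.ndarray

    @property
    def n_cells(self) -> int:
        return len(self.owners)

    @property
    def site_of(self) -> np.ndarray:
        return self.owners[self.cell_of]


@dataclass
class VoronoiCell:
    """Single Voronoi cell: ordered vertex coordinates plus area/perimeter."""

    owner: int
    vertices: np.ndarray  # (n, 2), counter-clockwise
    neighbours: np.ndarray  # (n,) site across each edge vertices[k] -> vertices[k+1]

    @property
    def area(self) -> float:
        v = self.vertices
        w = np.roll(v, -1, axis=0)
        return 0.5 * float(np.sum(v[:, 0] * w[:, 1] - v[:, 1] * w[:, 0]))

    @property
    def perimeter(self) -> float:
        v = self.vertices
        return float(np.sum(np.linalg.norm(np.roll(v, -1, axis=0) - v, axis=1)))


# ---------------------------------------------------------------------------
# the mesh
# ---------------------------------------------------------------------------

class TriMesh:
    """Triangulation of sites with interior/boundary flags and flip maintenance.

    ``points`` is held by reference: the owner may move sites in place and
    then call :meth:`equiangulate` to restore the Delaunay property.  The
    ordered cell complex (:meth:`cells`) is cached and only invalidated by
    topology changes (flips), not by smooth site motion.
    """

    def __init__(self, points: np.ndarray, interior: np.ndarray, triangles: np.ndarray):
        self.points = points
        self.interior = np.asarray(interior, dtype=bool)
        self.triangles = np.ascontiguousarray(triangles, dtype=np.int64)
        self._orient()
        self._canonicalize()
        self._cells: CellComplex | None = None

    # -- basic structure ----------------------------------------------------

    def _orient(self) -> None:
        area = _signed_area(self.points, *self.triangles.T)
        flip = area < 0
        if np.any(flip):
            t = self.triangles
            t[flip, 1], t[flip, 2] = t[flip, 2].copy(), t[flip, 1].copy()

    def _canonicalize(self) -> None:
        """Rotate and sort triangles into a position-independent order.

        Force assembly sums floating-point contributions in triangle order;
        a canonical order makes trajectories bit-reproducible regardless of
        whether the mesh arrived via incremental flips or a from-scratch
        rebuild (e.g. on restart from a snapshot).
        """
        t = self.triangles
        n = len(t)
        rows = np.arange(n)
        k = np.argmin(t, axis=1)
        t = np.stack([t[rows, k], t[rows, (k + 1) % 3], t[rows, (k + 2) % 3]], axis=1)
        order = np.lexsort((t[:, 2], t[:, 1], t[:, 0]))
        self.triangles = np.ascontiguousarray(t[order])

    @property
    def n_sites(self) -> int:
        return len(self.points)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def edges(self) -> np.ndarray:
        """Unique undirected Delaunay edges, shape (E, 2), sorted pairs."""
        t = self.triangles
        e = np.vstack([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])
        e.sort(axis=1)
        return np.unique(e, axis=0)

    def _edge_map(self) -> dict[tuple[int, int], list[int]]:
        emap: dict[tuple[int, int], list[int]] = {}
        for t, (a, b, c) in enumerate(self.triangles):
            for u, v in ((a, b), (b, c), (c, a)):
                key = (u, v) if u < v else (v, u)
                emap.setdefault(key, []).append(t)
        return emap

    # -- equiangulation -----------------------------------------------------

    def _violated_edges(self) -> list[tuple[int, int]]:
        """Vectorised scan for interior edges failing the Delaunay condition."""
        t = self.triangles
        e = np.vstack([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])
        opp = np.concatenate([t[:, 2], t[:, 0], t[:, 1]])
        es = np.sort(e, axis=1)
        order = np.lexsort((es[:, 1], es[:, 0]))
        es = es[order]
        opp = opp[order]
        same = np.all(es[:-1] == es[1:], axis=1)
        i = np.nonzero(same)[0]
        if len(i) == 0:
            return []
        a, b = es[i, 0].copy(), es[i, 1].copy()
        c, d = opp[i], opp[i + 1]
        # orient (a, b, c) counter-clockwise before the signed predicate
        cw = _signed_area(self.points, a, b, c) < 0
        a[cw], b[cw] = b[cw], a[cw].copy()
        bad = _incircle(self.points, a, b, c, d) > 0
        return [(int(x), int(y)) for x, y in zip(a[bad], b[bad])]

    def is_delaunay(self) -> bool:
        return len(self._violated_edges()) == 0

    def equiangulate(self, max_flips: int | None = None):
        """Flip edges until the Delaunay angle condition holds everywhere.

        Returns ``(flip_count, flipped)`` where ``flipped`` is a list of
        quadruples ``(a, b, c, d)``: the old Delaunay edge ``a-b`` was
        replaced by ``c-d``.  When all four sites are interior cells the flip
        is a T1 neighbour exchange between the corresponding Voronoi cells.

        Edges whose flip would create an inverted triangle are skipped and
        re-queued; exceeding a safety bound on the number of flips raises
        :class:`MeshError` (a corrupted mesh, e.g. after too large a move).
        """
        seed = self._violated_edges()
        if not seed:
            return 0, []
        emap = self._edge_map()
        pts = self.points
        tris = self.triangles
        if max_flips is None:
            max_flips = 20 * len(tris) + 1000
        queue: deque[tuple[int, int]] = deque(seed)
        flips = 0
        flipped: list[tuple[int, int, int, int]] = []
        attempts = 0
        while queue:
            attempts += 1
            if attempts > 50 * max_flips:
                raise MeshError("equiangulation did not converge (corrupted mesh?)")
            a, b = queue.popleft()
            key = (a, b) if a < b else (b, a)
            ts = emap.get(key)
            if ts is None or len(ts) != 2:
                continue
            t1, t2 = ts
            tri1 = tris[t1]
            # orient so that t1 holds the directed edge a->b
            if not _directed_in(tri1, a, b):
                t1, t2 = t2, t1
                tri1 = tris[t1]
            tri2 = tris[t2]
            c = _third(tri1, a, b)
            d = _third(tri2, a, b)
            if _incircle(pts, a, b, c, d) <= 0:
                continue
            # flip a-b -> c-d; new triangles (a, d, c) and (d, b, c)
            if _signed_area(pts, a, d, c) <= 0 or _signed_area(pts, d, b, c) <= 0:
                queue.append((a, b))  # skip and re-queue
                continue
            tris[t1] = (a, d, c)
            tris[t2] = (d, b, c)
            # update edge map
            del emap[key]
            newkey = (c, d) if c < d else (d, c)
            emap[newkey] = [t1, t2]
            _replace(emap, (a, d), t2, t1)  # edge (a,d) moved from t2 to t1
            _replace(emap, (b, c), t1, t2)  # edge (b,c) moved from t1 to t2
            flips += 1
            flipped.append((int(a), int(b), int(c), int(d)))
            if flips > max_flips:
                raise MeshError("equiangulation exceeded flip safety bound")
            for u, v in ((a, d), (d, b), (b, c), (c, a)):
                queue.append((u, v))
        if flips:
            self._canonicalize()
        self._cells = None
        return flips, flipped

    # -- dual cells ---------------------------------------------------------

    def cells(self) -> CellComplex:
        if self._cells is None:
            self._cells = self._build_cells()
        return self._cells

    def _build_cells(self) -> CellComplex:
        tris = self.triangles
        # wedge[(i, j)] = (t, k): triangle t contains the CCW wedge at i
        # entered along edge (i, j) and exited along (i, k).
        wedge: dict[tuple[int, int], tuple[int, int]] = {}
        start: dict[int, int] = {}
        interior = self.interior
        for t in range(len(tris)):
            a, b, c = tris[t]
            for i, j, k in ((a, b, c), (b, c, a), (c, a, b)):
                if interior[i]:
                    wedge[(i, j)] = (t, k)
                    start.setdefault(int(i), int(j))
        owners = np.nonzero(interior)[0]
        ptr = [0]
        tri_occ: list[int] = []
        nbr_occ: list[int] = []
        cell_of: list[int] = []
        for ci, i in enumerate(owners):
            i = int(i)
            if i not in start:
                raise MeshError(f"interior site {i} has no incident triangles")
            j0 = start[i]
            j = j0
            guard = 0
            while True:
                entry = wedge.get((i, j))
                if entry is None:
                    raise MeshError(
                        f"interior site {i} is not fully surrounded by triangles; "
                        "add boundary ghosts so its Voronoi cell is finite"
                    )
                t, k = entry
                tri_occ.append(t)
                nbr_occ.append(k)
                cell_of.append(ci)
                j = k
                guard += 1
                if j == j0:
                    break
                if guard > len(tris) + 3:
                    raise MeshError(f"cell walk around site {i} did not close")
            ptr.append(len(tri_occ))
        ptr_arr = np.asarray(ptr, dtype=np.int64)
        L = ptr_arr[-1]
        nxt = np.arange(1, L + 1, dtype=np.int64)
        prv = np.arange(-1, L - 1, dtype=np.int64)
        nxt[ptr_arr[1:] - 1] = ptr_arr[:-1]
        prv[ptr_arr[:-1]] = ptr_arr[1:] - 1
        return CellComplex(
            owners=owners.astype(np.int64),
            ptr=ptr_arr,
            tri=np.asarray(tri_occ, dtype=np.int64),
            nbr=np.asarray(nbr_occ, dtype=np.int64),
            nxt=nxt,
            prv=prv,
            cell_of=np.asarray(cell_of, dtype=np.int64),
        )

    def dual_cells(self) -> list[VoronoiCell]:
        """Materialise the Voronoi cell of every interior site."""
        cx = self.cells()
        cc = triangle_circumcenters(self.points, self.triangles)
        out = []
        for ci in range(cx.n_cells):
            sl = slice(cx.ptr[ci], cx.ptr[ci + 1])
            out.append(
                VoronoiCell(
                    owner=int(cx.owners[ci]),
                    vertices=cc[cx.tri[sl]],
                    neighbours=cx.nbr[sl].copy(),
                )
            )
        return out


def _directed_in(tri, a, b) -> bool:
    for u, v in ((tri[0], tri[1]), (tri[1], tri[2]), (tri[2], tri[0])):
        if u == a and v == b:
            return True
    return False


def _third(tri, a, b) -> int:
    for v in tri:
        if v != a and v != b:
            return int(v)
    raise MeshError("degenerate triangle in flip")


def _replace(emap, edge, drop, keep):
    key = (edge[0], edge[1]) if edge[0] < edge[1] else (edge[1], edge[0])
    ts = emap.get(key)
    if ts is None:
        return
    # ensure the triangle list reflects the post-flip incidence
    fixed = []
    for t in ts:
        fixed.append(keep if t == drop else t)
    # deduplicate while preserving pairs
    emap[key] = list(dict.fromkeys(fixed))


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

def build_triangulation(
    points: np.ndarray,
    interior: np.ndarray,
    boundary_loops: list[np.ndarray] | None = None,
) -> TriMesh:
    """From-scratch Delaunay triangulation of interior sites + boundary ghosts.

    Validates that no two sites coincide, that every convex-hull site is a
    boundary ghost (otherwise some interior cell would be unbounded) and, if
    ``boundary_loops`` is given, that each loop is a simple polygon.
    """
    points = np.ascontiguousarray(points, dtype=float)
    interior = np.asarray(interior, dtype=bool)
    if len(points) < 3:
        raise MeshError("need at least 3 sites to triangulate")
    if not np.all(np.isfinite(points)):
        raise MeshError("non-finite site coordinates")
    uniq = np.unique(points, axis=0)
    if len(uniq) != len(points):
        raise MeshError("duplicate site positions")
    if boundary_loops:
        from shapely.geometry import LinearRing

        for li, loop in enumerate(boundary_loops):
            if len(loop) >= 3 and not LinearRing(points[loop]).is_simple:
                raise MeshError(f"boundary loop {li} self-intersects")
    try:
        dt = _SciPyDelaunay(points)
    except QhullError as exc:
        raise MeshError(f"degenerate site configuration: {exc}") from exc
    hull = np.unique(dt.convex_hull)
    if np.any(interior[hull]):
        offender = int(hull[interior[hull]][0])
        raise MeshError(
            f"interior site {offender} lies on the convex hull; its Voronoi "
            "cell is unbounded — enclose the tissue with boundary ghosts"
        )
    return TriMesh(points, interior, dt.simplices)


def junction_length(mesh: TriMesh, i: int, j: int) -> float:
    """Length of the Voronoi junction dual to Delaunay edge (i, j).

    Zero-length exactly at a cocircular (T1) configuration.  Raises
    ``KeyError`` if (i, j) is not a Delaunay edge.
    """
    key = (i, j) if i < j else (j, i)
    ts = mesh._edge_map().get(key)
    if ts is None or len(ts) != 2:
        raise KeyError(f"({i}, {j}) is not an interior Delaunay edge")
    cc = triangle_circumcenters(mesh.points, mesh.triangles[ts])
    return float(np.linalg.norm(cc[0] - cc[1]))
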