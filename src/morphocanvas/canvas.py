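"""The canvas: a thin tissue sheet discretised as a two-surface wedge mesh.

A canvas is a triangulated midplane together with two offset surfaces A and
B.  Each midplane triangle, extruded between its copies on A and B, is a
six-node wedge (pentahedral) finite element.  All regulatory fields live on
midplane vertices; mechanics lives on the A/B vertex pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    GeometryError,
    ParameterError,
    PlacementError,
    TopologyError,
)

__all__ = [
    "Canvas",
    "CloneSet",
    "build_flat_sheet",
    "build_disc",
    "build_cylinder",
    "mark_circular_clones",
    "clone_shape_stats",
    "cut_along_path",
]


@dataclass
class Canvas:
    """Two-surface pentahedral tissue mesh.

    Parameters
    ----------
    pos_a, pos_b
        ``(N, 3)`` vertex coordinates of surfaces A and B.  The two
        surfaces share one index set and one triangulation, so wedge
        ``e`` is the prism between ``triangles[e]`` on A and the same
        triple on B.
    triangles
        ``(M, 3)`` midplane connectivity.
    vertex_sets
        Named vertex index arrays (``"boundary"``, ``"rim"``, ...) used by
        presets to seed organisers and constraints.
    """

    pos_a: np.ndarray
    pos_b: np.ndarray
    triangles: np.ndarray
    vertex_sets: dict = field(default_factory=dict)

    def __post_init__(self):
        self.pos_a = np.asarray(self.pos_a, dtype=float)
        self.pos_b = np.asarray(self.pos_b, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        if self.pos_a.shape != self.pos_b.shape:
            raise ParameterError("surfaces A and B must share one index set")

    # -- basic queries -------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return self.pos_a.shape[0]

    @property
    def n_elements(self) -> int:
        return self.triangles.shape[0]

    @property
    def midplane(self) -> np.ndarray:
        """Midplane vertex positions, the average of the paired surfaces."""
        return 0.5 * (self.pos_a + self.pos_b)

    @property
    def thickness(self) -> np.ndarray:
        """Per-vertex thickness |posA - posB|."""
        return np.linalg.norm(self.pos_a - self.pos_b, axis=1)

    def copy(self) -> "Canvas":
        return Canvas(
            self.pos_a.copy(),
            self.pos_b.copy(),
            self.triangles.copy(),
            {k: np.array(v, copy=True) for k, v in self.vertex_sets.items()},
        )

    # -- geometry ------------------------------------------------------

    def triangle_areas(self) -> np.ndarray:
        p = self.midplane[self.triangles]
        c = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
        return 0.5 * np.linalg.norm(c, axis=1)

    def triangle_normals(self) -> np.ndarray:
        p = self.midplane[self.triangles]
        c = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
        n = np.linalg.norm(c, axis=1, keepdims=True)
        n[n == 0.0] = 1.0
        return c / n

    def vertex_normals(self) -> np.ndarray:
        """Area-weighted average of incident triangle normals."""
        p = self.midplane[self.triangles]
        c = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])  # 2*area*normal
        out = np.zeros_like(self.pos_a)
        for k in range(3):
            np.add.at(out, self.triangles[:, k], c)
        nrm = np.linalg.norm(out, axis=1, keepdims=True)
        nrm[nrm == 0.0] = 1.0
        return out / nrm

    def total_area(self) -> float:
        return float(self.triangle_areas().sum())

    def wedge_volumes(self) -> np.ndarray:
        """Signed wedge volumes via a three-tetrahedron decomposition."""
        a = self.pos_a[self.triangles]
        b = self.pos_b[self.triangles]

        def tet(p0, p1, p2, p3):
            return np.einsum("ij,ij->i", np.cross(p1 - p0, p2 - p0), p3 - p0) / 6.0

        v = (
            tet(a[:, 0], a[:, 1], a[:, 2], b[:, 0])
            + tet(a[:, 1], a[:, 2], b[:, 0], b[:, 1])
            + tet(a[:, 2], b[:, 0], b[:, 1], b[:, 2])
        )
        return np.abs(v)

    def vertex_areas(self) -> np.ndarray:
        """Lumped midplane control areas (one third of incident triangles)."""
        areas = self.triangle_areas()
        out = np.zeros(self.n_vertices)
        for k in range(3):
            np.add.at(out, self.triangles[:, k], areas / 3.0)
        return out

    def vertex_volumes(self) -> np.ndarray:
        """Control volumes: lumped midplane area times local thickness."""
        return self.vertex_areas() * self.thickness

    # -- connectivity --------------------------------------------------

    def edges(self) -> np.ndarray:
        e = np.concatenate(
            [self.triangles[:, [0, 1]], self.triangles[:, [1, 2]], self.triangles[:, [2, 0]]]
        )
        e.sort(axis=1)
        return np.unique(e, axis=0)

    def edge_triangle_map(self) -> dict:
        """Map (lo, hi) vertex pair -> list of incident triangle indices."""
        out: dict = {}
        for t, (i, j, k) in enumerate(self.triangles):
            for a, b in ((i, j), (j, k), (k, i)):
                key = (int(min(a, b)), int(max(a, b)))
                out.setdefault(key, []).append(t)
        return out

    def boundary_edges(self) -> np.ndarray:
        em = self.edge_triangle_map()
        return np.array([e for e, ts in em.items() if len(ts) == 1], dtype=np.int64).reshape(-1, 2)

    def boundary_vertices(self) -> np.ndarray:
        be = self.boundary_edges()
        return np.unique(be) if be.size else np.array([], dtype=np.int64)

    def euler_characteristic(self) -> int:
        return self.n_vertices - len(self.edges()) + self.n_elements

    def validate(self) -> None:
        if np.any(self.triangle_areas() <= 0.0):
            raise GeometryError("midplane triangle with non-positive area")
        if np.any(self.wedge_volumes() <= 0.0):
            raise GeometryError("wedge element with non-positive volume")


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------


def _offset_surfaces(midplane: np.ndarray, triangles: np.ndarray, thickness: float):
    c = Canvas(midplane, midplane.copy(), triangles)
    n = c.vertex_normals()
    return midplane - 0.5 * thickness * n, midplane + 0.5 * thickness * n


def build_flat_sheet(
    nx: int,
    ny: int,
    side: float = 1.0,
    thickness: float = 0.1,
    bow: float = 0.0,
) -> Canvas:
    """Structured triangulated square sheet, optionally bowed upward.

    The bow is a smooth C1 cosine bump, peaking at ``bow`` in the centre
    and vanishing on the edges; its only role is to break the up/down
    symmetry of out-of-plane buckling.
    """
    if nx < 1 or ny < 1:
        raise ParameterError("grid resolution must be >= 1 in each direction")
    if side <= 0 or thickness <= 0:
        raise ParameterError("side and thickness must be positive")
    if bow < 0:
        raise ParameterError("bow must be non-negative")

    xs = np.linspace(0.0, side, nx + 1)
    ys = np.linspace(0.0, side, ny + 1)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    u = 2.0 * X / side - 1.0
    v = 2.0 * Y / side - 1.0
    Z = bow * np.cos(0.5 * np.pi * u) * np.cos(0.5 * np.pi * v)
    mid = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    def vid(i, j):
        return i * (ny + 1) + j

    tris = []
    for i in range(nx):
        for j in range(ny):
            a, b, c, d = vid(i, j), vid(i + 1, j), vid(i + 1, j + 1), vid(i, j + 1)
            # alternate the diagonal for a symmetric union-jack-free pattern
            if (i + j) % 2 == 0:
                tris += [[a, b, c], [a, c, d]]
            else:
                tris += [[a, b, d], [b, c, d]]
    tris = np.asarray(tris, dtype=np.int64)

    pos_a, pos_b = _offset_surfaces(mid, tris, thickness)
    canvas = Canvas(pos_a, pos_b, tris)
    tol = 1e-12 * side
    idx = np.arange(mid.shape[0])
    canvas.vertex_sets = {
        "bottom": idx[np.abs(mid[:, 1]) < tol],
        "top": idx[np.abs(mid[:, 1] - side) < tol],
        "left": idx[np.abs(mid[:, 0]) < tol],
        "right": idx[np.abs(mid[:, 0] - side) < tol],
        "midline": idx[np.abs(mid[:, 1] - 0.5 * side) < 0.51 * side / ny],
    }
    canvas.vertex_sets["boundary"] = canvas.boundary_vertices()
    canvas.validate()
    return canvas


def _loop_triangulate(inner: np.ndarray, outer: np.ndarray, th_in, th_out):
    """Triangulate the annulus between two concentric vertex loops by an
    angle-merge walk."""
    tris = []
    ni, no = len(inner), len(outer)
    i = j = 0
    # walk both loops by increasing angle
    while i < ni or j < no:
        th_i = th_in[i % ni] + (2 * np.pi if i >= ni else 0.0)
        th_j = th_out[j % no] + (2 * np.pi if j >= no else 0.0)
        if j < no and (i >= ni or th_j <= th_i):
            tris.append([inner[i % ni], outer[j % no], outer[(j + 1) % no]])
            j += 1
        else:
            tris.append([inner[i % ni], outer[j % no], inner[(i + 1) % ni]])
            i += 1
    return tris


def build_disc(radius: float, resolution: int = 8, thickness: float = 0.05) -> Canvas:
    """Disc-shaped canvas built from concentric hexagonal rings.

    ``resolution`` is the number of rings; ring ``k`` carries ``6k``
    vertices, giving near-equilateral triangles throughout.
    """
    if radius <= 0 or thickness <= 0:
        raise ParameterError("radius and thickness must be positive")
    if resolution < 1:
        raise ParameterError("resolution must be >= 1")

    verts = [np.array([0.0, 0.0, 0.0])]
    rings = [[0]]
    thetas = [[0.0]]
    for k in range(1, resolution + 1):
        n = 6 * k
        th = 2.0 * np.pi * np.arange(n) / n
        r = radius * k / resolution
        start = len(verts)
        for t in th:
            verts.append(np.array([r * np.cos(t), r * np.sin(t), 0.0]))
        rings.append(list(range(start, start + n)))
        thetas.append(list(th))

    tris = []
    # centre fan
    for j in range(6):
        tris.append([0, rings[1][j], rings[1][(j + 1) % 6]])
    for k in range(1, resolution):
        tris += _loop_triangulate(
            np.array(rings[k]), np.array(rings[k + 1]), thetas[k], thetas[k + 1]
        )
    mid = np.array(verts)
    tris = np.asarray(tris, dtype=np.int64)
    pos_a, pos_b = _offset_surfaces(mid, tris, thickness)
    canvas = Canvas(pos_a, pos_b, tris)
    canvas.vertex_sets = {"rim": np.array(rings[-1], dtype=np.int64)}
    canvas.vertex_sets["boundary"] = canvas.boundary_vertices()
    canvas.validate()
    return canvas


def build_cylinder(
    radius: float,
    height: float,
    closed_top: bool = True,
    resolution: int = 16,
    thickness: float = 0.05,
) -> Canvas:
    """Cylindrical tube of given radius/height, optionally closed at the top
    by a triangle fan to a single apex vertex.

    The base ring and top rim are labelled in ``vertex_sets`` so presets
    can seed organisers and fix the base.
    """
    if radius <= 0 or thickness <= 0:
        raise ParameterError("radius and thickness must be positive")
    if height <= 1e-3 * radius:
        raise ParameterError("degenerate height: cylinder height too small")
    if resolution < 3:
        raise ParameterError("resolution < 3 cannot form a cap")

    ntheta = int(resolution)
    dl = 2.0 * np.pi * radius / ntheta
    nz = max(2, int(round(height / dl)))
    th = 2.0 * np.pi * np.arange(ntheta) / ntheta
    verts = []
    for i in range(nz + 1):
        z = height * i / nz
        off = 0.5 * (i % 2) * (th[1] - th[0])  # stagger rings for quality
        for t in th + off:
            verts.append([radius * np.cos(t), radius * np.sin(t), z])
    tris = []
    for i in range(nz):
        a0, b0 = i * ntheta, (i + 1) * ntheta
        for j in range(ntheta):
            j1 = (j + 1) % ntheta
            if i % 2 == 0:
                tris.append([a0 + j, a0 + j1, b0 + j])
                tris.append([a0 + j1, b0 + j1, b0 + j])
            else:
                tris.append([a0 + j, a0 + j1, b0 + j1])
                tris.append([a0 + j, b0 + j1, b0 + j])
    rim = np.arange(nz * ntheta, (nz + 1) * ntheta)
    if closed_top:
        apex = len(verts)
        verts.append([0.0, 0.0, height])
        for j in range(ntheta):
            tris.append([rim[j], rim[(j + 1) % ntheta], apex])

    mid = np.asarray(verts, dtype=float)
    tris = np.asarray(tris, dtype=np.int64)
    # outward normals: radial on the wall, +z at the apex
    pos_a, pos_b = _offset_surfaces(mid, tris, thickness)
    canvas = Canvas(pos_a, pos_b, tris)
    canvas.vertex_sets = {
        "base": np.arange(ntheta, dtype=np.int64),
        "rim": rim.astype(np.int64),
    }
    if closed_top:
        canvas.vertex_sets["apex"] = np.array([apex], dtype=np.int64)
    canvas.vertex_sets["boundary"] = canvas.boundary_vertices()
    canvas.validate()
    return canvas


# ---------------------------------------------------------------------------
# clones
# ---------------------------------------------------------------------------


@dataclass
class CloneSet:
    """Passively advected circular marker clones.

    Each clone is a ring of sample points stored in barycentric form
    (containing element + weights) so that they ride along with any
    deformation of the midplane mesh, exerting no mechanical feedback.
    """

    elements: list  # per clone: (P,) int array of containing triangles
    barycentric: list  # per clone: (P, 3) weights, >= 0, summing to 1
    radius: float

    @property
    def n_clones(self) -> int:
        return len(self.elements)

    def world_positions(self, canvas: Canvas) -> list:
        out = []
        for tri, bary in zip(self.elements, self.barycentric):
            p = canvas.midplane[canvas.triangles[tri]]  # (P,3,3)
            out.append(np.einsum("pk,pkd->pd", bary, p))
        return out


def _closest_point_barycentric(point: np.ndarray, tri_pts: np.ndarray):
    """Barycentric coordinates of the closest point of a triangle to ``point``."""
    a, b, c = tri_pts
    ab, ac, ap = b - a, c - a, point - a
    d00, d01, d11 = ab @ ab, ab @ ac, ac @ ac
    d20, d21 = ap @ ab, ap @ ac
    den = d00 * d11 - d01 * d01
    if den <= 0:
        return np.array([1.0, 0.0, 0.0]), float(np.linalg.norm(ap))
    v = (d11 * d20 - d01 * d21) / den
    w = (d00 * d21 - d01 * d20) / den
    v, w = np.clip(v, 0.0, 1.0), np.clip(w, 0.0, 1.0)
    if v + w > 1.0:
        s = v + w
        v, w = v / s, w / s
    bary = np.array([1.0 - v - w, v, w])
    closest = bary @ tri_pts
    return bary, float(np.linalg.norm(point - closest))


def locate_points(canvas: Canvas, points: np.ndarray, candidates=None):
    """Locate points on the midplane: containing/closest triangle + barycentric."""
    tris = candidates if candidates is not None else np.arange(canvas.n_elements)
    mp = canvas.midplane
    elems = np.empty(len(points), dtype=np.int64)
    barys = np.empty((len(points), 3))
    for p_i, pt in enumerate(points):
        best = (np.inf, -1, None)
        for t in tris:
            bary, dist = _closest_point_barycentric(pt, mp[canvas.triangles[t]])
            if dist < best[0]:
                best = (dist, t, bary)
                if dist < 1e-13:
                    break
        elems[p_i], barys[p_i] = best[1], best[2]
    return elems, barys


def mark_circular_clones(
    canvas: Canvas,
    n: int,
    radius: float,
    seed: int,
    points_per_clone: int = 24,
    max_attempts_per_clone: int = 200,
) -> CloneSet:
    """Scatter ``n`` non-overlapping circular clones of given radius.

    Deterministic for a fixed seed.  Raises :class:`PlacementError`
    reporting how many clones fitted if ``n`` cannot be placed within the
    retry budget.
    """
    if points_per_clone < 24:
        points_per_clone = 24
    areas = canvas.triangle_areas()
    if radius <= 0 or np.pi * radius**2 > canvas.total_area():
        raise ParameterError("clone radius incompatible with canvas extent")
    rng = np.random.default_rng(seed)
    probs = areas / areas.sum()
    mp = canvas.midplane
    normals = canvas.triangle_normals()
    centers: list = []
    clone_elems, clone_barys = [], []
    attempts_left = max_attempts_per_clone * n
    bverts = canvas.midplane[canvas.boundary_vertices()]
    tri_centers = mp[canvas.triangles].mean(axis=1)
    while len(centers) < n and attempts_left > 0:
        attempts_left -= 1
        t = rng.choice(canvas.n_elements, p=probs)
        w = rng.dirichlet(np.ones(3))
        center = w @ mp[canvas.triangles[t]]
        if centers and np.min(
            np.linalg.norm(np.asarray(centers) - center, axis=1)
        ) < 2.0 * radius:
            continue
        if bverts.size and np.min(np.linalg.norm(bverts - center, axis=1)) < radius:
            continue
        nrm = normals[t]
        e0 = mp[canvas.triangles[t, 1]] - mp[canvas.triangles[t, 0]]
        u = e0 - (e0 @ nrm) * nrm
        u /= np.linalg.norm(u)
        v = np.cross(nrm, u)
        th = 2.0 * np.pi * np.arange(points_per_clone) / points_per_clone
        ring = center + radius * (np.outer(np.cos(th), u) + np.outer(np.sin(th), v))
        # restrict the search to triangles near the clone for speed
        near = np.where(np.linalg.norm(tri_centers - center, axis=1) < radius + 2.0 * np.sqrt(areas.max()))[0]
        elems, barys = locate_points(canvas, ring, candidates=near)
        centers.append(center)
        clone_elems.append(elems)
        clone_barys.append(barys)
    if len(centers) < n:
        raise PlacementError(n, len(centers))
    return CloneSet(clone_elems, clone_barys, radius)


def clone_shape_stats(canvas: Canvas, clones: CloneSet):
    """Best-fit-ellipse statistics for each clone on the (possibly
    deformed) canvas.

    The clone boundary points were sampled at uniform angles on a circle,
    so under any affine map their second-moment matrix is exactly
    ``0.5 * A A^T``; the ellipse axes are recovered from its eigenpairs.

    Returns a list of dicts with ``area_ratio``, ``anisotropy_ratio``
    (major/minor, >= 1; ``inf`` for degenerate clones) and
    ``major_axis_angle_deg`` (in the clone's best-fit plane, mod 180).
    """
    stats = []
    for pts in clones.world_positions(canvas):
        centered = pts - pts.mean(axis=0)
        cov = centered.T @ centered / len(pts)
        evals, evecs = np.linalg.eigh(cov)
        # the two largest eigenvalues span the clone's plane
        l_major, l_minor = evals[2], evals[1]
        a = np.sqrt(2.0 * max(l_major, 0.0))
        b = np.sqrt(2.0 * max(l_minor, 0.0))
        degenerate = b < 1e-12 * max(a, 1.0)
        major = evecs[:, 2]
        angle = np.degrees(np.arctan2(major[1], major[0])) % 180.0
        stats.append(
            {
                "area_ratio": np.pi * a * b / (np.pi * clones.radius**2),
                "anisotropy_ratio": np.inf if degenerate else a / b,
                "major_axis_angle_deg": angle,
                "degenerate": degenerate,
            }
        )
    return stats


# ---------------------------------------------------------------------------
# cutting
# ---------------------------------------------------------------------------


def cut_along_path(canvas: Canvas, path):
    """Cut the canvas along a connected chain of midplane edges.

    Vertices whose triangle fan is disconnected by removing adjacency
    across the path edges are duplicated (on both surfaces); triangles on
    the far side are rewired to the duplicate, so the two banks of the cut
    share no vertices.  Returns ``(new_canvas, duplicates)`` where
    ``duplicates`` is a list of ``(original, copy)`` vertex index pairs so
    that callers can extend their per-vertex fields.
    """
    path = [int(v) for v in path]
    if len(path) < 2:
        raise TopologyError("cut path must contain at least one edge")
    em = canvas.edge_triangle_map()
    path_edges = set()
    for a, b in zip(path[:-1], path[1:]):
        key = (min(a, b), max(a, b))
        if key not in em:
            raise TopologyError(f"cut path contains non-edge {key}")
        path_edges.add(key)

    tris = canvas.triangles.copy()
    pos_a = [row for row in canvas.pos_a]
    pos_b = [row for row in canvas.pos_b]
    duplicates = []

    for v in path:
        fan = [t for t, tri in enumerate(tris) if v in tri]
        # union-find over fan triangles; adjacency through non-path edges at v
        parent = {t: t for t in fan}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        incident = {}
        for t in fan:
            tri = tris[t]
            for w in tri:
                if w == v:
                    continue
                key = (min(v, int(w)), max(v, int(w)))
                if key in path_edges:
                    continue
                incident.setdefault(key, []).append(t)
        for ts in incident.values():
            for t in ts[1:]:
                parent[find(ts[0])] = find(t)
        comps: dict = {}
        for t in fan:
            comps.setdefault(find(t), []).append(t)
        groups = list(comps.values())
        for extra in groups[1:]:
            new_v = len(pos_a)
            pos_a.append(canvas.pos_a[v].copy())
            pos_b.append(canvas.pos_b[v].copy())
            duplicates.append((v, new_v))
            for t in extra:
                tris[t][tris[t] == v] = new_v

    new = Canvas(np.array(pos_a), np.array(pos_b), tris)
    sets = {}
    for name, idx in canvas.vertex_sets.items():
        extra = [nv for ov, nv in duplicates if ov in set(idx.tolist())]
        sets[name] = np.concatenate([idx, np.array(extra, dtype=np.int64)])
    new.vertex_sets = sets
    return new, duplicates
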