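"""Dynamic remeshing.

Anisotropic growth stretches elements until the equations become
ill-conditioned, so the mesh is refined on the fly: whenever any midplane
edge exceeds an upper threshold, every edge exceeding a lower threshold is
split in the same pass (splitting many edges at once keeps the mesh
graded).  New vertices are placed by the interpolating butterfly
subdivision rule — applied independently to the two surfaces so repeated
splits converge to a smooth canvas — and factor values are interpolated
with the same stencil.  Thin elements are removed by min-angle-improving
edge flips.
"""

from __future__ import annotations

import numpy as np

from .canvas import Canvas, CloneSet, locate_points
from .errors import ParameterError

__all__ = ["split_long_edges", "improve_quality"]

# butterfly weights: endpoints 1/2, wing apexes 1/8, outer wings -1/16
_W_END, _W_APEX, _W_OUT = 0.5, 0.125, -0.0625


def _third_vertex(tri, a, b):
    for v in tri:
        if v != a and v != b:
            return int(v)
    raise ValueError


def _butterfly_stencil(canvas: Canvas, edge_map: dict, a: int, b: int):
    """Return (vertices, weights) for the split point of edge (a, b);
    falls back to the midpoint when the 8-point stencil is incomplete
    (boundary edges and their neighbourhood)."""
    key = (min(a, b), max(a, b))
    tris_ab = edge_map[key]
    if len(tris_ab) != 2:
        return [a, b], [0.5, 0.5]
    apexes = [_third_vertex(canvas.triangles[t], a, b) for t in tris_ab]
    verts = [a, b] + apexes
    weights = [_W_END, _W_END, _W_APEX, _W_APEX]
    for apex, t_main in zip(apexes, tris_ab):
        for end in (a, b):
            k2 = (min(end, apex), max(end, apex))
            wing_tris = [t for t in edge_map.get(k2, []) if t != t_main]
            if len(wing_tris) != 1:
                return [a, b], [0.5, 0.5]
            verts.append(_third_vertex(canvas.triangles[wing_tris[0]], end, apex))
            weights.append(_W_OUT)
    return verts, weights


def split_long_edges(
    canvas: Canvas,
    lower: float,
    upper: float,
    fields: dict | None = None,
    clones: CloneSet | None = None,
):
    """Two-threshold split pass.

    If the longest midplane edge exceeds ``upper``, every edge longer
    than ``lower`` is split; otherwise nothing happens.  Returns
    ``(canvas, parent_elements, n_split)`` where ``parent_elements`` maps
    each new element to the element it was carved from (identity map when
    no split triggers), so callers can remap per-element state.  The
    supplied ``fields`` (dict of FactorField) and ``clones`` are updated
    in place.
    """
    if lower <= 0 or upper <= 0 or lower > upper:
        raise ParameterError("thresholds must satisfy 0 < lower <= upper")
    mp = canvas.midplane
    edges = canvas.edges()
    lengths = np.linalg.norm(mp[edges[:, 0]] - mp[edges[:, 1]], axis=1)
    identity_map = np.arange(canvas.n_elements)
    if lengths.size == 0 or lengths.max() <= upper:
        return canvas, identity_map, 0
    to_split = edges[lengths > lower]

    edge_map = canvas.edge_triangle_map()
    pos_a = [r for r in canvas.pos_a]
    pos_b = [r for r in canvas.pos_b]
    field_vals = {name: [v for v in f.values] for name, f in (fields or {}).items()}

    # clone world positions must be captured before connectivity changes
    clone_world = clone_parents = None
    if clones is not None:
        clone_world = clones.world_positions(canvas)
        clone_parents = [els.copy() for els in clones.elements]

    midpoint_of = {}
    for a, b in to_split:
        a, b = int(a), int(b)
        verts, weights = _butterfly_stencil(canvas, edge_map, a, b)
        new_idx = len(pos_a)
        pos_a.append(sum(w * canvas.pos_a[v] for v, w in zip(verts, weights)))
        pos_b.append(sum(w * canvas.pos_b[v] for v, w in zip(verts, weights)))
        for name, f in (fields or {}).items():
            val = float(sum(w * f.values[v] for v, w in zip(verts, weights)))
            if f.kind == "identity":
                val = 1.0 if val >= 0.5 else 0.0
            field_vals[name].append(val)
        midpoint_of[(min(a, b), max(a, b))] = new_idx

    new_tris = []
    parents = []
    children: dict = {}

    def emit(tri, parent):
        children.setdefault(parent, []).append(len(new_tris))
        new_tris.append(list(tri))
        parents.append(parent)

    for t, (i, j, k) in enumerate(canvas.triangles):
        i, j, k = int(i), int(j), int(k)
        m_ij = midpoint_of.get((min(i, j), max(i, j)))
        m_jk = midpoint_of.get((min(j, k), max(j, k)))
        m_ki = midpoint_of.get((min(k, i), max(k, i)))
        n_split_local = sum(m is not None for m in (m_ij, m_jk, m_ki))
        if n_split_local == 0:
            emit((i, j, k), t)
        elif n_split_local == 3:
            emit((i, m_ij, m_ki), t)
            emit((j, m_jk, m_ij), t)
            emit((k, m_ki, m_jk), t)
            emit((m_ij, m_jk, m_ki), t)
        elif n_split_local == 1:
            # rotate so the split edge is (i, j)
            if m_jk is not None:
                i, j, k, m = j, k, i, m_jk
            elif m_ki is not None:
                i, j, k, m = k, i, j, m_ki
            else:
                m = m_ij
            emit((i, m, k), t)
            emit((m, j, k), t)
        else:
            # rotate so the unsplit edge is (k, i)
            if m_ij is None:
                i, j, k = j, k, i
                m1, m2 = m_jk, m_ki
            elif m_jk is None:
                i, j, k = k, i, j
                m1, m2 = m_ki, m_ij
            else:
                m1, m2 = m_ij, m_jk
            emit((j, m2, m1), t)
            # split the quad (i, m1, m2, k) along its shorter diagonal
            pa = np.array(pos_a)
            if np.linalg.norm(pa[i] - pa[m2]) <= np.linalg.norm(pa[m1] - pa[k]):
                emit((i, m1, m2), t)
                emit((i, m2, k), t)
            else:
                emit((i, m1, k), t)
                emit((m1, m2, k), t)

    new_canvas = Canvas(
        np.array(pos_a), np.array(pos_b), np.array(new_tris, dtype=np.int64),
        {k2: np.array(v, copy=True) for k2, v in canvas.vertex_sets.items()},
    )
    if "boundary" in new_canvas.vertex_sets:
        new_canvas.vertex_sets["boundary"] = new_canvas.boundary_vertices()

    if fields:
        for name, f in fields.items():
            f.values = np.array(field_vals[name])
            if np.ndim(f.production) == 1:
                f.production = np.concatenate(
                    [f.production, np.zeros(new_canvas.n_vertices - len(f.production))]
                )

    if clones is not None:
        for ci in range(clones.n_clones):
            pts = clone_world[ci]
            cands = []
            for parent in np.unique(clone_parents[ci]):
                cands.extend(children.get(int(parent), []))
            elems, barys = locate_points(new_canvas, pts, candidates=np.array(cands))
            clones.elements[ci] = elems
            clones.barycentric[ci] = barys

    return new_canvas, np.array(parents, dtype=np.int64), len(midpoint_of)


def _tri_min_angle(p0, p1, p2):
    e = [p1 - p0, p2 - p1, p0 - p2]
    ln = [np.linalg.norm(v) for v in e]
    if min(ln) == 0.0:
        return 0.0
    angles = []
    for i in range(3):
        a, b = e[i] / ln[i], -e[(i + 2) % 3] / ln[(i + 2) % 3]
        angles.append(np.arccos(np.clip(a @ b, -1.0, 1.0)))
    return min(angles)


def improve_quality(canvas: Canvas, max_passes: int = 10):
    """Greedy edge flips: flip any interior edge whose flip strictly
    increases the local minimum triangle angle.  The boundary and
    manifoldness are preserved.  Returns ``(canvas, parent_elements,
    n_flips)``.
    """
    canvas = canvas.copy()
    tris = canvas.triangles
    parents = np.arange(canvas.n_elements)
    mp = canvas.midplane
    total_flips = 0
    for _ in range(max_passes):
        edge_map = {}
        for t, (i, j, k) in enumerate(tris):
            for a, b in ((i, j), (j, k), (k, i)):
                edge_map.setdefault((min(a, b), max(a, b)), []).append(t)
        existing = set(edge_map.keys())
        flips = 0
        dirty = set()
        for (a, b), ts in edge_map.items():
            if len(ts) != 2:
                continue
            t1, t2 = ts
            if t1 in dirty or t2 in dirty:
                continue
            c = _third_vertex(tris[t1], a, b)
            d = _third_vertex(tris[t2], a, b)
            if (min(c, d), max(c, d)) in existing:
                continue
            old_min = min(
                _tri_min_angle(mp[a], mp[b], mp[c]), _tri_min_angle(mp[a], mp[b], mp[d])
            )
            new_min = min(
                _tri_min_angle(mp[c], mp[d], mp[a]), _tri_min_angle(mp[d], mp[c], mp[b])
            )
            if new_min <= old_min + 1e-12:
                continue
            # orient (a, b) as it appears in t1, so t1 = (a, b, c) up to
            # cyclic order; the orientation-preserving flip is then
            # (a, d, c) + (d, b, c)
            tri1 = list(tris[t1])
            ia = tri1.index(a)
            if tri1[(ia + 1) % 3] != b:
                a, b = b, a
            n_old = np.cross(mp[b] - mp[a], mp[c] - mp[a])
            n1 = np.cross(mp[d] - mp[a], mp[c] - mp[a])
            n2 = np.cross(mp[b] - mp[d], mp[c] - mp[d])
            if n1 @ n_old <= 0 or n2 @ n_old <= 0:
                continue
            tris[t1] = [a, d, c]
            tris[t2] = [d, b, c]
            existing.add((min(c, d), max(c, d)))
            dirty |= {t1, t2}
            flips += 1
        total_flips += flips
        if flips == 0:
            break
    canvas.triangles = tris
    return canvas, parents, total_flips
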