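"""Mesh snapshot export (VTK legacy ASCII, PLY, OBJ) and OBJ import.

VTK files carry the full wedge mesh with factor fields and polarity as
point data and growth tensors (Voigt order xx, yy, zz, yz, xz, xy) as
cell data; PLY/OBJ carry midplane geometry only.
"""

from __future__ import annotations

import numpy as np

from .canvas import Canvas
from .errors import ParameterError

__all__ = ["write_vtk", "write_ply", "write_obj", "read_obj"]

_VOIGT = [(0, 0), (1, 1), (2, 2), (1, 2), (0, 2), (0, 1)]


def write_vtk(
    path,
    canvas: Canvas,
    point_fields: dict | None = None,
    polarity_vectors: np.ndarray | None = None,
    cell_tensors: dict | None = None,
) -> None:
    """Write the wedge mesh as a legacy ASCII VTK unstructured grid.

    ``point_fields`` maps names to per-midplane-vertex scalars (written to
    both surface copies); ``polarity_vectors`` is per-element and averaged
    onto vertices for display; ``cell_tensors`` maps names to (E, 3, 3)
    symmetric tensors written in Voigt order.
    """
    N = canvas.n_vertices
    E = canvas.n_elements
    pts = np.vstack([canvas.pos_a, canvas.pos_b])
    lines = [
        "# vtk DataFile Version 3.0",
        "morphocanvas snapshot",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {2 * N} double",
    ]
    lines += [" ".join(f"{v:.10g}" for v in p) for p in pts]
    lines.append(f"CELLS {E} {7 * E}")
    for tri in canvas.triangles:
        a, b, c = (int(v) for v in tri)
        lines.append(f"6 {a} {b} {c} {a + N} {b + N} {c + N}")
    lines.append(f"CELL_TYPES {E}")
    lines += ["13"] * E

    pf = dict(point_fields or {})
    if polarity_vectors is not None:
        acc = np.zeros((N, 3))
        cnt = np.zeros(N)
        for k in range(3):
            np.add.at(acc, canvas.triangles[:, k], polarity_vectors)
            np.add.at(cnt, canvas.triangles[:, k], 1.0)
        acc /= np.maximum(cnt, 1.0)[:, None]
    if pf or polarity_vectors is not None:
        lines.append(f"POINT_DATA {2 * N}")
        for name, vals in pf.items():
            vals = np.asarray(vals, dtype=float)
            lines.append(f"SCALARS {name} double 1")
            lines.append("LOOKUP_TABLE default")
            both = np.concatenate([vals, vals])
            lines += [f"{v:.10g}" for v in both]
        if polarity_vectors is not None:
            lines.append("VECTORS polarity double")
            both = np.vstack([acc, acc])
            lines += [" ".join(f"{v:.10g}" for v in row) for row in both]

    if cell_tensors:
        lines.append(f"CELL_DATA {E}")
        for name, tens in cell_tensors.items():
            tens = np.asarray(tens)
            lines.append(f"FIELD {name}_field 1")
            lines.append(f"{name} 6 {E} double")
            for t in tens:
                lines.append(" ".join(f"{t[i, j]:.10g}" for i, j in _VOIGT))

    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_ply(path, canvas: Canvas) -> None:
    mp = canvas.midplane
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {canvas.n_vertices}\n")
        fh.write("property double x\nproperty double y\nproperty double z\n")
        fh.write(f"element face {canvas.n_elements}\n")
        fh.write("property list uchar int vertex_indices\nend_header\n")
        for p in mp:
            fh.write(f"{p[0]:.10g} {p[1]:.10g} {p[2]:.10g}\n")
        for t in canvas.triangles:
            fh.write(f"3 {t[0]} {t[1]} {t[2]}\n")


def write_obj(path, canvas: Canvas) -> None:
    mp = canvas.midplane
    with open(path, "w") as fh:
        for p in mp:
            fh.write(f"v {p[0]:.10g} {p[1]:.10g} {p[2]:.10g}\n")
        for t in canvas.triangles:
            fh.write(f"f {t[0] + 1} {t[1] + 1} {t[2] + 1}\n")


def read_obj(path, thickness: float) -> Canvas:
    """Import a triangulated OBJ surface as a midplane with uniform
    thickness."""
    if thickness <= 0:
        raise ParameterError("thickness must be positive")
    verts, faces = [], []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if parts[0] == "v":
                verts.append([float(x) for x in parts[1:4]])
            elif parts[0] == "f":
                idx = [int(p.split("/")[0]) - 1 for p in parts[1:]]
                if len(idx) != 3:
                    raise ParameterError("only triangulated OBJ meshes are supported")
                faces.append(idx)
    mid = np.asarray(verts, dtype=float)
    tris = np.asarray(faces, dtype=np.int64)
    tmp = Canvas(mid, mid.copy(), tris)
    n = tmp.vertex_normals()
    canvas = Canvas(mid - 0.5 * thickness * n, mid + 0.5 * thickness * n, tris)
    canvas.vertex_sets["boundary"] = canvas.boundary_vertices()
    canvas.validate()
    return canvas
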