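"""Propagation of signalling factors: finite-element diffusion with
production and decay on the midplane triangulation, and the separate
dilution step.

Factor concentrations are assumed uniform through the thickness, so the
operator lives on the midplane triangles (P1 elements, consistent mass by
default).  Dilution — the proportional drop in concentration when the
carrying volume expands — is applied as its own bookkeeping step after
the mechanics, not folded into the transport equation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .canvas import Canvas
from .errors import GeometryError, ParameterError, StepSizeError
from .factors import FactorField

__all__ = [
    "DiffusionSystem",
    "build_diffusion_system",
    "step_signalling_field",
    "steady_state",
    "apply_dilution",
]


@dataclass
class DiffusionSystem:
    """Assembled P1 mass and stiffness matrices on the midplane mesh."""

    mass: sp.csr_matrix  # consistent mass, SPD
    mass_lumped: np.ndarray  # row sums
    stiffness: sp.csr_matrix  # Laplacian stiffness, PSD


def build_diffusion_system(canvas: Canvas) -> DiffusionSystem:
    mp = canvas.midplane
    tris = canvas.triangles
    p = mp[tris]
    e1 = p[:, 1] - p[:, 0]
    e2 = p[:, 2] - p[:, 0]
    nrm = np.cross(e1, e2)
    a2 = np.linalg.norm(nrm, axis=1)
    if np.any(a2 <= 0):
        raise GeometryError("degenerate triangle in diffusion assembly")
    areas = 0.5 * a2
    nhat = nrm / a2[:, None]
    # in-plane gradients of barycentric coordinates
    g = np.empty((len(tris), 3, 3))
    g[:, 0] = np.cross(nhat, p[:, 2] - p[:, 1]) / a2[:, None]
    g[:, 1] = np.cross(nhat, p[:, 0] - p[:, 2]) / a2[:, None]
    g[:, 2] = np.cross(nhat, p[:, 1] - p[:, 0]) / a2[:, None]

    Ke = areas[:, None, None] * np.einsum("eik,ejk->eij", g, g)
    Mref = (np.ones((3, 3)) + np.eye(3)) / 12.0
    Me = areas[:, None, None] * Mref[None]

    rows = np.repeat(tris, 3, axis=1).ravel()
    cols = np.tile(tris, (1, 3)).ravel()
    n = canvas.n_vertices
    K = sp.coo_matrix((Ke.ravel(), (rows, cols)), shape=(n, n)).tocsr()
    M = sp.coo_matrix((Me.ravel(), (rows, cols)), shape=(n, n)).tocsr()
    return DiffusionSystem(M, np.asarray(M.sum(axis=1)).ravel(), K)


def step_signalling_field(
    canvas: Canvas,
    field: FactorField,
    dt: float,
    scheme: str = "implicit",
    tol: float = 1e-4,
    system: DiffusionSystem | None = None,
) -> np.ndarray:
    """One Euler step of dc/dt = D lap(c) + p - d c, clamped nodes fixed.

    The implicit (backward) scheme is unconditionally stable and exactly
    conserves total mass (integral of c) when p = d = 0 with no clamped
    nodes.  The explicit scheme (lumped mass) raises
    :class:`StepSizeError` beyond its stability bound.  Dilution is not
    applied here.
    """
    if field.kind != "signalling":
        raise ParameterError("only signalling factors propagate")
    if dt <= 0:
        raise ParameterError("dt must be positive")
    sys_ = system or build_diffusion_system(canvas)
    n = canvas.n_vertices
    c = field.values
    p = field.production_vector(n)
    d = field.decay
    fixed = field.fixed_nodes
    free = np.setdiff1d(np.arange(n), fixed)

    if scheme == "implicit":
        A = sys_.mass + dt * (field.D * sys_.stiffness + d * sys_.mass)
        b = sys_.mass @ c + dt * (sys_.mass @ p)
        new = c.copy()
        if len(free) == n:
            new = spla.spsolve(A.tocsc(), b)
        elif len(free):
            Aff = A[np.ix_(free, free)] if False else A[free][:, free]
            bf = b[free] - A[free][:, fixed] @ c[fixed]
            new[free] = spla.spsolve(Aff.tocsc(), bf)
        return new
    if scheme == "explicit":
        Ml = sys_.mass_lumped
        diagK = sys_.stiffness.diagonal()
        denom = field.D * diagK + d * Ml
        with np.errstate(divide="ignore"):
            bound = np.where(denom > 0, Ml / np.maximum(denom, 1e-300), np.inf)
        if dt > bound.min():
            raise StepSizeError(
                f"dt = {dt:g} exceeds the explicit stability bound {bound.min():g}"
            )
        rate = -field.D * (sys_.stiffness @ c) + Ml * p - d * Ml * c
        new = c + dt * rate / Ml
        new[fixed] = c[fixed]
        return new
    raise ParameterError(f"unknown scheme {scheme!r}")


def steady_state(
    canvas: Canvas,
    field: FactorField,
    system: DiffusionSystem | None = None,
) -> np.ndarray:
    """Steady solution of D lap(c) + p - d c = 0 with the field's clamps.

    Used by preset setup phases to equilibrate organiser-anchored
    signals (e.g. the polariser) without time stepping.
    """
    sys_ = system or build_diffusion_system(canvas)
    n = canvas.n_vertices
    A = field.D * sys_.stiffness + field.decay * sys_.mass
    b = sys_.mass @ field.production_vector(n)
    fixed = field.fixed_nodes
    free = np.setdiff1d(np.arange(n), fixed)
    out = field.values.copy()
    if len(free) == 0:
        return out
    if len(fixed) == 0:
        if field.decay == 0.0:
            raise ParameterError("steady state needs decay or clamped nodes")
        return spla.spsolve(A.tocsc(), b)
    Aff = A[free][:, free]
    bf = b[free] - A[free][:, fixed] @ out[fixed]
    out[free] = spla.spsolve(Aff.tocsc(), bf)
    return out


def apply_dilution(fields, volumes_old: np.ndarray, volumes_new: np.ndarray) -> None:
    """Dilute every dilutable signalling field in place so that per-vertex
    tracked mass c*V is conserved: c_new = c_old * V_old / V_new.

    Identity and non-dilutable fields are untouched.
    """
    if np.any(volumes_old <= 0) or np.any(volumes_new <= 0):
        raise GeometryError("non-positive control volume in dilution")
    ratio = volumes_old / volumes_new
    for f in fields.values() if isinstance(fields, dict) else fields:
        if f.kind == "signalling" and f.dilutable:
            f.values = f.values * ratio
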