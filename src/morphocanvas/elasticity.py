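"""Linear elasticity on the wedge mesh.

Specified growth enters the equilibrium equations as an initial strain:
the equilibrium displacement field u minimises the energy of the
unrealised (residual) strain, 1/2 * (Du - eps_spec) : C : (Du - eps_spec),
integrated over the canvas.  By the principle of virtual work this gives a
sparse symmetric linear system K u = f in the vertex displacements.  The
stiffness scale cancels (no external forces), so only Poisson's ratio of
the isotropic material matters, and only weakly.

Elements are six-node linear isoparametric wedges integrated with three
in-plane points and two through-thickness Gauss points; the two thickness
points coincide with the layers at which specified growth is sampled, so
per-surface growth differences generate bending moments naturally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
import sympy as sym

from .canvas import Canvas
from .errors import ConstraintError, ParameterError, SolverError
from .growth import GAUSS_ZETA

__all__ = [
    "ElasticMaterial",
    "isotropic_stiffness",
    "independent_stiffness_components",
    "positive_definiteness_boundary",
    "ConstraintSet",
    "ElasticSystem",
    "assemble_elastic_system",
    "solve_displacements",
    "DeformationResult",
    "decompose_growth",
    "deformation_energy",
    "stored_strain_energy",
    "stvenant_residual",
    "voigt_to_full",
    "full_to_voigt",
    "rotate_stiffness",
    "isotropic_compliance_full",
    "stiffness_modulation_strain",
]

_VOIGT_PAIRS = [(0, 0), (1, 1), (2, 2), (1, 2), (0, 2), (0, 1)]
_VOIGT_INDEX = np.array([[0, 5, 4], [5, 1, 3], [4, 3, 2]])


# ---------------------------------------------------------------------------
# material
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ElasticMaterial:
    """Isotropic material: shear modulus (arbitrary units, cancels) and
    Poisson's ratio."""

    shear_modulus: float = 1.0
    poisson: float = 0.3

    def __post_init__(self):
        if self.shear_modulus <= 0:
            raise ParameterError("shear modulus must be positive")
        if not (0.0 <= self.poisson < 0.5):
            raise ParameterError(
                "Poisson's ratio must lie in [0, 0.5); at 0.5 the equations degenerate"
            )


def isotropic_stiffness(material: ElasticMaterial) -> np.ndarray:
    """6x6 Voigt stiffness (engineering shear strains) for an isotropic
    material, lambda = 2*mu*nu / (1 - 2*nu)."""
    mu, nu = material.shear_modulus, material.poisson
    lam = 2.0 * mu * nu / (1.0 - 2.0 * nu)
    C = np.zeros((6, 6))
    C[:3, :3] = lam
    C[np.diag_indices(3)] += 2.0 * mu
    C[3, 3] = C[4, 4] = C[5, 5] = mu
    return C


def independent_stiffness_components() -> int:
    """Number of independent components of a 4th-rank stiffness tensor
    under the minor (ij<->ji, kl<->lk) and major ((ij)<->(kl)) symmetries,
    counted by explicit orbit enumeration over all 81 index quadruples."""
    seen = set()
    for i in range(3):
        for j in range(3):
            for k in range(3):
                for l in range(3):  # noqa: E741
                    a = tuple(sorted((i, j)))
                    b = tuple(sorted((k, l)))
                    seen.add(tuple(sorted((a, b))))
    return len(seen)


def positive_definiteness_boundary(mu: float = 1.0, tol: float = 1e-9) -> float:
    """Bisection on Poisson's ratio for loss of positive-definiteness of
    the isotropic Voigt stiffness (the physical limit is 0.5)."""

    def is_pd(nu: float) -> bool:
        if abs(1.0 - 2.0 * nu) < 1e-300:
            return False
        lam = 2.0 * mu * nu / (1.0 - 2.0 * nu)
        C = np.zeros((6, 6))
        C[:3, :3] = lam
        C[np.diag_indices(3)] += 2.0 * mu
        C[3, 3] = C[4, 4] = C[5, 5] = mu
        return bool(np.all(np.linalg.eigvalsh(C) > 0.0))

    lo, hi = 0.0, 0.999
    if not is_pd(lo) or is_pd(hi):
        raise RuntimeError("bisection bracket invalid")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if is_pd(mid):
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# wedge element quadrature
# ---------------------------------------------------------------------------

_TRI_GAUSS = np.array([[1 / 6, 1 / 6], [2 / 3, 1 / 6], [1 / 6, 2 / 3]])
_TRI_W = np.full(3, 1 / 6)
_DLAM = np.array([[-1.0, -1.0], [1.0, 0.0], [0.0, 1.0]])  # dlambda/d(xi,eta)


def _shape_derivatives(xi: float, eta: float, zeta: float) -> np.ndarray:
    """dN/d(xi,eta,zeta) for the 6-node wedge, shape (6, 3)."""
    lam = np.array([1.0 - xi - eta, xi, eta])
    d = np.zeros((6, 3))
    d[:3, :2] = _DLAM * 0.5 * (1.0 - zeta)
    d[3:, :2] = _DLAM * 0.5 * (1.0 + zeta)
    d[:3, 2] = -0.5 * lam
    d[3:, 2] = 0.5 * lam
    return d


def _gauss_points():
    """(xi, eta, zeta, weight, layer) for the 3x2 wedge rule."""
    pts = []
    for layer, zeta in enumerate(GAUSS_ZETA):
        for (xi, eta), w in zip(_TRI_GAUSS, _TRI_W):
            pts.append((xi, eta, zeta, w, layer))
    return pts


def _element_coords(canvas: Canvas) -> np.ndarray:
    """(E, 6, 3) wedge node coordinates: A triangle then B triangle."""
    return np.concatenate(
        [canvas.pos_a[canvas.triangles], canvas.pos_b[canvas.triangles]], axis=1
    )


def _batched_B(coords: np.ndarray, xi, eta, zeta):
    """Strain-displacement matrices at one quadrature point for all
    elements: returns (detJ (E,), B (E, 6, 18))."""
    dN = _shape_derivatives(xi, eta, zeta)  # (6,3)
    J = np.einsum("eni,nj->eij", coords, dN)  # J[i,j] = dx_i/dxi_j
    detJ = np.linalg.det(J)
    invJ = np.linalg.inv(J)
    # dN/dx_k = dN/dxi_j * dxi_j/dx_k ; inv(J)[j,k] = dxi_j/dx_k
    dNdx = np.einsum("nj,ejk->enk", dN, invJ)
    E = coords.shape[0]
    B = np.zeros((E, 6, 18))
    for n in range(6):
        c = 3 * n
        B[:, 0, c + 0] = dNdx[:, n, 0]
        B[:, 1, c + 1] = dNdx[:, n, 1]
        B[:, 2, c + 2] = dNdx[:, n, 2]
        B[:, 3, c + 1] = dNdx[:, n, 2]
        B[:, 3, c + 2] = dNdx[:, n, 1]
        B[:, 4, c + 0] = dNdx[:, n, 2]
        B[:, 4, c + 2] = dNdx[:, n, 0]
        B[:, 5, c + 0] = dNdx[:, n, 1]
        B[:, 5, c + 1] = dNdx[:, n, 0]
    return detJ, B


def _tensor_to_voigt_strain(t: np.ndarray) -> np.ndarray:
    """Symmetric 3x3 (batched) -> engineering Voigt 6-vector."""
    t = np.asarray(t)
    out = np.empty(t.shape[:-2] + (6,))
    out[..., 0] = t[..., 0, 0]
    out[..., 1] = t[..., 1, 1]
    out[..., 2] = t[..., 2, 2]
    out[..., 3] = 2.0 * t[..., 1, 2]
    out[..., 4] = 2.0 * t[..., 0, 2]
    out[..., 5] = 2.0 * t[..., 0, 1]
    return out


# ---------------------------------------------------------------------------
# constraints
# ---------------------------------------------------------------------------


@dataclass
class ConstraintSet:
    """Zero-displacement constraints plus flatness couplings.

    ``fixed_dofs`` holds global dof indices (node = A vertex i -> i,
    B vertex i -> N + i; dof = 3*node + axis) clamped to zero.
    ``flatness_vertices`` lists midplane vertices whose paired A/B z
    displacements are reduced to a single thickness unknown h with
    uzA = -h/2, uzB = +h/2, keeping the midplane flat while the thickness
    varies.
    """

    fixed_dofs: set = dc_field(default_factory=set)
    flatness_vertices: list = dc_field(default_factory=list)

    @staticmethod
    def _dofs(canvas: Canvas, vertices, axes, surfaces="both"):
        N = canvas.n_vertices
        nodes = []
        for v in np.atleast_1d(vertices):
            if surfaces in ("a", "both"):
                nodes.append(int(v))
            if surfaces in ("b", "both"):
                nodes.append(int(v) + N)
        return {3 * n + ax for n in nodes for ax in np.atleast_1d(axes)}

    def fix_vertices(self, canvas: Canvas, vertices, axes=(0, 1, 2), surfaces="both"):
        self.fixed_dofs |= self._dofs(canvas, vertices, axes, surfaces)
        return self

    def add_flatness(self, canvas: Canvas, vertices=None):
        verts = np.arange(canvas.n_vertices) if vertices is None else np.atleast_1d(vertices)
        self.flatness_vertices.extend(int(v) for v in verts)
        return self

    def validate(self, canvas: Canvas):
        N = canvas.n_vertices
        pair_dofs = set()
        for v in self.flatness_vertices:
            a, b = 3 * v + 2, 3 * (v + N) + 2
            if a in pair_dofs or b in pair_dofs:
                raise ConstraintError(f"vertex {v} appears in multiple flatness pairs")
            pair_dofs |= {a, b}
        clash = pair_dofs & self.fixed_dofs
        if clash:
            raise ConstraintError(f"dofs both fixed and flatness-paired: {sorted(clash)[:5]}")


def _build_transform(canvas: Canvas, constraints: ConstraintSet | None):
    """Sparse map T from reduced unknowns to the full 6N displacement dofs."""
    n_full = 6 * canvas.n_vertices
    if constraints is None:
        constraints = ConstraintSet()
    constraints.validate(canvas)
    N = canvas.n_vertices
    pair_of = {}
    for col_extra, v in enumerate(constraints.flatness_vertices):
        pair_of[3 * v + 2] = (col_extra, -0.5)
        pair_of[3 * (v + N) + 2] = (col_extra, +0.5)

    rows, cols, vals = [], [], []
    col = 0
    colmap = {}
    for dof in range(n_full):
        if dof in constraints.fixed_dofs or dof in pair_of:
            continue
        rows.append(dof)
        cols.append(col)
        vals.append(1.0)
        colmap[dof] = col
        col += 1
    pair_col0 = col
    for dof, (extra, val) in pair_of.items():
        rows.append(dof)
        cols.append(pair_col0 + extra)
        vals.append(val)
    n_red = pair_col0 + len(constraints.flatness_vertices)
    T = sp.csr_matrix((vals, (rows, cols)), shape=(n_full, n_red))
    return T


# ---------------------------------------------------------------------------
# assembly and solve
# ---------------------------------------------------------------------------


@dataclass
class ElasticSystem:
    K: sp.csr_matrix  # reduced, symmetric PSD
    f: np.ndarray  # reduced
    T: sp.csr_matrix  # reduced -> full dofs
    canvas: Canvas


def assemble_elastic_system(
    canvas: Canvas,
    stiffness: np.ndarray,
    specified_growth: np.ndarray | None,
    constraints: ConstraintSet | None = None,
) -> ElasticSystem:
    """Assemble K u = f for the initial-strain problem.

    ``specified_growth`` is the (E, 2, 3, 3) per-layer strain increment
    (may be None for zero growth).  Constrained rows/columns are
    eliminated through the reduction transform; on an unconstrained mesh
    the reduced K keeps the six rigid-body null modes.
    """
    coords = _element_coords(canvas)
    E = canvas.n_elements
    N = canvas.n_vertices
    C = np.asarray(stiffness, dtype=float)

    Ke = np.zeros((E, 18, 18))
    fe = np.zeros((E, 18))
    for xi, eta, zeta, w, layer in _gauss_points():
        detJ, B = _batched_B(coords, xi, eta, zeta)
        wdet = w * detJ
        CB = np.einsum("ab,ebj->eaj", C, B)
        Ke += wdet[:, None, None] * np.einsum("eai,eaj->eij", B, CB)
        if specified_growth is not None:
            eps = _tensor_to_voigt_strain(specified_growth[:, layer])
            sig = eps @ C.T
            fe += wdet[:, None] * np.einsum("eai,ea->ei", B, sig)

    tris = canvas.triangles
    nodes = np.concatenate([tris, tris + N], axis=1)  # (E, 6)
    edofs = (3 * nodes[:, :, None] + np.arange(3)[None, None, :]).reshape(E, 18)
    rows = np.repeat(edofs, 18, axis=1).ravel()
    cols = np.tile(edofs, (1, 18)).ravel()
    K = sp.coo_matrix((Ke.ravel(), (rows, cols)), shape=(6 * N, 6 * N)).tocsr()
    f = np.zeros(6 * N)
    np.add.at(f, edofs.ravel(), fe.ravel())

    T = _build_transform(canvas, constraints)
    Kr = (T.T @ K @ T).tocsr()
    fr = T.T @ f
    return ElasticSystem(Kr, fr, T, canvas)


def _rigid_modes(canvas: Canvas) -> np.ndarray:
    """Candidate rigid-body modes (6, 6N) in the full dof space."""
    P = np.vstack([canvas.pos_a, canvas.pos_b])
    c = P.mean(axis=0)
    X = P - c
    modes = []
    for k in range(3):
        m = np.zeros_like(P)
        m[:, k] = 1.0
        modes.append(m.ravel())
    for k in range(3):
        e = np.zeros(3)
        e[k] = 1.0
        modes.append(np.cross(np.broadcast_to(e, X.shape), X).ravel())
    return np.array(modes)


def solve_displacements(
    system: ElasticSystem,
    tol: float = 1e-6,
    norm: str = "rms",
    method: str = "minres",
    max_iter: int | None = None,
) -> np.ndarray:
    """Solve for vertex displacements; returns an array of shape (2N, 3)
    (surface-A rows then surface-B rows).

    The solution of the unconstrained (or partially constrained) problem
    is only defined up to rigid motions; any rigid mode lying in the
    null space of the reduced operator is projected out after the solve,
    making results reproducible across solvers.
    """
    if tol <= 0:
        raise ParameterError("solver tolerance must be positive")
    K, f, T = system.K, system.f, system.T
    n = K.shape[0]
    fnorm = np.linalg.norm(f)
    if fnorm == 0.0:
        return np.zeros((2 * system.canvas.n_vertices, 3))

    # rigid modes compatible with the constraints span the null space
    D = np.asarray((T.T @ T).diagonal())
    kscale = max(np.abs(K.diagonal()).max(), 1e-300)
    admissible = []
    for m in _rigid_modes(system.canvas):
        mr = (T.T @ m) / D
        if np.linalg.norm(T @ mr - m) > 1e-9 * np.linalg.norm(m):
            continue
        if np.linalg.norm(K @ mr) > 1e-7 * kscale * np.linalg.norm(mr):
            continue
        admissible.append(mr)

    if max_iter is None:
        max_iter = max(2000, 20 * n)
    if method == "direct":
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("error")
                if admissible:
                    # bordered system: Lagrange multipliers pin the rigid modes
                    M = np.array(admissible).T
                    A = sp.bmat(
                        [[K, sp.csc_matrix(M)], [sp.csc_matrix(M.T), None]], format="csc"
                    )
                    sol = spla.spsolve(A, np.concatenate([f, np.zeros(M.shape[1])]))
                    u = sol[:n]
                else:
                    u = spla.spsolve(K.tocsc(), f)
            if not np.all(np.isfinite(u)):
                raise RuntimeError("singular")
        except Exception:
            u = np.linalg.lstsq(K.toarray(), f, rcond=None)[0]
    elif method in ("minres", "cgs"):
        solver = spla.minres if method == "minres" else spla.cgs
        # Jacobi preconditioning: thin-sheet meshes are badly scaled
        d = K.diagonal()
        d = np.where(d > 0, d, 1.0)
        M = sp.diags(1.0 / d)
        u, info = solver(K, f, rtol=tol * 1e-2, maxiter=max_iter, M=M)
        if info > 0:
            # fall back to a least-squares Krylov solve
            u = spla.lsmr(K, f, atol=tol * 1e-3, btol=tol * 1e-3, maxiter=4 * max_iter)[0]
    else:
        raise ParameterError(f"unknown solver {method!r}")

    r = K @ u - f
    if norm == "rms":
        ok = np.linalg.norm(r) <= 10.0 * tol * fnorm
    elif norm == "max":
        ok = np.abs(r).max() <= 10.0 * tol * np.abs(f).max()
    else:
        raise ParameterError(f"unknown residual norm {norm!r}")
    if not ok:
        raise SolverError(
            f"elasticity solve did not reach tolerance: |r|/|f| = "
            f"{np.linalg.norm(r) / fnorm:.3e}"
        )

    # deterministic removal of free rigid modes
    if admissible:
        Q, _ = np.linalg.qr(np.array(admissible).T)
        u = u - Q @ (Q.T @ u)

    full = T @ u
    return full.reshape(-1, 3)


# ---------------------------------------------------------------------------
# resultant growth decomposition
# ---------------------------------------------------------------------------


@dataclass
class DeformationResult:
    """Resultant growth of one solve step.

    ``grad`` is the per-element displacement gradient at the element
    centre; ``strain``/``vorticity`` its symmetric and skew parts;
    ``strain_layers`` the strain at the two through-thickness Gauss
    layers (needed for bending residuals); ``def_grad`` = I + grad.
    """

    displacements: np.ndarray  # (2N, 3)
    grad: np.ndarray  # (E, 3, 3)
    strain: np.ndarray  # (E, 3, 3) symmetric
    vorticity: np.ndarray  # (E, 3, 3) skew
    strain_layers: np.ndarray  # (E, 2, 3, 3)
    def_grad: np.ndarray  # (E, 3, 3)

    def rotation_vectors(self) -> np.ndarray:
        w = self.vorticity
        return np.stack([w[:, 2, 1], w[:, 0, 2], w[:, 1, 0]], axis=1)

    def rotation_angles(self) -> np.ndarray:
        return np.linalg.norm(self.rotation_vectors(), axis=1)

    def principal_growth(self):
        """Eigenvalues (ascending) and eigenvectors of the resultant
        strain: principal growth rates and directions."""
        return np.linalg.eigh(self.strain)


def decompose_growth(canvas: Canvas, displacements: np.ndarray) -> DeformationResult:
    """Differentiate the displacement field element-wise and split it into
    resultant strain (symmetric) and vorticity (skew)."""
    coords = _element_coords(canvas)
    tris = canvas.triangles
    N = canvas.n_vertices
    u_nodes = np.concatenate(
        [displacements[tris], displacements[tris + N]], axis=1
    )  # (E, 6, 3)

    def grad_at(xi, eta, zeta):
        dN = _shape_derivatives(xi, eta, zeta)
        J = np.einsum("eni,nj->eij", coords, dN)
        invJ = np.linalg.inv(J)
        dNdx = np.einsum("nj,ejk->enk", dN, invJ)
        return np.einsum("eni,enk->eik", u_nodes, dNdx)

    g = grad_at(1 / 3, 1 / 3, 0.0)
    strain = 0.5 * (g + np.swapaxes(g, 1, 2))
    vort = 0.5 * (g - np.swapaxes(g, 1, 2))
    layers = np.empty((canvas.n_elements, 2, 3, 3))
    for layer, zeta in enumerate(GAUSS_ZETA):
        gl = grad_at(1 / 3, 1 / 3, zeta)
        layers[:, layer] = 0.5 * (gl + np.swapaxes(gl, 1, 2))
    return DeformationResult(
        displacements=displacements,
        grad=g,
        strain=strain,
        vorticity=vort,
        strain_layers=layers,
        def_grad=np.eye(3)[None] + g,
    )


def deformation_energy(
    canvas: Canvas,
    stiffness: np.ndarray,
    displacements: np.ndarray,
    specified_growth: np.ndarray | None,
) -> float:
    """Residual-strain energy 1/2 * int (Du - eps_spec) : C : (Du - eps_spec).

    The equilibrium solution minimises this functional; used by tests and
    by the incremental strain-release loop.
    """
    coords = _element_coords(canvas)
    N = canvas.n_vertices
    tris = canvas.triangles
    edisp = np.concatenate([displacements[tris], displacements[tris + N]], axis=1)
    ue = edisp.reshape(canvas.n_elements, 18)
    C = np.asarray(stiffness)
    total = 0.0
    for xi, eta, zeta, w, layer in _gauss_points():
        detJ, B = _batched_B(coords, xi, eta, zeta)
        eps = np.einsum("eaj,ej->ea", B, ue)
        if specified_growth is not None:
            eps = eps - _tensor_to_voigt_strain(specified_growth[:, layer])
        total += float(np.sum(w * detJ * np.einsum("ea,ab,eb->e", eps, C, eps)))
    return 0.5 * total


def stored_strain_energy(canvas: Canvas, stiffness: np.ndarray, layers: np.ndarray) -> float:
    """Energy of a stored per-layer strain field, 1/2 * int eps : C : eps."""
    C = np.asarray(stiffness)
    vols = canvas.wedge_volumes()
    eps = _tensor_to_voigt_strain(layers)  # (E, 2, 6)
    dens = np.einsum("ela,ab,elb->el", eps, C, eps)
    return 0.5 * float(np.sum(0.5 * vols[:, None] * dens))


# ---------------------------------------------------------------------------
# St. Venant compatibility oracle
# ---------------------------------------------------------------------------


def stvenant_residual(strain_exprs, points) -> float:
    """Maximum absolute St. Venant compatibility residual of a closed-form
    strain field at the given sample points.

    The identity checked is
    ``e_ij,kl + e_kl,ij - e_ik,jl - e_jl,ik = 0`` for all index
    quadruples; it vanishes identically iff the field is (locally) the
    symmetric gradient of some displacement field.  Intended as an oracle
    and diagnostic, not a production path.
    """
    x, y, z = sym.symbols("x y z")
    M = sym.Matrix(strain_exprs)
    if M.shape != (3, 3):
        raise ParameterError("strain field must be a 3x3 expression matrix")
    coords = [x, y, z]
    funcs = []
    for i in range(3):
        for j in range(3):
            for k in range(3):
                for l in range(3):  # noqa: E741
                    expr = (
                        sym.diff(M[i, j], coords[k], coords[l])
                        + sym.diff(M[k, l], coords[i], coords[j])
                        - sym.diff(M[i, k], coords[j], coords[l])
                        - sym.diff(M[j, l], coords[i], coords[k])
                    )
                    expr = sym.simplify(expr)
                    if expr != 0:
                        funcs.append(sym.lambdify((x, y, z), expr, "numpy"))
    if not funcs:
        return 0.0
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    worst = 0.0
    for fn in funcs:
        vals = np.abs(np.asarray(fn(pts[:, 0], pts[:, 1], pts[:, 2]), dtype=float))
        worst = max(worst, float(np.max(vals)))
    return worst


# ---------------------------------------------------------------------------
# full-tensor utilities and the stiffness-modulation equivalence
# ---------------------------------------------------------------------------


def voigt_to_full(C6: np.ndarray) -> np.ndarray:
    """6x6 Voigt stiffness -> full 3x3x3x3 tensor."""
    C6 = np.asarray(C6, dtype=float)
    out = np.empty((3, 3, 3, 3))
    for i in range(3):
        for j in range(3):
            for k in range(3):
                for l in range(3):  # noqa: E741
                    out[i, j, k, l] = C6[_VOIGT_INDEX[i, j], _VOIGT_INDEX[k, l]]
    return out


def full_to_voigt(C: np.ndarray) -> np.ndarray:
    C6 = np.empty((6, 6))
    for I, (i, j) in enumerate(_VOIGT_PAIRS):
        for J, (k, l) in enumerate(_VOIGT_PAIRS):  # noqa: E741
            C6[I, J] = C[i, j, k, l]
    return C6


def rotate_stiffness(C: np.ndarray, R: np.ndarray) -> np.ndarray:
    """Rotate a full 4th-rank stiffness tensor by rotation matrix R."""
    return np.einsum("ia,jb,kc,ld,abcd->ijkl", R, R, R, R, C)


def isotropic_compliance_full(material: ElasticMaterial) -> np.ndarray:
    """Closed-form compliance tensor S = C^-1 of an isotropic material."""
    mu, nu = material.shear_modulus, material.poisson
    lam = 2.0 * mu * nu / (1.0 - 2.0 * nu)
    delta = np.eye(3)
    I_sym = 0.5 * (
        np.einsum("ik,jl->ijkl", delta, delta) + np.einsum("il,jk->ijkl", delta, delta)
    )
    dd = np.einsum("ij,kl->ijkl", delta, delta)
    return I_sym / (2.0 * mu) - lam / (2.0 * mu * (3.0 * lam + 2.0 * mu)) * dd


def stiffness_modulation_strain(
    material: ElasticMaterial,
    delta_C: np.ndarray,
    turgor: float = 1.0,
):
    """Specified strain equivalent to a small stiffness modulation.

    For a tissue under isotropic turgor pressure p with isotropic
    background stiffness C and a small orthotropic stiffness change dC,
    growing by loosening (dC) is equivalent to growing by the specified
    strain kappa = S : dC : S : p  (S = C^-1).  The principal axes of
    kappa coincide with those of dC, so a single polarity field serves
    both descriptions.

    Returns ``(kappa, eigenvalues, eigenvectors)`` with eigenpairs of the
    3x3 kappa tensor (ascending).
    """
    S = isotropic_compliance_full(material)
    dC = np.asarray(delta_C, dtype=float)
    if dC.shape == (6, 6):
        dC = voigt_to_full(dC)
    C6 = isotropic_stiffness(material)
    if np.linalg.norm(full_to_voigt(dC)) > 0.1 * np.linalg.norm(C6):
        warnings.warn(
            "stiffness change is not small relative to the background; "
            "the equivalence is first-order only",
            stacklevel=2,
        )
    p = turgor * np.eye(3)
    t1 = np.einsum("ijkl,kl->ij", S, p)
    t2 = np.einsum("ijkl,kl->ij", dC, t1)
    kappa = np.einsum("ijkl,kl->ij", S, t2)
    evals, evecs = np.linalg.eigh(kappa)
    return kappa, evals, evecs
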