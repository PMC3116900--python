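"""Residual-strain bookkeeping.

Each step of growth specifies a strain; the part that mechanical
continuity does not realise is the step's residual strain.  A region may
dissipate it (the default: the tissue absorbs its own pre-stress) or
retain any fraction of it as stored strain.  Stored tensors are material
quantities: as the tissue rotates they are convected with it.  Retained
strain is revealed by cutting or by releasing constraints, and the
resulting (large) motion is computed incrementally: apply a small fraction
of the store as specified strain, solve the small-displacement problem,
subtract what was realised, rotate the remainder, repeat to equilibrium.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .canvas import Canvas
from .elasticity import (
    ConstraintSet,
    assemble_elastic_system,
    decompose_growth,
    solve_displacements,
    stored_strain_energy,
)
from .errors import ModelError, RelaxationError

__all__ = [
    "ResidualStore",
    "accumulate_residual",
    "convect_residual",
    "relax_residual",
]


@dataclass
class ResidualStore:
    """Retained symmetric strain per element and quadrature layer."""

    layers: np.ndarray  # (E, 2, 3, 3)

    @classmethod
    def zeros(cls, n_elements: int) -> "ResidualStore":
        return cls(np.zeros((n_elements, 2, 3, 3)))

    def norm(self) -> float:
        return float(np.sqrt(np.sum(self.layers**2)))

    def copy(self) -> "ResidualStore":
        return ResidualStore(self.layers.copy())


def accumulate_residual(
    store: ResidualStore,
    step_residual: np.ndarray,
    retention,
) -> ResidualStore:
    """Add the retained fraction of a step's residual strain to the store.

    ``retention`` is a scalar or per-element array in [0, 1]; 0 discards
    (dissipation), 1 retains fully.
    """
    r = np.asarray(retention, dtype=float)
    if np.any(r < 0) or np.any(r > 1):
        raise ModelError("retention fraction must lie in [0, 1]")
    if r.ndim == 0:
        r = np.full(store.layers.shape[0], float(r))
    store.layers = store.layers + r[:, None, None, None] * step_residual
    return store


def convect_residual(store: ResidualStore, rotation_vectors: np.ndarray) -> ResidualStore:
    """Conjugate each stored tensor by its element's incremental rotation.

    ``rotation_vectors`` are the per-element rotation increments (axis *
    angle, from the step's vorticity); trace and determinant of every
    stored tensor are invariant.
    """
    angles = np.linalg.norm(rotation_vectors, axis=1)
    active = angles > 0.0
    if not np.any(active):
        return store
    R = Rotation.from_rotvec(rotation_vectors[active]).as_matrix()
    for layer in range(store.layers.shape[1]):
        t = store.layers[active, layer]
        store.layers[active, layer] = np.einsum("eij,ejk,elk->eil", R, t, R)
    return store


def relax_residual(
    canvas: Canvas,
    store: ResidualStore,
    stiffness: np.ndarray,
    constraints: ConstraintSet | None = None,
    fraction_per_iter: float = 0.1,
    tol: float = 1e-6,
    max_iters: int = 200,
    solver: str = "direct",
    solver_tol: float = 1e-6,
):
    """Incrementally release stored strain until equilibrium.

    Returns ``(canvas, store, info)`` where ``info`` carries the energy
    trace and iteration count.  Energy of the store is non-increasing; if
    the loop fails to settle within ``max_iters`` a
    :class:`RelaxationError` is raised with the trace attached.
    """
    if not (0.0 < fraction_per_iter <= 1.0):
        raise ModelError("fraction_per_iter must lie in (0, 1]")
    canvas = canvas.copy()
    store = store.copy()
    N = canvas.n_vertices
    energies = [stored_strain_energy(canvas, stiffness, store.layers)]
    scale = max(store.norm(), 1e-300)
    for it in range(max_iters):
        if store.norm() <= tol * scale:
            break
        applied = fraction_per_iter * store.layers
        system = assemble_elastic_system(canvas, stiffness, applied, constraints)
        u = solve_displacements(system, tol=solver_tol, method=solver)
        result = decompose_growth(canvas, u)
        canvas.pos_a = canvas.pos_a + u[:N]
        canvas.pos_b = canvas.pos_b + u[N:]
        store.layers = store.layers - result.strain_layers
        convect_residual(store, result.rotation_vectors())
        energies.append(stored_strain_energy(canvas, stiffness, store.layers))
        moved = float(np.abs(u).max())
        if moved <= tol * max(1.0, float(np.abs(canvas.midplane).max())):
            break
        # equilibrium: the store's energy has stopped releasing (an
        # incompatible remainder plateaus at positive energy)
        if len(energies) >= 3 and abs(energies[-1] - energies[-2]) <= 1e-4 * max(
            energies[-2], 1e-300
        ):
            break
    else:
        raise RelaxationError(
            f"strain release did not settle in {max_iters} iterations",
            energy_trace=energies,
        )
    return canvas, store, {"iterations": it + 1, "energy_trace": energies}
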