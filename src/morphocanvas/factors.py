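"""Regulatory factor fields, the polariser-derived polarity state, and the
interaction-function API.

Two factor classes exist.  *Identity* factors are regional labels carried
with the tissue: they never diffuse and are never diluted.  *Signalling*
factors propagate by diffusion, are produced and decayed, and are diluted
as the tissue expands.  A distinguished signalling factor, the POLARISER
(``POL``), defines local tissue polarity through its gradient: growth rates
are specified parallel and perpendicular to that axis.  Organisers are
vertex sets where POL production or degradation is clamped, anchoring the
polarity field.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field as dc_field
from enum import IntEnum

import numpy as np

from .canvas import Canvas
from .errors import ContractViolation, DomainError, ParameterError

__all__ = [
    "FactorField",
    "PolarityMode",
    "PolarityState",
    "pro",
    "inh",
    "compute_pol_gradient",
    "update_polarity",
    "apply_threshold_rule",
    "run_interaction",
]


@dataclass
class FactorField:
    """A per-vertex scalar factor concentration field.

    Parameters
    ----------
    kind
        ``"identity"`` or ``"signalling"``.  Identity factors must have
        ``D == 0`` and are never dilutable.
    D
        Diffusion constant (length^2 / time).
    production
        Per-vertex production rate (concentration / time); a scalar is
        broadcast.
    decay
        Uniform first-order decay rate (1 / time).
    dilutable
        Whether growth dilutes the field.
    fixed_nodes
        Vertex indices clamped to their current value (organisers,
        Dirichlet boundaries).
    """

    name: str
    kind: str
    values: np.ndarray
    D: float = 0.0
    production: np.ndarray | float = 0.0
    decay: float = 0.0
    dilutable: bool = False
    fixed_nodes: np.ndarray = dc_field(default_factory=lambda: np.array([], dtype=np.int64))

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.fixed_nodes = np.asarray(self.fixed_nodes, dtype=np.int64)
        if self.kind not in ("identity", "signalling"):
            raise ParameterError(f"unknown factor kind {self.kind!r}")
        if self.kind == "identity":
            if self.D != 0.0:
                raise ParameterError("identity factors do not propagate (D must be 0)")
            self.dilutable = False

    def production_vector(self, n: int) -> np.ndarray:
        p = np.asarray(self.production, dtype=float)
        return np.full(n, float(p)) if p.ndim == 0 else p

    def copy(self) -> "FactorField":
        return FactorField(
            self.name,
            self.kind,
            self.values.copy(),
            self.D,
            np.array(self.production, copy=True) if np.ndim(self.production) else self.production,
            self.decay,
            self.dilutable,
            self.fixed_nodes.copy(),
        )


# ---------------------------------------------------------------------------
# promotion / inhibition primitives
# ---------------------------------------------------------------------------


def pro(k: float, x) -> np.ndarray:
    """Promotion multiplier ``1 + k*x`` (elementwise).

    Tends to 1 as ``x`` tends to zero; monotone non-decreasing; composes
    multiplicatively with other promotions and inhibitions.
    """
    x = np.asarray(x, dtype=float)
    if k < 0:
        raise DomainError("promotion gain k must be >= 0")
    if np.any(x < 0):
        raise DomainError("factor levels must be >= 0")
    return 1.0 + k * x


def inh(k: float, x) -> np.ndarray:
    """Inhibition multiplier ``1 / (1 + k*x)`` (elementwise).

    Tends to 1 as ``x`` tends to zero, to 0 as ``x`` grows; the exact
    reciprocal of :func:`pro` with the same arguments.
    """
    x = np.asarray(x, dtype=float)
    if k < 0:
        raise DomainError("inhibition gain k must be >= 0")
    if np.any(x < 0):
        raise DomainError("factor levels must be >= 0")
    return 1.0 / (1.0 + k * x)


# ---------------------------------------------------------------------------
# polarity
# ---------------------------------------------------------------------------


class PolarityMode(IntEnum):
    ABSENT = 0
    LIVE = 1
    FROZEN = 2
    EXTERNAL = 3


@dataclass
class PolarityState:
    """Per-element growth axis derived from the POL gradient.

    ``axis`` is a unit vector in each element's midplane (zero where the
    mode is ABSENT).  In LIVE mode the axis follows the instantaneous POL
    gradient; FROZEN axes are material vectors convected with the element;
    EXTERNAL axes are the in-plane projection of a fixed lab-frame
    direction.  The axis is axial: only its line matters, growth tensors
    are invariant under ``axis -> -axis``.
    """

    axis: np.ndarray  # (E, 3)
    mode: np.ndarray  # (E,) PolarityMode values
    gradient_threshold: float = 0.0
    shallow_policy: str = "freeze"  # freeze | absent
    external_direction: np.ndarray | None = None

    @classmethod
    def blank(cls, n_elements: int, **kw) -> "PolarityState":
        return cls(
            axis=np.zeros((n_elements, 3)),
            mode=np.full(n_elements, int(PolarityMode.ABSENT)),
            **kw,
        )

    def copy(self) -> "PolarityState":
        return PolarityState(
            self.axis.copy(),
            self.mode.copy(),
            self.gradient_threshold,
            self.shallow_policy,
            None if self.external_direction is None else self.external_direction.copy(),
        )


def compute_pol_gradient(canvas: Canvas, pol: FactorField) -> np.ndarray:
    """Per-element gradient of the linear interpolant of POL.

    The gradient lies in each triangle's plane; degenerate triangles get a
    zero gradient.
    """
    if pol.kind != "signalling":
        raise ParameterError("POL must be a signalling factor")
    mp = canvas.midplane
    tris = canvas.triangles
    p0, p1, p2 = mp[tris[:, 0]], mp[tris[:, 1]], mp[tris[:, 2]]
    c0, c1, c2 = (pol.values[tris[:, k]] for k in range(3))
    n = np.cross(p1 - p0, p2 - p0)
    a2 = np.linalg.norm(n, axis=1)  # 2*area
    ok = a2 > 1e-300
    nhat = np.zeros_like(n)
    nhat[ok] = n[ok] / a2[ok, None]
    # gradient of P1 interpolant: sum c_i * (n x opposite_edge) / (2A)
    g = (
        c0[:, None] * np.cross(nhat, p2 - p1)
        + c1[:, None] * np.cross(nhat, p0 - p2)
        + c2[:, None] * np.cross(nhat, p1 - p0)
    )
    g[ok] /= a2[ok, None]
    g[~ok] = 0.0
    return g


def _project_unit(vecs: np.ndarray, normals: np.ndarray) -> np.ndarray:
    v = vecs - np.einsum("ij,ij->i", vecs, normals)[:, None] * normals
    n = np.linalg.norm(v, axis=1)
    out = np.zeros_like(v)
    ok = n > 1e-300
    out[ok] = v[ok] / n[ok, None]
    return out


def update_polarity(
    canvas: Canvas,
    state: PolarityState,
    gradients: np.ndarray | None = None,
    deformation_gradients: np.ndarray | None = None,
) -> PolarityState:
    """Advance the polarity state for the current geometry.

    LIVE elements take the (negated, normalised) POL gradient where its
    magnitude exceeds the detection threshold; below it the configured
    shallow-gradient policy applies (freeze the current axis, or drop to
    isotropy).  FROZEN axes are convected by the per-element deformation
    gradient of the last step, then re-projected into the element plane
    and renormalised.  EXTERNAL axes are the projection of the fixed
    lab-frame direction.
    """
    new = state.copy()
    normals = canvas.triangle_normals()
    live = state.mode == int(PolarityMode.LIVE)
    frozen = state.mode == int(PolarityMode.FROZEN)
    ext = state.mode == int(PolarityMode.EXTERNAL)

    if np.any(live):
        if gradients is None:
            raise ParameterError("LIVE polarity requires POL gradients")
        mag = np.linalg.norm(gradients, axis=1)
        usable = live & (mag >= max(state.gradient_threshold, 1e-300))
        # polarity points down-gradient (away from + organisers)
        new.axis[usable] = _project_unit(-gradients[usable], normals[usable])
        shallow = live & ~usable
        if np.any(shallow):
            if state.shallow_policy == "absent":
                new.axis[shallow] = 0.0
                new.mode[shallow] = int(PolarityMode.ABSENT)
            else:  # freeze the last usable axis in material coordinates
                had_axis = shallow & (np.linalg.norm(state.axis, axis=1) > 0.5)
                new.mode[had_axis] = int(PolarityMode.FROZEN)
                new.axis[had_axis] = _project_unit(state.axis[had_axis], normals[had_axis])
                none_yet = shallow & ~had_axis
                new.axis[none_yet] = 0.0
                new.mode[none_yet] = int(PolarityMode.ABSENT)

    if np.any(frozen):
        a = state.axis[frozen]
        if deformation_gradients is not None:
            a = np.einsum("eij,ej->ei", deformation_gradients[frozen], a)
        new.axis[frozen] = _project_unit(a, normals[frozen])

    if np.any(ext):
        if state.external_direction is None:
            raise ParameterError("EXTERNAL polarity requires external_direction")
        d = np.broadcast_to(state.external_direction, (int(ext.sum()), 3))
        new.axis[ext] = _project_unit(d.copy(), normals[ext])

    return new


def apply_threshold_rule(
    field_values: np.ndarray, threshold: float, identity_values: np.ndarray
) -> np.ndarray:
    """Latch an identity factor on wherever a signal drops below a threshold.

    Once a vertex is switched on (value 1) it stays on, so regions can
    only gain territory — the rule partitions the canvas irreversibly.
    """
    if not np.isfinite(threshold):
        if threshold > 0:
            return np.ones_like(identity_values)
        return identity_values.copy()
    out = identity_values.copy()
    out[field_values < threshold] = 1.0
    return out


# ---------------------------------------------------------------------------
# interaction hooks
# ---------------------------------------------------------------------------


def _geometry_checksum(canvas: Canvas) -> str:
    h = hashlib.sha256()
    h.update(canvas.pos_a.tobytes())
    h.update(canvas.pos_b.tobytes())
    h.update(canvas.triangles.tobytes())
    return h.hexdigest()


def run_interaction(hook, state) -> None:
    """Invoke the user interaction function for one step.

    The hook receives the full simulation state and may update factor
    production/decay rates, the five growth-rate fields, the retention
    fraction, and polarity modes — but must not move vertices.  Geometry
    is checksummed before and after; any mutation raises
    :class:`ContractViolation`.
    """
    if hook is None:
        return
    before = _geometry_checksum(state.canvas)
    hook(state)
    if _geometry_checksum(state.canvas) != before:
        raise ContractViolation("interaction hook modified mesh geometry")
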