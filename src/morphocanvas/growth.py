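"""Specified growth tensors.

The regulatory layer hands this module five per-element rates: growth
parallel to the polarity axis on each surface (kpar_a, kpar_b), growth
perpendicular to it in-plane (kper_a, kper_b), and thickness growth
(kthick).  Together with the polarity axis these define, per element and
per through-thickness quadrature layer, the symmetric strain increment the
element would undergo in a time step dt if it grew in mechanical isolation
— the *specified* growth.  Differences between the two surfaces put the
two quadrature layers in different states, which is what generates bending
moments (curling, invagination).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .canvas import Canvas
from .errors import GeometryError, ModelError
from .factors import PolarityMode, PolarityState

__all__ = ["GrowthSpec", "local_frame", "assemble_specified_growth", "GAUSS_ZETA"]

# through-thickness Gauss points (reference coordinate zeta in [-1, 1]);
# layer 0 is biased to surface A, layer 1 to surface B
GAUSS_ZETA = np.array([-1.0 / np.sqrt(3.0), 1.0 / np.sqrt(3.0)])


@dataclass
class GrowthSpec:
    """Per-element specified growth rates (1/time).

    Negative rates (contraction) are permitted.  ``isotropic_fallback``
    selects the in-plane rate used where polarity is absent: the mean of
    kpar and kper (preserving specified areal growth), or one of them.
    """

    kpar_a: np.ndarray
    kpar_b: np.ndarray
    kper_a: np.ndarray
    kper_b: np.ndarray
    kthick: np.ndarray
    isotropic_fallback: str = "mean"

    @classmethod
    def zeros(cls, n_elements: int, **kw) -> "GrowthSpec":
        z = lambda: np.zeros(n_elements)  # noqa: E731
        return cls(z(), z(), z(), z(), z(), **kw)

    @classmethod
    def from_vertex_fields(
        cls, canvas: Canvas, kpar_a, kpar_b=None, kper_a=0.0, kper_b=None,
        kthick=0.0, isotropic_fallback: str = "mean",
    ) -> "GrowthSpec":
        """Average per-vertex KRN outputs onto elements.

        Omitted B-surface rates default to the A-surface values (no
        bending moment)."""
        def elem_mean(v):
            v = np.asarray(v, dtype=float)
            if v.ndim == 0:
                return np.full(canvas.n_elements, float(v))
            return v[canvas.triangles].mean(axis=1)

        kpar_b = kpar_a if kpar_b is None else kpar_b
        kper_b = kper_a if kper_b is None else kper_b
        return cls(
            elem_mean(kpar_a), elem_mean(kpar_b),
            elem_mean(kper_a), elem_mean(kper_b),
            elem_mean(kthick), isotropic_fallback,
        )

    def max_rate(self) -> float:
        return float(
            max(
                np.abs(self.kpar_a).max(initial=0.0),
                np.abs(self.kpar_b).max(initial=0.0),
                np.abs(self.kper_a).max(initial=0.0),
                np.abs(self.kper_b).max(initial=0.0),
                np.abs(self.kthick).max(initial=0.0),
            )
        )


def local_frame(canvas: Canvas, element: int, polarity: PolarityState | None = None):
    """Right-handed orthonormal frame (u, v, n) for one element.

    ``u`` is the polarity axis (projected in-plane), ``v`` the in-plane
    perpendicular, ``n`` the element normal.  With polarity absent the
    in-plane pair is an arbitrary but deterministic choice (first edge
    direction).
    """
    tri = canvas.triangles[element]
    p = canvas.midplane[tri]
    c = np.cross(p[1] - p[0], p[2] - p[0])
    a2 = np.linalg.norm(c)
    if a2 <= 0.0:
        raise GeometryError(f"element {element} has zero area")
    n = c / a2
    axis = None
    if polarity is not None and polarity.mode[element] != int(PolarityMode.ABSENT):
        axis = polarity.axis[element]
        if np.linalg.norm(axis) == 0.0:
            axis = None
    if axis is None:
        axis = p[1] - p[0]
    u = axis - (axis @ n) * n
    nu = np.linalg.norm(u)
    if nu <= 1e-300:
        u = p[1] - p[0]
        u = u - (u @ n) * n
        nu = np.linalg.norm(u)
    u = u / nu
    v = np.cross(n, u)
    return u, v, n


def assemble_specified_growth(
    canvas: Canvas,
    spec: GrowthSpec,
    polarity: PolarityState | None,
    dt: float,
) -> np.ndarray:
    """Specified strain increments, shape ``(E, 2, 3, 3)``.

    Rates interpolate linearly through the thickness between the two
    surfaces and are evaluated at the two Gauss layers used by the
    elasticity quadrature.  The tensor in the local frame is
    ``dt * (kpar u⊗u + kper v⊗v + kthick n⊗n)``; where polarity is absent
    the in-plane part becomes isotropic at the configured fallback rate.
    """
    E = canvas.n_elements
    for name in ("kpar_a", "kpar_b", "kper_a", "kper_b", "kthick"):
        arr = getattr(spec, name)
        if not np.all(np.isfinite(arr)):
            bad = int(np.flatnonzero(~np.isfinite(arr))[0])
            raise ModelError(f"non-finite growth rate {name} in element {bad}")

    tris = canvas.triangles
    mp = canvas.midplane
    p0, p1, p2 = mp[tris[:, 0]], mp[tris[:, 1]], mp[tris[:, 2]]
    cvec = np.cross(p1 - p0, p2 - p0)
    a2 = np.linalg.norm(cvec, axis=1)
    if np.any(a2 <= 0.0):
        raise GeometryError("zero-area element in specified-growth assembly")
    n = cvec / a2[:, None]

    if polarity is None:
        absent = np.ones(E, dtype=bool)
        axes = np.zeros((E, 3))
    else:
        absent = polarity.mode == int(PolarityMode.ABSENT)
        axes = polarity.axis.copy()
    absent = absent | (np.linalg.norm(axes, axis=1) < 1e-300)

    u = np.where(absent[:, None], p1 - p0, axes)
    u = u - np.einsum("ij,ij->i", u, n)[:, None] * n
    nrm = np.linalg.norm(u, axis=1)
    weak = nrm <= 1e-300
    if np.any(weak):  # axis parallel to normal: fall back to first edge
        u[weak] = p1[weak] - p0[weak]
        u[weak] -= np.einsum("ij,ij->i", u[weak], n[weak])[:, None] * n[weak]
        nrm[weak] = np.linalg.norm(u[weak], axis=1)
        absent = absent | weak
    u /= nrm[:, None]
    v = np.cross(n, u)

    out = np.zeros((E, 2, 3, 3))
    for layer, zeta in enumerate(GAUSS_ZETA):
        wa, wb = 0.5 * (1.0 - zeta), 0.5 * (1.0 + zeta)
        kpar = wa * spec.kpar_a + wb * spec.kpar_b
        kper = wa * spec.kper_a + wb * spec.kper_b
        if spec.isotropic_fallback == "mean":
            iso = 0.5 * (kpar + kper)
        elif spec.isotropic_fallback == "kpar":
            iso = kpar
        elif spec.isotropic_fallback == "kper":
            iso = kper
        else:
            raise ModelError(f"unknown isotropic fallback {spec.isotropic_fallback!r}")
        kpar = np.where(absent, iso, kpar)
        kper = np.where(absent, iso, kper)
        out[:, layer] = dt * (
            kpar[:, None, None] * np.einsum("ei,ej->eij", u, u)
            + kper[:, None, None] * np.einsum("ei,ej->eij", v, v)
            + spec.kthick[:, None, None] * np.einsum("ei,ej->eij", n, n)
        )
    return out
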