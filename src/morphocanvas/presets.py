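"""Named case presets.

Each preset wires a canvas, factor fields, organisers, a polarity mode and
an interaction hook into a ready-to-run :class:`Simulation`.  The cases
form a combinatorial ladder: uniform anisotropic growth (A), differential
isotropic growth (B), their combinations under frozen / external / live
polarity (C, D, E), non-uniform polarity fields (F-I), out-of-plane
outgrowths on a bowed sheet (J-Q), the simplified corolla tube (R-T),
residual-strain retention and release experiments (U-Y), diffusion
patterning on a disc (Z), and a furrow-invagination demonstration driven
by per-surface negative growth.

Resolutions are parameters; the defaults here are sized so every case
runs in minutes on one CPU, and can be raised toward the mesh densities
typical for these models.
"""

from __future__ import annotations

import numpy as np

from .canvas import Canvas, build_cylinder, build_disc, build_flat_sheet, mark_circular_clones
from .diffusion import steady_state
from .elasticity import ConstraintSet
from .errors import ParameterError
from .factors import (
    FactorField,
    PolarityMode,
    PolarityState,
    apply_threshold_rule,
    compute_pol_gradient,
    inh,
    update_polarity,
)
from .simulation import SimConfig, SimState, Simulation

__all__ = ["PRESETS", "get_preset", "run_case", "run_residual_experiment"]


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _clamp(field: FactorField, vertices, value: float):
    vertices = np.asarray(vertices, dtype=np.int64)
    field.values[vertices] = value
    field.fixed_nodes = np.unique(np.concatenate([field.fixed_nodes, vertices]))


def _make_pol(canvas: Canvas, plus, minus, D: float = 1.0, decay: float = 0.0) -> FactorField:
    """Polariser anchored by clamped organisers, equilibrated to steady
    state (the setup phase)."""
    pol = FactorField("POL", "signalling", np.zeros(canvas.n_vertices), D=D, decay=decay,
                      dilutable=False)
    if plus is not None and len(np.atleast_1d(plus)):
        _clamp(pol, plus, 1.0)
    if minus is not None and len(np.atleast_1d(minus)):
        _clamp(pol, minus, 0.0)
    pol.values = steady_state(canvas, pol)
    return pol


def _polarity_from_pol(canvas: Canvas, pol: FactorField, mode: str,
                       external=None) -> PolarityState:
    state = PolarityState.blank(canvas.n_elements)
    state.gradient_threshold = 1e-6
    if mode == "external":
        state.mode[:] = int(PolarityMode.EXTERNAL)
        state.external_direction = np.asarray(external, dtype=float)
        return update_polarity(canvas, state)
    state.mode[:] = int(PolarityMode.LIVE)
    grads = compute_pol_gradient(canvas, pol)
    state = update_polarity(canvas, state, grads)
    if mode == "frozen":
        live = state.mode == int(PolarityMode.LIVE)
        state.mode[live] = int(PolarityMode.FROZEN)
    elif mode != "live":
        raise ParameterError(f"unknown polarity mode {mode!r}")
    return state


def _graded_field(canvas: Canvas, name: str, source_vertices, D: float, decay: float,
                  dilutable: bool = False) -> FactorField:
    """A static graded pattern: equilibrate a clamped source against
    diffusion/decay during setup, then freeze (no further propagation)."""
    f = FactorField(name, "signalling", np.zeros(canvas.n_vertices), D=D, decay=decay,
                    dilutable=dilutable)
    _clamp(f, source_vertices, 1.0)
    f.values = steady_state(canvas, f)
    f.D = 0.0
    f.decay = 0.0
    f.fixed_nodes = np.array([], dtype=np.int64)
    return f


def _radius_mask(canvas: Canvas, center, r_inner: float, r_outer: float) -> np.ndarray:
    """1 inside r_inner, 0 outside r_outer, linear ramp between."""
    d = np.linalg.norm(canvas.midplane[:, :2] - np.asarray(center)[:2], axis=1)
    return np.clip((r_outer - d) / max(r_outer - r_inner, 1e-12), 0.0, 1.0)


def _flat_common(resolution, side=1.0, thickness=0.1, bow=0.0, clones=True, seed=0):
    canvas = build_flat_sheet(resolution, resolution, side, thickness, bow)
    cl = None
    if clones:
        cl = mark_circular_clones(canvas, 5, 0.05 * side, seed=seed)
    return canvas, cl


# ---------------------------------------------------------------------------
# 2D cases (flat canvas constrained to stay flat, thickness free)
# ---------------------------------------------------------------------------


def _flat_2d_state(canvas, fields, polarity, clones, retention=0.0):
    cons = ConstraintSet().add_flatness(canvas)
    return SimState(canvas=canvas, fields=fields, polarity=polarity,
                    constraints=cons, clones=clones, retention=retention)


def _case_A(resolution=20, seed=0, K=1.0, total_time=0.8, **cfg):
    canvas, clones = _flat_common(resolution, seed=seed)
    pol = _make_pol(canvas, canvas.vertex_sets["bottom"], canvas.vertex_sets["top"])
    polarity = _polarity_from_pol(canvas, pol, "frozen")
    g = FactorField("g", "identity", np.ones(canvas.n_vertices))
    state = _flat_2d_state(canvas, {"POL": pol, "g": g}, polarity, clones)

    def hook(s):
        s.set_rates(kpar=K * s.fields["g"].values, kper=0.0)

    return Simulation(state, hook, SimConfig(total_time=total_time, seed=seed, **cfg))


def _case_B(resolution=20, seed=0, K=1.0, total_time=0.8, **cfg):
    canvas, clones = _flat_common(resolution, seed=seed)
    f = _graded_field(canvas, "f", canvas.vertex_sets["right"], D=0.05, decay=2.0)
    polarity = PolarityState.blank(canvas.n_elements)
    state = _flat_2d_state(canvas, {"f": f}, polarity, clones)

    def hook(s):
        areal = K * s.fields["f"].values
        s.set_rates(kpar=0.5 * areal, kper=0.5 * areal)

    return Simulation(state, hook, SimConfig(total_time=total_time, seed=seed, **cfg))


def _case_C_like(mode, resolution=20, seed=0, K=1.0, total_time=0.8,
                 retention=0.0, fix_boundary=False, **cfg):
    canvas, clones = _flat_common(resolution, seed=seed)
    pol = _make_pol(canvas, canvas.vertex_sets["bottom"], canvas.vertex_sets["top"])
    polarity = _polarity_from_pol(
        canvas, pol, mode, external=(0.0, 1.0, 0.0) if mode == "external" else None
    )
    f = _graded_field(canvas, "f", canvas.vertex_sets["right"], D=0.05, decay=2.0)
    state = _flat_2d_state(canvas, {"POL": pol, "f": f}, polarity, clones, retention)
    if fix_boundary:
        # in-plane fixing; flatness already pins the midplane vertically
        state.constraints.fix_vertices(canvas, canvas.vertex_sets["boundary"], axes=(0, 1))

    def hook(s):
        s.set_rates(kpar=K * s.fields["f"].values, kper=0.0)

    return Simulation(state, hook, SimConfig(total_time=total_time, seed=seed, **cfg))


def _case_C(**kw):
    return _case_C_like("frozen", **kw)


def _case_D(**kw):
    return _case_C_like("external", **kw)


def _case_E(**kw):
    return _case_C_like("live", **kw)


def _case_F_like(mode, grade_growth, resolution=20, seed=0, K=1.0, total_time=0.8, **cfg):
    canvas, clones = _flat_common(resolution, seed=seed)
    vs = canvas.vertex_sets
    minus = np.unique(np.concatenate([vs["top"], vs["bottom"], vs["right"]]))
    plus = np.setdiff1d(vs["midline"], minus)
    pol = _make_pol(canvas, plus, minus)
    polarity = _polarity_from_pol(canvas, pol, mode)
    fields = {"POL": pol}
    if grade_growth:
        fields["f"] = _graded_field(canvas, "f", vs["right"], D=0.05, decay=2.0)

    state = _flat_2d_state(canvas, fields, polarity, clones)

    def hook(s):
        kp = K * s.fields["f"].values if grade_growth else K
        s.set_rates(kpar=kp, kper=0.0)

    return Simulation(state, hook, SimConfig(total_time=total_time, seed=seed, **cfg))


def _case_F(**kw):
    return _case_F_like("frozen", False, **kw)


def _case_G(**kw):
    return _case_F_like("live", False, **kw)


def _case_H(**kw):
    return _case_F_like("frozen", True, **kw)


def _case_I(**kw):
    return _case_F_like("live", True, **kw)


# ---------------------------------------------------------------------------
# 3D outgrowth cases on a bowed sheet
# ---------------------------------------------------------------------------


def _sheet_3d(resolution, seed, bow=0.02):
    canvas, clones = _flat_common(resolution, bow=bow, clones=False, seed=seed)
    cons = ConstraintSet().fix_vertices(canvas, canvas.vertex_sets["boundary"], axes=2)
    return canvas, cons


def _case_J_like(enhancement, no_growth_core=False, resolution=20, seed=0,
                 A0=0.5, total_time=1.0, **cfg):
    """Divergent polarity from a central organiser (cases J, L, M).

    The base areal rate ``A0`` is uniform; within the polarised annulus it
    is split anisotropically along the radial polarity.  ``enhancement``
    scales the extra growth recruited by the centrally graded factor
    (zero in Case J, positive in L/M)."""
    canvas, cons = _sheet_3d(resolution, seed)
    center = (0.5, 0.5)
    inner = np.where(_radius_mask(canvas, center, 0.06, 0.08) > 0.5)[0]
    outer = np.where(_radius_mask(canvas, center, 0.33, 0.35) < 0.5)[0]
    pol = _make_pol(canvas, inner, outer, D=0.5)
    polarity = _polarity_from_pol(canvas, pol, "live")
    fields = {"POL": pol}
    mask = _radius_mask(canvas, center, 0.15, 0.33)
    if enhancement:
        fields["f"] = _graded_field(canvas, "f", inner, D=0.2, decay=4.0)
    core = _radius_mask(canvas, center, 0.04, 0.06) if no_growth_core else None

    state = SimState(canvas=canvas, fields=fields, polarity=polarity, constraints=cons)

    def hook(s):
        areal = A0 * (1.0 + (enhancement * s.fields["f"].values if enhancement else 0.0))
        kpar = (0.5 + 0.4 * mask) * areal
        kper = (0.5 - 0.4 * mask) * areal
        if core is not None:
            kpar = kpar * (1.0 - core)
            kper = kper * (1.0 - core)
        s.set_rates(kpar=kpar, kper=kper)

    return Simulation(state, hook, SimConfig(total_time=total_time, seed=seed, **cfg))


def _case_J(**kw):
    return _case_J_like(0.0, **kw)


def _case_K(resolution=20, seed=0, K=1.0, bg=0.2, total_time=1.0, **cfg):
    canvas, cons = _sheet_3d(resolution, seed)
    inner = np.where(_radius_mask(canvas, (0.5, 0.5), 0.06, 0.08) > 0.5)[0]
    f = _graded_field(canvas, "f", inner, D=0.2, decay=4.0)
    polarity = PolarityState.blank(canvas.n_elements)
    state = SimState(canvas=canvas, fields={"f": f}, polarity=polarity, constraints=cons)

    def hook(s):
        areal = bg + K * s.fields["f"].values
        s.set_rates(kpar=0.5 * areal, kper=0.5 * areal)

    return Simulation(state, hook, SimConfig(total_time=total_time, seed=seed, **cfg))


def _case_L(**kw):
    return _case_J_like(3.0, **kw)


def _case_M(**kw):
    return _case_J_like(3.0, no_growth_core=True, **kw)


def _case_NOPQ(central, central_growth, resolution=20, seed=0, K=1.0, bg=0.2,
               kper_frac=0.2, total_time=1.0, **cfg):
    """Uniform bottom-to-top polarity, optionally distorted by a central
    organiser (N: none, O/P: plus, Q: minus), with uniform or centrally
    enhanced growth."""
    canvas, cons = _sheet_3d(resolution, seed)
    vs = canvas.vertex_sets
    inner = np.where(_radius_mask(canvas, (0.5, 0.5), 0.06, 0.08) > 0.5)[0]
    plus, minus = [vs["bottom"]], [vs["top"]]
    if central == "plus":
        plus.append(inner)
    elif central == "minus":
        minus.append(inner)
    pol = _make_pol(canvas, np.concatenate(plus), np.concatenate(minus), D=0.5)
    polarity = _polarity_from_pol(canvas, pol, "live")
    fields = {"POL": pol}
    if central_growth:
        fields["f"] = _graded_field(canvas, "f", inner, D=0.2, decay=4.0)

    state = SimState(canvas=canvas, fields=fields, polarity=polarity, constraints=cons)

    def hook(s):
        kpar = bg + (K * s.fields["f"].values if central_growth else K * 0.6)
        kper = bg + kper_frac * (kpar - bg)
        s.set_rates(kpar=kpar, kper=kper)

    return Simulation(state, hook, SimConfig(total_time=total_time, seed=seed, **cfg))


def _case_N(**kw):
    return _case_NOPQ(None, True, **kw)


def _case_O(**kw):
    return _case_NOPQ("plus", False, **kw)


def _case_P(**kw):
    return _case_NOPQ("plus", True, **kw)


def _case_Q(**kw):
    return _case_NOPQ("minus", True, **kw)


# ---------------------------------------------------------------------------
# simplified corolla tube (cylinder closed at one end)
# ---------------------------------------------------------------------------


def _tube_setup(resolution, seed, radius=1.0, height=2.0, thickness=0.08):
    canvas = build_cylinder(radius, height, True, resolution, thickness)
    mp = canvas.midplane
    theta = np.arctan2(mp[:, 1], mp[:, 0])
    base_region = np.where(mp[:, 2] < 0.2 * height)[0]
    # growth-restricted strips on opposite sides (theta = +-90 deg)
    strip = (np.abs(np.abs(theta) - 0.5 * np.pi) < np.radians(20)) & (
        mp[:, 2] > 0.1 * height
    ) & (mp[:, 2] < 0.95 * height)
    cons = ConstraintSet().fix_vertices(canvas, canvas.vertex_sets["base"], axes=2)
    return canvas, base_region, np.where(strip)[0], cons


def _case_RST(anisotropic, reorient, resolution=40, seed=0, K=0.018,
              target_area=2.2, **cfg):
    canvas, base_region, strip, cons = _tube_setup(resolution, seed)
    n = canvas.n_vertices
    mp0 = canvas.midplane.copy()
    height = mp0[:, 2].max()

    b = FactorField("b", "identity", np.zeros(n))
    b.values[base_region] = 1.0
    m = FactorField("m", "identity", np.zeros(n))
    m.values[strip] = 1.0
    s_sig = FactorField("s", "signalling", np.zeros(n), D=0.4, decay=1.0,
                        production=0.0, dilutable=True)
    s_sig.production = 3.0 * m.values
    s_sig.values = steady_state(canvas, s_sig)
    fields = {"b": b, "m": m, "s": s_sig}

    if anisotropic:
        distal = np.where(mp0[:, 2] > 0.9 * height)[0]
        pol = _make_pol(canvas, canvas.vertex_sets["base"], distal, D=1.0)
        polarity = _polarity_from_pol(canvas, pol, "live")
        fields["POL"] = pol
        # late-phase distal organiser patches at the arch apexes
        patch = np.where((mp0[:, 2] > 0.75 * height) & (np.abs(mp0[:, 1]) < 0.35))[0]
    else:
        polarity = PolarityState.blank(canvas.n_elements)
        patch = None

    state = SimState(canvas=canvas, fields=fields, polarity=polarity, constraints=cons)
    switched = {"done": False}

    def hook(s):
        areal = K * inh(4.0, s.fields["s"].values) * inh(100.0, s.fields["b"].values)
        if anisotropic:
            if reorient and not switched["done"] and s.area_multiple >= target_area:
                pol_f = s.fields["POL"]
                keep = np.isin(pol_f.fixed_nodes, s.canvas.vertex_sets["base"])
                pol_f.fixed_nodes = pol_f.fixed_nodes[keep]
                _clamp(pol_f, patch, 0.0)
                switched["done"] = True
            s.set_rates(kpar=areal / 1.1, kper=0.1 * areal / 1.1)
        else:
            s.set_rates(kpar=0.5 * areal, kper=0.5 * areal)

    cfg.setdefault("dt_init", 3.0)
    cfg.setdefault("total_time", 1e9)  # horizon set by target area
    return Simulation(state, hook, SimConfig(seed=seed, **cfg))


def _case_R(**kw):
    return _case_RST(False, False, **kw)


def _case_S(**kw):
    return _case_RST(True, False, **kw)


def _case_T(**kw):
    return _case_RST(True, True, **kw)


# ---------------------------------------------------------------------------
# residual strain experiments (based on Case C)
# ---------------------------------------------------------------------------


def _case_U(**kw):
    kw.setdefault("remesh", False)
    return _case_C(retention=0.0, **kw)


def _case_V(**kw):
    kw.setdefault("remesh", False)
    return _case_C(retention=0.0, fix_boundary=True, **kw)


def _case_W(**kw):
    kw.setdefault("remesh", False)
    return _case_C(retention=1.0, **kw)


def _case_X(**kw):
    kw.setdefault("remesh", False)
    return _case_C(retention=1.0, fix_boundary=True, **kw)


def _case_Y(resolution=24, seed=0, **kw):
    kw.setdefault("remesh", False)
    sim = _case_RST(True, True, resolution=resolution, seed=seed, **kw)
    mp = sim.state.canvas.midplane
    sim.state.retention = (mp[:, 0] > 0.0).astype(float)
    return sim


def run_residual_experiment(case: str, resolution=12, seed=0, total_time=0.6,
                            relax_kwargs=None, **kw):
    """Grow one of cases U/V/W/X, then cut (U, W) or release constraints
    (V, X) and relax.

    Returns a dict with the grown simulation, the post-release maximum
    displacement, the store norm before release, and the energy trace of
    the incremental relaxation.
    """
    from .canvas import cut_along_path
    from .elasticity import isotropic_stiffness
    from .residual import relax_residual

    case = case.upper()
    if case not in "UVWX" or len(case) != 1:
        raise ParameterError("experiment cases are U, V, W, X")
    sim = get_preset(case)(resolution=resolution, seed=seed, total_time=total_time, **kw)
    sim.run()
    s = sim.state
    store = s.store
    C = isotropic_stiffness(s.material)

    if case in ("U", "W"):  # vertical midline cut
        i0 = resolution // 2
        path = [i0 * (resolution + 1) + j for j in range(resolution + 1)]
        canvas, dups = cut_along_path(s.canvas, path)
        layers = store.layers  # elements unchanged by cutting
        from .residual import ResidualStore

        store = ResidualStore(layers.copy())
        cons = ConstraintSet().add_flatness(canvas)
    else:  # release: drop the boundary fixing, keep flatness
        canvas = s.canvas
        cons = ConstraintSet().add_flatness(canvas)

    before = canvas.midplane.copy()
    relaxed, store_after, info = relax_residual(
        canvas, store, C, cons, **(relax_kwargs or {})
    )
    disp = float(np.abs(relaxed.midplane - before).max())
    return {
        "simulation": sim,
        "store_norm_before": store.norm() if case in ("V", "X") else float(
            np.sqrt((store.layers**2).sum())
        ),
        "max_release_displacement": disp,
        "energy_trace": info["energy_trace"],
        "relaxed_canvas": relaxed,
    }


# ---------------------------------------------------------------------------
# diffusion patterning and invagination
# ---------------------------------------------------------------------------


def _case_Z(resolution=10, seed=0, threshold=0.4, total_time=6.0, **cfg):
    canvas = build_disc(1.0, resolution, 0.05)
    n = canvas.n_vertices
    b = FactorField("b", "identity", np.zeros(n))
    b.values[canvas.vertex_sets["rim"]] = 1.0
    s_sig = FactorField("s", "signalling", np.ones(n), D=0.05, decay=1.5, dilutable=True)
    inner = FactorField("inner", "identity", np.zeros(n))
    polarity = PolarityState.blank(canvas.n_elements)
    state = SimState(canvas=canvas, fields={"b": b, "s": s_sig, "inner": inner},
                     polarity=polarity)

    def hook(s):
        s.fields["s"].production = 12.0 * s.fields["b"].values
        s.fields["inner"].values = apply_threshold_rule(
            s.fields["s"].values, threshold, s.fields["inner"].values
        )
        s.set_rates()  # no growth: pure patterning

    cfg.setdefault("dt_init", 0.2)
    return Simulation(state, hook, SimConfig(total_time=total_time, seed=seed, **cfg))


def _case_invagination(resolution=20, seed=0, c_rate=0.6, total_time=0.8, **cfg):
    """Furrow formation by per-surface growth of opposite signs: in a
    polarised band, the outer surface shrinks transversely while the inner
    surface expands, bending the sheet inward."""
    canvas, cons = _sheet_3d(resolution, seed, bow=0.02)
    mp = canvas.midplane
    n = canvas.n_vertices
    ventral = FactorField("ventral", "identity",
                          (np.abs(mp[:, 1] - 0.5) < 0.18).astype(float))
    polarity = PolarityState.blank(canvas.n_elements)
    polarity.mode[:] = int(PolarityMode.EXTERNAL)
    polarity.external_direction = np.array([1.0, 0.0, 0.0])
    polarity = update_polarity(canvas, polarity)
    state = SimState(canvas=canvas, fields={"ventral": ventral}, polarity=polarity,
                     constraints=cons)

    def hook(s):
        v = s.fields["ventral"].values
        zero = np.zeros(s.canvas.n_vertices)
        # pure bending moment: the outer (upper, B) surface shrinks
        # transversely while the inner surface expands by the same amount,
        # folding the band inward
        s.set_rates(kpar=zero, kper=c_rate * v, kper_b=-c_rate * v)

    return Simulation(state, hook, SimConfig(total_time=total_time, seed=seed, **cfg))


# ---------------------------------------------------------------------------
# registry
# ---------------------------------------------------------------------------

PRESETS = {
    "A": _case_A, "B": _case_B, "C": _case_C, "D": _case_D, "E": _case_E,
    "F": _case_F, "G": _case_G, "H": _case_H, "I": _case_I,
    "J": _case_J, "K": _case_K, "L": _case_L, "M": _case_M,
    "N": _case_N, "O": _case_O, "P": _case_P, "Q": _case_Q,
    "R": _case_R, "S": _case_S, "T": _case_T,
    "U": _case_U, "V": _case_V, "W": _case_W, "X": _case_X, "Y": _case_Y,
    "Z": _case_Z,
    "invagination": _case_invagination,
}


def get_preset(name: str):
    key = name if name in PRESETS else name.upper()
    if key not in PRESETS:
        raise ParameterError(
            f"unknown preset {name!r}; available: {', '.join(sorted(PRESETS))}"
        )
    return PRESETS[key]


def run_case(name: str, overrides: dict | None = None, until_area: float | None = None):
    """Build and run a named case; returns the snapshot list."""
    sim = get_preset(name)(**(overrides or {}))
    return sim.run(until_area=until_area)
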