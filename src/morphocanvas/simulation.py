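"""The simulation loop.

Each step runs, in a fixed canonical order: (1) the interaction function
(the model's regulatory networks), (2) diffusion of signalling factors,
(3) assembly of the specified growth tensor from rates and polarity,
(4) the elastic equilibrium solve and vertex update, (5) dilution and
identity inheritance, (6) residual-strain retention or discard, (7) time
advance, (8) optional snapshot.  A remeshing check runs alongside the
post-solve bookkeeping.  The time step is capped so specified growth per
step stays below a maximum (default 10%) and resultant rotations below a
cap (default 10 degrees, enforced by halving and repeating).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .canvas import Canvas, CloneSet, clone_shape_stats
from .diffusion import apply_dilution, step_signalling_field
from .elasticity import (
    ConstraintSet,
    ElasticMaterial,
    assemble_elastic_system,
    decompose_growth,
    isotropic_stiffness,
    solve_displacements,
)
from .errors import ParameterError
from .factors import (
    FactorField,
    PolarityState,
    compute_pol_gradient,
    run_interaction,
    update_polarity,
)
from .growth import GrowthSpec, assemble_specified_growth
from .remesh import split_long_edges
from .residual import ResidualStore, accumulate_residual, convect_residual

__all__ = [
    "SimConfig",
    "SimState",
    "Snapshot",
    "Simulation",
    "choose_timestep",
    "summarize",
]


@dataclass
class SimConfig:
    total_time: float = 1.0
    dt_init: float = 0.05
    max_step_growth: float = 0.10
    max_step_rotation_deg: float = 10.0
    solver: str = "direct"
    solver_tol: float = 1e-6
    diffusion_tol: float = 1e-4
    remesh: bool = True
    remesh_lower: float = 1.5  # x initial mean edge length
    remesh_upper: float = 2.0
    snapshot_every: float | None = None  # simulated-time cadence
    snapshot_areas: tuple = ()  # areal multiples to snapshot at
    seed: int = 0
    isotropic_fallback: str = "mean"

    def __post_init__(self):
        if not (0.0 < self.max_step_growth < 1.0):
            raise ParameterError("max_step_growth must lie in (0, 1)")
        if self.total_time <= 0 or self.dt_init <= 0:
            raise ParameterError("times must be positive")


@dataclass
class SimState:
    """Mutable state threaded through the loop and handed to hooks."""

    canvas: Canvas
    fields: dict
    polarity: PolarityState
    material: ElasticMaterial = ElasticMaterial()
    constraints: ConstraintSet | None = None
    clones: CloneSet | None = None
    store: ResidualStore | None = None
    retention: np.ndarray | float = 0.0
    rates: dict = dc_field(default_factory=dict)
    time: float = 0.0
    initial_area: float = 0.0
    step_index: int = 0

    def __post_init__(self):
        n = self.canvas.n_vertices
        defaults = {k: np.zeros(n) for k in ("kpar_a", "kpar_b", "kper_a", "kper_b", "kthick")}
        defaults.update(self.rates)
        self.rates = defaults
        if self.store is None:
            self.store = ResidualStore.zeros(self.canvas.n_elements)
        if self.initial_area == 0.0:
            self.initial_area = self.canvas.total_area()

    @property
    def area_multiple(self) -> float:
        return self.canvas.total_area() / self.initial_area

    def set_rates(self, kpar=0.0, kper=0.0, kthick=0.0, kpar_b=None, kper_b=None):
        """Convenience for hooks: per-vertex (or scalar) rate assignment;
        B-surface rates default to the A-surface values."""
        n = self.canvas.n_vertices

        def vec(v):
            v = np.asarray(v, dtype=float)
            return np.full(n, float(v)) if v.ndim == 0 else v.copy()

        self.rates["kpar_a"] = vec(kpar)
        self.rates["kpar_b"] = vec(kpar if kpar_b is None else kpar_b)
        self.rates["kper_a"] = vec(kper)
        self.rates["kper_b"] = vec(kper if kper_b is None else kper_b)
        self.rates["kthick"] = vec(kthick)


@dataclass
class Snapshot:
    time: float
    canvas: Canvas
    field_values: dict
    area_multiple: float
    element_count: int
    residual_norm: float
    max_resultant_anisotropy: float
    clone_stats: list | None


def choose_timestep(config: SimConfig, max_rate: float, dt_current: float | None = None) -> float:
    """dt = min(dt_init, max_step_growth / max |k|); with all rates zero
    the configured initial step is used."""
    dt = config.dt_init if dt_current is None else dt_current
    if max_rate > 0.0:
        dt = min(dt, config.max_step_growth / max_rate)
    return dt


def _positions_hash(canvas: Canvas) -> str:
    h = hashlib.sha256()
    h.update(np.round(canvas.pos_a, 12).tobytes())
    h.update(np.round(canvas.pos_b, 12).tobytes())
    return h.hexdigest()[:16]


class Simulation:
    """Driver binding a canvas, factor fields, polarity, an interaction
    hook and a configuration into a runnable model."""

    def __init__(
        self,
        state: SimState,
        hook=None,
        config: SimConfig | None = None,
    ):
        self.state = state
        self.hook = hook
        self.config = config or SimConfig()
        mp = state.canvas.midplane
        e = state.canvas.edges()
        self._mean_edge0 = float(
            np.mean(np.linalg.norm(mp[e[:, 0]] - mp[e[:, 1]], axis=1))
        )
        self.snapshots: list[Snapshot] = []
        self._pending_areas = sorted(self.config.snapshot_areas)
        self._last_snapshot_time = -np.inf
        self._last_result = None
        self.log: list[dict] = []

    # -- snapshotting --------------------------------------------------

    def _take_snapshot(self):
        s = self.state
        res = self._last_result
        if res is not None:
            ev = np.linalg.eigvalsh(res.strain)
            aniso = float(np.max(ev[:, 2] - ev[:, 0]))
        else:
            aniso = 0.0
        self.snapshots.append(
            Snapshot(
                time=s.time,
                canvas=s.canvas.copy(),
                field_values={k: f.values.copy() for k, f in s.fields.items()},
                area_multiple=s.area_multiple,
                element_count=s.canvas.n_elements,
                residual_norm=s.store.norm(),
                max_resultant_anisotropy=aniso,
                clone_stats=(
                    clone_shape_stats(s.canvas, s.clones) if s.clones is not None else None
                ),
            )
        )
        self._last_snapshot_time = s.time

    # -- the loop ------------------------------------------------------

    def _diffuse(self, dt: float):
        for f in self.state.fields.values():
            if f.kind == "signalling" and (f.D > 0 or f.decay > 0 or np.any(f.production)):
                f.values = step_signalling_field(
                    self.state.canvas, f, dt, tol=self.config.diffusion_tol
                )

    def _mechanics(self, dt: float):
        s = self.state
        spec = GrowthSpec.from_vertex_fields(
            s.canvas,
            s.rates["kpar_a"], s.rates["kpar_b"],
            s.rates["kper_a"], s.rates["kper_b"],
            s.rates["kthick"],
            isotropic_fallback=self.config.isotropic_fallback,
        )
        spec_layers = assemble_specified_growth(s.canvas, spec, s.polarity, dt)
        system = assemble_elastic_system(
            s.canvas, isotropic_stiffness(s.material), spec_layers, s.constraints
        )
        u = solve_displacements(system, tol=self.config.solver_tol, method=self.config.solver)
        result = decompose_growth(s.canvas, u)
        return spec_layers, u, result

    def step(self):
        """Advance the model by one (possibly internally halved) step."""
        s = self.state
        cfg = self.config

        run_interaction(self.hook, s)  # (1)

        max_rate = max(abs(np.asarray(v)).max(initial=0.0) for v in s.rates.values())
        dt = choose_timestep(cfg, max_rate)

        rot_cap = np.radians(cfg.max_step_rotation_deg)
        for _attempt in range(8):
            saved_fields = {k: f.values.copy() for k, f in s.fields.items()}
            self._diffuse(dt)  # (2)
            spec_layers, u, result = self._mechanics(dt)  # (3)+(4) solve
            if result.rotation_angles().max(initial=0.0) <= rot_cap:
                break
            for k, f in s.fields.items():  # roll back and repeat with dt/2
                f.values = saved_fields[k]
            dt *= 0.5
        N = s.canvas.n_vertices
        vol_old = s.canvas.vertex_volumes()
        s.canvas.pos_a = s.canvas.pos_a + u[:N]  # (4) vertex update
        s.canvas.pos_b = s.canvas.pos_b + u[N:]

        # (5) dilution on the pre-remesh connectivity (exact bookkeeping);
        # identity regions inherit automatically by riding on the vertices
        apply_dilution(s.fields, vol_old, s.canvas.vertex_volumes())

        # (6) residual strain: retain the configured fraction per element
        step_residual = spec_layers - result.strain_layers
        retention = s.retention
        if np.ndim(retention) == 1 and len(np.asarray(retention)) == N:
            retention = np.asarray(retention)[s.canvas.triangles].mean(axis=1)
        convect_residual(s.store, result.rotation_vectors())
        accumulate_residual(s.store, step_residual, retention)

        # polarity follows the deformed geometry
        pol_field = s.fields.get("POL")
        grads = compute_pol_gradient(s.canvas, pol_field) if pol_field is not None else None
        s.polarity = update_polarity(s.canvas, s.polarity, grads, result.def_grad)

        # remeshing check
        if cfg.remesh:
            new_canvas, parents, n_split = split_long_edges(
                s.canvas,
                cfg.remesh_lower * self._mean_edge0,
                cfg.remesh_upper * self._mean_edge0,
                fields=s.fields,
                clones=s.clones,
            )
            if n_split:
                s.canvas = new_canvas
                s.polarity = PolarityState(
                    s.polarity.axis[parents],
                    s.polarity.mode[parents],
                    s.polarity.gradient_threshold,
                    s.polarity.shallow_policy,
                    s.polarity.external_direction,
                )
                s.store = ResidualStore(s.store.layers[parents])
                n_new = s.canvas.n_vertices
                for key, v in s.rates.items():
                    if len(v) < n_new:
                        s.rates[key] = np.concatenate([v, np.zeros(n_new - len(v))])
                if np.ndim(s.retention) == 1:
                    s.retention = np.concatenate(
                        [s.retention, np.zeros(n_new - len(s.retention))]
                    )
                self.log.append({"step": s.step_index, "remesh_split": n_split})

        s.time += dt  # (7)
        s.step_index += 1
        self._last_result = result

        # (8) snapshots by time cadence or crossed areal multiples
        if cfg.snapshot_every is not None and (
            s.time - self._last_snapshot_time >= cfg.snapshot_every - 1e-12
        ):
            self._take_snapshot()
        while self._pending_areas and s.area_multiple >= self._pending_areas[0]:
            self._pending_areas.pop(0)
            self._take_snapshot()
        return dt

    def run(self, total_time: float | None = None, until_area: float | None = None):
        """Run to the configured horizon (or an areal multiple) and return
        the snapshot list (always including initial and final states)."""
        horizon = total_time if total_time is not None else self.config.total_time
        self._take_snapshot()
        guard = 0
        while self.state.time < horizon - 1e-12:
            if until_area is not None and self.state.area_multiple >= until_area:
                break
            self.step()
            guard += 1
            if guard > 100000:
                raise RuntimeError("step guard tripped")
        self._take_snapshot()
        return self.snapshots

    def manifest(self) -> dict:
        return {
            "time": self.state.time,
            "steps": self.state.step_index,
            "elements": self.state.canvas.n_elements,
            "area_multiple": self.state.area_multiple,
            "config": {k: str(v) for k, v in vars(self.config).items()},
            "positions_hash": _positions_hash(self.state.canvas),
        }


def summarize(snapshots) -> pd.DataFrame:
    """One row per snapshot: time, areal multiple, shape statistics."""
    rows = []
    for s in snapshots:
        clone_ratio = np.nan
        if s.clone_stats:
            finite = [c["anisotropy_ratio"] for c in s.clone_stats if not c["degenerate"]]
            if finite:
                clone_ratio = float(np.mean(finite))
        rows.append(
            {
                "time": s.time,
                "area_multiple": s.area_multiple,
                "max_resultant_anisotropy": s.max_resultant_anisotropy,
                "mean_clone_anisotropy": clone_ratio,
                "residual_norm": s.residual_norm,
                "element_count": s.element_count,
            }
        )
    return pd.DataFrame(rows)
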