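"""Model definition from a YAML/JSON config file.

A model file declares the canvas, the factor fields (with initial values
as expressions over coordinates and region labels, and optional clamps),
the polarity mode, and the growth-rate expressions that stand in for the
regulatory networks.  Expressions are numpy expressions over ``x, y, z``
(midplane coordinates), previously declared factor names, and the helper
functions ``pro``/``inh``.
"""

from __future__ import annotations

import json

import numpy as np
import yaml

from .canvas import build_cylinder, build_disc, build_flat_sheet
from .diffusion import steady_state
from .elasticity import ConstraintSet
from .errors import ParameterError
from .factors import FactorField, PolarityState, inh, pro
from .presets import _polarity_from_pol  # shared construction
from .simulation import SimConfig, SimState, Simulation

__all__ = ["load_model"]

_BUILDERS = {
    "flat_sheet": build_flat_sheet,
    "disc": build_disc,
    "cylinder": build_cylinder,
}


def _namespace(canvas, fields):
    mp = canvas.midplane
    ns = {
        "x": mp[:, 0], "y": mp[:, 1], "z": mp[:, 2],
        "pro": pro, "inh": inh, "np": np,
        "ones": np.ones(canvas.n_vertices), "zeros": np.zeros(canvas.n_vertices),
    }
    for name, f in fields.items():
        ns[name] = f.values
    return ns


def _eval(expr, canvas, fields):
    if isinstance(expr, (int, float)):
        return np.full(canvas.n_vertices, float(expr))
    out = eval(str(expr), {"__builtins__": {}}, _namespace(canvas, fields))  # noqa: S307
    return np.broadcast_to(np.asarray(out, dtype=float), (canvas.n_vertices,)).copy()


def _region(canvas, label):
    if label not in canvas.vertex_sets:
        raise ParameterError(f"unknown region label {label!r}")
    return canvas.vertex_sets[label]


def load_model(path) -> Simulation:
    """Build a runnable :class:`Simulation` from a model file."""
    text = open(path).read()
    spec = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)

    cdef = dict(spec["canvas"])
    kind = cdef.pop("type")
    if kind not in _BUILDERS:
        raise ParameterError(f"unknown canvas type {kind!r}")
    canvas = _BUILDERS[kind](**cdef)

    fields: dict[str, FactorField] = {}
    for fdef in spec.get("factors", []):
        f = FactorField(
            fdef["name"], fdef.get("kind", "identity"),
            _eval(fdef.get("init", 0.0), canvas, fields),
            D=float(fdef.get("D", 0.0)),
            decay=float(fdef.get("decay", 0.0)),
            dilutable=bool(fdef.get("dilutable", False)),
        )
        for clamp in fdef.get("clamp", []):
            verts = _region(canvas, clamp["region"])
            f.values[verts] = float(clamp["value"])
            f.fixed_nodes = np.unique(np.concatenate([f.fixed_nodes, verts]))
        if fdef.get("equilibrate"):
            f.values = steady_state(canvas, f)
        fields[f.name] = f

    pdef = spec.get("polarity")
    if pdef:
        mode = pdef.get("mode", "live")
        if mode == "external":
            polarity = _polarity_from_pol(canvas, None, "external",
                                          external=pdef["direction"])
        else:
            polarity = _polarity_from_pol(canvas, fields[pdef.get("from", "POL")], mode)
    else:
        polarity = PolarityState.blank(canvas.n_elements)

    cons = None
    cdef2 = spec.get("constraints", {})
    if cdef2:
        cons = ConstraintSet()
        if cdef2.get("flatness"):
            cons.add_flatness(canvas)
        for fix in cdef2.get("fix", []):
            cons.fix_vertices(canvas, _region(canvas, fix["region"]),
                              axes=fix.get("axes", (0, 1, 2)))

    gdef = spec.get("growth", {})

    def hook(s):
        kw = {}
        for key, cfg_key in (("kpar", "kpar"), ("kper", "kper"), ("kthick", "kthick"),
                             ("kpar_b", "kpar_b"), ("kper_b", "kper_b")):
            if cfg_key in gdef:
                kw[key] = _eval(gdef[cfg_key], s.canvas, s.fields)
        s.set_rates(**kw)

    state = SimState(canvas=canvas, fields=fields, polarity=polarity, constraints=cons,
                     retention=float(spec.get("retention", 0.0)))
    config = SimConfig(**spec.get("config", {}))
    return Simulation(state, hook if gdef else None, config)
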