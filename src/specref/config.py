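"""Declarative JSON model configuration.

A single config file describes parameters (with priors and algebraic
constraints), structures built from components, per-dataset models, and
fit/sample settings, so a whole co-refinement is reproducible from two
artifacts: the data files and the config.

Scalar fields accept three forms:

* a number — a fixed (non-varying) parameter;
* a string — a reference to a named entry in the ``parameters`` table
  (this is how parameters are shared across components and contrasts);
* an object ``{"value": v, "vary": true, "bounds": [lo, hi]}`` — an inline
  parameter; ``"bounds"`` may also be
  ``{"dist": "norm", "args": [mu, sd]}`` for a scipy.stats prior.

Constraint strings are algebraic expressions over parameter names, e.g.
``"T - t1 - t2"``; they are evaluated with the same lazy expression
machinery used by the Python API.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from . import parameters as _pm
from .parameters import Interval, PDF, Parameter, Parameters
from .reflectivity import Resolution
from .structure import (
    SLD,
    LipidLeaflet,
    MixedReflectModel,
    ReflectModel,
    Slab,
    Spline,
    Structure,
)

__all__ = ["load_config", "build_session", "parameters_to_config", "structure_to_config"]

_EXPR_FUNCS = {
    name: getattr(_pm, name) for name in ("sqrt", "exp", "log", "log10", "sin", "cos", "tan")
}


class ConfigError(ValueError):
    """Malformed configuration; the message names the offending key."""


def load_config(path):
    try:
        return json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise ConfigError(f"config is not valid JSON: {e}") from e


def _make_bounds(spec):
    if spec is None:
        return Interval()
    if isinstance(spec, (list, tuple)):
        return Interval(*spec)
    if isinstance(spec, dict):
        import scipy.stats as st

        name = spec.get("dist")
        if not hasattr(st, name or ""):
            raise ConfigError(f"unknown prior distribution {name!r}")
        return PDF(getattr(st, name)(*spec.get("args", [])))
    raise ConfigError(f"cannot interpret bounds {spec!r}")


class ParameterRegistry:
    """Named-parameter table with deferred constraint wiring."""

    def __init__(self, table=None):
        self.named = {}
        table = table or {}
        for name, spec in table.items():
            if not isinstance(spec, dict):
                spec = {"value": spec}
            p = Parameter(
                spec.get("value", 0.0),
                name=name,
                vary=spec.get("vary", False),
                bounds=_make_bounds(spec.get("bounds")) if "bounds" in spec else None,
            )
            self.named[name] = p
        # constraints second, so forward references resolve
        for name, spec in table.items():
            if isinstance(spec, dict) and spec.get("constraint"):
                self.named[name].constrain(self.parse_expr(spec["constraint"]))

    def parse_expr(self, text):
        ns = dict(_EXPR_FUNCS)
        ns.update(self.named)
        try:
            expr = eval(text, {"__builtins__": {}}, ns)  # noqa: S307 - restricted namespace
        except Exception as e:
            raise ConfigError(f"bad constraint expression {text!r}: {e}") from e
        if isinstance(expr, (int, float)):
            raise ConfigError(f"constraint {text!r} references no parameters")
        return expr

    def resolve(self, spec, context=""):
        """Number / name-reference / inline-object → Parameter."""
        if isinstance(spec, Parameter):
            return spec
        if isinstance(spec, str):
            if spec not in self.named:
                raise ConfigError(f"{context}: unknown parameter reference {spec!r}")
            return self.named[spec]
        if isinstance(spec, (int, float)):
            return Parameter(float(spec), name=context)
        if isinstance(spec, dict):
            p = Parameter(
                spec.get("value", 0.0),
                name=spec.get("name", context),
                vary=spec.get("vary", False),
                bounds=_make_bounds(spec.get("bounds")) if "bounds" in spec else None,
            )
            if spec.get("constraint"):
                p.constrain(self.parse_expr(spec["constraint"]))
            return p
        raise ConfigError(f"{context}: cannot interpret parameter spec {spec!r}")


def _build_component(cfg, reg, ctx):
    kind = cfg.get("kind")
    name = cfg.get("name", kind or "")
    r = lambda key, default=None: (
        reg.resolve(cfg[key], context=f"{ctx}.{key}") if key in cfg else default
    )
    if kind in ("sld", "slab"):  # "sld" = semi-infinite medium, thickness 0
        sld = SLD(0.0, name=name)
        sld.real = reg.resolve(cfg.get("rho", 0.0), context=f"{ctx}.rho")
        sld.imag = reg.resolve(cfg.get("irho", 0.0), context=f"{ctx}.irho")
        return Slab(
            r("thickness", Parameter(0.0)),
            sld,
            r("roughness", Parameter(0.0)),
            vfsolv=r("vfsolv", Parameter(0.0)),
            name=name,
        )
    if kind == "lipid_leaflet":
        required = (
            "apm", "b_heads", "vm_heads", "thickness_heads",
            "b_tails", "vm_tails", "thickness_tails",
        )
        for k in required:
            if k not in cfg:
                raise ConfigError(f"{ctx}: lipid_leaflet missing key {k!r}")
        head_solv = r("head_solvent") if "head_solvent" in cfg else None
        tail_solv = r("tail_solvent") if "tail_solvent" in cfg else None
        return LipidLeaflet(
            r("apm"), r("b_heads"), r("vm_heads"), r("thickness_heads"),
            r("b_tails"), r("vm_tails"), r("thickness_tails"),
            r("rough_head_tail", Parameter(0.0)), r("rough_preceding", Parameter(0.0)),
            head_solvent=None if head_solv is None else SLD(head_solv.value),
            tail_solvent=None if tail_solv is None else SLD(tail_solv.value),
            reverse=bool(cfg.get("reverse", False)),
            name=name,
        )
    if kind == "spline":
        if "knot_distances" not in cfg or "knot_slds" not in cfg:
            raise ConfigError(f"{ctx}: spline needs knot_distances and knot_slds")
        return Spline(
            r("extent", Parameter(float(np.max(cfg["knot_distances"])))),
            cfg["knot_distances"],
            [reg.resolve(v, context=f"{ctx}.knot_slds") for v in cfg["knot_slds"]]
            if any(isinstance(v, str) for v in cfg["knot_slds"])
            else cfg["knot_slds"],
            m=cfg.get("m"),
            name=name,
        )
    raise ConfigError(f"{ctx}: unknown component kind {kind!r}")


def _build_structure(name, cfg, reg):
    comps = cfg.get("components")
    if not comps or len(comps) < 2:
        raise ConfigError(f"structures.{name}: need >= 2 components")
    s = Structure(name=name)
    for i, c in enumerate(comps):
        s.append(_build_component(c, reg, ctx=f"structures.{name}.components[{i}]"))
    if cfg.get("solvent") is not None:
        s.solvent = SLD(reg.resolve(cfg["solvent"], context=f"structures.{name}.solvent").value)
    return s


def _build_resolution(cfg):
    if cfg is None:
        return Resolution("none")
    if isinstance(cfg, (int, float)):
        return Resolution.constant(float(cfg))
    kind = cfg.get("kind", "none")
    if kind == "constant":
        return Resolution.constant(cfg.get("value", 0.05))
    if kind == "pointwise":
        return Resolution.pointwise(cfg.get("value"))
    if kind == "none":
        return Resolution("none")
    raise ConfigError(f"resolution kind {kind!r} not supported in configs")


def build_session(config):
    """Instantiate everything a CLI run needs from a config dict.

    Returns ``(models, registry, config)`` where ``models`` maps model name
    → ReflectModel.
    """
    if "structures" not in config or "models" not in config:
        raise ConfigError("config requires 'structures' and 'models' sections")
    reg = ParameterRegistry(config.get("parameters", {}))
    structures = {
        name: _build_structure(name, cfg, reg)
        for name, cfg in config["structures"].items()
    }
    models = {}
    for name, mcfg in config["models"].items():
        sname = mcfg.get("structure")
        if sname not in structures:
            raise ConfigError(f"models.{name}: unknown structure {sname!r}")
        models[name] = ReflectModel(
            structures[sname],
            scale=reg.resolve(mcfg.get("scale", 1.0), context=f"models.{name}.scale"),
            bkg=reg.resolve(mcfg.get("background", 0.0), context=f"models.{name}.background"),
            resolution=_build_resolution(mcfg.get("resolution")),
            name=name,
        )
    return models, reg, config


# --------------------------------------------------------------------------
# serialization (object → config fragments)
# --------------------------------------------------------------------------
def _param_to_config(p):
    out = {"value": p.value, "vary": bool(p.vary)}
    b = p.bounds
    if isinstance(b, Interval):
        if np.isfinite(b.lower) or np.isfinite(b.upper):
            out["bounds"] = [b.lower, b.upper]
    else:
        out["bounds"] = {"dist": b.dist.dist.name, "args": list(np.atleast_1d(b.dist.args))}
    if p.constraint is not None:
        out["constraint"] = repr(p.constraint)
    return out


def parameters_to_config(pset):
    """Serialize a ParameterSet to the config 'parameters' table form."""
    if isinstance(pset, Parameters):
        ps = pset.flattened()
    else:
        ps = list(pset)
    return {p.name or f"p{i}": _param_to_config(p) for i, p in enumerate(ps)}


def structure_to_config(structure):
    """Serialize a Structure to the config 'structures' entry form."""
    comps = []
    for c in structure.components:
        if isinstance(c, Slab):
            comps.append(
                {
                    "kind": "slab",
                    "name": c.name,
                    "thickness": c.thickness.value,
                    "rho": c.sld.real.value,
                    "irho": c.sld.imag.value,
                    "roughness": c.roughness.value,
                    "vfsolv": c.vfsolv.value,
                }
            )
        elif isinstance(c, LipidLeaflet):
            comps.append(
                {
                    "kind": "lipid_leaflet",
                    "name": c.name,
                    "apm": c.apm.value,
                    "b_heads": c.b_heads.value,
                    "vm_heads": c.vm_heads.value,
                    "thickness_heads": c.thickness_heads.value,
                    "b_tails": c.b_tails.value,
                    "vm_tails": c.vm_tails.value,
                    "thickness_tails": c.thickness_tails.value,
                    "rough_head_tail": c.rough_head_tail.value,
                    "rough_preceding": c.rough_preceding.value,
                    "reverse": c.reverse,
                }
            )
        elif isinstance(c, Spline):
            comps.append(
                {
                    "kind": "spline",
                    "name": c.name,
                    "extent": c.extent.value,
                    "knot_distances": list(map(float, c.knot_distances)),
                    "knot_slds": [p.value for p in c.knot_slds],
                    "m": c.m,
                }
            )
        else:
            raise TypeError(f"cannot serialize component {type(c).__name__}")
    out = {"components": comps}
    if structure.solvent is not None:
        out["solvent"] = structure.solvent.real.value
    return out
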