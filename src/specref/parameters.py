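"""Named model values with priors and algebraic constraints.

A :class:`Parameter` is a scalar with a name, a ``vary`` flag and a prior
probability distribution (its *bounds*).  Parameters can be tied together
algebraically — ``p3.constrain(p1 + p2)`` — and the same Parameter object
may be shared by several components or models, which is how co-refinement
links quantities across datasets: identity, not name, is the linking key.

Priors come in two flavours:

* :class:`Interval` — a uniform box prior whose log-density is 0 inside the
  bounds and −inf outside.  Deliberately unnormalized, so log-posterior
  values are relative quantities.
* :class:`PDF` — wraps any ``scipy.stats`` frozen continuous distribution
  (normal, lognormal, ...) as a properly normalized prior.
"""

from __future__ import annotations

import math
import operator
import warnings
from collections.abc import Iterable

import numpy as np

__all__ = ["Interval", "PDF", "Parameter", "Parameters", "possibly_create_parameter"]


# --------------------------------------------------------------------------
# priors
# --------------------------------------------------------------------------
class Bounds:
    """Base class for prior probability distributions."""

    def logp(self, value):
        raise NotImplementedError

    def rvs(self, size=1, random_state=None):
        raise NotImplementedError

    @property
    def support(self):
        """(lower, upper) of the region where logp is finite."""
        raise NotImplementedError


class Interval(Bounds):
    """Uniform prior on ``[lower, upper]``.

    ``logp`` is 0 inside the interval and −inf outside (unnormalized; any
    additive constant cancels in posterior ratios).
    """

    def __init__(self, lower=-np.inf, upper=np.inf):
        lower, upper = float(lower), float(upper)
        if lower > upper:
            lower, upper = upper, lower
        self.lower = lower
        self.upper = upper

    def logp(self, value):
        if self.lower <= value <= self.upper:
            return 0.0
        return -np.inf

    def rvs(self, size=1, random_state=None):
        rng = np.random.default_rng(random_state)
        lo, hi = self.lower, self.upper
        if not (np.isfinite(lo) and np.isfinite(hi)):
            raise ValueError("cannot sample from an unbounded Interval prior")
        return rng.uniform(lo, hi, size=size)

    @property
    def support(self):
        return (self.lower, self.upper)

    def __repr__(self):
        return f"Interval({self.lower!r}, {self.upper!r})"


class PDF(Bounds):
    """Prior given by a frozen ``scipy.stats`` continuous distribution."""

    def __init__(self, dist):
        if not (hasattr(dist, "logpdf") and hasattr(dist, "rvs")):
            raise TypeError("PDF requires a frozen scipy.stats-like distribution")
        self.dist = dist

    def logp(self, value):
        return float(self.dist.logpdf(value))

    def rvs(self, size=1, random_state=None):
        return np.atleast_1d(self.dist.rvs(size=size, random_state=random_state))

    @property
    def support(self):
        return tuple(self.dist.support())

    def __repr__(self):
        return f"PDF({self.dist!r})"


def _to_bounds(bounds):
    if bounds is None:
        return Interval()
    if isinstance(bounds, Bounds):
        return bounds
    if isinstance(bounds, Iterable):
        lo, hi = bounds
        return Interval(lo, hi)
    return PDF(bounds)


# --------------------------------------------------------------------------
# constraint expressions
# --------------------------------------------------------------------------
_BINOPS = {
    "+": operator.add,
    "-": operator.sub,
    "*": operator.mul,
    "/": operator.truediv,
    "**": operator.pow,
}
_UNARY = {
    "-": operator.neg,
    "abs": abs,
    "sqrt": math.sqrt,
    "exp": math.exp,
    "log": math.log,
    "log10": math.log10,
    "sin": math.sin,
    "cos": math.cos,
    "tan": math.tan,
}


class _ExprMixin:
    """Arithmetic on Parameters/expressions builds lazy constraint trees."""

    def __add__(self, other):
        return Expression("+", self, other)

    def __radd__(self, other):
        return Expression("+", other, self)

    def __sub__(self, other):
        return Expression("-", self, other)

    def __rsub__(self, other):
        return Expression("-", other, self)

    def __mul__(self, other):
        return Expression("*", self, other)

    def __rmul__(self, other):
        return Expression("*", other, self)

    def __truediv__(self, other):
        return Expression("/", self, other)

    def __rtruediv__(self, other):
        return Expression("/", other, self)

    def __pow__(self, other):
        return Expression("**", self, other)

    def __neg__(self):
        return Expression("-", self)

    def __abs__(self):
        return Expression("abs", self)


class Expression(_ExprMixin):
    """Node of a constraint tree over Parameters and constants.

    Evaluation is lazy with memoization; the cache is invalidated whenever
    any Parameter in the tree changes (tracked by per-Parameter version
    counters, so invalidation is O(#dependencies) per read, not global).
    """

    def __init__(self, op, *operands):
        if op in _BINOPS and len(operands) == 2:
            pass
        elif op in _UNARY and len(operands) == 1:
            pass
        else:
            raise ValueError(f"unknown operation {op!r} with {len(operands)} operands")
        self.op = op
        self.operands = operands
        self._cache = None
        self._cache_versions = None

    def dependencies(self):
        """All Parameter objects this expression reads, recursively."""
        out = []
        for o in self.operands:
            if isinstance(o, Parameter):
                out.append(o)
                if o.constraint is not None:
                    out.extend(o.constraint.dependencies())
            elif isinstance(o, Expression):
                out.extend(o.dependencies())
        # dedupe by identity preserving order
        seen, uniq = set(), []
        for p in out:
            if id(p) not in seen:
                seen.add(id(p))
                uniq.append(p)
        return uniq

    def _versions(self):
        return tuple(p._version for p in self.dependencies())

    def value(self):
        vers = self._versions()
        if self._cache is not None and vers == self._cache_versions:
            return self._cache
        vals = [
            o.value if isinstance(o, Parameter) else o.value() if isinstance(o, Expression) else o
            for o in self.operands
        ]
        if self.op in _BINOPS:
            v = _BINOPS[self.op](*vals)
        else:
            v = _UNARY[self.op](*vals)
        self._cache = v
        self._cache_versions = vers
        return v

    def __repr__(self):
        def fmt(o):
            if isinstance(o, Parameter):
                return o.name
            if isinstance(o, Expression):
                return f"({o!r})"
            return repr(o)

        if self.op in _BINOPS:
            a, b = self.operands
            return f"{fmt(a)} {self.op} {fmt(b)}"
        (a,) = self.operands
        if self.op == "-":
            return f"-{fmt(a)}"
        return f"{self.op}({fmt(a)})"


def _unary_factory(name):
    def f(x):
        if isinstance(x, (Parameter, Expression)):
            return Expression(name, x)
        return _UNARY[name](x)

    f.__name__ = name
    return f


sqrt = _unary_factory("sqrt")
exp = _unary_factory("exp")
log = _unary_factory("log")
log10 = _unary_factory("log10")
sin = _unary_factory("sin")
cos = _unary_factory("cos")
tan = _unary_factory("tan")


# --------------------------------------------------------------------------
# Parameter
# --------------------------------------------------------------------------
class Parameter(_ExprMixin):
    """A named scalar model value.

    Parameters
    ----------
    value : float
        Current value (units are context dependent: Å, 10⁻⁶ Å⁻², unitless).
    name : str, optional
        Label used in reports and serialized configs.
    vary : bool
        Whether the parameter is free in a fit.  A constrained parameter
        never varies.
    bounds : Interval, PDF, (lo, hi) tuple or scipy.stats frozen dist
        Prior probability distribution.
    """

    def __init__(self, value=0.0, name=None, vary=False, bounds=None, constraint=None):
        self.name = name if name is not None else ""
        self._value = float(value)
        self._vary = bool(vary)
        self.bounds = _to_bounds(bounds)
        self.constraint = None
        self._version = 0
        if constraint is not None:
            self.constrain(constraint)

    # -- value -----------------------------------------------------------
    @property
    def value(self):
        if self.constraint is not None:
            return float(self.constraint.value())
        return self._value

    @value.setter
    def value(self, v):
        if self.constraint is not None:
            raise ValueError(
                f"parameter {self.name!r} is constrained; remove the constraint "
                "before assigning a value"
            )
        self._value = float(v)
        self._version += 1

    @property
    def vary(self):
        return self._vary and self.constraint is None

    @vary.setter
    def vary(self, v):
        if v and self.constraint is not None:
            raise ValueError(f"constrained parameter {self.name!r} cannot vary")
        self._vary = bool(v)

    # -- constraints -----------------------------------------------------
    def constrain(self, expr):
        """Tie this parameter to an algebraic expression of others.

        Sets ``vary`` to False; the value re-evaluates lazily whenever a
        dependency changes.  Raises ``ValueError`` on a dependency cycle.
        """
        if isinstance(expr, Parameter):
            expr = Expression("+", expr, 0.0)
        if not isinstance(expr, Expression):
            raise TypeError("constraint must be an expression over Parameters")
        deps = expr.dependencies()
        if any(d is self for d in deps):
            cyc = " -> ".join([self.name or "<unnamed>"] + [d.name or "<unnamed>" for d in deps])
            raise ValueError(f"constraint cycle detected: {cyc}")
        self.constraint = expr
        self._vary = False
        self._version += 1
        return self

    def unconstrain(self):
        if self.constraint is not None:
            self._value = float(self.constraint.value())
            self.constraint = None
            self._version += 1
        return self

    def dependencies(self):
        return self.constraint.dependencies() if self.constraint is not None else []

    # -- prior -----------------------------------------------------------
    def logp(self, value=None):
        """Log prior density at ``value`` (default: current value)."""
        v = self.value if value is None else value
        return self.bounds.logp(v)

    def set_bounds(self, bounds):
        self.bounds = _to_bounds(bounds)
        return self

    def rvs(self, size=1, random_state=None):
        return self.bounds.rvs(size=size, random_state=random_state)

    def __repr__(self):
        s = f"<Parameter {self.name!r}, value={self.value:.6g}"
        if self.constraint is not None:
            s += f", constraint={self.constraint!r}"
        elif self.vary:
            s += f", vary, bounds={self.bounds!r}"
        return s + ">"

    def __float__(self):
        return float(self.value)


def possibly_create_parameter(value, name=""):
    """Pass Parameters through; wrap bare numbers as fixed Parameters."""
    if isinstance(value, Parameter):
        return value
    return Parameter(float(value), name=name)


# --------------------------------------------------------------------------
# Parameters (an ordered set, possibly nested, possibly sharing objects)
# --------------------------------------------------------------------------
class Parameters(list):
    """Ordered collection of Parameter objects (nesting allowed).

    Flattening deduplicates by object identity, which is what makes a
    Parameter shared between two components appear exactly once in the
    fit vector and once in the prior sum.
    """

    def __init__(self, items=(), name=None):
        super().__init__(items)
        self.name = name

    def flattened(self):
        out, seen = [], set()

        def walk(items):
            for it in items:
                if isinstance(it, Parameters) or isinstance(it, (list, tuple)):
                    walk(it)
                elif isinstance(it, Parameter):
                    if id(it) not in seen:
                        seen.add(id(it))
                        out.append(it)
                elif it is None:
                    continue
                else:
                    raise TypeError(f"not a Parameter: {it!r}")

        walk(self)
        return out

    def varying_parameters(self):
        return [p for p in self.flattened() if p.vary]

    def names(self):
        return [p.name for p in self.flattened()]

    # -- fit-vector plumbing --------------------------------------------
    def flatten_varying(self):
        """Values of varying, unconstrained parameters in stable order."""
        return np.array([p.value for p in self.varying_parameters()], dtype=float)

    def set_from_vector(self, vec):
        vp = self.varying_parameters()
        vec = np.asarray(vec, dtype=float).ravel()
        if len(vec) != len(vp):
            raise ValueError(f"vector length {len(vec)} != {len(vp)} varying parameters")
        for p, v in zip(vp, vec):
            p.value = v

    def logp(self):
        """Σ log-prior over varying parameters; −inf if any violates its prior."""
        tot = 0.0
        for p in self.varying_parameters():
            lp = p.logp()
            if not np.isfinite(lp):
                return -np.inf
            tot += lp
        return tot

    def warn_duplicate_names(self):
        names = [p.name for p in self.flattened() if p.name]
        dup = {n for n in names if names.count(n) > 1}
        if dup:
            warnings.warn(f"duplicate parameter names: {sorted(dup)}", stacklevel=2)
        return dup

    def __repr__(self):
        inner = ", ".join(repr(p) for p in self.flattened())
        return f"Parameters([{inner}])"
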