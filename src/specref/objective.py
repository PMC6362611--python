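"""Model–data comparison: χ², log-likelihood, log-prior, log-posterior.

The log-likelihood assumes normally distributed measurement uncertainties:

    ln L = −½ Σ_n [ (y_n − y_model,n)² / σ_n² + ln(2π σ_n²) ],

evaluated in the fitting space selected by a :class:`Transform` (R, log₁₀R
or R·Q⁴ versus Q) with first-order-propagated uncertainties.  The
log-posterior is log-prior + log-likelihood, the prior summing over varying
parameters plus any component-level terms; an infinite prior short-circuits
the (possibly expensive) likelihood evaluation.

Several objectives combine into a :class:`GlobalObjective` for
co-refinement: its log-likelihood is the sum over members, while parameters
shared between members (by object identity) are counted once in the prior
and appear once in the fit vector.
"""

from __future__ import annotations

import warnings

import numpy as np

from .data import Transform
from .parameters import Parameters

__all__ = ["Objective", "GlobalObjective"]

_LN2PI = np.log(2.0 * np.pi)


class _BaseObjective:
    """Shared fit-vector plumbing and summary-style reporting."""

    @property
    def parameters(self):
        raise NotImplementedError

    def varying_parameters(self):
        return self.parameters.varying_parameters()

    @property
    def nvary(self):
        return len(self.varying_parameters())

    def setp(self, pvals):
        if pvals is not None:
            self.parameters.set_from_vector(pvals)

    def getp(self):
        return self.parameters.flatten_varying()

    def logpost(self, pvals=None):
        """Log-posterior = log-prior + log-likelihood.

        A −inf prior returns immediately without evaluating the model.
        """
        self.setp(pvals)
        lp = self.logp()
        if not np.isfinite(lp):
            return -np.inf
        return lp + self.logl()

    def nlpost(self, pvals=None):
        return -self.logpost(pvals)

    def fit(self, method="differential_evolution", seed=None, **kws):
        """Least-squares refinement; see :meth:`CurveFitter.fit`."""
        from .fitting import CurveFitter

        return CurveFitter(self).fit(method=method, seed=seed, **kws)

    def sample(self, steps, nwalkers=None, seed=None, ntemps=None, **kws):
        """MCMC sampling; see :meth:`CurveFitter.sample`."""
        from .fitting import CurveFitter

        return CurveFitter(self, nwalkers=nwalkers, ntemps=ntemps).sample(
            steps, seed=seed, **kws
        )


class Objective(_BaseObjective):
    """Comparator of one model with one dataset.

    Parameters
    ----------
    model : ReflectModel or MixedReflectModel (anything with ``model(q,
        x_err)``, ``parameters`` and ``logp()``)
    data : Data1D
    transform : Transform or str, optional
        Fitting space; default is R vs Q.
    name : str
    """

    def __init__(self, model, data, transform=None, name=""):
        self.model = model
        self.data = data
        if not isinstance(transform, Transform):
            transform = Transform(transform)
        self.transform = transform
        self.name = name or getattr(data, "name", "")

    @property
    def parameters(self):
        return Parameters([self.model.parameters], name=self.name)

    def generative(self, pvals=None):
        """Model curve in data space at the data's Q points."""
        self.setp(pvals)
        return self.model.model(self.data.q, x_err=self.data.dq)

    def _transformed(self, pvals=None):
        ym = self.generative(pvals)
        y, dy = self.transform(self.data.q, self.data.r, self.data.dr)
        ym_t, _ = self.transform(self.data.q, ym, None)
        return y, dy, ym_t

    def residuals(self, pvals=None):
        """(y_n − y_model,n)/σ_n in the transformed fitting space."""
        y, dy, ym = self._transformed(pvals)
        return (y - ym) / dy

    def chisqr(self, pvals=None):
        r = self.residuals(pvals)
        return float(np.sum(r * r))

    def logl(self, pvals=None):
        """Gaussian log-likelihood in the transformed space."""
        y, dy, ym = self._transformed(pvals)
        if not np.all(np.isfinite(ym)):
            warnings.warn("non-finite model values; log-likelihood set to -inf", stacklevel=2)
            return -np.inf
        return float(-0.5 * np.sum(((y - ym) / dy) ** 2 + np.log(2.0 * np.pi * dy**2)))

    def logp(self, pvals=None):
        """Log-prior: varying-parameter priors plus component-level terms."""
        self.setp(pvals)
        lp = self.parameters.logp()
        if not np.isfinite(lp):
            return -np.inf
        extra = self.model.logp() if hasattr(self.model, "logp") else 0.0
        if not np.isfinite(extra):
            return -np.inf
        return lp + extra

    def __repr__(self):
        return f"<Objective {self.name!r}, {len(self.data)} points, nvary={self.nvary}>"


class GlobalObjective(_BaseObjective):
    """Co-refinement of several objectives with (optionally) shared
    parameters.  Log-likelihood and χ² are sums over members; shared
    Parameter objects are deduplicated by identity in the prior and in the
    fit vector."""

    def __init__(self, objectives, name="global"):
        self.objectives = list(objectives)
        if not self.objectives:
            raise ValueError("need at least one Objective")
        self.name = name

    @property
    def parameters(self):
        return Parameters([o.parameters for o in self.objectives], name=self.name)

    def residuals(self, pvals=None):
        self.setp(pvals)
        return np.concatenate([o.residuals() for o in self.objectives])

    def chisqr(self, pvals=None):
        self.setp(pvals)
        return float(sum(o.chisqr() for o in self.objectives))

    def logl(self, pvals=None):
        self.setp(pvals)
        return float(sum(o.logl() for o in self.objectives))

    def logp(self, pvals=None):
        self.setp(pvals)
        lp = self.parameters.logp()  # shared parameters counted once
        if not np.isfinite(lp):
            return -np.inf
        for o in self.objectives:
            extra = o.model.logp() if hasattr(o.model, "logp") else 0.0
            if not np.isfinite(extra):
                return -np.inf
            lp += extra
        return lp

    def __repr__(self):
        inner = ", ".join(o.name or "?" for o in self.objectives)
        return f"<GlobalObjective [{inner}], nvary={self.nvary}>"
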