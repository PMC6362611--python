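"""Refinement of an objective: least squares and Bayesian MCMC.

:class:`CurveFitter` drives either route over the same :class:`Objective`
interface.  Least squares uses SciPy (differential evolution,
Levenberg–Marquardt, L-BFGS-B) and reports covariance-based uncertainties
from the Jacobian of the σ-weighted residuals at the optimum.  MCMC uses
affine-invariant ensemble sampling (emcee's stretch move); an in-package
parallel-tempering variant runs coupled ensembles along a geometric
temperature ladder with neighbour swap moves and estimates the
log-evidence by trapezoidal thermodynamic integration of ⟨ln L⟩_β.

Chain post-processing follows the reflectometry convention: after burn-in
and thinning, each parameter is reported as the median of its flattened
marginal, with a standard uncertainty equal to half of the
[15.87, 84.13] percentile range (the 1-σ interval of a normal
distribution).
"""

from __future__ import annotations

import json
import warnings

import numpy as np
from scipy import optimize

from .parameters import Interval

__all__ = ["CurveFitter", "FitResult", "Chain", "PosteriorResult", "process_chain"]

_LS_METHODS = ("differential_evolution", "levenberg_marquardt", "lbfgsb")


def _prior_bounds(par):
    """Finite (lo, hi) box for bounded optimizers, from the parameter prior."""
    b = par.bounds
    lo, hi = b.support
    if isinstance(b, Interval):
        return lo, hi
    # distribution prior: clip to a generous quantile box if unbounded
    if not np.isfinite(lo):
        lo = float(b.dist.ppf(1e-7))
    if not np.isfinite(hi):
        hi = float(b.dist.ppf(1.0 - 1e-7))
    return lo, hi


# --------------------------------------------------------------------------
# results containers
# --------------------------------------------------------------------------
class FitResult:
    """Point estimate from a least-squares refinement.

    Attributes: ``x`` (best values), ``stderr`` (may contain NaN when the
    covariance is singular), ``covar``, ``chisqr``, ``names``, ``success``.
    """

    def __init__(self, names, x, stderr, covar, chisqr, method, success, message, nfev):
        self.names = list(names)
        self.x = np.asarray(x, dtype=float)
        self.stderr = np.asarray(stderr, dtype=float)
        self.covar = covar
        self.chisqr = float(chisqr)
        self.method = method
        self.success = bool(success)
        self.message = message
        self.nfev = int(nfev)

    def summary(self):
        lines = [
            f"Least-squares fit ({self.method})",
            f"chi-square: {self.chisqr:.6g}   success: {self.success}   nfev: {self.nfev}",
            f"{'parameter':<32} {'value':>14} {'stderr':>12}",
            "-" * 60,
        ]
        for n, v, s in zip(self.names, self.x, self.stderr):
            ss = f"{s:.4g}" if np.isfinite(s) else "n/a"
            lines.append(f"{n:<32} {v:>14.6g} {ss:>12}")
        return "\n".join(lines)

    def __repr__(self):
        return f"<FitResult {self.method}, chisqr={self.chisqr:.4g}, nvary={len(self.x)}>"


class Chain:
    """MCMC sample store.

    ``samples`` has shape (n_steps, n_walkers, n_dim) — the β = 1 block
    when parallel tempering was used.  ``logpost`` holds the matching
    log-posterior values.  Tempered runs also carry the temperature ladder
    ``betas``, per-temperature mean log-likelihoods and the
    thermodynamic-integration ``logz`` estimate.
    """

    def __init__(
        self,
        samples,
        logpost,
        names,
        acceptance_fraction=None,
        betas=None,
        mean_logl_by_beta=None,
        logz=None,
    ):
        self.samples = np.asarray(samples, dtype=float)
        if self.samples.ndim != 3:
            raise ValueError("samples must be (n_steps, n_walkers, n_dim)")
        self.logpost = np.asarray(logpost, dtype=float)
        self.names = list(names)
        if self.samples.shape[2] != len(self.names):
            raise ValueError("n_dim does not match number of parameter names")
        self.acceptance_fraction = acceptance_fraction
        self.betas = betas
        self.mean_logl_by_beta = mean_logl_by_beta
        self.logz = logz

    @property
    def shape(self):
        return self.samples.shape

    def process(self, nburn=0, nthin=1, objective=None):
        return process_chain(self, nburn=nburn, nthin=nthin, objective=objective)

    # -- plain-text persistence -----------------------------------------
    def save(self, path):
        """Persist as text: a JSON header line then the flattened array."""
        meta = {
            "names": self.names,
            "shape": list(self.samples.shape),
            "betas": None if self.betas is None else list(map(float, self.betas)),
            "logz": None if self.logz is None else float(self.logz),
        }
        flat = self.samples.reshape(-1, self.samples.shape[2])
        lp = self.logpost.reshape(-1, 1)
        np.savetxt(path, np.hstack([lp, flat]), header=json.dumps(meta), fmt="%.12e")
        return path

    @classmethod
    def load(cls, path):
        with open(path) as fh:
            header = fh.readline().lstrip("# ").strip()
        meta = json.loads(header)
        arr = np.loadtxt(path)
        steps, walkers, ndim = meta["shape"]
        lp = arr[:, 0].reshape(steps, walkers)
        samples = arr[:, 1:].reshape(steps, walkers, ndim)
        return cls(samples, lp, meta["names"], betas=meta.get("betas"), logz=meta.get("logz"))

    def __repr__(self):
        s = f"<Chain shape={self.samples.shape}"
        if self.logz is not None:
            s += f", logz={self.logz:.4g}"
        return s + ">"


class PosteriorResult:
    """Per-parameter posterior summary plus the flattened samples.

    ``median`` and ``stderr`` follow the [15.87, 84.13] percentile rule;
    ``flat`` is the (n_samples, n_dim) post-burn, thinned, walker-flattened
    sample array used for corner plots and curve/SLD-spread exports.
    """

    def __init__(self, names, flat, flat_logpost=None, logz=None):
        self.names = list(names)
        self.flat = np.asarray(flat, dtype=float)
        if self.flat.ndim != 2 or self.flat.shape[0] == 0:
            raise ValueError("no samples remain after burn/thin")
        self.flat_logpost = flat_logpost
        self.logz = logz
        lo, med, hi = np.percentile(self.flat, [15.87, 50.0, 84.13], axis=0)
        self.median = med
        self.stderr = 0.5 * (hi - lo)
        self.percentiles = (lo, hi)

    def sample_rows(self, k=500, seed=None):
        """k random posterior draws (rows of ``flat``) for spread plots."""
        rng = np.random.default_rng(seed)
        k = min(int(k), self.flat.shape[0])
        idx = rng.choice(self.flat.shape[0], size=k, replace=False)
        return self.flat[idx]

    def summary(self):
        lines = [
            f"Posterior summary ({self.flat.shape[0]} samples)",
            f"{'parameter':<32} {'median':>14} {'stderr':>12}",
            "-" * 60,
        ]
        for n, m, s in zip(self.names, self.median, self.stderr):
            lines.append(f"{n:<32} {m:>14.6g} {s:>12.4g}")
        if self.logz is not None:
            lines.append(f"log-evidence (thermodynamic integration): {self.logz:.6g}")
        return "\n".join(lines)

    def __repr__(self):
        return f"<PosteriorResult {self.flat.shape[0]} samples, ndim={self.flat.shape[1]}>"


def process_chain(chain, nburn=0, nthin=1, objective=None):
    """Burn, thin and flatten a chain; summarize and update parameters.

    Discards the first ``nburn`` steps, keeps every ``nthin``-th of the
    rest, flattens walkers, and reports the median and the half
    [15.87, 84.13] percentile range per parameter.  When ``objective`` is
    given its varying parameters are set to the medians.
    """
    if nthin < 1:
        raise ValueError("nthin must be >= 1")
    nsteps = chain.samples.shape[0]
    if nburn >= nsteps:
        raise ValueError(f"nburn={nburn} leaves no steps of {nsteps}")
    kept = chain.samples[nburn::nthin]
    kept_lp = chain.logpost[nburn::nthin]
    flat = kept.reshape(-1, kept.shape[2])
    flat_lp = kept_lp.reshape(-1)
    res = PosteriorResult(chain.names, flat, flat_logpost=flat_lp, logz=chain.logz)
    if objective is not None:
        objective.setp(res.median)
    return res


# --------------------------------------------------------------------------
# the fitter
# --------------------------------------------------------------------------
class CurveFitter:
    """Least-squares and MCMC refinement of an Objective.

    Parameters
    ----------
    objective : Objective or GlobalObjective
    nwalkers : int, optional
        Ensemble size; default ``max(2·n_dim, 100)``.
    ntemps : int, optional
        Number of parallel-tempering temperatures; None → plain ensemble.
    """

    def __init__(self, objective, nwalkers=None, ntemps=None):
        self.objective = objective
        ndim = objective.nvary
        if nwalkers is None:
            nwalkers = max(2 * ndim, 100)
        self.nwalkers = int(nwalkers)
        self.ntemps = ntemps

    # -- least squares ---------------------------------------------------
    def fit(self, method="differential_evolution", seed=None, **kws):
        obj = self.objective
        vp = obj.varying_parameters()
        if len(vp) == 0:
            raise ValueError("no varying parameters to fit")
        x0 = obj.getp()
        if not np.all(np.isfinite(x0)):
            raise ValueError("non-finite starting parameter values")
        if method not in _LS_METHODS:
            raise ValueError(f"method must be one of {_LS_METHODS}")

        if method == "levenberg_marquardt":
            if any(np.isfinite(_prior_bounds(p)).any() for p in vp):
                warnings.warn(
                    "Levenberg–Marquardt ignores parameter bounds", stacklevel=2
                )
            sol = optimize.least_squares(lambda x: obj.residuals(x), x0, method="lm", **kws)
            xbest, success, message, nfev = sol.x, sol.success, sol.message, sol.nfev
        else:
            bounds = [_prior_bounds(p) for p in vp]
            if not all(np.isfinite(b).all() for b in bounds):
                raise ValueError(f"{method} requires finite prior bounds on all varying parameters")
            def nl(x):
                # hard prior vetoes (e.g. lipid packing) can sit inside the
                # box bounds; a large finite penalty keeps line searches alive
                v = obj.nlpost(x)
                return v if np.isfinite(v) else 1e15

            if not np.isfinite(obj.nlpost(x0)) and method == "lbfgsb":
                raise ValueError("objective is not finite at the starting point")
            if method == "differential_evolution":
                sol = optimize.differential_evolution(nl, bounds, seed=seed, **kws)
            else:
                # finite-difference step scaled to each parameter's magnitude;
                # the absolute default is far below the objective's resolution
                # for parameters of order 10-100
                opts = kws.pop("options", {})
                opts.setdefault("eps", np.maximum(1e-6 * np.abs(x0), 1e-7))
                sol = optimize.minimize(
                    nl, x0, method="L-BFGS-B", bounds=bounds, options=opts, **kws
                )
            xbest, success, message, nfev = sol.x, sol.success, sol.message, sol.nfev

        obj.setp(xbest)
        covar, stderr = self._covar(xbest)
        result = FitResult(
            [p.name for p in vp], xbest, stderr, covar, obj.chisqr(), method, success,
            message, nfev,
        )
        return result

    def _covar(self, x):
        """Gauss–Newton covariance from a finite-difference Jacobian of the
        σ-weighted residuals (residuals are already normalized, so
        cov = (JᵀJ)⁻¹)."""
        obj = self.objective
        try:
            r0 = obj.residuals(x)
            n, m = r0.size, x.size
            jac = np.empty((n, m))
            for j in range(m):
                h = 1e-6 * max(abs(x[j]), 1e-3)
                xp = x.copy()
                xp[j] += h
                jac[:, j] = (obj.residuals(xp) - r0) / h
            obj.setp(x)
            covar = np.linalg.inv(jac.T @ jac)
            stderr = np.sqrt(np.diag(covar))
        except np.linalg.LinAlgError:
            covar = None
            stderr = np.full(x.size, np.nan)
        return covar, stderr

    # -- walker initialization ------------------------------------------
    def _init_walkers(self, nwalkers, rng):
        obj = self.objective
        vp = obj.varying_parameters()
        ndim = len(vp)
        x0 = obj.getp()
        pos = np.empty((nwalkers, ndim))
        for i in range(nwalkers):
            # try prior draws first, fall back to jitter around current values
            for _ in range(50):
                try:
                    cand = np.array(
                        [float(p.rvs(1, random_state=rng)[0]) for p in vp]
                    )
                except ValueError:
                    cand = x0 * (1 + 1e-4 * rng.standard_normal(ndim)) + 1e-8 * rng.standard_normal(ndim)
                if np.isfinite(obj.logpost(cand)):
                    pos[i] = cand
                    break
            else:
                cand = x0 * (1 + 1e-4 * rng.standard_normal(ndim)) + 1e-8 * rng.standard_normal(ndim)
                if not np.isfinite(obj.logpost(cand)):
                    raise ValueError(
                        "could not initialize walkers at finite log-posterior; "
                        "review priors and starting values"
                    )
                pos[i] = cand
        obj.setp(x0)
        return pos

    # -- MCMC ------------------------------------------------------------
    def sample(self, steps, seed=None, init_pos=None, thin_by=1, progress=False):
        """Sample the posterior.

        Parameters
        ----------
        steps : number of saved steps (each walker advances
            ``steps·thin_by`` times; only every ``thin_by``-th is stored).
        seed : int, for reproducible chains.
        init_pos : (n_walkers, n_dim) array, optional — e.g. the last step
            of a previous chain to resume sampling.
        """
        if self.ntemps is not None and self.ntemps > 1:
            return self._sample_pt(steps, seed=seed, init_pos=init_pos, thin_by=thin_by)

        import emcee

        obj = self.objective
        ndim = obj.nvary
        if ndim == 0:
            raise ValueError("no varying parameters to sample")
        nwalkers = self.nwalkers
        if nwalkers < 2 * ndim:
            raise ValueError(f"need nwalkers >= 2*ndim ({2 * ndim}), got {nwalkers}")
        rng = np.random.default_rng(seed)
        pos = self._init_walkers(nwalkers, rng) if init_pos is None else np.asarray(init_pos)

        sampler = emcee.EnsembleSampler(nwalkers, ndim, obj.logpost)
        sampler.random_state = np.random.RandomState(
            rng.integers(0, 2**31 - 1)
        ).get_state()
        sampler.run_mcmc(pos, steps, thin_by=thin_by, progress=progress)
        names = [p.name for p in obj.varying_parameters()]
        chain = Chain(
            sampler.get_chain(),
            sampler.get_log_prob(),
            names,
            acceptance_fraction=sampler.acceptance_fraction,
        )
        return chain

    def _sample_pt(self, steps, seed=None, init_pos=None, thin_by=1):
        """Parallel-tempering ensemble sampling.

        Coupled stretch-move ensembles at inverse temperatures β along a
        geometric ladder (β_i = 2⁻ⁱ), tempering the likelihood only:
        target_i(θ) ∝ prior(θ)·L(θ)^β_i.  After each sweep, neighbouring
        temperatures propose walker swaps accepted with probability
        min(1, exp[(β_cold − β_hot)(lnL_hot − lnL_cold)]).  The log-evidence
        ln Z = ∫₀¹ ⟨ln L⟩_β dβ is estimated by the trapezoid rule over the
        ladder, extended to β = 0 with the hottest ensemble's mean.
        """
        obj = self.objective
        ndim = obj.nvary
        if ndim == 0:
            raise ValueError("no varying parameters to sample")
        nwalkers = self.nwalkers
        if nwalkers < 2 * ndim or nwalkers % 2:
            raise ValueError("nwalkers must be even and >= 2*ndim")
        ntemps = int(self.ntemps)
        betas = 2.0 ** (-np.arange(ntemps))
        rng = np.random.default_rng(seed)

        def logp(x):
            return obj.logp(x)

        def logl(x):
            lp = obj.logp(x)
            if not np.isfinite(lp):
                return -np.inf
            return obj.logl()

        # positions / cached log terms per temperature
        if init_pos is None:
            pos = np.stack([self._init_walkers(nwalkers, rng) for _ in range(ntemps)])
        else:
            init_pos = np.asarray(init_pos)
            pos = (
                init_pos.copy()
                if init_pos.ndim == 3
                else np.stack([init_pos.copy() for _ in range(ntemps)])
            )
        lps = np.empty((ntemps, nwalkers))
        lls = np.empty((ntemps, nwalkers))
        for t in range(ntemps):
            for w in range(nwalkers):
                lps[t, w] = logp(pos[t, w])
                lls[t, w] = logl(pos[t, w])

        a = 2.0  # stretch-move scale
        half = nwalkers // 2
        nacc = np.zeros(ntemps)
        nprop = 0
        out = np.empty((steps, nwalkers, ndim))
        out_lp = np.empty((steps, nwalkers))
        logl_accum = np.zeros(ntemps)
        n_accum = 0

        total_iters = steps * thin_by
        for it in range(total_iters):
            for t in range(ntemps):
                beta = betas[t]
                for first, second in (
                    (np.arange(half), np.arange(half, nwalkers)),
                    (np.arange(half, nwalkers), np.arange(half)),
                ):
                    z = ((a - 1.0) * rng.random(len(first)) + 1) ** 2 / a
                    partners = second[rng.integers(0, len(second), size=len(first))]
                    prop = pos[t, partners] + z[:, None] * (pos[t, first] - pos[t, partners])
                    for idx, w in enumerate(first):
                        lp_new = logp(prop[idx])
                        if np.isfinite(lp_new):
                            ll_new = logl(prop[idx])
                            cur = lps[t, w] + beta * lls[t, w]
                            new = lp_new + beta * ll_new
                            lnq = (ndim - 1) * np.log(z[idx]) + new - cur
                            if np.log(rng.random()) < lnq:
                                pos[t, w] = prop[idx]
                                lps[t, w] = lp_new
                                lls[t, w] = ll_new
                                nacc[t] += 1
                nprop += nwalkers
            # neighbour swaps, hottest to coldest
            for t in range(ntemps - 1, 0, -1):
                cold, hot = t - 1, t
                perm = rng.permutation(nwalkers)
                for w in range(nwalkers):
                    wh = perm[w]
                    lnalpha = (betas[cold] - betas[hot]) * (lls[hot, wh] - lls[cold, w])
                    if np.log(rng.random()) < lnalpha:
                        pos[cold, w], pos[hot, wh] = pos[hot, wh].copy(), pos[cold, w].copy()
                        lps[cold, w], lps[hot, wh] = lps[hot, wh], lps[cold, w]
                        lls[cold, w], lls[hot, wh] = lls[hot, wh], lls[cold, w]
            logl_accum += lls.mean(axis=1)
            n_accum += 1
            if (it + 1) % thin_by == 0:
                k = (it + 1) // thin_by - 1
                out[k] = pos[0]
                out_lp[k] = lps[0] + lls[0]

        mean_logl = logl_accum / n_accum
        # trapezoid over ascending beta, extended to beta=0 with the hottest mean
        bs = np.concatenate([[0.0], betas[::-1]])
        ls = np.concatenate([[mean_logl[-1]], mean_logl[::-1]])
        logz = float(np.trapezoid(ls, bs))
        names = [p.name for p in obj.varying_parameters()]
        return Chain(
            out,
            out_lp,
            names,
            acceptance_fraction=nacc / max(nprop, 1),
            betas=betas,
            mean_logl_by_beta=mean_logl,
            logz=logz,
        )
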