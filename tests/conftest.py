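"""Shared fixtures and independent oracles.

The oracles here deliberately re-derive the physics by different routes
than the package (Parratt recursive ratios instead of characteristic
matrices; adaptive quadrature instead of fixed-order Gauss–Legendre;
brute-force micro-slicing instead of the Névot–Croce factor) so that
agreement is evidence of correctness rather than of shared code.
"""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.special import ndtr

from specref.parameters import Parameter, Parameters
from specref.objective import _BaseObjective
from specref.reflectivity import FWHM_TO_SIGMA


# --------------------------------------------------------------------------
# oracles
# --------------------------------------------------------------------------
def parratt_reflectivity(q, slabs):
    """Parratt recursive-ratio reflectivity with Névot–Croce roughness.

    Independent of the Abeles matrix implementation; same physical
    conventions (k relative to fronting, decaying branch).
    """
    slabs = np.asarray(slabs, float)
    qv = np.atleast_1d(np.asarray(q, float))
    sre = (slabs[:, 1] - slabs[0, 1]) * 1e-6
    sim = slabs[:, 2] * 1e-6
    k = np.sqrt((qv[:, None] / 2) ** 2 - 4 * np.pi * (sre - 1j * sim)[None, :] + 0j)
    n = slabs.shape[0]
    r = np.zeros(qv.size, complex)
    for j in range(n - 2, -1, -1):
        rj = (k[:, j] - k[:, j + 1]) / (k[:, j] + k[:, j + 1] + 1e-30)
        rj = rj * np.exp(-2 * k[:, j] * k[:, j + 1] * slabs[j + 1, 3] ** 2)
        if j == n - 2:
            r = rj
        else:
            phase = np.exp(2j * k[:, j + 1] * slabs[j + 1, 0])
            r = (rj + r * phase) / (1 + rj * r * phase)
    return np.abs(r) ** 2


def random_stack(rng, max_layers=8, sigma_max=6.0, absorption=True):
    """A random physical slab stack [thickness, sld_re, sld_im, rough]."""
    n = int(rng.integers(0, max_layers + 1))
    s = np.zeros((n + 2, 4))
    s[:, 1] = rng.uniform(-2, 8, n + 2)
    if absorption:
        s[:, 2] = rng.uniform(0, 0.1, n + 2)
        s[0, 2] = 0.0
    s[1:-1, 0] = rng.uniform(5, 300, n)
    s[1:, 3] = rng.uniform(0, sigma_max, n + 1)
    return s


def microsliced_erf_reflectivity(q, rho0, rho1, sigma, dz=0.1, span=6.0):
    """Exact (dynamical) reflectivity of an error-function interface,
    via fine zero-roughness slicing of the continuous profile."""
    from specref.reflectivity import abeles

    n = int(np.ceil(2 * span * sigma / dz))
    zs = np.linspace(-span * sigma, span * sigma, n + 1)
    mids = 0.5 * (zs[:-1] + zs[1:])
    s = np.zeros((n + 2, 4))
    s[0, 1] = rho0
    s[-1, 1] = rho1
    s[1:-1, 0] = zs[1] - zs[0]
    s[1:-1, 1] = rho0 + (rho1 - rho0) * ndtr(mids / sigma)
    return abeles(q, s)


def quadrature_smear(r_of_scalar_q, q, fwhm, nsigma=3.5):
    """Adaptive-quadrature Gaussian convolution (truncated at ±nsigma·σ,
    renormalized), one point at a time."""
    s = fwhm * FWHM_TO_SIGMA
    norm = quad(lambda x: np.exp(-0.5 * (x / s) ** 2), -nsigma * s, nsigma * s)[0]
    val = quad(
        lambda x: r_of_scalar_q(q + x) * np.exp(-0.5 * (x / s) ** 2),
        -nsigma * s,
        nsigma * s,
        limit=400,
        epsabs=0,
        epsrel=1e-10,
    )[0]
    return val / norm


# --------------------------------------------------------------------------
# toy analytic posterior for sampler validation
# --------------------------------------------------------------------------
class GaussianPosterior(_BaseObjective):
    """An objective whose likelihood is an analytic multivariate normal."""

    def __init__(self, mean, cov, half_width=10.0):
        mean = np.asarray(mean, float)
        self.mean = mean
        self.cov = np.asarray(cov, float)
        self.icov = np.linalg.inv(self.cov)
        self._params = Parameters(
            [
                Parameter(
                    m, name=f"x{i}", vary=True,
                    bounds=(m - half_width, m + half_width),
                )
                for i, m in enumerate(mean)
            ]
        )

    @property
    def parameters(self):
        return self._params

    def logp(self, pvals=None):
        self.setp(pvals)
        return self._params.logp()

    def logl(self, pvals=None):
        self.setp(pvals)
        d = self.getp() - self.mean
        return float(-0.5 * d @ self.icov @ d)


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture(scope="session")
def single_slab():
    """A fringed single-slab stack used across kernel tests."""
    return np.array([[0, 0, 0, 0], [100.0, 4.0, 0, 2.0], [0, 6.36, 0, 3.0]])
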