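"""Specular reflectivity of a stratified medium and resolution smearing.

The kernel uses the Abeles (characteristic 2×2 matrix) method for a stack
of uniform slabs.  For each momentum transfer Q the normal component of the
wavevector in medium j is

    k_j = sqrt((Q/2)² − 4π(ρ_j − ρ_fronting)),

with a complex square root (absorption enters ρ_j as a positive imaginary
part).  The Fresnel coefficient at each interface is attenuated by the
Névot–Croce factor exp(−2 k_j k_{j+1} σ²) to model Gaussian interfacial
roughness, and the reflectivity is |M₁₀/M₀₀|² of the matrix product over
slabs.

Instrument resolution is applied by Gaussian convolution in Q.  dQ values
are interpreted as the FWHM of the resolution function; the convolution is
evaluated by fixed-order Gauss–Legendre quadrature over ±3.5 standard
deviations of the (renormalized, truncated) Gaussian.
"""

from __future__ import annotations

import numpy as np

__all__ = ["q_from_angle", "abeles", "smear", "Resolution", "FWHM_TO_SIGMA"]

# FWHM = 2 sqrt(2 ln 2) σ for a Gaussian
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))  # ≈ 1/2.35482
_SMEAR_NSIGMA = 3.5
_QUAD_ORDER = 17
_TINY = 1e-30


def q_from_angle(omega, wavelength):
    """Momentum transfer Q = (4π/λ) sin Ω.

    Parameters
    ----------
    omega : angle of incidence, degrees.
    wavelength : incident wavelength, Å.  Must be > 0.

    Returns
    -------
    Q in Å⁻¹ (scalar or array following the inputs).
    """
    wavelength = np.asarray(wavelength, dtype=float)
    if np.any(wavelength <= 0):
        raise ValueError("wavelength must be positive")
    out = 4.0 * np.pi / wavelength * np.sin(np.radians(np.asarray(omega, dtype=float)))
    return out if out.ndim else float(out)


def _validate_slabs(slabs):
    slabs = np.atleast_2d(np.asarray(slabs, dtype=float))
    if slabs.shape[1] < 4:
        raise ValueError("slab array needs columns [thickness, sld_re, sld_im, roughness]")
    if not np.all(np.isfinite(slabs)):
        raise ValueError("non-finite slab entries")
    if slabs.shape[0] < 2:
        raise ValueError("need at least fronting and backing media")
    if np.any(slabs[1:-1, 0] < 0):
        raise ValueError("negative slab thickness")
    if np.any(slabs[1:, 3] < 0):
        raise ValueError("negative roughness")
    if np.any(slabs[:, 2] < 0):
        raise ValueError("negative imaginary SLD (absorption must be >= 0)")
    return slabs


def abeles(q, slabs, scale=1.0, bkg=0.0):
    """Abeles-matrix specular reflectivity of a slab stack.

    Parameters
    ----------
    q : array_like
        Momentum transfer values, Å⁻¹ (>= 0; Q = 0 handled as the limiting
        total-reflection value).
    slabs : (N+2, 4) array
        Rows ``[thickness (Å), SLD_real, SLD_imag, roughness (Å)]`` with SLD
        quoted in 10⁻⁶ Å⁻².  Row 0 is the semi-infinite fronting medium
        (thickness ignored), row −1 the backing.  ``roughness`` of row j is
        the Gaussian width of the interface between slab j and slab j−1;
        the fronting row's roughness is ignored.
    scale, bkg : float
        Multiplicative scale and additive (Q-independent) background.

    Returns
    -------
    R : ndarray of reflectivities, in [0, 1] for physical inputs (before
        scale/background).
    """
    slabs = _validate_slabs(slabs)
    q = np.asarray(q, dtype=float)
    scalar = q.ndim == 0
    qv = np.atleast_1d(q).astype(float)
    if np.any(qv < 0):
        raise ValueError("Q must be >= 0")

    nlayers = slabs.shape[0] - 2
    # k_j² = (Q/2)² − 4π(ρ_j − ρ_fronting).  Absorption enters with +i so
    # the principal square root has Re(k) ≥ 0 and Im(k) ≥ 0: transmitted
    # and evanescent waves decay into the stack.
    sld_re = (slabs[:, 1] - slabs[0, 1]) * 1e-6
    sld_im = slabs[:, 2] * 1e-6
    kn = np.sqrt(
        (qv[:, None] / 2.0) ** 2 - 4.0 * np.pi * (sld_re - 1j * sld_im)[None, :] + 0j
    )

    # interfacial Fresnel coefficients with Névot–Croce attenuation
    k = kn[:, :-1]
    k_next = kn[:, 1:]
    rj = (k - k_next) / (k + k_next + _TINY)
    rj *= np.exp(-2.0 * k * k_next * slabs[1:, 3] ** 2)

    mrtot00 = np.ones_like(qv, dtype=complex)
    mrtot01 = rj[:, 0].copy()
    mrtot10 = rj[:, 0].copy()
    mrtot11 = np.ones_like(qv, dtype=complex)
    for j in range(1, nlayers + 1):
        # phase factor of slab j; the e^{+2ikd} (Parratt) branch decays for
        # evanescent/absorbing layers
        beta = np.exp(-1j * kn[:, j] * slabs[j, 0])
        m00 = beta
        m11 = 1.0 / beta
        m01 = rj[:, j] * m00
        m10 = rj[:, j] * m11
        p00 = mrtot00 * m00 + mrtot01 * m10
        p01 = mrtot00 * m01 + mrtot01 * m11
        p10 = mrtot10 * m00 + mrtot11 * m10
        p11 = mrtot10 * m01 + mrtot11 * m11
        mrtot00, mrtot01, mrtot10, mrtot11 = p00, p01, p10, p11

    r = mrtot10 / mrtot00
    refl = np.abs(r) ** 2

    # Q = 0 exactly: total external reflection if the media differ, else 0
    zero = qv == 0.0
    if np.any(zero):
        refl[zero] = 1.0 if not np.isclose(slabs[-1, 1], slabs[0, 1]) else 0.0

    refl = scale * refl + bkg
    return float(refl[0]) if scalar else refl


# --------------------------------------------------------------------------
# resolution smearing
# --------------------------------------------------------------------------
class Resolution:
    """Instrument Q-resolution specification.

    kind
        ``'none'`` — no smearing;
        ``'constant'`` — constant dQ/Q, ``value`` is the fractional FWHM
        (e.g. 0.05 for 5%);
        ``'pointwise'`` — per-point dQ FWHM array, usually the 4th data
        column;
        ``'kernel'`` — arbitrary per-point discrete probability kernel,
        ``offsets`` (n_points, m) Å⁻¹ and ``weights`` (n_points, m)
        summing to 1 per point.
    """

    def __init__(self, kind="none", value=None, offsets=None, weights=None):
        if kind not in ("none", "constant", "pointwise", "kernel"):
            raise ValueError(f"unknown resolution kind {kind!r}")
        self.kind = kind
        self.value = value
        self.offsets = None
        self.weights = None
        if kind == "constant":
            if value is None or value < 0:
                raise ValueError("constant resolution needs a fractional FWHM >= 0")
            self.value = float(value)
        elif kind == "pointwise":
            if value is not None:
                v = np.asarray(value, dtype=float)
                if np.any(v < 0):
                    raise ValueError("pointwise dQ must be >= 0")
                self.value = v
        elif kind == "kernel":
            offsets = np.atleast_2d(np.asarray(offsets, dtype=float))
            weights = np.atleast_2d(np.asarray(weights, dtype=float))
            if offsets.shape != weights.shape:
                raise ValueError("kernel offsets/weights shape mismatch")
            if np.any(weights < 0):
                raise ValueError("kernel weights must be >= 0")
            if np.any(np.abs(weights.sum(axis=1) - 1.0) > 1e-9):
                raise ValueError("kernel weights must sum to 1 (within 1e-9)")
            self.offsets = offsets
            self.weights = weights

    @classmethod
    def constant(cls, dq_over_q):
        return cls("constant", value=dq_over_q)

    @classmethod
    def pointwise(cls, dq=None):
        return cls("pointwise", value=dq)

    @classmethod
    def kernel(cls, offsets, weights):
        return cls("kernel", offsets=offsets, weights=weights)

    def __repr__(self):
        if self.kind == "constant":
            return f"Resolution.constant({self.value})"
        return f"Resolution({self.kind!r})"


def _gauss_legendre_smear(r_of_q, q, fwhm):
    """Gaussian convolution at each q, FWHM given per point.

    Fixed 17-point Gauss–Legendre over ±3.5σ of the truncated, renormalized
    Gaussian.  Zero-FWHM points fall back to the unsmeared value.
    """
    q = np.asarray(q, dtype=float)
    fwhm = np.broadcast_to(np.asarray(fwhm, dtype=float), q.shape)
    sigma = fwhm * FWHM_TO_SIGMA

    x, w = np.polynomial.legendre.leggauss(_QUAD_ORDER)
    # nodes mapped to [-3.5σ, 3.5σ]; weights times Gaussian pdf, renormalized
    offsets = _SMEAR_NSIGMA * x  # in units of σ
    gauss = np.exp(-0.5 * offsets**2)
    wts = w * gauss
    wts = wts / wts.sum()

    qs = q[:, None] + sigma[:, None] * offsets[None, :]
    qs = np.clip(qs, 0.0, None)  # reflectivity undefined for Q<0; clamp
    rs = r_of_q(qs.ravel()).reshape(qs.shape)
    out = rs @ wts
    if np.any(sigma == 0):
        out = np.where(sigma == 0, r_of_q(q), out)
    return out


def smear(r_of_q, q, resolution):
    """Apply instrument resolution to a reflectivity function.

    Parameters
    ----------
    r_of_q : callable
        Vectorized unsmeared reflectivity, R(Q).
    q : array_like
        Nominal Q values at which the smeared curve is reported.
    resolution : Resolution

    Returns
    -------
    Smeared reflectivity at each ``q``.
    """
    q = np.asarray(q, dtype=float)
    if resolution is None or resolution.kind == "none":
        return r_of_q(q)
    if resolution.kind == "constant":
        if resolution.value == 0:
            return r_of_q(q)
        return _gauss_legendre_smear(r_of_q, q, resolution.value * q)
    if resolution.kind == "pointwise":
        dq = resolution.value
        if dq is None:
            raise ValueError("pointwise resolution requires per-point dQ values")
        dq = np.broadcast_to(np.asarray(dq, dtype=float), q.shape)
        return _gauss_legendre_smear(r_of_q, q, dq)
    # discrete kernel
    offsets, weights = resolution.offsets, resolution.weights
    if offsets.shape[0] not in (1, q.size):
        raise ValueError("kernel rows must match number of Q points (or be 1)")
    offs = np.broadcast_to(offsets, (q.size, offsets.shape[1]))
    wts = np.broadcast_to(weights, (q.size, weights.shape[1]))
    qs = np.clip(q[:, None] + offs, 0.0, None)
    rs = r_of_q(qs.ravel()).reshape(qs.shape)
    return np.sum(rs * wts, axis=1)
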