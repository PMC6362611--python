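# Methods

## Reflectivity model

The interface is modelled as a stack of uniform slabs between two
semi-infinite media (fronting first, backing last).  For momentum transfer
Q, the normal wavevector in medium *j* is

    k_j = sqrt( (Q/2)² − 4π(ρ_j − ρ_fronting) ),

with ρ the complex SLD (Å⁻²; the user API quotes SLDs in 10⁻⁶ Å⁻² and the
kernel converts once).  Absorption enters the dispersion as
ρ = ρ′ − iρ″ (ρ″ ≥ 0) so the principal square root automatically yields
Re k ≥ 0, Im k ≥ 0 — both transmitted and evanescent waves decay into the
stack.  This branch choice matters: taking the opposite sign lets lossy or
sub-critical layers amplify and produces R > 1.

Reflectivity is the |M₁₀/M₀₀|² of the 2×2 characteristic-matrix product
over slabs (Abeles method), with the Fresnel coefficient at each interface
attenuated by the Névot–Croce factor exp(−2 k_j k_{j+1} σ²_{j+1}), σ the
Gaussian roughness between slab j+1 and its predecessor.  The factor is
applied at every interface, including to/from the semi-infinite media.
At Q = 0 exactly the kernel returns 1 when backing ≠ fronting SLD
(total external reflection) and 0 otherwise, avoiding a 0/0.

**Validity of Névot–Croce.**  Against an exactly micro-sliced
error-function interface (0.1 Å slices, ±6σ), the factor is accurate to
better than 1e-4 for Qσ ≲ 2.5.  It degrades at large Qσ: by Qσ ≈ 4.5
(σ = 15 Å at Q = 0.3 Å⁻¹) the relative deviation reaches 0.3–3%
depending on contrast — at reflectivities of order 1e-15, far below
anything measurable, but a genuine limit of the approximation.  Roughness
values should also stay below the adjoining layer thicknesses, as in any
slab model.

A continuous SLD profile for plotting and posterior-spread export joins
slab SLDs with error-function steps Φ((z − z_i)/σ_i), the real-space
profile consistent with the Névot–Croce treatment.

## Resolution smearing

dQ is interpreted throughout as the FWHM of a Gaussian resolution
function (σ_Q = dQ/2.35482).  Constant-dQ/Q and per-point smearing
evaluate the convolution by 17-point Gauss–Legendre quadrature over
±3.5 σ_Q of the truncated, renormalized Gaussian; this matches adaptive
quadrature of the same integral to ~1e-11 on smooth curves, and
convergence to the unsmeared curve as FWHM → 0 is monotone.  Near a
non-smooth feature (the critical edge) fixed-order quadrature is accurate
to ~1e-4 rather than 1e-6; the quadrature order is a speed/accuracy
compromise, not a physical statement.  Arbitrary discrete kernels
(offsets + weights per point) are supported for non-Gaussian resolution.

## Parameters, priors, constraints

A `Parameter` owns a value, a vary flag and a prior: either an
unnormalized uniform `Interval` (logp = 0 inside, −inf outside; evidence
values are therefore relative) or any frozen `scipy.stats` distribution.
Arithmetic on parameters builds lazy expression trees; `p.constrain(expr)`
ties a parameter to others (it stops varying, re-evaluates on dependency
change via version counters, and cycles are rejected at construction).
Object identity — not name — links parameters across components, models
and datasets; duplicate names only warn.  The log-prior sums over varying
parameters only; fixed parameters contribute no prior term.

Component-level physics enters the prior through `Component.logp()`:
a `LipidLeaflet` whose head or tail volume exceeds the available space
(V_x > A·t_x) contributes −inf, vetoing the configuration rather than
silently clipping it.

## Likelihood and fitting

The likelihood assumes normally distributed measurement uncertainties;
χ², residuals and ln L are all evaluated in the chosen fitting space
(R, log₁₀R, or RQ⁴ with first-order-propagated uncertainties) so they
remain mutually consistent.  The log-posterior is log-prior +
log-likelihood; an infinite prior short-circuits the model evaluation.

Least squares: differential evolution and L-BFGS-B minimize the negative
log-posterior inside prior boxes (distribution priors are boxed at their
1e-7 quantiles); Levenberg–Marquardt minimizes the weighted residuals
directly and ignores bounds (with a warning).  For the smooth optimizers,
prior vetoes inside the box are replaced by a large finite penalty (1e15)
so line searches survive, and finite-difference steps are scaled to each
parameter's magnitude.  Quasi-Newton refinement should start within a few
percent of the optimum (reflectivity landscapes are multimodal);
differential evolution is the global starter.  Reported uncertainties are
Gauss–Newton: sqrt diag (JᵀJ)⁻¹ from a finite-difference Jacobian of the
σ-weighted residuals.

## MCMC

Single-temperature sampling uses emcee's affine-invariant stretch move.
Walkers default to max(2·n_dim, 100) and are initialized from prior draws
(falling back to 1e-4 multiplicative jitter around current values when
draws land outside the likelihood's support); an all-infinite start
raises with instructions to review priors.  Chains are seeded and
reproducible.

Parallel tempering is implemented in-package: one stretch-move ensemble
per inverse temperature β on a geometric ladder (β_i = 2⁻ⁱ), tempering
the likelihood only (target_i ∝ prior·L^β), with neighbour swap moves
accepted at min(1, exp[(β_cold − β_hot)(lnL_hot − lnL_cold)]) after each
sweep.  The log-evidence is estimated by trapezoidal thermodynamic
integration of ⟨ln L⟩_β over the ladder, extended to β = 0 with the
hottest ensemble's mean — adequate for model comparison at modest
n_temps, not a precision evidence method.

Post-processing discards a burn-in, keeps every *thin*-th step, flattens
walkers, and reports per-parameter median and half the [15.87, 84.13]
percentile range (linear-interpolation percentiles), the 1σ interval of a
normal distribution.  Parameter values are updated to the medians, and k
random posterior rows (default 500) are exportable for curve- and
SLD-spread plots.  Burn-in and thinning are user choices; the defaults in
the CLI (no burn, no thinning) are deliberately neutral.

## Synthetic data generator

The generator emulates a time-of-flight solid–liquid reflectometry
measurement: 120 log-spaced Q points in [0.008, 0.3] Å⁻¹, constant
dQ/Q = 5% (FWHM), Gaussian noise with a 2% relative-error floor
(dR = 0.02·max(R, background)) and a 1e-7 constant background; an
optional Poisson-count mode (counts = R·flux, flux ∝ Q⁻²) is available.
Reported dR always equals the σ used to draw the noise, so the reduced χ²
at the generating truth is ≈ 1 by construction.

The three-contrast bilayer suite builds Si / SiO₂(15 Å, 10% solvated) /
inner leaflet / reversed outer leaflet / solvent structures at solvent
SLDs 6.36 (D₂O), 2.07 (silicon-contrast-matched water) and −0.56 (H₂O)
×10⁻⁶ Å⁻², sharing a single area-per-molecule parameter and one set of
DMPC-like lipid constants (b_h = 6.01e-4 Å, V_h = 319 Å³, t_h = 9 Å,
b_t = −2.92e-4 Å, V_t = 782 Å³, t_t = 14 Å — representative fixture
values, not measured ground truth) across all six leaflets.  The default
generating area per molecule is 57.0 Å².

What the generator does *not* emulate: instrument backgrounds with Q
structure, footprint/gravity corrections, wavelength-dependent
resolution shapes, counting-time heterogeneity between contrasts, or
imperfect contrast exchange.  Passing recovery tests therefore
demonstrates the correctness of the inference chain under the stated
noise model, not robustness to every systematic present in measured data.

## Problem sizes in the test and acceptance runs

Kernel cross-checks use 200 random stacks of up to 8 layers on 100–120
point Q grids.  Sampler validation uses a 2-D analytic Gaussian posterior
(50 walkers × 1200 steps ≈ 50k post-burn samples).  The co-refinement
exercises use the full 3 × 120-point suite with 4 varying parameters,
16 walkers and 250 saved steps (100 burn-in, thin 2); interval-coverage
checks repeat a reduced version (60-point grids, one varying parameter)
over 20 seeds.  These sizes were chosen so the entire chain remains
comfortable on a single CPU while keeping Monte-Carlo errors small
relative to the tolerances being asserted.

## Design notes and limitations

- The spline component uses monotone (PCHIP) interpolation through its
  knots to avoid unphysical overshoot, discretized into equal slices
  (default 0.5 Å, capped at 500); slice staircasing biases reflectivity
  by ΔR/R ≈ Q²dz²/12, so fine slicing matters at high Q.
- Slab solvation resolves against the backing medium by default (the
  solid–liquid geometry); both the structure solvent and per-leaflet
  head/tail solvents are overrideable for air–liquid work.
- The JSON config covers slab/leaflet/spline structures and single
  `ReflectModel`s per dataset; mixed-area models are available in the
  Python API only.
- No polarized/magnetic reflectivity, no off-specular scattering, no
  energy-dispersive (Ω, λ) datasets.
- Multi-core likelihood parallelism is not built in; the likelihood is a
  pure function of the parameter vector, so an external map can shard
  walker evaluations if needed.
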