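# specref

Modelling and Bayesian co-refinement of specular neutron and X-ray
reflectometry data.

Specular reflectometry measures the reflectivity *R(Q)* of a layered
interface as a function of momentum transfer *Q* = (4π/λ)sin Ω, and is the
workhorse technique for resolving thin-film structure (10–5000 Å) normal to
a surface: supported lipid bilayers, polymer brushes, oxide layers.
Because the measurement loses phase information, a single curve rarely
determines a structure; the standard remedy is **contrast variation** —
re-measuring the same interface under solvents of different scattering
length density (SLD) — followed by **co-refinement** of all curves against
one chemically-parameterized model.

`specref` provides that entire chain:

- **Kernel** — reflectivity of a stratified medium by the Abeles
  characteristic-matrix method, with interfacial Gaussian roughness via the
  Névot–Croce factor exp(−2 k_j k_{j+1} σ²) and instrument resolution
  smearing (constant dQ/Q, per-point dQ as Gaussian FWHM, or an arbitrary
  discrete kernel).
- **Structure layer** — composable `Component` objects (`Slab`, `Spline`,
  `LipidLeaflet`) assembled into a `Structure`; `ReflectModel` adds scale
  and constant background, `MixedReflectModel` forms incoherent
  area-weighted sums for laterally patchy samples.  The `LipidLeaflet`
  parameterizes a leaflet by area per molecule *A*, region thicknesses
  t_h, t_t, scattering-length sums b_h, b_t and partial volumes V_h, V_t,
  giving region SLDs ρ_x = b_x/(A·t_x) + (1 − V_x/(A·t_x))·ρ_solv with a
  hard physicality veto when V_x > A·t_x.
- **Inference** — `Parameter` objects carry priors (uniform intervals or
  any `scipy.stats` distribution) and algebraic constraints; an
  `Objective` compares model and data through the Gaussian log-likelihood

      ln L = −½ Σ_n [ (y_n − y_model,n)²/σ_n² + ln(2π σ_n²) ],

  optionally in log₁₀R or RQ⁴ fitting space; a `GlobalObjective` sums
  members for co-refinement with parameters shared by object identity.
  `CurveFitter` drives least squares (differential evolution,
  Levenberg–Marquardt, L-BFGS-B) and affine-invariant ensemble MCMC
  (emcee), with an in-package parallel-tempering sampler that also
  estimates the log-evidence by thermodynamic integration.  Posterior
  summaries follow the reflectometry convention: median and half of the
  [15.87, 84.13] percentile range.
- **Synthetic data** — seeded generators for single curves and for a
  three-contrast supported-bilayer suite (D₂O / silicon-contrast-matched
  water / H₂O) with truth sidecars, so every fit in the test suite checks
  recovery of known ground truth.

## Worked example

Co-refine three synthetic contrasts of a DMPC-like bilayer on silicon,
sharing one area-per-molecule parameter:

```python
import numpy as np
from specref import (make_bilayer_suite, Objective, GlobalObjective, CurveFitter)

datasets, models, truth = make_bilayer_suite(apm=57.0, seed=7)
objective = GlobalObjective(
    [Objective(models[k], datasets[k]) for k in datasets]
)

apm = models["d2o"].structure[2].apm      # shared across all six leaflets
apm.vary = True
apm.set_bounds((54, 62))

objective.fit(method="lbfgsb")            # point estimate
chain = CurveFitter(objective, nwalkers=16).sample(250, seed=7)
print(chain.process(nburn=100, nthin=2, objective=objective).summary())
```

Output:

```
Posterior summary (1200 samples)
parameter                                median       stderr
------------------------------------------------------------
area per molecule                       57.0071      0.03619
```

The posterior median recovers the generating area per molecule
(57.0 Å²) to within 0.01 Å², with a standard uncertainty of ~0.04 Å² —
each lipid occupies ≈ 57 Å² of interface, jointly constrained by all
three solvent contrasts.

The same analysis runs from the shell against data files via the
`specref` command (`simulate`, `fit`, `sample`, `summarize`), driven by a
JSON config that records parameters, priors, links and datasets; every run
writes a provenance record (versions, seed, config hash).

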