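"""Synthetic reflectivity datasets from known structures.

These generators exist so that fits, recovery tests and demonstrations run
from first principles, with the generating truth recorded alongside each
dataset.  The default measurement emulation is typical of a time-of-flight
neutron reflectometer operated on a solid–liquid cell: 120 log-spaced Q
points in [0.008, 0.3] Å⁻¹, constant dQ/Q = 5% (FWHM), a relative-error
floor on dR and a small constant background.

:func:`make_bilayer_suite` builds the canonical co-refinement exercise: a
supported phospholipid bilayer on silicon measured at three solvent
contrasts (D₂O, an Si contrast-matched H₂O/D₂O mix, and H₂O), with the
area per molecule and all lipid chemistry shared across contrasts so that
only the solvent SLD differs — the configuration that makes area per
molecule a well-determined quantity.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .data import Data1D
from .parameters import Parameter
from .structure import SLD, LipidLeaflet, ReflectModel, Structure
from .reflectivity import Resolution

__all__ = ["NoiseModel", "generate_dataset", "make_bilayer_suite", "DMPC", "CONTRASTS"]

# fixture constants for a DMPC-like lipid (b in Å, V in Å³, t in Å);
# representative literature-style values shipped for synthetic-data work,
# not asserted ground truth for any real sample
DMPC = {
    "b_heads": 6.01e-4,
    "vm_heads": 319.0,
    "thickness_heads": 9.0,
    "b_tails": -2.92e-4,
    "vm_tails": 782.0,
    "thickness_tails": 14.0,
}

# solvent SLDs, 1e-6 Å⁻²: D₂O, Si contrast-match (HDmix), H₂O
CONTRASTS = {"d2o": 6.36, "hdmix": 2.07, "h2o": -0.56}

DEFAULT_QGRID = dict(qmin=0.008, qmax=0.3, npoints=120)
DEFAULT_DQ_OVER_Q = 0.05


def default_q_grid(qmin=None, qmax=None, npoints=None):
    g = dict(DEFAULT_QGRID)
    if qmin is not None:
        g["qmin"] = qmin
    if qmax is not None:
        g["qmax"] = qmax
    if npoints is not None:
        g["npoints"] = npoints
    return np.logspace(np.log10(g["qmin"]), np.log10(g["qmax"]), g["npoints"])


class NoiseModel:
    """Measurement-uncertainty emulation for synthetic curves.

    Parameters
    ----------
    rel_error : float
        Relative 1-σ error floor: dR = rel_error·R (plus the background
        term).  Must be > 0 for Gaussian noise to be well defined.
    background : float
        Constant incoherent background added to the true curve (and to the
        uncertainty floor, emulating subtracted-background statistics).
    poisson_flux : float or None
        When set, switch to count statistics: counts = R·flux(Q) with
        flux(Q) = poisson_flux·Q⁻² (beam footprint grows at low Q),
        dR = sqrt(counts)/flux.
    """

    def __init__(self, rel_error=0.02, background=1e-7, poisson_flux=None):
        if rel_error <= 0:
            raise ValueError("rel_error must be > 0")
        if background < 0:
            raise ValueError("background must be >= 0")
        if poisson_flux is not None and poisson_flux <= 0:
            raise ValueError("poisson_flux must be > 0")
        self.rel_error = float(rel_error)
        self.background = float(background)
        self.poisson_flux = poisson_flux

    def sigma(self, q, r_true):
        """1-σ uncertainty reported for (and used to perturb) each point."""
        if self.poisson_flux is None:
            return self.rel_error * np.maximum(r_true, self.background)
        flux = self.poisson_flux * np.clip(q, 1e-4, None) ** -2
        counts = np.clip((r_true + self.background) * flux, 1.0, None)
        return np.sqrt(counts) / flux

    def to_dict(self):
        return {
            "rel_error": self.rel_error,
            "background": self.background,
            "poisson_flux": self.poisson_flux,
        }


def generate_dataset(model, q=None, noise=None, seed=0, path=None, name="", perturb=True):
    """Simulate one measured curve from a model.

    R_true is the smeared model curve; R_obs = R_true + N(0, dR) with dR
    from the noise model (the reported dR equals the σ actually used).
    ``perturb=False`` keeps R_obs = R_true exactly (noise-free data with
    realistic weights).  When ``path`` is given, the 4-column file plus a
    ``.truth.json`` sidecar recording the generator parameters are written.

    Returns the Data1D (noise drawn with the given seed).
    """
    if q is None:
        q = default_q_grid()
    q = np.asarray(q, dtype=float)
    noise = noise or NoiseModel()
    rng = np.random.default_rng(seed)

    if model.resolution.kind == "constant":
        dq = model.resolution.value * q
    elif model.resolution.kind == "pointwise" and model.resolution.value is not None:
        dq = np.broadcast_to(np.asarray(model.resolution.value, float), q.shape)
    else:
        dq = np.zeros_like(q)
    # the model curve is the truth; its bkg parameter carries any background
    r_true = model.model(q, x_err=dq if model.resolution.kind == "pointwise" else None)
    dr = noise.sigma(q, r_true)
    r_obs = r_true + dr * rng.standard_normal(q.shape) if perturb else r_true.copy()
    data = Data1D(q, r_obs, dr, dq=dq, name=name)

    if path is not None:
        path = Path(path)
        data.save(path)
        truth = {
            "name": name,
            "seed": int(seed),
            "noise": noise.to_dict(),
            "parameters": {
                p.name: p.value for p in model.parameters.flattened() if p.name
            },
        }
        path.with_suffix(path.suffix + ".truth.json").write_text(
            json.dumps(truth, indent=2)
        )
    return data


def make_bilayer_structure(
    apm,
    solvent_sld,
    lipid=None,
    sio2_thick=15.0,
    sio2_rough=3.0,
    sio2_vfsolv=0.1,
    bilayer_rough=3.0,
    name="",
):
    """Si / SiO₂ / inner leaflet / outer leaflet / solvent structure.

    ``apm`` may be a shared Parameter so several contrasts co-refine one
    area per molecule.  The inner leaflet points head-first at the oxide;
    the outer leaflet is reversed (tail then head) so the two leaflets form
    a bilayer with tails together.
    """
    lipid = dict(DMPC, **(lipid or {}))
    apm = apm if isinstance(apm, Parameter) else Parameter(float(apm), name="area per molecule")
    si = SLD(2.07, name="Si")
    sio2 = SLD(3.47, name="SiO2")
    solvent = SLD(solvent_sld, name=f"{name} solvent")

    inner = LipidLeaflet(
        apm,
        lipid["b_heads"], lipid["vm_heads"], lipid["thickness_heads"],
        lipid["b_tails"], lipid["vm_tails"], lipid["thickness_tails"],
        rough_head_tail=bilayer_rough, rough_preceding=bilayer_rough,
        name=f"{name} inner leaflet",
    )
    outer = LipidLeaflet(
        apm,
        lipid["b_heads"], lipid["vm_heads"], lipid["thickness_heads"],
        lipid["b_tails"], lipid["vm_tails"], lipid["thickness_tails"],
        rough_head_tail=bilayer_rough, rough_preceding=bilayer_rough,
        reverse=True,
        name=f"{name} outer leaflet",
    )
    # share the leaflet thickness/chemistry parameters between leaflets
    outer.b_heads = inner.b_heads
    outer.vm_heads = inner.vm_heads
    outer.thickness_heads = inner.thickness_heads
    outer.b_tails = inner.b_tails
    outer.vm_tails = inner.vm_tails
    outer.thickness_tails = inner.thickness_tails

    s = si() | sio2(sio2_thick, sio2_rough, vfsolv=sio2_vfsolv) | inner | outer | solvent(0, bilayer_rough)
    s.name = name
    return s, apm


def make_bilayer_suite(
    apm=57.0,
    lipid=None,
    contrasts=None,
    seed=0,
    q=None,
    dq_over_q=DEFAULT_DQ_OVER_Q,
    noise=None,
    outdir=None,
):
    """Generate the three-contrast supported-bilayer co-refinement suite.

    Parameters
    ----------
    apm : true area per molecule, Å².
    contrasts : mapping name → solvent SLD (1e-6 Å⁻²); defaults to
        D₂O 6.36 / HDmix 2.07 / H₂O −0.56.
    seed : base RNG seed; contrast i uses seed + i.
    outdir : optional directory to write 4-column files + truth sidecars.

    Returns
    -------
    datasets : dict name → Data1D
    models : dict name → ReflectModel (sharing one apm Parameter)
    truth : dict of generating values (including ``apm``)
    """
    contrasts = contrasts or dict(CONTRASTS)
    if len(contrasts) < 2:
        raise ValueError("need at least 2 contrasts for co-refinement")
    if q is None:
        q = default_q_grid()
    noise = noise or NoiseModel()

    apm_par = Parameter(float(apm), name="area per molecule")
    datasets, models = {}, {}
    for i, (cname, sld) in enumerate(contrasts.items()):
        struct, _ = make_bilayer_structure(apm_par, sld, lipid=lipid, name=cname)
        model = ReflectModel(
            struct, scale=1.0, bkg=noise.background,
            resolution=Resolution.constant(dq_over_q), name=cname,
        )
        path = None if outdir is None else Path(outdir) / f"synthetic_{cname}.dat"
        datasets[cname] = generate_dataset(
            model, q=q, noise=noise, seed=seed + i, path=path, name=cname
        )
        models[cname] = model

    truth = {
        "apm": float(apm),
        "contrasts": dict(contrasts),
        "lipid": dict(DMPC, **(lipid or {})),
        "dq_over_q": dq_over_q,
        "noise": noise.to_dict(),
        "seed": int(seed),
    }
    if outdir is not None:
        (Path(outdir) / "suite_truth.json").write_text(json.dumps(truth, indent=2))
    return datasets, models, truth
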