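"""Composable interfacial models.

A :class:`Structure` is an ordered series of :class:`Component` objects:
the first is the semi-infinite fronting medium, the last the semi-infinite
backing.  Each component contributes one or more uniform slices via its
``slabs`` property — a :class:`Slab` is one slice, a :class:`LipidLeaflet`
two (head and tail regions), a :class:`Spline` many thin slices
approximating a free-form SLD profile.  Components may also contribute
extra log-prior terms, which is how physicality constraints (e.g. a lipid
volume fraction exceeding 1) are vetoed.

:class:`ReflectModel` wraps a structure with scale and background
parameters and a resolution specification; :class:`MixedReflectModel`
forms an incoherent, area-fraction-weighted sum of reflectivities from
several structures (lateral "patchiness").

SLDs are quoted in 10⁻⁶ Å⁻² throughout the user API.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.special import ndtr

from .parameters import Parameter, Parameters, possibly_create_parameter
from .reflectivity import Resolution, abeles, smear

__all__ = [
    "SLD",
    "Component",
    "Slab",
    "LipidLeaflet",
    "Spline",
    "Structure",
    "ReflectModel",
    "MixedReflectModel",
]


class SLD:
    """A material's scattering length density (real + imaginary, 10⁻⁶ Å⁻²).

    Calling an SLD, e.g. ``si(0, 3)``, makes a :class:`Slab` of the given
    thickness and roughness, which reads naturally when assembling
    structures: ``air(0, 0) | sio2(15, 3) | d2o(0, 3)``.
    """

    def __init__(self, value, name=""):
        if isinstance(value, SLD):
            self.real = value.real
            self.imag = value.imag
            self.name = name or value.name
            return
        if isinstance(value, complex):
            re, im = value.real, value.imag
        elif isinstance(value, (tuple, list)):
            re, im = value
        else:
            re, im = value, 0.0
        self.name = name
        self.real = possibly_create_parameter(re, name=f"{name} - sld" if name else "sld")
        self.imag = possibly_create_parameter(im, name=f"{name} - isld" if name else "isld")

    @property
    def parameters(self):
        return Parameters([self.real, self.imag], name=self.name)

    def __call__(self, thickness=0.0, roughness=0.0, vfsolv=0.0):
        return Slab(thickness, self, roughness, vfsolv=vfsolv, name=self.name)

    def __repr__(self):
        return f"SLD({self.real.value:+.4g}{self.imag.value:+.4g}j, name={self.name!r})"


def _to_sld(obj, name=""):
    if isinstance(obj, SLD):
        return obj
    return SLD(obj, name=name)


class Component:
    """Abstract piece of an interfacial model.

    Subclasses provide ``parameters`` and ``slabs(structure)``, the latter
    returning an (n, 5) array of rows
    ``[thickness, sld_re, sld_im, roughness, vfsolv]`` (SLD in 10⁻⁶ Å⁻²;
    roughness is to the *previous* slice).  ``logp`` may add a prior term.
    """

    name = ""

    @property
    def parameters(self):
        raise NotImplementedError

    def slabs(self, structure=None):
        raise NotImplementedError

    def logp(self):
        return 0.0

    def __or__(self, other):
        """``a | b`` chains components into a Structure."""
        s = Structure()
        s.append(self)
        if isinstance(other, Structure):
            for c in other.components:
                s.append(c)
        else:
            s.append(other)
        return s


class Slab(Component):
    """A single uniform slice: thickness, SLD, roughness, solvent fraction.

    The effective SLD of a solvated slab is
    ``(1 − φ_solv)·ρ + φ_solv·ρ_solvent`` with the solvent medium resolved
    by the parent Structure.
    """

    def __init__(self, thickness, sld, roughness, vfsolv=0.0, name=""):
        self.name = name
        self.thickness = possibly_create_parameter(thickness, name=f"{name} - thick")
        self.sld = _to_sld(sld, name=name)
        self.roughness = possibly_create_parameter(roughness, name=f"{name} - rough")
        self.vfsolv = possibly_create_parameter(vfsolv, name=f"{name} - volfrac solvent")

    @property
    def parameters(self):
        return Parameters(
            [self.thickness, self.sld.real, self.sld.imag, self.roughness, self.vfsolv],
            name=self.name,
        )

    def slabs(self, structure=None):
        return np.array(
            [[
                self.thickness.value,
                self.sld.real.value,
                self.sld.imag.value,
                self.roughness.value,
                self.vfsolv.value,
            ]]
        )

    def logp(self):
        if not 0.0 <= self.vfsolv.value <= 1.0:
            return -np.inf
        return 0.0

    def __repr__(self):
        return (
            f"Slab({self.thickness.value:.4g}, {self.sld!r}, "
            f"{self.roughness.value:.4g}, name={self.name!r})"
        )


class LipidLeaflet(Component):
    """One leaflet of a lipid bilayer (or a monolayer), chemically
    parameterized so that heads and tails stay in 1:1 correspondence.

    The leaflet occupies area-per-molecule ``A`` (Å²); the head region has
    thickness ``t_h`` (Å), summed coherent scattering length ``b_h`` (Å)
    and partial molecular volume ``V_h`` (Å³), and likewise for the tails.
    The lipid volume fraction in region x is V_x/(A·t_x), so the region SLD
    is

        ρ_x = b_x/(A·t_x) + (1 − V_x/(A·t_x))·ρ_x,solv,

    with the region solvents defaulting to the structure's solvent (the
    solid–liquid case); different head/tail solvents can be supplied for
    air–liquid work.  ``reverse`` flips the head/tail order so that two
    leaflet objects describe the inner and outer halves of a bilayer.

    An unphysical configuration (V_x > A·t_x, i.e. more lipid than space)
    contributes −inf to the log-prior rather than being silently clipped.
    """

    def __init__(
        self,
        apm,
        b_heads,
        vm_heads,
        thickness_heads,
        b_tails,
        vm_tails,
        thickness_tails,
        rough_head_tail,
        rough_preceding,
        head_solvent=None,
        tail_solvent=None,
        reverse=False,
        name="",
    ):
        self.name = name
        self.apm = possibly_create_parameter(apm, name=f"{name} - area per molecule")
        self.b_heads = possibly_create_parameter(b_heads, name=f"{name} - b_heads")
        self.vm_heads = possibly_create_parameter(vm_heads, name=f"{name} - vm_heads")
        self.thickness_heads = possibly_create_parameter(
            thickness_heads, name=f"{name} - thickness_heads"
        )
        self.b_tails = possibly_create_parameter(b_tails, name=f"{name} - b_tails")
        self.vm_tails = possibly_create_parameter(vm_tails, name=f"{name} - vm_tails")
        self.thickness_tails = possibly_create_parameter(
            thickness_tails, name=f"{name} - thickness_tails"
        )
        self.rough_head_tail = possibly_create_parameter(
            rough_head_tail, name=f"{name} - rough_head_tail"
        )
        self.rough_preceding = possibly_create_parameter(
            rough_preceding, name=f"{name} - rough_preceding"
        )
        self.head_solvent = None if head_solvent is None else _to_sld(head_solvent)
        self.tail_solvent = None if tail_solvent is None else _to_sld(tail_solvent)
        self.reverse = bool(reverse)

    @property
    def parameters(self):
        items = [
            self.apm,
            self.b_heads,
            self.vm_heads,
            self.thickness_heads,
            self.b_tails,
            self.vm_tails,
            self.thickness_tails,
            self.rough_head_tail,
            self.rough_preceding,
        ]
        for s in (self.head_solvent, self.tail_solvent):
            if s is not None:
                items.extend([s.real, s.imag])
        return Parameters(items, name=self.name)

    def _volfracs(self):
        a = self.apm.value
        phi_h = self.vm_heads.value / (a * self.thickness_heads.value)
        phi_t = self.vm_tails.value / (a * self.thickness_tails.value)
        return phi_h, phi_t

    def slabs(self, structure=None):
        phi_h, phi_t = self._volfracs()
        a = self.apm.value

        rows = []
        for region, phi, t, b, solvent, rough in (
            ("head", phi_h, self.thickness_heads.value, self.b_heads.value,
             self.head_solvent, None),
            ("tail", phi_t, self.thickness_tails.value, self.b_tails.value,
             self.tail_solvent, self.rough_head_tail.value),
        ):
            # SLD of the pure lipid region, quoted in 1e-6 Å⁻²
            rho_lipid = b / (t * a * phi) * 1e6 if phi != 0 else 0.0  # = b/V_x
            if solvent is None:
                # defer mixing to the structure solvent via vfsolv
                rows.append([t, rho_lipid, 0.0, 0.0, 1.0 - phi])
            else:
                rho = phi * rho_lipid + (1.0 - phi) * solvent.real.value
                rho_i = (1.0 - phi) * solvent.imag.value
                rows.append([t, rho, rho_i, 0.0, 0.0])

        if self.reverse:
            rows = rows[::-1]
        rows[0][3] = self.rough_preceding.value
        rows[1][3] = self.rough_head_tail.value
        return np.array(rows)

    def logp(self):
        phi_h, phi_t = self._volfracs()
        if not (0.0 <= phi_h <= 1.0 and 0.0 <= phi_t <= 1.0):
            return -np.inf
        return 0.0

    def __repr__(self):
        return f"LipidLeaflet(A={self.apm.value:.4g}, name={self.name!r}, reverse={self.reverse})"


class Spline(Component):
    """Free-form SLD region: a monotone (shape-preserving) cubic through
    knots, discretized into ``m`` equal-thickness slices.

    Parameters
    ----------
    extent : total thickness of the region, Å.
    knot_distances : strictly increasing positions of the knots, Å, from
        the start of the region (first typically 0, last = extent).
    knot_slds : SLD value at each knot, 10⁻⁶ Å⁻².
    m : number of slices; defaults to extent/0.5 Å, capped at 500.
    """

    def __init__(self, extent, knot_distances, knot_slds, m=None, name=""):
        self.name = name
        knot_distances = np.asarray(knot_distances, dtype=float)
        if knot_distances.size < 2:
            raise ValueError("need at least 2 knots")
        if np.any(np.diff(knot_distances) <= 0):
            raise ValueError("knot distances must be strictly increasing")
        self.extent = possibly_create_parameter(extent, name=f"{name} - extent")
        self.knot_distances = knot_distances
        self.knot_slds = [
            possibly_create_parameter(v, name=f"{name} - knot sld {i}")
            for i, v in enumerate(np.asarray(knot_slds, dtype=float))
        ]
        if len(self.knot_slds) != knot_distances.size:
            raise ValueError("one SLD per knot required")
        if m is None:
            m = int(min(500, max(2, round(float(self.extent.value) / 0.5))))
        if m < 2:
            raise ValueError("m must be >= 2")
        self.m = int(m)

    @property
    def parameters(self):
        return Parameters([self.extent] + self.knot_slds, name=self.name)

    def slabs(self, structure=None):
        ext = self.extent.value
        vals = np.array([p.value for p in self.knot_slds])
        interp = PchipInterpolator(self.knot_distances, vals)
        dz = ext / self.m
        mids = (np.arange(self.m) + 0.5) * dz
        # knots live on [0, max(knot_distances)]; scale to the extent
        x = mids * (self.knot_distances[-1] / ext)
        slds = interp(x)
        rows = np.zeros((self.m, 5))
        rows[:, 0] = dz
        rows[:, 1] = slds
        return rows

    def __repr__(self):
        return f"Spline(extent={self.extent.value:.4g}, knots={len(self.knot_slds)}, m={self.m})"


class Structure:
    """An ordered series of components, fronting medium first, backing last.

    ``solvent`` is the medium used to resolve slab solvent volume
    fractions; by default it is the backing medium (the solid–liquid
    geometry, where the subphase bathes the interface).
    """

    def __init__(self, components=(), name="", solvent=None):
        self.components = list(components)
        self.name = name
        self.solvent = None if solvent is None else _to_sld(solvent)

    def append(self, item):
        if isinstance(item, SLD):
            item = item()
        if not isinstance(item, Component):
            raise TypeError("can only append Component or SLD objects")
        self.components.append(item)
        return self

    def __or__(self, other):
        if isinstance(other, Structure):
            self.components.extend(other.components)
        else:
            self.append(other)
        return self

    def __len__(self):
        return len(self.components)

    def __getitem__(self, i):
        return self.components[i]

    @property
    def parameters(self):
        items = [c.parameters for c in self.components]
        if self.solvent is not None:
            items.append(self.solvent.parameters)
        return Parameters(items, name=self.name)

    def _solvent_sld(self):
        if self.solvent is not None:
            return self.solvent.real.value, self.solvent.imag.value
        back = self.components[-1].slabs(self)
        return back[-1, 1], back[-1, 2]

    def slabs(self):
        """Concatenate component slices and resolve solvation.

        Returns an (N+2, 4) array ready for the reflectivity kernel:
        ``[thickness, sld_re, sld_im, roughness]`` with solvent volume
        fractions already folded into effective SLDs.
        """
        if len(self.components) < 2:
            raise ValueError("a Structure needs at least fronting and backing media")
        rows = np.concatenate([np.atleast_2d(c.slabs(self)) for c in self.components], axis=0)
        solv_re, solv_im = self._solvent_sld()
        vf = rows[:, 4]
        eff = rows[:, :4].copy()
        eff[:, 1] = (1.0 - vf) * rows[:, 1] + vf * solv_re
        eff[:, 2] = (1.0 - vf) * rows[:, 2] + vf * solv_im
        # semi-infinite media: thickness meaningless
        eff[0, 0] = 0.0
        eff[-1, 0] = 0.0
        return eff

    def logp(self):
        """Extra (component-level) prior terms, e.g. lipid packing vetoes."""
        tot = 0.0
        for c in self.components:
            lp = c.logp()
            if not np.isfinite(lp):
                return -np.inf
            tot += lp
        return tot

    def reflectivity(self, q):
        """Unsmeared reflectivity of the assembled stack."""
        return abeles(q, self.slabs())

    def sld_profile(self, z=None):
        """Continuous SLD(z) with error-function interfaces.

        Each interface of Gaussian roughness σ becomes a smooth step
        ρ₀ + (ρ₁−ρ₀)·Φ((z−z_interface)/σ), Φ the standard normal CDF —
        the real-space profile consistent with the Névot–Croce treatment.

        Returns ``(z, sld)``; ``z`` defaults to a grid padded 4σ (min
        10 Å) beyond the outermost interfaces.
        """
        slabs = self.slabs()
        thicks = slabs[1:-1, 0]
        zints = np.concatenate([[0.0], np.cumsum(thicks)])  # interface positions
        sigmas = np.clip(slabs[1:, 3], 1e-3, None)
        slds = slabs[:, 1]
        if z is None:
            pad = max(10.0, 4.0 * sigmas.max() if sigmas.size else 10.0)
            z = np.linspace(zints[0] - pad, zints[-1] + pad, 500)
        z = np.asarray(z, dtype=float)
        prof = np.full_like(z, slds[0])
        for i, zi in enumerate(zints):
            prof = prof + (slds[i + 1] - slds[i]) * ndtr((z - zi) / sigmas[i])
        return z, prof

    def __repr__(self):
        names = " | ".join(c.name or type(c).__name__ for c in self.components)
        return f"<Structure {self.name!r}: {names}>"


class ReflectModel:
    """Resolution-smeared reflectivity of a Structure, with scale and
    additive constant background: ``R_model = scale·smear(R) + background``.
    """

    def __init__(self, structure, scale=1.0, bkg=0.0, resolution=None, name=""):
        self.structure = structure
        self.name = name
        self.scale = possibly_create_parameter(scale, name=f"{name} - scale")
        self.bkg = possibly_create_parameter(bkg, name=f"{name} - bkg")
        if resolution is None:
            resolution = Resolution("none")
        elif isinstance(resolution, (int, float)):
            resolution = Resolution.constant(float(resolution))
        self.resolution = resolution

    @property
    def parameters(self):
        return Parameters([self.scale, self.bkg, self.structure.parameters], name=self.name)

    def logp(self):
        return self.structure.logp()

    def __call__(self, q, x_err=None):
        return self.model(q, x_err=x_err)

    def model(self, q, x_err=None):
        """Smeared model curve at ``q``; ``x_err`` supplies per-point dQ
        (FWHM) when the resolution kind is pointwise."""
        q = np.asarray(q, dtype=float)
        slabs = self.structure.slabs()
        r_of_q = lambda qq: abeles(qq, slabs)
        res = self.resolution
        if res.kind == "pointwise":
            dq = x_err if x_err is not None else res.value
            if dq is None:
                raise ValueError("pointwise resolution requires dQ values (x_err)")
            res = Resolution.pointwise(np.broadcast_to(np.asarray(dq, float), q.shape))
        smeared = smear(r_of_q, q, res)
        return self.scale.value * smeared + self.bkg.value

    def __repr__(self):
        return f"<ReflectModel {self.name!r}, scale={self.scale.value:.4g}, bkg={self.bkg.value:.3g}>"


class MixedReflectModel:
    """Incoherent area-weighted sum of reflectivities from several
    structures: ``R = Σ_i s_i·smear(R_i) + background``.

    Used for laterally patchy samples, where distinct regions of the
    surface reflect independently.
    """

    def __init__(self, structures, scales=None, bkg=0.0, resolution=None, name=""):
        self.structures = list(structures)
        if scales is None:
            scales = [1.0 / len(self.structures)] * len(self.structures)
        if len(scales) != len(self.structures):
            raise ValueError("one area fraction per structure required")
        self.scales = Parameters(
            [possibly_create_parameter(s, name=f"{name} - scale{i}") for i, s in enumerate(scales)]
        )
        self.bkg = possibly_create_parameter(bkg, name=f"{name} - bkg")
        if resolution is None:
            resolution = Resolution("none")
        elif isinstance(resolution, (int, float)):
            resolution = Resolution.constant(float(resolution))
        self.resolution = resolution
        self.name = name

    @property
    def parameters(self):
        items = [self.scales, self.bkg] + [s.parameters for s in self.structures]
        return Parameters(items, name=self.name)

    def logp(self):
        if any(s.value < 0 for s in self.scales):
            return -np.inf
        tot = 0.0
        for s in self.structures:
            lp = s.logp()
            if not np.isfinite(lp):
                return -np.inf
            tot += lp
        return tot

    def __call__(self, q, x_err=None):
        return self.model(q, x_err=x_err)

    def model(self, q, x_err=None):
        q = np.asarray(q, dtype=float)
        res = self.resolution
        if res.kind == "pointwise":
            dq = x_err if x_err is not None else res.value
            if dq is None:
                raise ValueError("pointwise resolution requires dQ values (x_err)")
            res = Resolution.pointwise(np.broadcast_to(np.asarray(dq, float), q.shape))
        out = np.zeros_like(q, dtype=float)
        for sc, struct in zip(self.scales, self.structures):
            slabs = struct.slabs()
            out += sc.value * smear(lambda qq: abeles(qq, slabs), q, res)
        return out + self.bkg.value
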