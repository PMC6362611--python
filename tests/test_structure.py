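"""Structural components: slabs, lipid leaflets, splines, assembled models."""

import numpy as np
import pytest
from scipy.special import ndtr

from specref import (
    SLD,
    LipidLeaflet,
    MixedReflectModel,
    Objective,
    ReflectModel,
    Slab,
    Spline,
    Structure,
)
from specref.reflectivity import Resolution, abeles


def simple_structure(vfsolv=0.0, rho=2.0, solvent=6.36):
    si = SLD(0.0, "front")
    film = SLD(rho, "film")
    back = SLD(solvent, "solvent")
    return si() | film(100, 3, vfsolv=vfsolv) | back(0, 3)


class TestStructureAssembly:
    def test_three_row_slab_array(self):
        s = simple_structure()
        arr = s.slabs()
        assert arr.shape == (3, 4)
        assert arr[1, 1] == 2.0 and arr[1, 0] == 100.0

    def test_full_solvation_takes_solvent_sld(self):
        arr = simple_structure(vfsolv=1.0).slabs()
        assert arr[1, 1] == pytest.approx(6.36)

    def test_partial_solvation_linear_mixing(self):
        # 0.7*2 + 0.3*6.36
        arr = simple_structure(vfsolv=0.3).slabs()
        assert arr[1, 1] == pytest.approx(3.308)

    def test_solvent_defaults_to_backing_but_is_overrideable(self):
        s = simple_structure(vfsolv=0.5)
        assert s.slabs()[1, 1] == pytest.approx(0.5 * 2 + 0.5 * 6.36)
        s.solvent = SLD(0.0)
        assert s.slabs()[1, 1] == pytest.approx(1.0)

    def test_too_few_components_rejected(self):
        s = Structure()
        s.append(SLD(0.0)())
        with pytest.raises(ValueError, match="at least"):
            s.slabs()

    def test_structure_reflectivity_equals_kernel_on_same_slabs(self):
        s = simple_structure(vfsolv=0.3)
        q = np.linspace(0.01, 0.3, 50)
        np.testing.assert_array_equal(s.reflectivity(q), abeles(q, s.slabs()))

    def test_reversal_symmetry_for_symmetric_stack(self):
        med = SLD(1.0)
        a, b = SLD(4.0), SLD(6.0)
        s1 = med() | a(50, 0) | b(80, 0) | a(50, 0) | med(0, 0)
        s2 = Structure(list(reversed(s1.components)))
        q = np.linspace(0.01, 0.3, 60)
        np.testing.assert_allclose(s1.reflectivity(q), s2.reflectivity(q), rtol=1e-9)


class TestStructureSerialization:
    def test_structure_config_roundtrip(self):
        from specref.config import ParameterRegistry, _build_structure, structure_to_config

        leaf = LipidLeaflet(57.0, 6.01e-4, 319.0, 9.0, -2.92e-4, 782.0, 14.0, 3.0, 3.0,
                            name="leaf")
        s = SLD(2.07, "Si")() | SLD(3.47, "SiO2")(15, 3, vfsolv=0.1) | leaf | SLD(6.36)(0, 3)
        cfg = structure_to_config(s)
        rebuilt = _build_structure("rt", cfg, ParameterRegistry({}))
        q = np.linspace(0.01, 0.3, 50)
        np.testing.assert_allclose(rebuilt.reflectivity(q), s.reflectivity(q), rtol=1e-12)


class TestLipidLeaflet:
    kwargs = dict(
        apm=57.0,
        b_heads=6.01e-4, vm_heads=319.0, thickness_heads=9.0,
        b_tails=-2.92e-4, vm_tails=782.0, thickness_tails=14.0,
        rough_head_tail=3.0, rough_preceding=5.0,
    )

    def test_two_rows_head_then_tail(self):
        rows = LipidLeaflet(**self.kwargs).slabs()
        assert rows.shape[0] == 2
        assert rows[0, 0] == 9.0 and rows[1, 0] == 14.0
        assert rows[0, 3] == 5.0 and rows[1, 3] == 3.0

    def test_fully_packed_head_has_pure_lipid_sld(self):
        kw = dict(self.kwargs, apm=50.0, vm_heads=450.0)  # V_h = A*t_h
        rows = LipidLeaflet(**kw).slabs()
        assert rows[0, 4] == pytest.approx(0.0)  # no solvent in the head
        assert rows[0, 1] == pytest.approx(6.01e-4 / 450.0 * 1e6)

    def test_half_filled_tail_mixes_solvent(self):
        # b_t = 0, V_t = A*t_t/2, explicit tail solvent 6 -> tail SLD 3
        kw = dict(
            self.kwargs, apm=50.0, b_tails=0.0, vm_tails=350.0,
            tail_solvent=SLD(6.0),
        )
        rows = LipidLeaflet(**kw).slabs()
        assert rows[1, 1] == pytest.approx(3.0)
        assert rows[1, 4] == 0.0  # already mixed, nothing left for the structure

    def test_reverse_swaps_rows_not_slds(self):
        fwd = LipidLeaflet(**self.kwargs).slabs()
        rev = LipidLeaflet(**dict(self.kwargs, reverse=True)).slabs()
        assert rev[0, 1] == fwd[1, 1] and rev[1, 1] == fwd[0, 1]
        assert rev[0, 0] == fwd[1, 0] and rev[1, 0] == fwd[0, 0]

    def test_overfilled_region_vetoed_not_clipped(self):
        kw = dict(self.kwargs, apm=40.0)  # V_t/(A*t_t) = 782/560 > 1
        leaf = LipidLeaflet(**kw)
        assert leaf.logp() == -np.inf
        assert np.isfinite(LipidLeaflet(**self.kwargs).logp())

    def test_uniform_leaflet_equivalent_to_single_slab(self):
        # head chemistry == tail chemistry -> one uniform 23 A layer
        kw = dict(
            self.kwargs,
            b_heads=2e-4, vm_heads=50.0 * 9.0, thickness_heads=9.0,
            b_tails=2e-4 * (14.0 / 9.0), vm_tails=50.0 * 14.0, thickness_tails=14.0,
            apm=50.0, rough_head_tail=0.0, rough_preceding=0.0,
        )
        leaf = LipidLeaflet(**kw)
        front, back = SLD(0.0), SLD(6.36)
        s1 = front() | leaf | back(0, 0)
        rho = 2e-4 / (50.0 * 9.0) * 1e6
        s2 = front() | SLD(rho)(23.0, 0) | back(0, 0)
        q = np.linspace(0.01, 0.3, 60)
        np.testing.assert_allclose(s1.reflectivity(q), s2.reflectivity(q), rtol=1e-9)


class TestSpline:
    def test_constant_knots_give_constant_slices(self):
        sp = Spline(40.0, [0, 40], [3.0, 3.0], m=10)
        rows = sp.slabs()
        assert rows.shape[0] == 10
        np.testing.assert_allclose(rows[:, 1], 3.0)
        assert rows[:, 0].sum() == pytest.approx(40.0)

    def test_linear_knots_interpolate_linearly(self):
        sp = Spline(40.0, [0, 20, 40], [1.0, 2.0, 3.0], m=20)
        rows = sp.slabs()
        mids = np.cumsum(rows[:, 0]) - rows[0, 0] / 2
        np.testing.assert_allclose(rows[:, 1], 1.0 + 2.0 * mids / 40.0, rtol=1e-9)

    def test_non_increasing_knots_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            Spline(40.0, [0, 20, 20], [1, 2, 3])

    def test_slice_count_convergence(self):
        front, back = SLD(0.0), SLD(6.36)
        q = np.linspace(0.01, 0.3, 80)
        curves = {}
        # slices must be well below 1/Q_max for the staircase bias
        # (ΔR/R ≈ Q²dz²/12) to sit under the tolerance
        for m in (400, 800):
            sp = Spline(40.0, [0, 20, 40], [1.0, 4.5, 6.36], m=m)
            s = front() | sp | back(0, 0)
            curves[m] = s.reflectivity(q)
        np.testing.assert_allclose(curves[400], curves[800], rtol=1e-4)


class TestSldProfile:
    def test_sharp_interfaces_give_steps(self):
        s = simple_structure()
        for c in s.components:
            c.roughness.value = 0.0
        z, prof = s.sld_profile(np.array([-20.0, 50.0, 150.0]))
        np.testing.assert_allclose(prof, [0.0, 2.0, 6.36], atol=1e-6)

    def test_single_interface_erf_closed_form(self):
        front, back = SLD(1.0), SLD(5.0)
        s = front() | back(0, 5.0)
        z = np.linspace(-25, 25, 101)
        _, prof = s.sld_profile(z)
        np.testing.assert_allclose(prof, 1.0 + 4.0 * ndtr(z / 5.0), rtol=1e-10)

    def test_backing_asymptote(self):
        s = simple_structure()
        _, prof = s.sld_profile(np.array([1e4]))
        assert prof[0] == pytest.approx(6.36)


class TestReflectModel:
    def test_scale_one_background_zero_is_plain_smeared(self, single_slab):
        front, film, back = SLD(0.0), SLD(4.0), SLD(6.36)
        s = front() | film(100, 2) | back(0, 3)
        m = ReflectModel(s, scale=1.0, bkg=0.0, resolution=0.05)
        q = np.linspace(0.01, 0.3, 40)
        from specref.reflectivity import smear

        expected = smear(lambda qq: abeles(qq, s.slabs()), q, Resolution.constant(0.05))
        np.testing.assert_allclose(m(q), expected, rtol=1e-12)

    def test_background_floor_at_high_q(self):
        front, back = SLD(0.0), SLD(6.36)
        s = front() | back(0, 3)
        m = ReflectModel(s, bkg=1e-7)
        r = m(np.array([2.0]))
        assert r[0] == pytest.approx(1e-7, rel=0.05)

    def test_pointwise_resolution_requires_dq(self):
        s = SLD(0.0)() | SLD(6.36)(0, 3)
        m = ReflectModel(s, resolution=Resolution.pointwise())
        with pytest.raises(ValueError, match="dQ"):
            m(np.linspace(0.01, 0.1, 5))

    def test_degenerate_mixture_equals_single_model(self):
        front, film, back = SLD(0.0), SLD(4.0), SLD(6.36)
        s1 = front() | film(100, 2) | back(0, 3)
        s2 = front() | film(100, 2) | back(0, 3)
        mixed = MixedReflectModel([s1, s2], scales=[0.5, 0.5], bkg=1e-8, resolution=0.05)
        single = ReflectModel(s1, scale=1.0, bkg=1e-8, resolution=0.05)
        q = np.linspace(0.01, 0.3, 40)
        np.testing.assert_allclose(mixed(q), single(q), rtol=1e-12)
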