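"""Least-squares fitting, MCMC sampling and chain post-processing."""

import numpy as np
import pytest

from conftest import GaussianPosterior
from specref import (
    SLD,
    Chain,
    CurveFitter,
    Objective,
    ReflectModel,
    generate_dataset,
    process_chain,
)


def slab_objective(seed=0, perturb=False, vary=("thickness", "sld", "rough")):
    front, film, back = SLD(0.0), SLD(4.0, "film"), SLD(6.36)
    s = front() | film(100.0, 3.0) | back(0, 3.0)
    model = ReflectModel(s, resolution=0.05)
    data = generate_dataset(model, seed=seed, perturb=perturb, name="slab")
    slab = s[1]
    truth = {}
    if "thickness" in vary:
        slab.thickness.vary = True
        slab.thickness.set_bounds((50, 150))
        truth["thickness"] = 100.0
    if "sld" in vary:
        slab.sld.real.vary = True
        slab.sld.real.set_bounds((2, 6))
        truth["sld"] = 4.0
    if "rough" in vary:
        slab.roughness.vary = True
        slab.roughness.set_bounds((0.1, 10))
        truth["rough"] = 3.0
    return Objective(model, data), truth


class TestLeastSquares:
    def test_no_varying_parameters_is_an_error(self):
        obj, _ = slab_objective(vary=())
        with pytest.raises(ValueError, match="varying"):
            obj.fit()

    @pytest.mark.parametrize(
        ("method", "start"),
        [
            # Gauss-Newton steps tolerate a distant start...
            ("levenberg_marquardt", [120.0, 3.5, 5.0]),
            # ...the quasi-Newton polisher needs to begin inside the basin
            ("lbfgsb", [105.0, 4.1, 3.3]),
        ],
    )
    def test_noise_free_recovery_from_offset_start(self, method, start):
        obj, truth = slab_objective(perturb=False)
        obj.setp(np.array(start))
        res = obj.fit(method=method)
        np.testing.assert_allclose(res.x, [100.0, 4.0, 3.0], rtol=1e-3)

    def test_differential_evolution_seeded_reproducible(self):
        obj, _ = slab_objective(perturb=False, vary=("thickness",))
        obj.setp(np.array([120.0]))
        r1 = obj.fit(method="differential_evolution", seed=42, maxiter=20)
        obj.setp(np.array([120.0]))
        r2 = obj.fit(method="differential_evolution", seed=42, maxiter=20)
        np.testing.assert_array_equal(r1.x, r2.x)

    def test_lm_warns_bounds_ignored(self):
        obj, _ = slab_objective(perturb=False, vary=("thickness",))
        with pytest.warns(UserWarning, match="bounds"):
            obj.fit(method="levenberg_marquardt")

    def test_stderr_scales_with_data_noise(self):
        obj, _ = slab_objective(seed=1, perturb=True, vary=("thickness",))
        res = obj.fit(method="lbfgsb")
        assert np.isfinite(res.stderr[0]) and 0 < res.stderr[0] < 1.0

    def test_summary_mentions_parameters(self):
        obj, _ = slab_objective(perturb=False, vary=("thickness",))
        res = obj.fit(method="lbfgsb")
        assert "film - thick" in res.summary()


class TestMCMC:
    def test_chain_shape_and_seed_determinism(self):
        obj, _ = slab_objective(seed=2, perturb=True, vary=("thickness",))
        c1 = CurveFitter(obj, nwalkers=8).sample(20, seed=7)
        assert c1.samples.shape == (20, 8, 1)
        obj.setp(np.array([100.0]))
        c2 = CurveFitter(obj, nwalkers=8).sample(20, seed=7)
        np.testing.assert_array_equal(c1.samples, c2.samples)

    def test_walker_floor_enforced(self):
        obj, _ = slab_objective(vary=("thickness", "sld", "rough"))
        with pytest.raises(ValueError, match="nwalkers"):
            CurveFitter(obj, nwalkers=4).sample(5)

    def test_gaussian_posterior_recovered(self):
        mean = np.array([1.0, -2.0])
        cov = np.array([[1.0, 0.6], [0.6, 2.0]])
        toy = GaussianPosterior(mean, cov)
        chain = CurveFitter(toy, nwalkers=50).sample(700, seed=10)
        flat = chain.samples[200:].reshape(-1, 2)
        est_mean = flat.mean(axis=0)
        est_cov = np.cov(flat.T)
        np.testing.assert_allclose(est_mean, mean, atol=0.08)
        np.testing.assert_allclose(est_cov, cov, rtol=0.08)

    def test_resume_continues_from_last_position(self):
        obj, _ = slab_objective(seed=3, perturb=True, vary=("thickness",))
        c1 = CurveFitter(obj, nwalkers=8).sample(10, seed=1)
        c2 = CurveFitter(obj, nwalkers=8).sample(5, seed=2, init_pos=c1.samples[-1])
        assert c2.samples.shape == (5, 8, 1)
        # first saved step is one move past the init positions: walkers whose
        # first proposal was rejected sit exactly at the old chain's end
        moved = np.abs(c2.samples[0] - c1.samples[-1])
        assert np.median(moved) < 1.0
        assert np.any(moved == 0.0)


class TestParallelTempering:
    def test_tempered_sampling_and_evidence_on_gaussian(self):
        # 1-D: prior U(-10,10), likelihood N(0,1) ->
        # Z = integral = (1/20) * 1 -> logZ ~ -log 20
        toy = GaussianPosterior([0.0], [[1.0]], half_width=10.0)
        fitter = CurveFitter(toy, nwalkers=20, ntemps=6)
        chain = fitter.sample(400, seed=4)
        assert chain.samples.shape == (400, 20, 1)
        flat = chain.samples[100:].reshape(-1)
        assert abs(np.median(flat)) < 0.1
        assert np.std(flat) == pytest.approx(1.0, rel=0.12)
        # thermodynamic-integration log-evidence: log(sqrt(2*pi)/20) = -2.08
        assert chain.logz == pytest.approx(np.log(np.sqrt(2 * np.pi) / 20.0), abs=0.3)

    def test_multimodal_posterior_both_modes_visited(self):
        from specref.objective import _BaseObjective
        from specref.parameters import Parameter, Parameters

        class TwoWells(_BaseObjective):
            def __init__(self):
                self._p = Parameters([Parameter(0.0, "x", vary=True, bounds=(-12, 12))])

            @property
            def parameters(self):
                return self._p

            def logp(self, pvals=None):
                self.setp(pvals)
                return self._p.logp()

            def logl(self, pvals=None):
                self.setp(pvals)
                x = self._p[0].value
                return float(
                    np.logaddexp(-0.5 * ((x - 6) / 0.4) ** 2, -0.5 * ((x + 6) / 0.4) ** 2)
                )

        chain = CurveFitter(TwoWells(), nwalkers=30, ntemps=6).sample(300, seed=9)
        flat = chain.samples[100:].reshape(-1)
        frac_right = np.mean(flat > 0)
        assert 0.2 < frac_right < 0.8  # tempering swaps populate both modes


class TestProcessChain:
    def _fake_chain(self, samples):
        lp = np.zeros(samples.shape[:2])
        return Chain(samples, lp, [f"p{i}" for i in range(samples.shape[2])])

    def test_standard_normal_stderr_is_one(self):
        rng = np.random.default_rng(5)
        chain = self._fake_chain(rng.standard_normal((500, 20, 1)))
        post = process_chain(chain)
        assert post.stderr[0] == pytest.approx(1.0, rel=0.03)
        assert post.median[0] == pytest.approx(0.0, abs=0.05)

    def test_constant_chain(self):
        chain = self._fake_chain(np.full((50, 4, 2), 3.14))
        post = process_chain(chain)
        np.testing.assert_array_equal(post.median, [3.14, 3.14])
        np.testing.assert_array_equal(post.stderr, [0.0, 0.0])

    def test_burn_and_thin_bookkeeping(self):
        # thinning an 8000-step chain by 400 keeps 20 saved steps
        chain = self._fake_chain(np.zeros((8000, 2, 1)))
        post = process_chain(chain, nburn=0, nthin=400)
        assert post.flat.shape[0] == 20 * 2

    def test_empty_after_burn_rejected(self):
        chain = self._fake_chain(np.zeros((10, 2, 1)))
        with pytest.raises(ValueError, match="burn"):
            process_chain(chain, nburn=10)
        with pytest.raises(ValueError, match="thin"):
            process_chain(chain, nthin=0)

    def test_updates_objective_parameters_to_medians(self):
        obj, _ = slab_objective(seed=6, perturb=True, vary=("thickness",))
        chain = CurveFitter(obj, nwalkers=8).sample(30, seed=3)
        post = process_chain(chain, nburn=10, objective=obj)
        assert obj.getp()[0] == post.median[0]

    def test_sample_rows_shape_and_membership(self):
        rng = np.random.default_rng(6)
        chain = self._fake_chain(rng.standard_normal((100, 5, 3)))
        post = process_chain(chain)
        rows = post.sample_rows(50, seed=1)
        assert rows.shape == (50, 3)

    def test_chain_save_load_roundtrip(self, tmp_path):
        rng = np.random.default_rng(7)
        chain = Chain(
            rng.standard_normal((20, 4, 2)),
            rng.standard_normal((20, 4)),
            ["a", "b"],
        )
        p = tmp_path / "chain.txt"
        chain.save(p)
        c2 = Chain.load(p)
        np.testing.assert_allclose(c2.samples, chain.samples, rtol=1e-10)
        np.testing.assert_allclose(c2.logpost, chain.logpost, rtol=1e-10)
        assert c2.names == ["a", "b"]
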