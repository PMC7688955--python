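import numpy as np
import pytest

from her2forecast.grid import ImageVolume, StudyConfig, TreatmentSchedule
from her2forecast.model import (
    ModelParameters,
    check_stability,
    chemo_field,
    growth_modulation,
    simulate,
    step,
)
from her2forecast.quantities import CellularityMap, DrugFieldSet

from conftest import make_single_voxel


class TestChemoField:
    def _setup(self, dose_times=(5.0,), alpha1=0.3, beta1=0.1, alpha2=0.0, beta2=0.2):
        _, _, drugs, params = make_single_voxel(
            alpha1=alpha1, beta1=beta1, alpha2=alpha2, beta2=beta2,
            dose_times=dose_times, scan2_time=50.0, surgery_time=100.0,
        )
        return drugs, params

    def test_zero_before_first_dose(self):
        drugs, params = self._setup(dose_times=(5.0,))
        assert chemo_field(4.9, drugs, params).max() == 0.0

    def test_single_dose_formula(self):
        drugs, params = self._setup(dose_times=(5.0,), alpha1=0.3, beta1=0.1)
        t = 12.0
        expected = 0.3 * np.exp(-0.1 * (t - 5.0))
        np.testing.assert_allclose(chemo_field(t, drugs, params), expected, rtol=1e-12)

    def test_dose_superposition(self):
        drugs, params = self._setup(dose_times=(0.0, 21.0), alpha1=0.3, beta1=0.1)
        t = 30.0
        expected = 0.3 * (np.exp(-0.1 * 30.0) + np.exp(-0.1 * 9.0))
        np.testing.assert_allclose(chemo_field(t, drugs, params), expected, rtol=1e-12)

    def test_decay_limit(self):
        drugs, params = self._setup(dose_times=(0.0, 21.0), alpha1=0.5, beta1=0.2)
        assert chemo_field(5000.0, drugs, params).max() < 1e-12


class TestGrowthModulation:
    def test_identity_when_mu_zero(self):
        t_map = ImageVolume(np.random.default_rng(0).uniform(0, 1, (3, 3, 3)))
        np.testing.assert_array_equal(growth_modulation(t_map, 0.0, True), 1.0)

    def test_identity_before_first_dose(self):
        t_map = ImageVolume(np.full((2, 2, 2), 1.0))
        np.testing.assert_array_equal(growth_modulation(t_map, 0.9, False), 1.0)

    @pytest.mark.parametrize("mu,expected", [(0.25, 0.5), (0.75, -0.5)])
    def test_full_concentration_arithmetic(self, mu, expected):
        t_map = ImageVolume(np.ones((2, 2, 2)))
        np.testing.assert_allclose(growth_modulation(t_map, mu, True), expected)


class TestCheckStability:
    def test_zero_diffusivity_always_stable(self):
        stable, dt = check_stability(0.0, (1.0, 1.0, 1.0), 0.25)
        assert stable and dt == 0.25

    def test_large_diffusivity_substeps_evenly(self):
        stable, dt_sub = check_stability(1e4, (1.0, 1.0, 1.0), 0.25)
        assert not stable
        ratio = 0.25 / dt_sub
        assert abs(ratio - round(ratio)) < 1e-12
        assert dt_sub <= 1.0 / (2 * 1e4 * 3.0)

    def test_substepped_trajectory_consistency(self):
        # same stable problem integrated at dt and at a finer sub-step agrees
        state, domain, drugs, params = make_single_voxel(k=0.08)
        res_a = simulate(state, 0.0, 10.0, params, drugs, domain)
        fine_cfg = StudyConfig(dt=0.05)
        params_fine = ModelParameters(
            d0=0.0, k_map=params.k_map, theta=params.theta,
            alpha1=0.0, alpha2=0.0, beta1=0.1, beta2=0.1, mu=0.0, config=fine_cfg,
        )
        res_b = simulate(state, 0.0, 10.0, params_fine, drugs, domain)
        a = res_a.final.counts.values[0, 0, 0]
        b = res_b.final.counts.values[0, 0, 0]
        assert abs(a - b) / b < 0.005


class TestStep:
    def test_null_dynamics(self):
        state, domain, drugs, params = make_single_voxel()
        new, nclip = step(
            state, 0.0, 0.25, params, drugs, domain,
            d_field=np.zeros((1, 1, 1)), g_field=np.ones((1, 1, 1)),
        )
        np.testing.assert_array_equal(new.counts.values, state.counts.values)
        assert nclip == 0

    def test_logistic_closed_form(self):
        # k = 0.1/day, N0 = theta/2, 10 days: N/theta = e/(1+e)
        state, domain, drugs, params = make_single_voxel(k=0.1)
        res = simulate(state, 0.0, 10.0, params, drugs, domain)
        frac = res.final.counts.values[0, 0, 0] / params.theta
        exact = np.e / (1.0 + np.e)
        assert abs(frac - exact) / exact < 1e-3

    def test_drug_decay_closed_form(self):
        # k = 0, single dose: N(t) = N0 exp(-(alpha/beta)(1 - e^{-beta t}));
        # rates gentle enough for the explicit scheme to hit 0.1 %
        alpha, beta, t_end = 0.02, 0.02, 10.0
        state, domain, drugs, params = make_single_voxel(
            alpha1=alpha, beta1=beta, dose_times=(0.0,)
        )
        res = simulate(state, 0.0, t_end, params, drugs, domain)
        n0 = state.counts.values[0, 0, 0]
        exact = n0 * np.exp(-(alpha / beta) * (1.0 - np.exp(-beta * t_end)))
        num = res.final.counts.values[0, 0, 0]
        assert abs(num - exact) / exact < 1e-3

    def test_violent_reaction_is_clipped_not_divergent(self):
        state, domain, drugs, params = make_single_voxel(k=1e3)
        res = simulate(state, 0.0, 10.0, params, drugs, domain)
        assert res.clip_events > 0
        assert np.all(np.isfinite(res.final.counts.values))
        assert res.final.counts.values.max() <= params.theta

    def test_non_finite_state_raises(self):
        from her2forecast.grid import BreastDomain

        shape = (2, 1, 1)
        state = CellularityMap(
            ImageVolume(np.array([[[1e5]], [[0.0]]])), 1e6, np.ones(shape, bool)
        )
        domain = BreastDomain(ImageVolume(np.ones(shape)), ImageVolume(np.ones(shape)))
        sched = TreatmentSchedule((), 0.0, 10.0, 100.0)
        one = ImageVolume(np.ones(shape))
        drugs = DrugFieldSet(one, one, ImageVolume(np.zeros(shape)), sched)
        params = ModelParameters(
            d0=0.0, k_map=np.ones(shape), theta=1e6,
            alpha1=0.0, alpha2=0.0, beta1=0.1, beta2=0.1, mu=0.0,
        )
        with pytest.raises(FloatingPointError):
            step(state, 0.0, 0.25, params, drugs, domain,
                 d_field=np.zeros(shape), g_field=np.full(shape, np.inf))


class TestSimulate:
    def _phantom(self, breast_phantom_factory=None, d0=0.5, gamma=None):
        from her2forecast.synthetic import (
            SyntheticPatientSpec,
            generate_breast_domain,
            generate_scan1_cellularity,
        )

        cfg = StudyConfig() if gamma is None else StudyConfig(gamma=gamma)
        spec = SyntheticPatientSpec(
            shape=(16, 16, 16), spacing=(2.0, 2.0, 2.0),
            breast_semiaxes_mm=(13.0, 13.0, 13.0), tumor_radius_mm=6.0,
            seed=1, config=cfg,
        )
        domain = generate_breast_domain(spec)
        cells = generate_scan1_cellularity(spec, domain)
        cells = CellularityMap(cells.counts, spec.theta(), domain.mask_array)
        sched = TreatmentSchedule((), 0.0, 10.0, 100.0)
        zero = domain.mask.with_values(np.zeros(spec.shape))
        one = domain.mask.with_values(np.ones(spec.shape))
        drugs = DrugFieldSet(one, one, zero, sched)
        params = ModelParameters(
            d0=d0, k_map=np.zeros(spec.shape), theta=spec.theta(),
            alpha1=0.0, alpha2=0.0, beta1=0.1, beta2=0.1, mu=0.0, config=cfg,
        )
        return cells, domain, drugs, params, spec

    def test_no_flux_conservation(self):
        cells, domain, drugs, params, spec = self._phantom()
        res = simulate(cells, 0.0, 25.0, params, drugs, domain, mechanics_cadence=25)
        drift = abs(res.total_cellularity[-1] - res.total_cellularity[0])
        assert drift < 1e-6 * res.total_cellularity[0]
        assert res.clip_events == 0

    def test_state_bounded(self):
        cells, domain, drugs, params, spec = self._phantom()
        res = simulate(cells, 0.0, 10.0, params, drugs, domain, mechanics_cadence=10)
        assert res.final.counts.values.min() >= 0.0
        assert res.final.counts.values.max() <= params.theta

    def test_variant_equivalence_at_mu_zero(self):
        cells, domain, drugs, params, spec = self._phantom()
        a = simulate(cells, 0.0, 5.0, params, drugs, domain,
                     model_variant="mri", mechanics_cadence=5)
        b = simulate(cells, 0.0, 5.0, params, drugs, domain,
                     model_variant="pet_mri", mechanics_cadence=5)
        np.testing.assert_array_equal(a.final.counts.values, b.final.counts.values)

    def test_mu_monotonicity(self):
        # larger targeted effect never increases the final burden
        finals = []
        for mu in (0.0, 0.2, 0.4):
            state, domain, drugs, params = make_single_voxel(
                k=0.1, mu=mu, trastuzumab=1.0, dose_times=(0.0,)
            )
            res = simulate(state, 0.0, 20.0, params, drugs, domain,
                           model_variant="pet_mri")
            finals.append(res.final.total)
        assert finals[0] >= finals[1] >= finals[2]

    def test_heat_kernel_variance_growth(self):
        # diffusion-only Gaussian blob: per-axis variance grows by 2 D t
        shape = (33, 33, 33)
        h = 1.0
        cfg = StudyConfig(gamma=0.0)
        idx = np.indices(shape).astype(float)
        c = (np.asarray(shape) - 1) / 2.0
        sig0 = 2.5
        blob = 1e5 * np.exp(-((idx[0] - c[0]) ** 2 + (idx[1] - c[1]) ** 2
                              + (idx[2] - c[2]) ** 2) / (2 * sig0**2))
        from her2forecast.grid import BreastDomain

        domain = BreastDomain(ImageVolume(np.ones(shape)), ImageVolume(np.ones(shape)))
        cells = CellularityMap(ImageVolume(blob), 1e6, np.ones(shape, bool))
        sched = TreatmentSchedule((), 0.0, 10.0, 100.0)
        one = ImageVolume(np.ones(shape))
        drugs = DrugFieldSet(one, one, ImageVolume(np.zeros(shape)), sched)
        d0, t_end = 0.4, 5.0
        params = ModelParameters(
            d0=d0, k_map=np.zeros(shape), theta=1e6,
            alpha1=0.0, alpha2=0.0, beta1=0.1, beta2=0.1, mu=0.0, config=cfg,
        )
        res = simulate(cells, 0.0, t_end, params, drugs, domain)

        def variance(field):
            w = field / field.sum()
            mean = (w * idx[0]).sum()
            return (w * (idx[0] - mean) ** 2).sum()

        v0 = variance(blob)
        v1 = variance(res.final.counts.values)
        expected = v0 + 2 * d0 * t_end
        assert abs(v1 - expected) / expected < 0.02

    def test_time_grid_validation(self):
        state, domain, drugs, params = make_single_voxel()
        with pytest.raises(ValueError):
            simulate(state, 5.0, 5.0, params, drugs, domain)
        with pytest.raises(ValueError, match="multiple"):
            simulate(state, 0.0, 1.1, params, drugs, domain)
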