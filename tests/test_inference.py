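import numpy as np
import pytest

from geldiff import (
    HankelSolver,
    InitialCondition,
    Observations,
    QuadratureConfig,
    Transport,
    WeibullSource,
    bootstrap_ci,
    diffusivity_scale_estimate,
    fit_diffusivity,
    fit_initial_condition,
    initial_condition_profile,
    model_residuals,
    simulate_observations,
)
from geldiff.errors import BootstrapError, FitError, ParameterError

STUDY_RADII = np.array([2.475, 4.243, 6.790, 8.770, 11.170])


@pytest.fixture(scope="module")
def noiseless_obs(ref, fast_solver):
    src, ic, tr = ref
    return simulate_observations(src, ic, tr, STUDY_RADII,
                                 np.arange(0.0, 61.0), solver=fast_solver)


@pytest.fixture(scope="module")
def small_obs(ref, fast_solver):
    """Compact noisy dataset for the slower bootstrap/profile tests."""
    src, ic, tr = ref
    return simulate_observations(src, ic, tr, STUDY_RADII[:3],
                                 np.arange(0.0, 61.0, 6.0), noise_rel=0.05,
                                 seed=11, solver=fast_solver)


class TestObservations:
    def test_shape_mismatch_rejected(self):
        with pytest.raises(ParameterError, match="shape"):
            Observations(radii=[1.0, 2.0], times=[0.0, 1.0],
                         intensities=np.zeros((3, 2)))

    def test_non_monotone_axes_rejected(self):
        with pytest.raises(ParameterError, match="strictly increasing"):
            Observations(radii=[2.0, 1.0], times=[0.0, 1.0],
                         intensities=np.zeros((2, 2)))

    def test_csv_round_trip(self, tmp_path, noiseless_obs):
        path = tmp_path / "obs.csv"
        noiseless_obs.to_csv(path)
        back = Observations.from_csv(path)
        assert np.allclose(back.radii, noiseless_obs.radii)
        assert np.allclose(back.times, noiseless_obs.times)
        assert np.allclose(back.intensities, noiseless_obs.intensities)


class TestResiduals:
    def test_self_consistency(self, ref, fast_solver, noiseless_obs):
        src, ic, tr = ref
        res = model_residuals(noiseless_obs, src, ic, tr, solver=fast_solver)
        assert res.shape == (STUDY_RADII.size * 61,)
        assert np.linalg.norm(res) < 1e-4

    def test_offset_linearity(self, ref, fast_solver, noiseless_obs):
        src, ic, tr = ref
        shifted = Observations(noiseless_obs.radii, noiseless_obs.times,
                               noiseless_obs.intensities + 0.05)
        r0 = model_residuals(noiseless_obs, src, ic, tr, solver=fast_solver)
        r1 = model_residuals(shifted, src, ic, tr, solver=fast_solver)
        assert np.allclose(r1 - r0, 0.05)


class TestInitialConditionFit:
    def test_noiseless_self_recovery(self, ref):
        _, ic, _ = ref
        r = np.arange(0.0, 15.5, 0.5)
        fit = fit_initial_condition(r, initial_condition_profile(r, ic))
        for name, truth in (("c0", ic.c0), ("c1", ic.c1),
                            ("a", ic.a), ("alpha", ic.alpha)):
            assert fit.estimates[name] == pytest.approx(truth, rel=1e-3)
        assert fit.converged
        assert fit.initial_condition.alpha == pytest.approx(1.5, rel=1e-3)

    def test_flat_profile_flags_unidentifiable_decay(self):
        r = np.arange(0.0, 8.0, 1.0)
        fit = fit_initial_condition(r, np.full(r.size, 0.3))
        assert fit.estimates["c1"] == pytest.approx(0.0, abs=1e-6)
        assert any("unidentifiable" in w for w in fit.warnings)

    def test_too_few_radii_rejected(self):
        with pytest.raises(FitError, match="6 distinct"):
            fit_initial_condition([0.0, 1.0, 2.0], [0.9, 0.5, 0.3])

    def test_noisy_alpha_recovery_over_seeds(self, ref):
        # median recovered stretching power stays within 10% at 5% noise
        _, ic, _ = ref
        r = np.arange(0.0, 15.5, 0.5)
        clean = initial_condition_profile(r, ic)
        alphas = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            y = clean * (1.0 + rng.normal(0.0, 0.05, clean.size))
            alphas.append(fit_initial_condition(r, y).estimates["alpha"])
        assert np.median(alphas) == pytest.approx(1.5, rel=0.10)


class TestDiffusivityFit:
    def test_noiseless_self_recovery_from_doubled_start(
            self, ref, fast_solver, noiseless_obs):
        src, ic, tr = ref
        fit = fit_diffusivity(noiseless_obs, src, ic, init_D=2 * tr.D,
                              solver=fast_solver)
        assert fit.converged
        assert fit.estimates["D"] == pytest.approx(tr.D, rel=1e-3)

    def test_constant_observations_rejected(self, ref):
        src, ic, _ = ref
        obs = Observations(STUDY_RADII, np.arange(0.0, 11.0),
                           np.full((5, 11), 0.1))
        with pytest.raises(FitError, match="no diffusivity information"):
            fit_diffusivity(obs, src, ic, init_D=4.0)

    def test_rescaling_shifts_amplitudes_not_diffusivity(self, ref):
        # scaling all intensities by s must rescale fitted c1 and A by s
        # and leave D unchanged, when the amplitudes are co-fitted
        # (baseline-free data: c0 = 0)
        src, _, tr = ref
        ic0 = InitialCondition(c0=0.0, c1=0.8, a=0.16, alpha=1.5)
        solver = HankelSolver(src, ic0, None, QuadratureConfig.fast())
        obs = simulate_observations(src, ic0, tr, STUDY_RADII,
                                    np.arange(0.0, 61.0, 3.0),
                                    solver=HankelSolver(src, ic0, tr,
                                                        QuadratureConfig.fast()))
        s = 2.5
        scaled = Observations(obs.radii, obs.times, s * obs.intensities)
        free = ("D", "A", "c1")
        f1 = fit_diffusivity(obs, src, ic0, init_D=tr.D, free=free,
                             solver=solver)
        f2 = fit_diffusivity(scaled, src, ic0, init_D=tr.D, free=free,
                             solver=solver)
        assert f2.estimates["D"] == pytest.approx(f1.estimates["D"], rel=1e-3)
        assert f2.estimates["A"] == pytest.approx(s * f1.estimates["A"], rel=1e-2)
        assert f2.estimates["c1"] == pytest.approx(s * f1.estimates["c1"], rel=1e-2)

    def test_profile_likelihood_single_minimum(self, ref, fast_solver,
                                               small_obs):
        # RSS over a log-spaced D grid in [D/4, 4D] has one interior minimum
        src, ic, tr = ref
        grid = np.exp(np.linspace(np.log(tr.D / 4), np.log(4 * tr.D), 9))
        rss = [float(np.sum(model_residuals(
            small_obs, src, ic, Transport(D=d), solver=fast_solver) ** 2))
            for d in grid]
        k = int(np.argmin(rss))
        assert 0 < k < len(rss) - 1
        assert all(rss[i] > rss[i + 1] for i in range(k))
        assert all(rss[i] < rss[i + 1] for i in range(k, len(rss) - 1))

    def test_unknown_free_parameter_rejected(self, ref, noiseless_obs):
        src, ic, _ = ref
        with pytest.raises(ParameterError, match="cannot free"):
            fit_diffusivity(noiseless_obs, src, ic, init_D=4.0,
                            free=("D", "R"))


class TestBootstrap:
    def test_noiseless_interval_collapses(self, ref, fast_solver,
                                          noiseless_obs):
        src, ic, tr = ref
        fit = fit_diffusivity(noiseless_obs, src, ic, init_D=tr.D,
                              solver=fast_solver)
        ci = bootstrap_ci(noiseless_obs, src, ic, fit, n_boot=200, seed=5,
                          solver=fast_solver)
        level, lo, hi = ci["D"]
        assert level == 0.9
        assert hi - lo < 1e-3 * fit.estimates["D"]

    def test_seed_determinism_and_coverage_of_truth(self, ref, fast_solver,
                                                    small_obs):
        src, ic, tr = ref
        fit = fit_diffusivity(small_obs, src, ic, init_D=tr.D,
                              solver=fast_solver)
        ci1 = bootstrap_ci(small_obs, src, ic, fit, n_boot=200, seed=7,
                           solver=fast_solver)
        ci2 = bootstrap_ci(small_obs, src, ic, fit, n_boot=200, seed=7,
                           solver=fast_solver)
        assert ci1 == ci2
        level, lo, hi = ci1["D"]
        assert lo < hi
        assert lo < tr.D < hi  # truth inside the 90% interval at 5% noise

    def test_small_n_boot_rejected(self, ref, fast_solver, noiseless_obs):
        src, ic, tr = ref
        fit = fit_diffusivity(noiseless_obs, src, ic, init_D=tr.D,
                              solver=fast_solver)
        with pytest.raises(ParameterError, match="n_boot"):
            bootstrap_ci(noiseless_obs, src, ic, fit, n_boot=50)


class TestScaleEstimate:
    def test_study_scale_argument(self):
        # ~10 mm diffusive length over ~20 day characteristic time
        assert diffusivity_scale_estimate(10.0, 20.0) == pytest.approx(5.0)

    def test_positive_inputs_required(self):
        with pytest.raises(ParameterError):
            diffusivity_scale_estimate(-1.0, 5.0)
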