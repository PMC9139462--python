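"""Objective, multistart optimization and profile likelihood."""

import numpy as np
import pandas as pd
import pytest

import erbbsig as e
from erbbsig.estimation import (
    ObjectiveSpec,
    classify_and_reduce,
    multistart_fit,
    objective_chi2,
    profile_likelihood,
)


def _one_condition_dataset(comp, truth, offsets):
    """Noise-free single-condition dataset with chosen residual offsets.

    ``offsets`` maps (observable, time) -> shift added to the clean value.
    """
    cond = e.ConditionSpec("MCF7", "NRG1", ())
    times = (0.0, 90.0, 240.0)
    traj = e.simulate_condition(comp, truth.for_cell_line("MCF7"), cond,
                                times)
    y = e.observe(traj, truth.obs_map)
    rows = []
    for obs in truth.obs_map.observables:
        for i, t in enumerate(times):
            v = y[obs][i] + offsets.get((obs, t), 0.0)
            rows.append(("MCF7", "NRG1", "", obs, t, "merged", v))
    return e.TimeCourseDataset(pd.DataFrame(
        rows, columns=["cell_line", "ligand", "drug", "observable", "time",
                       "replicate", "value"]))


class TestObjectiveChi2:
    def test_perfect_fit_unit_sigma_gives_zero(self, comp, truth):
        ds = _one_condition_dataset(comp, truth, {})
        om = truth.obs_map.copy()
        for o in om.observables:
            om.sigma[o] = 1.0
        spec = ObjectiveSpec(ds, comp, om, truth.for_cell_line("MCF7"),
                             free_names=("bas_MEK",), sigma_mode="fixed",
                             rtol=1e-10, atol=1e-12)
        theta = spec.start_from_params()
        assert objective_chi2(theta, spec) == pytest.approx(0.0, abs=1e-8)

    def test_single_unit_residual(self, comp, truth):
        ds = _one_condition_dataset(comp, truth, {("pAKT", 90.0): 1.0})
        om = truth.obs_map.copy()
        for o in om.observables:
            om.sigma[o] = 1.0
        spec = ObjectiveSpec(ds, comp, om, truth.for_cell_line("MCF7"),
                             free_names=("bas_MEK",), sigma_mode="fixed",
                             rtol=1e-10, atol=1e-12)
        assert objective_chi2(spec.start_from_params(), spec) == \
            pytest.approx(1.0, abs=1e-7)

    def test_unit_residual_half_sigma(self, comp, truth):
        # one residual of 1 at sigma 0.5: 4 + 2 ln 0.5 = 2.6137...
        ds = _one_condition_dataset(comp, truth, {("pAKT", 90.0): 1.0})
        om = truth.obs_map.copy()
        for o in om.observables:
            om.sigma[o] = 1.0
        om.sigma["pAKT"] = 0.5
        spec = ObjectiveSpec(ds, comp, om, truth.for_cell_line("MCF7"),
                             free_names=("bas_MEK",), sigma_mode="fixed",
                             rtol=1e-10, atol=1e-12)
        expected = 4.0 + 2.0 * np.log(0.5) + 2 * 2 * np.log(0.5)
        # the two residual-free pAKT points also contribute 2 ln sigma each
        assert objective_chi2(spec.start_from_params(), spec) == \
            pytest.approx(expected, abs=1e-7)

    def test_free_sigma_parameter_matches_fixed(self, comp, truth):
        ds = _one_condition_dataset(comp, truth, {("pAKT", 90.0): 0.3})
        om = truth.obs_map.copy()
        for o in om.observables:
            om.sigma[o] = 1.0
        spec_fixed = ObjectiveSpec(ds, comp, om, truth.for_cell_line("MCF7"),
                                   free_names=("bas_MEK",),
                                   sigma_mode="fixed", rtol=1e-10, atol=1e-12)
        om2 = om.copy()
        spec_free = ObjectiveSpec(ds, comp, om2, truth.for_cell_line("MCF7"),
                                  free_names=("bas_MEK", "sigma_pAKT"),
                                  sigma_mode="fixed", rtol=1e-10, atol=1e-12)
        th_fixed = spec_fixed.start_from_params()
        th_free = np.concatenate([th_fixed, [0.0]])   # log10 sigma = 0 -> 1
        assert objective_chi2(th_free, spec_free) == pytest.approx(
            objective_chi2(th_fixed, spec_fixed), abs=1e-9)

    def test_profiled_sigma_is_the_argmin(self, comp, truth):
        ds = _one_condition_dataset(comp, truth, {("pAKT", 90.0): 0.3,
                                                  ("pAKT", 240.0): -0.2})
        base = truth.for_cell_line("MCF7")
        spec_prof = ObjectiveSpec(ds, comp, truth.obs_map, base,
                                  free_names=("bas_MEK",),
                                  sigma_mode="profile", rtol=1e-10,
                                  atol=1e-12)
        f_prof = objective_chi2(spec_prof.start_from_params(), spec_prof)
        spec_free = ObjectiveSpec(ds, comp, truth.obs_map, base,
                                  free_names=("bas_MEK",)
                                  + tuple(f"sigma_{o}"
                                          for o in truth.obs_map.observables),
                                  sigma_mode="fixed", rtol=1e-10, atol=1e-12)
        sig = spec_prof.residual_sd(spec_prof.start_from_params())
        th = np.concatenate([
            spec_prof.start_from_params(),
            [np.log10(max(sig[o], 1e-6))
             for o in truth.obs_map.observables]])
        assert objective_chi2(th, spec_free) == pytest.approx(f_prof,
                                                              abs=1e-9)
        # any other sigma is worse
        th_bad = th.copy()
        th_bad[1] += 0.3
        assert objective_chi2(th_bad, spec_free) > f_prof


class _Quadratic:
    """Convex toy objective with a known minimum."""

    def __init__(self, target, lower=-5.0, upper=5.0):
        self.target = np.asarray(target, dtype=float)
        n = len(self.target)
        self.free_names = tuple(f"p{i}" for i in range(n))
        self.lower = np.full(n, lower)
        self.upper = np.full(n, upper)

    def objective(self, theta, grad=True):
        d = np.asarray(theta) - self.target
        return float(d @ d), (2 * d if grad else None)


class TestMultistartFit:
    def test_recovers_quadratic_minimum(self):
        spec = _Quadratic([0.7, -1.3, 2.1])
        fit = multistart_fit(spec, n_starts=3, seed=1)
        np.testing.assert_allclose(fit.theta, spec.target, atol=1e-6)

    def test_deterministic_given_seed(self):
        spec = _Quadratic([0.5, 0.5])
        a = multistart_fit(spec, n_starts=4, seed=9)
        b = multistart_fit(spec, n_starts=4, seed=9)
        assert a.objective == b.objective
        np.testing.assert_array_equal(a.theta, b.theta)

    def test_best_of_k_monotone_for_nested_starts(self):
        class Bumpy(_Quadratic):
            def objective(self, theta, grad=True):
                d = np.asarray(theta) - self.target
                f = float(d @ d + 2 * np.sin(3 * theta[0]) ** 2)
                g = 2 * d
                g[0] += 12 * np.sin(3 * theta[0]) * np.cos(3 * theta[0])
                return f, (g if grad else None)

        spec = Bumpy([1.0, 0.0])
        best = [multistart_fit(spec, n_starts=k, seed=2).objective
                for k in (1, 2, 4, 8)]
        assert all(b2 <= b1 + 1e-12 for b1, b2 in zip(best, best[1:]))

    def test_ode_fit_beats_truth_objective(self, comp, truth, small_dataset):
        base = truth.for_cell_line("MCF7")
        free = ("bas_MEK", "dephos_ERK")
        spec = ObjectiveSpec(small_dataset, comp, truth.obs_map, base, free)
        th_truth = spec.start_from_params()
        f_truth = objective_chi2(th_truth, spec)
        fit = multistart_fit(spec, n_starts=1, seed=0, start=th_truth,
                             maxiter=60)
        assert fit.objective <= f_truth + 1e-9

    def test_all_starts_failed_raises(self):
        class Failing(_Quadratic):
            def objective(self, theta, grad=True):
                return 1e12, (np.zeros(len(theta)) if grad else None)

        with pytest.raises(RuntimeError, match="failed"):
            multistart_fit(Failing([0.0]), n_starts=2, seed=0)


class _GaussianMean:
    """-2 log L of n Gaussian draws: mean plus a nuisance parameter."""

    def __init__(self, data, sigma):
        self.data = np.asarray(data, dtype=float)
        self.sigma = sigma
        self.free_names = ("mu", "nu")
        self.lower = np.array([-10.0, -10.0])
        self.upper = np.array([10.0, 10.0])

    def objective(self, theta, grad=True):
        mu, nu = theta
        r = (self.data - mu) / self.sigma
        f = float(r @ r + (nu - 3.0) ** 2)
        g = np.array([-2 * r.sum() / self.sigma, 2 * (nu - 3.0)])
        return f, (g if grad else None)


class TestProfileLikelihood:
    def test_zero_delta_at_optimum(self):
        spec = _Quadratic([0.3, -0.4])
        fit = multistart_fit(spec, n_starts=2, seed=0)
        pr = profile_likelihood(fit, spec, "p0")
        i = np.argmin(np.abs(pr.theta_grid - fit.theta[0]))
        assert pr.delta[i] == pytest.approx(0.0, abs=1e-9)

    def test_gaussian_mean_ci_matches_closed_form(self):
        rng = np.random.default_rng(8)
        n, sigma = 50, 0.7
        data = 1.2 + sigma * rng.standard_normal(n)
        spec = _GaussianMean(data, sigma)
        fit = multistart_fit(spec, n_starts=2, seed=1)
        pr = profile_likelihood(fit, spec, "mu", step_init=0.02)
        half = 1.96 * sigma / np.sqrt(n)
        xbar = data.mean()
        assert pr.label == "identifiable"
        assert pr.ci_lower == pytest.approx(xbar - half, rel=0.01)
        assert pr.ci_upper == pytest.approx(xbar + half, rel=0.01)

    def test_degenerate_scale_pair_is_structural(self):
        class ScalePair:
            # only the sum theta1 + theta2 (log of a product) is constrained
            free_names = ("log_a", "log_b")
            lower = np.array([-3.0, -3.0])
            upper = np.array([3.0, 3.0])

            def objective(self, theta, grad=True):
                d = theta[0] + theta[1] - 0.8
                f = float(d * d)
                return f, (np.array([2 * d, 2 * d]) if grad else None)

        spec = ScalePair()
        fit = multistart_fit(spec, n_starts=1, seed=0,
                             start=np.array([0.4, 0.4]))
        pr_a = profile_likelihood(fit, spec, "log_a")
        pr_b = profile_likelihood(fit, spec, "log_b")
        assert pr_a.label == "structurally non-identifiable"
        assert pr_b.label == "structurally non-identifiable"
        # flat except where the compensating partner saturates at its bound
        assert np.nanmedian(pr_a.delta) < 1e-9
        assert not np.isfinite(pr_a.ci_lower) and not np.isfinite(pr_a.ci_upper)

        report = classify_and_reduce([pr_a, pr_b])
        assert len(report) == 2
        assert all("fix" in a for a in report["suggested_action"])
        assert "log_b" in report.iloc[0]["suggested_action"]

    def test_identifiable_parameters_give_empty_report(self):
        spec = _Quadratic([0.0, 1.0])
        fit = multistart_fit(spec, n_starts=1, seed=0)
        profiles = [profile_likelihood(fit, spec, n)
                    for n in spec.free_names]
        assert all(p.label == "identifiable" for p in profiles)
        assert len(classify_and_reduce(profiles)) == 0

    def test_one_flat_profile_one_entry(self):
        class OneFlat(_Quadratic):
            def objective(self, theta, grad=True):
                d = theta[0] - 0.5
                return float(d * d), (np.array([2 * d, 0.0])
                                      if grad else None)

        spec = OneFlat([0.5, 0.0])
        fit = multistart_fit(spec, n_starts=1, seed=0,
                             start=np.array([0.5, 0.0]))
        profiles = [profile_likelihood(fit, spec, n) for n in spec.free_names]
        report = classify_and_reduce(profiles)
        assert list(report["parameter"]) == ["p1"]


class TestGradientCheck:
    def test_sensitivity_gradient_matches_finite_differences(
            self, comp, truth, small_dataset):
        """ODE sensitivity gradients agree with central differences."""
        base = truth.for_cell_line("MCF7")
        free = ("act_cRAF_dimers", "bas_MEK", "phos_S6K_AKT", "k_cetuximab",
                "dim_23_NRG1", "total_MEK", "dephos_AKT", "bas_PI3K")
        spec = ObjectiveSpec(small_dataset, comp, truth.obs_map, base, free,
                             rtol=1e-10, atol=1e-13)
        th0 = spec.start_from_params()
        rng = np.random.default_rng(17)
        h = 1e-4
        for _ in range(10):
            th = th0 + rng.uniform(-0.2, 0.2, size=len(free))
            f, g = spec.objective(th)
            j = rng.integers(len(free))
            tp, tm = th.copy(), th.copy()
            tp[j] += h
            tm[j] -= h
            fp, _ = spec.objective(tp, grad=False)
            fm, _ = spec.objective(tm, grad=False)
            fd = (fp - fm) / (2 * h)
            assert fd == pytest.approx(g[j], rel=1e-4, abs=1e-4 * abs(f))
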