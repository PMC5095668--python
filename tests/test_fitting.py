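"""Exponential-decay fitting and the two-stage constrained search."""

import numpy as np
import pytest
from dataclasses import replace

from mitoswitch import fitting, population, synthetic
from mitoswitch.errors import ValidationError
from mitoswitch.fitting import FitProblem, default_bounds, fit, fit_decay, objective

GRID = np.linspace(0.0, 48.0, 33)


def quadrature_targets(truth, knockdown=0.2):
    conditions = {
        "control": truth,
        "mcl1kd": replace(truth, knockdown_m=knockdown),
        "bclxlkd": replace(truth, knockdown_x=knockdown),
    }
    return {
        cond: population.survival_curve_quadrature(pop, GRID, label=cond)
        for cond, pop in conditions.items()
    }


def truth_parameters(truth, knockdown=0.2):
    return {
        "mu_m": truth.mu_m, "sigma_m": truth.sigma_m,
        "mu_x": truth.mu_x, "sigma_x": truth.sigma_x,
        "sigma_b": truth.sigma_b, "tau_M": truth.tau_M, "tau_X": truth.tau_X,
        "theta_ref": truth.theta_ref,
        "knockdown_m": knockdown, "knockdown_x": knockdown,
    }


class TestFitDecay:
    def test_noiseless_recovery_is_exact(self):
        t = np.array([0.0, 2.0, 4.0, 8.0])
        a0, tau = fit_decay(t, 2.0 * np.exp(-t / 4.0))
        assert a0 == pytest.approx(2.0, abs=1e-6)
        assert tau == pytest.approx(4.0, abs=1e-6)

    def test_half_life_conversion(self):
        t = np.array([0.0, 1.0, 2.0, 3.0])
        _, half = fit_decay(t, np.exp(-t / 4.0), return_half_life=True)
        assert half == pytest.approx(4.0 * np.log(2.0), rel=1e-6)

    def test_constant_series_pins_tau_at_upper_bound(self):
        t = np.array([0.0, 1.0, 2.0, 3.0])
        with pytest.warns(RuntimeWarning):
            _, tau = fit_decay(t, np.ones_like(t))
        assert tau == fitting.TAU_UPPER

    def test_too_few_points_rejected(self):
        with pytest.raises(ValidationError):
            fit_decay([0.0, 1.0], [1.0, 0.5])


class TestObjective:
    def test_self_consistency_at_generating_parameters(self, default_pop):
        problem = FitProblem(curves=quadrature_targets(default_pop),
                             bounds=default_bounds(), quad_nodes=24)
        sse = objective(truth_parameters(default_pop), problem)
        assert 0.0 <= sse < 1e-6

    def test_perturbation_sensitivity_follows_dominance(self):
        """Raising mu_x by 10% hurts the fit more in a Bcl-xL-dominant line
        than in an Mcl-1-dominant one (knockdown-asymmetry mirror)."""
        x_dom = population.CellLinePopulation(
            mu_m=np.log(5.0), sigma_m=0.4, mu_x=np.log(3.0), sigma_x=0.4,
            sigma_b=0.2, tau_M=2.0, tau_X=24.0, theta_ref=1.0,
        )
        m_dom = population.CellLinePopulation(
            mu_m=np.log(60.0), sigma_m=0.4, mu_x=np.log(0.05), sigma_x=0.4,
            sigma_b=0.2, tau_M=2.0, tau_X=24.0, theta_ref=1.0,
        )
        deltas = {}
        for name, truth in (("x_dom", x_dom), ("m_dom", m_dom)):
            problem = FitProblem(curves=quadrature_targets(truth),
                                 bounds=default_bounds(), quad_nodes=24)
            base = truth_parameters(truth)
            bumped = dict(base, mu_x=base["mu_x"] + np.log(1.1))
            deltas[name] = objective(bumped, problem) - objective(base, problem)
        assert deltas["x_dom"] > deltas["m_dom"]

    def test_unknown_condition_rejected(self, default_pop):
        curve = population.survival_curve_quadrature(default_pop, GRID)
        with pytest.raises(ValidationError):
            FitProblem(curves={"mystery": curve}, bounds=default_bounds())

    def test_unbounded_unfixed_parameter_rejected(self, default_pop):
        bounds = default_bounds()
        del bounds["tau_X"]
        with pytest.raises(ValidationError):
            FitProblem(curves=quadrature_targets(default_pop), bounds=bounds)


class TestFit:
    def make_problem(self, default_pop, **kw):
        bounds = default_bounds()
        bounds["mu_m"] = (default_pop.mu_m - 0.7, default_pop.mu_m + 0.7)
        bounds["mu_x"] = (default_pop.mu_x - 0.7, default_pop.mu_x + 0.7)
        bounds["tau_M"] = (1.6, 2.5)
        del bounds["theta_ref"]
        return FitProblem(curves=quadrature_targets(default_pop),
                          bounds=bounds, fixed={"theta_ref": 1.0},
                          quad_nodes=16, **kw)

    def test_seed_determinism(self, default_pop):
        problem = self.make_problem(default_pop)
        a = fit(problem, n_random=40, n_starts=2, seed=3, max_iter=15)
        b = fit(problem, n_random=40, n_starts=2, seed=3, max_iter=15)
        assert a.parameters == b.parameters
        assert a.sse == b.sse

    def test_descent_is_monotone(self, default_pop):
        problem = self.make_problem(default_pop)
        result = fit(problem, n_random=60, n_starts=2, seed=5, max_iter=40)
        sses = [s for _, s in result.trace]
        assert all(b <= a + 1e-15 for a, b in zip(sses, sses[1:]))
        assert result.sse >= 0.0

    def test_collapsed_bounds_return_the_point(self, default_pop):
        bounds = {k: (v, v) for k, v in truth_parameters(default_pop).items()
                  if k != "theta_ref"}
        problem = FitProblem(curves=quadrature_targets(default_pop),
                             bounds=bounds, fixed={"theta_ref": 1.0},
                             quad_nodes=16)
        result = fit(problem, n_random=5, n_starts=1, seed=1, max_iter=10)
        assert result.parameters["mu_m"] == pytest.approx(default_pop.mu_m)
        assert result.sse < 1e-6

    def test_invalid_budgets_rejected(self, default_pop):
        problem = self.make_problem(default_pop)
        with pytest.raises(ValidationError):
            fit(problem, n_random=2, n_starts=5, seed=1)

    def test_restart_table_is_complete(self, default_pop):
        problem = self.make_problem(default_pop)
        result = fit(problem, n_random=30, n_starts=3, seed=7, max_iter=10)
        assert len(result.restarts) == 3
        assert (result.restarts["final_sse"] <= result.restarts["initial_sse"]).all()
        assert "sse" in result.to_text()


class TestIdentifiability:
    @staticmethod
    def noisy_curves(master_seed, default_pop, n_cells=2000):
        """Exit-corrected curves from synthetic fate tables, per condition."""
        from mitoswitch import empirical

        conditions = {
            "control": (default_pop, 0),
            "mcl1kd": (replace(default_pop, knockdown_m=0.2), 1),
            "bclxlkd": (replace(default_pop, knockdown_x=0.2), 2),
        }
        curves = {}
        for cond, (pop, offset) in conditions.items():
            gt = synthetic.GroundTruth(pop=pop, seed=master_seed * 10 + offset)
            tab = synthetic.generate_fates(gt, n_cells)
            est = empirical.estimate_hazards(tab, 0.5)
            curve = empirical.corrected_survival(est, label=cond)
            keep = np.isfinite(curve.fraction) & (curve.times <= 48.0)
            curves[cond] = population.SurvivalCurve(
                curve.times[keep], curve.fraction[keep], label=cond
            )
        return curves

    def test_knockdown_conditions_break_ratio_degeneracy(self, default_pop):
        """On noisy exit-corrected curves with realistic (wide) bounds for
        the spreads and decay constants, fitting the control curve alone
        confounds the two inhibitor medians; adding the two knockdown
        curves shrinks the (mu_m, mu_x) recovery error by at least 2x
        (median over replicates)."""
        bounds = {
            "mu_m": (default_pop.mu_m - 1.2, default_pop.mu_m + 1.2),
            "mu_x": (default_pop.mu_x - 1.2, default_pop.mu_x + 1.2),
            "sigma_m": (0.05, 1.5),
            "sigma_x": (0.05, 1.5),
            "tau_M": (1.8, 2.2),       # half-life measurement constraint
            "tau_X": (4.0, 100.0),
        }
        fixed = {"sigma_b": default_pop.sigma_b, "theta_ref": 1.0,
                 "knockdown_m": 0.2, "knockdown_x": 0.2}

        errors = {"control_only": [], "with_knockdowns": []}
        for master_seed in (21, 22, 23):
            targets = self.noisy_curves(master_seed, default_pop)
            for label, curves in (
                ("control_only", {"control": targets["control"]}),
                ("with_knockdowns", targets),
            ):
                problem = FitProblem(curves=curves, bounds=bounds,
                                     fixed=fixed, quad_nodes=16)
                result = fit(problem, n_random=400, n_starts=3, seed=17,
                             max_iter=100)
                err = 0.5 * (
                    abs(result.parameters["mu_m"] - default_pop.mu_m)
                    + abs(result.parameters["mu_x"] - default_pop.mu_x)
                )
                errors[label].append(err)
        assert np.median(errors["control_only"]) >= 2.0 * np.median(
            errors["with_knockdowns"]
        )
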