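"""MAP estimation and diagnostics tests.

Exact parameter recovery is not expected of a MAP estimator — the prior
pulls the estimate toward zero by an amount set by the data's information
content — so these tests check the estimator's defining properties:
optimality of the returned minimum, the shrinkage limits, invariances,
and unbiasedness on average over a simulated cohort.
"""

import numpy as np
import pytest

from meropk import (
    CovariateSet,
    DosingRegimen,
    OptimizerSettings,
    PopPKParams,
    conc_profile,
    fit_cohort,
    fit_diagnostics,
    fit_map,
    generate_cohort,
    individual_params,
    map_objective,
)
from meropk.bayes_fit import ObservationSet
from meropk.synthetic import CohortSpec
from .conftest import NINE_POINT_SCHEDULE


def make_obs(pop, cov, regimen, eta, noise_rng=None, sigma=None,
             times=NINE_POINT_SCHEDULE, pid="P1"):
    ind = individual_params(pop, cov, np.asarray(eta, float))
    y = conc_profile(ind, regimen, times)
    if noise_rng is not None:
        y = y * (1 + noise_rng.normal(0, sigma, times.size))
    return ObservationSet(
        patient_id=pid,
        times=np.asarray(times, float),
        concentrations=y,
        sites=np.array(["systemic"] * len(times), dtype=object),
        regimen=regimen,
        covariates=cov,
    )


def brute_objective(eta, obs, pop):
    """Independent re-implementation of the MAP objective as a plain loop."""
    ind = individual_params(pop, obs.covariates, eta)
    total = 0.0
    omegas = [pop.omega_cl, pop.omega_v1, pop.omega_v2]
    for t, y, site in zip(obs.times, obs.concentrations, obs.sites):
        if site not in ("systemic", "pre_filter") or y <= 0:
            continue
        f = float(conc_profile(ind, obs.regimen, [t])[0])
        var = (pop.sigma_prop * f) ** 2
        total += (y - f) ** 2 / var + np.log(var)
    for e, w in zip(eta, omegas):
        total += e**2 / w**2
    return total


class TestObjective:
    def test_matches_brute_force_reimplementation(self, pop, template_cov,
                                                  regimen_q8h):
        rng = np.random.default_rng(3)
        obs = make_obs(pop, template_cov, regimen_q8h, [0.1, -0.2, 0.4],
                       noise_rng=rng, sigma=pop.sigma_prop)
        for _ in range(5):
            eta = rng.normal(0, 0.3, 3)
            assert map_objective(eta, obs, pop) == pytest.approx(
                brute_objective(eta, obs, pop), rel=1e-10
            )

    def test_perfect_fit_zeroes_residual_part(self, pop, template_cov,
                                              regimen_q8h):
        obs = make_obs(pop, template_cov, regimen_q8h, np.zeros(3))
        f = conc_profile(individual_params(pop, template_cov, np.zeros(3)),
                         regimen_q8h, obs.times)
        ln_var = float(np.sum(np.log((pop.sigma_prop * f) ** 2)))
        # at eta = 0 the prior is 0 and residuals vanish: only ln-var remains
        assert map_objective(np.zeros(3), obs, pop) == pytest.approx(ln_var)

    def test_prior_term_is_one_at_one_omega(self, pop, template_cov,
                                            regimen_q8h):
        obs = make_obs(pop, template_cov, regimen_q8h, np.zeros(3))

        def prior_part(eta):
            return map_objective(eta, obs, pop) - brute_data_only(eta)

        def brute_data_only(eta):
            return brute_objective(eta, obs, pop) - float(
                np.sum(np.asarray(eta) ** 2 / pop.omegas**2)
            )

        assert prior_part(np.array([pop.omega_cl, 0, 0])) == pytest.approx(1.0)

    def test_zero_record_and_postfilter_excluded(self, pop, template_cov,
                                                 regimen_q8h):
        obs = ObservationSet(
            patient_id="P1",
            times=np.array([3.0, 5.0, 8.0]),
            concentrations=np.array([20.0, 0.0, 10.0]),
            sites=np.array(["systemic", "systemic", "post_filter"],
                           dtype=object),
            regimen=regimen_q8h,
            covariates=template_cov,
        )
        assert obs.fitting_mask().tolist() == [True, False, False]


class TestFitMap:
    def test_empty_observations_return_prior_mode(self, pop, template_cov,
                                                  regimen_q8h):
        obs = ObservationSet("P0", np.array([]), np.array([]),
                             np.array([], dtype=object), regimen_q8h,
                             template_cov)
        fit = fit_map(obs, pop)
        np.testing.assert_array_equal(fit.eta_hat, np.zeros(3))
        assert fit.individual.cl == pytest.approx(
            individual_params(pop, template_cov, np.zeros(3)).cl
        )

    def test_all_unusable_observations_rejected(self, pop, template_cov,
                                                regimen_q8h):
        obs = ObservationSet(
            "P0", np.array([3.0]), np.array([12.0]),
            np.array(["post_filter"], dtype=object), regimen_q8h,
            template_cov,
        )
        with pytest.raises(ValueError):
            fit_map(obs, pop)

    def test_estimate_is_a_genuine_minimum(self, pop, template_cov,
                                           regimen_q8h):
        obs = make_obs(pop, template_cov, regimen_q8h, [0.2, -0.1, 0.3])
        fit = fit_map(obs, pop)
        assert fit.converged
        # better than both the init and the generating parameters
        assert fit.objective_value <= map_objective(np.zeros(3), obs, pop)
        assert fit.objective_value <= map_objective(
            np.array([0.2, -0.1, 0.3]), obs, pop
        )
        # local perturbations do not improve it
        rng = np.random.default_rng(0)
        for _ in range(20):
            trial = fit.eta_hat + rng.normal(0, 0.02, 3)
            assert map_objective(trial, obs, pop) >= fit.objective_value - 1e-9

    def test_multistart_agreement(self, pop, template_cov, regimen_q8h):
        rng = np.random.default_rng(9)
        obs = make_obs(pop, template_cov, regimen_q8h, [0.3, 0.1, -0.5],
                       noise_rng=rng, sigma=pop.sigma_prop)
        fits = [
            fit_map(obs, pop, OptimizerSettings(seed=s))
            for s in (1, 2, 3)
        ]
        objs = [f.objective_value for f in fits]
        assert max(objs) - min(objs) < 1e-6

    def test_noise_free_recovery_up_to_shrinkage(self, pop, template_cov,
                                                 regimen_q8h):
        # MAP shrinkage bounds exact recovery; the estimate must stay close
        # to the generating eta and reproduce the data almost exactly
        eta_true = np.array([0.2, -0.1, 0.3])
        obs = make_obs(pop, template_cov, regimen_q8h, eta_true)
        fit = fit_map(obs, pop)
        assert np.all(np.abs(fit.eta_hat - eta_true) < 0.1)
        rel_misfit = np.abs(fit.predictions - obs.concentrations)
        rel_misfit /= obs.concentrations
        assert rel_misfit.max() < 0.05

    def test_scale_invariance_dose_and_observations(self, pop, template_cov,
                                                    regimen_q8h):
        rng = np.random.default_rng(21)
        obs = make_obs(pop, template_cov, regimen_q8h, [0.1, 0.2, -0.3],
                       noise_rng=rng, sigma=pop.sigma_prop)
        scaled = ObservationSet(
            obs.patient_id, obs.times, 2.0 * obs.concentrations, obs.sites,
            DosingRegimen(2 * regimen_q8h.dose, regimen_q8h.interval,
                          regimen_q8h.infusion_duration),
            template_cov,
        )
        f1, f2 = fit_map(obs, pop), fit_map(scaled, pop)
        assert np.allclose(f1.eta_hat, f2.eta_hat, atol=1e-5)

    def test_shrinkage_to_prior_mode_as_omega_vanishes(self, template_cov,
                                                       regimen_q8h):
        tight = PopPKParams(omega_cl=1e-4, omega_v1=1e-4, omega_v2=1e-4)
        obs = make_obs(tight, template_cov, regimen_q8h, [0.3, 0.3, 0.3])
        fit = fit_map(obs, tight)
        assert np.all(np.abs(fit.eta_hat) < 1e-3)

    def test_approaches_els_estimate_as_prior_widens(self, template_cov):
        # 2-point toy fit: the MAP estimate must walk toward the grid-search
        # optimum of the no-prior (extended least squares) objective as the
        # prior widens
        reg = DosingRegimen(1000, 8, 3)
        base = PopPKParams()
        cov = template_cov
        rng = np.random.default_rng(4)
        times = np.array([3.0, 8.0])
        obs0 = make_obs(base, cov, reg, [0.35, 0.0, 0.0], noise_rng=rng,
                        sigma=base.sigma_prop, times=times)

        def els_objective(eta_cl):
            ind = individual_params(base, cov, np.array([eta_cl, 0, 0]))
            f = conc_profile(ind, reg, times)
            var = (base.sigma_prop * f) ** 2
            return float(
                np.sum((obs0.concentrations - f) ** 2 / var + np.log(var))
            )

        grid = np.linspace(-1.2, 1.2, 4801)
        eta_els = grid[np.argmin([els_objective(g) for g in grid])]
        gaps = []
        for w in (0.3, 0.6, 0.99):
            pop_w = PopPKParams(omega_cl=w, omega_v1=1e-4, omega_v2=1e-4)
            fit = fit_map(obs0, pop_w)
            gaps.append(abs(fit.eta_hat[0] - eta_els))
        assert gaps[0] > gaps[1] > gaps[2]
        assert gaps[2] < 0.02

    def test_mean_bias_small_over_simulated_cohort(self, pop, template_cov,
                                                   regimen_q8h):
        """Over 50 noisy simulated patients the eta estimates are unbiased
        on average (mean bias within +/-0.05 per component) and the fitted
        clearances span the clinically reported range."""
        rng = np.random.default_rng(11)
        errs = []
        for i in range(50):
            eta = rng.normal(0, pop.omegas)
            obs = make_obs(pop, template_cov, regimen_q8h, eta,
                           noise_rng=rng, sigma=pop.sigma_prop,
                           pid=f"P{i}")
            errs.append(fit_map(obs, pop).eta_hat - eta)
        bias = np.mean(errs, axis=0)
        assert np.all(np.abs(bias) < 0.05)

    def test_fitted_clearances_span_clinical_range(self):
        spec = CohortSpec(n=50, seed=3)
        patients = generate_cohort(spec)
        fits = fit_cohort([p.observations for p in patients], spec.pop)
        cls = np.array([f.individual.cl for f in fits])
        assert cls.min() < 3.0 and cls.max() > 9.0


class TestDiagnostics:
    def test_identity_pairs(self):
        d = fit_diagnostics([10.0, 20.0], [10.0, 20.0])
        assert d.rmse == 0.0 and d.mape == 0.0 and d.r2 == 1.0

    def test_hand_worked_values(self):
        # |10-12|/10 = 20% and |20-20|/20 = 0% -> MAPE 10%
        d = fit_diagnostics([10.0, 20.0], [12.0, 20.0])
        assert d.mape == pytest.approx(10.0)
        assert d.rmse == pytest.approx(np.sqrt(2.0))
        assert d.frac_within_2sd == 1.0
        assert d.n_points == 2

    def test_requires_two_pairs(self):
        with pytest.raises(ValueError):
            fit_diagnostics([10.0], [10.0])
        with pytest.raises(ValueError):
            fit_diagnostics([0.0, 10.0], [1.0, 10.0])
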