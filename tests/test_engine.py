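"""FOCE estimation engine: likelihood limits, EBEs, shrinkage, CWRES."""

import math
from dataclasses import replace

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

import vancopk as v
from vancopk import engine
from vancopk.model import ResidualModel


def _one_subject_table(n_obs=10, eta=0.0, seed=5, sd0=2.187):
    """Richly sampled single subject simulated from the published model."""
    rng = np.random.default_rng(seed)
    cov = v.Covariates(BBW=3.22, PNA=29.0)
    doses = tuple(v.DoseEvent(8.0 * k, 45.0, 1.0) for k in range(6))
    times = np.sort(rng.uniform(1.0, 47.0, size=n_obs))
    sp = v.FINAL_MODEL.structural_params(cov, {"CL": eta})
    c = np.atleast_1d(v.concentration(times, list(doses), sp))
    y = np.maximum(c + rng.standard_normal(n_obs) * sd0, 1.0)
    obs = tuple(v.Observation(float(t), float(yy)) for t, yy in zip(times, y))
    return v.EventTable.from_subjects([v.SubjectData("R1", doses, obs, cov)]), sp


class TestOfvLimits:
    def test_zero_iiv_limit_is_least_squares_deviance(self):
        """With omega -> 0 the marginal collapses to the fixed-effect Gaussian."""
        table, _ = _one_subject_table()
        model = v.FINAL_MODEL.with_values(omCL=1e-8)
        got = v.ofv(model, table, condition_on_quantifiable=False)
        subj = next(iter(table.iter_subjects()))
        sp = v.FINAL_MODEL.structural_params(subj.covariates)
        pred = np.atleast_1d(v.concentration(subj.times, list(subj.doses), sp))
        rss = float(np.sum((subj.concs - pred) ** 2))
        sigma2 = 2.187**2
        expected = len(pred) * math.log(2 * math.pi * sigma2) + rss / sigma2
        assert got == pytest.approx(expected, rel=1e-6)

    def test_linear_mixed_model_closed_form(self, rng):
        """For predictions linear in eta the FOCE objective is the exact
        marginal Gaussian -2 log-likelihood."""
        S, q = 6, 1
        omega2 = np.array([0.4**2])
        sd0 = 0.7
        residual = ResidualModel("additive", sd0=sd0)
        n_per = rng.integers(2, 5, size=S)
        obs_subj = np.repeat(np.arange(S), n_per)
        N = len(obs_subj)
        a = rng.uniform(5, 15, size=N)
        b = rng.uniform(0.5, 2.0, size=N)
        y = a + b * rng.normal(0, math.sqrt(omega2[0]), size=S)[obs_subj]
        y += rng.normal(0, sd0, size=N)

        def predict(eta):
            return a + b * eta[obs_subj, 0]

        eta, f, G, var, conv = engine.conditional_modes(
            predict, y, obs_subj, S, omega2, residual
        )
        assert conv.all()
        foce = float(np.sum(engine.foce_ofv_terms(
            y, f, G, var, eta, obs_subj, S, omega2
        )))
        laplace = float(np.sum(engine.laplace_ofv_terms(
            y, f, G, var, eta, obs_subj, S, omega2
        )))
        exact = 0.0
        for s in range(S):
            idx = obs_subj == s
            V = np.outer(b[idx], b[idx]) * omega2[0] + np.eye(idx.sum()) * sd0**2
            r = y[idx] - a[idx]
            _, logdet = np.linalg.slogdet(V)
            exact += (
                idx.sum() * math.log(2 * math.pi)
                + logdet
                + float(r @ np.linalg.solve(V, r))
            )
        assert foce == pytest.approx(exact, rel=1e-6)
        assert laplace == pytest.approx(exact, rel=1e-6)

    def test_true_parameters_beat_perturbed_clearance(self):
        for seed in (31, 32, 33):
            table = v.simulate_cohort(v.CohortSpec(n_subjects=150, seed=seed))
            truth = v.ofv(v.FINAL_MODEL, table)
            off = v.ofv(v.FINAL_MODEL, table, params={"tvCL": 0.42 * 1.5})
            assert truth < off

    def test_deterministic_given_data_and_params(self, cohort60):
        assert v.ofv(v.FINAL_MODEL, cohort60) == v.ofv(v.FINAL_MODEL, cohort60)


class TestOfvInvariances:
    def test_invariant_to_subject_order(self, cohort60):
        frame = cohort60.frame
        ids = cohort60.subject_ids
        reordered = v.EventTable(
            frame.set_index("subject_id").loc[ids[::-1]].reset_index()
        )
        assert v.ofv(v.FINAL_MODEL, reordered) == pytest.approx(
            v.ofv(v.FINAL_MODEL, cohort60), abs=1e-8
        )

    def test_invariant_to_time_origin_shift(self, cohort60):
        shifted = cohort60.frame.copy()
        shifted["time"] += 5.0
        assert v.ofv(v.FINAL_MODEL, v.EventTable(shifted)) == pytest.approx(
            v.ofv(v.FINAL_MODEL, cohort60), abs=1e-8
        )

    def test_spurious_covariate_never_raises_minimized_ofv(self, cohort60):
        base_fit = v.fit(v.FINAL_MODEL, cohort60, compute_se=False)
        bigger = replace(
            base_fit.model,
            effects=base_fit.model.effects
            + (v.CovariateEffect("CL", "ALB", 0.0, reference=33.1),),
        )
        full_fit = v.fit(bigger, cohort60, compute_se=False)
        assert full_fit.ofv <= base_fit.ofv + 1e-6


class TestFit:
    def test_zero_iiv_data_shrinks_omega(self):
        gen = replace(v.FINAL_MODEL, iiv={"CL": 0.0})
        table = v.simulate_cohort(v.CohortSpec(n_subjects=60, model=gen, seed=9))
        fr = v.fit(v.FINAL_MODEL, table, compute_se=False)
        assert fr.estimates["omCL"] <= 0.05

    def test_degenerate_dataset_raises_identifiability_error(self):
        table, _ = _one_subject_table(n_obs=1)
        with pytest.raises(v.IdentifiabilityError):
            v.fit(v.FINAL_MODEL, table)

    def test_estimates_table_has_wald_intervals(self, fit100):
        tab = fit100.to_table()
        assert set(tab.columns) == {"parameter", "estimate", "se", "ci95_lo", "ci95_hi"}
        assert len(tab) == 8


class TestEbe:
    def test_no_observations_returns_prior_mode(self):
        subj = v.SubjectData(
            "empty", (v.DoseEvent(0, 40, 1),), (), v.Covariates(BBW=3.2, PNA=20)
        )
        assert v.ebe(v.FINAL_MODEL, subj) == {"CL": 0.0}

    def test_rich_subject_recovers_positive_eta(self):
        table, sp = _one_subject_table(n_obs=12, eta=0.3, seed=11)
        subj = next(iter(table.iter_subjects()))
        eta_hat = v.ebe(v.FINAL_MODEL, subj)["CL"]
        assert 0.0 < eta_hat < 0.6
        sp_hat = v.FINAL_MODEL.structural_params(subj.covariates, {"CL": eta_hat})
        ipred = np.atleast_1d(v.concentration(subj.times, list(subj.doses), sp_hat))
        rmse = float(np.sqrt(np.mean((subj.concs - ipred) ** 2)))
        assert rmse < 2.187

    def test_flat_prior_limit_is_least_squares(self):
        table, _ = _one_subject_table(n_obs=12, eta=0.3, seed=11)
        subj = next(iter(table.iter_subjects()))
        model = v.FINAL_MODEL.with_values(omCL=50.0)
        eta_hat = v.ebe(model, subj, condition_on_quantifiable=False)["CL"]

        def rss(eta):
            sp = v.FINAL_MODEL.structural_params(subj.covariates, {"CL": eta})
            pred = np.atleast_1d(v.concentration(subj.times, list(subj.doses), sp))
            return float(np.sum((subj.concs - pred) ** 2))

        ls = minimize_scalar(rss, bounds=(-2, 2), method="bounded").x
        assert eta_hat == pytest.approx(ls, abs=1e-3)


class TestShrinkage:
    def test_all_zero_ebes_give_full_shrinkage(self):
        assert v.shrinkage(np.zeros(20), 0.3) == 1.0

    def test_sd_equal_omega_gives_zero(self, rng):
        etas = rng.normal(0, 1, size=500)
        etas = etas / np.std(etas, ddof=1) * 0.3
        assert v.shrinkage(etas, 0.3) == pytest.approx(0.0, abs=1e-12)

    def test_sparser_sampling_shrinks_more(self):
        rich = v.CohortSpec(
            n_subjects=60, seed=77, samples_pmf=(0, 0, 0, 0, 0, 1.0)
        )
        sparse = v.CohortSpec(
            n_subjects=60, seed=77, samples_pmf=(1.0, 0, 0, 0, 0, 0)
        )
        shr = {}
        for name, spec in (("rich", rich), ("sparse", sparse)):
            table = v.simulate_cohort(spec)
            etas = v.ebes(v.FINAL_MODEL, table)["CL"].to_numpy()
            shr[name] = v.shrinkage(etas, 0.317)
        assert shr["sparse"] > shr["rich"]


class TestCwres:
    def test_no_iiv_reduction_to_standardized_residuals(self):
        table, _ = _one_subject_table(n_obs=8, seed=3)
        model = v.FINAL_MODEL.with_values(omCL=1e-8)
        space = engine.ParameterSpace.from_model(model)
        obj = engine._Objective(model, engine.compile_dataset(table), space)
        _, det = obj.evaluate(space.pack(model), details=True)
        tab = engine._prediction_table(engine.compile_dataset(table), det, ("CL",))
        np.testing.assert_allclose(
            tab["CWRES"], (tab["DV"] - tab["PRED"]) / 2.187, atol=1e-5
        )

    def test_calibrated_under_true_model(self, fit316):
        cw = v.cwres(fit316)
        assert abs(np.mean(cw)) < 0.1
        assert 0.85 < np.std(cw) < 1.15

    def test_repeat_extraction_identical(self, fit100):
        np.testing.assert_array_equal(v.cwres(fit100), v.cwres(fit100))
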