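"""Structural kinetics, covariate model and residual-error model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

import vancopk as v
from vancopk.model import ResidualModel, apply_residual


# ---------------------------------------------------------------------------
# covariate model


class TestIndividualParam:
    def test_reference_covariates_return_typical_clearance(self, ref_cov):
        assert v.individual_param(v.FINAL_MODEL, "CL", ref_cov, 0.0) == pytest.approx(0.42)

    def test_exponential_eta_scaling(self, ref_cov):
        val = v.individual_param(v.FINAL_MODEL, "CL", ref_cov, math.log(2.0))
        assert val == pytest.approx(0.84)

    def test_power_covariate_evaluation(self):
        cov = v.Covariates(BBW=3.9, PNA=23.0)
        expected = 0.42 * (3.9 / 3.22) ** 0.888 * (23 / 29) ** 0.449
        got = v.individual_param(v.FINAL_MODEL, "CL", cov, 0.0)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(0.4487, abs=5e-5)

    def test_no_effects_returns_typical_value(self, ref_cov):
        for p, tv in (("V1", 1.27), ("V2", 2.422), ("Q", 1.161)):
            assert v.individual_param(v.FINAL_MODEL, p, ref_cov, 0.0) == tv

    def test_missing_covariate_names_the_covariate(self):
        with pytest.raises(KeyError, match="PNA"):
            v.individual_param(v.FINAL_MODEL, "CL", v.Covariates(BBW=3.0), 0.0)

    def test_nonpositive_continuous_covariate_rejected(self):
        with pytest.raises(ValueError, match="BBW"):
            v.individual_param(v.FINAL_MODEL, "CL", v.Covariates(BBW=-1.0, PNA=29), 0.0)

    def test_categorical_effect_is_log_linear(self, ref_cov):
        model = v.PopulationModel(
            typical={"V1": 1.0, "V2": 1.0, "CL": 1.0, "Q": 1.0},
            effects=(v.CovariateEffect("CL", "furosemide", -0.3, kind="categorical"),),
        )
        on = v.Covariates(furosemide=1.0)
        off = v.Covariates(furosemide=0.0)
        assert v.individual_param(model, "CL", on, 0.0) == pytest.approx(math.exp(-0.3))
        assert v.individual_param(model, "CL", off, 0.0) == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# disposition


class TestDisposition:
    def test_quadratic_root_oracle(self, final_sp):
        alpha, beta, A, B = v.disposition(final_sp)
        k10, k12, k21 = final_sp.k10, final_sp.k12, final_sp.k21
        roots = np.roots([1.0, -(k10 + k12 + k21), k10 * k21])
        assert alpha == pytest.approx(max(roots), rel=1e-12)
        assert beta == pytest.approx(min(roots), rel=1e-12)
        assert alpha == pytest.approx(1.644, abs=5e-4)
        assert beta == pytest.approx(0.103, abs=5e-4)

    def test_one_compartment_limit(self):
        sp = v.StructuralParams(V1=2.0, V2=0.0, CL=0.5, Q=0.0)
        alpha, beta, A, B = v.disposition(sp)
        assert alpha == pytest.approx(0.25)
        assert B == 0.0
        # bolus-like short infusion decays mono-exponentially
        dose = v.DoseEvent(0.0, 10.0, 1e-6)
        c = v.concentration(np.array([1.0, 3.0]), [dose], sp)
        assert c[0] == pytest.approx(10.0 / 2.0 * math.exp(-0.25 * 1.0), rel=1e-4)
        assert c[1] / c[0] == pytest.approx(math.exp(-0.25 * 2.0), rel=1e-6)

    @settings(max_examples=50, deadline=None)
    @given(
        v1=st.floats(0.2, 10), v2=st.floats(0.2, 10),
        cl=st.floats(0.05, 5), q=st.floats(0.05, 5),
    )
    def test_vieta_identities(self, v1, v2, cl, q):
        sp = v.StructuralParams(V1=v1, V2=v2, CL=cl, Q=q)
        alpha, beta, A, B = v.disposition(sp)
        assert alpha > beta > 0
        assert alpha * beta == pytest.approx(sp.k10 * sp.k21, rel=1e-12)
        assert alpha + beta == pytest.approx(sp.k10 + sp.k12 + sp.k21, rel=1e-12)
        assert A + B == pytest.approx(1.0 / v1, rel=1e-9)


# ---------------------------------------------------------------------------
# concentration-time course


def _ode_concentration(times, doses, sp):
    """Piecewise ODE integration oracle for the two-compartment infusion model."""
    k10, k12, k21 = sp.k10, sp.k12, sp.k21

    def rhs(t, y, rate):
        a1, a2 = y
        return [rate - (k10 + k12) * a1 + k21 * a2, k12 * a1 - k21 * a2]

    breaks = sorted(
        {0.0, *times}
        | {d.start_time for d in doses}
        | {d.start_time + d.infusion_duration for d in doses}
    )
    y = np.zeros(2)
    out = {}
    for lo, hi in zip(breaks, breaks[1:]):
        rate = sum(
            d.amount / d.infusion_duration
            for d in doses
            if d.start_time <= lo < d.start_time + d.infusion_duration
        )
        sol = solve_ivp(
            rhs, (lo, hi), y, args=(rate,), rtol=1e-11, atol=1e-12,
            dense_output=True, method="LSODA",
        )
        for t in times:
            if lo < t <= hi:
                out[t] = sol.sol(t)[0] / sp.V1
        y = sol.y[:, -1]
    for t in times:
        if t <= breaks[0]:
            out[t] = 0.0
    return np.array([out[t] for t in times])


class TestConcentration:
    def test_no_doses_is_zero(self, final_sp):
        assert v.concentration(5.0, [], final_sp) == 0.0

    def test_negative_time_rejected(self, final_sp):
        with pytest.raises(ValueError):
            v.concentration(-1.0, [v.DoseEvent(0, 10, 1)], final_sp)

    def test_linearity_in_dose(self, final_sp):
        doses = [v.DoseEvent(0, 35, 1), v.DoseEvent(8, 35, 1)]
        double = [v.DoseEvent(0, 70, 1), v.DoseEvent(8, 70, 1)]
        t = np.linspace(0.25, 20, 40)
        np.testing.assert_allclose(
            v.concentration(t, double, final_sp),
            2.0 * v.concentration(t, doses, final_sp),
            rtol=1e-12,
        )

    def test_superposition_of_single_doses(self, final_sp):
        doses = [v.DoseEvent(8.0 * k, 35.0, 1.0) for k in range(4)]
        t = np.linspace(0.5, 40, 60)
        total = v.concentration(t, doses, final_sp)
        summed = sum(v.concentration(t, [d], final_sp) for d in doses)
        np.testing.assert_allclose(total, summed, rtol=1e-10)

    def test_rises_monotonically_during_infusion(self, final_sp):
        doses = [v.DoseEvent(0, 35, 1), v.DoseEvent(8, 35, 1)]
        t = np.linspace(8.01, 9.0, 25)
        c = v.concentration(t, doses, final_sp)
        assert np.all(np.diff(c) > 0)

    def test_decays_to_zero_after_last_dose(self, final_sp):
        doses = [v.DoseEvent(0, 35, 1)]
        assert v.concentration(500.0, doses, final_sp) < 1e-12

    def test_matches_ode_oracle_on_randomized_regimens(self, rng):
        for _ in range(30):
            sp = v.StructuralParams(
                V1=rng.uniform(0.5, 4), V2=rng.uniform(0.5, 6),
                CL=rng.uniform(0.1, 1.5), Q=rng.uniform(0.1, 3),
            )
            tau = rng.choice([6.0, 8.0, 12.0])
            dur = rng.uniform(0.5, 2.0)
            doses = [
                v.DoseEvent(k * tau, rng.uniform(10, 80), dur) for k in range(3)
            ]
            times = np.sort(rng.uniform(0.1, 3 * tau, size=5))
            closed = v.concentration(times, doses, sp)
            ode = _ode_concentration(times, doses, sp)
            np.testing.assert_allclose(closed, ode, rtol=1e-6, atol=1e-10)

    def test_steady_state_accumulation_is_geometric(self, final_sp):
        """Trough before dose n approaches the steady-state trough monotonically."""
        tau, amt = 8.0, 35.0
        troughs = []
        for n in (3, 6, 12, 24, 60):
            doses = [v.DoseEvent(k * tau, amt, 1.0) for k in range(n - 1)]
            troughs.append(v.concentration((n - 1) * tau, doses, final_sp))
        assert np.all(np.diff(troughs) > 0)
        # remaining distance to SS shrinks like e^{-beta n tau}
        _, beta, _, _ = v.disposition(final_sp)
        ss = troughs[-1]
        gap6 = ss - troughs[1]
        gap12 = ss - troughs[2]
        assert gap12 / gap6 == pytest.approx(math.exp(-beta * 6 * tau), rel=0.15)


# ---------------------------------------------------------------------------
# residual error


class TestResidualModel:
    def test_additive_zero_eps_identity(self):
        res = ResidualModel("additive", sd0=2.187)
        assert apply_residual(10.0, res, 0.0) == 10.0

    def test_additive_variance_is_constant(self):
        res = ResidualModel("additive", sd0=2.187)
        np.testing.assert_allclose(
            res.variance(np.array([0.0, 10.0, 30.0])), 2.187**2
        )
        assert res.variance(5.0) == pytest.approx(4.783, abs=5e-4)

    def test_combined_variance_algebra(self):
        res = ResidualModel("combined", cv=0.1, sd0=1.0)
        assert res.variance(10.0) == pytest.approx((10 * 0.1) ** 2 + 1.0)
        # independent draws: var of simulated values matches the formula
        rng = np.random.default_rng(0)
        sims = apply_residual(
            np.full(200_000, 10.0), res,
            rng.standard_normal(200_000), rng.standard_normal(200_000),
        )
        assert np.var(sims) == pytest.approx(2.0, rel=0.02)

    def test_proportional_scales_with_prediction(self):
        res = ResidualModel("proportional", cv=0.2)
        assert apply_residual(10.0, res, 1.0) == pytest.approx(12.0)
        assert res.variance(10.0) == pytest.approx(4.0)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            ResidualModel("exponential", sd0=1.0)


# ---------------------------------------------------------------------------
# misc


class TestWeightNormalized:
    def test_median_clearance_per_kg(self):
        assert v.weight_normalized(0.42, 3.95) == pytest.approx(0.106, abs=5e-4)

    def test_total_distribution_volume_per_kg(self):
        assert v.weight_normalized(1.27 + 2.422, 3.95) == pytest.approx(0.935, abs=5e-4)

    def test_zero_value(self):
        assert v.weight_normalized(0.0, 3.95) == 0.0

    def test_nonpositive_weight_rejected(self):
        with pytest.raises(ValueError):
            v.weight_normalized(1.0, 0.0)


class TestModelSpecFile:
    def test_packaged_final_model_round_trips(self, tmp_path):
        assert v.final_model() == v.FINAL_MODEL
        path = tmp_path / "m.yaml"
        v.save_model_spec(v.FINAL_MODEL, path)
        assert v.load_model_spec(path) == v.FINAL_MODEL

    def test_final_model_constants(self):
        m = v.FINAL_MODEL
        assert m.typical == {"V1": 1.27, "V2": 2.422, "CL": 0.42, "Q": 1.161}
        assert m.iiv == {"CL": 0.317}
        assert m.residual == ResidualModel("additive", sd0=2.187)
        assert {(e.covariate, e.exponent, e.reference) for e in m.effects} == {
            ("BBW", 0.888, 3.22), ("PNA", 0.449, 29.0),
        }
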