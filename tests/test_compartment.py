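"""Compartment-model simulation, fitting, AIC and model comparison."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from petkin.compartment import (
    CompartmentModel,
    KineticParams,
    akaike,
    compare_models,
    fit_compartment_model,
    simulate_1tc,
    simulate_2tc,
)
from petkin.input_function import BiexpParams, evaluate_input
from petkin.simulate import default_frame_times, make_lesion_tac
from petkin.tac import TimeActivityCurve

INPUT = BiexpParams(amplitude=800.0, frac_fast=0.25, t_half_fast=0.71, t_half_slow=8.4)
# well-identified reference rates for fitting tests
RATES_2TC = KineticParams(0.5, 0.5, 0.3, 0.1, "2TCMR")


def ode_oracle(params: KineticParams, input_params: BiexpParams, times):
    """Stiff-safe numerical integration of the compartment ODEs."""

    def rhs(t, y):
        cp = evaluate_input(input_params, t)
        c1, c2 = y
        dc1 = params.k1 * cp - (params.k2 + params.k3) * c1 + params.k4 * c2
        dc2 = params.k3 * c1 - params.k4 * c2
        return [dc1, dc2]

    sol = solve_ivp(
        rhs, (0.0, times[-1]), [0.0, 0.0], t_eval=times, method="LSODA",
        rtol=1e-10, atol=1e-12,
    )
    return sol.y.sum(axis=0)


class TestSimulate:
    def test_one_tissue_matches_ode_oracle(self):
        t = np.linspace(0.5, 60, 60)
        p = KineticParams(0.4, 0.25, model_order="1TCMR")
        analytic = simulate_1tc(p, INPUT, t).values
        numeric = ode_oracle(p, INPUT, t)
        np.testing.assert_allclose(analytic, numeric, rtol=1e-3)

    @pytest.mark.parametrize("seed", range(5))
    def test_two_tissue_matches_ode_oracle_random_rates(self, seed):
        rng = np.random.default_rng(seed)
        p = KineticParams(
            rng.uniform(0.05, 1.0), rng.uniform(0.05, 1.0),
            rng.uniform(0.01, 0.8), rng.uniform(0.02, 0.5), "2TCMR",
        )
        t = np.linspace(0.5, 60, 60)
        analytic = simulate_2tc(p, INPUT, t).values
        numeric = ode_oracle(p, INPUT, t)
        np.testing.assert_allclose(analytic, numeric, rtol=1e-3)

    def test_two_tissue_reduces_to_one_tissue_at_k3_zero(self):
        t = np.linspace(0.25, 60, 100)
        p2 = KineticParams(0.5, 0.3, 0.0, 0.0, "2TCMR")
        p1 = KineticParams(0.5, 0.3, model_order="1TCMR")
        a = simulate_2tc(p2, INPUT, t).values
        b = simulate_1tc(p1, INPUT, t).values
        np.testing.assert_allclose(a, b, rtol=1e-10)

    def test_constant_input_plateau_is_vd_times_input(self):
        """With a constant input the tissue curve plateaus at Vd * c."""
        c = 10.0
        t_in = np.linspace(0, 2000, 40)
        const = TimeActivityCurve(t_in, np.full_like(t_in, c))
        t = np.linspace(1, 2000, 50)
        p1 = KineticParams(0.5, 0.25, model_order="1TCMR")
        out1 = simulate_1tc(p1, const, t).values
        assert out1[-1] == pytest.approx(p1.vd * c, rel=1e-4)
        p2 = KineticParams(0.5, 0.25, 0.3, 0.1, "2TCMR")
        out2 = simulate_2tc(p2, const, t).values
        assert out2[-1] == pytest.approx(p2.vd * c, rel=1e-3)

    def test_sampled_input_agrees_with_analytic_biexp(self):
        """Exact per-segment convolution of a finely sampled input matches
        the closed-form biexponential convolution."""
        t_in = np.linspace(0, 60, 3000)
        sampled = TimeActivityCurve(t_in, evaluate_input(INPUT, t_in))
        t = np.linspace(0.5, 59.5, 40)
        a = simulate_2tc(RATES_2TC, INPUT, t).values
        b = simulate_2tc(RATES_2TC, sampled, t).values
        np.testing.assert_allclose(a, b, rtol=2e-3)

    def test_increasing_k3_never_decreases_late_uptake(self):
        t, _ = default_frame_times()
        late = []
        for k3 in [0.0, 0.1, 0.2, 0.4, 0.8]:
            p = KineticParams(0.5, 0.5, k3, 0.1, "2TCMR")
            late.append(simulate_2tc(p, INPUT, t).values[-1])
        assert np.all(np.diff(late) >= 0)

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            KineticParams(0.5, 0.0, model_order="1TCMR")
        # irreversible trapping (k4=0 with k3>0) is a valid simulation mode
        # with an infinite binding potential
        assert KineticParams(0.5, 0.5, 0.3, 0.0, "2TCMR").bp == np.inf
        with pytest.raises(ValueError):
            KineticParams(0.5, 0.5, -0.1, 0.1, "2TCMR")

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        k2=st.floats(0.01, 5.0), k3=st.floats(0.0, 5.0), k4=st.floats(0.01, 5.0)
    )
    def test_eigenrates_always_real_nonnegative(self, k2, k3, k4):
        """(k2+k3+k4)^2 - 4 k2 k4 = (k2-k4)^2 + k3^2 + 2 k3 (k2+k4) >= 0."""
        p = KineticParams(0.5, k2, k3, k4, "2TCMR")
        terms = p.impulse_response_terms()
        for _, theta in terms:
            assert np.isreal(theta) and theta >= 0


class TestDerivedMeasures:
    def test_vd_bp_identities_exact(self):
        p = KineticParams(0.5, 0.5, 0.3, 0.1, "2TCMR")
        assert p.bp == 0.3 / 0.1
        assert p.vd == (0.5 / 0.5) * (1 + p.bp)
        p1 = KineticParams(0.5, 0.25, model_order="1TCMR")
        assert p1.vd == 2.0 and p1.bp == 0.0


class TestAkaike:
    def test_ln_e_identity(self):
        n = 24
        assert akaike(np.e * n, n, 0) == pytest.approx(n)

    def test_parameter_penalty_linearity(self):
        base = akaike(10.0, 24, 2)
        assert akaike(10.0, 24, 4) - base == pytest.approx(4.0)

    def test_exhaustive_ranking_consistency(self):
        """Ranking three candidates by AIC equals all pairwise comparisons."""
        fits = [(12.0, 2), (9.0, 4), (8.9, 6)]
        aics = [akaike(rss, 24, p) for rss, p in fits]
        order = np.argsort(aics)
        for i in range(3):
            for j in range(3):
                pairwise = aics[i] < aics[j]
                ranked = list(order).index(i) < list(order).index(j)
                if aics[i] != aics[j]:
                    assert pairwise == ranked

    def test_error_paths(self):
        with pytest.raises(ValueError):
            akaike(0.0, 10, 2)
        with pytest.raises(ValueError):
            akaike(1.0, 2, 4)


class TestFit:
    def test_noiseless_2tc_parameter_recovery(self):
        """Rates (0.5, 0.5, 0.3, 0.1) recovered within 1%; BP=3, Vd=4."""
        t, _ = default_frame_times()
        tac = simulate_2tc(RATES_2TC, INPUT, t)
        fit = fit_compartment_model(tac, INPUT, "2TCMR")
        assert fit.params.k1 == pytest.approx(0.5, rel=0.01)
        assert fit.params.k2 == pytest.approx(0.5, rel=0.01)
        assert fit.params.k3 == pytest.approx(0.3, rel=0.01)
        assert fit.params.k4 == pytest.approx(0.1, rel=0.01)
        assert fit.bp == pytest.approx(3.0, rel=0.01)
        assert fit.vd == pytest.approx(4.0, rel=0.01)

    def test_noiseless_1tc_vd_identity(self):
        t, _ = default_frame_times()
        p = KineticParams(0.4, 0.2, model_order="1TCMR")
        tac = simulate_1tc(p, INPUT, t)
        fit = fit_compartment_model(tac, INPUT, "1TCMR")
        assert fit.vd == pytest.approx(p.vd, rel=1e-4)
        assert fit.vd == fit.params.k1 / fit.params.k2  # exact identity

    def test_noisy_median_bp_within_ten_percent(self):
        """5% noise, 50 seeded replicates: median recovered BP near truth."""
        t, durations = default_frame_times()
        clean = simulate_2tc(RATES_2TC, INPUT, t)
        bps = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            noisy = np.maximum(
                clean.values * (1 + 0.05 * rng.standard_normal(t.size)), 0.0
            )
            tac = TimeActivityCurve(t, noisy, frame_durations=durations)
            bps.append(fit_compartment_model(tac, INPUT, "2TCMR").bp)
        assert np.median(bps) == pytest.approx(3.0, rel=0.10)

    def test_flat_curve_rejected(self):
        t, _ = default_frame_times()
        tac = TimeActivityCurve(t, np.full_like(t, 5.0))
        with pytest.raises(ValueError, match="flat"):
            fit_compartment_model(tac, INPUT, "2TCMR")

    def test_too_few_points_rejected(self):
        tac = TimeActivityCurve([1, 2, 3, 4, 5], [1, 2, 3, 2, 1])
        with pytest.raises(ValueError):
            fit_compartment_model(tac, INPUT, "2TCMR")


class TestCompare:
    def test_two_tissue_data_prefers_2tcmr(self):
        """2TC data with distinct k3, k4 and realistic noise: the two-tissue
        model wins the AIC comparison in >= 90% of replicates."""
        t, durations = default_frame_times()
        clean = simulate_2tc(RATES_2TC, INPUT, t)
        wins = 0
        n_rep = 25
        for seed in range(n_rep):
            rng = np.random.default_rng(1000 + seed)
            noisy = np.maximum(
                clean.values * (1 + 0.05 * rng.standard_normal(t.size)), 0.0
            )
            tac = TimeActivityCurve(t, noisy, frame_durations=durations)
            f1 = fit_compartment_model(tac, INPUT, "1TCMR")
            f2 = fit_compartment_model(tac, INPUT, "2TCMR")
            if compare_models(f1, f2).preferred == "2TCMR":
                wins += 1
        assert wins >= 0.9 * n_rep

    def test_one_tissue_data_prefers_1tcmr(self):
        """1TC data: the extra parameters of the 2TCMR are penalized."""
        t, durations = default_frame_times()
        p = KineticParams(0.4, 0.2, model_order="1TCMR")
        clean = simulate_1tc(p, INPUT, t)
        wins = 0
        n_rep = 15
        for seed in range(n_rep):
            rng = np.random.default_rng(2000 + seed)
            noisy = np.maximum(
                clean.values * (1 + 0.05 * rng.standard_normal(t.size)), 0.0
            )
            tac = TimeActivityCurve(t, noisy, frame_durations=durations)
            f1 = fit_compartment_model(tac, INPUT, "1TCMR")
            f2 = fit_compartment_model(tac, INPUT, "2TCMR")
            if compare_models(f1, f2).preferred == "1TCMR":
                wins += 1
        assert wins > n_rep / 2

    def test_tie_reported_explicitly(self):
        from petkin.compartment import KineticFitResult

        p = KineticParams(0.5, 0.5, model_order="1TCMR")
        f = KineticFitResult(params=p, rss=1.0, aic=10.0, n_points=24, converged=True)
        assert compare_models(f, f).preferred == "tie"

    def test_mismatched_point_counts_rejected(self):
        from petkin.compartment import KineticFitResult

        p = KineticParams(0.5, 0.5, model_order="1TCMR")
        f1 = KineticFitResult(params=p, rss=1.0, aic=10.0, n_points=24, converged=True)
        f2 = KineticFitResult(params=p, rss=1.0, aic=10.0, n_points=20, converged=True)
        with pytest.raises(ValueError, match="point counts"):
            compare_models(f1, f2)


class TestEstimatorApi:
    def test_fit_exposes_rate_attributes(self):
        t, _ = default_frame_times()
        tac = simulate_2tc(RATES_2TC, INPUT, t)
        est = CompartmentModel(input_function=INPUT, order="2TCMR")
        est.fit(t, tac.values)
        assert est.bp_ == pytest.approx(3.0, rel=0.01)
        assert est.vd_ == pytest.approx(4.0, rel=0.01)
        np.testing.assert_allclose(est.predict(t), tac.values, rtol=1e-3)

    def test_get_set_params(self):
        est = CompartmentModel(order="1TCMR")
        assert est.get_params()["order"] == "1TCMR"
        est.set_params(order="2TCMR", input_function=INPUT)
        assert est.get_params()["order"] == "2TCMR"
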