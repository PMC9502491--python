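"""Structural model: closed forms vs independent numerical oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from scipy.integrate import quad, solve_ivp
from scipy.optimize import minimize_scalar

from nebpk.structural import (
    PKParams,
    Regimen,
    REGIMEN_PRESETS,
    conc_regimen,
    conc_single_dose,
    interval_metrics,
    micro_constants,
    parse_regimen,
)

positive = st.floats(min_value=1e-3, max_value=1e3, allow_nan=False,
                     allow_infinity=False)


def params_strategy():
    return st.builds(PKParams, tlag=positive, ka=positive, cl=positive,
                     v1=positive, q=positive, v2=positive)


class TestMicroConstants:
    def test_sum_and_product_identities(self, final_params):
        mc = micro_constants(final_params)
        assert mc.lambda1 > mc.lambda2 > 0
        np.testing.assert_allclose(mc.lambda1 + mc.lambda2,
                                   mc.k10 + mc.k12 + mc.k21, rtol=1e-12)
        np.testing.assert_allclose(mc.lambda1 * mc.lambda2,
                                   mc.k10 * mc.k21, rtol=1e-12)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(params=params_strategy())
    def test_identities_hold_for_any_valid_params(self, params):
        mc = micro_constants(params)
        np.testing.assert_allclose(mc.lambda1 + mc.lambda2,
                                   mc.k10 + mc.k12 + mc.k21, rtol=1e-10)
        np.testing.assert_allclose(mc.lambda1 * mc.lambda2,
                                   mc.k10 * mc.k21, rtol=1e-10)

    def test_one_compartment_collapse_as_q_vanishes(self, final_params):
        p = final_params.scaled(q=1e-10 / final_params.q)
        mc = micro_constants(p)
        np.testing.assert_allclose(mc.lambda1, p.cl / p.v1, rtol=1e-6)
        assert mc.lambda2 == pytest.approx(0.0, abs=1e-9)

    def test_exponents_match_eigenvalue_oracle(self, final_params):
        """lambdas are the negated eigenvalues of the disposition rate matrix."""
        mc = micro_constants(final_params)
        a = np.array([[-(mc.k10 + mc.k12), mc.k21],
                      [mc.k12, -mc.k21]])
        eig = np.sort(-np.linalg.eigvals(a))
        np.testing.assert_allclose([mc.lambda2, mc.lambda1], eig[::-1][::-1],
                                   rtol=1e-10)

    def test_nonpositive_parameter_rejected(self):
        with pytest.raises(ValueError, match="strictly positive"):
            PKParams(tlag=0.3, ka=2.0, cl=-0.2, v1=4.2, q=0.6, v2=7.1)
        with pytest.raises(ValueError):
            PKParams(tlag=0.3, ka=np.inf, cl=0.2, v1=4.2, q=0.6, v2=7.1)


def _ode_profile(t_grid, dose, p: PKParams):
    """Stiff ODE integration of the 3-state system (independent oracle)."""
    mc = micro_constants(p)

    def rhs(t, y):
        depot, central, periph = y
        return [
            -p.ka * depot,
            p.ka * depot - (mc.k10 + mc.k12) * central + mc.k21 * periph,
            mc.k12 * central - mc.k21 * periph,
        ]

    shifted = np.maximum(t_grid - p.tlag, 0.0)
    uniq = np.unique(shifted)
    sol = solve_ivp(rhs, (0.0, float(uniq[-1])), [dose, 0.0, 0.0],
                    method="LSODA", rtol=1e-10, atol=1e-12, t_eval=uniq)
    lookup = dict(zip(uniq, sol.y[1] / p.v1))
    c = np.array([lookup[s] for s in shifted])
    return np.where(t_grid > p.tlag, c, 0.0)


class TestSingleDose:
    def test_zero_before_and_at_lag(self, final_params):
        assert conc_single_dose(0.0, 5.0, final_params) == 0.0
        assert conc_single_dose(final_params.tlag, 5.0, final_params) == 0.0

    def test_agrees_with_stiff_ode_oracle(self, final_params):
        t = np.linspace(0.0, 72.0, 289)
        closed = conc_single_dose(t, 5.0, final_params)
        ode = _ode_profile(t, 5.0, final_params)
        scale = closed.max()
        np.testing.assert_allclose(closed / scale, ode / scale, atol=1e-6)

    def test_auc_infinity_equals_dose_over_cl(self, final_params):
        auc, err = quad(lambda t: conc_single_dose(t, 5.0, final_params),
                        0.0, np.inf, limit=400)
        np.testing.assert_allclose(auc, 5.0 / final_params.cl, rtol=1e-6)

    def test_continuity_at_ka_degeneracy(self, final_params):
        """ka numerically equal to a disposition exponent: perturbed, continuous."""
        mc = micro_constants(final_params)
        t = np.linspace(0.5, 48.0, 97)
        exact_lambda = final_params.scaled(ka=mc.lambda1 / final_params.ka)
        near = PKParams(tlag=final_params.tlag, ka=mc.lambda1 * (1 + 1e-5),
                        cl=final_params.cl, v1=final_params.v1,
                        q=final_params.q, v2=final_params.v2)
        c_deg = conc_single_dose(t, 5.0, exact_lambda)
        c_near = conc_single_dose(t, 5.0, near)
        assert np.all(np.isfinite(c_deg))
        np.testing.assert_allclose(c_deg, c_near, rtol=1e-3)

    def test_terminal_slope_is_minus_lambda2(self, final_params):
        mc = micro_constants(final_params)
        t = np.linspace(200.0, 400.0, 201)
        c = conc_single_dose(t, 5.0, final_params)
        slope = stats.linregress(t, np.log(c)).slope
        np.testing.assert_allclose(slope, -mc.lambda2, rtol=1e-6)

    def test_vanishes_at_long_times(self, final_params):
        assert conc_single_dose(5000.0, 5.0, final_params) < 1e-12

    def test_negative_time_rejected(self, final_params):
        with pytest.raises(ValueError):
            conc_single_dose(-1.0, 5.0, final_params)


class TestRegimen:
    def test_single_dose_regimen_equals_single_dose(self, final_params):
        r = Regimen(dose=5.0, interval=24.0, n_doses=1)
        t = np.linspace(0, 48, 50)
        np.testing.assert_array_equal(conc_regimen(t, r, final_params),
                                      conc_single_dose(t, 5.0, final_params))

    def test_dose_linearity(self, final_params):
        r1 = Regimen(dose=5.0, interval=24.0, n_doses=10)
        r2 = Regimen(dose=10.0, interval=24.0, n_doses=10)
        t = np.linspace(0, 240, 100)
        np.testing.assert_allclose(2 * conc_regimen(t, r1, final_params),
                                   conc_regimen(t, r2, final_params), rtol=1e-12)

    def test_steady_state_accumulation_vs_brute_force(self, final_params):
        """Each exponential term accumulates by 1/(1 - exp(-lambda tau))."""
        mc = micro_constants(final_params)
        tau = 24.0
        n = 200
        t_obs = np.array([(n - 1) * tau + 12.0])
        brute = conc_regimen(t_obs, Regimen(5.0, tau, n), final_params)[0]

        from nebpk.structural import _biexp_coeffs
        (l1, l2, ka), (a1, a2, a3) = _biexp_coeffs(final_params)
        tp = 12.0 - final_params.tlag
        ss = 0.0
        for lam, coef in ((l1, a1), (l2, a2), (ka, a3)):
            ss += coef * np.exp(-lam * tp) / (1.0 - np.exp(-lam * tau))
        ss *= 5.0 * ka / final_params.v1
        np.testing.assert_allclose(brute, ss, rtol=1e-8)

    def test_time_shift_invariance_of_superposition(self, final_params):
        r = Regimen(dose=5.0, interval=24.0, n_doses=3)
        t = np.linspace(49, 71, 23)
        direct = conc_regimen(t, r, final_params)
        shifted = sum(conc_single_dose(t - k * 24.0, 5.0, final_params)
                      for k in range(3))
        np.testing.assert_allclose(direct, shifted, rtol=1e-12)

    def test_regimen_validation(self):
        with pytest.raises(ValueError):
            Regimen(dose=0.0, interval=24.0, n_doses=1)
        with pytest.raises(ValueError):
            Regimen(dose=5.0, interval=-1.0, n_doses=1)
        with pytest.raises(ValueError):
            Regimen(dose=5.0, interval=24.0, n_doses=0)


class TestIntervalMetrics:
    def test_ordering_and_bounds(self, final_params):
        r = REGIMEN_PRESETS["5mg-qd"]
        m = interval_metrics(r, final_params, r.n_doses - 1)
        assert m["cmin"] <= m["cavg"] <= m["cmax"]
        assert r.duration - r.interval <= m["tmax"] <= r.duration

    def test_steady_state_cavg_equals_dose_over_cl_tau(self, final_params):
        """Quadrature oracle: at steady state, Cavg = dose/(cl*tau)."""
        r = Regimen(dose=5.0, interval=24.0, n_doses=120)  # deep steady state
        m = interval_metrics(r, final_params, r.n_doses - 1, grid_step=0.01)
        expected = 5.0 / (final_params.cl * 24.0)
        np.testing.assert_allclose(m["cavg"], expected, rtol=1e-3)

    def test_tmax_matches_golden_section_oracle(self, final_params):
        r = REGIMEN_PRESETS["5mg-qd"]
        grid_step = 0.01
        m = interval_metrics(r, final_params, r.n_doses - 1, grid_step=grid_step)
        t0 = (r.n_doses - 1) * r.interval
        res = minimize_scalar(lambda t: -conc_regimen(np.array([t]), r, final_params)[0],
                              bounds=(t0, t0 + r.interval), method="bounded",
                              options={"xatol": 1e-8})
        assert abs(m["tmax"] - res.x) <= grid_step

    def test_out_of_range_interval_rejected(self, final_params):
        with pytest.raises(ValueError):
            interval_metrics(REGIMEN_PRESETS["5mg-qd"], final_params, 99)


class TestRegimenGrammar:
    @pytest.mark.parametrize("text,dose,interval,n", [
        ("6mg q36h x15d", 6.0, 36.0, 10),
        ("5mg q24h x15d", 5.0, 24.0, 15),
        ("2.5mg q6h x15d", 2.5, 6.0, 60),
        ("6mg q48h x15d", 6.0, 48.0, 8),
    ])
    def test_parses_doses_intervals_counts(self, text, dose, interval, n):
        r = parse_regimen(text)
        assert (r.dose, r.interval, r.n_doses) == (dose, interval, n)

    def test_rejects_malformed(self):
        with pytest.raises(ValueError, match="cannot parse"):
            parse_regimen("five mg daily")

    def test_presets_cover_the_eight_simulated_regimens(self):
        assert len(REGIMEN_PRESETS) == 8
        assert all(r.duration >= 360.0 for r in REGIMEN_PRESETS.values())
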