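"""Two-compartment closed-form kinetics against independent oracles."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.integrate import solve_ivp

from certepk.dataset import DoseEvent
from certepk.twocomp import (
    IndividualParams,
    conc_profile,
    conc_single_infusion,
    micro_constants,
    steady_state_conc,
    steady_state_metrics,
)

REF = IndividualParams(vc=5.87, cl=6.88, vp=10.3, q=24.9)

params_strategy = st.builds(
    IndividualParams,
    vc=st.floats(1.0, 50.0),
    cl=st.floats(0.5, 30.0),
    vp=st.floats(1.0, 100.0),
    q=st.floats(0.5, 60.0),
)


def ode_concentration(p, dose, duration, times):
    """Numerical integration of the two-compartment ODE system (oracle)."""
    k = micro_constants(p)

    def rhs(t, a, rate):
        a1, a2 = a
        return [rate - (k.k10 + k.k12) * a1 + k.k21 * a2, k.k12 * a1 - k.k21 * a2]

    times = np.asarray(times, dtype=float)
    # integrate the infusion and washout phases separately: the forcing is
    # discontinuous at t = duration
    sol1 = solve_ivp(
        rhs, (0.0, duration), [0.0, 0.0], args=(dose / duration,),
        rtol=1e-11, atol=1e-14, dense_output=True, method="DOP853",
    )
    a_end = sol1.y[:, -1]
    t_max = max(times.max(), duration) + 1e-9
    sol2 = solve_ivp(
        rhs, (duration, t_max), a_end, args=(0.0,),
        rtol=1e-11, atol=1e-14, dense_output=True, method="DOP853",
    )
    out = np.empty_like(times)
    for i, t in enumerate(times):
        a1 = sol1.sol(t)[0] if t <= duration else sol2.sol(t)[0]
        out[i] = a1 / p.vc * 1000.0
    return out


class TestMicroConstants:
    def test_reference_parameters_give_published_terminal_half_life(self):
        k = micro_constants(REF)
        assert k.lambda2 == pytest.approx(0.380, abs=5e-4)
        assert np.log(2) / k.lambda2 == pytest.approx(1.82, abs=0.01)

    def test_one_compartment_limit_at_zero_distribution_clearance(self):
        k = micro_constants(IndividualParams(vc=10.0, cl=5.0, vp=8.0, q=0.0))
        assert k.k12 == 0.0 and k.k21 == 0.0
        assert k.lambda2 == pytest.approx(0.5)

    @given(params_strategy)
    def test_exponents_satisfy_root_identities(self, p):
        k = micro_constants(p)
        assert k.lambda1 * k.lambda2 == pytest.approx(k.k10 * k.k21, rel=1e-12)
        assert k.lambda1 + k.lambda2 == pytest.approx(
            k.k10 + k.k12 + k.k21, rel=1e-12
        )

    def test_nonpositive_parameters_rejected(self):
        with pytest.raises(ValueError):
            IndividualParams(vc=-1.0, cl=1.0, vp=1.0, q=1.0)


class TestSingleInfusion:
    def test_zero_at_time_zero_and_before(self):
        assert conc_single_infusion(REF, 224.0, 1 / 60, 0.0) == 0.0
        assert conc_single_infusion(REF, 224.0, 1 / 60, -1.0) == 0.0

    def test_short_infusion_approaches_bolus_solution(self):
        k = micro_constants(REF)
        denom = k.lambda1 - k.lambda2
        A = (k.lambda1 - k.k21) / denom
        B = (k.k21 - k.lambda2) / denom
        t = np.array([0.1, 0.5, 1.0, 3.0, 6.0])
        bolus = (
            224.0 / REF.vc * (A * np.exp(-k.lambda1 * t) + B * np.exp(-k.lambda2 * t))
        ) * 1000.0
        infusion = conc_single_infusion(REF, 224.0, 1e-6, t + 1e-6)
        np.testing.assert_allclose(infusion, bolus, rtol=1e-3)

    @given(params_strategy, st.floats(10.0, 500.0))
    def test_matches_ode_integration(self, p, dose):
        times = np.array([0.02, 0.1, 0.5, 1.0, 2.5, 6.0])
        closed = conc_single_infusion(p, dose, 1 / 60, times)
        numeric = ode_concentration(p, dose, 1 / 60, times)
        np.testing.assert_allclose(closed, numeric, rtol=1e-6)

    def test_continuous_at_end_of_infusion(self):
        dur = 1 / 60
        left = conc_single_infusion(REF, 224.0, dur, dur - 1e-9)
        right = conc_single_infusion(REF, 224.0, dur, dur + 1e-9)
        assert left == pytest.approx(right, rel=1e-5)


class TestSuperposition:
    def test_single_dose_profile_equals_single_infusion(self):
        times = np.linspace(0.0, 8.0, 40)
        doses = [DoseEvent("a", 0.0, 224.0, 1 / 60)]
        np.testing.assert_allclose(
            conc_profile(REF, doses, times),
            conc_single_infusion(REF, 224.0, 1 / 60, times),
        )

    def test_washout_symmetry_between_well_separated_doses(self):
        # 168 h apart ~ 92 terminal half-lives: windows must match closely
        doses = [DoseEvent("a", 0.0, 224.0, 1 / 60), DoseEvent("a", 168.0, 224.0, 1 / 60)]
        w = np.linspace(0.05, 6.0, 25)
        first = conc_profile(REF, doses, w)
        second = conc_profile(REF, doses, 168.0 + w)
        np.testing.assert_allclose(second, first, rtol=1e-6)

    def test_weekly_dosing_trough_below_quantification(self):
        doses = [DoseEvent("a", 168.0 * i, 224.0, 1 / 60) for i in range(10)]
        trough = conc_profile(REF, doses, np.array([10 * 168.0 - 1e-6]))
        assert trough[0] < 50.0


class TestSteadyState:
    def test_auc_is_dose_over_clearance(self):
        m = steady_state_metrics(REF, 224.0, 8.0, 1 / 60)
        assert m.auc_ss == pytest.approx(224.0 / 6.88 * 1000.0, rel=1e-12)

    def test_trapezoidal_auc_of_profile_matches_dose_over_cl(self):
        grid = np.linspace(0.0, 8.0, 10_000)
        css = steady_state_conc(REF, 224.0, 8.0, 1 / 60, grid)
        auc = np.trapezoid(css, grid)
        assert auc == pytest.approx(224.0 / 6.88 * 1000.0, rel=1e-3)

    def test_infinite_interval_recovers_single_dose_metrics(self):
        m = steady_state_metrics(REF, 224.0, 10_000.0, 1 / 60)
        # grid dense around the end of the 1-minute infusion where the peak sits
        t = np.concatenate(
            [np.linspace(1e-6, 1 / 60, 300), 1 / 60 + np.geomspace(1e-6, 8.0, 3000)]
        )
        single_peak = conc_single_infusion(REF, 224.0, 1 / 60, t).max()
        assert m.cmax_ss == pytest.approx(single_peak, rel=1e-4)
        assert m.auc_ss == pytest.approx(224.0 / 6.88 * 1000.0, rel=1e-12)

    def test_accumulation_formula_matches_brute_force_superposition(self):
        n_doses, tau, dur = 100, 8.0, 1 / 60
        for p in (REF, IndividualParams(vc=8.19, cl=6.88, vp=14.09, q=24.9)):
            doses = [DoseEvent("a", tau * i, 224.0, dur) for i in range(n_doses)]
            t0 = (n_doses - 1) * tau
            grid = np.concatenate(
                [np.linspace(t0, t0 + dur, 300), t0 + dur + np.geomspace(1e-4, tau - dur, 1500)]
            )
            brute = conc_profile(p, doses, grid).max()
            m = steady_state_metrics(p, 224.0, tau, dur)
            assert m.cmax_ss == pytest.approx(brute, rel=1e-4)

    def test_cmax_monotonicity_in_volumes(self):
        """Cmax falls with Vc; a larger Vp dilutes a single dose's peak but
        raises the steady-state peak through slower terminal elimination
        (higher accumulation), so the Vp sweep is checked single-dose."""
        scales = [0.6, 0.8, 1.0, 1.3, 1.7]
        cmax_vc = [
            steady_state_metrics(
                IndividualParams(vc=REF.vc * s, cl=REF.cl, vp=REF.vp, q=REF.q),
                224.0, 8.0, 1 / 60,
            ).cmax_ss
            for s in scales
        ]
        cmax_vp_single = [
            steady_state_metrics(
                IndividualParams(vc=REF.vc, cl=REF.cl, vp=REF.vp * s, q=REF.q),
                224.0, 10_000.0, 1 / 60,
            ).cmax_ss
            for s in scales
        ]
        assert all(np.diff(cmax_vc) < 0)
        assert all(np.diff(cmax_vp_single) < 0)

    def test_interval_must_exceed_infusion(self):
        with pytest.raises(ValueError):
            steady_state_metrics(REF, 224.0, 0.01, 1 / 60)
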