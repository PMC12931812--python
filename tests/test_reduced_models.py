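import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from damagepde.fv_solver import simulate
from damagepde.metrics import linear_fit_mean, mean_damage
from damagepde.model_core import DeathModel, DediffRule, FeedbackParams, ModelParams, make_grid
from damagepde.reduced_models import (
    TotalsParams,
    attrition_steady_ratio,
    critical_renewal_attrition,
    linear_stability,
    quiescence_delta_f,
    simulate_no_partition,
    simulate_totals,
    totals_rhs,
)


def baseline_params_local():
    """Baseline comparator setting: balanced symmetric division, constant death."""
    return ModelParams(
        v_P=0.2,
        v_W=0.2,
        feedback=FeedbackParams(p1_hat=0.5, p2_hat=0.5, lam_P_hat=1.0, lam_R_hat=0.0),
        death=DeathModel("constant", 0.5),
        dediff=DediffRule("constant"),
    )


class TestTotalsRhs:
    def test_baseline_steady_state(self):
        tp = TotalsParams(f=0.5, lam_P=1.0, lam_R=0.0, delta_W=0.5)
        assert totals_rhs(20.0, 40.0, tp) == pytest.approx((0.0, 0.0))

    def test_pure_renewal(self):
        tp = TotalsParams(f=1.0, lam_P=0.7, lam_R=0.0, delta_W=0.3)
        dP, dW = totals_rhs(5.0, 0.0, tp)
        assert dP == pytest.approx(0.7 * 5.0)
        assert dW == pytest.approx(0.0)

    def test_matches_structured_model_first_step(self):
        """The totals drift of the full PDE in one step equals the planar ODE
        right-hand side (constant death, no feedback)."""
        g = make_grid(20.0, 400)
        params = baseline_params_local()
        ic = g.indicator(2.0, 4.0, 10.0)
        traj = simulate(params, g, (ic.copy(), ic.copy()), t_end=params.courant * g.dx / 0.2)
        dt = traj.times[1] - traj.times[0]
        tp = TotalsParams(f=0.5, lam_P=1.0, lam_R=0.0, delta_W=0.5)
        dP, dW = totals_rhs(traj.P_bar[0], traj.W_bar[0], tp)
        assert (traj.P_bar[1] - traj.P_bar[0]) / dt == pytest.approx(dP, abs=1e-10)
        assert (traj.W_bar[1] - traj.W_bar[0]) / dt == pytest.approx(dW, rel=1e-10)


class TestNoPartitionComparator:
    def test_totals_agree_with_partitioned_model(self):
        g = make_grid(20.0, 400)
        params = baseline_params_local()
        ic = g.indicator(2.0, 4.0, 10.0)
        full = simulate(params, g, (ic.copy(), ic.copy()), 30.0)
        local = simulate_no_partition(params, g, (ic.copy(), ic.copy()), 30.0)
        assert np.allclose(full.P_bar, local.P_bar, rtol=1e-10)
        assert np.allclose(full.W_bar, local.W_bar, rtol=1e-10)

    def test_mean_damage_drifts_at_advection_speed(self):
        g = make_grid(20.0, 800)
        params = baseline_params_local()
        ic = g.indicator(2.0, 4.0, 10.0)
        times = np.arange(0.0, 31.0, 1.0)
        traj = simulate_no_partition(params, g, (ic.copy(), ic.copy()), 30.0, snapshot_times=times)
        ts = sorted(traj.snapshots)
        means = [mean_damage(traj.snapshots[t][0], g) for t in ts]
        slope, intercept, r2 = linear_fit_mean(np.asarray(ts), np.asarray(means))
        assert slope == pytest.approx(0.2, abs=0.005)
        assert intercept == pytest.approx(3.0, abs=0.05)
        assert r2 > 0.9999

    def test_reaction_free_profile_is_fixed_point(self):
        g = make_grid(2.0, 100)
        params = ModelParams(
            v_P=0.0,
            v_W=0.0,
            feedback=FeedbackParams(p1_hat=0.5, p2_hat=0.5, lam_P_hat=0.0, lam_R_hat=0.0),
            death=DeathModel("constant", 0.0),
            dediff=DediffRule("constant"),
        )
        ic = g.indicator(0.3, 0.7, 2.0)
        traj = simulate_no_partition(params, g, (ic.copy(), ic.copy()), 1.0, dt=0.05)
        assert traj.P_bar[-1] == pytest.approx(traj.P_bar[0], rel=1e-14)


class TestLinearStability:
    def test_zero_matrix_not_stable(self):
        rep = linear_stability(TotalsParams(f=0.5, lam_P=0.0, lam_R=0.0, delta_W=0.0))
        assert rep.trace == 0.0 and rep.det == 0.0 and not rep.stable

    def test_determinant_changes_sign_at_f_crit(self):
        lam_P, lam_R, dW, dP = 1.0, 0.1, 0.5, 0.2
        f_crit = critical_renewal_attrition(dP, dW, lam_P, lam_R)
        below = linear_stability(TotalsParams(f=f_crit - 1e-6, lam_P=lam_P, lam_R=lam_R, delta_W=dW, delta_P=dP))
        above = linear_stability(TotalsParams(f=f_crit + 1e-6, lam_P=lam_P, lam_R=lam_R, delta_W=dW, delta_P=dP))
        at = linear_stability(TotalsParams(f=f_crit, lam_P=lam_P, lam_R=lam_R, delta_W=dW, delta_P=dP))
        assert below.det > 0 > above.det
        assert at.det == pytest.approx(0.0, abs=1e-12)

    def test_stable_flag_is_routh_hurwitz(self):
        rep = linear_stability(TotalsParams(f=0.3, lam_P=1.0, lam_R=0.05, delta_W=0.5, delta_P=0.1))
        assert rep.stable == (rep.trace < 0 and rep.det > 0)


class TestCriticalRenewal:
    def test_reduces_to_attrition_free_form_at_zero_stem_death(self):
        assert critical_renewal_attrition(0.0, 0.5, 1.0, 0.1) == pytest.approx(0.4)

    def test_vanishes_when_reflux_balances_td_death(self):
        assert critical_renewal_attrition(0.0, 0.3, 1.0, 0.3) == pytest.approx(0.0)

    @given(
        dP=st.floats(0.0, 0.5),
        dW=st.floats(0.05, 1.0),
        lam_P=st.floats(0.1, 2.0),
        lam_R=st.floats(0.0, 0.5),
    )
    @settings(max_examples=50, deadline=None)
    def test_attrition_surcharge_decomposition(self, dP, dW, lam_P, lam_R):
        f_crit = critical_renewal_attrition(dP, dW, lam_P, lam_R)
        f_tilde = (dW - lam_R) / (2 * dW)
        surcharge = dP * (dW + lam_R) / (2 * dW * lam_P)
        assert f_crit == pytest.approx(f_tilde + surcharge, rel=1e-10, abs=1e-12)

    def test_degenerate_denominators_rejected(self):
        with pytest.raises(ValueError):
            critical_renewal_attrition(0.1, 0.0, 1.0, 0.1)
        with pytest.raises(ValueError):
            critical_renewal_attrition(0.1, 0.5, 0.0, 0.1)


class TestAttritionSteadyRatio:
    @pytest.mark.parametrize(
        "dP, dW, lam_P, expected",
        [(0.0, 0.5, 1.0, 0.5), (0.5, 0.5, 1.0, 1.0)],
    )
    def test_closed_form(self, dP, dW, lam_P, expected):
        assert attrition_steady_ratio(dP, dW, lam_P) == pytest.approx(expected)

    def test_no_positive_ratio_beyond_replication(self):
        with pytest.raises(ValueError):
            attrition_steady_ratio(1.0, 0.5, 1.0)

    def test_matches_totals_ode_simulation(self):
        """At f = f_crit the planar system has a nontrivial equilibrium ray;
        the simulated trajectory settles onto the closed-form stem/TD ratio."""
        dP, dW, lam_P, lam_R = 0.1, 0.5, 1.0, 0.05
        f_crit = critical_renewal_attrition(dP, dW, lam_P, lam_R)
        tp = TotalsParams(f=f_crit, lam_P=lam_P, lam_R=lam_R, delta_W=dW, delta_P=dP)
        _, P, W = simulate_totals(tp, (1.0, 1.0), t_end=400.0, dt=0.01)
        assert P[-1] / W[-1] == pytest.approx(attrition_steady_ratio(dP, dW, lam_P), rel=1e-3)


class TestQuiescence:
    def test_no_surcharge_without_dormant_death(self):
        assert quiescence_delta_f(0.3, 0.2, 0.0, 1.0, 0.5, 0.05) == 0.0

    def test_faster_reactivation_reduces_surcharge(self):
        vals = [quiescence_delta_f(0.3, rQ, 0.1, 1.0, 0.5, 0.05) for rQ in (0.1, 0.5, 2.0, 10.0)]
        assert all(a > b for a, b in zip(vals, vals[1:]))
        assert vals[-1] < 0.01

    def test_shifted_threshold_zeroes_reduced_system_determinant(self):
        """Under the quasi-steady dormant pool, the effective stem loss is
        delta_P + s_P delta_Q / (r_Q + delta_Q); the planar determinant must
        vanish at f_crit + delta_f."""
        s_P, r_Q, d_Q, lam_P, d_W, lam_R, d_P = 0.3, 0.4, 0.2, 1.0, 0.5, 0.05, 0.1
        delta_f = quiescence_delta_f(s_P, r_Q, d_Q, lam_P, d_W, lam_R)
        f_crit = critical_renewal_attrition(d_P, d_W, lam_P, lam_R)
        eff_dP = d_P + s_P * d_Q / (r_Q + d_Q)
        rep = linear_stability(
            TotalsParams(f=f_crit + delta_f, lam_P=lam_P, lam_R=lam_R, delta_W=d_W, delta_P=eff_dP)
        )
        assert rep.det == pytest.approx(0.0, abs=1e-12)

    @given(
        s_P=st.floats(0.01, 1.0),
        r_Q=st.floats(0.01, 2.0),
        d_Q=st.floats(0.0, 1.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_surcharge_nonnegative_and_monotone(self, s_P, r_Q, d_Q):
        base = quiescence_delta_f(s_P, r_Q, d_Q, 1.0, 0.5, 0.05)
        assert base >= 0.0
        assert quiescence_delta_f(2 * s_P, r_Q, d_Q, 1.0, 0.5, 0.05) >= base
        assert quiescence_delta_f(s_P, 2 * r_Q, d_Q, 1.0, 0.5, 0.05) <= base


class TestStructuredSteadyBalance:
    def test_replication_balances_death_at_steady_state(self):
        """For the feedback-regulated model with constant TD death, the steady
        totals satisfy lam_P(Wbar*) Pbar* = delta Wbar* (within 1%)."""
        from damagepde.fv_solver import run_to_steady
        from damagepde.model_core import effective_rates

        g = make_grid(2.0, 200)
        params = ModelParams(
            v_P=0.05,
            v_W=0.05,
            feedback=FeedbackParams(
                p1_hat=0.45, p2_hat=0.55, lam_P_hat=1.0, lam_R_hat=0.05, k1=0.1, k2=0.01, k3=0.02, p2_complement=True
            ),
            death=DeathModel("constant", 0.3),
            dediff=DediffRule("constant"),
        )
        ic = g.indicator(0.2, 0.4, 10.0)
        state, converged, _ = run_to_steady(params, g, (ic.copy(), ic.copy()), tol=1e-7, t_max=400.0)
        assert converged
        P_bar, W_bar = state.totals
        rates = effective_rates(state.totals, params.feedback)
        assert rates.lam_P * P_bar == pytest.approx(0.3 * W_bar, rel=0.01)
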