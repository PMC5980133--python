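"""Structural PK model: QSS root, route covariate, ODE simulation."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.linalg import expm
from scipy.optimize import brentq

import cd38pkpd as m
from cd38pkpd.pk import dense_simulation_grid, pk_rhs


def bisect_qss(ctot, rtot, kss):
    """Independent oracle: solve C + rtot*C/(KSS+C) = ctot by bracketing."""
    if ctot == 0:
        return 0.0
    return brentq(lambda c: c + rtot * c / (kss + c) - ctot, 0.0, ctot, xtol=1e-15)


def linear_2cpt_solution(params, doses, times):
    """Matrix-exponential oracle for the linear (no-TMDD) model."""
    A = np.array([
        [-params.KA, 0.0, 0.0],
        [params.KA, -(params.CL + params.Q) / params.VC, params.Q / params.VP],
        [0.0, params.Q / params.VC, -params.Q / params.VP],
    ])
    out = np.zeros(len(times))
    for i, t in enumerate(times):
        state = np.zeros(3)
        t_prev = 0.0
        for d in sorted(doses, key=lambda d: d.time):
            if d.time >= t:
                break
            state = expm(A * (d.time - t_prev)) @ state
            if d.route == m.Route.IV_BOLUS:
                state[1] += d.amount
            elif d.route == m.Route.SC:
                state[0] += params.F * d.amount
            t_prev = d.time
        state = expm(A * (t - t_prev)) @ state
        out[i] = state[1] / params.VC
    return out


class TestBioavailability:
    def test_logit_symmetry(self):
        assert m.bioavailability(0.0) == pytest.approx(0.5)

    def test_large_negative_limit(self):
        assert m.bioavailability(-100.0) == pytest.approx(0.0, abs=1e-12)

    def test_table_value_inverts(self):
        """logit(0.227) maps back to the printed bioavailability."""
        f_logit = brentq(lambda x: m.bioavailability(x) - 0.227, -10, 10)
        assert f_logit == pytest.approx(math.log(0.227 / 0.773), abs=1e-9)
        assert m.bioavailability(f_logit) == pytest.approx(0.227, abs=1e-12)

    @given(st.floats(-20, 20), st.floats(-20, 20))
    def test_strictly_monotone(self, a, b):
        if a < b:
            assert m.bioavailability(a) < m.bioavailability(b)


class TestRouteCovariate:
    def test_iv_unchanged(self):
        assert m.apply_route_covariate(0.141, m.Route.IV_BOLUS, -0.697) == 0.141

    def test_sc_shrinks_central_volume(self):
        """SC typical VC is about 70% smaller: 0.141 L -> 0.043 L."""
        vc = m.apply_route_covariate(0.141, m.Route.SC, -0.697)
        assert vc == pytest.approx(0.0427, abs=5e-4)
        assert vc == pytest.approx(0.043, abs=5e-4)

    def test_sc_zero_effect(self):
        assert m.apply_route_covariate(0.141, m.Route.SC, 0.0) == 0.141

    def test_degenerate_covariate_rejected(self):
        with pytest.raises(ValueError):
            m.apply_route_covariate(0.141, m.Route.SC, -1.0)


class TestQSSRoot:
    @pytest.mark.parametrize(
        "ctot, rtot, kss",
        [(1.0, 0.0, 5.68), (0.0, 8.85, 5.68), (1.0, 8.85, 5.68),
         (100.0, 8.85, 5.68), (0.01, 50.0, 5.68)],
    )
    def test_matches_bisection_oracle(self, ctot, rtot, kss):
        assert m.qss_free_concentration(ctot, rtot, kss) == pytest.approx(
            bisect_qss(ctot, rtot, kss), rel=1e-9, abs=1e-12
        )

    def test_no_receptor_returns_total(self):
        assert m.qss_free_concentration(1.0, 0.0, 5.68) == pytest.approx(1.0)

    def test_zero_drug(self):
        assert m.qss_free_concentration(0.0, 8.85, 5.68) == 0.0

    @given(
        ctot=st.floats(0, 1e4),
        rtot=st.floats(0, 1e3),
        kss=st.floats(1e-3, 1e3),
    )
    def test_conservation_identity(self, ctot, rtot, kss):
        """The root satisfies C + rtot*C/(KSS+C) = ctot to 1e-10 relative."""
        c = m.qss_free_concentration(ctot, rtot, kss)
        assert 0.0 <= c <= ctot
        recon = c + rtot * c / (kss + c)
        assert recon == pytest.approx(ctot, rel=1e-10, abs=1e-10)

    @given(st.floats(0.01, 100), st.floats(0, 100), st.floats(0.1, 100))
    def test_monotone_in_ctot_and_rtot(self, ctot, rtot, kss):
        c = m.qss_free_concentration(ctot, rtot, kss)
        assert m.qss_free_concentration(ctot * 1.1, rtot, kss) >= c
        assert m.qss_free_concentration(ctot, rtot + 1.0, kss) <= c


class TestRHS:
    def test_drug_free_steady_state(self, typical_pk):
        state = [0.0, 0.0, 0.0, typical_pk.rtot_baseline]
        assert np.allclose(pk_rhs(state, typical_pk), 0.0, atol=1e-12)

    def test_linear_limit_is_two_compartment(self, linear_pk):
        """With no receptor the RHS equals the hand-coded linear model."""
        state = [0.5, 2.0, 0.7, 0.0]
        d, cen, per, _ = state
        c, cp = cen / linear_pk.VC, per / linear_pk.VP
        expected = [
            -linear_pk.KA * d,
            linear_pk.KA * d - linear_pk.CL * c - linear_pk.Q * (c - cp),
            linear_pk.Q * (c - cp),
            0.0,
        ]
        assert np.allclose(pk_rhs(state, linear_pk), expected, rtol=1e-12)

    def test_term_by_term_oracle(self, typical_pk, rng):
        """Each balance term matches independent recomputation from the formulas."""
        for _ in range(20):
            depot, cen, per, rtot = rng.uniform(0, 10, size=4)
            p = typical_pk
            ctot = cen / p.VC
            c = bisect_qss(ctot, rtot, p.KSS)
            rc = rtot * c / (p.KSS + c)
            cp = per / p.VP
            expected = np.array([
                -p.KA * depot,
                p.KA * depot - p.CL * c - p.Q * (c - cp) - p.KINT * rc * p.VC,
                p.Q * (c - cp),
                p.KSYN - p.KDEG * rtot - (p.KINT - p.KDEG) * rc,
            ])
            assert np.allclose(pk_rhs([depot, cen, per, rtot], p), expected,
                               rtol=1e-8, atol=1e-10)


class TestSimulate:
    def test_bolus_initial_concentration(self, linear_pk):
        """C(0+) = dose/VC for an IV bolus without target binding."""
        prof = m.simulate_pk(linear_pk, [m.DoseEvent(0.0, 0.9, m.Route.IV_BOLUS)], [1e-6])
        assert prof.cfree[0] == pytest.approx(0.9 / 0.141, rel=1e-4)

    def test_sample_on_dose_time_is_predose(self, linear_pk):
        prof = m.simulate_pk(linear_pk, [m.DoseEvent(0.0, 0.9, m.Route.IV_BOLUS)], [0.0])
        assert prof.cfree[0] == 0.0

    def test_linear_limit_matches_matrix_exponential(self, linear_pk):
        """Full solver vs independent expm solution across a mixed schedule."""
        doses = [
            m.DoseEvent(0.0, 3.0, m.Route.IV_BOLUS),
            m.DoseEvent(7.0, 2.0, m.Route.SC),
            m.DoseEvent(21.0, 3.0, m.Route.IV_BOLUS),
        ]
        times = np.array([0.5, 1, 3, 6.9, 7.5, 10, 14, 20.9, 21.5, 28, 42, 60])
        prof = m.simulate_pk(linear_pk, doses, times, rtol=1e-10, atol=1e-12)
        oracle = linear_2cpt_solution(linear_pk, doses, times)
        assert np.allclose(prof.cfree, oracle, rtol=1e-6)

    def test_superposition_in_linear_regime(self, linear_pk):
        """Far-apart equal boluses superpose within 0.1%."""
        t_obs = np.array([100.5, 101, 103, 107, 114, 128])
        single = m.simulate_pk(
            linear_pk, [m.DoseEvent(100.0, 9.0, m.Route.IV_BOLUS)], t_obs
        ).cfree
        first = m.simulate_pk(
            linear_pk, [m.DoseEvent(0.0, 9.0, m.Route.IV_BOLUS)], t_obs
        ).cfree
        both = m.simulate_pk(
            linear_pk,
            [m.DoseEvent(0.0, 9.0, m.Route.IV_BOLUS), m.DoseEvent(100.0, 9.0, m.Route.IV_BOLUS)],
            t_obs,
        ).cfree
        assert np.allclose(both, single + first, rtol=1e-3)

    def test_mass_balance_without_elimination(self, typical_pk):
        """depot+cen+per is conserved when every elimination pathway is off."""
        from scipy.integrate import solve_ivp

        p = typical_pk.replace(CL=1e-12, KSYN=0.0)
        state = np.array([0.0, 3.0, 0.0, 0.0])  # 3 mg IV bolus at t=0
        sol = solve_ivp(lambda t, y: pk_rhs(y, p), (0, 5), state,
                        rtol=1e-10, atol=1e-12)
        state = sol.y[:, -1]
        state[0] += p.F * 2.0  # 2 mg SC at t=5
        sol = solve_ivp(lambda t, y: pk_rhs(y, p), (5, 60), state,
                        rtol=1e-10, atol=1e-12)
        totals = sol.y[0] + sol.y[1] + sol.y[2]
        assert np.allclose(totals, 3.0 + p.F * 2.0, rtol=1e-7)

    def test_infusion_profile_peaks_at_end_of_infusion(self, linear_pk):
        dur = 0.5 / 24.0
        doses = [m.DoseEvent(0.0, 9.0, m.Route.IV_INFUSION, dur)]
        times = np.array([dur / 2, dur, 0.1, 0.5, 1.0])
        prof = m.simulate_pk(linear_pk, doses, times)
        assert np.argmax(prof.cfree) == 1

    def test_dose_proportionality_and_tmdd_acceleration(self, typical_pk, linear_pk):
        """Target-mediated loss is concentrated at low concentrations: total-drug
        AUC is near dose-proportional at >=1 mg/kg, the dose-normalised free AUC
        rises monotonically with dose (the fixed binding capacity matters less
        and less), and at 0.03 mg/kg the free AUC is markedly reduced relative
        to the linear model (augmented clearance below ~0.5 μg/mL)."""
        from cd38pkpd.nca import auc_trapezoid

        t = np.unique(np.concatenate([np.linspace(0, 2, 400), np.linspace(0, 300, 2000)]))
        auc_free, auc_tot = {}, {}
        for mgkg in (1.0, 2.0, 10.0):
            prof = m.simulate_pk(typical_pk, [m.DoseEvent(0.0, 3 * mgkg, m.Route.IV_BOLUS)], t)
            auc_free[mgkg] = auc_trapezoid(t, prof.cfree)
            auc_tot[mgkg] = auc_trapezoid(t, prof.ctot)
        assert auc_tot[2.0] / auc_tot[1.0] == pytest.approx(2.0, rel=0.05)
        assert auc_free[1.0] / 1.0 < auc_free[2.0] / 2.0 < auc_free[10.0] / 10.0

        t_low = np.unique(np.concatenate([np.linspace(0, 2, 400), np.linspace(0, 60, 1200)]))
        low_dose = [m.DoseEvent(0.0, 3 * 0.03, m.Route.IV_BOLUS)]
        auc_tmdd = auc_trapezoid(t_low, m.simulate_pk(typical_pk, low_dose, t_low).cfree)
        auc_lin = auc_trapezoid(t_low, m.simulate_pk(linear_pk, low_dose, t_low).cfree)
        assert auc_tmdd < 0.75 * auc_lin  # markedly augmented clearance at low dose

    def test_dense_grid_refines_near_doses(self):
        doses = [m.DoseEvent(0.0, 1.0, m.Route.IV_BOLUS), m.DoseEvent(7.0, 1.0, m.Route.IV_BOLUS)]
        grid = dense_simulation_grid(doses, 14.0)
        near = grid[(grid >= 7.0) & (grid <= 7.1)]
        assert np.max(np.diff(near)) <= 0.01 + 1e-12


class TestTerminalHalflife:
    def test_one_compartment_limit(self):
        """A vanishing peripheral volume recovers t1/2 -> ln2*VC/CL."""
        t_half = m.terminal_halflife(0.0187, 0.141, 0.127, 1e-9)
        assert t_half == pytest.approx(math.log(2) * 0.141 / 0.0187, rel=1e-4)

    def test_typical_values_give_ten_days(self, typical_pk):
        """Eigenvalue oracle: Table-typical disposition gives t1/2 ≈ 10.3 d."""
        A = np.array([
            [-(0.0187 / 0.141 + 0.127 / 0.141), 0.127 / 0.127],
            [0.127 / 0.141, -0.127 / 0.127],
        ])
        lam_z = min(abs(np.linalg.eigvals(A)))
        expected = math.log(2) / lam_z
        got = m.terminal_halflife(typical_pk.CL, typical_pk.VC, typical_pk.Q, typical_pk.VP)
        assert got == pytest.approx(expected, rel=1e-10)
        assert got == pytest.approx(10.3, abs=0.05)

    def test_joint_scaling_invariance(self):
        """Scaling CL, Q and both volumes by k leaves the half-life unchanged."""
        base = m.terminal_halflife(0.0187, 0.141, 0.127, 0.127)
        scaled = m.terminal_halflife(0.0187 * 3, 0.141 * 3, 0.127 * 3, 0.127 * 3)
        assert scaled == pytest.approx(base, rel=1e-12)
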