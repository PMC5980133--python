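"""Likelihood values, exact recovery on noise-free data, identifiability."""

import math

import numpy as np
import pytest

import cd38pkpd as m
from cd38pkpd.datamodel import (
    Dataset,
    Observable,
    ObservationRecord,
    ResidualSpec,
    SubjectData,
)
from cd38pkpd.estimation import fit_pd, fit_pk, neg2_loglik, pk_neg2_loglik
from cd38pkpd.pk import dense_simulation_grid


def _noise_free_pk_subject(params, dose_mg=9.0, sid="s1"):
    sub = SubjectData(subject_id=sid, body_weight=3.0, sex="F")
    sub.doses.append(m.DoseEvent(0.0, dose_mg, m.Route.IV_BOLUS))
    times = np.array([0.05, 0.25, 0.5, 1, 2, 3, 5, 7, 10, 14, 21, 28, 35, 42])
    conc = m.simulate_pk(params, sub.doses, times, rtol=1e-10, atol=1e-12).cfree
    for t, c in zip(times, conc):
        sub.observations.append(ObservationRecord(sid, float(t), Observable.PK, float(c)))
    return sub


class TestNeg2LogLik:
    def test_zero_residual_leaves_normalising_constant(self):
        """A perfect prediction contributes exactly ln(2*pi*sigma^2)."""
        got = neg2_loglik([2.0], [2.0], additive_var=1e-4, proportional_var=0.01)
        s2 = 1e-4 + 0.01 * 4.0
        assert got == pytest.approx(math.log(2 * math.pi * s2), rel=1e-12)

    def test_three_point_hand_computation(self):
        """Matches an independent per-point summation to 1e-10."""
        y = np.array([1.2, 0.8, 2.5])
        f = np.array([1.0, 1.0, 2.0])
        add, prop = 3.17e-4, 0.0677
        expected = 0.0
        for yi, fi in zip(y, f):
            s2 = add + prop * fi * fi
            expected += math.log(2 * math.pi * s2) + (yi - fi) ** 2 / s2
        assert neg2_loglik(y, f, additive_var=add, proportional_var=prop) == pytest.approx(
            expected, abs=1e-10
        )

    def test_variance_scaling_shift(self):
        """With zero residuals, scaling sigma^2 by 4 adds 2*N*ln 2."""
        y = f = np.linspace(1, 3, 7)
        base = neg2_loglik(y, f, proportional_var=0.01)
        scaled = neg2_loglik(y, f, proportional_var=0.04)
        assert scaled - base == pytest.approx(2 * len(y) * math.log(2), rel=1e-10)

    def test_dataset_level_wrapper(self, typical_pk):
        ds = Dataset(subjects=[_noise_free_pk_subject(typical_pk)])
        val = pk_neg2_loglik(ds, typical_pk, ResidualSpec(), rtol=1e-8)
        n = len(ds.subjects[0].observations)
        # zero residuals: only normalising terms remain
        f = np.array([o.value for o in ds.subjects[0].observations])
        expected = float(np.sum(np.log(2 * np.pi * (3.17e-4 + 0.0677 * f**2))))
        assert val == pytest.approx(expected, rel=1e-4)
        assert val < n * 10  # finite and sane


class TestFitPK:
    def test_noise_free_exact_recovery(self, typical_pk):
        """Rich single-subject IV data, TMDD frozen: CL/VC/Q/VP to < 0.1%."""
        ds = Dataset(subjects=[_noise_free_pk_subject(typical_pk)])
        init = typical_pk.replace(CL=0.03, VC=0.2, Q=0.2, VP=0.08)
        res = fit_pk(ds, init, mode="pooled", rtol=1e-8)
        for name, truth in [("CL", 0.0187), ("VC", 0.141), ("Q", 0.127), ("VP", 0.127)]:
            assert res.estimates[name] == pytest.approx(truth, rel=1e-3), name

    def test_tenfold_misspecified_init_same_optimum(self, typical_pk):
        """A x10 initial clearance still reaches the same optimum."""
        ds = Dataset(subjects=[_noise_free_pk_subject(typical_pk)])
        res = fit_pk(ds, typical_pk.replace(CL=0.187), mode="pooled", rtol=1e-8)
        assert res.estimates["CL"] == pytest.approx(0.0187, rel=1e-3)

    def test_fixed_mask_honoured(self, typical_pk):
        ds = Dataset(subjects=[_noise_free_pk_subject(typical_pk)])
        res = fit_pk(ds, typical_pk, fit=("CL",), mode="pooled")
        assert set(res.estimates) == {"CL"}
        assert "VC" in res.fixed and "KSS" in res.fixed

    def test_estimates_invariant_to_subject_order(self, typical_pk):
        subs = [
            _noise_free_pk_subject(typical_pk, 9.0, "a"),
            _noise_free_pk_subject(typical_pk, 6.0, "b"),
        ]
        init = typical_pk.replace(CL=0.025)
        r1 = fit_pk(Dataset(subjects=subs), init, mode="pooled")
        r2 = fit_pk(Dataset(subjects=subs[::-1]), init, mode="pooled")
        for k in r1.estimates:
            assert r1.estimates[k] == pytest.approx(r2.estimates[k], rel=1e-9)

    def test_unknown_parameter_rejected(self, typical_pk):
        with pytest.raises(ValueError, match="unknown"):
            fit_pk(Dataset(subjects=[]), typical_pk, fit=("NOPE",))

    def test_two_stage_median_of_individuals(self, typical_pk):
        subs = [
            _noise_free_pk_subject(typical_pk, 9.0, "a"),
            _noise_free_pk_subject(typical_pk, 6.0, "b"),
            _noise_free_pk_subject(typical_pk, 12.0, "c"),
        ]
        res = fit_pk(Dataset(subjects=subs), typical_pk.replace(CL=0.03),
                     mode="two-stage")
        assert len(res.individual) == 3
        assert res.estimates["CL"] == pytest.approx(0.0187, rel=1e-3)


class TestFitPD:
    @staticmethod
    def _pd_dataset(pk_params, cell, doses_mgkg, times, pd_true):
        subs = []
        for i, mgkg in enumerate(doses_mgkg):
            sid = f"d{i}"
            sub = SubjectData(subject_id=sid, body_weight=3.0, sex="F")
            sub.doses.append(m.DoseEvent(0.0, 3.0 * mgkg, m.Route.IV_BOLUS))
            grid = dense_simulation_grid(sub.doses, float(times[-1]))
            conc = m.simulate_pk(pk_params, sub.doses, grid, rtol=1e-10).cfree
            from cd38pkpd.pd import simulate_cells

            counts = simulate_cells(pd_true, (grid, conc), times).counts
            for t, c in zip(times, counts):
                sub.observations.append(ObservationRecord(
                    sid, float(t), cell, float(c), baseline=pd_true.BL))
            subs.append(sub)
        return Dataset(subjects=subs)

    def test_noise_free_tcell_recovery(self, typical_pk):
        """Three informative doses pin down (C50, EMAX) exactly."""
        truth = m.PDParams.t_typical()
        times = np.array([0.25, 1.0, 3.0, 7.0, 14.0])
        ds = self._pd_dataset(typical_pk, Observable.T, [0.3, 3.0, 30.0], times, truth)
        init = truth.replace(C50=30.0, EMAX=0.3)
        res = fit_pd(ds, Observable.T, typical_pk, init, rtol=1e-8)
        assert res.estimates["C50"] == pytest.approx(11.86, rel=1e-3)
        assert res.estimates["EMAX"] == pytest.approx(0.4656, rel=1e-3)

    def test_noise_free_bcell_recovery(self, typical_pk):
        truth = m.PDParams.b_typical()
        times = np.array([1, 3, 7, 14, 21, 28, 42, 56, 70, 91], dtype=float)
        ds = self._pd_dataset(typical_pk, Observable.B, [0.3, 3.0, 30.0], times, truth)
        init = truth.replace(MTT=4.0, C50=40.0, EMAX=1.0)
        res = fit_pd(ds, Observable.B, typical_pk, init, rtol=1e-8)
        assert res.estimates["MTT"] == pytest.approx(8.19, rel=0.01)
        assert res.estimates["C50"] == pytest.approx(19.8, rel=0.01)
        assert res.estimates["EMAX"] == pytest.approx(2.43, rel=0.01)

    def test_early_samples_are_ignored(self, typical_pk):
        """Flagged < 8 h samples do not influence the fit."""
        truth = m.PDParams.t_typical()
        times = np.array([0.5, 2.0, 7.0])
        ds = self._pd_dataset(typical_pk, Observable.T, [1.0, 10.0], times, truth)
        # corrupt an extra early sample; it must be dropped by the filter
        for sub in ds.subjects:
            sub.observations.append(ObservationRecord(
                sub.subject_id, 0.1, Observable.T, 1.0, baseline=truth.BL,
                early_flag=True))
        res = fit_pd(ds, Observable.T, typical_pk, truth.replace(C50=20.0), rtol=1e-8)
        assert res.estimates["C50"] == pytest.approx(11.86, rel=1e-3)

    def test_c50_identifiability_requires_informative_doses(self, typical_pk):
        """The C50 curvature of -2LL collapses on a lowest-dose-only design:
        its implied standard error is >= 5x that of the multi-dose design."""
        truth = m.PDParams.nk_typical()
        times = np.array([0.5, 1, 2, 3, 5, 7, 10, 14, 21, 28], dtype=float)

        def curvature(doses_mgkg):
            ds = self._pd_dataset(typical_pk, Observable.NK, doses_mgkg, times, truth)
            res = fit_pd(ds, Observable.NK, typical_pk, truth, rtol=1e-8,
                         compute_se=True, presearch="off")
            return res.se_percent["C50"]

        se_low = curvature([0.03] * 4)
        # doses bracketing C50 (peak free concentrations ~ 10-600 μg/mL)
        se_multi = curvature([1.0, 2.0, 3.0, 30.0])
        assert se_low >= 5.0 * se_multi
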