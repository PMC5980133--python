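"""Population layer: between-subject variability, residual error and whole
trial simulation.

Individual parameters are lognormal around the typical values,
PAR_i = TVPAR * exp(eta_i) with eta_i ~ N(0, omega^2) and a diagonal omega
(no correlated random effects).  Observations receive a combined
additive + proportional error for the drug assay and a proportional-only
error for cell counts.  A whole simulated trial is a pure function of
(design, parameters, seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .datamodel import (
    BSVSpec,
    Dataset,
    DoseEvent,
    EARLY_PD_WINDOW_DAYS,
    Observable,
    ObservationRecord,
    PDParams,
    PKParams,
    ResidualSpec,
    Route,
    StudyDesign,
    Subject,
    SubjectData,
)
from .pk import apply_route_covariate, dense_simulation_grid, simulate_pk
from .pd import simulate_cells
from .synthetic import BaselineSpec, sample_baselines
from .datamodel import MONKEY_WEIGHT_RANGE_KG

__all__ = [
    "SimulatedTrial",
    "draw_individual_params",
    "add_residual_error",
    "simulate_trial",
    "PD_BSV_TYPICAL",
]

#: Printed between-subject variabilities of the PD structural parameters.
PD_BSV_TYPICAL: dict[Observable, BSVSpec] = {
    Observable.NK: BSVSpec({"KIN": 1.11, "C50": 1.46}),
    Observable.B: BSVSpec({"MTT": 1.35}),
    Observable.T: BSVSpec({"EMAX": 0.6946}),
}


@dataclass
class SimulatedTrial:
    subjects: list[Subject]
    data: list[SubjectData]
    seed: int
    design: StudyDesign
    lloq: float
    n_floored: int = 0  # negative residual draws floored at zero

    def to_dataset(self) -> Dataset:
        return Dataset(subjects=[
            SubjectData(
                subject_id=d.subject_id,
                doses=list(d.doses),
                observations=list(d.observations),
                body_weight=d.body_weight,
                sex=d.sex,
            )
            for d in self.data
        ], lloq=self.lloq)


def draw_individual_params(
    typical,
    bsv: BSVSpec | None,
    rng,
) -> tuple[object, dict[str, float]]:
    """One subject's parameters: lognormal deviations around the typicals.

    ``typical`` is a PKParams or PDParams; parameters absent from the BSV
    map (CV 0) are returned exactly at their typical value.  The median over
    many draws equals the typical value (lognormal median = e^mu).
    Returns (individual_params, etas).
    """
    rng = np.random.default_rng(rng)
    if bsv is None or not bsv.cv_by_param:
        return typical, {}
    etas: dict[str, float] = {}
    changes: dict[str, float] = {}
    for name in sorted(bsv.cv_by_param):
        omega = bsv.omega(name)
        eta = rng.normal(0.0, omega) if omega > 0 else 0.0
        etas[name] = eta
        base = getattr(typical, name)
        if base is None:
            raise ValueError(f"BSV requested on undefined parameter {name}")
        changes[name] = base * float(np.exp(eta))
    return typical.replace(**changes), etas


def add_residual_error(
    prediction,
    observable: Observable,
    residual: ResidualSpec | None,
    rng,
    floored_counter: list | None = None,
):
    """Noisy observation(s) from model prediction(s).

    PK: y = f*(1 + eps_p) + eps_a (combined error).  PD: y = f*(1 + eps_p)
    (proportional only, so a zero prediction stays exactly zero).  Negative
    draws are floored at 0; ``floored_counter`` (a one-element list) is
    incremented when that happens.
    """
    rng = np.random.default_rng(rng)
    f = np.asarray(prediction, dtype=float)
    if np.any(f < 0):
        raise ValueError("predictions must be non-negative")
    if residual is None:
        residual = ResidualSpec.none()
    add_var, prop_var = residual.variances(observable)
    y = f.copy()
    if prop_var > 0:
        y = f * (1.0 + rng.normal(0.0, np.sqrt(prop_var), size=f.shape))
    if add_var > 0:
        y = y + rng.normal(0.0, np.sqrt(add_var), size=f.shape)
    n_neg = int(np.sum(y < 0))
    if n_neg:
        if floored_counter is not None:
            floored_counter[0] += n_neg
        else:
            warnings.warn(f"{n_neg} negative residual draw(s) floored at 0", stacklevel=2)
        y = np.maximum(y, 0.0)
    return float(y) if y.ndim == 0 else y


def _build_doses(arm, design: StudyDesign, body_weight: float) -> list[DoseEvent]:
    doses = []
    for t, mgkg in arm.dosing(design.schedule):
        duration = design.infusion_duration if arm.route == Route.IV_INFUSION else 0.0
        doses.append(DoseEvent(time=t, amount=mgkg * body_weight,
                               route=arm.route, duration=duration))
    return doses


def simulate_trial(
    design: StudyDesign,
    *,
    pk_params: PKParams | None = None,
    pd_params: Mapping[Observable, PDParams] | None = None,
    pk_bsv: BSVSpec | None = None,
    pd_bsv: Mapping[Observable, BSVSpec] | None = None,
    residual: ResidualSpec | None = None,
    baseline_spec: BaselineSpec | None = None,
    seed=0,
    placebo_cv: float = 0.27,
    early_dip: bool = False,
    early_dip_fraction: float = 0.15,
    observe_cells: tuple = (Observable.NK, Observable.B, Observable.T),
    pk_rtol: float = 1e-8,
) -> SimulatedTrial:
    """Simulate one whole trial from a design template.

    Per subject: a body weight uniform on the plausible monkey range, actual
    dose amounts = dose level (mg/kg) x body weight, lognormal individual
    parameters, model-predicted profiles, residual error, and BLQ flags for
    drug assay values below the design's LLOQ.  Predose cell counts (times
    <= 0) fluctuate around the subject's true baseline, and their per-subject
    average is reported in the BL column, mirroring how baselines enter the
    analysis dataset.  PD samples within 8 h of a dose carry ``early_flag``
    (optionally with a transient nonspecific dip, off by default).

    ``pd_params=None`` with default arguments simulates the typical models at
    each subject's sampled baseline; pass an explicit empty mapping and
    ``observe_cells=()`` for a PK-only trial.
    """
    if pk_params is None:
        pk_params = PKParams.monkey_typical()

    ss = np.random.SeedSequence([int(seed) % (2**31), 0x51B])
    rng_cov, rng_par, rng_obs, rng_base = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )

    n_total = design.n_subjects
    if baseline_spec is not None:
        base_draws = sample_baselines(n_total, baseline_spec, seed=rng_base)
    else:
        # no sampling requested: every subject at the typical medians
        spec = BaselineSpec()
        base_draws = {
            cell: {"counts": np.full(n_total, cb.median)}
            for cell, cb in spec.cells.items()
        }
    lo, hi = MONKEY_WEIGHT_RANGE_KG
    weights = rng_cov.uniform(lo, hi, size=n_total)
    n_female = design.n_female if design.n_female is not None else n_total // 2
    sexes = ["F"] * n_female + ["M"] * (n_total - n_female)
    floored = [0]

    subjects: list[Subject] = []
    data: list[SubjectData] = []
    idx = 0
    for arm_no, arm in enumerate(design.arms):
        for k in range(arm.n):
            sid = f"{design.name}-a{arm_no + 1}-{k + 1:02d}"
            bw = float(weights[idx])
            baselines = {
                cell: float(base_draws[cell]["counts"][idx]) for cell in base_draws
            }
            ipk, etas = draw_individual_params(pk_params, pk_bsv, rng_par)
            ipk = ipk.replace(
                VC=apply_route_covariate(ipk.VC, arm.route, ipk.THETA_ROUT),
                THETA_ROUT=0.0,
            )
            ipd: dict[Observable, PDParams] = {}
            for cell in observe_cells:
                cell = Observable(cell)
                tv = (pd_params or {}).get(cell) or PDParams.typical(cell)
                tv = tv.replace(BL=baselines[cell])
                cell_bsv = (pd_bsv or {}).get(cell)
                drawn, pd_etas = draw_individual_params(tv, cell_bsv, rng_par)
                etas.update({f"{cell.value}.{k2}": v for k2, v in pd_etas.items()})
                ipd[cell] = drawn

            doses = _build_doses(arm, design, bw)
            sub = SubjectData(subject_id=sid, doses=doses,
                              body_weight=bw, sex=sexes[idx])

            pk_times = np.asarray(design.pk_sampling_times, dtype=float)
            pd_times = np.asarray(design.pd_sampling_times, dtype=float)
            t_end = float(max(
                pk_times[-1] if pk_times.size else 0.0,
                pd_times[-1] if pd_times.size else 0.0,
                0.0,
            ))

            if doses:
                grid = np.union1d(dense_simulation_grid(doses, t_end),
                                  pk_times[pk_times >= 0])
                profile = simulate_pk(ipk, doses, grid, rtol=pk_rtol, atol=1e-10)
                conc = (grid, profile.cfree)
            else:
                conc = (np.array([0.0, t_end]), np.zeros(2))

            # --- drug assay rows
            if doses and pk_times.size:
                pred = np.interp(pk_times, conc[0], conc[1], left=0.0)
                yobs = add_residual_error(pred, Observable.PK, residual,
                                          rng_obs, floored)
                for t, y in zip(pk_times, yobs):
                    sub.observations.append(ObservationRecord(
                        subject_id=sid, time=float(t), observable=Observable.PK,
                        value=float(y), blq_flag=bool(y < design.lloq),
                    ))

            # --- cell count rows
            dose_times = np.array([d.time for d in doses]) if doses else np.empty(0)
            for cell in ipd:
                pdp = ipd[cell]
                pre_mask = pd_times <= 0
                post_mask = ~pre_mask
                pred = np.empty_like(pd_times)
                pred[pre_mask] = pdp.BL
                if post_mask.any():
                    if doses:
                        prof = simulate_cells(pdp, conc, pd_times[post_mask])
                        pred[post_mask] = prof.counts
                    else:
                        pred[post_mask] = pdp.BL
                early = np.zeros(pd_times.shape, dtype=bool)
                for dt in dose_times:
                    early |= (pd_times > dt) & (pd_times - dt < EARLY_PD_WINDOW_DAYS)
                if early_dip and early.any():
                    pred = np.where(early, pred * (1.0 - early_dip_fraction), pred)
                if doses:
                    yobs = add_residual_error(pred, cell, residual, rng_obs, floored)
                else:
                    # placebo: within-animal fluctuation around the baseline
                    eps = rng_obs.normal(0.0, placebo_cv, size=pred.shape)
                    yobs = np.maximum(pred * (1.0 + eps), 0.0)
                bl_obs = yobs[pre_mask]
                bl_column = float(np.mean(bl_obs)) if bl_obs.size else pdp.BL
                if bl_column <= 0:
                    bl_column = pdp.BL
                for t, y, e in zip(pd_times, yobs, early):
                    sub.observations.append(ObservationRecord(
                        subject_id=sid, time=float(t), observable=cell,
                        value=float(y), baseline=bl_column, early_flag=bool(e),
                    ))

            sub.observations.sort(key=lambda o: (o.time, o.observable.value))
            subjects.append(Subject(
                subject_id=sid, sex=sexes[idx], body_weight=bw,
                route=arm.route, baselines=baselines, individual_etas=etas,
            ))
            data.append(sub)
            idx += 1

    return SimulatedTrial(subjects=subjects, data=data, seed=int(seed),
                          design=design, lloq=design.lloq, n_floored=floored[0])
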