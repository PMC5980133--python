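"""Monkey-to-human parameter scaling and first-in-human (FIH) simulation.

Volumes and clearances are scaled by body-weight power laws, the standard
practice for monoclonal antibodies:

    P_human = P_monkey * (BW_human / BW_monkey)^b

with b = 1.0 for the two volumes of distribution and b = 0.85 for the two
clearances.  Absorption, bioavailability and the target-binding (TMDD)
parameters are carried over unchanged — a conservative choice in the
absence of human target-turnover data — as are the cell-depletion
parameters, whose percent-of-baseline outputs depend only weakly on the
absolute baselines.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .datamodel import DoseEvent, Observable, PDParams, PKParams, Route
from .pd import simulate_cells
from .pk import apply_route_covariate, dense_simulation_grid, simulate_pk

__all__ = ["ScalingSpec", "scale_params", "simulate_fih", "FIHCellSummary", "FIHResult"]

SCALED_AS_VOLUME = ("VC", "VP")
SCALED_AS_CLEARANCE = ("CL", "Q")


@dataclass(frozen=True)
class ScalingSpec:
    reference_weight_monkey: float = 3.0  # kg
    reference_weight_human: float = 70.0  # kg
    exponent_volumes: float = 1.0
    exponent_clearances: float = 0.85

    def __post_init__(self) -> None:
        if self.reference_weight_monkey <= 0 or self.reference_weight_human <= 0:
            raise ValueError("reference weights must be positive")
        for e in (self.exponent_volumes, self.exponent_clearances):
            if not 0.0 <= e <= 1.2:
                raise ValueError("allometric exponents expected in [0, 1.2]")


def scale_params(monkey: PKParams, spec: ScalingSpec | None = None) -> PKParams:
    """Human PK parameters from the monkey typical values.

    Multiplicative and composition-consistent: scaling 3→21 kg then
    21→70 kg equals scaling 3→70 kg directly.
    """
    spec = spec or ScalingSpec()
    ratio = spec.reference_weight_human / spec.reference_weight_monkey
    changes = {}
    for name in SCALED_AS_VOLUME:
        changes[name] = getattr(monkey, name) * ratio**spec.exponent_volumes
    for name in SCALED_AS_CLEARANCE:
        changes[name] = getattr(monkey, name) * ratio**spec.exponent_clearances
    return monkey.replace(**changes)


@dataclass
class FIHCellSummary:
    nadir_percent: float  # % of baseline at the deepest depletion
    time_to_nadir: float  # day
    time_to_50pct_recovery: float | None  # day; None if not reached in horizon


@dataclass
class FIHResult:
    dose_mg_per_kg: float
    route: Route
    times: np.ndarray
    concentration: np.ndarray  # free drug, μg/mL
    Cmax: float
    cells_percent: dict[Observable, np.ndarray]
    summaries: dict[Observable, FIHCellSummary]


def simulate_fih(
    dose_mg_per_kg: float,
    route: Route,
    human_pk: PKParams | None = None,
    pd_params: Mapping[Observable, PDParams] | None = None,
    *,
    body_weight: float = 70.0,
    infusion_duration: float = 2.0 / 24.0,  # 2-hour IV infusion
    horizon: float = 84.0,  # days
    spec: ScalingSpec | None = None,
) -> FIHResult:
    """Deterministic typical-human profiles after a single dose.

    IV doses are given as a 2-hour zero-order infusion, SC doses as a depot
    injection (with the SC route effect on the central volume).  Returns the
    free-concentration profile plus percent-of-baseline curves and nadir /
    recovery summaries for NK, B and T cells.  ``human_pk`` defaults to the
    monkey typical values scaled by ``spec``.
    """
    route = Route(route)
    if human_pk is None:
        human_pk = scale_params(PKParams.monkey_typical(), spec)
    if pd_params is None:
        pd_params = {
            Observable.NK: PDParams.nk_typical(),
            Observable.B: PDParams.b_typical(),
            Observable.T: PDParams.t_typical(),
        }
    times = np.unique(np.concatenate([
        np.linspace(0.0, horizon, 600),
        np.linspace(0.0, min(2.0, horizon), 200),
    ]))
    if dose_mg_per_kg > 0:
        amount = dose_mg_per_kg * body_weight
        if route == Route.IV_INFUSION:
            doses = [DoseEvent(0.0, amount, route, infusion_duration)]
        elif route == Route.IV_BOLUS:
            doses = [DoseEvent(0.0, amount, route)]
        else:
            doses = [DoseEvent(0.0, amount, Route.SC)]
        params = human_pk.replace(
            VC=apply_route_covariate(human_pk.VC, route, human_pk.THETA_ROUT),
            THETA_ROUT=0.0,
        )
        grid = dense_simulation_grid(doses, horizon)
        prof = simulate_pk(params, doses, grid)
        conc = np.interp(times, grid, prof.cfree)
        conc_input = (grid, prof.cfree)
    else:
        conc = np.zeros_like(times)
        conc_input = (times, conc)

    cells_percent: dict[Observable, np.ndarray] = {}
    summaries: dict[Observable, FIHCellSummary] = {}
    for cell, pdp in pd_params.items():
        prof_pd = simulate_cells(pdp, conc_input, times)
        pct = prof_pd.percent_of_baseline
        cells_percent[cell] = pct
        i_nadir = int(np.argmin(pct))
        recovery = None
        after = np.nonzero((times > times[i_nadir]) & (pct >= 50.0))[0]
        if after.size:
            recovery = float(times[after[0]])
        summaries[cell] = FIHCellSummary(
            nadir_percent=float(pct[i_nadir]),
            time_to_nadir=float(times[i_nadir]),
            time_to_50pct_recovery=recovery,
        )
    return FIHResult(
        dose_mg_per_kg=dose_mg_per_kg, route=route, times=times,
        concentration=conc, Cmax=float(np.max(conc)),
        cells_percent=cells_percent, summaries=summaries,
    )
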