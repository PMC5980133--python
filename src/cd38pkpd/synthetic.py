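"""Synthetic monkey-trial data generation.

Everything downstream (estimation, NCA, scaling) is exercised on data built
here: lognormal baseline cell counts calibrated to the observed population
median/IQR, CD38-positive fractions, anti-drug-antibody (ADA) emergence over
time, placebo fluctuation, and the eight historical study designs (dose
range 0.03–100 mg/kg; IV bolus, 30-min IV infusion and SC; single, weekly
and every-other-week schedules).

The ADA onset model is *fabricated*: the source data only support the
qualitative statement that immunogenicity developed over time in the
repeated-dose studies.  Every parameter of it is config-exposed
(:class:`AdaOnsetConfig`) and the defaults should be treated as such.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .datamodel import (
    Dataset,
    Observable,
    Route,
    StudyArm,
    StudyDesign,
)

__all__ = [
    "BaselineSpec",
    "CellBaseline",
    "AdaOnsetConfig",
    "lognormal_from_median_iqr",
    "sample_baselines",
    "generate_ada_flags",
    "generate_study_dataset",
    "STUDY_DESIGNS",
    "TABLE1_SAMPLE_COUNTS",
]

Z75 = 0.6744897501960817  # standard normal upper quartile


@dataclass(frozen=True)
class CellBaseline:
    median: float  # cells/μL
    q1: float
    q3: float
    cd38_mean: float  # fraction of cells expressing the target
    cd38_sd: float

    def __post_init__(self):
        if not 0 < self.q1 < self.median < self.q3:
            raise ValueError("quartiles must satisfy q1 < median < q3")
        if not 0 <= self.cd38_mean <= 1:
            raise ValueError("CD38+ fraction must lie in [0, 1]")


@dataclass(frozen=True)
class BaselineSpec:
    """Population baseline distributions per cell type.

    Defaults reproduce the observed healthy-monkey summaries: NK 685
    (IQR 482.8–970.1), B 1279 (860.8–1890), T 3732 (2881–5176) cells/μL,
    with CD38+ fractions 86.7% (SD 11.3), 58.7% (27.0), 34.5% (24.5).
    """

    cells: Mapping[Observable, CellBaseline] = field(
        default_factory=lambda: {
            Observable.NK: CellBaseline(685.0, 482.8, 970.1, 0.867, 0.113),
            Observable.B: CellBaseline(1279.0, 860.8, 1890.0, 0.587, 0.270),
            Observable.T: CellBaseline(3732.0, 2881.0, 5176.0, 0.345, 0.245),
        }
    )


def lognormal_from_median_iqr(median: float, q1: float, q3: float) -> tuple[float, float]:
    """(mu, sigma) of the lognormal matching a printed median and IQR.

    mu = ln(median); sigma = (ln q3 - ln q1) / (2 * z_0.75).  When the IQR is
    log-symmetric about the median the quantiles are recovered exactly;
    otherwise sigma is the symmetrised compromise between the two one-sided
    estimates.
    """
    if not 0 < q1 < median < q3:
        raise ValueError("require 0 < q1 < median < q3")
    mu = math.log(median)
    sigma = (math.log(q3) - math.log(q1)) / (2.0 * Z75)
    return mu, sigma


def sample_baselines(
    n: int,
    spec: BaselineSpec | None = None,
    seed=None,
) -> dict[Observable, dict[str, np.ndarray]]:
    """Draw per-subject baseline counts and CD38+ fractions.

    Counts are lognormal per cell type; CD38+ fractions are normal truncated
    to [0, 1].  Returns, per cell type, arrays ``counts`` and ``cd38``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    spec = spec or BaselineSpec()
    rng = np.random.default_rng(seed)
    out: dict[Observable, dict[str, np.ndarray]] = {}
    for cell, cb in spec.cells.items():
        mu, sigma = lognormal_from_median_iqr(cb.median, cb.q1, cb.q3)
        counts = rng.lognormal(mean=mu, sigma=sigma, size=n)
        if cb.cd38_sd > 0:
            loc = _truncnorm_loc(cb.cd38_mean, cb.cd38_sd)
            a = (0.0 - loc) / cb.cd38_sd
            b = (1.0 - loc) / cb.cd38_sd
            cd38 = stats.truncnorm.rvs(
                a, b, loc=loc, scale=cb.cd38_sd, size=n, random_state=rng
            )
        else:
            cd38 = np.full(n, cb.cd38_mean)
        out[cell] = {"counts": counts, "cd38": cd38}
    return out


def _truncnorm_loc(target_mean: float, sd: float) -> float:
    """Location of a [0, 1]-truncated normal whose *truncated* mean is the
    printed population mean (moment matching; plain truncation would shift
    the NK mean by ~0.02)."""
    from scipy.optimize import brentq

    def trunc_mean(loc):
        a, b = (0.0 - loc) / sd, (1.0 - loc) / sd
        return stats.truncnorm.mean(a, b, loc=loc, scale=sd)

    return brentq(lambda loc: trunc_mean(loc) - target_mean, -1.0, 2.0, xtol=1e-10)


@dataclass(frozen=True)
class AdaOnsetConfig:
    """Invented ADA emergence model: a per-subject onset time.

    A subject ever seroconverts with probability ``p_ever`` (defaults differ
    between repeated- and single-dose designs); onset is ``start_day`` plus
    an exponential delay with mean ``mean_delay_days``.  Once positive a
    subject stays positive, so flags are monotone in time.
    """

    p_ever_repeat: float = 0.3
    p_ever_single: float = 0.05
    start_day: float = 28.0
    mean_delay_days: float = 28.0

    def p_ever(self, n_doses: int) -> float:
        return self.p_ever_repeat if n_doses > 1 else self.p_ever_single


def generate_ada_flags(
    observation_times: Sequence[float],
    n_doses: int,
    config: AdaOnsetConfig | None = None,
    seed=None,
) -> np.ndarray:
    """ADA present/absent flags for one subject's observation times.

    Monotone within subject: False before the drawn onset, True from onset
    onward.  ``p_ever`` of zero (or a hazardless config) yields no flags.
    """
    config = config or AdaOnsetConfig()
    rng = np.random.default_rng(seed)
    times = np.asarray(observation_times, dtype=float)
    if rng.random() >= config.p_ever(n_doses):
        return np.zeros(times.shape, dtype=bool)
    onset = config.start_day + rng.exponential(config.mean_delay_days)
    return times >= onset


# ---------------------------------------------------------------------------
# The eight historical study templates
# ---------------------------------------------------------------------------

_INF = 0.5 / 24.0  # 30-minute infusion, in days

def _qw(n):  # weekly dosing days
    return tuple(7.0 * i for i in range(n))


STUDY_DESIGNS: dict[int, StudyDesign] = {
    1: StudyDesign(
        name="study-1",
        arms=(
            StudyArm(0.0, Route.IV_INFUSION, 2),
            StudyArm(1.0, Route.IV_INFUSION, 4, schedule=((0.0, 1.0), (28.0, 2.0))),
        ),
        schedule=(0.0, 28.0),
        pk_sampling_times=(0.0, 0.083, 0.25, 1, 2, 4, 7, 10, 14, 21, 28,
                           28.083, 28.25, 29, 31, 35, 42, 49, 56),
        pd_sampling_times=(-3, 0.0, 1, 4, 7, 14, 28, 31, 42, 56),
        infusion_duration=_INF,
        lloq=0.061,
        n_female=0,
    ),
    2: StudyDesign(
        name="study-2",
        arms=(
            StudyArm(0.0, Route.IV_INFUSION, 3),
            StudyArm(0.3, Route.IV_INFUSION, 3),
            StudyArm(3.0, Route.IV_INFUSION, 3),
        ),
        schedule=(0.0,),
        pk_sampling_times=(0.0, 0.083, 0.25, 1, 2, 4, 7, 10, 14, 21, 28, 35, 42, 56),
        pd_sampling_times=(-3, 0.0, 1, 4, 7, 14, 28, 42, 56),
        infusion_duration=_INF,
        n_female=0,
    ),
    3: StudyDesign(
        name="study-3",
        arms=(
            StudyArm(0.0, Route.IV_INFUSION, 3),
            StudyArm(1.0, Route.IV_INFUSION, 3),
            StudyArm(30.0, Route.IV_INFUSION, 3),
            StudyArm(100.0, Route.IV_INFUSION, 3),
        ),
        schedule=_qw(4),
        pk_sampling_times=(0.0, 0.083, 1, 4, 7, 14, 21, 21.083, 22, 25, 28,
                           35, 42, 49, 56),
        pd_sampling_times=(-3, 0.0, 4, 7, 14, 22, 28, 42),
        infusion_duration=_INF,
        n_female=4,
    ),
    4: StudyDesign(
        name="study-4",
        arms=(
            StudyArm(0.0, Route.IV_INFUSION, 10),
            StudyArm(3.0, Route.IV_INFUSION, 10),
            StudyArm(30.0, Route.IV_INFUSION, 10),
            StudyArm(80.0, Route.IV_INFUSION, 10),
        ),
        schedule=tuple(14.0 * i for i in range(7)),
        pk_sampling_times=(0.0, 0.083, 1, 4, 7, 14, 14.083, 28, 28.083, 42,
                           42.083, 56, 56.083, 70, 70.083, 84, 84.083, 85, 88,
                           91, 98, 105, 112, 126, 140, 154, 168, 182),
        pd_sampling_times=(-3, 0.0, 1, 7, 14, 28, 42, 56, 70, 84, 85, 91, 98,
                           112, 126, 154, 182),
        infusion_duration=_INF,
        n_female=20,
    ),
    5: StudyDesign(
        name="study-5",
        arms=(
            StudyArm(0.0, Route.IV_BOLUS, 13),
            StudyArm(0.1, Route.IV_BOLUS, 13),
            StudyArm(0.3, Route.IV_BOLUS, 13),
            StudyArm(1.0, Route.IV_BOLUS, 13),
        ),
        schedule=_qw(13),
        pk_sampling_times=(0.0, 0.083, 0.25, 1, 2, 4, 7, 14, 21, 28, 35, 42,
                           49, 56, 63, 70, 77, 84, 84.083, 85, 86, 88, 91, 98,
                           105, 112, 119, 126, 140, 154, 168),
        pd_sampling_times=(-3, 0.0, 7, 28, 56, 84, 91, 112, 140),
        n_female=26,
    ),
    6: StudyDesign(
        name="study-6",
        arms=(
            StudyArm(0.0, Route.IV_BOLUS, 10),
            StudyArm(0.1, Route.IV_BOLUS, 10),
        ),
        schedule=_qw(13),
        pk_sampling_times=(0.0, 0.083, 0.25, 1, 2, 4, 7, 14, 21, 28, 35, 42,
                           49, 56, 63, 70, 77, 84, 84.083, 85, 86, 88, 91, 98,
                           105, 112, 119, 126, 140, 154, 168),
        pd_sampling_times=(-3, 0.0, 7, 28, 56, 84, 91, 112, 140, 168),
        n_female=20,
    ),
    7: StudyDesign(
        name="study-7",
        arms=(
            StudyArm(0.1, Route.IV_BOLUS, 3),
            StudyArm(0.3, Route.IV_BOLUS, 3),
            StudyArm(1.0, Route.IV_BOLUS, 3),
            StudyArm(1.0, Route.SC, 3),
        ),
        schedule=(0.0,),
        pk_sampling_times=(0.0, 0.083, 0.25, 0.5, 1, 2, 3, 5, 7, 10, 14, 21,
                           28, 35, 42, 56),
        pd_sampling_times=(-3, 0.0, 0.25, 1, 2, 3, 5, 7, 10, 14, 21, 28, 35,
                           42, 49, 56),
        n_female=12,
    ),
    8: StudyDesign(
        name="study-8",
        arms=(
            StudyArm(0.03, Route.IV_BOLUS, 4),
            StudyArm(0.1, Route.IV_BOLUS, 4),
            StudyArm(0.3, Route.IV_BOLUS, 4),
            StudyArm(0.03, Route.SC, 4),
            StudyArm(0.1, Route.SC, 4),
            StudyArm(0.3, Route.SC, 4),
        ),
        schedule=(0.0,),
        pk_sampling_times=(0.0, 0.083, 0.25, 0.5, 1, 2, 3, 4, 5, 7, 10, 14,
                           17, 21, 24, 28, 35, 42, 56),
        pd_sampling_times=(-3, 0.0, 0.25, 1, 2, 3, 4, 5, 7, 10, 14, 17, 21,
                           24, 28, 35, 42, 49, 56),
        n_female=24,
    ),
}

#: (PK, PD) samples per animal in the historical study table.
TABLE1_SAMPLE_COUNTS = {
    1: (19, 10), 2: (14, 9), 3: (15, 8), 4: (28, 17),
    5: (31, 9), 6: (31, 10), 7: (16, 16), 8: (19, 19),
}

for _sid, (_npk, _npd) in TABLE1_SAMPLE_COUNTS.items():
    assert len(STUDY_DESIGNS[_sid].pk_sampling_times) == _npk, _sid
    assert len(STUDY_DESIGNS[_sid].pd_sampling_times) == _npd, _sid


def generate_study_dataset(
    study,
    seed,
    *,
    pk_params=None,
    pd_params=None,
    pk_bsv=None,
    pd_bsv=None,
    residual=None,
    baseline_spec=None,
    ada_config: AdaOnsetConfig | None = None,
    early_dip: bool = False,
) -> Dataset:
    """Generate one complete synthetic study dataset.

    ``study`` is a template id (1..8) or a custom :class:`StudyDesign`.
    Defaults: final typical PK/PD parameters, printed between-subject
    variabilities and residual variances, baselines per
    :class:`BaselineSpec`, and the (fabricated) default ADA onset model.
    The result is reproducible from ``seed`` alone and round-trips through
    the CSV dialect.
    """
    from .population import simulate_trial  # deferred: population imports us

    design = STUDY_DESIGNS[study] if isinstance(study, int) else study
    trial = simulate_trial(
        design,
        pk_params=pk_params,
        pd_params=pd_params,
        pk_bsv=pk_bsv,
        pd_bsv=pd_bsv,
        residual=residual,
        baseline_spec=baseline_spec or BaselineSpec(),
        seed=seed,
        early_dip=early_dip,
    )
    dataset = trial.to_dataset()

    # overlay ADA flags on post-dose PK observations, monotone per subject
    ada_config = ada_config or AdaOnsetConfig()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), 0xADA]))
    for sub in dataset.subjects:
        n_doses = len(sub.doses)
        if n_doses == 0:
            continue
        pk_idx = [
            i for i, o in enumerate(sub.observations)
            if o.observable == Observable.PK and o.time > 0
        ]
        flags = generate_ada_flags(
            [sub.observations[i].time for i in pk_idx], n_doses, ada_config,
            seed=rng.integers(2**31),
        )
        for i, flag in zip(pk_idx, flags):
            if flag:
                obs = sub.observations[i]
                sub.observations[i] = type(obs)(
                    subject_id=obs.subject_id, time=obs.time,
                    observable=obs.observable, value=obs.value,
                    baseline=obs.baseline, ada_flag=True,
                    blq_flag=obs.blq_flag, early_flag=obs.early_flag,
                )
    dataset.lloq = design.lloq
    return dataset
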