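"""Shared domain types and the longitudinal dataset dialect.

The package exchanges trial data in a NONMEM-flavoured wide CSV: one row per
dosing event or observation, with an ``OBS_TYPE`` column multiplexing serum
drug concentration (PK) and the three lymphocyte counts (NK, B, T cells).
Dose rows are identified by a non-empty ``AMT``.  All times are in days,
concentrations in μg/mL, cell counts in cells/μL, amounts in mg.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field, fields, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Route",
    "Observable",
    "CellType",
    "PKParams",
    "PDParams",
    "BSVSpec",
    "ResidualSpec",
    "DoseEvent",
    "ObservationRecord",
    "Subject",
    "SubjectData",
    "Dataset",
    "StudyArm",
    "StudyDesign",
    "read_dataset",
    "write_dataset",
    "relative_to_baseline",
    "exclude_flagged",
    "ExclusionResult",
    "MONKEY_WEIGHT_RANGE_KG",
    "DEFAULT_LLOQ",
    "EARLY_PD_WINDOW_DAYS",
]

MONKEY_WEIGHT_RANGE_KG = (2.1, 4.7)
DEFAULT_LLOQ = 0.05  # μg/mL (first study used 0.061)
EARLY_PD_WINDOW_DAYS = 8.0 / 24.0  # PD samples this close after a dose are flagged


class Route(str, enum.Enum):
    IV_BOLUS = "IV_BOLUS"
    IV_INFUSION = "IV_INFUSION"
    SC = "SC"


class Observable(str, enum.Enum):
    PK = "PK"
    NK = "NK"
    B = "B"
    T = "T"


#: The three measured lymphocyte populations.
CellType = Observable  # PD observables; Observable.PK is the drug assay


@dataclass(frozen=True)
class PKParams:
    """Fixed-effect parameters of the two-compartment QSS-TMDD model.

    ``F_logit`` is the logit-scale bioavailability parameter (the model is
    estimated on logit scale so that F stays in (0, 1)); ``THETA_ROUT`` is the
    proportional effect of the SC route on the central volume ``VC``.
    Receptor amounts use an arbitrary unit "u" coupled 1:1 to drug
    concentration units (1 u/L binds one μg/mL-equivalent of drug).
    """

    F_logit: float  # unitless, logit of bioavailability
    KA: float  # 1/day, first-order absorption from the SC depot
    CL: float  # L/day, linear clearance
    VC: float  # L, central volume
    Q: float  # L/day, intercompartmental clearance
    VP: float  # L, peripheral volume
    KINT: float  # 1/day, drug-target complex internalisation
    KSS: float  # μg/mL, quasi-steady-state constant (KOFF+KINT)/KON
    KSYN: float  # u/L per day, receptor synthesis
    KDEG: float  # 1/day, receptor degradation
    THETA_ROUT: float = 0.0  # proportional SC-route effect on VC

    def __post_init__(self) -> None:
        for name in ("KA", "CL", "VC", "Q", "VP", "KINT", "KSS", "KDEG"):
            if getattr(self, name) <= 0:
                raise ValueError(f"PKParams.{name} must be strictly positive")
        if self.KSYN < 0:
            raise ValueError("PKParams.KSYN must be non-negative")
        if not math.isfinite(self.F_logit):
            raise ValueError("PKParams.F_logit must be finite")
        if 1.0 + self.THETA_ROUT <= 0:
            raise ValueError("route covariate must leave VC positive")

    @property
    def F(self) -> float:
        """Bioavailability on the natural (0, 1) scale."""
        return 1.0 / (1.0 + math.exp(-self.F_logit))

    @property
    def rtot_baseline(self) -> float:
        """Drug-free equilibrium total receptor concentration KSYN/KDEG (u/L)."""
        return self.KSYN / self.KDEG

    def replace(self, **changes) -> "PKParams":
        return replace(self, **changes)

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def monkey_typical(cls) -> "PKParams":
        """Final population estimates in the 2.1–4.7 kg cynomolgus monkey."""
        return cls(
            F_logit=math.log(0.227 / (1.0 - 0.227)),
            KA=0.399,
            CL=0.0187,
            VC=0.141,
            Q=0.127,
            VP=0.127,
            KINT=0.1,
            KSS=5.68,
            KSYN=0.04,
            KDEG=0.00452,
            THETA_ROUT=-0.697,
        )


@dataclass(frozen=True)
class PDParams:
    """Structural parameters of one cell-depletion model.

    For NK cells (turnover model) and B cells (4-transit-compartment model)
    ``EMAX`` is the maximal *additional depletion rate* (1/day) acting on the
    cell pool; for T cells (direct response) it is the maximal depleted
    *fraction* and must lie in [0, 1].  ``KIN`` is NK-only, ``MTT`` B-only.
    ``BL`` is the individual baseline count.
    """

    cell_type: Observable
    C50: float  # μg/mL
    EMAX: float
    BL: float  # cells/μL
    KIN: float | None = None  # cells/μL per day (NK)
    MTT: float | None = None  # day (B)
    hill: float = 1.0  # fixed to 1 in the final models; exposed as an option

    def __post_init__(self) -> None:
        if self.cell_type == Observable.PK:
            raise ValueError("PDParams.cell_type must be NK, B or T")
        if self.C50 <= 0:
            raise ValueError("C50 must be positive")
        if self.BL <= 0:
            raise ValueError("baseline must be positive")
        if self.EMAX < 0:
            raise ValueError("EMAX must be non-negative")
        if self.cell_type == Observable.T and not 0.0 <= self.EMAX <= 1.0:
            raise ValueError("T-cell EMAX is a depleted fraction in [0, 1]")
        if self.cell_type == Observable.NK and (self.KIN is None or self.KIN <= 0):
            raise ValueError("NK model requires KIN > 0")
        if self.cell_type == Observable.B and (self.MTT is None or self.MTT <= 0):
            raise ValueError("B-cell model requires MTT > 0")
        if self.hill <= 0:
            raise ValueError("Hill exponent must be positive")

    @property
    def KOUT(self) -> float:
        """NK first-order elimination rate, fixed by KOUT = KIN/BL (1/day)."""
        if self.cell_type != Observable.NK:
            raise AttributeError("KOUT is defined for the NK turnover model only")
        return self.KIN / self.BL

    @property
    def KTR(self) -> float:
        """Transit/proliferation/circulation rate 4/MTT (1/day, B cells)."""
        if self.cell_type != Observable.B:
            raise AttributeError("KTR is defined for the B-cell transit model only")
        return 4.0 / self.MTT

    def effect(self, c):
        """Emax drug effect E(c) = EMAX * c^h / (c^h + C50^h)."""
        c = np.asarray(c, dtype=float)
        ch = np.power(np.maximum(c, 0.0), self.hill)
        return self.EMAX * ch / (ch + self.C50**self.hill)

    def replace(self, **changes) -> "PDParams":
        return replace(self, **changes)

    @classmethod
    def nk_typical(cls, BL: float = 685.0) -> "PDParams":
        return cls(Observable.NK, C50=27.5, EMAX=414.6, BL=BL, KIN=13957.0)

    @classmethod
    def b_typical(cls, BL: float = 1279.0) -> "PDParams":
        return cls(Observable.B, C50=19.8, EMAX=2.43, BL=BL, MTT=8.19)

    @classmethod
    def t_typical(cls, BL: float = 3732.0) -> "PDParams":
        return cls(Observable.T, C50=11.86, EMAX=0.4656, BL=BL)

    @classmethod
    def typical(cls, cell_type: Observable, BL: float | None = None) -> "PDParams":
        factory = {
            Observable.NK: cls.nk_typical,
            Observable.B: cls.b_typical,
            Observable.T: cls.t_typical,
        }[Observable(cell_type)]
        return factory() if BL is None else factory(BL)


@dataclass(frozen=True)
class BSVSpec:
    """Between-subject variability: parameter name -> %CV as a fraction.

    Individual parameters are lognormal, PAR_i = TVPAR * exp(eta_i) with
    eta_i ~ N(0, omega^2).  By the common reporting convention the printed
    %CV is taken as omega directly; set ``exact_lognormal`` for
    omega^2 = ln(1 + CV^2).  Random effects are uncorrelated (diagonal).
    """

    cv_by_param: Mapping[str, float] = field(default_factory=dict)
    exact_lognormal: bool = False

    def __post_init__(self) -> None:
        for name, cv in self.cv_by_param.items():
            if cv < 0:
                raise ValueError(f"CV for {name} must be >= 0")

    def omega(self, name: str) -> float:
        cv = self.cv_by_param.get(name, 0.0)
        if self.exact_lognormal:
            return math.sqrt(math.log1p(cv * cv))
        return cv

    @classmethod
    def pk_typical(cls) -> "BSVSpec":
        return cls({"KA": 0.421, "CL": 0.429, "VC": 0.198, "VP": 0.394, "KINT": 0.493})

    @classmethod
    def none(cls) -> "BSVSpec":
        return cls({})


@dataclass(frozen=True)
class ResidualSpec:
    """Residual (unexplained) variability.

    PK uses a combined model y = f*(1+eps_p) + eps_a; PD is proportional-only
    per cell type.  Magnitudes are variances (NONMEM SIGMA convention); set
    ``magnitudes_are_sd`` if supplying standard deviations instead.
    """

    pk_additive_var: float = 3.17e-4  # (μg/mL)^2
    pk_proportional_var: float = 0.0677
    pd_proportional_var: Mapping[Observable, float] = field(
        default_factory=lambda: {
            Observable.NK: 0.2905,
            Observable.B: 0.136,
            Observable.T: 0.1343,
        }
    )
    magnitudes_are_sd: bool = False

    def __post_init__(self) -> None:
        if self.pk_additive_var < 0 or self.pk_proportional_var < 0:
            raise ValueError("variances must be non-negative")
        for v in self.pd_proportional_var.values():
            if v < 0:
                raise ValueError("variances must be non-negative")

    def _var(self, x: float) -> float:
        return x * x if self.magnitudes_are_sd else x

    def variances(self, observable: Observable) -> tuple[float, float]:
        """(additive_var, proportional_var) for one observable."""
        observable = Observable(observable)
        if observable == Observable.PK:
            return self._var(self.pk_additive_var), self._var(self.pk_proportional_var)
        return 0.0, self._var(self.pd_proportional_var.get(observable, 0.0))

    @classmethod
    def none(cls) -> "ResidualSpec":
        return cls(0.0, 0.0, {o: 0.0 for o in (Observable.NK, Observable.B, Observable.T)})


@dataclass(frozen=True)
class DoseEvent:
    time: float  # day
    amount: float  # mg
    route: Route
    duration: float = 0.0  # day; positive iff IV infusion

    def __post_init__(self) -> None:
        if self.amount <= 0:
            raise ValueError("dose amount must be positive")
        if self.route == Route.IV_INFUSION:
            if self.duration <= 0:
                raise ValueError("infusion requires a positive duration")
        elif self.duration != 0:
            raise ValueError("duration must be 0 unless route is IV_INFUSION")


@dataclass(frozen=True)
class ObservationRecord:
    subject_id: str
    time: float  # day
    observable: Observable
    value: float  # μg/mL (PK) or cells/μL (PD)
    baseline: float | None = None  # cells/μL; present iff PD row
    ada_flag: bool = False
    blq_flag: bool = False
    early_flag: bool = False  # PD sample < 8 h after a dose

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("observed value must be non-negative")
        if self.blq_flag and self.observable != Observable.PK:
            raise ValueError("BLQ flags apply to PK observations only")
        is_pd = self.observable != Observable.PK
        if is_pd and self.baseline is None:
            raise ValueError("PD observations require a baseline")
        if not is_pd and self.baseline is not None:
            raise ValueError("PK observations carry no baseline")


@dataclass(frozen=True)
class Subject:
    """A simulated animal: realized covariates, baselines and random effects."""

    subject_id: str
    sex: str  # "F" / "M"
    body_weight: float  # kg
    route: Route
    baselines: Mapping[Observable, float] = field(default_factory=dict)
    individual_etas: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lo, hi = MONKEY_WEIGHT_RANGE_KG
        if not lo <= self.body_weight <= hi:
            warnings.warn(
                f"body weight {self.body_weight} kg outside the plausible "
                f"monkey range [{lo}, {hi}]",
                stacklevel=2,
            )
        for cell, bl in self.baselines.items():
            if bl <= 0:
                raise ValueError(f"baseline for {cell} must be positive")


@dataclass
class SubjectData:
    """All dosing events and observations of one subject."""

    subject_id: str
    doses: list[DoseEvent] = field(default_factory=list)
    observations: list[ObservationRecord] = field(default_factory=list)
    body_weight: float | None = None
    sex: str | None = None

    @property
    def route(self) -> Route | None:
        """Primary route of administration (from the first dose)."""
        return self.doses[0].route if self.doses else None


@dataclass
class Dataset:
    subjects: list[SubjectData] = field(default_factory=list)
    lloq: float = DEFAULT_LLOQ

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def observations(self) -> list[ObservationRecord]:
        return [o for s in self.subjects for o in s.observations]

    def subject(self, subject_id: str) -> SubjectData:
        for s in self.subjects:
            if s.subject_id == subject_id:
                return s
        raise KeyError(subject_id)


@dataclass(frozen=True)
class StudyArm:
    """One dose group.  ``dose_mg_per_kg`` 0 denotes placebo.

    ``schedule`` optionally overrides the design-level dosing times with
    per-occasion (time, mg/kg) pairs (used by designs whose dose level
    changes between occasions).
    """

    dose_mg_per_kg: float
    route: Route
    n: int
    schedule: tuple[tuple[float, float], ...] | None = None

    def __post_init__(self) -> None:
        if self.dose_mg_per_kg < 0 or self.n < 1:
            raise ValueError("invalid study arm")

    @property
    def is_placebo(self) -> bool:
        return self.dose_mg_per_kg == 0 and self.schedule is None

    def dosing(self, design_times: Sequence[float]) -> list[tuple[float, float]]:
        """(time, mg/kg) dose occasions for this arm."""
        if self.schedule is not None:
            return list(self.schedule)
        if self.is_placebo:
            return []
        return [(t, self.dose_mg_per_kg) for t in design_times]


@dataclass(frozen=True)
class StudyDesign:
    """A trial template: arms, dosing schedule and sampling times (days)."""

    name: str
    arms: tuple[StudyArm, ...]
    schedule: tuple[float, ...]  # dosing times (day), placebo-adjusted per arm
    pk_sampling_times: tuple[float, ...]
    pd_sampling_times: tuple[float, ...]
    infusion_duration: float = 0.0  # day; >0 when IV doses are infusions
    lloq: float = DEFAULT_LLOQ
    n_female: int | None = None

    def __post_init__(self) -> None:
        for times in (self.pk_sampling_times, self.pd_sampling_times):
            arr = np.asarray(times, dtype=float)
            if arr.size and np.any(np.diff(arr) <= 0):
                raise ValueError("sampling times must be strictly increasing")
        if any(t < 0 for t in self.schedule):
            raise ValueError("dosing times must be non-negative")

    @property
    def n_subjects(self) -> int:
        return sum(a.n for a in self.arms)

    @property
    def dose_levels(self) -> tuple[float, ...]:
        return tuple(sorted({a.dose_mg_per_kg for a in self.arms}))

    @property
    def route(self) -> Route | None:
        """The common route, or None for mixed-route designs."""
        routes = {a.route for a in self.arms if not a.is_placebo}
        return routes.pop() if len(routes) == 1 else None


# ---------------------------------------------------------------------------
# Dataset CSV dialect
# ---------------------------------------------------------------------------

CSV_COLUMNS = [
    "ID", "TIME", "AMT", "DUR", "ROUTE", "DV", "OBS_TYPE",
    "BL", "ADA", "BLQ", "EARLY", "BW", "SEX",
]
_MANDATORY = ["ID", "TIME", "AMT", "DUR", "ROUTE", "DV", "OBS_TYPE", "BL", "ADA", "BLQ"]


class SchemaError(ValueError):
    pass


def _fmt(x) -> str:
    if x is None:
        return ""
    if isinstance(x, bool):
        return "1" if x else "0"
    if isinstance(x, str):
        return x
    if isinstance(x, float) and math.isnan(x):
        return ""
    return repr(float(x))


def dataset_to_frame(dataset: Dataset) -> pd.DataFrame:
    rows = []
    for s in dataset.subjects:
        events: list[tuple[float, int, dict]] = []
        for d in s.doses:
            events.append((d.time, 0, {
                "ID": s.subject_id, "TIME": d.time, "AMT": d.amount,
                "DUR": d.duration if d.duration else "",
                "ROUTE": d.route.value, "DV": "", "OBS_TYPE": "",
                "BL": "", "ADA": "", "BLQ": "", "EARLY": "",
                "BW": s.body_weight, "SEX": s.sex or "",
            }))
        for o in s.observations:
            events.append((o.time, 1, {
                "ID": s.subject_id, "TIME": o.time, "AMT": "", "DUR": "",
                "ROUTE": "", "DV": o.value, "OBS_TYPE": o.observable.value,
                "BL": o.baseline if o.baseline is not None else "",
                "ADA": int(o.ada_flag), "BLQ": int(o.blq_flag),
                "EARLY": int(o.early_flag),
                "BW": s.body_weight, "SEX": s.sex or "",
            }))
        events.sort(key=lambda e: (e[0], e[1]))
        rows.extend(e[2] for e in events)
    frame = pd.DataFrame(rows, columns=CSV_COLUMNS)
    return frame


def write_dataset(dataset: Dataset, path) -> None:
    """Write the canonical CSV form (stable float formatting via repr)."""
    frame = dataset_to_frame(dataset)
    with open(path, "w", newline="") as fh:
        fh.write(",".join(CSV_COLUMNS) + "\n")
        for row in frame.itertuples(index=False):
            fh.write(",".join(_fmt(v) for v in row) + "\n")


def _flag(value) -> bool:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return False
    return bool(int(float(value)))


def read_dataset(path, lloq: float = DEFAULT_LLOQ) -> Dataset:
    """Parse the CSV dialect into per-subject dose events and observations.

    Rows with a non-empty AMT are dose events; all others are observations.
    """
    frame = pd.read_csv(path, dtype={"ID": str}, keep_default_na=True,
                        float_precision="round_trip")
    missing = [c for c in _MANDATORY if c not in frame.columns]
    if missing:
        raise SchemaError(f"dataset is missing mandatory column(s): {', '.join(missing)}")
    if (frame["TIME"] < 0).any() and (
        frame.loc[frame["TIME"] < 0, "AMT"].notna().any()
    ):
        raise ValueError("dose events cannot have negative times")
    dataset = Dataset(lloq=lloq)
    for sid, grp in frame.groupby("ID", sort=False):
        sub = SubjectData(subject_id=str(sid))
        if "BW" in grp.columns and grp["BW"].notna().any():
            sub.body_weight = float(grp["BW"].dropna().iloc[0])
        if "SEX" in grp.columns and grp["SEX"].notna().any():
            sub.sex = str(grp["SEX"].dropna().iloc[0])
        for row in grp.itertuples(index=False):
            amt = getattr(row, "AMT")
            if amt is not None and not (isinstance(amt, float) and math.isnan(amt)):
                dur = getattr(row, "DUR")
                dur = 0.0 if (isinstance(dur, float) and math.isnan(dur)) else float(dur)
                sub.doses.append(DoseEvent(
                    time=float(row.TIME), amount=float(amt),
                    route=Route(str(row.ROUTE)), duration=dur,
                ))
            else:
                obs_type = Observable(str(row.OBS_TYPE))
                bl = getattr(row, "BL")
                bl = None if (bl is None or (isinstance(bl, float) and math.isnan(bl))) else float(bl)
                early = _flag(getattr(row, "EARLY", 0)) if hasattr(row, "EARLY") else False
                sub.observations.append(ObservationRecord(
                    subject_id=str(sid), time=float(row.TIME),
                    observable=obs_type, value=float(row.DV),
                    baseline=bl, ada_flag=_flag(row.ADA),
                    blq_flag=_flag(row.BLQ), early_flag=early,
                ))
        dataset.subjects.append(sub)
    return dataset


# ---------------------------------------------------------------------------
# Elementary transforms and filters
# ---------------------------------------------------------------------------

def relative_to_baseline(count, baseline):
    """Express a cell count as percent of the individual baseline.

    A value of 33% means the sample held one third of the baseline count.
    """
    count = np.asarray(count, dtype=float)
    baseline = np.asarray(baseline, dtype=float)
    if np.any(baseline <= 0):
        raise ValueError("baseline must be strictly positive")
    out = 100.0 * count / baseline
    return float(out) if out.ndim == 0 else out


@dataclass
class ExclusionResult:
    retained: list[ObservationRecord]
    excluded: list[ObservationRecord]
    counts: dict[str, int]


def exclude_flagged(
    records: Iterable[ObservationRecord],
    drop_ada: bool = True,
    drop_blq: bool = True,
    drop_early_pd: bool = True,
) -> ExclusionResult:
    """Partition records into retained and excluded by their QC flags.

    ADA-affected and below-LLOQ samples are excluded from model development;
    PD samples within 8 h of a dose reflect a nonspecific drug-independent
    effect and are likewise dropped.  Counts report each flag category
    independently (a doubly-flagged record increments both).
    """
    retained: list[ObservationRecord] = []
    excluded: list[ObservationRecord] = []
    counts = {"ada": 0, "blq": 0, "early_pd": 0}
    for rec in records:
        drop = False
        if drop_ada and rec.ada_flag:
            counts["ada"] += 1
            drop = True
        if drop_blq and rec.blq_flag:
            counts["blq"] += 1
            drop = True
        if drop_early_pd and rec.early_flag and rec.observable != Observable.PK:
            counts["early_pd"] += 1
            drop = True
        (excluded if drop else retained).append(rec)
    return ExclusionResult(retained=retained, excluded=excluded, counts=counts)
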