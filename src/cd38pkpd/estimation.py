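"""Likelihood construction and parameter estimation.

Estimation follows the staged strategy used for this class of models: the
PK model is fitted first (optionally with the target-binding block frozen
via a fixed-parameter mask), then each cell-depletion model is fitted with
the PK fixed.

Two modes are provided:

* ``pooled`` — naive-pooled maximum likelihood: one set of typical values
  fitted to all subjects' data at once.
* ``two-stage`` — each subject fitted separately, the reported estimate
  being the median of the individual estimates (a robust estimator of the
  population median under lognormal between-subject variability).

Both minimise the Gaussian -2*log-likelihood with a combined
additive + proportional error for the drug assay and proportional-only for
cell counts.  Numerically this is iteratively reweighted least squares:
weights are frozen at the current predictions, a Levenberg-Marquardt pass
updates the parameters on log scale (logit scale for bioavailability), and
the weights are refreshed — frozen-weight refits avoid the downward-bias of
letting the proportional weights track the parameters inside the solver.
Below-quantification observations are excluded (M1), as are ADA-affected
samples and early (<8 h) cell counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize

from .datamodel import (
    Dataset,
    Observable,
    PDParams,
    PKParams,
    ResidualSpec,
    SubjectData,
    exclude_flagged,
)
from .pk import SolverError, apply_route_covariate, dense_simulation_grid, simulate_pk
from .pd import simulate_cells, turnover_on_grid

__all__ = [
    "FitResult",
    "neg2_loglik",
    "pk_neg2_loglik",
    "fit_pk",
    "fit_pd",
]

_PRED_FLOOR = 1e-12
# parameters optimised on an unconstrained scale rather than log scale
_UNCONSTRAINED = {"F_logit", "THETA_ROUT"}


def _sigma2(f, add_var: float, prop_var: float):
    f = np.maximum(np.asarray(f, dtype=float), _PRED_FLOOR)
    return add_var + prop_var * f * f


def neg2_loglik(y, f, *, additive_var: float = 0.0, proportional_var: float) -> float:
    """-2 log-likelihood of observations under the Gaussian residual model.

    Per observation: ln(2*pi*sigma^2(f)) + (y - f)^2 / sigma^2(f) with
    sigma^2(f) = additive_var + proportional_var * f^2.
    """
    y = np.asarray(y, dtype=float)
    f = np.asarray(f, dtype=float)
    s2 = _sigma2(f, additive_var, proportional_var)
    if np.any(s2 <= 0):
        raise FloatingPointError("non-positive predicted variance")
    return float(np.sum(np.log(2.0 * math.pi * s2) + (y - f) ** 2 / s2))


@dataclass
class FitResult:
    estimates: dict[str, float]
    objective: float  # -2 log-likelihood at the estimates
    fixed: tuple[str, ...]
    mode: str
    n_obs: int
    converged: bool
    message: str = ""
    se_percent: dict[str, float] | None = None
    individual: "object | None" = None  # per-subject estimates (two-stage)
    history: list = field(default_factory=list)

    def __getitem__(self, name: str) -> float:
        return self.estimates[name]


# ---------------------------------------------------------------------------
# parameter packing
# ---------------------------------------------------------------------------

def _is_fraction(params, name: str) -> bool:
    # the T-cell maximal effect is a depleted fraction, bounded in (0, 1)
    return name == "EMAX" and getattr(params, "cell_type", None) == Observable.T


def _pack(params, names: Sequence[str]) -> np.ndarray:
    out = []
    for n in names:
        v = getattr(params, n)
        if n in _UNCONSTRAINED:
            out.append(v)
        elif _is_fraction(params, n):
            out.append(math.log(v / (1.0 - v)))  # logit
        else:
            out.append(math.log(v))
    return np.array(out)


# |log parameter| cap: keeps trial iterates physically sane (e.g. a peripheral
# volume of e-12 L would make the disposition system pathologically stiff and
# can stall the ODE solver for minutes inside one optimizer step)
_LOG_BOUND = 12.0


def _unpack(params, names: Sequence[str], theta: np.ndarray):
    changes = {}
    for n, t in zip(names, theta):
        if n in _UNCONSTRAINED:
            changes[n] = t
        else:
            t = min(max(t, -_LOG_BOUND), _LOG_BOUND)
            if _is_fraction(params, n):
                changes[n] = 1.0 / (1.0 + math.exp(-t))  # inverse logit
            else:
                changes[n] = math.exp(t)
    return params.replace(**changes)


def _irls(residual_fn, theta0: np.ndarray, n_rounds: int = 6,
          presearch: str = "auto"):
    """Frozen-weight IRLS: residual_fn(theta, reweight) -> whitened residuals.

    Weights are refreshed at each outer iterate and frozen during the inner
    Levenberg-Marquardt solve; iteration stops once the (log-scale)
    parameters move by less than 1e-5.  When ``presearch`` is on and the
    start is far from the data (mean whitened residual^2 > 9; mode
    "auto") or unconditionally (mode "always"), a derivative-free simplex
    pass runs first so the gradient polish starts inside the right basin.  The first pass uses data-based weights (set by
    the caller): model-based weights at a far-off start would distort the
    search objective.
    """
    theta = np.asarray(theta0, dtype=float)
    result = None
    if presearch != "off":
        r0 = residual_fn(theta, False)
        if presearch == "always" or np.mean(r0 * r0) > 9.0:
            sol = optimize.minimize(
                lambda th: float(np.sum(residual_fn(th, False) ** 2)),
                theta,
                method="Nelder-Mead",
                options={"maxiter": 400 * theta.size, "xatol": 1e-7, "fatol": 1e-9},
            )
            theta = sol.x
    for _ in range(n_rounds):
        residual_fn(theta, True)  # refresh weights at the current iterate
        result = optimize.least_squares(
            lambda th: residual_fn(th, False), theta, method="lm", x_scale="jac",
            # finite-difference step must sit well above the ODE solver noise,
            # or the Jacobian degenerates and the solve stalls at the start
            diff_step=1e-3,
            max_nfev=120 * theta.size,
        )
        done = np.max(np.abs(result.x - theta)) < 1e-5
        theta = result.x
        if done:
            break
    return theta, result


# ---------------------------------------------------------------------------
# PK fitting
# ---------------------------------------------------------------------------

def _pk_observations(sub: SubjectData, drop_ada: bool, drop_blq: bool):
    kept = exclude_flagged(
        [o for o in sub.observations if o.observable == Observable.PK],
        drop_ada=drop_ada, drop_blq=drop_blq, drop_early_pd=False,
    ).retained
    times = np.array([o.time for o in kept])
    y = np.array([o.value for o in kept])
    order = np.argsort(times, kind="stable")
    return times[order], y[order]


_MAX_RATE = 1e3  # 1/day; no mAb disposition process is faster — reject sooner


def _pk_predict(params: PKParams, sub: SubjectData, times: np.ndarray,
                rtol: float) -> np.ndarray:
    ind = params.replace(
        VC=apply_route_covariate(params.VC, sub.route, params.THETA_ROUT),
        THETA_ROUT=0.0,
    )
    rates = (ind.CL / ind.VC, ind.Q / ind.VC, ind.Q / ind.VP, ind.KA)
    if max(rates) > _MAX_RATE:
        raise SolverError(f"implausibly fast disposition rate {max(rates):.3g}/day")
    return simulate_pk(ind, sub.doses, times, rtol=rtol, atol=1e-10).cfree


def pk_neg2_loglik(
    dataset: Dataset,
    params: PKParams,
    residual: ResidualSpec,
    *,
    drop_ada: bool = True,
    drop_blq: bool = True,
    rtol: float = 1e-6,
) -> float:
    """Naive-pooled -2LL of a dataset's drug-assay records under ``params``."""
    add_var, prop_var = residual.variances(Observable.PK)
    total = 0.0
    for sub in dataset.subjects:
        times, y = _pk_observations(sub, drop_ada, drop_blq)
        if not times.size:
            continue
        f = _pk_predict(params, sub, times, rtol)
        total += neg2_loglik(y, f, additive_var=add_var, proportional_var=prop_var)
    return total


def _fit_pk_single(
    subjects: list[SubjectData],
    init: PKParams,
    names: Sequence[str],
    residual: ResidualSpec,
    drop_ada: bool,
    drop_blq: bool,
    rtol: float,
    presearch: str = "auto",
):
    add_var, prop_var = residual.variances(Observable.PK)
    obs = []
    for sub in subjects:
        times, y = _pk_observations(sub, drop_ada, drop_blq)
        if times.size:
            obs.append((sub, times, y))
    if not obs:
        raise ValueError("no usable drug-assay observations to fit")
    y_all = np.concatenate([y for _, _, y in obs])
    y_floor = np.maximum(y_all, 1e-3 * np.max(y_all))  # zero obs: finite weight
    weights = {"w": 1.0 / np.sqrt(_sigma2(y_floor, add_var, prop_var))}

    def predict_all(params):
        return np.concatenate([_pk_predict(params, s, t, rtol) for s, t, _ in obs])

    def residuals(theta, reweight):
        params = _unpack(init, names, theta)
        try:
            f = predict_all(params)
        except SolverError:
            if reweight:  # keep previous weights on a failed trial point
                return None
            return np.full_like(y_all, 1e6)  # push the optimizer away
        if reweight:
            weights["w"] = 1.0 / np.sqrt(_sigma2(f, add_var, prop_var))
            return None
        return (y_all - f) * weights["w"]

    theta, res = _irls(residuals, _pack(init, names), presearch=presearch)
    est_params = _unpack(init, names, theta)
    obj = neg2_loglik(y_all, predict_all(est_params),
                      additive_var=add_var, proportional_var=prop_var)
    return est_params, obj, y_all.size, res


def fit_pk(
    dataset: Dataset,
    init: PKParams,
    *,
    fit: Sequence[str] = ("CL", "VC", "Q", "VP"),
    residual: ResidualSpec | None = None,
    mode: str = "pooled",
    drop_ada: bool = True,
    drop_blq: bool = True,
    rtol: float = 1e-6,
    compute_se: bool = False,
) -> FitResult:
    """Fit the PK model.  Parameters not named in ``fit`` are held fixed.

    The fixed mask mirrors the staged strategy in which the target-binding
    (TMDD) block, estimated from low-dose data, is frozen while the
    disposition parameters are refitted on richer data.  Warns when every
    dose lies above the TMDD-sensitive range yet TMDD parameters are free.
    """
    import warnings

    residual = residual or ResidualSpec()
    names = list(fit)
    all_names = set(init.as_dict())
    unknown = [n for n in names if n not in all_names]
    if unknown:
        raise ValueError(f"unknown parameter(s): {unknown}")
    tmdd_free = {"KSS", "KSYN", "KDEG", "KINT"} & set(names)
    if tmdd_free:
        min_dose = min(
            (d.amount for s in dataset.subjects for d in s.doses), default=None
        )
        if min_dose is not None and min_dose / init.VC > 20.0 * init.KSS:
            warnings.warn(
                "all doses are far above the target-mediated range; "
                f"TMDD parameters {sorted(tmdd_free)} are poorly identifiable",
                stacklevel=2,
            )
    fixed = tuple(sorted(all_names - set(names)))

    if mode == "pooled":
        est, obj, n_obs, res = _fit_pk_single(
            dataset.subjects, init, names, residual, drop_ada, drop_blq, rtol
        )
        result = FitResult(
            estimates={n: getattr(est, n) for n in names},
            objective=obj, fixed=fixed, mode=mode, n_obs=n_obs,
            converged=bool(res.success), message=str(res.message),
        )
    elif mode == "two-stage":
        import pandas as pd

        rows = []
        total_obj = 0.0
        total_n = 0
        ok = True
        for sub in dataset.subjects:
            try:
                est, obj, n_obs, res = _fit_pk_single(
                    [sub], init, names, residual, drop_ada, drop_blq, rtol,
                    presearch="off",  # the median across subjects absorbs strays
                )
            except (ValueError, SolverError):
                continue
            ok &= bool(res.success)
            total_obj += obj
            total_n += n_obs
            rows.append({"subject_id": sub.subject_id,
                         **{n: getattr(est, n) for n in names}})
        if not rows:
            raise ValueError("no subject could be fitted")
        individual = pd.DataFrame(rows)
        result = FitResult(
            estimates={n: float(individual[n].median()) for n in names},
            objective=total_obj, fixed=fixed, mode=mode, n_obs=total_n,
            converged=ok, individual=individual,
        )
    else:
        raise ValueError(f"unknown mode {mode!r} (expected 'pooled' or 'two-stage')")

    if compute_se:
        result.se_percent = _se_percent(
            lambda p: pk_neg2_loglik(dataset, p, residual, drop_ada=drop_ada,
                                     drop_blq=drop_blq, rtol=rtol),
            _unpack(init, names, _pack(init, names)).replace(**result.estimates),
            names,
        )
    return result


# ---------------------------------------------------------------------------
# PD fitting (PK fixed)
# ---------------------------------------------------------------------------

def _pd_observations(sub: SubjectData, cell: Observable, drop_ada: bool):
    kept = exclude_flagged(
        [o for o in sub.observations if o.observable == cell and o.time > 0],
        drop_ada=drop_ada, drop_blq=False, drop_early_pd=True,
    ).retained
    times = np.array([o.time for o in kept])
    y = np.array([o.value for o in kept])
    bl = float(kept[0].baseline) if kept else np.nan
    order = np.argsort(times, kind="stable")
    return times[order], y[order], bl


def fit_pd(
    dataset: Dataset,
    cell_type: Observable,
    pk_params: PKParams,
    init: PDParams,
    *,
    fit: Sequence[str] | None = None,
    residual: ResidualSpec | None = None,
    mode: str = "pooled",
    drop_ada: bool = False,
    rtol: float = 1e-6,
    compute_se: bool = False,
    presearch: str = "always",
    estimate_baselines: bool | None = None,
) -> FitResult:
    """Fit one cell-depletion model with the PK model frozen (sequential fit).

    Each subject's concentration time-course is tabulated once from its own
    dosing history under ``pk_params``, then the structural PD parameters
    are estimated from the cell counts.  Early (<8 h post-dose) samples are
    excluded; the per-subject BL column anchors the baseline.

    ``estimate_baselines`` mirrors the random effect the published analysis
    places on the individual baseline: the BL column (a mean of a couple of
    noisy predose samples) is refined against all of the animal's
    measurements.  For the B and T models the prediction is proportional to
    the baseline, so the per-subject adjustment factor is profiled out in
    closed form at every objective evaluation (bounded to [1/2, 2]); it is
    on by default for those models and unavailable for NK, whose baseline
    also sets the elimination rate KOUT = KIN/BL.
    """
    cell_type = Observable(cell_type)
    residual = residual or ResidualSpec()
    _, prop_var = residual.variances(cell_type)
    if prop_var <= 0:
        prop_var = 1e-4  # unweighted limit: proportional-only model needs var > 0
    if fit is None:
        fit = {"NK": ("KIN", "C50", "EMAX"),
               "B": ("MTT", "C50", "EMAX"),
               "T": ("C50", "EMAX")}[cell_type.value]
    names = list(fit)

    prepared = []
    for sub in dataset.subjects:
        if not sub.doses:
            continue  # placebo animals carry no exposure information
        times, y, bl = _pd_observations(sub, cell_type, drop_ada)
        if not times.size:
            continue
        t_end = float(times[-1])
        grid = dense_simulation_grid(sub.doses, t_end)
        ind_pk = pk_params.replace(
            VC=apply_route_covariate(pk_params.VC, sub.route, pk_params.THETA_ROUT),
            THETA_ROUT=0.0,
        )
        prof = simulate_pk(ind_pk, sub.doses, grid, rtol=rtol, atol=1e-10)
        prepared.append({"times": times, "y": y, "bl": bl,
                         "conc": (grid, prof.cfree)})
    if not prepared:
        raise ValueError(f"no usable {cell_type.value}-cell observations to fit")

    if estimate_baselines is None:
        estimate_baselines = cell_type != Observable.NK
    if estimate_baselines and cell_type == Observable.NK:
        raise ValueError("baseline profiling is unavailable for the NK model")

    y_all = np.concatenate([p["y"] for p in prepared])
    y_floor = np.maximum(y_all, 1e-3 * np.max(y_all))  # zero obs: finite weight
    weights = {"w": 1.0 / np.sqrt(_sigma2(y_floor, 0.0, prop_var))}
    slices = []
    start = 0
    for p in prepared:
        slices.append(slice(start, start + p["times"].size))
        start += p["times"].size

    def predict_all(pd_typ: PDParams) -> np.ndarray:
        preds = []
        for p in prepared:
            pdi = pd_typ.replace(BL=p["bl"])
            if cell_type == Observable.T:
                preds.append(simulate_cells(pdi, p["conc"], p["times"]).counts)
            else:
                # exponential integrator: stable for any trial parameters
                grid, conc = p["conc"]
                preds.append(turnover_on_grid(pdi, grid, conc, p["times"]))
        f = np.concatenate(preds)
        if estimate_baselines:
            # per-subject baseline adjustment, profiled by weighted regression
            w2 = weights["w"] ** 2
            for sl in slices:
                g, yy, ww = f[sl], y_all[sl], w2[sl]
                denom = float(np.sum(ww * g * g))
                if denom > 0:
                    s = float(np.sum(ww * g * yy)) / denom
                    f[sl] = g * min(max(s, 0.5), 2.0)
        return f

    def residuals(theta, reweight):
        pd_typ = _unpack(init, names, theta)
        try:
            f = predict_all(pd_typ)
        except SolverError:
            if reweight:
                return None
            return np.full_like(y_all, 1e6)  # push the optimizer away
        if reweight:
            weights["w"] = 1.0 / np.sqrt(_sigma2(f, 0.0, prop_var))
            return None
        return (y_all - f) * weights["w"]

    if mode != "pooled":
        raise ValueError("fit_pd supports the pooled mode")
    theta, res = _irls(residuals, _pack(init, names), presearch=presearch)
    est = _unpack(init, names, theta)
    obj = neg2_loglik(y_all, predict_all(est), proportional_var=prop_var)
    result = FitResult(
        estimates={n: getattr(est, n) for n in names},
        objective=obj, fixed=tuple(sorted({"KIN", "MTT", "C50", "EMAX"} - set(names))),
        mode=mode, n_obs=y_all.size,
        converged=bool(res.success), message=str(res.message),
    )
    if compute_se:
        def obj_fn(p: PDParams) -> float:
            return neg2_loglik(y_all, predict_all(p), proportional_var=prop_var)

        result.se_percent = _se_percent(obj_fn, est, names)
    return result


def _se_percent(obj_fn, params, names: Sequence[str], h: float = 1e-3):
    """Percent standard errors from a finite-difference Hessian of -2LL.

    The Hessian is taken on the transformed (log/unconstrained) scale; for
    log-scale parameters the SD of the log estimate is, by the delta method,
    the relative SE of the natural-scale estimate.
    """
    theta0 = _pack(params, names)
    k = theta0.size

    def f(th):
        return obj_fn(_unpack(params, names, th))

    hess = np.empty((k, k))
    f0 = f(theta0)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h
            ej = np.zeros(k); ej[j] = h
            if i == j:
                hess[i, i] = (f(theta0 + ei) - 2 * f0 + f(theta0 - ei)) / h**2
            else:
                hess[i, j] = hess[j, i] = (
                    f(theta0 + ei + ej) - f(theta0 + ei - ej)
                    - f(theta0 - ei + ej) + f(theta0 - ei - ej)
                ) / (4 * h**2)
    try:
        cov = 2.0 * np.linalg.inv(hess)  # Cov = [0.5 * Hessian(-2LL)]^-1
    except np.linalg.LinAlgError:
        return None
    sd = np.sqrt(np.maximum(np.diag(cov), 0.0))
    out = {}
    for i, n in enumerate(names):
        if n in _UNCONSTRAINED:
            denom = abs(getattr(params, n)) or 1.0
            out[n] = 100.0 * sd[i] / denom
        else:
            out[n] = 100.0 * sd[i]
    return out
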