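"""Noncompartmental analysis of concentration-time profiles.

Standard conventions: linear-up/log-down trapezoidal AUC; the terminal rate
constant λ_z from a log-linear regression over the best window (highest
adjusted R², candidate windows of at least 3 of the last 6 quantifiable
post-peak points); AUC extrapolated to infinity with C_last/λ_z;
CL = dose/AUC_inf (apparent CL/F for extravascular input) and
V_z = CL/λ_z.  Per-kg normalisations are reported when a body weight is
supplied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["NCAResult", "LambdaZFit", "auc_trapezoid", "lambda_z_fit", "nca_summary"]


@dataclass
class LambdaZFit:
    lambda_z: float  # 1/day
    intercept: float  # ln-concentration at t=0 of the regression
    r2_adjusted: float
    n_points: int
    window: tuple[float, float]  # (t_first, t_last) of the regression window


@dataclass
class NCAResult:
    Cmax: float  # μg/mL
    Tmax: float  # day
    AUC_last: float  # μg*day/mL
    AUC_inf: float | None
    lambda_z: float | None  # 1/day
    t_half: float | None  # day
    CL: float | None  # L/day (CL/F for extravascular dosing)
    Vz: float | None  # L
    CL_per_kg: float | None = None  # mL/kg/day
    Vz_per_kg: float | None = None  # mL/kg
    lambda_z_fit: LambdaZFit | None = None


def auc_trapezoid(times, concs, method: str = "linear-up/log-down") -> float:
    """AUC from t[0] to t[-1] by the trapezoidal rule.

    ``linear-up/log-down`` uses the logarithmic trapezoid on strictly
    decreasing positive segments (exact for mono-exponential decline) and
    the linear trapezoid elsewhere; ``linear`` is plain trapezoids.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(concs, dtype=float)
    if t.size < 2:
        raise ValueError("AUC needs at least two points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if np.any(c < 0):
        raise ValueError("concentrations must be non-negative")
    dt = np.diff(t)
    c1, c2 = c[:-1], c[1:]
    lin = 0.5 * (c1 + c2) * dt
    if method == "linear":
        return float(np.sum(lin))
    if method != "linear-up/log-down":
        raise ValueError(f"unknown AUC method {method!r}")
    down = (c2 < c1) & (c2 > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        logseg = (c1 - c2) * dt / np.log(c1 / c2)
    seg = np.where(down, logseg, lin)
    return float(np.sum(seg))


def lambda_z_fit(
    times,
    concs,
    *,
    min_points: int = 3,
    max_points: int = 6,
    lloq: float = 0.0,
) -> LambdaZFit | None:
    """Terminal slope by log-linear regression with best-window selection.

    Candidate windows are the last ``k`` quantifiable points strictly after
    Tmax, for k = min_points..max_points; the window with the highest
    adjusted R² wins (ties to the longer window).  Returns None when no
    admissible window exists or the slope is non-negative.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(concs, dtype=float)
    keep = c > max(lloq, 0.0)
    t, c = t[keep], c[keep]
    if t.size < min_points:
        return None
    i_max = int(np.argmax(c))
    t_tail, c_tail = t[i_max + 1:], c[i_max + 1:]
    if t_tail.size < min_points:
        return None
    best: LambdaZFit | None = None
    for k in range(min_points, min(max_points, t_tail.size) + 1):
        tw, cw = t_tail[-k:], np.log(c_tail[-k:])
        slope, intercept = np.polyfit(tw, cw, 1)
        if slope >= 0:
            continue
        pred = slope * tw + intercept
        ss_res = float(np.sum((cw - pred) ** 2))
        ss_tot = float(np.sum((cw - cw.mean()) ** 2))
        if ss_tot == 0:
            r2 = 1.0
        else:
            r2 = 1.0 - ss_res / ss_tot
        r2_adj = 1.0 - (1.0 - r2) * (k - 1) / (k - 2)
        cand = LambdaZFit(-slope, intercept, r2_adj, k, (float(tw[0]), float(tw[-1])))
        if best is None or cand.r2_adjusted >= best.r2_adjusted - 1e-12:
            best = cand
    return best


def nca_summary(
    times,
    concs,
    dose: float,
    *,
    body_weight: float | None = None,
    lloq: float = 0.0,
) -> NCAResult:
    """Full noncompartmental summary of one profile after a single dose.

    When no terminal slope can be estimated, AUC_inf and its dependants are
    reported as missing (partial result).
    """
    if dose <= 0:
        raise ValueError("dose must be positive")
    t = np.asarray(times, dtype=float)
    c = np.asarray(concs, dtype=float)
    i_max = int(np.argmax(c))
    cmax, tmax = float(c[i_max]), float(t[i_max])
    auc_last = auc_trapezoid(t, c)
    lam = lambda_z_fit(t, c, lloq=lloq)
    if lam is None:
        return NCAResult(cmax, tmax, auc_last, None, None, None, None, None)
    quant = c > max(lloq, 0.0)
    c_last = float(c[quant][-1])
    auc_inf = auc_last + c_last / lam.lambda_z
    cl = dose / auc_inf  # μg·day/mL and mg -> L/day
    vz = cl / lam.lambda_z
    res = NCAResult(
        Cmax=cmax, Tmax=tmax, AUC_last=auc_last, AUC_inf=auc_inf,
        lambda_z=lam.lambda_z, t_half=math.log(2.0) / lam.lambda_z,
        CL=cl, Vz=vz, lambda_z_fit=lam,
    )
    if body_weight is not None and body_weight > 0:
        res.CL_per_kg = 1000.0 * cl / body_weight  # mL/kg/day
        res.Vz_per_kg = 1000.0 * vz / body_weight  # mL/kg
    return res
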