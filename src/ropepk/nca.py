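"""Non-compartmental analysis of individual concentration-time profiles.

Model-free exposure metrics: peak concentration, linear-trapezoid AUC,
log-linear terminal slope (lambda_z) with adjusted-R^2 point selection, the
extrapolated AUC to infinity and the empirical apparent clearance
``CL/F = dose / AUC(0-inf)``.

Below-quantification values are expected to be filtered out upstream (the
same M1 convention the estimation uses); the pre-dose zero concentration is
included as the (0, 0) anchor of the AUC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import PKDataset, filter_blq

__all__ = [
    "NCAResult",
    "cmax_tmax",
    "auc_linear_trapezoid",
    "lambda_z_fit",
    "nca_summary",
    "nca_table",
]


@dataclass(frozen=True)
class NCAResult:
    cmax: float                   # ng/ml
    tmax: float                   # h
    auc_0_t: float                # ng*h/ml
    auc_0_inf: float              # ng*h/ml (nan when lambda_z undefined)
    lambda_z: float               # 1/h     (nan when undefined)
    n_lambda_points: int
    r2_adj: float
    extrapolated_fraction: float  # in [0, 1)
    cl_f: float                   # L/h (dose / auc_0_inf)


def cmax_tmax(times, conc) -> tuple[float, float]:
    """Peak concentration and its time, taken directly from the profile.

    Ties resolve to the earliest time.
    """
    times = np.asarray(times, dtype=float)
    conc = np.asarray(conc, dtype=float)
    if times.size == 0:
        raise ValueError("empty profile")
    i = int(np.argmax(conc))  # argmax returns the first maximum
    return float(conc[i]), float(times[i])


def auc_linear_trapezoid(times, conc, t_end: float | None = None) -> float:
    """Linear trapezoidal AUC from the first sampled time up to ``t_end``.

    ``t_end`` defaults to the last sampled time and may fall between grid
    points, in which case the profile is interpolated linearly (which keeps
    the trapezoid rule additive over subintervals).
    """
    times = np.asarray(times, dtype=float)
    conc = np.asarray(conc, dtype=float)
    if times.size < 2:
        return 0.0
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    if t_end is None:
        t_end = float(times[-1])
    if t_end > times[-1] + 1e-12:
        raise ValueError("t_end beyond the sampled range")
    mask = times <= t_end
    t_used = times[mask]
    c_used = conc[mask]
    total = float(np.trapezoid(c_used, t_used))
    if t_used.size and t_end > t_used[-1] + 1e-12:
        c_end = float(np.interp(t_end, times, conc))
        total += 0.5 * (c_used[-1] + c_end) * (t_end - t_used[-1])
    return total


def lambda_z_fit(times, conc, min_points: int = 3):
    """Terminal log-linear slope with automatic point selection.

    Among suffixes of the strictly-post-tmax positive concentrations with at
    least ``min_points`` points, picks the one maximising the adjusted R^2 of
    the log-linear least-squares fit (ties broken toward more points).  A
    non-negative slope (no decay) is rejected.

    Returns ``(lambda_z, n_points, r2_adj)`` or ``None`` when no usable fit
    exists; callers then report AUC(0-inf) as missing.
    """
    times = np.asarray(times, dtype=float)
    conc = np.asarray(conc, dtype=float)
    if times.size == 0:
        return None
    _, tmax = cmax_tmax(times, conc)
    mask = (times > tmax) & (conc > 0)
    t_term = times[mask]
    c_term = np.log(conc[mask])
    n = t_term.size
    if n < min_points:
        return None

    best = None  # (r2_adj, n_points, lambda_z)
    for start in range(0, n - min_points + 1):
        t_s = t_term[start:]
        c_s = c_term[start:]
        k = t_s.size
        slope, intercept, r, _, _ = stats.linregress(t_s, c_s)
        if slope >= 0 or not math.isfinite(slope):
            continue
        r2 = r * r
        r2_adj = 1.0 - (1.0 - r2) * (k - 1) / (k - 2) if k > 2 else r2
        cand = (r2_adj, k, -slope)
        if best is None or cand[0] > best[0] + 1e-12 or (abs(cand[0] - best[0]) <= 1e-12 and k > best[1]):
            best = cand
    if best is None:
        return None
    r2_adj, k, lam = best
    return float(lam), int(k), float(r2_adj)


def nca_summary(times, conc, dose: float, min_points: int = 3) -> NCAResult:
    """Full single-profile NCA.

    ``AUC(0-inf) = AUC(0-tlast) + Clast/lambda_z`` with ``Clast`` the last
    positive observed concentration; ``CL/F = dose / AUC(0-inf)``.
    """
    times = np.asarray(times, dtype=float)
    conc = np.asarray(conc, dtype=float)
    cmax, tmax = cmax_tmax(times, conc)
    auc_t = auc_linear_trapezoid(times, conc)
    fit = lambda_z_fit(times, conc, min_points=min_points)
    if fit is None:
        return NCAResult(cmax, tmax, auc_t, math.nan, math.nan, 0, math.nan, math.nan, math.nan)
    lam, n_pts, r2_adj = fit
    positive = conc > 0
    c_last = float(conc[positive][-1]) if positive.any() else 0.0
    tail = c_last / lam
    auc_inf = auc_t + tail
    frac = tail / auc_inf if auc_inf > 0 else math.nan
    cl_f = dose / auc_inf if auc_inf > 0 else math.nan
    return NCAResult(cmax, tmax, auc_t, auc_inf, lam, n_pts, r2_adj, frac, cl_f)


def nca_table(dataset: PKDataset, min_points: int = 3) -> pd.DataFrame:
    """Per-subject NCA over a dataset (BLQ samples excluded)."""
    ds = filter_blq(dataset)
    rows = []
    for sid in ds.subject_ids:
        doses = ds.doses(sid)
        if not doses:
            continue
        dose = sum(a for _, a in doses)
        times, conc = ds.observations(sid)
        if times.size == 0:
            continue
        res = nca_summary(times, conc, dose, min_points=min_points)
        cov = ds.covariates.get(sid)
        rows.append({
            "ID": sid,
            "study": cov.study if cov else None,
            "dose": dose,
            "cmax": res.cmax,
            "tmax": res.tmax,
            "auc_0_t": res.auc_0_t,
            "auc_0_inf": res.auc_0_inf,
            "lambda_z": res.lambda_z,
            "n_lambda_points": res.n_lambda_points,
            "r2_adj": res.r2_adj,
            "extrapolated_fraction": res.extrapolated_fraction,
            "cl_f": res.cl_f,
            "cl_f_per_day": res.cl_f * 24.0 if math.isfinite(res.cl_f) else math.nan,
        })
    return pd.DataFrame(rows)
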