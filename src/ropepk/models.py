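"""Structural pharmacokinetic models for a subcutaneously dosed PEGylated interferon.

Two one-compartment disposition models with first-order absorption and an
absorption lag are provided:

* a quasi-equilibrium target-mediated drug disposition (QE-TMDD) model, in
  which drug binds interferon receptors with dissociation constant ``KD``;
  the drug–receptor complex is internalised at rate ``kint`` and the free
  receptor pool turns over with synthesis rate ``ksyn = R0 * kdeg`` and
  degradation rate ``kdeg``.  Receptor-mediated uptake is a saturable,
  concentration-dependent elimination route on top of linear clearance.
* an empirical Michaelis–Menten (MM) elimination model, the conventional
  phenomenological description of saturable clearance.

All quantities are kept in a coherent internal unit system: time in hours,
amounts in micrograms, volumes in litres and concentrations in ng/ml
(1 ug/L == 1 ng/ml, so amount/volume needs no conversion factor).
Literature-style per-day rate constants are converted at the reporting
boundary with :data:`HOURS_PER_DAY`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.integrate import odeint

HOURS_PER_DAY = 24.0

__all__ = [
    "HOURS_PER_DAY",
    "TMDDParams",
    "MMParams",
    "DoseSchedule",
    "free_concentration",
    "tmdd_rhs",
    "tmdd_jacobian",
    "total_clearance",
    "mm_clearance",
    "solve_tmdd",
    "solve_mm",
    "bateman",
    "solve_onecpt",
    "TMDDModel",
    "MMModel",
    "OneCompartmentModel",
]


# ---------------------------------------------------------------------------
# parameter containers


@dataclass(frozen=True)
class TMDDParams:
    """QE-TMDD parameters in internal units (hours, litres, ng/ml).

    ``cl``   linear apparent clearance CL/F [L/h]
    ``v``    apparent central volume V/F [L]
    ``ka``   first-order absorption rate [1/h]
    ``tlag`` absorption lag time [h]
    ``r0``   baseline receptor concentration [ng/ml]
    ``kdeg`` receptor degradation rate [1/h]
    ``kint`` drug-receptor complex internalisation rate [1/h]
    ``kd``   equilibrium dissociation constant [ng/ml]

    The receptor synthesis rate is tied to the drug-free steady state,
    ``ksyn = r0 * kdeg``, so it is exposed as a derived property rather
    than an independent field.
    """

    cl: float
    v: float
    ka: float
    tlag: float
    r0: float
    kdeg: float
    kint: float
    kd: float

    def __post_init__(self) -> None:
        if self.v <= 0:
            raise ValueError("central volume must be positive")
        if self.kd <= 0:
            raise ValueError("KD must be positive (use a small value for the high-affinity limit)")
        for name in ("cl", "ka", "tlag", "r0", "kdeg", "kint"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def ksyn(self) -> float:
        """Receptor synthesis rate [ng/ml/h], pinned by the baseline."""
        return self.r0 * self.kdeg

    def with_(self, **kwargs) -> "TMDDParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class MMParams:
    """Michaelis-Menten elimination parameters (internal units).

    ``form`` selects how the printed clearance relation is turned into an
    elimination rate:

    * ``"printed"``     CL(C) = Vm*C/(Km+C), elimination rate CL(C)*C —
      clearance grows with concentration.
    * ``"conventional"`` elimination rate Vm*C/(Km+C), i.e.
      CL(C) = Vm/(Km+C) — clearance falls as elimination saturates, the
      classical Michaelis-Menten behaviour.
    """

    vm: float
    km: float
    v: float
    ka: float
    tlag: float
    form: str = "printed"

    def __post_init__(self) -> None:
        if self.vm <= 0 or self.km <= 0 or self.v <= 0:
            raise ValueError("vm, km and v must be positive")
        if self.ka < 0 or self.tlag < 0:
            raise ValueError("ka and tlag must be non-negative")
        if self.form not in ("printed", "conventional"):
            raise ValueError("form must be 'printed' or 'conventional'")


class DoseSchedule:
    """Ordered subcutaneous dose events ``(time [h], amount [ug])``."""

    def __init__(self, events: Iterable[tuple[float, float]]):
        events = [(float(t), float(a)) for t, a in events]
        for (t0, _), (t1, _) in zip(events, events[1:]):
            if t1 < t0:
                raise ValueError("dose times must be non-decreasing")
        for t, a in events:
            if t < 0:
                raise ValueError("dose times must be non-negative")
            if a <= 0:
                raise ValueError("dose amounts must be positive")
        self.events: list[tuple[float, float]] = events

    def __iter__(self):
        return iter(self.events)

    def __len__(self) -> int:
        return len(self.events)

    @classmethod
    def single(cls, amount: float, time: float = 0.0) -> "DoseSchedule":
        return cls([(time, amount)])


# ---------------------------------------------------------------------------
# binding equilibrium


def free_concentration(ctotal, rtotal, kd):
    """Free drug concentration at binding quasi-equilibrium.

    Solves the mass-balance quadratic
    ``Cfree * (1 + Rtotal/(KD + Cfree)) = Ctotal`` for the physical root

        Cfree = 0.5*[(Ctotal-Rtotal-KD) + sqrt((Ctotal-Rtotal-KD)^2 + 4*KD*Ctotal)]

    using the numerically stable branch (the naive formula cancels
    catastrophically when ``Ctotal - Rtotal - KD`` is large and negative).
    ``kd == 0`` is accepted as the infinite-affinity limit
    ``max(Ctotal - Rtotal, 0)``.  Accepts scalars or arrays.
    """
    ctotal = np.asarray(ctotal, dtype=float)
    rtotal = np.asarray(rtotal, dtype=float)
    kd_arr = np.asarray(kd, dtype=float)
    if np.any(ctotal < 0) or np.any(rtotal < 0) or np.any(kd_arr < 0):
        raise ValueError("free_concentration requires non-negative inputs")

    b = ctotal - rtotal - kd_arr
    disc = np.sqrt(b * b + 4.0 * kd_arr * ctotal)
    with np.errstate(divide="ignore", invalid="ignore"):
        # stable in both regimes: direct sum for b >= 0, rationalised for b < 0
        direct = 0.5 * (b + disc)
        rational = np.where(disc - b > 0, 2.0 * kd_arr * ctotal / np.where(disc - b > 0, disc - b, 1.0), 0.0)
    out = np.where(b >= 0, direct, rational)
    out = np.where(kd_arr == 0, np.maximum(b + kd_arr, 0.0), out)  # b+kd = ctotal-rtotal
    out = np.where(ctotal == 0, 0.0, out)
    if out.ndim == 0:
        return float(out)
    return out


def _cfree_scalar(ctotal: float, rtotal: float, kd: float) -> float:
    # scalar fast path used inside ODE right-hand sides
    if ctotal <= 0.0:
        return 0.0
    b = ctotal - rtotal - kd
    disc = math.sqrt(b * b + 4.0 * kd * ctotal)
    if b >= 0.0:
        return 0.5 * (b + disc)
    return 2.0 * kd * ctotal / (disc - b)


# ---------------------------------------------------------------------------
# QE-TMDD dynamics


def tmdd_rhs(t: float, state: Sequence[float], params: TMDDParams):
    """Time derivatives of ``(Adepot, Atotal, Rtotal)`` under the QE-TMDD model.

    ``dAdepot/dt = -ka*Adepot``
    ``dAtotal/dt = ka*Adepot - (CL/V)*Afree - Rtotal*kint*Afree/(KD + Cfree)``
    ``dRtotal/dt = ksyn - kdeg*Rtotal - (kint - kdeg)*(Ctotal - Cfree)``
    """
    adep, atot, rtot = state
    if not (math.isfinite(adep) and math.isfinite(atot) and math.isfinite(rtot)):
        raise FloatingPointError(f"non-finite TMDD state {state!r} at t={t}")
    p = params
    ctot = atot / p.v
    cfree = _cfree_scalar(ctot, rtot, p.kd)
    afree = cfree * p.v
    dadep = -p.ka * adep
    datot = p.ka * adep - (p.cl / p.v) * afree - rtot * p.kint * afree / (p.kd + cfree)
    drtot = p.ksyn - p.kdeg * rtot - (p.kint - p.kdeg) * (ctot - cfree)
    return (dadep, datot, drtot)


def tmdd_jacobian(t: float, state: Sequence[float], params: TMDDParams):
    """Analytic Jacobian of :func:`tmdd_rhs`; supplied to the stiff integrator."""
    adep, atot, rtot = state
    p = params
    ctot = atot / p.v
    cfree = _cfree_scalar(ctot, rtot, p.kd)

    b = ctot - rtot - p.kd
    disc = math.sqrt(b * b + 4.0 * p.kd * ctot)
    if disc == 0.0:  # only at ctot == 0 with kd -> 0; treat as unbound
        dcf_dct, dcf_dr = 1.0, 0.0
    else:
        dcf_dct = 0.5 * (1.0 + (b + 2.0 * p.kd) / disc)
        dcf_dr = -0.5 * (1.0 + b / disc)

    kd_cf = p.kd + cfree
    # d/dCfree of [CL*Cfree + R*kint*V*Cfree/(KD+Cfree)]
    delim_dcf = p.cl + rtot * p.kint * p.v * p.kd / (kd_cf * kd_cf)

    j21 = p.ka
    j22 = -delim_dcf * dcf_dct / p.v
    j23 = -p.kint * p.v * cfree / kd_cf - delim_dcf * dcf_dr
    j32 = -(p.kint - p.kdeg) * (1.0 - dcf_dct) / p.v
    j33 = -p.kdeg + (p.kint - p.kdeg) * dcf_dr
    return ((-p.ka, 0.0, 0.0), (j21, j22, j23), (0.0, j32, j33))


def total_clearance(cfree: float, params: TMDDParams, rtotal: float | None = None):
    """Decompose total clearance into linear and receptor-mediated parts.

    ``CLnonlinear = Rtotal*kint*V/KD * (1 - Cfree/(Cfree+KD))``, which
    collapses to ``Rtotal*kint*V/(KD+Cfree)``: fully available at low free
    concentration and vanishing as the receptor pool saturates.  ``rtotal``
    defaults to the drug-free baseline ``r0``.

    Returns ``(cl_total, cl_linear, cl_nonlinear)`` in L/h.
    """
    if cfree < 0:
        raise ValueError("cfree must be non-negative")
    rt = params.r0 if rtotal is None else rtotal
    cl_lin = params.cl
    cl_nl = rt * params.kint * params.v / params.kd * (1.0 - cfree / (cfree + params.kd))
    return cl_lin + cl_nl, cl_lin, cl_nl


# ---------------------------------------------------------------------------
# Michaelis-Menten dynamics


def mm_clearance(c: float, params: MMParams) -> float:
    """Concentration-dependent clearance CL(C) [L/h] under the selected form."""
    if c < 0:
        raise ValueError("concentration must be non-negative")
    if params.form == "printed":
        return params.vm * c / (params.km + c)
    return params.vm / (params.km + c)


def _mm_rhs(t, state, p: MMParams):
    adep, acen = state
    c = acen / p.v
    elim = mm_clearance(c, p) * c  # [L/h]*[ng/ml] = ug/h
    return (-p.ka * adep, p.ka * adep - elim)


# ---------------------------------------------------------------------------
# profile integration


def _dose_entries(params, doses: DoseSchedule) -> list[tuple[float, float]]:
    # lag is an exact time shift of each dose's arrival in the depot
    return sorted((t + params.tlag, a) for t, a in doses)


_MAX_LSODA_STEPS = 10000


def _odeint_checked(rhs, y, grid, args, jac, rtol, atol):
    import warnings

    from scipy.integrate import ODEintWarning

    with warnings.catch_warnings():
        # failures surface as exceptions below; the warning is redundant
        warnings.simplefilter("ignore", ODEintWarning)
        sol, info = odeint(
            rhs, y, grid, args=args, Dfun=jac, col_deriv=False, tfirst=True,
            rtol=rtol, atol=atol, mxstep=_MAX_LSODA_STEPS, full_output=True,
        )
    if info["message"] != "Integration successful." or not np.all(np.isfinite(sol)):
        raise FloatingPointError(
            f"ODE integration failed ({info['message']}; rtol={rtol}, atol={atol})"
        )
    return sol


def _integrate_segments(rhs, jac, y0, entries, times, args, rtol, atol):
    """Piecewise integration over dose-entry discontinuities.

    ``entries`` are (time, depot increment) events; between events the system
    is smooth and handled by LSODA.  Requested ``times`` must be sorted.
    Integration failures raise ``FloatingPointError`` with the tolerances in
    the message rather than returning partial trajectories.
    """
    times = np.asarray(times, dtype=float)
    if times.size and np.any(np.diff(times) < 0):
        raise ValueError("requested times must be sorted ascending")
    out = np.empty((times.size, len(y0)))
    y = np.array(y0, dtype=float)

    t_now = 0.0
    idx = 0
    # times at or before the first entry see the drug-free initial state
    first_entry = entries[0][0] if entries else math.inf
    while idx < times.size and times[idx] <= first_entry:
        out[idx] = y
        idx += 1

    boundaries = [e[0] for e in entries] + [math.inf]
    for k, (t_e, amt) in enumerate(entries):
        if t_e < t_now - 1e-12:
            raise ValueError("dose entries must be non-decreasing in time")
        # advance to the entry time if integration lags behind (no samples needed)
        if t_e > t_now:
            if y.any():
                y = _odeint_checked(rhs, y, [t_now, t_e], args, jac, rtol, atol)[-1]
            t_now = t_e
        y[0] += amt
        t_end = boundaries[k + 1]
        seg_times = []
        j = idx
        while j < times.size and times[j] <= t_end:
            seg_times.append(times[j])
            j += 1
        if seg_times:
            grid = np.concatenate(([t_now], seg_times))
            sol = _odeint_checked(rhs, y, grid, args, jac, rtol, atol)
            out[idx:j] = sol[1:]
            y = sol[-1]
            t_now = grid[-1]
            idx = j
    return out


def solve_tmdd(
    params: TMDDParams,
    doses: DoseSchedule,
    times: Sequence[float],
    output: str = "free",
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> np.ndarray:
    """Integrate the QE-TMDD system and return concentrations at ``times``.

    ``output`` selects the free (``"free"``, default: what the bioassay is
    taken to measure) or total (``"total"``) drug concentration in ng/ml.
    """
    if output not in ("free", "total"):
        raise ValueError("output must be 'free' or 'total'")
    entries = _dose_entries(params, doses)
    y0 = (0.0, 0.0, params.r0)
    states = _integrate_segments(
        tmdd_rhs, tmdd_jacobian, y0, entries, times, (params,), rtol, atol
    )
    ctot = np.maximum(states[:, 1], 0.0) / params.v
    if output == "total":
        return ctot
    rtot = np.maximum(states[:, 2], 0.0)
    return free_concentration(ctot, rtot, params.kd)


def solve_mm(
    params: MMParams,
    doses: DoseSchedule,
    times: Sequence[float],
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> np.ndarray:
    """Integrate the MM elimination model; returns central concentration [ng/ml]."""
    entries = _dose_entries(params, doses)
    states = _integrate_segments(_mm_rhs, None, (0.0, 0.0), entries, times, (params,), rtol, atol)
    return np.maximum(states[:, 1], 0.0) / params.v


# ---------------------------------------------------------------------------
# linear one-compartment closed form


def bateman(
    dose: float, times, cl: float, v: float, ka: float, tlag: float = 0.0, dose_time: float = 0.0
) -> np.ndarray:
    """Closed-form one-compartment concentration after one first-order SC dose.

    ``C(t') = D*ka / (V*(ka-ke)) * (exp(-ke t') - exp(-ka t'))`` with
    ``t' = t - dose_time - tlag`` and ``ke = CL/V``; the removable
    ``ka == ke`` singularity is handled by its limit ``D*ka*t'/V * exp(-ka t')``.
    """
    times = np.asarray(times, dtype=float)
    ke = cl / v
    tp = times - dose_time - tlag
    tp = np.maximum(tp, 0.0)
    if abs(ka - ke) < 1e-12 * max(ka, ke, 1e-300):
        c = dose * ka * tp / v * np.exp(-ka * tp)
    else:
        c = dose * ka / (v * (ka - ke)) * (np.exp(-ke * tp) - np.exp(-ka * tp))
    return np.where(tp > 0, c, 0.0)


def solve_onecpt(cl, v, ka, tlag, doses: DoseSchedule, times) -> np.ndarray:
    """Linear one-compartment profile by superposition of Bateman terms."""
    times = np.asarray(times, dtype=float)
    c = np.zeros_like(times)
    for t_d, amt in doses:
        c = c + bateman(amt, times, cl, v, ka, tlag, dose_time=t_d)
    return c


# ---------------------------------------------------------------------------
# structural-model adapters used by the mixed-effects engine


class TMDDModel:
    """QE-TMDD structural model exposed through the generic predict interface."""

    param_names = ("cl", "v", "ka", "tlag", "r0", "kdeg", "kint", "kd")

    def __init__(self, output: str = "free", rtol: float = 1e-8, atol: float = 1e-10):
        self.output = output
        self.rtol = rtol
        self.atol = atol

    def predict(self, params: dict, doses: DoseSchedule, times) -> np.ndarray:
        p = TMDDParams(**{k: params[k] for k in self.param_names})
        return solve_tmdd(p, doses, times, output=self.output, rtol=self.rtol, atol=self.atol)


class MMModel:
    """Michaelis-Menten structural model (printed clearance form by default)."""

    param_names = ("vm", "km", "v", "ka", "tlag")

    def __init__(self, form: str = "printed", rtol: float = 1e-8, atol: float = 1e-10):
        self.form = form
        self.rtol = rtol
        self.atol = atol

    def predict(self, params: dict, doses: DoseSchedule, times) -> np.ndarray:
        p = MMParams(**{k: params[k] for k in self.param_names}, form=self.form)
        return solve_mm(p, doses, times, rtol=self.rtol, atol=self.atol)


class OneCompartmentModel:
    """Linear one-compartment model with closed-form prediction.

    Cheap and exact; the TMDD model degenerates to it when the receptor
    pool is absent (``r0 = 0``), which makes it both a useful oracle and a
    fast stand-in for exercising the estimation machinery.
    """

    param_names = ("cl", "v", "ka", "tlag")

    def predict(self, params: dict, doses: DoseSchedule, times) -> np.ndarray:
        return solve_onecpt(params["cl"], params["v"], params["ka"], params["tlag"], doses, times)
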