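"""Covariate screening and stepwise covariate modelling.

Candidate covariate effects are screened against the empirical Bayes
estimates (rank correlation for continuous covariates, point-biserial
correlation for two-level categorical ones), thinned for collinearity
(weight, BMI and BSA are nearly interchangeable in these trials), then
tested by the classical stepwise procedure: forward inclusion at a drop in
objective function value (OFV) greater than the chi-square(df=1) 5%
critical value 3.84, backward elimination retaining only effects whose
removal raises the OFV by more than the 1% critical value 6.63.
Both inequalities are strict.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import PKDataset
from .nlme import CovariateLink, FitResult, PopulationModel, fit

log = logging.getLogger(__name__)

FORWARD_ALPHA = 0.05
BACKWARD_ALPHA = 0.01


def _cov_value_num(cov, name: str):
    return getattr(cov, name) if not isinstance(cov, dict) else cov[name]

__all__ = [
    "CovariateCandidate",
    "ScreenResult",
    "StepRecord",
    "StepwiseTrace",
    "chi2_threshold",
    "covariate_table",
    "screen_covariates",
    "collinearity_filter",
    "stepwise_select",
]

CONTINUOUS = ("weight", "bmi", "bsa", "age")
CATEGORICAL = ("sex", "ethnicity")


@dataclass(frozen=True)
class CovariateCandidate:
    parameter: str
    covariate: str
    form: str                    # "power" (continuous) | "proportional" (categorical)
    reference: float | str

    def to_link(self, coef: float) -> CovariateLink:
        return CovariateLink(self.parameter, self.covariate, self.form, self.reference, coef)

    @property
    def name(self) -> str:
        return f"{self.parameter}~{self.covariate}"


@dataclass(frozen=True)
class ScreenResult:
    candidate: CovariateCandidate
    statistic: float             # rank / point-biserial correlation of eta vs covariate


@dataclass(frozen=True)
class StepRecord:
    phase: str                   # "forward" | "backward"
    candidate: str
    delta_ofv: float
    threshold: float
    decision: str                # "included" | "rejected" | "retained" | "removed"


StepwiseTrace = list[StepRecord]


def chi2_threshold(alpha: float, df: int) -> float:
    """Upper-tail chi-square critical value used for nested-model OFV tests."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if df < 1:
        raise ValueError("df must be >= 1")
    return float(stats.chi2.ppf(1.0 - alpha, df))


def covariate_table(dataset: PKDataset) -> pd.DataFrame:
    """Per-subject covariates as a DataFrame indexed by subject id."""
    rows = {sid: cov.as_dict() for sid, cov in dataset.covariates.items()}
    return pd.DataFrame.from_dict(rows, orient="index")


def _reference_value(covariate: str, table: pd.DataFrame):
    if covariate in CATEGORICAL:
        # modal level is the reference (the multiplier-1 group)
        return table[covariate].mode().iloc[0]
    return float(table[covariate].median())


def screen_covariates(
    fit_result: FitResult,
    table: pd.DataFrame,
    parameters: tuple[str, ...] | None = None,
    covariates: tuple[str, ...] = CONTINUOUS + CATEGORICAL,
    threshold: float = 0.2,
) -> list[ScreenResult]:
    """Rank (parameter, covariate) pairs by correlation with the EBEs.

    Continuous covariates use Spearman rank correlation between the
    subject-level ``eta`` estimates and the covariate; two-level categorical
    covariates use the point-biserial correlation.  Pairs with
    ``|statistic|`` above ``threshold`` are returned, strongest first.
    Constant covariates (e.g. sex in an all-male study) are skipped.
    """
    bsv = fit_result.model.bsv_parameters
    parameters = parameters if parameters is not None else tuple(bsv)
    etas = {ind.subject_id: ind.eta for ind in fit_result.individuals}
    sids = [s for s in table.index if s in etas]
    results: list[ScreenResult] = []
    for pname in parameters:
        if pname not in bsv:
            continue
        j = bsv.index(pname)
        e = np.array([etas[s][j] for s in sids])
        for cname in covariates:
            if cname not in table.columns:
                continue
            col = table.loc[sids, cname]
            if col.nunique() < 2:
                log.info("screen: %s constant, skipped", cname)
                continue
            if cname in CATEGORICAL:
                levels = sorted(col.unique())
                if len(levels) != 2:
                    log.info("screen: %s has %d levels, skipped", cname, len(levels))
                    continue
                x = (col == levels[1]).to_numpy(dtype=float)
                rho = float(stats.pearsonr(x, e).statistic)
                ref = _reference_value(cname, table)
                cand = CovariateCandidate(pname, cname, "proportional", ref)
            else:
                rho = float(stats.spearmanr(col.to_numpy(dtype=float), e).statistic)
                ref = _reference_value(cname, table)
                cand = CovariateCandidate(pname, cname, "power", ref)
            if abs(rho) > threshold:
                results.append(ScreenResult(cand, rho))
    results.sort(key=lambda r: -abs(r.statistic))
    return results


def collinearity_filter(
    candidates: list[CovariateCandidate],
    table: pd.DataFrame,
    threshold: float = 0.8,
    priority: tuple[str, ...] = ("weight", "bmi", "bsa", "age"),
) -> list[CovariateCandidate]:
    """Drop near-collinear continuous covariates targeting the same parameter.

    Among candidates whose pairwise Pearson ``|r|`` strictly exceeds
    ``threshold``, the highest-priority covariate (weight first, the usual
    pharmacological choice) is kept.
    """
    def prio(name: str) -> int:
        return priority.index(name) if name in priority else len(priority)

    keep = list(candidates)
    by_param: dict[str, list[CovariateCandidate]] = {}
    for c in candidates:
        if c.form == "power":
            by_param.setdefault(c.parameter, []).append(c)
    removed: set[tuple[str, str]] = set()
    for pname, group in by_param.items():
        for a, b in itertools.combinations(group, 2):
            xa = table[a.covariate].to_numpy(dtype=float)
            xb = table[b.covariate].to_numpy(dtype=float)
            r = float(np.corrcoef(xa, xb)[0, 1])
            if abs(r) > threshold:
                loser = a if prio(a.covariate) > prio(b.covariate) else b
                removed.add((loser.parameter, loser.covariate))
    return [c for c in keep if (c.parameter, c.covariate) not in removed]


def _fit_with_links(dataset, model: PopulationModel, links, structural, fit_kwargs):
    m = model.copy()
    m.covariate_links = list(links)
    return fit(dataset, m, structural, estimate_se=False, **fit_kwargs)


def stepwise_select(
    dataset: PKDataset,
    base_fit: FitResult,
    candidates: list[CovariateCandidate],
    structural,
    forward_threshold: float | None = None,
    backward_threshold: float | None = None,
    **fit_kwargs,
) -> tuple[FitResult, StepwiseTrace]:
    """Greedy forward inclusion / backward elimination over the candidates.

    Forward: at each round every remaining candidate is added to the current
    model and refitted; the largest OFV drop wins if strictly greater than
    the threshold (default chi2(1) at 5%, 3.84).  Backward: from the full
    forward model, each included effect is removed in turn and kept only if
    its removal raises the OFV strictly more than the 1% value 6.63.
    Deterministic given the dataset and fit settings.
    """
    fwd = forward_threshold if forward_threshold is not None else chi2_threshold(FORWARD_ALPHA, 1)
    bwd = backward_threshold if backward_threshold is not None else chi2_threshold(BACKWARD_ALPHA, 1)
    trace: StepwiseTrace = []

    base_model = base_fit.model
    current_links: list[CovariateLink] = list(base_model.covariate_links)
    current_fit = base_fit
    remaining = list(candidates)

    def init_coef(cand: CovariateCandidate, fit_result: FitResult) -> float:
        # seed the effect from a regression of the empirical Bayes estimates
        # on the covariate (the usual EBE screen): starting near the
        # conditional estimate keeps the refit from stalling on the long
        # theta-omega valley between "no effect" and the optimum
        try:
            bsv = fit_result.model.bsv_parameters
            j = bsv.index(cand.parameter)
            covs = {ind.subject_id: ind.eta[j] for ind in fit_result.individuals}
            sids = [s for s in covs if s in dataset.covariates]
            e = np.array([covs[s] for s in sids])
            if cand.form == "power":
                x = np.array([
                    math.log(_cov_value_num(dataset.covariates[s], cand.covariate)
                             / float(cand.reference))
                    for s in sids
                ])
                denom = float(np.sum((x - x.mean()) ** 2))
                if denom <= 0:
                    return 0.0
                return float(np.sum((x - x.mean()) * (e - e.mean())) / denom)
            groups = {}
            for s in sids:
                level = _cov_value_num(dataset.covariates[s], cand.covariate)
                groups.setdefault(level, []).append(covs[s])
            other = [lv for lv in groups if lv != cand.reference]
            if not other or cand.reference not in groups:
                return 1.0
            diff = np.mean(groups[other[0]]) - np.mean(groups[cand.reference])
            return float(np.exp(diff))
        except (AttributeError, KeyError, TypeError, ValueError):
            return 0.0 if cand.form == "power" else 1.0

    # forward inclusion
    while remaining:
        trials = []
        for cand in remaining:
            links = current_links + [cand.to_link(init_coef(cand, current_fit))]
            try:
                f = _fit_with_links(dataset, current_fit.model, links, structural, fit_kwargs)
            except (FloatingPointError, np.linalg.LinAlgError) as exc:
                raise RuntimeError(
                    f"forward fit failed for {cand.name}; trace so far: {trace}"
                ) from exc
            trials.append((current_fit.ofv - f.ofv, cand, f))
        trials.sort(key=lambda t: -t[0])
        best_drop, best_cand, best_fit_res = trials[0]
        for drop, cand, _ in trials:
            if cand is not best_cand:
                trace.append(StepRecord("forward", cand.name, drop, fwd, "rejected"))
        if best_drop > fwd:
            trace.append(StepRecord("forward", best_cand.name, best_drop, fwd, "included"))
            current_links = list(best_fit_res.model.covariate_links)
            current_fit = best_fit_res
            remaining = [c for c in remaining if c is not best_cand]
        else:
            trace.append(StepRecord("forward", best_cand.name, best_drop, fwd, "rejected"))
            break

    # backward elimination
    changed = True
    while changed and current_links:
        changed = False
        increases = []
        for link in current_links:
            reduced = [l for l in current_links if l is not link]
            f = _fit_with_links(dataset, current_fit.model, reduced, structural, fit_kwargs)
            increases.append((f.ofv - current_fit.ofv, link, f))
        increases.sort(key=lambda t: t[0])
        worst_inc, worst_link, worst_fit = increases[0]
        if worst_inc <= bwd:
            trace.append(StepRecord("backward", worst_link.name, worst_inc, bwd, "removed"))
            current_links = [l for l in current_links if l is not worst_link]
            current_fit = worst_fit
            changed = True
        else:
            for inc, link, _ in increases:
                trace.append(StepRecord("backward", link.name, inc, bwd, "retained"))
    return current_fit, trace
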