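"""Covariate screening, collinearity handling and stepwise selection."""

import math

import numpy as np
import pandas as pd
import pytest

from ropepk.covariates import (
    CovariateCandidate,
    chi2_threshold,
    collinearity_filter,
    covariate_table,
    screen_covariates,
    stepwise_select,
)
from ropepk.nlme import CovariateLink, fit
from conftest import make_onecpt_dataset, onecpt_truth


class TestChi2Thresholds:
    def test_stepwise_critical_values(self):
        assert round(chi2_threshold(0.05, 1), 2) == 3.84
        assert round(chi2_threshold(0.01, 1), 2) == 6.63

    def test_two_degrees_of_freedom(self):
        assert chi2_threshold(0.05, 2) == pytest.approx(5.99, abs=5e-3)

    def test_invalid_alpha(self):
        with pytest.raises(ValueError):
            chi2_threshold(1.5, 1)


def _fake_fit(etas: dict[str, np.ndarray], bsv=("cl", "v", "ka")):
    """Minimal FitResult stand-in carrying EBEs for the screen."""
    from ropepk.nlme import FitResult, IndividualEstimate, PopulationModel

    n = len(next(iter(etas.values())))
    model = PopulationModel(
        theta={k: 1.0 for k in bsv}, omega2={k: 0.1 for k in bsv},
        sigma2={"prop": 0.0, "add": 1.0}, error_model="additive",
    )
    individuals = []
    for i in range(n):
        eta = np.array([etas.get(k, np.zeros(n))[i] for k in bsv])
        individuals.append(IndividualEstimate(
            subject_id=f"S{i:03d}", eta=eta, params={}, times=np.array([]),
            y=np.array([]), ipred=np.array([])))
    return FitResult(model=model, ofv=0.0, aic=0.0, bic=0.0, n_estimated=0,
                     n_obs=0, n_subjects=n, estimates={}, rse_percent=None,
                     condition_number=None, eta_shrinkage_percent={},
                     eps_shrinkage_percent=0.0, individuals=individuals,
                     convergence_status="", success=True)


def _table(n=57, seed=4, all_male=False):
    rng = np.random.default_rng(seed)
    wt = rng.normal(74, 11, n)
    ht = rng.normal(171, 9, n)
    df = pd.DataFrame({
        "weight": wt,
        "bmi": wt / (ht / 100) ** 2,
        "bsa": np.sqrt(wt * ht / 3600),
        "age": rng.normal(32, 6, n),
        "sex": ["male"] * n if all_male else rng.choice(["male", "female"], n),
        "ethnicity": rng.choice(["Caucasian", "Chinese"], n),
    }, index=[f"S{i:03d}" for i in range(n)])
    return df


class TestScreen:
    def test_null_covariate_uncorrelated(self):
        rng = np.random.default_rng(9)
        table = _table()
        fr = _fake_fit({"cl": rng.normal(0, 0.3, 57)})
        res = screen_covariates(fr, table, parameters=("cl",), threshold=0.0)
        stats = {r.candidate.covariate: abs(r.statistic) for r in res}
        assert stats["weight"] < 0.3

    def test_planted_weight_signal_ranks_first(self):
        table = _table()
        eta = 0.9 * np.log(table["weight"].to_numpy() / 70.0)
        fr = _fake_fit({"cl": eta + np.random.default_rng(1).normal(0, 0.05, 57)})
        res = screen_covariates(fr, table, parameters=("cl",))
        # weight and its body-size proxies dominate; weight leads
        assert res[0].candidate.covariate in ("weight", "bmi", "bsa")
        assert any(r.candidate.covariate == "weight" for r in res[:2])

    def test_constant_covariate_skipped(self):
        table = _table(all_male=True)
        fr = _fake_fit({"cl": np.random.default_rng(2).normal(0, 0.3, 57)})
        res = screen_covariates(fr, table, parameters=("cl",), threshold=0.0)
        assert not any(r.candidate.covariate == "sex" for r in res)


class TestCollinearity:
    def test_body_size_triplet_reduces_to_weight(self):
        table = _table()
        cands = [CovariateCandidate("cl", c, "power", 70.0) for c in ("weight", "bmi", "bsa")]
        kept = collinearity_filter(cands, table)
        names = {c.covariate for c in kept}
        assert "weight" in names
        assert "bsa" not in names  # bsa ~ weight with r > 0.8

    def test_uncorrelated_pair_retained(self):
        table = _table()
        cands = [CovariateCandidate("cl", "weight", "power", 70.0),
                 CovariateCandidate("cl", "age", "power", 32.0)]
        assert len(collinearity_filter(cands, table)) == 2

    def test_threshold_is_strict(self):
        table = _table()
        r = abs(float(np.corrcoef(table["weight"], table["bsa"])[0, 1]))
        cands = [CovariateCandidate("cl", "weight", "power", 70.0),
                 CovariateCandidate("cl", "bsa", "power", 1.9)]
        # correlation exactly at the threshold: strictly-greater rule keeps both
        assert len(collinearity_filter(cands, table, threshold=r)) == 2
        assert len(collinearity_filter(cands, table, threshold=r - 1e-9)) == 1


class StubFit:
    """Deterministic OFV oracle for exercising the stepwise decision rules."""

    def __init__(self, ofvs: dict[frozenset, float]):
        self.ofvs = ofvs

    def __call__(self, dataset, model, structural, estimate_se=False, **kw):
        from ropepk.nlme import FitResult

        key = frozenset(l.name for l in model.covariate_links)
        return FitResult(model=model, ofv=self.ofvs[key], aic=0, bic=0,
                         n_estimated=0, n_obs=0, n_subjects=0, estimates={},
                         rse_percent=None, condition_number=None,
                         eta_shrinkage_percent={}, eps_shrinkage_percent=0.0,
                         individuals=[], convergence_status="stub", success=True)


class TestStepwiseRules:
    def _base_fit(self):
        return _fake_fit({"cl": np.zeros(5)})

    def test_inclusion_threshold_is_strict(self, monkeypatch):
        import ropepk.covariates as cov_mod

        cand = CovariateCandidate("cl", "weight", "power", 70.0)
        for drop, expect_included in [(3.84, False), (3.85, True)]:
            stub = StubFit({frozenset(): 100.0, frozenset({"cl~weight"}): 100.0 - drop})
            monkeypatch.setattr(cov_mod, "fit", stub)
            base = self._base_fit()
            base.ofv = 100.0
            final, trace = stepwise_select(None, base, [cand], None,
                                           backward_threshold=6.63)
            included = any(t.decision == "included" for t in trace)
            assert included is expect_included

    def test_backward_removes_weak_covariate(self, monkeypatch):
        import ropepk.covariates as cov_mod

        cand = CovariateCandidate("cl", "weight", "power", 70.0)
        # forward drop 5 (included), but removal costs only 5 (< 6.63): removed
        stub = StubFit({frozenset(): 100.0, frozenset({"cl~weight"}): 95.0})
        monkeypatch.setattr(cov_mod, "fit", stub)
        base = self._base_fit()
        base.ofv = 100.0
        final, trace = stepwise_select(None, base, [cand], None)
        assert any(t.phase == "backward" and t.decision == "removed" for t in trace)
        assert not final.model.covariate_links


@pytest.fixture(scope="module")
def planted():
    # a wide weight range makes the planted power law carry a decisive OFV
    # signal (a narrow cohort leaves it between the 5% and 1% thresholds)
    truth = onecpt_truth(with_weight_link=True)
    rng = np.random.default_rng(1021)
    weights = rng.uniform(45.0, 120.0, 50)
    ds = make_onecpt_dataset(n_subjects=50, seed=21, model=truth, weights=weights)
    return ds, truth


class TestStepwiseOnData:
    def test_planted_weight_effect_recovered(self, planted, onecpt_structural):
        ds, truth = planted
        base = truth.copy()
        base.covariate_links = []
        base_fit = fit(ds, base, onecpt_structural, estimate_se=False, outer_maxfev=1200)
        cands = [CovariateCandidate("cl", "weight", "power", 70.0)]
        final, trace = stepwise_select(ds, base_fit, cands, onecpt_structural,
                                       outer_maxfev=1200)
        assert any(t.decision == "included" and t.candidate == "cl~weight" for t in trace)
        link = final.model.covariate_links[0]
        assert 0.5 <= link.coef <= 1.4  # generating exponent 0.927
        # reference-point identity: at 70 kg the link multiplier is exactly 1
        assert link.multiplier({"weight": 70.0}) == pytest.approx(1.0)
        # deterministic: identical rerun gives an identical trace
        final2, trace2 = stepwise_select(ds, base_fit, cands, onecpt_structural,
                                        outer_maxfev=1200)
        assert [ (t.phase, t.candidate, t.decision) for t in trace ] == \
               [ (t.phase, t.candidate, t.decision) for t in trace2 ]
        assert [t.delta_ofv for t in trace] == pytest.approx([t.delta_ofv for t in trace2])


def test_covariate_table_roundtrip(onecpt_dataset):
    table = covariate_table(onecpt_dataset)
    assert set(table.columns) >= {"weight", "bmi", "bsa", "age", "sex", "ethnicity"}
    assert len(table) == onecpt_dataset.n_subjects
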