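"""Residual calibration, pc-VPC behaviour, bootstrap and sensitivity checks."""

import math

import numpy as np
import pytest

from ropepk.dataset import EventRecord, PKDataset
from ropepk.diagnostics import bootstrap, gof_residuals, pc_vpc, sensitivity_fixed
from ropepk.nlme import PopulationModel, fit
from conftest import ONECPT_TIMES, make_onecpt_dataset, onecpt_truth


@pytest.fixture(scope="module")
def calibration_fit(onecpt_structural):
    """Large simulated dataset evaluated at its own generating model."""
    ds = make_onecpt_dataset(n_subjects=60, seed=31)
    truth = onecpt_truth()
    res = fit(ds, truth, onecpt_structural, estimate_se=False, evaluate_only=True)
    return ds, truth, res


class TestCWRES:
    def test_calibrated_under_true_model(self, calibration_fit, onecpt_structural):
        ds, truth, res = calibration_fit
        table = gof_residuals(res, ds, onecpt_structural)
        assert len(table) == sum(1 for r in ds.records if not r.is_dose and not r.blq)
        assert abs(table["cwres"].mean()) < 0.15
        assert 0.7 < table["cwres"].var() < 1.3
        assert np.isfinite(table["cwres"]).all()

    def test_skewness_small_on_large_sample(self, calibration_fit, onecpt_structural):
        from scipy import stats

        ds, truth, res = calibration_fit
        table = gof_residuals(res, ds, onecpt_structural)
        assert abs(stats.skew(table["cwres"])) < 0.5

    def test_no_bsv_additive_reduces_to_weighted_residual(self, onecpt_structural):
        truth = onecpt_truth()
        model = PopulationModel(
            theta=dict(truth.theta), omega2={},
            sigma2={"prop": 0.0, "add": 0.25}, error_model="additive",
            fixed=truth.fixed,
        )
        ds = make_onecpt_dataset(n_subjects=5, seed=8, model=model)
        res = fit(ds, model, onecpt_structural, estimate_se=False, evaluate_only=True)
        table = gof_residuals(res, ds, onecpt_structural)
        expected = (table["dv"] - table["pred"]) / 0.5
        np.testing.assert_allclose(table["cwres"], expected, rtol=1e-10)

    def test_misspecified_clearance_biases_cwres(self, calibration_fit, onecpt_structural):
        ds, truth, _ = calibration_fit
        wrong = truth.copy()
        wrong.theta = dict(truth.theta)
        wrong.theta["cl"] *= 3.0
        res = fit(ds, wrong, onecpt_structural, estimate_se=False, evaluate_only=True)
        table = gof_residuals(res, ds, onecpt_structural)
        assert abs(table["cwres"].mean()) > 0.5


class TestPcVPC:
    def test_correction_is_identity_for_homogeneous_cohort(self, onecpt_structural):
        # one dose level, identical covariates: all PREDs agree within a bin,
        # so prediction correction cancels and pc-VPC equals the raw VPC
        truth = onecpt_truth()
        ds = make_onecpt_dataset(n_subjects=12, seed=17,
                                 weights=np.full(12, 70.0))
        res = pc_vpc(truth, onecpt_structural, ds, n_sim=20, seed=3, censor=False)
        from ropepk.nlme import build_subjects

        subjects = build_subjects(ds)
        times = np.concatenate([s.times for s in subjects])
        ys = np.concatenate([s.y for s in subjects])
        for k, (lo, hi) in enumerate(res.bin_edges):
            raw = np.percentile(ys[(times >= lo) & (times <= hi)], [10, 50, 90])
            np.testing.assert_allclose(res.observed[k], raw, rtol=1e-10)

    def test_self_coverage_under_true_model(self, onecpt_structural):
        truth = onecpt_truth()
        ds = make_onecpt_dataset(n_subjects=30, seed=23)
        res = pc_vpc(truth, onecpt_structural, ds, n_sim=150, seed=7)
        inside = (res.observed >= res.sim_lower) & (res.observed <= res.sim_upper)
        assert inside.mean() >= 0.8

    def test_exposure_misspecification_detected(self, onecpt_structural):
        # simulating with doubled doses pushes the simulated median band
        # above the observed one
        truth = onecpt_truth()
        ds = make_onecpt_dataset(n_subjects=25, seed=29, dose=90.0)
        doubled = PKDataset(
            records=[
                EventRecord(r.subject_id, r.time, "dose", amount=2 * r.amount,
                            compartment="depot") if r.is_dose else r
                for r in ds.records
            ],
            covariates=dict(ds.covariates), lloq=ds.lloq,
        )
        res = pc_vpc(truth, onecpt_structural, doubled, n_sim=60, seed=5)
        med = res.percentiles.index(50.0)
        frac_below = np.mean(res.observed[:, med] < res.sim_lower[:, med])
        assert frac_below > 0.6

    def test_duplicating_subjects_leaves_percentiles_unchanged(self, onecpt_structural):
        truth = onecpt_truth()
        ds = make_onecpt_dataset(n_subjects=10, seed=37)
        dup_records = list(ds.records) + [
            EventRecord("D" + r.subject_id, r.time, r.event_type, r.amount,
                        r.concentration, r.blq, r.compartment)
            for r in ds.records
        ]
        dup_covs = {**ds.covariates, **{"D" + k: v for k, v in ds.covariates.items()}}
        dup = PKDataset(records=dup_records, covariates=dup_covs, lloq=ds.lloq)
        r1 = pc_vpc(truth, onecpt_structural, ds, n_sim=10, seed=9, censor=False)
        r2 = pc_vpc(truth, onecpt_structural, dup, n_sim=10, seed=9, censor=False)
        # medians are exactly invariant; outer percentiles move only by the
        # order-statistic interpolation between n and 2n samples
        med = r1.percentiles.index(50.0)
        np.testing.assert_allclose(r1.observed[:, med], r2.observed[:, med], rtol=1e-12)
        np.testing.assert_allclose(r1.observed, r2.observed, rtol=0.06)


class TestBootstrap:
    fit_opts = dict(outer_maxfev=600, outer_ftol=1e-3)

    def test_deterministic_under_seed(self, onecpt_structural):
        ds = make_onecpt_dataset(n_subjects=10, seed=41)
        truth = onecpt_truth()
        b1 = bootstrap(ds, truth, onecpt_structural, n=4, seed=13, **self.fit_opts)
        b2 = bootstrap(ds, truth, onecpt_structural, n=4, seed=13, **self.fit_opts)
        assert b1.summary.equals(b2.summary)
        assert b1.n_successful == b2.n_successful

    def test_cloned_subject_gives_zero_width_intervals(self, onecpt_structural):
        base = make_onecpt_dataset(n_subjects=1, seed=43)
        rec = []
        covs = {}
        for i in range(12):
            for r in base.records:
                rec.append(EventRecord(f"c{i:02d}", r.time, r.event_type, r.amount,
                                       r.concentration, r.blq, r.compartment))
            covs[f"c{i:02d}"] = base.covariates["S000"]
        ds = PKDataset(records=rec, covariates=covs, lloq=base.lloq)
        truth = onecpt_truth()
        res = bootstrap(ds, truth, onecpt_structural, n=3, seed=17,
                        stratify_by=None, **self.fit_opts)
        width = (res.summary["p95"] - res.summary["p5"]).abs()
        assert (width < 1e-8).all()

    def test_intervals_widen_with_fewer_subjects(self, onecpt_structural):
        truth = onecpt_truth()
        widths = {}
        for n_sub in (24, 8):
            w = []
            for seed in (3, 5):
                ds = make_onecpt_dataset(n_subjects=n_sub, seed=seed)
                res = bootstrap(ds, truth, onecpt_structural, n=5, seed=seed,
                                stratify_by=None, **self.fit_opts)
                s = res.summary.loc["cl"]
                w.append((s["p95"] - s["p5"]) / s["median"])
            widths[n_sub] = np.mean(w)
        assert widths[8] > widths[24]


class TestSensitivity:
    def test_reference_row_zero_by_construction(self, onecpt_structural):
        # factor 1.0 row is exact zeros regardless of the data
        ds = make_onecpt_dataset(n_subjects=6, seed=47)
        truth = onecpt_truth()
        model = truth.copy()
        model.theta = dict(truth.theta)
        model.fixed = frozenset({"tlag"})
        table = sensitivity_fixed(ds, model, onecpt_structural,
                                  factors=(), parameters=("tlag",),
                                  outer_maxfev=60, outer_ftol=1e-3)
        ref = table[table["parameter"] == "(reference)"]
        assert (ref[[c for c in table.columns if c.startswith("pct_")]] == 0).all().all()

    def test_inert_parameter_when_receptor_absent(self):
        # with no receptor pool the internalisation rate cannot influence the
        # likelihood: the objective is exactly invariant to scaling it
        from ropepk.models import TMDDModel
        from ropepk.nlme import build_subjects, foce_objective
        from ropepk.trial_data import final_model
        import ropepk.trial_data as td

        truth = final_model()
        truth.theta["r0"] = 0.0
        design = td.design_a17_101()
        ds = td.generate_trial(design, truth, seed=53)
        subjects = build_subjects(ds)[:4]
        struct = TMDDModel(output="free", rtol=1e-8, atol=1e-10)
        ofv1, _ = foce_objective(subjects, truth, struct)
        scaled = truth.copy()
        scaled.theta = dict(truth.theta)
        scaled.theta["kint"] *= 2.0
        ofv2, _ = foce_objective(subjects, scaled, struct)
        # agreement to integrator noise; a real receptor contribution would
        # shift the objective by tens of points
        assert ofv1 == pytest.approx(ofv2, abs=0.01)
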