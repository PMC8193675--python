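"""Mixed-effects engine: objective correctness, fitting, diagnostics arithmetic."""

import math

import numpy as np
import pytest

from ropepk.models import DoseSchedule, OneCompartmentModel
from ropepk.nlme import (
    CovariateLink,
    PopulationModel,
    SubjectData,
    build_subjects,
    cv_percent,
    fit,
    foce_objective,
    individual_params,
    omega2_from_cv,
    residual_variance,
)
from conftest import ONECPT_TIMES, make_onecpt_dataset, onecpt_truth

LOG2PI = math.log(2 * math.pi)


class LogConst:
    """Structural stub whose prediction is log(mu): turns the exponential BSV
    into an additive one, so the marginal likelihood has a closed form."""

    param_names = ("mu",)

    def predict(self, params, doses, times):
        return np.full(len(times), math.log(params["mu"]))


def _subject(y, times=None):
    y = np.atleast_1d(np.asarray(y, float))
    times = np.arange(1.0, y.size + 1) if times is None else np.asarray(times, float)
    return SubjectData("s1", DoseSchedule.single(1.0), times, y, None)


class TestIndividualParams:
    def test_typical_at_zero_eta(self):
        theta = {"cl": 0.03, "v": 2.3}
        p = individual_params(theta, [], np.zeros(2), None, ["cl", "v"])
        assert p == pytest.approx(theta)

    def test_eta_log2_doubles(self):
        p = individual_params({"cl": 0.03}, [], np.array([math.log(2)]), None, ["cl"])
        assert p["cl"] == pytest.approx(0.06)

    def test_weight_power_link(self):
        link = CovariateLink("cl", "weight", "power", 70.0, 0.927)
        p = individual_params({"cl": 0.778}, [link], np.zeros(1), {"weight": 80.0}, ["cl"])
        assert p["cl"] == pytest.approx(0.8805, abs=2e-4)

    def test_proportional_link(self):
        link = CovariateLink("cl", "sex", "proportional", "male", 0.8)
        male = individual_params({"cl": 1.0}, [link], np.zeros(1), {"sex": "male"}, ["cl"])
        female = individual_params({"cl": 1.0}, [link], np.zeros(1), {"sex": "female"}, ["cl"])
        assert male["cl"] == 1.0 and female["cl"] == pytest.approx(0.8)

    def test_unknown_covariate_raises(self):
        link = CovariateLink("cl", "nope", "power", 70.0, 1.0)
        with pytest.raises(KeyError):
            individual_params({"cl": 1.0}, [link], np.zeros(1), {"weight": 70.0}, ["cl"])


class TestResidualVariance:
    def test_combined_at_zero_prediction(self):
        s2 = {"prop": 0.035, "add": 0.117}
        assert residual_variance(0.0, s2, "combined") == pytest.approx(0.117)

    def test_proportional_scales_quadratically(self):
        s2 = {"prop": 0.04, "add": 0.0}
        assert (residual_variance(2.0, s2, "proportional")
                == pytest.approx(4 * residual_variance(1.0, s2, "proportional")))

    def test_final_model_arithmetic(self):
        s2 = {"prop": 0.187**2, "add": 0.342**2}
        assert residual_variance(5.0, s2, "combined") == pytest.approx(0.991, abs=1e-3)


class TestObjectiveClosedForm:
    @pytest.mark.parametrize("method", ["foce", "laplace"])
    def test_matches_gaussian_marginal(self, method):
        a, w2, s2, y = 1.3, 0.5, 0.25, 2.1
        pm = PopulationModel(theta={"mu": math.exp(a)}, omega2={"mu": w2},
                             sigma2={"prop": 0.0, "add": s2}, error_model="additive")
        ofv, _ = foce_objective([_subject([y])], pm, LogConst(), method=method)
        exact = LOG2PI + math.log(w2 + s2) + (y - a) ** 2 / (w2 + s2)
        assert ofv == pytest.approx(exact, abs=1e-8)

    def test_multiple_observations(self):
        # n repeated measurements of a + eta: marginal is N(a, w2*J + s2*I)
        a, w2, s2 = 0.7, 0.3, 0.2
        y = np.array([1.1, 0.4, 0.9])
        pm = PopulationModel(theta={"mu": math.exp(a)}, omega2={"mu": w2},
                             sigma2={"prop": 0.0, "add": s2}, error_model="additive")
        ofv, _ = foce_objective([_subject(y)], pm, LogConst())
        C = w2 * np.ones((3, 3)) + s2 * np.eye(3)
        r = y - a
        exact = 3 * LOG2PI + np.linalg.slogdet(C)[1] + r @ np.linalg.solve(C, r)
        assert ofv == pytest.approx(exact, abs=1e-8)

    def test_zero_bsv_reduces_to_wls(self):
        a, s2, y = 1.3, 0.25, 2.1
        pm = PopulationModel(theta={"mu": math.exp(a)}, omega2={"mu": 0.0},
                             sigma2={"prop": 0.0, "add": s2}, error_model="additive")
        ofv, inds = foce_objective([_subject([y])], pm, LogConst())
        assert inds[0].eta == pytest.approx(0.0)
        assert ofv == pytest.approx(LOG2PI + math.log(s2) + (y - a) ** 2 / s2)

    def test_subject_order_invariance(self, onecpt_dataset, onecpt_model, onecpt_structural):
        subjects = build_subjects(onecpt_dataset)
        ofv1, _ = foce_objective(subjects, onecpt_model, onecpt_structural)
        ofv2, _ = foce_objective(subjects[::-1], onecpt_model, onecpt_structural)
        assert ofv1 == pytest.approx(ofv2, abs=1e-6)

    def test_truth_beats_perturbed(self, onecpt_dataset, onecpt_model, onecpt_structural):
        subjects = build_subjects(onecpt_dataset)
        ofv_true, _ = foce_objective(subjects, onecpt_model, onecpt_structural)
        pert = onecpt_model.copy()
        pert.theta = {k: (2 * v if k != "tlag" else v) for k, v in pert.theta.items()}
        ofv_pert, _ = foce_objective(subjects, pert, onecpt_structural)
        assert ofv_true < ofv_pert


class TestCV:
    def test_zero(self):
        assert cv_percent(0.0) == 0.0

    def test_table_value(self):
        assert cv_percent(0.120) == pytest.approx(35.7, abs=0.1)

    def test_log2_gives_100(self):
        assert cv_percent(math.log(2)) == pytest.approx(100.0)

    def test_inverse(self):
        assert omega2_from_cv(cv_percent(0.3)) == pytest.approx(0.3)


class TestFit:
    def test_recovery_onecpt(self, onecpt_dataset, onecpt_structural):
        truth = onecpt_truth()
        init = truth.copy()
        init.theta = {"cl": 0.05, "v": 3.2, "ka": 0.004, "tlag": 0.426}
        init.omega2 = {"cl": 0.25, "v": 0.3, "ka": 0.3}
        init.sigma2 = {"prop": 0.06, "add": 0.2}
        res = fit(onecpt_dataset, init, onecpt_structural,
                  estimate_se=False, outer_maxfev=2000)
        assert res.success
        # n=20 subjects: typical values recover within the sampling spread
        for name in ("cl", "v", "ka"):
            assert res.model.theta[name] == pytest.approx(truth.theta[name], rel=0.35)
        # and the optimum genuinely improves on the generating parameters
        ofv_truth, _ = foce_objective(build_subjects(onecpt_dataset), truth, onecpt_structural)
        assert res.ofv < ofv_truth
        # information criteria identities hold exactly
        assert res.aic == pytest.approx(res.ofv + 2 * res.n_estimated)
        assert res.bic == pytest.approx(res.ofv + res.n_estimated * math.log(res.n_obs))

    def test_self_consistent_refit(self, onecpt_dataset, onecpt_structural):
        # refit started at the truth stays within the stochastic neighbourhood
        truth = onecpt_truth()
        res = fit(onecpt_dataset, truth, onecpt_structural,
                  estimate_se=False, outer_maxfev=250)
        ofv0, _ = foce_objective(build_subjects(onecpt_dataset), truth, onecpt_structural)
        # small slack: the warm-started conditional modes make successive
        # evaluations agree only to the inner tolerance
        assert res.ofv <= ofv0 + 0.05

    def test_evaluate_only(self, onecpt_dataset, onecpt_model, onecpt_structural):
        res = fit(onecpt_dataset, onecpt_model, onecpt_structural,
                  estimate_se=False, evaluate_only=True)
        assert res.convergence_status == "evaluation only"
        assert res.model.theta == pytest.approx(onecpt_model.theta)
        assert len(res.individuals) == onecpt_dataset.n_subjects

    def test_rse_and_condition_number_on_small_problem(self):
        # 12 subjects, additive-error linear model: SEs well defined and cheap
        rng = np.random.default_rng(42)
        a, w2, s2 = 1.0, 0.2, 0.1
        subjects = [
            _subject(a + rng.normal(0, math.sqrt(w2)) + rng.normal(0, math.sqrt(s2), 4))
            for _ in range(12)
        ]
        pm = PopulationModel(theta={"mu": math.exp(a)}, omega2={"mu": w2},
                             sigma2={"prop": 0.0, "add": s2}, error_model="additive")

        import ropepk.nlme as N
        packer = N._ParamPacker(pm)
        rse, cond, cov = N._estimate_uncertainty(
            packer, pm, subjects, LogConst(), "foce", 1e-8, {}, 1e-4)
        assert rse is not None and all(v > 0 for v in rse.values())
        assert cond >= 1.0


class TestShrinkage:
    def test_full_shrinkage_when_data_match_typical(self):
        # observations equal to the typical prediction: every EBE collapses to 0
        pm = PopulationModel(theta={"mu": math.exp(1.0)}, omega2={"mu": 0.4},
                             sigma2={"prop": 0.0, "add": 0.5}, error_model="additive")
        subjects = [_subject([1.0, 1.0]) for _ in range(6)]
        for i, s in enumerate(subjects):
            s.subject_id = f"s{i}"
        _, inds = foce_objective(subjects, pm, LogConst())
        etas = np.array([ind.eta[0] for ind in inds])
        shrinkage = (1 - np.std(etas) / math.sqrt(0.4)) * 100
        assert shrinkage == pytest.approx(100.0, abs=1e-4)

    def test_shrinkage_grows_with_sparser_sampling(self, onecpt_structural):
        truth = onecpt_truth()

        def shrink(n_times, seed=3):
            times = ONECPT_TIMES[:: max(1, len(ONECPT_TIMES) // n_times)][:n_times]
            ds = make_onecpt_dataset(n_subjects=25, seed=seed, times=times)
            _, inds = foce_objective(build_subjects(ds), truth, onecpt_structural)
            etas = np.array([ind.eta for ind in inds])
            w = np.sqrt([truth.omega2[k] for k in truth.bsv_parameters])
            return np.mean((1 - etas.std(axis=0) / w) * 100)

    # mean eta-shrinkage across parameters rises when subjects contribute
    # 3 samples instead of 12
        assert shrink(3) > shrink(12)
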