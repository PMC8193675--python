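"""Shared fixtures: small synthetic populations for exercising the pipeline.

The expensive machinery (FOCE fits, bootstrap, VPC) is tested on linear
one-compartment populations with closed-form predictions, which keeps the
suite fast while exercising exactly the same estimation code paths as the
QE-TMDD analyses.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from ropepk.dataset import EventRecord, PKDataset, SubjectCovariates
from ropepk.models import DoseSchedule, OneCompartmentModel
from ropepk.nlme import PopulationModel, residual_variance

ONECPT_TIMES = np.array([1, 3, 6, 12, 24, 48, 96, 168, 240, 336, 504, 672.0])


def onecpt_truth(with_weight_link: bool = False) -> PopulationModel:
    """A linear one-compartment population with realistic interferon-like values."""
    links = []
    if with_weight_link:
        from ropepk.nlme import CovariateLink

        links = [CovariateLink("cl", "weight", "power", 70.0, 0.927)]
    return PopulationModel(
        theta={"cl": 0.778 / 24.0, "v": 2.32, "ka": 0.14 / 24.0, "tlag": 0.426},
        omega2={"cl": 0.12, "v": 0.2, "ka": 0.2},
        sigma2={"prop": 0.035, "add": 0.117},
        error_model="combined",
        fixed=frozenset({"tlag"}),
        covariate_links=links,
    )


def make_onecpt_dataset(
    n_subjects: int = 20,
    seed: int = 11,
    dose: float = 180.0,
    times: np.ndarray = ONECPT_TIMES,
    model: PopulationModel | None = None,
    lloq: float = 0.05,
    weights: np.ndarray | None = None,
    eta_override=None,
) -> PKDataset:
    """Simulate a small single-dose trial under the linear model."""
    model = model if model is not None else onecpt_truth()
    rng = np.random.default_rng(seed)
    oc = OneCompartmentModel()
    sds = np.sqrt([model.omega2[k] for k in model.bsv_parameters])
    if weights is None:
        weights = np.clip(rng.normal(74.0, 11.0, n_subjects), 45, 120)
    records, covs = [], {}
    for i in range(n_subjects):
        sid = f"S{i:03d}"
        ht = 170.0
        covs[sid] = SubjectCovariates(
            age=30.0, sex="male" if i % 2 else "female", ethnicity="Caucasian",
            weight=float(weights[i]), bmi=float(weights[i] / 1.7**2),
            bsa=float(math.sqrt(weights[i] * ht / 3600.0)),
            study="A09-102", dose_cohort=dose, height=ht,
        )
        eta = rng.normal(0.0, sds)
        if eta_override is not None:
            eta = eta_override(i, covs[sid], eta)
        params = model.individual_params(eta, covs[sid])
        f = oc.predict(params, DoseSchedule.single(dose), times)
        sd_y = np.sqrt(residual_variance(f, model.sigma2, model.error_model))
        y = np.maximum(f + sd_y * rng.normal(size=f.size), 0.0)
        records.append(EventRecord(sid, 0.0, "dose", amount=dose, compartment="depot"))
        for t, obs in zip(times, y):
            records.append(EventRecord(sid, float(t), "observation",
                                       concentration=float(obs), blq=bool(obs < lloq)))
    return PKDataset(records=records, covariates=covs, lloq=lloq)


@pytest.fixture(scope="session")
def onecpt_model() -> PopulationModel:
    return onecpt_truth()


@pytest.fixture(scope="session")
def onecpt_dataset() -> PKDataset:
    return make_onecpt_dataset(n_subjects=20, seed=11)


@pytest.fixture(scope="session")
def onecpt_structural() -> OneCompartmentModel:
    return OneCompartmentModel()
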