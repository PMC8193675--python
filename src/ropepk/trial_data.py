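"""Synthetic emulation of the two phase-I single-dose trials.

The raw concentration data behind the published analysis are not publicly
deposited, so every pipeline stage is exercised on synthetic datasets that
reproduce the two trial designs:

* **A09-102** (Caucasian, all male): six cohorts of six subjects at
  24/48/90/180/225/270 ug single SC doses, sampled pre-dose and at 20
  post-dose times out to 672 h.
* **A17-101** (Chinese): three cohorts at 90/180/270 ug with 9/8/10
  evaluable subjects (male:female 5:4, 5:3, 5:5), 18 post-dose times
  (the 168 h and 288 h samples are not part of this schedule).

Demographics are drawn per study from the published summary moments
(weight/height bivariate normal with a configurable correlation, truncated
to physiological ranges), the generating PK model defaults to the published
final QE-TMDD population estimates, and observations below the 0.05 ng/ml
quantification limit are flagged BLQ.  Evaluable-subject counts are
generated directly; an ``enrolled`` switch adds the dropout subjects and
removes them at random for workflows that want the enrolled design.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .dataset import DEFAULT_LLOQ, EventRecord, PKDataset, SubjectCovariates
from .models import DoseSchedule, TMDDModel
from .nlme import CovariateLink, PopulationModel, omega2_from_cv, residual_variance

DEFAULT_SEED = 20210528

# post-dose sampling schedules [h]
TIMES_A09 = (1, 3, 6, 9, 12, 16, 24, 36, 48, 72, 96, 120, 144, 168, 192, 240, 288, 336, 504, 672)
TIMES_A17 = (1, 3, 6, 9, 12, 16, 24, 36, 48, 72, 96, 120, 144, 192, 240, 336, 504, 672)

__all__ = [
    "DEFAULT_SEED",
    "Cohort",
    "TrialDesign",
    "design_a09_102",
    "design_a17_101",
    "default_designs",
    "final_model",
    "final_structural",
    "WEIGHT_DISTRIBUTIONS",
    "draw_weights",
    "generate_trial",
    "generate_study_pool",
    "generate_replicates",
]


@dataclass(frozen=True)
class Cohort:
    dose: float      # ug
    n_male: int
    n_female: int
    n_enrolled: int | None = None   # defaults to the evaluable count

    @property
    def n(self) -> int:
        return self.n_male + self.n_female

    @property
    def enrolled(self) -> int:
        return self.n if self.n_enrolled is None else self.n_enrolled


@dataclass(frozen=True)
class TrialDesign:
    study: str
    ethnicity: str
    cohorts: tuple[Cohort, ...]
    sampling_times: tuple[float, ...]      # post-dose, hours
    weight_mean: float                     # kg
    weight_sd: float
    height_mean: float                     # cm
    height_sd: float
    age_mean: float                        # years
    age_sd: float
    weight_height_corr: float = 0.5        # not reported; realistic default
    weight_range: tuple[float, float] = (45.0, 120.0)
    height_range: tuple[float, float] = (145.0, 205.0)
    age_range: tuple[float, float] = (18.0, 45.0)
    lloq: float = DEFAULT_LLOQ

    @property
    def n_subjects(self) -> int:
        return sum(c.n for c in self.cohorts)


def design_a09_102() -> TrialDesign:
    return TrialDesign(
        study="A09-102",
        ethnicity="Caucasian",
        cohorts=tuple(
            Cohort(dose=d, n_male=5, n_female=0, n_enrolled=6)
            for d in (24, 48, 90, 180, 225, 270)
        ),
        sampling_times=tuple(float(t) for t in TIMES_A09),
        weight_mean=79.4, weight_sd=9.41,
        height_mean=176.0, height_sd=7.51,
        age_mean=32.3, age_sd=6.9,
    )


def design_a17_101() -> TrialDesign:
    return TrialDesign(
        study="A17-101",
        ethnicity="Chinese",
        cohorts=(
            Cohort(dose=90.0, n_male=5, n_female=4, n_enrolled=10),
            Cohort(dose=180.0, n_male=5, n_female=3, n_enrolled=10),
            Cohort(dose=270.0, n_male=5, n_female=5, n_enrolled=10),
        ),
        sampling_times=tuple(float(t) for t in TIMES_A17),
        weight_mean=68.1, weight_sd=10.0,
        height_mean=166.0, height_sd=8.51,
        age_mean=31.6, age_sd=6.19,
    )


def default_designs() -> tuple[TrialDesign, TrialDesign]:
    return design_a09_102(), design_a17_101()


#: weight moments used for virtual populations (kg): mean, sd, truncation
WEIGHT_DISTRIBUTIONS = {
    "Caucasian": (79.4, 9.41, 45.0, 120.0),
    "Chinese": (68.1, 10.0, 45.0, 120.0),
}


def final_model() -> PopulationModel:
    """The published final QE-TMDD population model in internal (hourly) units.

    Typical values: CL/F 0.778 L/day, V/F 2.32 L, ka 0.14 /day, tlag 0.426 h,
    R0 0.111 ng/ml, kdeg 0.544 /h; KD 0.142 ng/ml and kint 0.0788 /h fixed.
    Weight enters clearance as a power law with exponent 0.927 referenced to
    70 kg.  BSV CVs 35.7/90.8/63.5 % on CL/F, V/F, ka; combined residual
    error (18.7 % proportional, 0.342 ng/ml additive).
    """
    return PopulationModel(
        theta={
            "cl": 0.778 / 24.0,
            "v": 2.32,
            "ka": 0.14 / 24.0,
            "tlag": 0.426,
            "r0": 0.111,
            "kdeg": 0.544,
            "kint": 0.0788,
            "kd": 0.142,
        },
        omega2={
            "cl": omega2_from_cv(35.7),
            "v": omega2_from_cv(90.8),
            "ka": omega2_from_cv(63.5),
        },
        sigma2={"prop": 0.187**2, "add": 0.342**2},
        error_model="combined",
        fixed=frozenset({"kd", "kint"}),
        covariate_links=[
            CovariateLink(parameter="cl", covariate="weight", form="power",
                          reference=70.0, coef=0.927)
        ],
    )


def final_structural(rtol: float = 1e-8, atol: float = 1e-10) -> TMDDModel:
    """QE-TMDD structural model predicting the free concentration."""
    return TMDDModel(output="free", rtol=rtol, atol=atol)


def _truncated_bivariate(rng, mean1, sd1, range1, mean2, sd2, range2, corr, size):
    """Correlated (weight, height) draws, redrawn until inside both ranges."""
    cov = np.array([
        [sd1 ** 2, corr * sd1 * sd2],
        [corr * sd1 * sd2, sd2 ** 2],
    ])
    out = np.empty((size, 2))
    filled = 0
    while filled < size:
        draw = rng.multivariate_normal([mean1, mean2], cov, size=size)
        ok = (
            (draw[:, 0] >= range1[0]) & (draw[:, 0] <= range1[1])
            & (draw[:, 1] >= range2[0]) & (draw[:, 1] <= range2[1])
        )
        good = draw[ok]
        take = min(good.shape[0], size - filled)
        out[filled:filled + take] = good[:take]
        filled += take
    return out[:, 0], out[:, 1]


def draw_weights(rng, ethnicity: str, n: int) -> np.ndarray:
    """Truncated-normal body weights for one ethnic group."""
    mean, sd, lo, hi = WEIGHT_DISTRIBUTIONS[ethnicity]
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(mean, sd, size=n)
        good = draw[(draw >= lo) & (draw <= hi)]
        take = min(good.size, n - filled)
        out[filled:filled + take] = good[:take]
        filled += take
    return out


def generate_trial(
    design: TrialDesign,
    truth: PopulationModel | None = None,
    seed: int = DEFAULT_SEED,
    structural=None,
    enrolled: bool = False,
) -> PKDataset:
    """Simulate one trial under the generating population model.

    For each subject: demographics from the design's distributions, BSV
    draws from ``truth.omega2``, the free-concentration profile at the
    design's sampling times, combined residual error, and BLQ flagging
    below the assay limit.  The pre-dose sample is a true zero (flagged
    BLQ/MDV).  Deterministic for a fixed seed.
    """
    truth = truth if truth is not None else final_model()
    structural = structural if structural is not None else final_structural()
    rng = np.random.default_rng(seed)

    records: list[EventRecord] = []
    covariates: dict[str, SubjectCovariates] = {}
    bsv = truth.bsv_parameters
    sds = np.sqrt([truth.omega2[k] for k in bsv])

    subject_no = 0
    drop_candidates: list[str] = []
    for cohort in design.cohorts:
        # the enrolled design adds the to-be-dropped subjects (male, as in the
        # all-male Caucasian study; sex of dropouts is not reported)
        n_extra = cohort.enrolled - cohort.n if enrolled else 0
        sexes = ["male"] * cohort.n_male + ["female"] * cohort.n_female + ["male"] * n_extra
        wt, ht = _truncated_bivariate(
            rng, design.weight_mean, design.weight_sd, design.weight_range,
            design.height_mean, design.height_sd, design.height_range,
            design.weight_height_corr, len(sexes),
        )
        ages = np.clip(rng.normal(design.age_mean, design.age_sd, len(sexes)),
                       *design.age_range)
        for k, sex in enumerate(sexes):
            subject_no += 1
            sid = f"{design.study}-{int(cohort.dose):03d}-{subject_no:02d}"
            height_m = ht[k] / 100.0
            cov = SubjectCovariates(
                age=float(np.round(ages[k], 1)),
                sex=sex,
                ethnicity=design.ethnicity,
                weight=float(np.round(wt[k], 1)),
                bmi=float(np.round(wt[k] / height_m**2, 2)),
                bsa=float(np.round(math.sqrt(wt[k] * ht[k] / 3600.0), 3)),
                study=design.study,
                dose_cohort=cohort.dose,
                height=float(np.round(ht[k], 1)),
            )
            covariates[sid] = cov
            drop_candidates.append(sid)

            eta = rng.normal(0.0, sds)
            params = truth.individual_params(eta, cov)
            doses = DoseSchedule.single(cohort.dose)
            times = np.asarray(design.sampling_times, dtype=float)
            f = np.asarray(structural.predict(params, doses, times))
            sd_y = np.sqrt(residual_variance(f, truth.sigma2, truth.error_model))
            y = f + sd_y * rng.normal(size=f.size)
            y = np.maximum(y, 0.0)

            records.append(EventRecord(sid, 0.0, "dose", amount=cohort.dose, compartment="depot"))
            records.append(EventRecord(sid, 0.0, "observation", concentration=0.0, blq=True))
            for t, obs in zip(times, y):
                records.append(
                    EventRecord(sid, float(t), "observation",
                                concentration=float(obs), blq=bool(obs < design.lloq))
                )

    if enrolled:
        # dropout-at-random: the enrolled cohorts lose the trial's dropout
        # count anywhere in the study, so cohort compositions vary
        n_drop = sum(c.enrolled - c.n for c in design.cohorts)
        if n_drop:
            drop = set(rng.choice(drop_candidates, size=n_drop, replace=False))
            records = [r for r in records if r.subject_id not in drop]
            covariates = {k: v for k, v in covariates.items() if k not in drop}

    return PKDataset(records=records, covariates=covariates, lloq=design.lloq)


def generate_study_pool(
    seed: int = DEFAULT_SEED,
    truth: PopulationModel | None = None,
    structural=None,
) -> PKDataset:
    """Both trials pooled: the 57-subject analysis dataset."""
    a09, a17 = default_designs()
    d1 = generate_trial(a09, truth, seed=seed, structural=structural)
    d2 = generate_trial(a17, truth, seed=seed + 1, structural=structural)
    return d1.merged_with(d2)


def generate_replicates(
    designs,
    truth: PopulationModel | None = None,
    n_replicates: int = 5,
    base_seed: int = DEFAULT_SEED,
    structural=None,
) -> list[PKDataset]:
    """Independent replicate datasets with seeds ``base_seed + 1000*k``."""
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if isinstance(designs, TrialDesign):
        designs = [designs]
    out = []
    for k in range(n_replicates):
        parts = [
            generate_trial(d, truth, seed=base_seed + 1000 * k + i, structural=structural)
            for i, d in enumerate(designs)
        ]
        ds = parts[0]
        for p in parts[1:]:
            ds = ds.merged_with(p)
        out.append(ds)
    return out
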