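"""PK event dataset: in-memory model and delimited file I/O.

The on-disk format follows the NONMEM column conventions that are the
de-facto interchange standard in pharmacometrics:

``ID,TIME,AMT,DV,EVID,MDV,CMT,BLQ,AGE,SEX,RACE,HT,WT,BMI,BSA,STUDY,DOSE``

* ``EVID`` 1 marks a dose row (``AMT`` in ug, ``DV`` empty), 0 an
  observation row (``DV`` in ng/ml, ``AMT`` empty).
* ``MDV`` is 1 for dose rows and for below-quantification observations.
* ``BLQ`` flags observations below the assay's lower limit of
  quantification (0.05 ng/ml for this assay); such rows are retained in
  the file but excluded from estimation (M1 handling).
* ``CMT`` 1 = depot, 2 = central.
* ``SEX``/``RACE`` are stored as strings; numeric encodings are applied
  only inside covariate functions.

Files are comma-separated UTF-8 with ``.`` decimals and empty strings for
missing fields; float values are written with full precision so a dataset
round-trips through write/read bit-identically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

DEFAULT_LLOQ = 0.05  # ng/ml

COLUMNS = [
    "ID", "TIME", "AMT", "DV", "EVID", "MDV", "CMT", "BLQ",
    "AGE", "SEX", "RACE", "HT", "WT", "BMI", "BSA", "STUDY", "DOSE",
]

_CMT_CODE = {"depot": 1, "central": 2}
_CMT_NAME = {1: "depot", 2: "central"}


class DatasetError(ValueError):
    """Raised when a dataset file or record violates the format contract."""


@dataclass(frozen=True)
class EventRecord:
    """One dose or observation event."""

    subject_id: str
    time: float
    event_type: str  # "dose" | "observation"
    amount: float | None = None         # ug, dose events only
    concentration: float | None = None  # ng/ml, observation events only
    blq: bool = False
    compartment: str = "central"

    def __post_init__(self):
        if self.event_type not in ("dose", "observation"):
            raise DatasetError(f"unknown event_type {self.event_type!r}")
        if self.time < 0:
            raise DatasetError(f"negative time {self.time} for subject {self.subject_id}")
        if self.event_type == "dose":
            if self.amount is None or self.concentration is not None:
                raise DatasetError("dose events carry an amount and no concentration")
            if self.amount <= 0:
                raise DatasetError("dose amount must be positive")
        else:
            if self.concentration is None or self.amount is not None:
                raise DatasetError("observation events carry a concentration and no amount")
            if self.concentration < 0:
                raise DatasetError("concentration must be non-negative")
        if self.compartment not in _CMT_CODE:
            raise DatasetError(f"unknown compartment {self.compartment!r}")

    @property
    def is_dose(self) -> bool:
        return self.event_type == "dose"


@dataclass(frozen=True)
class SubjectCovariates:
    age: float
    sex: str            # "male" | "female"
    ethnicity: str      # "Caucasian" | "Chinese"
    weight: float       # kg
    bmi: float          # kg/m^2
    bsa: float          # m^2
    study: str          # "A09-102" | "A17-101"
    dose_cohort: float  # ug
    height: float | None = None  # cm, used to derive bmi/bsa when synthesising

    def __post_init__(self):
        if self.weight <= 0 or self.bmi <= 0 or self.bsa <= 0:
            raise DatasetError("weight, bmi and bsa must be positive")

    def as_dict(self) -> dict:
        return {
            "age": self.age, "sex": self.sex, "ethnicity": self.ethnicity,
            "weight": self.weight, "bmi": self.bmi, "bsa": self.bsa,
            "study": self.study, "dose_cohort": self.dose_cohort, "height": self.height,
        }


@dataclass
class PKDataset:
    """Ordered event records plus per-subject covariates."""

    records: list[EventRecord]
    covariates: dict[str, SubjectCovariates]
    lloq: float = DEFAULT_LLOQ

    def __post_init__(self):
        self.validate()

    # -- queries ------------------------------------------------------------

    @property
    def subject_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.subject_id, None)
        return list(seen)

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_observations(self) -> int:
        return sum(1 for r in self.records if not r.is_dose)

    @property
    def n_blq(self) -> int:
        return sum(1 for r in self.records if not r.is_dose and r.blq)

    def subject_records(self, subject_id: str) -> list[EventRecord]:
        return [r for r in self.records if r.subject_id == subject_id]

    def doses(self, subject_id: str) -> list[tuple[float, float]]:
        return [(r.time, r.amount) for r in self.records if r.subject_id == subject_id and r.is_dose]

    def observations(self, subject_id: str, include_blq: bool = True):
        obs = [
            r for r in self.records
            if r.subject_id == subject_id and not r.is_dose and (include_blq or not r.blq)
        ]
        times = np.array([r.time for r in obs])
        conc = np.array([r.concentration for r in obs])
        return times, conc

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        by_subject: dict[str, list[EventRecord]] = {}
        seen_keys: set[tuple] = set()
        for i, r in enumerate(self.records):
            key = (r.subject_id, r.time, r.event_type)
            if key in seen_keys:
                raise DatasetError(f"record {i}: duplicate {key}")
            seen_keys.add(key)
            if not r.is_dose and r.blq and r.concentration >= self.lloq:
                raise DatasetError(
                    f"record {i}: BLQ flag with concentration {r.concentration} >= LLOQ {self.lloq}"
                )
            by_subject.setdefault(r.subject_id, []).append(r)
        for sid, recs in by_subject.items():
            # sorted by time; dose events precede observations at equal times
            order = [(r.time, 0 if r.is_dose else 1) for r in recs]
            if order != sorted(order):
                raise DatasetError(f"subject {sid}: records not sorted (dose-before-observation at ties)")
            if sid not in self.covariates and any(not r.is_dose for r in recs):
                raise DatasetError(f"subject {sid}: observations without covariates")

    # -- transforms ---------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            cov = self.covariates.get(r.subject_id)
            rows.append({
                "ID": r.subject_id,
                "TIME": r.time,
                "AMT": r.amount if r.is_dose else None,
                "DV": r.concentration if not r.is_dose else None,
                "EVID": 1 if r.is_dose else 0,
                "MDV": 1 if (r.is_dose or r.blq) else 0,
                "CMT": _CMT_CODE[r.compartment],
                "BLQ": int(r.blq),
                "AGE": cov.age if cov else None,
                "SEX": cov.sex if cov else None,
                "RACE": cov.ethnicity if cov else None,
                "HT": cov.height if cov else None,
                "WT": cov.weight if cov else None,
                "BMI": cov.bmi if cov else None,
                "BSA": cov.bsa if cov else None,
                "STUDY": cov.study if cov else None,
                "DOSE": cov.dose_cohort if cov else None,
            })
        return pd.DataFrame(rows, columns=COLUMNS)

    def merged_with(self, other: "PKDataset") -> "PKDataset":
        if self.lloq != other.lloq:
            raise DatasetError("cannot merge datasets with different LLOQ")
        overlap = set(self.covariates) & set(other.covariates)
        if overlap:
            raise DatasetError(f"overlapping subject ids: {sorted(overlap)[:3]}...")
        return PKDataset(
            records=self.records + other.records,
            covariates={**self.covariates, **other.covariates},
            lloq=self.lloq,
        )


def write_dataset(dataset: PKDataset, path) -> None:
    """Write the dataset as comma-separated text (deterministic column order)."""
    # %.17g guarantees bit-exact float round-trips through text
    dataset.to_frame().to_csv(path, index=False, na_rep="", float_format="%.17g")


def read_dataset(path, lloq: float = DEFAULT_LLOQ) -> PKDataset:
    """Read and validate a delimited PK dataset.

    Observations with ``DV`` below ``lloq`` are loaded with their BLQ flag
    set (whether or not the file carried a ``BLQ`` column).  Rows violating
    the event contract raise :class:`DatasetError` with the offending row
    number.
    """
    df = pd.read_csv(path, dtype={"ID": str, "SEX": str, "RACE": str, "STUDY": str},
                     float_precision="round_trip")
    required = ["ID", "TIME", "EVID"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DatasetError(f"missing required column(s): {missing}")
    if "AMT" not in df.columns and "DV" not in df.columns:
        raise DatasetError("dataset needs at least one of AMT/DV columns")

    records: list[EventRecord] = []
    covariates: dict[str, SubjectCovariates] = {}
    for i, row in df.iterrows():
        rowno = i + 2  # 1-based with header
        try:
            time = float(row["TIME"])
            evid = int(row["EVID"])
        except (TypeError, ValueError) as exc:
            raise DatasetError(f"row {rowno}: non-numeric TIME/EVID ({exc})") from None
        amt = row.get("AMT")
        dv = row.get("DV")
        amt = None if pd.isna(amt) else float(amt)
        dv = None if pd.isna(dv) else float(dv)
        if evid == 1:
            if amt is None:
                raise DatasetError(f"row {rowno}: dose row without AMT")
            if dv is not None:
                raise DatasetError(f"row {rowno}: dose row carries DV")
            rec = EventRecord(str(row["ID"]), time, "dose", amount=amt, compartment="depot")
        elif evid == 0:
            if dv is None:
                raise DatasetError(f"row {rowno}: observation row without DV")
            if amt is not None:
                raise DatasetError(f"row {rowno}: observation row carries AMT")
            blq = dv < lloq
            rec = EventRecord(str(row["ID"]), time, "observation", concentration=dv, blq=blq)
        else:
            raise DatasetError(f"row {rowno}: unsupported EVID {evid}")
        try:
            rec.__post_init__()
        except DatasetError as exc:
            raise DatasetError(f"row {rowno}: {exc}") from None
        records.append(rec)

        sid = str(row["ID"])
        if sid not in covariates and "WT" in df.columns and not pd.isna(row.get("WT")):
            ht = row.get("HT")
            covariates[sid] = SubjectCovariates(
                age=float(row["AGE"]),
                sex=str(row["SEX"]),
                ethnicity=str(row["RACE"]),
                weight=float(row["WT"]),
                bmi=float(row["BMI"]),
                bsa=float(row["BSA"]),
                study=str(row["STUDY"]),
                dose_cohort=float(row["DOSE"]),
                height=None if pd.isna(ht) else float(ht),
            )
    try:
        return PKDataset(records=records, covariates=covariates, lloq=lloq)
    except DatasetError as exc:
        raise DatasetError(f"{path}: {exc}") from None


def filter_blq(dataset: PKDataset) -> PKDataset:
    """Drop below-quantification observations (M1 handling); doses are kept."""
    kept = [r for r in dataset.records if r.is_dose or not r.blq]
    removed = len(dataset.records) - len(kept)
    if removed:
        log.info("filter_blq: removed %d BLQ observation(s) of %d", removed, dataset.n_observations)
    return PKDataset(records=kept, covariates=dict(dataset.covariates), lloq=dataset.lloq)
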