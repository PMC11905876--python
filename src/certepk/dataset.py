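"""Longitudinal PK data model and NONMEM-style tabular IO.

The dataset is a long-format collection of dosing events and concentration
observations keyed by subject, with baseline covariates attached per
subject.  Record-level filters implement the analysis conventions of the
trial dataset: below-quantification observations after the first dose are
excluded (M1 method), and individually flagged high predose measurements
can be removed on request.

The on-disk dialect is a delimited text table with NONMEM conventions:
``ID TIME AMT DV EVID`` mandatory, plus optional ``MDV``, ``DUR`` (or
``RATE``), ``OCC``, and baseline covariates ``WT AGE SEX SCR CRCL``
(``SEX``: 1 = male, 0 = female).  Time is hours since each subject's first
dose.  ``DUR`` defaults to 1/60 h — the drug is given as a 1-minute
intravenous push.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .covariates import cockcroft_gault

__all__ = [
    "DoseEvent",
    "ObservationRecord",
    "SubjectCovariates",
    "PKDataset",
    "DatasetFormatError",
    "read_dataset",
    "write_dataset",
    "apply_m1_filter",
    "exclude_flagged_predose",
    "disposition_summary",
    "DEFAULT_LLOQ",
    "DEFAULT_INFUSION_DURATION",
]

logger = logging.getLogger(__name__)

DEFAULT_LLOQ = 50.0  # ng/mL, assay lower limit of quantification
DEFAULT_INFUSION_DURATION = 1.0 / 60.0  # h; 1-minute IV push


class DatasetFormatError(ValueError):
    """Raised when an input table cannot be interpreted as a PK dataset."""


@dataclass(frozen=True)
class DoseEvent:
    subject_id: str
    time: float  # h since the subject's first dose
    amount: float  # mg
    duration: float = DEFAULT_INFUSION_DURATION  # h
    occasion: int = 0

    def __post_init__(self):
        if self.amount <= 0:
            raise ValueError("dose amount must be positive")
        if self.duration <= 0:
            raise ValueError("infusion duration must be positive")


@dataclass
class ObservationRecord:
    subject_id: str
    time: float  # h
    dv: float  # observed concentration, ng/mL
    blq: bool = False
    predose_excluded: bool = False
    ipred: float | None = None  # populated post-fit
    cwres: float | None = None  # populated post-fit

    def __post_init__(self):
        if self.dv < 0:
            raise ValueError("observed concentration must be non-negative")


@dataclass(frozen=True)
class SubjectCovariates:
    weight: float  # kg
    age: float  # years
    sex: str  # 'male' | 'female'
    serum_creatinine: float | None = None  # mg/dL
    bcrcl: float | None = None  # baseline CrCL, mL/min

    def __post_init__(self):
        if self.weight <= 0 or self.age <= 0:
            raise ValueError("weight and age must be positive")
        if self.sex not in ("male", "female"):
            raise ValueError("sex must be 'male' or 'female'")

    def with_derived_crcl(self) -> "SubjectCovariates":
        """Fill ``bcrcl`` via Cockcroft-Gault when only creatinine is given."""
        if self.bcrcl is not None:
            return self
        if self.serum_creatinine is None:
            raise ValueError("need serum creatinine or CrCL to derive bcrcl")
        crcl = cockcroft_gault(self.age, self.weight, self.serum_creatinine, self.sex)
        return replace(self, bcrcl=float(crcl))


@dataclass
class PKDataset:
    """Doses, observations and covariates for an analysis population."""

    doses: list = field(default_factory=list)
    observations: list = field(default_factory=list)
    covariates: dict = field(default_factory=dict)
    lloq: float = DEFAULT_LLOQ

    def __post_init__(self):
        if self.lloq <= 0:
            raise ValueError("lloq must be positive")

    @property
    def subject_ids(self) -> list:
        seen = dict.fromkeys(
            [d.subject_id for d in self.doses] + [o.subject_id for o in self.observations]
        )
        return list(seen)

    def doses_for(self, subject_id) -> list:
        return sorted(
            (d for d in self.doses if d.subject_id == subject_id), key=lambda d: d.time
        )

    def observations_for(self, subject_id) -> list:
        return sorted(
            (o for o in self.observations if o.subject_id == subject_id),
            key=lambda o: o.time,
        )

    def first_dose_time(self, subject_id) -> float:
        doses = self.doses_for(subject_id)
        if not doses:
            raise ValueError(f"subject {subject_id!r} has no dose events")
        return doses[0].time

    def validate(self) -> None:
        """Check structural invariants; raises on violation."""
        for sid in {o.subject_id for o in self.observations}:
            first = self.first_dose_time(sid)
            for o in self.observations_for(sid):
                if o.time < first:
                    raise ValueError(
                        f"subject {sid!r}: observation at t={o.time} h precedes "
                        f"the first dose at t={first} h"
                    )

    def refresh_blq(self) -> None:
        """(Re)flag observations strictly below the LLOQ."""
        for o in self.observations:
            o.blq = o.dv < self.lloq

    def copy(self) -> "PKDataset":
        return PKDataset(
            doses=list(self.doses),
            observations=[replace(o) for o in self.observations],
            covariates=dict(self.covariates),
            lloq=self.lloq,
        )


_MANDATORY = ("ID", "TIME", "AMT", "DV", "EVID")
_SEX_CODE = {1: "male", 0: "female"}


def read_dataset(
    path, lloq: float = DEFAULT_LLOQ, sep: str | None = None
) -> PKDataset:
    """Read a NONMEM-style delimited table into a validated :class:`PKDataset`.

    ``EVID=1`` rows become dose events, ``EVID=0`` rows observations;
    covariates are taken from each subject's first row.  ``sep=None``
    auto-detects comma versus whitespace delimiting.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if sep is None:
        first = path.read_text().splitlines()[0] if path.stat().st_size else ""
        sep = "," if "," in first else r"\s+"
    df = pd.read_csv(path, sep=sep, engine="python")
    df.columns = [str(c).strip().upper() for c in df.columns]
    for col in _MANDATORY:
        if col not in df.columns:
            raise DatasetFormatError(f"mandatory column {col!r} is missing")
    return dataset_from_frame(df, lloq=lloq)


def dataset_from_frame(df: pd.DataFrame, lloq: float = DEFAULT_LLOQ) -> PKDataset:
    """Build a dataset from an in-memory table in the same dialect."""
    ds = PKDataset(lloq=lloq)
    for sid, rows in df.groupby("ID", sort=False):
        sid = str(sid)
        first = rows.iloc[0]
        cov = _covariates_from_row(first)
        if cov is not None:
            ds.covariates[sid] = cov
        for _, r in rows.iterrows():
            evid = int(r["EVID"])
            t = float(r["TIME"])
            if evid == 1:
                dur = float(r["DUR"]) if "DUR" in rows.columns and pd.notna(r.get("DUR")) else None
                if dur is None and "RATE" in rows.columns and pd.notna(r.get("RATE")):
                    dur = float(r["AMT"]) / float(r["RATE"])
                ds.doses.append(
                    DoseEvent(
                        subject_id=sid,
                        time=t,
                        amount=float(r["AMT"]),
                        duration=dur if dur is not None else DEFAULT_INFUSION_DURATION,
                        occasion=int(r["OCC"]) if "OCC" in rows.columns and pd.notna(r.get("OCC")) else 0,
                    )
                )
            elif evid == 0:
                if "MDV" in rows.columns and pd.notna(r.get("MDV")) and int(r["MDV"]) == 1:
                    continue
                ds.observations.append(
                    ObservationRecord(subject_id=sid, time=t, dv=float(r["DV"]))
                )
    ds.refresh_blq()
    ds.validate()
    return ds


def _covariates_from_row(row) -> SubjectCovariates | None:
    def _get(col):
        v = row.get(col)
        return None if v is None or (isinstance(v, float) and np.isnan(v)) else float(v)

    wt, age = _get("WT"), _get("AGE")
    if wt is None or age is None:
        return None
    sex_raw = _get("SEX")
    sex = _SEX_CODE.get(int(sex_raw), "male") if sex_raw is not None else "male"
    cov = SubjectCovariates(
        weight=wt,
        age=age,
        sex=sex,
        serum_creatinine=_get("SCR"),
        bcrcl=_get("CRCL"),
    )
    if cov.bcrcl is None and cov.serum_creatinine is not None:
        cov = cov.with_derived_crcl()
    return cov


def to_frame(ds: PKDataset) -> pd.DataFrame:
    """Dataset as a long-format table in the on-disk dialect."""
    rows = []
    for sid in ds.subject_ids:
        cov = ds.covariates.get(sid)
        covcols = {
            "WT": cov.weight if cov else np.nan,
            "AGE": cov.age if cov else np.nan,
            "SEX": (1 if cov.sex == "male" else 0) if cov else np.nan,
            "SCR": cov.serum_creatinine if cov and cov.serum_creatinine is not None else np.nan,
            "CRCL": cov.bcrcl if cov and cov.bcrcl is not None else np.nan,
        }
        events = [
            {
                "ID": sid, "TIME": d.time, "AMT": d.amount, "DV": 0.0,
                "EVID": 1, "MDV": 1, "DUR": d.duration, "OCC": d.occasion, **covcols,
            }
            for d in ds.doses_for(sid)
        ] + [
            {
                "ID": sid, "TIME": o.time, "AMT": 0.0, "DV": o.dv,
                "EVID": 0, "MDV": 0, "DUR": np.nan, "OCC": 0, **covcols,
            }
            for o in ds.observations_for(sid)
        ]
        # stable sort: time, then doses before observations at the same time
        events.sort(key=lambda e: (e["TIME"], -e["EVID"]))
        rows.extend(events)
    return pd.DataFrame(rows)


def write_dataset(ds: PKDataset, path) -> None:
    """Write the dataset as a comma-delimited table (full float precision)."""
    to_frame(ds).to_csv(path, index=False, float_format="%.12g")


def apply_m1_filter(ds: PKDataset) -> tuple[PKDataset, int]:
    """Exclude post-dose observations below the LLOQ (M1 method).

    Observations at or before each subject's first dose time are predose
    records and are untouched by this rule.  Returns the filtered dataset
    and the number of records excluded; dose events are never removed.
    """
    out = ds.copy()
    kept, excluded = [], 0
    first_dose = {sid: ds.first_dose_time(sid) for sid in {o.subject_id for o in ds.observations}}
    for o in out.observations:
        post_dose = o.time > first_dose[o.subject_id]
        if post_dose and o.dv < ds.lloq:
            excluded += 1
        else:
            kept.append(o)
    out.observations = kept
    return out, excluded


def exclude_flagged_predose(ds: PKDataset, flagged: Iterable[tuple]) -> PKDataset:
    """Remove explicitly flagged records (e.g. high predose measurements).

    ``flagged`` is an iterable of ``(subject_id, time)`` references.  A
    reference matching no record raises ``KeyError``; duplicate references
    are removed once with a warning.  Automatic outlier screening is out of
    scope — records with extreme residuals are flagged downstream but never
    dropped here.
    """
    out = ds.copy()
    seen = set()
    for ref in flagged:
        sid, t = str(ref[0]), float(ref[1])
        if (sid, t) in seen:
            warnings.warn(f"record ({sid!r}, t={t}) flagged more than once; removed once")
            continue
        matches = [
            o for o in out.observations if o.subject_id == sid and o.time == t
        ]
        if not matches:
            raise KeyError(f"no observation for subject {sid!r} at t={t} h")
        for m in matches:
            out.observations.remove(m)
        seen.add((sid, t))
        logger.info("excluded flagged predose record (%s, t=%s h)", sid, t)
    return out


def dose_level_mg_per_kg(ds: PKDataset, dose: DoseEvent) -> float:
    """Weight-normalised dose level, rounded to 0.1 mg/kg for grouping."""
    cov = ds.covariates.get(dose.subject_id)
    if cov is None:
        return float("nan")
    return round(dose.amount / cov.weight, 1)


def disposition_summary(ds: PKDataset) -> pd.DataFrame:
    """Subjects, observations and BLQ counts per weight-normalised dose level.

    Each observation is attributed to the most recent dose at or before its
    time; counts therefore sum to the dataset totals.
    """
    rows = []
    for sid in ds.subject_ids:
        doses = ds.doses_for(sid)
        for o in ds.observations_for(sid):
            prior = [d for d in doses if d.time <= o.time]
            level = dose_level_mg_per_kg(ds, prior[-1]) if prior else float("nan")
            rows.append({"dose_mg_per_kg": level, "subject": sid, "blq": o.blq})
    if not rows:
        return pd.DataFrame(
            columns=["dose_mg_per_kg", "n_subjects", "n_observations", "n_blq"]
        )
    df = pd.DataFrame(rows)
    out = (
        df.groupby("dose_mg_per_kg", dropna=False)
        .agg(
            n_subjects=("subject", "nunique"),
            n_observations=("subject", "size"),
            n_blq=("blq", "sum"),
        )
        .reset_index()
    )
    out["n_blq"] = out["n_blq"].astype(int)
    return out
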