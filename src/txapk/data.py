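"""Event-record dataset handling.

Analysis datasets travel as NONMEM-style event-record tables: one CSV row
per dose or observation, identified by the conventional columns

====  =========================================================
ID    subject identifier (events of a subject are contiguous)
TIME  hours since the subject's first dose
AMT   dose amount in mg (dose rows; 0 on observation rows)
DV    observed concentration in mg/L (observation rows)
EVID  event type: 0 = observation, 1 = dose
MDV   1 if DV is missing, else 0
====  =========================================================

plus the covariate columns BW (kg), HT (cm), AGE (years), SEX (1 = male,
0 = female) and SCR (serum creatinine, umol/L), constant within a subject.
Derived covariates (creatinine clearance by Cockcroft-Gault, body surface
area by DuBois-DuBois) are computed, never stored.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import pk

__all__ = [
    "DatasetError",
    "DoseEvent",
    "Observation",
    "CovariateRecord",
    "SubjectRecord",
    "PopDataset",
    "read_dataset",
    "write_dataset",
]

REQUIRED_COLUMNS = ("ID", "TIME", "AMT", "DV", "EVID", "MDV", "BW", "HT", "AGE", "SEX", "SCR")
COVARIATE_COLUMNS = ("BW", "HT", "AGE", "SEX", "SCR")


class DatasetError(ValueError):
    """A dataset violates the event-record contract; the message names the row."""


@dataclass(frozen=True)
class DoseEvent:
    """An instantaneous IV bolus: ``time`` hours since first dose, ``amount`` mg."""

    time: float
    amount: float
    route: str = "iv_bolus"

    def __post_init__(self):
        if self.time < 0:
            raise ValueError(f"dose time must be >= 0, got {self.time}")
        if not self.amount > 0:
            raise ValueError(f"dose amount must be positive, got {self.amount}")


@dataclass(frozen=True)
class Observation:
    """A plasma concentration sample (mg/L == ug/mL); ``None`` when missing."""

    time: float
    concentration: float | None
    missing: bool = False

    def __post_init__(self):
        if self.time < 0:
            raise ValueError(f"observation time must be >= 0, got {self.time}")
        if not self.missing and not (
            self.concentration is not None and self.concentration > 0
        ):
            raise ValueError(
                f"non-missing concentration must be positive, got {self.concentration}"
            )


@dataclass(frozen=True)
class CovariateRecord:
    """One patient's covariates.

    Stored: sex, age (years), bw (kg), height (cm), scr (serum creatinine,
    umol/L as reported by the laboratory).  Derived deterministically:
    ``scr_mgdl`` (mg/dL), ``clcr`` (Cockcroft-Gault, mL/min) and ``bsa``
    (DuBois-DuBois, m^2).
    """

    sex: str
    age: float
    bw: float
    height: float
    scr: float

    def __post_init__(self):
        object.__setattr__(self, "sex", pk._norm_sex(self.sex))
        for name in ("age", "bw", "height", "scr"):
            if not getattr(self, name) > 0:
                raise ValueError(f"covariate {name} must be positive, got {getattr(self, name)}")

    @property
    def scr_mgdl(self) -> float:
        return self.scr / pk.SCR_UMOL_PER_MGDL

    @property
    def clcr(self) -> float:
        return pk.cockcroft_gault(self.age, self.bw, self.scr_mgdl, self.sex)

    @property
    def bsa(self) -> float:
        return pk.dubois_bsa(self.bw, self.height)


@dataclass(frozen=True)
class SubjectRecord:
    """Covariates plus time-ordered dose events and observations of one subject."""

    id: int | str
    covariates: CovariateRecord
    doses: tuple[DoseEvent, ...]
    observations: tuple[Observation, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "doses", tuple(self.doses))
        object.__setattr__(self, "observations", tuple(self.observations))
        if not self.doses:
            raise ValueError(f"subject {self.id}: at least one dose is required")
        for seq, what in ((self.doses, "doses"), (self.observations, "observations")):
            times = [e.time for e in seq]
            if any(b < a for a, b in zip(times, times[1:])):
                raise ValueError(f"subject {self.id}: {what} are not sorted by time")
        if self.observations:
            if self.doses[0].time > self.observations[0].time:
                raise ValueError(
                    f"subject {self.id}: first observation precedes the first dose"
                )

    @property
    def n_obs(self) -> int:
        return sum(1 for o in self.observations if not o.missing)


@dataclass(frozen=True)
class PopDataset:
    """A population dataset: subjects plus provenance metadata."""

    subjects: tuple[SubjectRecord, ...]
    provenance: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "subjects", tuple(self.subjects))
        object.__setattr__(self, "provenance", dict(self.provenance))
        if not self.subjects:
            raise ValueError("a dataset must contain at least one subject")
        ids = [s.id for s in self.subjects]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate subject IDs: {dup}")

    def __len__(self) -> int:
        return len(self.subjects)

    @property
    def n_obs(self) -> int:
        return sum(s.n_obs for s in self.subjects)

    def __eq__(self, other):
        if not isinstance(other, PopDataset):
            return NotImplemented
        return self.subjects == other.subjects  # provenance is metadata


def _parse_subject(sid, sub: pd.DataFrame) -> SubjectRecord:
    for col in COVARIATE_COLUMNS:
        if sub[col].nunique(dropna=False) != 1:
            row = sub[col].ne(sub[col].iloc[0]).idxmax()
            raise DatasetError(
                f"subject {sid}: covariate {col} varies within subject (data row {row + 2})"
            )
    times = sub["TIME"].to_numpy(dtype=float)
    if np.any(np.diff(times) < 0):
        row = sub.index[int(np.argmax(np.diff(times) < 0)) + 1]
        raise DatasetError(
            f"subject {sid}: TIME is not non-decreasing (data row {row + 2})"
        )
    first = sub.iloc[0]
    try:
        cov = CovariateRecord(
            sex=int(first["SEX"]) if not isinstance(first["SEX"], str) else first["SEX"],
            age=float(first["AGE"]),
            bw=float(first["BW"]),
            height=float(first["HT"]),
            scr=float(first["SCR"]),
        )
    except ValueError as exc:
        raise DatasetError(f"subject {sid}: invalid covariates: {exc}") from exc
    doses: list[DoseEvent] = []
    obs: list[Observation] = []
    for row, rec in sub.iterrows():
        evid = int(rec["EVID"])
        try:
            if evid == 1:
                doses.append(DoseEvent(time=float(rec["TIME"]), amount=float(rec["AMT"])))
            elif evid == 0:
                if int(rec["MDV"]) == 0:
                    obs.append(Observation(float(rec["TIME"]), float(rec["DV"])))
                else:
                    obs.append(Observation(float(rec["TIME"]), None, missing=True))
            else:
                raise ValueError(f"unsupported EVID {evid} (only 0 and 1)")
        except ValueError as exc:
            raise DatasetError(f"data row {row + 2} (subject {sid}): {exc}") from exc
    try:
        return SubjectRecord(id=sid, covariates=cov, doses=tuple(doses), observations=tuple(obs))
    except ValueError as exc:
        raise DatasetError(str(exc)) from exc


def read_dataset(path) -> PopDataset:
    """Read an event-record CSV into a :class:`PopDataset`.

    Rows with EVID=1 become dose events; rows with EVID=0 and MDV=0 become
    observations (MDV=1 rows are kept as missing-flagged placeholders).
    Structural violations — a missing required column, non-monotone TIME
    within a subject, a covariate varying within a subject, a negative
    time or nonpositive DV — raise :class:`DatasetError` naming the row.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise DatasetError(f"{path.name}: missing required column(s) {missing}")
    subjects = []
    for sid, sub in df.groupby("ID", sort=False):
        subjects.append(_parse_subject(sid, sub))
    return PopDataset(tuple(subjects), provenance={"source": str(path)})


def write_dataset(ds: PopDataset, path) -> None:
    """Write a :class:`PopDataset` as the event-record CSV ``read_dataset`` accepts.

    Events are emitted in time order within each subject (dose rows before
    observation rows at tied times); numeric values are written with full
    floating-point precision so a write/read cycle is lossless.
    """
    rows = []
    for sub in ds.subjects:
        cov = sub.covariates
        base = {
            "ID": sub.id,
            "BW": cov.bw,
            "HT": cov.height,
            "AGE": cov.age,
            "SEX": 1 if cov.sex == "male" else 0,
            "SCR": cov.scr,
        }
        events = [(d.time, 0, d) for d in sub.doses] + [
            (o.time, 1, o) for o in sub.observations
        ]
        events.sort(key=lambda e: (e[0], e[1]))
        for time, kind, ev in events:
            if kind == 0:
                rows.append(
                    {**base, "TIME": time, "AMT": ev.amount, "DV": 0.0, "EVID": 1, "MDV": 1}
                )
            else:
                rows.append(
                    {
                        **base,
                        "TIME": time,
                        "AMT": 0.0,
                        "DV": 0.0 if ev.missing else ev.concentration,
                        "EVID": 0,
                        "MDV": 1 if ev.missing else 0,
                    }
                )
    df = pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS))
    df.to_csv(path, index=False, float_format="%.17g")
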