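"""Domain types and NONMEM-style event-record input/output.

A longitudinal pharmacokinetic dataset is a list of :class:`SubjectRecord`
objects, each holding a constant covariate snapshot, the subject's dose
history, and trough observations.  On disk the same information is a flat
CSV of event rows (one row per dose or observation), in the spirit of a
NONMEM data file: ``ID, TIME, AMT, DUR, II, NDOSE, ROUTE, DV, MDV, BQL,
LLOQ`` plus one column per covariate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Lower limit of quantification of the plasma assay (ug/mL), the lower
#: bound of its linear calibration range.
DEFAULT_LLOQ = 0.1

ROUTE_ORAL = "oral"
ROUTE_IV = "intravenous"

#: Continuous covariate columns carried on every event row.
CONTINUOUS_COVARIATES = (
    "AGE", "WT", "ALB", "CRP", "AST", "ALT", "TBIL", "HB", "PLT", "SCR", "UA",
)

PHENOTYPES = ("NM", "IM", "PM")


class SchemaError(ValueError):
    """A mandatory column is missing or mis-typed in an event-record file."""


class ValidationError(ValueError):
    """A row or field violates a dataset invariant."""


@dataclass(frozen=True)
class DoseEvent:
    """One administration, or a q-``interval`` train of identical ones.

    ``time`` is hours since the subject's first dose.  IV doses are
    constant-rate infusions of length ``infusion_duration`` hours; oral
    doses have duration 0 and are scaled by bioavailability downstream.
    """

    time: float
    amount: float
    route: str = ROUTE_IV
    infusion_duration: float = 0.0
    interval: float | None = None
    n_doses: int = 1

    def __post_init__(self) -> None:
        if self.amount <= 0:
            raise ValidationError(f"dose amount must be > 0, got {self.amount}")
        if self.time < 0:
            raise ValidationError(f"dose time must be >= 0, got {self.time}")
        if self.route not in (ROUTE_ORAL, ROUTE_IV):
            raise ValidationError(f"unknown route {self.route!r}")
        if self.infusion_duration < 0:
            raise ValidationError("infusion_duration must be >= 0")
        if self.route == ROUTE_IV and self.infusion_duration == 0:
            raise ValidationError("intravenous doses require infusion_duration > 0")
        if self.route == ROUTE_ORAL and self.infusion_duration > 0:
            raise ValidationError("oral doses must have infusion_duration == 0")
        if self.n_doses > 1 and (self.interval is None or self.interval <= 0):
            raise ValidationError("interval must be > 0 when n_doses > 1")

    def expand(self) -> list["DoseEvent"]:
        """Expand the q-interval shorthand into single-dose events."""
        if self.n_doses <= 1:
            return [replace(self, interval=None, n_doses=1)]
        return [
            replace(self, time=self.time + i * self.interval,
                    interval=None, n_doses=1)
            for i in range(self.n_doses)
        ]


@dataclass(frozen=True)
class Observation:
    """A measured plasma concentration.

    ``bql_flag`` marks values below the quantification limit; it is derived
    from ``lloq`` when not supplied and checked for consistency when it is.
    """

    time: float
    concentration: float
    lloq: float = DEFAULT_LLOQ
    bql_flag: bool | None = None

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValidationError(f"observation time must be >= 0, got {self.time}")
        if self.concentration < 0:
            raise ValidationError("concentration must be >= 0")
        expected = self.concentration < self.lloq
        if self.bql_flag is None:
            object.__setattr__(self, "bql_flag", expected)
        elif self.bql_flag != expected:
            raise ValidationError(
                f"bql_flag={self.bql_flag} inconsistent with concentration "
                f"{self.concentration} vs lloq {self.lloq}"
            )


@dataclass(frozen=True)
class CovariateSet:
    """Single-snapshot covariates for one subject.

    Laboratory values use the units of routine chemistry panels: ALB g/L,
    CRP mg/L, AST/ALT U/L, TBIL umol/L, HB g/L, PLT 1e9/L, SCR umol/L,
    UA umol/L.
    """

    AGE: float
    WT: float
    SEX: str  # "male" | "female"
    ALB: float
    CRP: float
    phenotype: str  # CYP2C19 phenotype: "NM" | "IM" | "PM"
    ppi_flag: bool = False
    steroid_flag: bool = False
    AST: float = 34.7
    ALT: float = 25.35
    TBIL: float = 13.35
    HB: float = 96.0
    PLT: float = 165.0
    SCR: float = 78.0
    UA: float = 156.8

    def __post_init__(self) -> None:
        for name in CONTINUOUS_COVARIATES:
            if getattr(self, name) <= 0:
                raise ValidationError(f"covariate {name} must be > 0")
        if self.SEX not in ("male", "female"):
            raise ValidationError(f"unknown SEX {self.SEX!r}")
        if self.phenotype not in PHENOTYPES:
            raise ValidationError(
                f"phenotype must be one of {PHENOTYPES}, got {self.phenotype!r}"
            )

    def value(self, name: str) -> float:
        """Numeric value of a covariate by name, with categorical dummies.

        ``SEX`` resolves to the female indicator, ``IM``/``PM`` to phenotype
        dummies, ``PPI``/``STEROID`` to the co-medication flags.
        """
        if name in CONTINUOUS_COVARIATES:
            return float(getattr(self, name))
        if name == "SEX":
            return 1.0 if self.SEX == "female" else 0.0
        if name == "IM":
            return 1.0 if self.phenotype == "IM" else 0.0
        if name == "PM":
            return 1.0 if self.phenotype == "PM" else 0.0
        if name == "PPI":
            return 1.0 if self.ppi_flag else 0.0
        if name == "STEROID":
            return 1.0 if self.steroid_flag else 0.0
        raise KeyError(f"unknown covariate {name!r}")


@dataclass(frozen=True)
class SubjectRecord:
    """One patient: covariates, dose history, and observations."""

    id: str
    covariates: CovariateSet
    doses: tuple[DoseEvent, ...] = ()
    observations: tuple[Observation, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "doses", tuple(self.doses))
        object.__setattr__(self, "observations", tuple(self.observations))
        times = [o.time for o in self.observations]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValidationError(
                f"subject {self.id}: observation times must be strictly increasing"
            )
        if self.observations:
            if not self.doses:
                raise ValidationError(f"subject {self.id}: observations without doses")
            first_dose = min(d.time for d in self.doses)
            if times[0] <= first_dose:
                raise ValidationError(
                    f"subject {self.id}: first observation at t={times[0]} not "
                    f"preceded by any dose"
                )

    def expanded_doses(self) -> list[DoseEvent]:
        out: list[DoseEvent] = []
        for d in self.doses:
            out.extend(d.expand())
        return sorted(out, key=lambda d: d.time)


# ---------------------------------------------------------------------------
# CSV event-record IO

_BASE_COLUMNS = [
    "ID", "TIME", "AMT", "DUR", "II", "NDOSE", "ROUTE", "DV", "MDV", "BQL",
    "LLOQ", "SEX", "CYP2C19", "PPI", "STEROID",
]
DATASET_COLUMNS = _BASE_COLUMNS + list(CONTINUOUS_COVARIATES)

_MANDATORY = ["ID", "TIME", "AMT", "ROUTE", "DV", "MDV",
              "AGE", "WT", "SEX", "ALB", "CRP", "CYP2C19"]


def _apply_dialect(columns: Sequence[str], dialect: dict[str, str] | None) -> dict[str, str]:
    """Map canonical column names to actual file columns."""
    dialect = dialect or {}
    return {canon: dialect.get(canon, canon) for canon in DATASET_COLUMNS}


def write_dataset(subjects: Iterable[SubjectRecord], path,
                  dialect: dict[str, str] | None = None) -> None:
    """Write subjects as a flat event-record CSV re-readable by
    :func:`read_dataset`.

    Floats are rendered with 12 significant digits, so the round trip is
    lossless at that precision and byte-stable for a given input.
    """
    colmap = _apply_dialect(DATASET_COLUMNS, dialect)
    rows = []
    for s in subjects:
        cov = s.covariates
        base = {
            colmap["ID"]: s.id,
            colmap["SEX"]: cov.SEX,
            colmap["CYP2C19"]: cov.phenotype,
            colmap["PPI"]: int(cov.ppi_flag),
            colmap["STEROID"]: int(cov.steroid_flag),
        }
        for name in CONTINUOUS_COVARIATES:
            base[colmap[name]] = getattr(cov, name)
        events = [("dose", d.time, d) for d in s.doses]
        events += [("obs", o.time, o) for o in s.observations]
        events.sort(key=lambda e: (e[1], e[0] == "obs"))
        for kind, _, ev in events:
            row = dict(base)
            if kind == "dose":
                row.update({
                    colmap["TIME"]: ev.time, colmap["AMT"]: ev.amount,
                    colmap["DUR"]: ev.infusion_duration,
                    colmap["II"]: ev.interval if ev.interval is not None else 0.0,
                    colmap["NDOSE"]: ev.n_doses, colmap["ROUTE"]: ev.route,
                    colmap["DV"]: np.nan, colmap["MDV"]: 1,
                    colmap["BQL"]: 0, colmap["LLOQ"]: np.nan,
                })
            else:
                row.update({
                    colmap["TIME"]: ev.time, colmap["AMT"]: 0.0,
                    colmap["DUR"]: 0.0, colmap["II"]: 0.0,
                    colmap["NDOSE"]: 0, colmap["ROUTE"]: "",
                    colmap["DV"]: ev.concentration, colmap["MDV"]: 0,
                    colmap["BQL"]: int(ev.bql_flag), colmap["LLOQ"]: ev.lloq,
                })
            rows.append(row)
    columns = [colmap[c] for c in DATASET_COLUMNS]
    df = pd.DataFrame(rows, columns=columns)
    df.to_csv(path, index=False, float_format="%.12g")


def read_dataset(path, dialect: dict[str, str] | None = None) -> list[SubjectRecord]:
    """Read a flat event-record CSV into validated :class:`SubjectRecord` s.

    Rows with ``MDV == 1`` (or ``AMT > 0``) are dose events; the rest are
    observations.  BQL rows are retained with ``bql_flag`` set, ready for
    M1 exclusion at estimation time.
    """
    colmap = _apply_dialect(DATASET_COLUMNS, dialect)
    df = pd.read_csv(path, dtype={colmap["ID"]: str})
    for canon in _MANDATORY:
        if colmap[canon] not in df.columns:
            raise SchemaError(f"missing mandatory column {colmap[canon]!r}")

    def col(row, canon, default=None):
        name = colmap[canon]
        if name not in row.index:
            return default
        v = row[name]
        return default if pd.isna(v) else v

    subjects: list[SubjectRecord] = []
    for sid, g in df.groupby(colmap["ID"], sort=False):
        first = g.iloc[0]
        cov_kwargs = {name: float(first[colmap[name]])
                      for name in CONTINUOUS_COVARIATES
                      if colmap[name] in g.columns and not pd.isna(first[colmap[name]])}
        sex = str(first[colmap["SEX"]])
        sex = {"M": "male", "F": "female"}.get(sex, sex)
        cov = CovariateSet(
            SEX=sex, phenotype=str(first[colmap["CYP2C19"]]),
            ppi_flag=bool(int(col(first, "PPI", 0))),
            steroid_flag=bool(int(col(first, "STEROID", 0))),
            **cov_kwargs,
        )
        doses, obs = [], []
        for idx, row in g.iterrows():
            time = float(row[colmap["TIME"]])
            amt = float(col(row, "AMT", 0.0) or 0.0)
            if time < 0:
                raise ValidationError(f"row {idx}: negative TIME {time}")
            if amt < 0:
                raise ValidationError(f"row {idx}: negative AMT {amt}")
            mdv = int(col(row, "MDV", 1 if amt > 0 else 0))
            if mdv == 1 or amt > 0:
                n_doses = int(col(row, "NDOSE", 1) or 1)
                interval = float(col(row, "II", 0.0) or 0.0)
                doses.append(DoseEvent(
                    time=time, amount=amt, route=str(row[colmap["ROUTE"]]),
                    infusion_duration=float(col(row, "DUR", 0.0) or 0.0),
                    interval=interval if n_doses > 1 else None,
                    n_doses=max(n_doses, 1),
                ))
            else:
                dv = col(row, "DV")
                if dv is None:
                    raise ValidationError(f"row {idx}: observation row without DV")
                obs.append(Observation(
                    time=time, concentration=float(dv),
                    lloq=float(col(row, "LLOQ", DEFAULT_LLOQ)),
                ))
        obs.sort(key=lambda o: o.time)
        subjects.append(SubjectRecord(id=str(sid), covariates=cov,
                                      doses=tuple(doses), observations=tuple(obs)))
    return subjects


def apply_m1(subjects: Iterable[SubjectRecord]) -> list[SubjectRecord]:
    """Discard below-quantification-limit observations (M1 handling).

    Non-BQL observations are untouched, in order.  Subjects left without
    any observation are dropped from the estimation dataset; a summary of
    everything removed is logged.
    """
    out: list[SubjectRecord] = []
    n_bql = 0
    n_dropped_subjects = 0
    for s in subjects:
        kept = tuple(o for o in s.observations if not o.bql_flag)
        n_bql += len(s.observations) - len(kept)
        if s.observations and not kept:
            n_dropped_subjects += 1
            continue
        out.append(s if len(kept) == len(s.observations)
                   else replace(s, observations=kept))
    if n_bql:
        logger.info(
            "M1: discarded %d BQL observation(s); %d subject(s) dropped with "
            "no remaining observations", n_bql, n_dropped_subjects)
    return out
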