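"""Patient-level cohort tables: typed records, validation, and summaries.

The package ships three CSV fixtures (``patients.csv``, ``rtl.csv``,
``serum.csv``) transcribing the published patient tables of the adrenal
autopsy cohort: 14 sudden-death controls and 18 patients who died after
prolonged critical illness (PCI), with per-patient relative telomere
lengths (RTLs) for the four adrenal cell types and antemortem serum
DHEA-S and albumin values.  Missing cells are encoded with the literal
``NA`` and stay missing — they are never silently turned into zeros.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PatientRecord",
    "RTLRecord",
    "SerumRecord",
    "GroupSummary",
    "CohortTables",
    "CohortValidationError",
    "DurationConvention",
    "DurationParseError",
    "packaged_fixture_dir",
    "load_cohort_tables",
    "write_cohort_tables",
    "parse_duration",
    "summarize_group",
]

GROUPS = ("control", "PCI")
SEXES = ("M", "F")
CELL_TYPES = ("zg", "zf", "zr", "chromaffin")

_REQUIRED_FILES = {
    "patients.csv": ["patient_id", "group", "sex", "age", "disease_duration", "cause_of_death"],
    "rtl.csv": ["patient_id", "rtl_zg", "rtl_zf", "rtl_zr", "rtl_chromaffin"],
    "serum.csv": [
        "patient_id",
        "dheas_ug_dl",
        "dheas_collection",
        "albumin_g_dl",
        "albumin_collection",
    ],
}


class CohortValidationError(ValueError):
    """A fixture row failed validation; the message names file, row and column."""


class DurationParseError(ValueError):
    """A disease-duration string did not match any recognized dialect."""


@dataclass(frozen=True)
class DurationConvention:
    """Unit conversions used to map stated disease durations onto hours.

    The source tables state durations in hours, days, months and years;
    calendar conventions (days per month/year) are not universal, so they
    are explicit and configurable here.  Ranges such as ``"12-13 h"`` map
    to their midpoint.
    """

    hours_per_day: float = 24.0
    days_per_month: float = 30.0
    days_per_year: float = 365.0


_DURATION_RE = re.compile(
    r"^\s*(\d+(?:\.\d+)?)\s*(?:-\s*(\d+(?:\.\d+)?))?\s*"
    r"(h|hr|hrs|hour|hours|d|day|days|month|months|y|year|years)\s*$",
    re.IGNORECASE,
)


def parse_duration(text: str, convention: DurationConvention | None = None) -> float:
    """Parse a disease-duration string into hours.

    Recognized dialects: ``"15 h"``, ``"12-13 h"`` (midpoint), ``"46 days"``,
    ``"3 months"``, ``"1 year"``.
    """
    conv = convention or DurationConvention()
    m = _DURATION_RE.match(text)
    if m is None:
        raise DurationParseError(f"unparseable disease duration: {text!r}")
    lo = float(m.group(1))
    hi = float(m.group(2)) if m.group(2) is not None else lo
    value = (lo + hi) / 2.0
    unit = m.group(3).lower()
    if unit.startswith("h"):
        return value
    if unit.startswith("d"):
        return value * conv.hours_per_day
    if unit.startswith("m"):
        return value * conv.days_per_month * conv.hours_per_day
    return value * conv.days_per_year * conv.hours_per_day


@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    group: str
    sex: str
    age: int
    disease_duration_text: str
    cause_of_death: str

    def duration_hours(self, convention: DurationConvention | None = None) -> float:
        return parse_duration(self.disease_duration_text, convention)


@dataclass(frozen=True)
class RTLRecord:
    """Per-patient relative telomere lengths (mean NTCR) for four cell types."""

    patient_id: str
    rtl_zg: float
    rtl_zf: float
    rtl_zr: float
    rtl_chromaffin: float

    def value(self, cell_type: str) -> float:
        return getattr(self, f"rtl_{cell_type}")


@dataclass(frozen=True)
class SerumRecord:
    """Antemortem serum values; ``None`` encodes an ``N/A`` table cell."""

    patient_id: str
    dheas: float | None
    dheas_note: str | None
    albumin: float | None
    albumin_note: str | None


@dataclass(frozen=True)
class GroupSummary:
    """n, arithmetic mean, and sample SD (n-1 denominator; None for n=1)."""

    n: int
    mean: float
    sd: float | None


def summarize_group(values: Iterable[float]) -> GroupSummary:
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("summarize_group requires at least one value")
    if not np.all(np.isfinite(arr)):
        raise ValueError("summarize_group requires finite values")
    sd = float(np.std(arr, ddof=1)) if arr.size >= 2 else None
    return GroupSummary(n=int(arr.size), mean=float(np.mean(arr)), sd=sd)


@dataclass
class CohortTables:
    """Validated cohort: typed records plus the underlying data frames."""

    patients: list[PatientRecord]
    rtl: list[RTLRecord]
    serum: list[SerumRecord]
    patients_df: pd.DataFrame = field(repr=False)
    rtl_df: pd.DataFrame = field(repr=False)
    serum_df: pd.DataFrame = field(repr=False)

    def patient_ids(self, group: str | None = None, sex: str | None = None) -> list[str]:
        out = []
        for p in self.patients:
            if group is not None and p.group != group:
                continue
            if sex is not None and p.sex != sex:
                continue
            out.append(p.patient_id)
        return out

    def rtl_values(self, group: str, sex: str, cell_type: str) -> list[float]:
        ids = set(self.patient_ids(group, sex))
        return [r.value(cell_type) for r in self.rtl if r.patient_id in ids]

    def serum_values(self, group: str, sex: str, analyte: str) -> list[float]:
        """Non-missing serum values (``analyte`` in {'dheas', 'albumin'})."""
        ids = set(self.patient_ids(group, sex))
        vals = [getattr(s, analyte) for s in self.serum if s.patient_id in ids]
        return [v for v in vals if v is not None]

    def ages(self, group: str, sex: str) -> list[int]:
        return [p.age for p in self.patients if p.group == group and p.sex == sex]


def packaged_fixture_dir() -> Path:
    """Directory holding the packaged cohort CSV fixtures."""
    return Path(resources.files("adrenotelo").joinpath("data"))


def _read_csv(path: Path, name: str) -> pd.DataFrame:
    fp = path / name
    if not fp.is_file():
        raise CohortValidationError(f"missing fixture file: {fp}")
    df = pd.read_csv(fp, dtype=str, keep_default_na=False)
    missing = [c for c in _REQUIRED_FILES[name] if c not in df.columns]
    if missing:
        raise CohortValidationError(f"{name}: missing columns {missing}")
    dup = df["patient_id"][df["patient_id"].duplicated()]
    if len(dup):
        raise CohortValidationError(f"{name}: duplicate patient_id {sorted(set(dup))}")
    return df


def _to_float(raw: str, name: str, row: int, col: str, allow_na: bool) -> float | None:
    raw = raw.strip()
    if raw in ("NA", "N/A", ""):
        if allow_na:
            return None
        raise CohortValidationError(f"{name} row {row}: {col} may not be missing")
    try:
        return float(raw)
    except ValueError:
        raise CohortValidationError(f"{name} row {row}: {col}={raw!r} is not numeric") from None


def load_cohort_tables(path: str | Path | None = None) -> CohortTables:
    """Load and validate the cohort CSV tables.

    Parameters
    ----------
    path : optional
        Directory with ``patients.csv``, ``rtl.csv``, ``serum.csv``.
        Defaults to the packaged fixtures transcribing the published tables.
    """
    base = Path(path) if path is not None else packaged_fixture_dir()
    if not base.is_dir():
        raise CohortValidationError(f"fixture directory not found: {base}")
    pdf = _read_csv(base, "patients.csv")
    rdf = _read_csv(base, "rtl.csv")
    sdf = _read_csv(base, "serum.csv")

    patients: list[PatientRecord] = []
    for i, row in pdf.iterrows():
        group, sex = row["group"].strip(), row["sex"].strip()
        if group not in GROUPS:
            raise CohortValidationError(f"patients.csv row {i}: group={group!r} not in {GROUPS}")
        if sex not in SEXES:
            raise CohortValidationError(f"patients.csv row {i}: sex={sex!r} not in {SEXES}")
        age = _to_float(row["age"], "patients.csv", i, "age", allow_na=False)
        if not (0 <= age <= 120):
            raise CohortValidationError(f"patients.csv row {i}: age={age} outside [0, 120]")
        try:
            parse_duration(row["disease_duration"])
        except DurationParseError as exc:
            raise CohortValidationError(f"patients.csv row {i}: {exc}") from exc
        patients.append(
            PatientRecord(
                patient_id=row["patient_id"],
                group=group,
                sex=sex,
                age=int(age),
                disease_duration_text=row["disease_duration"],
                cause_of_death=row["cause_of_death"],
            )
        )

    known_ids = {p.patient_id for p in patients}
    rtl: list[RTLRecord] = []
    for i, row in rdf.iterrows():
        if row["patient_id"] not in known_ids:
            raise CohortValidationError(f"rtl.csv row {i}: unknown patient_id {row['patient_id']!r}")
        vals = {}
        for ct in CELL_TYPES:
            col = f"rtl_{ct}"
            v = _to_float(row[col], "rtl.csv", i, col, allow_na=False)
            if not (v > 0 and math.isfinite(v)):
                raise CohortValidationError(f"rtl.csv row {i}: {col}={v} must be finite and > 0")
            vals[col] = v
        rtl.append(RTLRecord(patient_id=row["patient_id"], **vals))

    serum: list[SerumRecord] = []
    for i, row in sdf.iterrows():
        if row["patient_id"] not in known_ids:
            raise CohortValidationError(
                f"serum.csv row {i}: unknown patient_id {row['patient_id']!r}"
            )
        dheas = _to_float(row["dheas_ug_dl"], "serum.csv", i, "dheas_ug_dl", allow_na=True)
        if dheas is not None and dheas < 0:
            raise CohortValidationError(f"serum.csv row {i}: dheas_ug_dl={dheas} must be >= 0")
        alb = _to_float(row["albumin_g_dl"], "serum.csv", i, "albumin_g_dl", allow_na=True)
        if alb is not None and not (0 < alb <= 6):
            raise CohortValidationError(f"serum.csv row {i}: albumin_g_dl={alb} outside (0, 6]")
        note = lambda c: (row[c].strip() or None) if row[c].strip() not in ("NA", "N/A") else None
        serum.append(
            SerumRecord(
                patient_id=row["patient_id"],
                dheas=dheas,
                dheas_note=note("dheas_collection"),
                albumin=alb,
                albumin_note=note("albumin_collection"),
            )
        )

    return CohortTables(
        patients=patients, rtl=rtl, serum=serum, patients_df=pdf, rtl_df=rdf, serum_df=sdf
    )


def write_cohort_tables(tables: CohortTables, path: str | Path) -> None:
    """Write a cohort back to the fixture schema (round-trips losslessly)."""
    base = Path(path)
    base.mkdir(parents=True, exist_ok=True)

    pdf = pd.DataFrame(
        [
            {
                "patient_id": p.patient_id,
                "group": p.group,
                "sex": p.sex,
                "age": p.age,
                "disease_duration": p.disease_duration_text,
                "cause_of_death": p.cause_of_death,
            }
            for p in tables.patients
        ]
    )
    rdf = pd.DataFrame(
        [
            {
                "patient_id": r.patient_id,
                **{f"rtl_{ct}": f"{r.value(ct):.2f}" for ct in CELL_TYPES},
            }
            for r in tables.rtl
        ]
    )

    def cell(v: float | None, fmt: str = "g") -> str:
        return "NA" if v is None else format(v, fmt)

    sdf = pd.DataFrame(
        [
            {
                "patient_id": s.patient_id,
                "dheas_ug_dl": cell(s.dheas),
                "dheas_collection": s.dheas_note or "NA",
                "albumin_g_dl": cell(s.albumin),
                "albumin_collection": s.albumin_note or "NA",
            }
            for s in tables.serum
        ]
    )
    pdf.to_csv(base / "patients.csv", index=False)
    rdf.to_csv(base / "rtl.csv", index=False)
    sdf.to_csv(base / "serum.csv", index=False)
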