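"""Cohort data model, delimited-text I/O and the study clock.

A patient's history is a :class:`PatientTimeline`: dated clinical events
(surgery, radiotherapy, optional re-resection / bevacizumab start, death or
loss to follow-up) plus an ordered series of MRI scans, each carrying
per-lesion volumes for the two compartments assessed in neuro-oncology
response criteria — contrast-enhancing tumor (CE, post-gadolinium T1) and
nonenhancing T2/FLAIR abnormality (NE).

All dates live on a *study clock*: integer day offsets from the preoperative
MRI (day 0, the date of diagnosis). Calendar dates in input files are
converted at read time, which removes any format/time-zone ambiguity from
downstream survival arithmetic. Endpoints are reported in months using a
fixed month of 30.4375 days (Julian year / 12).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

#: Fixed month length in days (Julian year / 12) used for every
#: day->month conversion in the package.
DAYS_PER_MONTH = 30.4375

#: Calendar anchor used when writing timelines back to dated CSV files.
#: Only day *offsets* are meaningful; the anchor is arbitrary but fixed so
#: that write -> read round-trips are exact.
EPOCH = date(2015, 1, 1)

#: Surgery must happen 1-14 days after the preoperative (diagnosis) MRI.
SURGERY_WINDOW_DAYS = (1, 14)
#: Post-operative baseline MRI window, days after surgery.
POSTOP_WINDOW_DAYS = (1, 2)
#: Post-radiotherapy baseline MRI window, days after the end of radiotherapy.
POSTRT_WINDOW_DAYS = (21, 35)


class Compartment(str, enum.Enum):
    """Lesion compartment: contrast-enhancing or nonenhancing T2/FLAIR."""

    CE = "CE"
    NE = "NE"


class ScanRole(str, enum.Enum):
    POSTOP_BASELINE = "postop_baseline"
    POSTRT_BASELINE = "postrt_baseline"
    FOLLOWUP = "followup"


class CohortSchemaError(ValueError):
    """An input file is missing a required column."""


class CohortIntegrityError(ValueError):
    """Duplicate (patient, scan, lesion, compartment) rows or similar."""


class TimelineValidationError(ValueError):
    """A timeline violates a hard invariant; carries the diagnostics."""

    def __init__(self, diagnostics: Sequence["Diagnostic"]):
        self.diagnostics = list(diagnostics)
        msg = "; ".join(f"{d.patient_id}[{d.rule_id}]: {d.message}" for d in self.diagnostics)
        super().__init__(f"timeline validation failed: {msg}")


@dataclass(frozen=True)
class Diagnostic:
    """A validation finding. ``severity`` is ``error`` for invariant
    violations and ``warning`` for soft findings (e.g. a missing baseline
    window, which excludes the patient from a criterion but is not a data
    defect)."""

    patient_id: str
    rule_id: str
    message: str
    severity: str = "error"


@dataclass(frozen=True)
class LesionMeasurement:
    lesion_id: str
    compartment: Compartment
    volume_cm3: float
    is_target: bool = True
    is_new: bool = False


@dataclass(frozen=True)
class ScanRecord:
    scan_day: int
    lesions: tuple[LesionMeasurement, ...] = ()
    role_hint: Optional[ScanRole] = None

    def compartment_lesions(self, compartment: Compartment) -> tuple[LesionMeasurement, ...]:
        return tuple(l for l in self.lesions if l.compartment is compartment)


@dataclass(frozen=True)
class PatientTimeline:
    patient_id: str
    surgery_day: int
    rt_start_day: int
    rt_end_day: int
    scans: tuple[ScanRecord, ...]
    last_followup_day: int
    alive_at_last_followup: bool
    diagnosis_day: int = 0
    reresection_day: Optional[int] = None
    bevacizumab_start_day: Optional[int] = None
    death_day: Optional[int] = None


def days_to_months(days: float, month_days: float = DAYS_PER_MONTH) -> float:
    """Convert a non-negative day count to months (``days / 30.4375``)."""
    if days < 0:
        raise ValueError(f"negative day count: {days}")
    return days / month_days


def months_to_days(months: float, month_days: float = DAYS_PER_MONTH) -> int:
    """Inverse of :func:`days_to_months`, rounded to the nearest whole day."""
    if months < 0:
        raise ValueError(f"negative month count: {months}")
    return round(months * month_days)


# ---------------------------------------------------------------------------
# validation

def _canonical_scan(scan: ScanRecord) -> ScanRecord:
    lesions = tuple(sorted(scan.lesions, key=lambda l: (l.compartment.value, l.lesion_id)))
    return replace(scan, lesions=lesions)


def validate_timeline(t: PatientTimeline) -> list[Diagnostic]:
    """Check every timeline invariant; returns diagnostics, never raises.

    An empty list means the timeline is fully well formed, including the
    presence of both baseline-window scans.
    """
    out: list[Diagnostic] = []
    pid = t.patient_id

    def err(rule: str, msg: str, severity: str = "error") -> None:
        out.append(Diagnostic(pid, rule, msg, severity))

    if not (t.diagnosis_day <= t.surgery_day < t.rt_start_day < t.rt_end_day):
        err("treatment-ordering",
            f"require diagnosis<=surgery<rt_start<rt_end, got "
            f"{t.diagnosis_day}/{t.surgery_day}/{t.rt_start_day}/{t.rt_end_day}")
    lo, hi = SURGERY_WINDOW_DAYS
    if not (lo <= t.surgery_day - t.diagnosis_day <= hi):
        err("surgery-window",
            f"surgery must fall {lo}-{hi} days after the diagnosis MRI, "
            f"got day {t.surgery_day - t.diagnosis_day}")
    if t.death_day is not None:
        if t.alive_at_last_followup:
            err("death-consistency", "death_day set but alive_at_last_followup is true")
        if t.last_followup_day != t.death_day:
            err("death-consistency",
                f"last_followup_day ({t.last_followup_day}) must equal death_day ({t.death_day})")

    prev = None
    for s in t.scans:
        if s.scan_day < 0:
            err("scan-range", f"scan_day {s.scan_day} negative")
        if s.scan_day > t.last_followup_day:
            err("scan-range", f"scan_day {s.scan_day} after last_followup_day {t.last_followup_day}")
        if prev is not None and s.scan_day <= prev:
            err("scan-ordering", f"scan days not strictly increasing at day {s.scan_day}")
        prev = s.scan_day
        seen: set[tuple[str, str]] = set()
        for l in s.lesions:
            if l.volume_cm3 < 0:
                err("volume-nonnegative",
                    f"lesion {l.lesion_id} at day {s.scan_day} has volume {l.volume_cm3}")
            key = (l.compartment.value, l.lesion_id)
            if key in seen:
                err("lesion-duplicate",
                    f"lesion {l.lesion_id} ({l.compartment.value}) duplicated at day {s.scan_day}")
            seen.add(key)

    days = [s.scan_day for s in t.scans]
    po_lo, po_hi = POSTOP_WINDOW_DAYS
    if not any(t.surgery_day + po_lo <= d <= t.surgery_day + po_hi for d in days):
        err("missing-postop-baseline",
            f"no scan {po_lo}-{po_hi} days after surgery (day {t.surgery_day})",
            severity="warning")
    pr_lo, pr_hi = POSTRT_WINDOW_DAYS
    if not any(t.rt_end_day + pr_lo <= d <= t.rt_end_day + pr_hi for d in days):
        err("missing-postrt-baseline",
            f"no scan {pr_lo}-{pr_hi} days after the end of radiotherapy (day {t.rt_end_day})",
            severity="warning")
    return out


# ---------------------------------------------------------------------------
# I/O

META_COLUMNS = [
    "patient_id", "diagnosis_date", "surgery_date", "rt_start_date", "rt_end_date",
    "reresection_date", "bevacizumab_start_date", "death_date", "last_followup_date",
    "alive",
]
SCAN_COLUMNS = ["patient_id", "scan_date", "lesion_id", "compartment", "volume_cm3", "is_new"]


def _require_columns(df: pd.DataFrame, required: Iterable[str], path: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise CohortSchemaError(f"{path}: missing required column(s): {', '.join(missing)}")


def _parse_date(value: object) -> Optional[date]:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    s = str(value).strip()
    if not s or s.lower() == "nan":
        return None
    return date.fromisoformat(s)


def read_cohort(metadata_path: str, scans_path: str) -> list[PatientTimeline]:
    """Read and validate a cohort from the two-file CSV schema.

    Raises :class:`CohortSchemaError` on missing columns,
    :class:`CohortIntegrityError` on duplicate lesion rows and
    :class:`TimelineValidationError` when a hard invariant fails.  Soft
    findings (missing baseline windows) are left to downstream stages.
    """
    meta = pd.read_csv(metadata_path, dtype=str)
    scans = pd.read_csv(scans_path, dtype=str)
    _require_columns(meta, META_COLUMNS, str(metadata_path))
    _require_columns(scans, SCAN_COLUMNS, str(scans_path))

    dup = scans.duplicated(subset=["patient_id", "scan_date", "lesion_id", "compartment"])
    if dup.any():
        row = scans[dup].iloc[0]
        raise CohortIntegrityError(
            f"duplicate lesion row: patient {row['patient_id']} scan {row['scan_date']} "
            f"lesion {row['lesion_id']} ({row['compartment']})")

    scans_by_pid: dict[str, list] = {}
    for rec in scans.to_dict("records"):
        scans_by_pid.setdefault(str(rec["patient_id"]), []).append(rec)

    timelines: list[PatientTimeline] = []
    errors: list[Diagnostic] = []
    for rec in meta.to_dict("records"):
        pid = str(rec["patient_id"])
        dx = _parse_date(rec["diagnosis_date"])
        if dx is None:
            raise CohortSchemaError(f"patient {pid}: diagnosis_date is required")

        def day(value: object) -> Optional[int]:
            d = _parse_date(value)
            return None if d is None else (d - dx).days

        for col in ("surgery_date", "rt_start_date", "rt_end_date", "last_followup_date"):
            if _parse_date(rec[col]) is None:
                raise CohortSchemaError(f"patient {pid}: {col} is required")
        death_day = day(rec["death_date"])
        alive = str(rec["alive"]).strip() in ("1", "True", "true")
        scan_map: dict[int, list[LesionMeasurement]] = {}
        for srec in scans_by_pid.get(pid, []):
            sday = (date.fromisoformat(str(srec["scan_date"]).strip()) - dx).days
            vol = float(srec["volume_cm3"])
            scan_map.setdefault(sday, []).append(LesionMeasurement(
                lesion_id=str(srec["lesion_id"]),
                compartment=Compartment(str(srec["compartment"]).strip()),
                volume_cm3=vol,
                is_new=str(srec["is_new"]).strip() in ("1", "True", "true"),
            ))
        scan_records = tuple(
            _canonical_scan(ScanRecord(scan_day=d, lesions=tuple(ls)))
            for d, ls in sorted(scan_map.items())
        )
        t = PatientTimeline(
            patient_id=pid,
            surgery_day=day(rec["surgery_date"]),
            rt_start_day=day(rec["rt_start_date"]),
            rt_end_day=day(rec["rt_end_date"]),
            scans=scan_records,
            last_followup_day=day(rec["last_followup_date"]),
            alive_at_last_followup=alive,
            reresection_day=day(rec["reresection_date"]),
            bevacizumab_start_day=day(rec["bevacizumab_start_date"]),
            death_day=death_day,
        )
        errors.extend(d for d in validate_timeline(t) if d.severity == "error")
        timelines.append(t)
    if errors:
        raise TimelineValidationError(errors)
    return timelines


def write_cohort(timelines: Sequence[PatientTimeline], metadata_path: str, scans_path: str) -> None:
    """Write the cohort back to the CSV schema (dates anchored at EPOCH)."""

    def iso(day: Optional[int]) -> str:
        return "" if day is None else (EPOCH + timedelta(days=int(day))).isoformat()

    meta_rows = []
    scan_rows = []
    for t in timelines:
        meta_rows.append({
            "patient_id": t.patient_id,
            "diagnosis_date": iso(t.diagnosis_day),
            "surgery_date": iso(t.surgery_day),
            "rt_start_date": iso(t.rt_start_day),
            "rt_end_date": iso(t.rt_end_day),
            "reresection_date": iso(t.reresection_day),
            "bevacizumab_start_date": iso(t.bevacizumab_start_day),
            "death_date": iso(t.death_day),
            "last_followup_date": iso(t.last_followup_day),
            "alive": int(t.alive_at_last_followup),
        })
        for s in t.scans:
            for l in _canonical_scan(s).lesions:
                scan_rows.append({
                    "patient_id": t.patient_id,
                    "scan_date": iso(s.scan_day),
                    "lesion_id": l.lesion_id,
                    "compartment": l.compartment.value,
                    "volume_cm3": repr(float(l.volume_cm3)),
                    "is_new": int(l.is_new),
                })
    pd.DataFrame(meta_rows, columns=META_COLUMNS).to_csv(metadata_path, index=False)
    pd.DataFrame(scan_rows, columns=SCAN_COLUMNS).to_csv(scans_path, index=False)
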