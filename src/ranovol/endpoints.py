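"""Per-patient survival endpoints derived from progression calls.

PFS runs from the preoperative MRI (day 0) to the dated progression (event)
or to the censoring scan; OS runs from day 0 to death or last follow-up;
PPS (post-progression survival) runs from progression to death or last
follow-up and is defined only for patients with an observed progression.
All durations are reported in months (30.4375-day months), so for a fully
observed patient PFS + PPS = OS up to day rounding.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .criteria import Criterion, ProgressionCall
from .timelines import DAYS_PER_MONTH, PatientTimeline, days_to_months


@dataclass(frozen=True)
class EndpointRow:
    patient_id: str
    criterion: Criterion
    pfs_months: float
    pfs_event: bool
    os_months: float
    os_event: bool
    pps_months: Optional[float] = None
    pps_event: Optional[bool] = None


ENDPOINT_COLUMNS = ["patient_id", "criterion", "pfs_months", "pfs_event",
                    "pps_months", "pps_event", "os_months", "os_event"]


def compute_endpoints(t: PatientTimeline, call: ProgressionCall,
                      month_days: float = DAYS_PER_MONTH) -> EndpointRow:
    """Derive one patient's PFS/PPS/OS row from a progression call."""
    if call.patient_id != t.patient_id:
        raise ValueError(f"call for {call.patient_id} does not belong to {t.patient_id}")
    os_day = t.death_day if t.death_day is not None else t.last_followup_day
    os_event = t.death_day is not None
    if call.progressed:
        if t.death_day is not None and call.progression_day > t.death_day:
            raise ValueError(
                f"patient {t.patient_id}: progression day {call.progression_day} "
                f"after death day {t.death_day}")
        pfs_day = call.progression_day
        pps_months = days_to_months(os_day - pfs_day, month_days)
        pps_event: Optional[bool] = os_event
        pfs_event = True
    else:
        pfs_day = call.censor_day
        pps_months = None
        pps_event = None
        pfs_event = False
    return EndpointRow(
        patient_id=t.patient_id,
        criterion=call.criterion,
        pfs_months=days_to_months(pfs_day, month_days),
        pfs_event=pfs_event,
        os_months=days_to_months(os_day, month_days),
        os_event=os_event,
        pps_months=pps_months,
        pps_event=pps_event,
    )


def cohort_endpoint_table(timelines: Sequence[PatientTimeline],
                          calls: Iterable[ProgressionCall],
                          month_days: float = DAYS_PER_MONTH) -> pd.DataFrame:
    """Long-format endpoint table: one row per patient x criterion.

    Requires exactly one call per patient for every criterion present in
    ``calls``; raises on duplicates or gaps.  Rows are ordered by
    (patient_id, criterion).
    """
    by_pid = {t.patient_id: t for t in timelines}
    seen: dict[tuple[str, Criterion], ProgressionCall] = {}
    criteria: set[Criterion] = set()
    for c in calls:
        key = (c.patient_id, c.criterion)
        if key in seen:
            raise ValueError(f"duplicate call for patient {c.patient_id} / {c.criterion.value}")
        if c.patient_id not in by_pid:
            raise ValueError(f"call for unknown patient {c.patient_id}")
        seen[key] = c
        criteria.add(c.criterion)
    rows = []
    for t in timelines:
        for crit in sorted(criteria, key=lambda c: c.value):
            call = seen.get((t.patient_id, crit))
            if call is None:
                raise ValueError(f"missing call for patient {t.patient_id} / {crit.value}")
            r = compute_endpoints(t, call, month_days)
            rows.append({
                "patient_id": r.patient_id,
                "criterion": r.criterion.value,
                "pfs_months": r.pfs_months,
                "pfs_event": r.pfs_event,
                "pps_months": r.pps_months,
                "pps_event": r.pps_event,
                "os_months": r.os_months,
                "os_event": r.os_event,
            })
    df = pd.DataFrame(rows, columns=ENDPOINT_COLUMNS)
    return df.sort_values(["patient_id", "criterion"], kind="stable").reset_index(drop=True)


def median_iqr(values: Sequence[float]) -> tuple[float, float]:
    """Median and interquartile range with linear quartile interpolation.

    The quartile convention matters on small n; this is numpy's default
    linear-interpolation rule.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        return float("nan"), float("nan")
    q1, q2, q3 = np.percentile(arr, [25, 50, 75])
    return float(q2), float(q3 - q1)
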