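from __future__ import annotations

import pytest

from ranovol.criteria import CriteriaConfig, Criterion
from ranovol.simulate import SimulationConfig, simulate_cohort
from ranovol.timelines import (
    Compartment,
    LesionMeasurement,
    PatientTimeline,
    ScanRecord,
    ScanRole,
)


def ce(lesion_id, vol, new=False):
    return LesionMeasurement(lesion_id, Compartment.CE, vol, is_new=new)


def ne(lesion_id, vol):
    return LesionMeasurement(lesion_id, Compartment.NE, vol)


@pytest.fixture(scope="session")
def fig2_timeline() -> PatientTimeline:
    """Representative worked-example patient.

    Gross total resection (no CE tumor post-op).  A new measurable lesion
    appears at the second follow-up (>12 weeks after radiotherapy), shrinks
    at the third, stays stable at the fourth; a second new lesion appears at
    the fifth follow-up and keeps growing at the sixth.  Expected:
    post-op-baseline criterion and post-RT criterion without late
    confirmation both call PD at follow-up 2; the always-confirm criterion
    relabels follow-up 2 as pseudoprogression and dates PD to follow-up 5.
    """
    scans = (
        ScanRecord(8, (ne("bg", 6.0),), ScanRole.POSTOP_BASELINE),
        ScanRecord(115, (ne("bg", 6.0),), ScanRole.POSTRT_BASELINE),
        ScanRecord(206, (ce("L1", 1.2, new=True), ne("bg", 6.0)), ScanRole.FOLLOWUP),
        ScanRecord(297, (ce("L1", 0.5), ne("bg", 6.0)), ScanRole.FOLLOWUP),
        ScanRecord(388, (ce("L1", 0.5), ne("bg", 6.0)), ScanRole.FOLLOWUP),
        ScanRecord(479, (ce("L1", 0.5), ce("L2", 1.5, new=True), ne("bg", 6.0)),
                   ScanRole.FOLLOWUP),
        ScanRecord(570, (ce("L1", 0.5), ce("L2", 3.5), ne("bg", 6.0)),
                   ScanRole.FOLLOWUP),
    )
    return PatientTimeline(
        patient_id="GB-0110",
        surgery_day=7,
        rt_start_day=45,
        rt_end_day=87,
        scans=scans,
        last_followup_day=640,
        alive_at_last_followup=False,
        death_day=640,
    )


@pytest.fixture(scope="session")
def configs() -> dict[Criterion, CriteriaConfig]:
    return {c: CriteriaConfig.preset(c) for c in Criterion}


@pytest.fixture(scope="session")
def small_cohort():
    """A 40-patient synthetic cohort shared by read-only tests."""
    return simulate_cohort(SimulationConfig(n_patients=40, seed=5))
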