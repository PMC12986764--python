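"""Volumetric response-criteria state machines: RANO, mRANO and RANO 2.0.

The three criteria share one volumetric rule set and differ in two knobs:

* **baseline scan** — RANO references the immediate post-operative MRI
  (24-48 h after surgery); mRANO and RANO 2.0 reference the post-radiotherapy
  MRI (21-35 days after the end of radiotherapy);
* **confirmation policy** — mRANO always requires a confirmatory scan before
  progression is final; RANO and RANO 2.0 require one only while inside the
  12-week post-radiotherapy guard window (where pseudoprogression is most
  likely).

Progressive disease (PD) is suspected when the contrast-enhancing (CE) total
volume rises >=40% above the nadir (smallest total observed since baseline)
and is measurable (>=1 cm^3), when the nonenhancing (NE) total doubles above
its nadir, or when a new measurable lesion appears.  A suspicion that
requires confirmation is labelled preliminary PD (pPD); the next scan
confirms it (a further >=40% increase, or further new lesions) or refutes it,
in which case the suspicion scan is retrospectively relabelled
pseudoprogression (PsP).  Confirmed PD is back-dated to the scan of first
suspicion.  Partial response (PR) is a >=65% CE decrease from baseline and
complete response (CR) the disappearance of CE tumor volume.

Re-resection and the start of second-line bevacizumab act as non-imaging
progression events: if imaging has not already declared PD by then, the last
MRI before the event becomes the progression date.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from statistics import median
from typing import Iterable, Mapping, Optional, Sequence

from .timelines import (
    Compartment,
    Diagnostic,
    PatientTimeline,
    POSTOP_WINDOW_DAYS,
    POSTRT_WINDOW_DAYS,
    ScanRecord,
)

MAX_TARGET_LESIONS = 5


class Criterion(str, enum.Enum):
    RANO = "rano"
    MRANO = "mrano"
    RANO2 = "rano2"


class BaselineRule(str, enum.Enum):
    POSTOP = "postop"
    POSTRT = "postrt"


class ConfirmationRule(str, enum.Enum):
    #: confirmation needed only inside the 12-week guard (classic RANO)
    NEVER_REQUIRED_AFTER_GUARD = "never_required_after_guard"
    #: confirmation always needed (mRANO)
    ALWAYS_REQUIRED = "always_required"
    #: confirmation needed only inside the guard (RANO 2.0)
    REQUIRED_WITHIN_GUARD_ONLY = "required_within_guard_only"


class Label(str, enum.Enum):
    CR = "CR"
    PR = "PR"
    SD = "SD"
    PD = "PD"
    PPD = "pPD"
    PSP = "PsP"
    NOT_EVALUABLE = "not_evaluable"


class RawLabel(str, enum.Enum):
    """Per-scan label before confirmation logic is applied."""

    CR = "CR"
    PR = "PR"
    SD = "SD"
    PD_CANDIDATE = "PD-candidate"


class Trigger(str, enum.Enum):
    NONE = "none"
    CE_INCREASE = "ce_increase"
    NE_INCREASE = "ne_increase"
    NEW_LESION = "new_lesion"
    CONFIRMATION = "confirmation"
    RETRO_PSP = "retro_psp"


class CallReason(str, enum.Enum):
    IMAGING_PD = "imaging_PD"
    RERESECTION = "reresection"
    BEVACIZUMAB = "bevacizumab"
    CENSORED_SD_LAST_SCAN = "censored_sd_last_scan"
    CENSORED_LOST = "censored_lost"


class BaselineMissingError(ValueError):
    """No scan in the criterion's baseline window; the patient is excluded."""


@dataclass(frozen=True)
class CriteriaConfig:
    """All thresholds and windows distinguishing the three criteria.

    Fractions are relative volume changes: ``pd_increase_frac=0.40`` means
    PD is suspected at a >=40% CE increase above the nadir;
    ``ne_pd_increase_frac=1.00`` means the NE total must double.
    """

    criterion: Criterion
    baseline_rule: BaselineRule
    confirmation_rule: ConfirmationRule
    pd_increase_frac: float = 0.40
    pr_decrease_frac: float = 0.65
    cr_volume_cm3: float = 0.0
    ne_pd_increase_frac: float = 1.00
    measurable_min_cm3: float = 1.0
    confirmation_window_weeks: tuple[float, float] = (4.0, 8.0)
    psp_extra_increase_frac: float = 0.40
    early_pd_guard_weeks: float = 12.0

    def __post_init__(self) -> None:
        for name in ("pd_increase_frac", "pr_decrease_frac", "cr_volume_cm3",
                     "ne_pd_increase_frac", "psp_extra_increase_frac"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.measurable_min_cm3 <= 0:
            raise ValueError("measurable_min_cm3 must be > 0")
        lo, hi = self.confirmation_window_weeks
        if not lo < hi:
            raise ValueError("confirmation window lower bound must be < upper bound")

    @property
    def guard_days(self) -> int:
        return round(self.early_pd_guard_weeks * 7)

    @classmethod
    def preset(cls, criterion: Criterion | str, **overrides) -> "CriteriaConfig":
        """The standard preset for a criterion; thresholds can be overridden."""
        criterion = Criterion(criterion)
        presets = {
            Criterion.RANO: (BaselineRule.POSTOP, ConfirmationRule.NEVER_REQUIRED_AFTER_GUARD),
            Criterion.MRANO: (BaselineRule.POSTRT, ConfirmationRule.ALWAYS_REQUIRED),
            Criterion.RANO2: (BaselineRule.POSTRT, ConfirmationRule.REQUIRED_WITHIN_GUARD_ONLY),
        }
        baseline, confirmation = presets[criterion]
        return cls(criterion=criterion, baseline_rule=baseline,
                   confirmation_rule=confirmation, **overrides)


@dataclass(frozen=True)
class ScanAssessment:
    scan_day: int
    label: Label
    ce_total_cm3: float
    ne_total_cm3: float
    reference_baseline_cm3: float
    reference_nadir_cm3: float
    trigger: Trigger = Trigger.NONE


@dataclass(frozen=True)
class ProgressionCall:
    patient_id: str
    criterion: Criterion
    progressed: bool
    progression_day: Optional[int] = None
    censor_day: Optional[int] = None
    reason: CallReason = CallReason.CENSORED_SD_LAST_SCAN
    #: scan day of the confirming MRI, when PD needed confirmation
    confirmed_day: Optional[int] = None

    def __post_init__(self) -> None:
        if (self.progression_day is None) == (self.censor_day is None):
            raise ValueError("exactly one of progression_day / censor_day must be set")


@dataclass(frozen=True)
class AssessmentTrack:
    patient_id: str
    criterion: Criterion
    baseline_day: int
    assessments: tuple[ScanAssessment, ...]
    call: ProgressionCall
    diagnostics: tuple[Diagnostic, ...] = ()


# ---------------------------------------------------------------------------
# building blocks

def select_baseline(t: PatientTimeline, cfg: CriteriaConfig,
                    diagnostics: Optional[list[Diagnostic]] = None) -> ScanRecord:
    """Pick the baseline scan for ``cfg.baseline_rule``.

    Post-op rule: the scan 1-2 days after surgery.  Post-RT rule: the scan
    21-35 days after the end of radiotherapy.  With several scans in the
    window the earliest is used and a warning diagnostic emitted; with none
    a :class:`BaselineMissingError` is raised (the patient would not have
    met the study's inclusion criteria).
    """
    if cfg.baseline_rule is BaselineRule.POSTOP:
        lo, hi = POSTOP_WINDOW_DAYS
        window = (t.surgery_day + lo, t.surgery_day + hi)
    else:
        lo, hi = POSTRT_WINDOW_DAYS
        window = (t.rt_end_day + lo, t.rt_end_day + hi)
    candidates = [s for s in t.scans if window[0] <= s.scan_day <= window[1]]
    if not candidates:
        raise BaselineMissingError(
            f"patient {t.patient_id}: no {cfg.baseline_rule.value} baseline scan in "
            f"days [{window[0]}, {window[1]}]")
    if len(candidates) > 1 and diagnostics is not None:
        diagnostics.append(Diagnostic(
            t.patient_id, "multiple-baseline-candidates",
            f"{len(candidates)} scans in the {cfg.baseline_rule.value} baseline window; "
            f"using day {candidates[0].scan_day}", severity="warning"))
    return candidates[0]


def total_volume(s: ScanRecord, compartment: Compartment,
                 max_targets: int = MAX_TARGET_LESIONS) -> float:
    """Total target volume of one compartment at one scan.

    CE totals are capped at the ``max_targets`` largest lesions (target
    lesion selection); NE abnormality is summed without a cap.
    """
    vols = sorted((l.volume_cm3 for l in s.lesions
                   if l.compartment is compartment and l.is_target), reverse=True)
    if compartment is Compartment.CE:
        vols = vols[:max_targets]
    return float(sum(vols))


def _raw_label(ce_total: float, ne_total: float, new_measurable: bool,
               baseline_vol: float, nadir_vol: float, ne_nadir_vol: float,
               cfg: CriteriaConfig) -> tuple[RawLabel, Trigger]:
    if baseline_vol < 0 or nadir_vol < 0 or ne_nadir_vol < 0:
        raise ValueError("reference volumes must be non-negative")
    if new_measurable:
        return RawLabel.PD_CANDIDATE, Trigger.NEW_LESION
    if (ce_total >= (1.0 + cfg.pd_increase_frac) * nadir_vol
            and ce_total >= cfg.measurable_min_cm3
            and ce_total > nadir_vol):
        return RawLabel.PD_CANDIDATE, Trigger.CE_INCREASE
    if (ne_total >= (1.0 + cfg.ne_pd_increase_frac) * ne_nadir_vol
            and ne_total >= cfg.measurable_min_cm3
            and ne_total > ne_nadir_vol):
        return RawLabel.PD_CANDIDATE, Trigger.NE_INCREASE
    if ce_total <= cfg.cr_volume_cm3:
        return RawLabel.CR, Trigger.NONE
    if baseline_vol > 0 and ce_total <= (1.0 - cfg.pr_decrease_frac) * baseline_vol:
        return RawLabel.PR, Trigger.NONE
    return RawLabel.SD, Trigger.NONE


def classify_scan(current: ScanRecord, baseline_vol: float, nadir_vol: float,
                  ne_baseline_vol: float, ne_nadir_vol: float,
                  cfg: CriteriaConfig) -> RawLabel:
    """Raw volumetric label of a single scan against given references.

    New-lesion status is taken from the scan's ``is_new`` flags.  Precedence:
    PD-candidate > CR > PR > SD.
    """
    ce = total_volume(current, Compartment.CE)
    ne = total_volume(current, Compartment.NE)
    new_measurable = any(l.is_new and l.volume_cm3 >= cfg.measurable_min_cm3
                         for l in current.lesions)
    label, _ = _raw_label(ce, ne, new_measurable, baseline_vol, nadir_vol,
                          ne_nadir_vol, cfg)
    return label


# ---------------------------------------------------------------------------
# the state machine

def run_criteria(t: PatientTimeline, cfg: CriteriaConfig) -> AssessmentTrack:
    """Walk a patient's scans under one criterion and produce the dated call.

    Maintains CE and NE nadirs (minimum totals from baseline onward, updated
    only by scans that are not PD suspicions).  Confirmation, retrospective
    PsP relabelling and back-dating follow the module docstring.  After a
    refuted suspicion the nadirs are reset to the resolving scan's totals and
    lesions present at that scan stop counting as "new".
    """
    diagnostics: list[Diagnostic] = []
    baseline = select_baseline(t, cfg, diagnostics)

    # Lesions seen at or before baseline are never "new"; if the baseline has
    # more than 5 CE lesions, only the 5 largest count toward CE totals
    # (non-target baseline lesions are excluded thereafter, but lesions that
    # appear later always contribute).
    baseline_ce = sorted(baseline.compartment_lesions(Compartment.CE),
                         key=lambda l: -l.volume_cm3)
    excluded_ce_ids = {l.lesion_id for l in baseline_ce[MAX_TARGET_LESIONS:]}
    known: set[tuple[str, str]] = set()
    for s in t.scans:
        if s.scan_day <= baseline.scan_day:
            known.update((l.compartment.value, l.lesion_id) for l in s.lesions)

    def ce_total(s: ScanRecord) -> float:
        return float(sum(l.volume_cm3 for l in s.lesions
                         if l.compartment is Compartment.CE
                         and l.lesion_id not in excluded_ce_ids))

    def ne_total(s: ScanRecord) -> float:
        return float(sum(l.volume_cm3 for l in s.lesions
                         if l.compartment is Compartment.NE))

    def new_measurable_ids(s: ScanRecord, accepted: set[tuple[str, str]]) -> set[str]:
        return {l.lesion_id for l in s.lesions
                if (l.compartment.value, l.lesion_id) not in accepted
                and l.volume_cm3 >= cfg.measurable_min_cm3}

    baseline_vol = ce_total(baseline)
    ne_baseline_vol = ne_total(baseline)
    nadir = baseline_vol
    ne_nadir = ne_baseline_vol
    accepted = set(known)

    post = [s for s in t.scans if s.scan_day > baseline.scan_day]
    assessments: list[ScanAssessment] = []
    call: Optional[ProgressionCall] = None
    guard_end = t.rt_end_day + cfg.guard_days

    i = 0
    while i < len(post):
        s = post[i]
        ce, ne = ce_total(s), ne_total(s)
        new_ids = new_measurable_ids(s, accepted)
        raw, trigger = _raw_label(ce, ne, bool(new_ids), baseline_vol, nadir,
                                  ne_nadir, cfg)
        if raw is not RawLabel.PD_CANDIDATE:
            assessments.append(ScanAssessment(s.scan_day, Label(raw.value), ce, ne,
                                              baseline_vol, nadir))
            nadir = min(nadir, ce)
            ne_nadir = min(ne_nadir, ne)
            i += 1
            continue

        in_guard = s.scan_day <= guard_end
        needs_confirmation = (cfg.confirmation_rule is ConfirmationRule.ALWAYS_REQUIRED
                              or in_guard)
        if not needs_confirmation:
            assessments.append(ScanAssessment(s.scan_day, Label.PD, ce, ne,
                                              baseline_vol, nadir, trigger))
            call = ProgressionCall(t.patient_id, cfg.criterion, True,
                                   progression_day=s.scan_day,
                                   reason=CallReason.IMAGING_PD)
            break

        if i + 1 >= len(post):
            # suspicion at the final scan: no confirmation possible; the
            # patient is censored rather than called progressive.
            assessments.append(ScanAssessment(s.scan_day, Label.PPD, ce, ne,
                                              baseline_vol, nadir, trigger))
            i += 1
            break

        sp = post[i + 1]
        gap_weeks = (sp.scan_day - s.scan_day) / 7.0
        lo, hi = cfg.confirmation_window_weeks
        if not lo <= gap_weeks <= hi:
            diagnostics.append(Diagnostic(
                t.patient_id, "confirmation-outside-window",
                f"confirmation scan {gap_weeks:.1f} weeks after suspicion at day "
                f"{s.scan_day} (ideal {lo:g}-{hi:g} weeks); using it regardless",
                severity="warning"))
        sp_ce, sp_ne = ce_total(sp), ne_total(sp)
        accepted_plus_s = accepted | {(l.compartment.value, l.lesion_id) for l in s.lesions}
        further_new = bool(new_measurable_ids(sp, accepted_plus_s))

        def further_growth(now: float, ref: float) -> bool:
            return (now >= (1.0 + cfg.psp_extra_increase_frac) * ref
                    and now > ref and now >= cfg.measurable_min_cm3)

        confirmed = further_growth(sp_ce, ce) or further_growth(sp_ne, ne) or further_new
        if confirmed:
            assessments.append(ScanAssessment(s.scan_day, Label.PD, ce, ne,
                                              baseline_vol, nadir, trigger))
            assessments.append(ScanAssessment(sp.scan_day, Label.PD, sp_ce, sp_ne,
                                              baseline_vol, nadir, Trigger.CONFIRMATION))
            call = ProgressionCall(t.patient_id, cfg.criterion, True,
                                   progression_day=s.scan_day,
                                   reason=CallReason.IMAGING_PD,
                                   confirmed_day=sp.scan_day)
            break

        # refuted: the suspicion scan becomes pseudoprogression; measurable
        # lesions present at the resolving scan are absorbed into the
        # reference set (sub-measurable ones still count as new once they
        # reach measurability) and the nadirs restart there — the transient
        # peak is never a reference.
        assessments.append(ScanAssessment(s.scan_day, Label.PSP, ce, ne,
                                          baseline_vol, nadir, Trigger.RETRO_PSP))
        accepted |= {(l.compartment.value, l.lesion_id) for l in sp.lesions
                     if l.volume_cm3 >= cfg.measurable_min_cm3}
        nadir = sp_ce
        ne_nadir = sp_ne
        raw_sp, _ = _raw_label(sp_ce, sp_ne, False, baseline_vol, nadir, ne_nadir, cfg)
        assessments.append(ScanAssessment(sp.scan_day, Label(raw_sp.value), sp_ce, sp_ne,
                                          baseline_vol, nadir))
        i += 2

    if call is None:
        if assessments:
            call = ProgressionCall(t.patient_id, cfg.criterion, False,
                                   censor_day=assessments[-1].scan_day,
                                   reason=CallReason.CENSORED_SD_LAST_SCAN)
        else:
            call = ProgressionCall(t.patient_id, cfg.criterion, False,
                                   censor_day=baseline.scan_day,
                                   reason=CallReason.CENSORED_LOST)
    call = apply_nonimaging_events(call, t)
    return AssessmentTrack(t.patient_id, cfg.criterion, baseline.scan_day,
                           tuple(assessments), call, tuple(diagnostics))


def apply_nonimaging_events(call: ProgressionCall, t: PatientTimeline) -> ProgressionCall:
    """Override a call with re-resection / bevacizumab progression dating.

    If such an event happened and imaging had not declared PD on or before
    the event day, the last MRI strictly before the event becomes the
    progression date.  Earlier imaging PD is never overridden.
    """
    events = []
    if t.reresection_day is not None:
        events.append((t.reresection_day, CallReason.RERESECTION))
    if t.bevacizumab_start_day is not None:
        events.append((t.bevacizumab_start_day, CallReason.BEVACIZUMAB))
    for event_day, reason in sorted(events):
        if call.progressed and call.progression_day <= event_day:
            continue
        prior = [s.scan_day for s in t.scans if s.scan_day < event_day]
        if not prior:
            raise ValueError(
                f"patient {t.patient_id}: {reason.value} at day {event_day} precedes all scans")
        call = ProgressionCall(call.patient_id, call.criterion, True,
                               progression_day=max(prior), reason=reason)
    return call


# ---------------------------------------------------------------------------
# pseudoprogression summary

@dataclass(frozen=True)
class PsPSummary:
    count: int
    n_cohort: int
    rate: float
    weeks_from_rt: tuple[float, ...]
    median_weeks: Optional[float]
    within_12_weeks: int


def detect_psp_events(tracks: Iterable[AssessmentTrack],
                      rt_end_days: Mapping[str, int]) -> PsPSummary:
    """Summarize pseudoprogression over confirmation-bearing tracks.

    A patient counts once if any of their scans carries the PsP label in any
    supplied track (e.g. mRANO and RANO 2.0 tracks together).  PsP timing is
    measured in weeks from the end of radiotherapy to the first PsP scan.
    """
    first_psp: dict[str, int] = {}
    cohort: set[str] = set()
    for tr in tracks:
        cohort.add(tr.patient_id)
        for a in tr.assessments:
            if a.label is Label.PSP:
                prev = first_psp.get(tr.patient_id)
                if prev is None or a.scan_day < prev:
                    first_psp[tr.patient_id] = a.scan_day
                break
    weeks = tuple(sorted((day - rt_end_days[pid]) / 7.0
                         for pid, day in first_psp.items()))
    n = len(cohort)
    return PsPSummary(
        count=len(first_psp),
        n_cohort=n,
        rate=len(first_psp) / n if n else 0.0,
        weeks_from_rt=weeks,
        median_weeks=float(median(weeks)) if weeks else None,
        within_12_weeks=sum(1 for w in weeks if w <= 12.0),
    )
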