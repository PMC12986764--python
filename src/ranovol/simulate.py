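"""Synthetic glioblastoma cohort generator.

Emulates the longitudinal structure the analysis assumes: a preoperative MRI
at day 0, surgery 1-14 days later, a post-operative baseline scan 1-2 days
after surgery, chemoradiation starting a median of 38 days after surgery and
lasting six weeks, a post-radiotherapy baseline scan 21-35 days after the
end of radiotherapy, and roughly 3-monthly follow-up MRIs until death or
loss to follow-up.

Disease dynamics are deliberately minimal — the simplest mechanisms that
exercise every branch of the response classifiers:

* contrast-enhancing (CE) recurrence is an exponentially growing lesion
  that crosses the 1 cm^3 measurability floor exactly at the latent
  progression time (log-normal); it is visible sub-measurably a little
  earlier, so depending on timing it may or may not already sit in the
  post-radiotherapy baseline.  A residual CE lesion (partial resections
  only, ~12% of patients) regrows with it;
* a stable treatment-related enhancement ("scar") appears at the
  post-radiotherapy baseline scan in a fraction of patients and persists.
  It inflates the post-RT baseline/nadir of the post-RT-referenced criteria
  (diluting their relative-increase threshold) while the post-operative
  baseline criterion sees it as a new lesion episode that fails
  confirmation — the classic source of divergence between baselines;
* pseudoprogression (PsP) is a single-scan transient CE lesion appearing at
  a log-normal time after radiotherapy (median 19.1 weeks) in ~17.5% of
  patients and resolving at the next scan;
* nonenhancing (NE) T2/FLAIR abnormality is a stable background volume that
  grows (more slowly) after true progression;
* death follows progression after an exponential post-progression survival
  whose scale is tuned so that cohort median OS is about 20.7 months;
  ~14% of patients are lost to follow-up (OS-censored) instead;
* optional re-resection / bevacizumab events occur after true progression.

For patients simulated with PsP, the latent progression time is pushed past
the PsP-resolving scan, so the realized PsP frequency stays an unbiased
Bernoulli draw and PsP patients live slightly longer — consistent with
observed cohorts.  A single root seed spawns one independent random stream
per patient, so cohorts are reproducible and patients independent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .timelines import (
    Compartment,
    DAYS_PER_MONTH,
    LesionMeasurement,
    PatientTimeline,
    ScanRecord,
    ScanRole,
)

LN2 = math.log(2.0)


def _lognormal(rng: np.random.Generator, median: float, sigma: float) -> float:
    return float(rng.lognormal(mean=math.log(median), sigma=sigma))


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort-level simulation parameters.

    Defaults encode the study conditions of a standard-of-care glioblastoma
    cohort: n=137, 87.6% gross total resection, median 38 days from surgery
    to radiotherapy, 42-day radiotherapy course, ~3-monthly follow-up,
    17.5% pseudoprogression at a median of 19.1 weeks after radiotherapy,
    ~14% lost to follow-up, and post-progression survival tuned for a median
    OS near 20.7 months.
    """

    n_patients: int = 137
    seed: int = 0
    #: fraction with gross total resection (no residual CE tumor post-op)
    frac_gtr: float = 0.876
    surgery_window_days: tuple[int, int] = (1, 14)
    surgery_to_rt_median_days: float = 38.0
    surgery_to_rt_sigma: float = 0.233          # matches IQR 12 at median 38
    rt_duration_days: int = 42
    postrt_window_days: tuple[int, int] = (21, 35)
    followup_interval_median_days: float = 91.0
    followup_interval_sigma: float = 0.18
    #: residual CE volume after partial resection, cm^3 (log-normal)
    postop_residual_median_cm3: float = 3.0
    postop_residual_sigma: float = 0.5
    #: CE volume doubling time of recurrent tumor, months (log-normal)
    doubling_time_median_months: float = 1.5
    doubling_time_sigma: float = 0.3
    #: recurrence volume at the latent progression day (the measurability
    #: floor: progression is "true" once the lesion is measurable)
    recurrence_at_progression_cm3: float = 1.0
    #: smallest volume recorded as visible on a scan, cm^3
    visible_min_cm3: float = 0.05
    #: probability of a stable treatment-related enhancement appearing at
    #: the post-RT baseline scan, and its volume (log-normal)
    scar_prob: float = 0.45
    scar_median_cm3: float = 5.0
    scar_sigma: float = 0.35
    #: latent time from diagnosis to true progression, months (log-normal)
    progression_median_months: float = 8.0
    progression_sigma: float = 0.75
    psp_prob: float = 0.175
    psp_onset_median_weeks: float = 19.1
    psp_onset_sigma: float = 0.30
    #: transient PsP lesion volume range, cm^3 (>=40% above any nadir)
    psp_bump_range_cm3: tuple[float, float] = (1.2, 2.5)
    #: exponential post-progression survival, median months (tuned for
    #: cohort median OS ~ 20.7 months)
    post_progression_median_months: float = 10.0
    #: couples post-progression hazard to progression speed: a patient whose
    #: latent progression time is half the cohort median has a
    #: 2**coupling-fold higher post-progression hazard (tumor
    #: aggressiveness drives both)
    aggressiveness_coupling: float = 1.0
    frac_lost_followup: float = 19.0 / 137.0
    reresection_prob: float = 0.10
    bevacizumab_prob: float = 0.12
    ne_background_median_cm3: float = 6.0
    ne_background_sigma: float = 0.4
    #: NE growth rate as a fraction of the CE growth rate after progression
    ne_growth_fraction: float = 0.5
    #: multiplicative log-normal measurement noise (coefficient of variation)
    noise_cv: float = 0.05
    max_lesion_cm3: float = 250.0

    def __post_init__(self) -> None:
        for name in ("frac_gtr", "psp_prob", "frac_lost_followup",
                     "reresection_prob", "bevacizumab_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        for name in ("surgery_to_rt_median_days", "followup_interval_median_days",
                     "doubling_time_median_months", "progression_median_months",
                     "post_progression_median_months", "psp_onset_median_weeks"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


GROUND_TRUTH_COLUMNS = ["patient_id", "true_progression_day", "psp", "psp_scan_day",
                        "gtr", "lost_to_followup", "death_day"]


def simulate_patient(cfg: SimulationConfig, rng: np.random.Generator,
                     patient_id: str) -> tuple[PatientTimeline, dict]:
    """Simulate one patient; returns the timeline and its ground truth."""
    surgery = int(rng.integers(cfg.surgery_window_days[0], cfg.surgery_window_days[1] + 1))
    postop_day = surgery + int(rng.integers(1, 3))
    rt_start = surgery + max(7, round(_lognormal(rng, cfg.surgery_to_rt_median_days,
                                                 cfg.surgery_to_rt_sigma)))
    rt_end = rt_start + cfg.rt_duration_days
    postrt_day = rt_end + int(rng.integers(cfg.postrt_window_days[0],
                                           cfg.postrt_window_days[1] + 1))
    # pre-draw the follow-up schedule (independent of survival, truncated later)
    followups: list[int] = []
    day = postrt_day
    for _ in range(60):
        day += max(14, round(_lognormal(rng, cfg.followup_interval_median_days,
                                        cfg.followup_interval_sigma)))
        followups.append(day)

    gtr = bool(rng.random() < cfg.frac_gtr)
    residual = 0.0 if gtr else _lognormal(rng, cfg.postop_residual_median_cm3,
                                          cfg.postop_residual_sigma)
    doubling_days = _lognormal(rng, cfg.doubling_time_median_months,
                               cfg.doubling_time_sigma) * DAYS_PER_MONTH
    scar = _lognormal(rng, cfg.scar_median_cm3, cfg.scar_sigma) \
        if rng.random() < cfg.scar_prob else 0.0
    t_raw_months = _lognormal(rng, cfg.progression_median_months, cfg.progression_sigma)
    t_prog = max(round(t_raw_months * DAYS_PER_MONTH), rt_end + 10)

    psp = bool(rng.random() < cfg.psp_prob)
    psp_onset_day = rt_end + round(_lognormal(rng, cfg.psp_onset_median_weeks,
                                              cfg.psp_onset_sigma) * 7)
    psp_bump = float(rng.uniform(*cfg.psp_bump_range_cm3))
    psp_scan_day: Optional[int] = None
    if psp:
        later = [d for d in followups if d >= psp_onset_day]
        psp_scan_day = later[0] if later else followups[-1]
        resolve_idx = followups.index(psp_scan_day) + 1
        resolve_day = followups[resolve_idx] if resolve_idx < len(followups) else psp_scan_day + 91
        # true progression waits until the PsP episode has resolved
        t_prog = max(t_prog, resolve_day + 30)

    pps_median = cfg.post_progression_median_months * (
        t_raw_months / cfg.progression_median_months) ** cfg.aggressiveness_coupling
    pps_days = rng.exponential(scale=pps_median * DAYS_PER_MONTH / LN2)
    death_day = t_prog + max(14, round(pps_days))
    death_day = max(death_day, postrt_day + 7)

    lost = bool(rng.random() < cfg.frac_lost_followup)
    if lost:
        lo = max(postrt_day + 1, round(0.35 * death_day))
        last_followup = int(rng.integers(lo, max(lo + 1, death_day)))
    else:
        last_followup = death_day

    reresection_day: Optional[int] = None
    bevacizumab_day: Optional[int] = None
    if rng.random() < cfg.reresection_prob:
        reresection_day = t_prog + int(rng.integers(30, 121))
    if rng.random() < cfg.bevacizumab_prob:
        bevacizumab_day = t_prog + int(rng.integers(45, 150))
    horizon = last_followup if lost else death_day
    if reresection_day is not None and reresection_day >= horizon:
        reresection_day = None
    if bevacizumab_day is not None and bevacizumab_day >= horizon:
        bevacizumab_day = None

    def noise() -> float:
        if cfg.noise_cv <= 0:
            return 1.0
        return float(rng.lognormal(mean=0.0, sigma=cfg.noise_cv))

    ne_background = _lognormal(rng, cfg.ne_background_median_cm3, cfg.ne_background_sigma)

    def recurrence_volume(day: int) -> float:
        # crosses the measurability floor exactly at the latent progression day
        return cfg.recurrence_at_progression_cm3 * 2.0 ** ((day - t_prog) / doubling_days)

    recurrence_seen = False

    def lesions_at(day: int) -> tuple[LesionMeasurement, ...]:
        nonlocal recurrence_seen
        days_since_prog = max(0, day - t_prog)
        regrowth = 2.0 ** (days_since_prog / doubling_days)
        out: list[LesionMeasurement] = []
        if residual > 0:
            v = residual * regrowth * noise()
            out.append(LesionMeasurement("ce-residual", Compartment.CE,
                                         min(v, cfg.max_lesion_cm3)))
        if scar > 0 and day >= postrt_day:
            out.append(LesionMeasurement("ce-scar", Compartment.CE,
                                         scar * noise(), is_new=(day == postrt_day)))
        rec = recurrence_volume(day) * noise()
        if rec >= cfg.visible_min_cm3:
            out.append(LesionMeasurement("ce-recurrence", Compartment.CE,
                                         min(rec, cfg.max_lesion_cm3),
                                         is_new=not recurrence_seen))
            recurrence_seen = True
        if psp and day == psp_scan_day and day < t_prog:
            out.append(LesionMeasurement("ce-psp", Compartment.CE, psp_bump, is_new=True))
        ne_v = ne_background * (regrowth ** cfg.ne_growth_fraction) * noise()
        out.append(LesionMeasurement("ne-background", Compartment.NE,
                                     min(ne_v, cfg.max_lesion_cm3)))
        return tuple(out)

    scan_days = [postop_day, postrt_day] + [d for d in followups
                                            if d <= last_followup and d < death_day]
    scan_days = [d for d in scan_days if d <= last_followup]
    roles = {postop_day: ScanRole.POSTOP_BASELINE, postrt_day: ScanRole.POSTRT_BASELINE}
    scans = [ScanRecord(scan_day=d, lesions=lesions_at(d),
                        role_hint=roles.get(d, ScanRole.FOLLOWUP))
             for d in scan_days]

    timeline = PatientTimeline(
        patient_id=patient_id,
        surgery_day=surgery,
        rt_start_day=rt_start,
        rt_end_day=rt_end,
        scans=tuple(scans),
        last_followup_day=last_followup,
        alive_at_last_followup=lost,
        reresection_day=reresection_day,
        bevacizumab_start_day=bevacizumab_day,
        death_day=None if lost else death_day,
    )
    truth = {
        "patient_id": patient_id,
        "true_progression_day": t_prog,
        "psp": psp,
        "psp_scan_day": psp_scan_day if psp else None,
        "gtr": gtr,
        "lost_to_followup": lost,
        "death_day": death_day,
    }
    return timeline, truth


def simulate_cohort(cfg: SimulationConfig) -> tuple[list[PatientTimeline], pd.DataFrame]:
    """Simulate ``cfg.n_patients`` independent patients.

    Returns the timelines plus a ground-truth table (latent progression day,
    PsP flag, resection extent, censoring) for parameter-recovery tests.
    Reproducible: one root seed spawns a child stream per patient.
    """
    root = np.random.SeedSequence(cfg.seed)
    children = root.spawn(cfg.n_patients)
    timelines: list[PatientTimeline] = []
    truths: list[dict] = []
    width = max(4, len(str(cfg.n_patients)))
    for i, child in enumerate(children):
        pid = f"GB-{i + 1:0{width}d}"
        t, truth = simulate_patient(cfg, np.random.default_rng(child), pid)
        timelines.append(t)
        truths.append(truth)
    truth_df = pd.DataFrame(truths, columns=GROUND_TRUTH_COLUMNS)
    return timelines, truth_df
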