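"""End-to-end orchestration: read -> classify -> endpoints -> statistics -> report.

`run_all` executes the whole comparison on a cohort CSV pair and writes
`assessments.csv`, `calls.csv`, `endpoints.csv`, `stats_report.json`,
`report.md` and a run manifest with content checksums.  Outputs are only
written after every stage has succeeded, so a failure never leaves partial
results behind.  All stages are deterministic given the inputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import asdict, dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from . import __version__
from .criteria import (
    AssessmentTrack,
    BaselineMissingError,
    CriteriaConfig,
    Criterion,
    detect_psp_events,
)
from .criteria import run_criteria as _run_criteria
from .endpoints import cohort_endpoint_table, median_iqr
from .stats import (
    DegenerateStratificationError,
    dunn_bonferroni,
    kruskal_wallis,
    landmark_analysis,
    spearman_pfs_os,
)
from .timelines import DAYS_PER_MONTH, PatientTimeline, read_cohort

log = logging.getLogger("ranovol")

REPORT_SCHEMA_VERSION = 1
ALL_CRITERIA = (Criterion.RANO, Criterion.MRANO, Criterion.RANO2)
#: criteria whose confirmation logic can label pseudoprogression
PSP_CRITERIA = (Criterion.MRANO, Criterion.RANO2)


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {cause}")


@dataclass(frozen=True)
class RunManifest:
    tool_version: str
    inputs: dict
    criteria: tuple[str, ...]
    landmarks: tuple[float, ...]
    n_patients_read: int
    n_patients_analyzed: int
    stage_rows: dict
    outputs: dict          # filename -> sha256
    started_at: str


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _jsonable(obj):
    """Replace NaN with None and +/-inf with string markers for strict JSON."""
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, float):
        if math.isnan(obj):
            return None
        if math.isinf(obj):
            return "inf" if obj > 0 else "-inf"
    return obj


def classify_cohort(timelines: Sequence[PatientTimeline],
                    criteria: Sequence[Criterion] = ALL_CRITERIA,
                    overrides: Optional[Mapping[str, object]] = None,
                    ) -> tuple[dict[Criterion, dict[str, AssessmentTrack]], list[str]]:
    """Run every requested criterion on every patient.

    Patients lacking a baseline for *any* requested criterion are excluded
    from all of them (mirroring paired inclusion criteria), and listed in
    the returned exclusion list.
    """
    overrides = dict(overrides or {})
    configs = {c: CriteriaConfig.preset(c, **overrides) for c in criteria}
    tracks: dict[Criterion, dict[str, AssessmentTrack]] = {c: {} for c in criteria}
    excluded: list[str] = []
    for t in timelines:
        per_patient = {}
        try:
            for c in criteria:
                per_patient[c] = _run_criteria(t, configs[c])
        except BaselineMissingError as exc:
            log.info("excluding %s: %s", t.patient_id, exc)
            excluded.append(t.patient_id)
            continue
        for c, tr in per_patient.items():
            tracks[c][t.patient_id] = tr
    return tracks, excluded


def _assessments_frame(tracks: dict[Criterion, dict[str, AssessmentTrack]]) -> pd.DataFrame:
    rows = []
    for crit in sorted(tracks, key=lambda c: c.value):
        for pid in sorted(tracks[crit]):
            tr = tracks[crit][pid]
            for a in tr.assessments:
                rows.append({
                    "patient_id": pid, "criterion": crit.value, "scan_day": a.scan_day,
                    "label": a.label.value, "ce_total": round(a.ce_total_cm3, 6),
                    "ne_total": round(a.ne_total_cm3, 6),
                    "baseline": round(a.reference_baseline_cm3, 6),
                    "nadir": round(a.reference_nadir_cm3, 6),
                    "trigger": a.trigger.value,
                })
    return pd.DataFrame(rows, columns=["patient_id", "criterion", "scan_day", "label",
                                       "ce_total", "ne_total", "baseline", "nadir",
                                       "trigger"])


def _calls_frame(tracks: dict[Criterion, dict[str, AssessmentTrack]]) -> pd.DataFrame:
    rows = []
    for crit in sorted(tracks, key=lambda c: c.value):
        for pid in sorted(tracks[crit]):
            c = tracks[crit][pid].call
            rows.append({
                "patient_id": pid, "criterion": crit.value, "progressed": int(c.progressed),
                "progression_day": c.progression_day if c.progression_day is not None else "",
                "censor_day": c.censor_day if c.censor_day is not None else "",
                "reason": c.reason.value,
                "confirmed_day": c.confirmed_day if c.confirmed_day is not None else "",
            })
    return pd.DataFrame(rows, columns=["patient_id", "criterion", "progressed",
                                       "progression_day", "censor_day", "reason",
                                       "confirmed_day"])


def compute_stats_report(timelines: Sequence[PatientTimeline],
                         tracks: dict[Criterion, dict[str, AssessmentTrack]],
                         endpoints: pd.DataFrame,
                         landmarks: Sequence[float] = (8.0, 12.0)) -> dict:
    """Assemble the full statistics report as a JSON-serializable dict."""
    criteria = sorted(tracks, key=lambda c: c.value)
    report: dict = {"schema_version": REPORT_SCHEMA_VERSION,
                    "criteria": [c.value for c in criteria],
                    "landmarks_months": list(map(float, landmarks))}

    summaries: dict = {}
    pfs_groups, pps_groups, labels = [], [], []
    for crit in criteria:
        rows = endpoints[endpoints["criterion"] == crit.value]
        ev = rows[rows["pfs_event"].astype(bool)]
        pfs_med, pfs_iqr = median_iqr(ev["pfs_months"].to_numpy())
        pps_vals = ev[ev["pps_event"].eq(True)]["pps_months"].to_numpy()
        pps_med, pps_iqr = median_iqr(pps_vals)
        summaries[crit.value] = {
            "n": int(len(rows)), "n_pfs_events": int(len(ev)),
            "median_pfs_months": pfs_med, "iqr_pfs_months": pfs_iqr,
            "median_pps_months": pps_med, "iqr_pps_months": pps_iqr,
            "n_pps_observed": int(len(pps_vals)),
        }
        pfs_groups.append(ev["pfs_months"].to_numpy())
        pps_groups.append(pps_vals)
        labels.append(crit.value)
    report["endpoint_summary"] = summaries

    any_crit = criteria[0].value
    os_rows = endpoints[endpoints["criterion"] == any_crit]
    os_obs = os_rows[os_rows["os_event"].astype(bool)]["os_months"].to_numpy()
    os_med, os_iqr = median_iqr(os_obs)
    report["os_summary"] = {"n": int(len(os_rows)), "n_events": int(len(os_obs)),
                            "median_os_months": os_med, "iqr_os_months": os_iqr}

    corr = {}
    for crit in criteria:
        rows = endpoints[endpoints["criterion"] == crit.value]
        try:
            r = spearman_pfs_os(rows["pfs_months"].to_numpy(),
                                rows["os_months"].to_numpy(), criterion=crit.value)
            corr[crit.value] = {"rho": r.rho, "p_value": r.p_value, "n": r.n}
        except ValueError as exc:       # tiny or degenerate cohorts
            corr[crit.value] = {"error": str(exc), "n": int(len(rows))}
    report["pfs_os_correlation"] = corr

    def group_block(groups):
        kw = kruskal_wallis(groups)
        pairs = dunn_bonferroni(groups, labels)
        return {"kruskal_h": kw.statistic, "kruskal_p": kw.p_value,
                "pairwise": [{"pair": list(p.pair), "z": p.z,
                              "p_adjusted": p.p_adjusted} for p in pairs]}

    if len(criteria) >= 2 and all(len(g) for g in pfs_groups):
        report["pfs_between_criteria"] = group_block(pfs_groups)
    if len(criteria) >= 2 and all(len(g) for g in pps_groups):
        report["pps_between_criteria"] = group_block(pps_groups)

    lm_rows = []
    for lm in landmarks:
        for crit in criteria:
            try:
                res = landmark_analysis(endpoints, lm, crit.value)
                d = asdict(res)
            except DegenerateStratificationError as exc:
                d = {"landmark_months": float(lm), "criterion": crit.value,
                     "error": str(exc)}
            lm_rows.append(d)
    report["landmark_analysis"] = lm_rows

    psp_tracks = [tr for c in PSP_CRITERIA if c in tracks for tr in tracks[c].values()]
    if psp_tracks:
        rt_end = {t.patient_id: t.rt_end_day for t in timelines}
        s = detect_psp_events(psp_tracks, rt_end)
        report["pseudoprogression"] = {
            "count": s.count, "n_cohort": s.n_cohort, "rate": s.rate,
            "median_weeks_from_rt": s.median_weeks,
            "within_12_weeks": s.within_12_weeks,
        }
    return report


def _fmt(x, nd=2) -> str:
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return "NA"
    if isinstance(x, float) and math.isinf(x):
        return "inf"
    return f"{x:.{nd}f}" if isinstance(x, float) else str(x)


def _fmt_p(p) -> str:
    if p is None or (isinstance(p, float) and math.isnan(p)):
        return "NA"
    return "<.001" if p < 0.001 else f"{p:.3f}"


def render_report(report: dict) -> str:
    """Render the statistics report as deterministic markdown.

    Nothing is recomputed: the renderer only formats numbers already in the
    report, so re-rendering cannot drift from the stored statistics.
    """
    if report.get("schema_version") != REPORT_SCHEMA_VERSION:
        raise ValueError(f"unsupported stats report schema: {report.get('schema_version')!r}")
    criteria = report.get("criteria", [])
    if not criteria:
        raise ValueError("report contains no criteria")
    lines = ["# Volumetric response-criteria comparison", ""]

    lines += ["## Endpoint summary (observed events)", "",
              "| Criterion | n | PFS events | Median PFS (mo) | IQR | Median PPS (mo) | IQR |",
              "|---|---|---|---|---|---|---|"]
    for c in criteria:
        s = report["endpoint_summary"][c]
        lines.append(f"| {c} | {s['n']} | {s['n_pfs_events']} | "
                     f"{_fmt(s['median_pfs_months'])} | {_fmt(s['iqr_pfs_months'])} | "
                     f"{_fmt(s['median_pps_months'])} | {_fmt(s['iqr_pps_months'])} |")
    osr = report["os_summary"]
    lines += ["", f"Median OS: {_fmt(osr['median_os_months'])} months "
                  f"(IQR {_fmt(osr['iqr_os_months'])}; {osr['n_events']}/{osr['n']} deaths).", ""]

    lines += ["## PFS-OS correlation (Spearman)", "",
              "| Criterion | rho | p | n |", "|---|---|---|---|"]
    for c in criteria:
        r = report["pfs_os_correlation"][c]
        if "error" in r:
            lines.append(f"| {c} | undefined | - | {r['n']} |")
        else:
            lines.append(f"| {c} | {_fmt(r['rho'])} | {_fmt_p(r['p_value'])} | {r['n']} |")
    lines.append("")

    for key, title in (("pfs_between_criteria", "PFS between criteria"),
                       ("pps_between_criteria", "PPS between criteria")):
        if key in report:
            b = report[key]
            lines += [f"## {title}", "",
                      f"Kruskal-Wallis H = {_fmt(b['kruskal_h'])}, p = {_fmt_p(b['kruskal_p'])}.",
                      ""]
            for pc in b["pairwise"]:
                lines.append(f"- {pc['pair'][0]} vs {pc['pair'][1]}: "
                             f"z = {_fmt(pc['z'])}, adjusted p = {_fmt_p(pc['p_adjusted'])}")
            lines.append("")

    lines += ["## Landmark analysis", "",
              "| Landmark (mo) | Criterion | SD n | SD median OS (IQR) | PD n | "
              "PD median OS (IQR) | rank p | HR (95% CI) | Cox p |",
              "|---|---|---|---|---|---|---|---|---|"]
    for row in report["landmark_analysis"]:
        if "error" in row:
            lines.append(f"| {_fmt(row['landmark_months'], 0)} | {row['criterion']} | "
                         f"- | - | - | - | - | undefined ({row['error']}) | - |")
            continue
        lines.append(
            f"| {_fmt(row['landmark_months'], 0)} | {row['criterion']} | {row['n_sd']} | "
            f"{_fmt(row['median_os_sd'])} ({_fmt(row['iqr_sd'])}) | {row['n_pd']} | "
            f"{_fmt(row['median_os_pd'])} ({_fmt(row['iqr_pd'])}) | {_fmt_p(row['rank_p'])} | "
            f"{_fmt(row['hr'])} ({_fmt(row['ci_low'])}-{_fmt(row['ci_high'])}) | "
            f"{_fmt_p(row['cox_p'])} |")
    lines.append("")

    if "pseudoprogression" in report:
        p = report["pseudoprogression"]
        lines += ["## Pseudoprogression", "",
                  f"{p['count']}/{p['n_cohort']} patients ({100 * p['rate']:.1f}%) with PsP; "
                  f"median onset {_fmt(p['median_weeks_from_rt'], 1)} weeks after "
                  f"radiotherapy; {p['within_12_weeks']} within 12 weeks.", ""]
    return "\n".join(lines)


def run_all(meta_path: str, scans_path: str, output_dir: str,
            criteria: Sequence[Criterion | str] = ALL_CRITERIA,
            landmarks: Sequence[float] = (8.0, 12.0),
            month_days: float = DAYS_PER_MONTH,
            overrides: Optional[Mapping[str, object]] = None) -> RunManifest:
    """Execute the full analysis and write all outputs to ``output_dir``."""
    criteria = tuple(Criterion(c) for c in criteria)
    if not criteria:
        raise ValueError("at least one criterion is required")
    out = Path(output_dir)
    started = datetime.now(timezone.utc).isoformat(timespec="seconds")

    try:
        timelines = read_cohort(meta_path, scans_path)
    except Exception as exc:
        raise PipelineStageError("read", exc) from exc
    log.info("read %d patients", len(timelines))

    try:
        tracks, excluded = classify_cohort(timelines, criteria, overrides)
        analyzed = [t for t in timelines if t.patient_id not in set(excluded)]
        assessments = _assessments_frame(tracks)
        calls_df = _calls_frame(tracks)
    except Exception as exc:
        raise PipelineStageError("classify", exc) from exc
    log.info("classified %d patients under %s (%d excluded)",
             len(analyzed), [c.value for c in criteria], len(excluded))

    try:
        all_calls = [tracks[c][t.patient_id].call for c in criteria for t in analyzed]
        endpoints = cohort_endpoint_table(analyzed, all_calls, month_days)
    except Exception as exc:
        raise PipelineStageError("endpoints", exc) from exc

    try:
        report = compute_stats_report(analyzed, tracks, endpoints, landmarks)
        rendered = render_report(report)
    except Exception as exc:
        raise PipelineStageError("stats", exc) from exc

    out.mkdir(parents=True, exist_ok=True)
    assessments.to_csv(out / "assessments.csv", index=False)
    calls_df.to_csv(out / "calls.csv", index=False)
    endpoints.to_csv(out / "endpoints.csv", index=False)
    (out / "stats_report.json").write_text(json.dumps(_jsonable(report), indent=2,
                                                      sort_keys=True) + "\n")
    (out / "report.md").write_text(rendered + "\n")

    outputs = {name: _sha256(out / name)
               for name in ("assessments.csv", "calls.csv", "endpoints.csv",
                            "stats_report.json", "report.md")}
    manifest = RunManifest(
        tool_version=__version__,
        inputs={"metadata": str(meta_path), "scans": str(scans_path),
                "metadata_sha256": _sha256(Path(meta_path)),
                "scans_sha256": _sha256(Path(scans_path))},
        criteria=tuple(c.value for c in criteria),
        landmarks=tuple(map(float, landmarks)),
        n_patients_read=len(timelines),
        n_patients_analyzed=len(analyzed),
        stage_rows={"assessments": int(len(assessments)), "calls": int(len(calls_df)),
                    "endpoints": int(len(endpoints)), "excluded": len(excluded)},
        outputs=outputs,
        started_at=started,
    )
    (out / "manifest.json").write_text(json.dumps(asdict(manifest), indent=2, sort_keys=True)
                                       + "\n")
    return manifest
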