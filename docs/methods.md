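# Methods

`ranovol` implements volumetric response assessment for newly diagnosed
glioblastoma under three criteria families — RANO, mRANO and RANO 2.0 — and
the comparative survival analysis that evaluates them: per-patient
PFS/PPS/OS derivation, Spearman PFS–OS correlation, Kruskal–Wallis with
Dunn/Bonferroni post-hoc tests, and fixed-landmark Cox models. A synthetic
cohort generator supplies longitudinal volume data with the structure the
classifiers assume, so the whole pipeline is testable without patient data.

## Response-criteria model

All three criteria share one volumetric rule set, applied to two
compartments measured in cm³: contrast-enhancing tumor (CE, post-gadolinium
T1) and nonenhancing T2/FLAIR abnormality (NE). Per scan, against a
baseline volume `B` and a nadir `N` (the smallest total observed from
baseline onward, updated only by scans that are not progression
suspicions):

* **PD suspicion** — CE total ≥ (1 + 0.40)·N with the total measurable
  (≥ 1 cm³), or NE total ≥ (1 + 1.00)·N_NE (a doubling), or a new
  measurable lesion (≥ 1 cm³ at a location not present at or before
  baseline). Precedence: PD > CR > PR > SD.
* **CR** — disappearance of CE target volume (total ≤ 0 cm³ by default).
* **PR** — CE total ≤ (1 − 0.65)·B, requiring B > 0.
* Sub-measurable new lesions do not trigger progression until they reach
  1 cm³.

The criteria differ in two configuration knobs (`CriteriaConfig`):

| | baseline scan | confirmation of suspected PD |
|---|---|---|
| RANO | post-operative MRI (24–48 h after surgery) | only within the 12-week post-RT guard |
| mRANO | post-RT MRI (21–35 d after radiotherapy) | always |
| RANO 2.0 | post-RT MRI (21–35 d after radiotherapy) | only within the 12-week guard |

A suspicion that requires confirmation is labelled preliminary PD (pPD).
The next scan confirms it — a further ≥ 40% increase of the same
compartment total (strict growth, measurable) or further new measurable
lesions — or refutes it, in which case the suspicion scan is retroactively
relabelled pseudoprogression (PsP). Confirmed PD is *back-dated* to the
scan of first suspicion; this convention is applied uniformly to the RANO
guard and to mRANO/RANO 2.0 confirmations, because the guard's dating rule
is explicit and internal consistency is preferable where the late-confirmation
dating is ambiguous.

Other deliberate choices, all configurable or documented here because the
design was genuinely open:

* **Nadir vs baseline references.** PD uses the nadir, PR/CR the baseline.
* **Confirmation window.** The ideal confirmation scan falls 4–8 weeks
  after suspicion; if routine cadence puts the next scan outside that
  window it is still used, with a warning diagnostic. Real-world
  three-monthly schedules would otherwise leave most suspicions
  unresolvable.
* **After a refuted suspicion** the nadirs restart at the resolving scan's
  totals, and measurable lesions present there are absorbed into the
  reference set (the transient peak never becomes a reference;
  sub-measurable lesions keep their new-lesion status).
* **Pending confirmation at end of follow-up** (death or loss before the
  confirming scan): the pPD is not converted to PD; the patient is censored
  at the last scan. This is the conservative reading.
* **Target lesions.** At most 5 CE lesions count toward the CE total; if a
  baseline has more, the 5 largest are retained as targets thereafter.
  Lesions appearing after baseline always contribute.
* **Guard arithmetic.** The guard spans 12 × 7 days from the last day of
  radiotherapy; PsP timing is reported in 7-day weeks.

Non-imaging progression events override censoring: if re-resection or
second-line bevacizumab occurred and imaging had not already dated PD at or
before that day, the last MRI strictly before the event becomes the
progression date. Earlier imaging PD is never overridden.

## Endpoints

PFS runs from the preoperative MRI (study day 0) to the dated progression
(event) or the censoring scan; OS from day 0 to death (event) or last
follow-up; PPS from progression to death/last follow-up, defined only when
progression was observed. Days convert to months at a fixed 30.4375 d/month
(Julian year / 12). Summaries are median + IQR with linear quartile
interpolation (the convention matters at small n). Between-criteria PFS/PPS
comparisons use observed events only; the PFS–OS correlation uses all
recorded times. Censoring handling in these rank tests is a reporting
choice, not an estimator: it is stated here because the field's published
analyses often leave it implicit.

## Survival statistics

Spearman (average ranks, t-approximation p), Kruskal–Wallis (tie-corrected
H, χ² p) and Mann–Whitney (two-sided normal approximation with tie and
continuity corrections) are delegated to scipy.stats. Dunn's post-hoc test
is implemented directly (z on mean ranks with tie correction; two-sided p ×
number of pairs, capped at 1) since no installed library provides it.

The landmark analysis at `L` ∈ {8, 12} months includes patients with OS
beyond `L` (death *or censoring* before the landmark excludes a patient —
slightly stricter than excluding deaths only, so the included set is fully
evaluable); status is PD if progression was dated ≤ `L`, with CR/PR/SD
pooled as the non-progressed stratum. Residual survival (OS − L) with the
patient's OS event enters a Cox model with the single binary covariate
PD-vs-SD. Group medians/IQRs are reported as total OS months among observed
deaths; the Mann–Whitney test runs on residual survival (rank tests are
shift-invariant, so the p-value is the same either way).

The Cox fit is a hand-written Newton–Raphson maximization of the partial
likelihood (the model has exactly one binary covariate, so a dependency-free
scalar fit is simpler and exactly testable): Efron tie handling by default,
Breslow available; convergence at |Δβ| < 1e-8 or 50 iterations; Wald 95% CI
on the log scale. Complete separation (all events in one group) is detected
up front — and divergence guarded at |β| > 30 — returning a flagged result
with an infinite-HR marker rather than a silently diverging estimate.
`lifelines` is used only as an independent cross-check in the test suite and
for Kaplan–Meier curve export.

Numerical notes: duplication of every data row leaves β exactly unchanged
under Breslow ties; under Efron the duplicated deaths are treated
sequentially within a tie, so β moves slightly (≈ 0.07 on a 6-patient
example). Relabelling the groups negates β exactly.

## Synthetic cohort generator

The generator emulates the longitudinal structure of a standard-of-care
glioblastoma cohort; defaults are the study conditions the analysis
targets:

| parameter | default | meaning |
|---|---|---|
| `n_patients` | 137 | cohort size |
| `frac_gtr` | 0.876 | gross total resection (no residual CE) |
| `surgery_to_rt_median_days` | 38 (log-normal, σ=0.233 ≈ IQR 12) | surgery → chemoradiation |
| `rt_duration_days` | 42 | radiotherapy course |
| `followup_interval_median_days` | 91 (log-normal, σ=0.18) | scan cadence |
| `progression_median_months` | 8.0 (log-normal, σ=0.75) | latent true progression from diagnosis |
| `doubling_time_median_months` | 1.5 (log-normal, σ=0.3) | CE doubling after progression |
| `psp_prob` | 0.175 | pseudoprogression frequency |
| `psp_onset_median_weeks` | 19.1 (log-normal, σ=0.30) | PsP onset after radiotherapy |
| `scar_prob` / `scar_median_cm3` | 0.45 / 5.0 | stable treatment-related enhancement at the post-RT baseline |
| `post_progression_median_months` | 10.0 | exponential PPS scale (see coupling) |
| `aggressiveness_coupling` | 1.0 | PPS hazard ∝ (median/latent progression time)^coupling |
| `frac_lost_followup` | 19/137 | OS-censored patients |
| `noise_cv` | 0.05 | multiplicative log-normal measurement noise |

Mechanisms, chosen as the simplest that exercise every classifier branch:

* **Recurrence** is a lesion crossing the 1 cm³ measurability floor exactly
  at the latent progression day, growing exponentially, visible
  sub-measurably from 0.05 cm³. Partial resections additionally regrow
  their residual lesion. Because the latent day is defined as the
  measurability crossing, "ground truth" is recoverable: the first scan at
  or after that day shows a new measurable lesion.
* **Scar** (stable treatment-related enhancement) appears at the post-RT
  baseline and persists. Post-RT-baseline criteria absorb it into their
  reference volumes, diluting the 40%-increase threshold for later true
  growth; the post-operative-baseline criterion instead sees a new-lesion
  episode that fails confirmation and later dates PD at the recurrence's
  measurability crossing. This asymmetry is what makes RANO date
  progression earlier than RANO 2.0, and it is the real clinical argument
  for the post-RT baseline.
* **PsP** is a single-scan transient CE lesion (1.2–2.5 cm³) at the first
  scan after its onset time, resolving at the next scan. Beyond the
  12-week guard, criteria without mandatory confirmation read it as PD;
  mRANO refutes it and progresses later — the mechanism behind the
  PFS divergence between mRANO and RANO 2.0 when PsP occurs late. For
  PsP-flagged patients the latent progression is deferred until after the
  resolving scan, so the realized PsP frequency stays an unbiased Bernoulli
  draw (and PsP patients live slightly longer, as observed cohorts do).
* **Survival.** Death follows progression after an exponential
  post-progression time whose patient-level scale is coupled to latent
  progression speed (`aggressiveness_coupling`): fast progressors die
  faster after progressing. Without this coupling, landmark hazard ratios
  are near 1 — progression status carries prognostic information only if
  tumor aggressiveness drives both clocks. The PPS scale is tuned so that
  cohort median OS is ≈ 20.7 months at large n.
* One root seed spawns an independent child stream per patient
  (`numpy.random.SeedSequence.spawn`), so cohorts are reproducible and
  patients independent.

What the generator does **not** emulate: imaging segmentation error beyond
i.i.d. multiplicative noise, NE-led progression preceding CE recurrence,
multifocal NE partitioning, corticosteroid or neurological confounding,
scanner/protocol drift, and non-exponential survival shapes. Passing tests
therefore demonstrate correctness of the assessment logic and statistics
under the stated structural assumptions — not clinical performance on real
MRI data.

The idealized "recovery" configuration used in tests switches off noise,
PsP, scar, partial resections, loss to follow-up and post-progression
events, isolating scan-cadence quantization as the only source of dating
error; under it every classifier dates progression to the first scan at or
after the latent day (with mRANO requiring one further scan to confirm).

## Problem sizes and determinism

The test suite exhaustively enumerates ~2×10⁴ quantized CE/new-lesion
trajectories (plus a 256-case NE grid) and checks the state machines
against a per-scan brute-force re-derivation; property checks run on
cohorts of 137–1000 synthetic patients. The acceptance script simulates a
137-patient cohort, round-trips it through the CSV schema and reruns the
full pipeline. All outputs are deterministic given the seed; rerunning
`run-all` on identical inputs reproduces byte-identical CSV/JSON outputs.

## Known limitations

* The PR/CR thresholds of the volumetric framework (65% decrease,
  disappearance) are defaults exposed in `CriteriaConfig`; published
  variants differ and no single supplement value is canonical.
* Confirmed-PD back-dating is a convention; dating to the confirming scan
  would lengthen mRANO/RANO 2.0 PFS by one scan interval.
* Scan-grid quantization delays detected PsP onset relative to its latent
  onset (median detected ≈ 28 weeks vs latent median 19.1 at 3-monthly
  cadence) — the same delayed-detection effect discussed for real
  retrospective cohorts.
* The landmark analysis excludes patients censored before the landmark,
  not only those who died; with near-complete follow-up the two rules
  coincide.
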