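"""Independent brute-force oracles used by the test suite.

Everything here re-derives results from first principles (explicit rank
arithmetic, naive per-scan rule evaluation, grid search) without reusing the
package's incremental state machines or scipy wrappers, so agreement is a
meaningful check.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np

from ranovol.criteria import (
    BaselineRule,
    ConfirmationRule,
    CriteriaConfig,
)
from ranovol.timelines import Compartment, PatientTimeline, ScanRecord

# ---------------------------------------------------------------------------
# rank-test oracles (hand computations)


def rank_with_ties(values):
    """Average ranks, 1-based."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def spearman_oracle(x, y):
    """Pearson correlation of average ranks + t-approximation p-value."""
    rx, ry = rank_with_ties(list(x)), rank_with_ties(list(y))
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry))
    rho = num / den
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * math.sqrt((n - 2) / (1 - rho ** 2))
    from scipy.stats import t as tdist
    return rho, 2 * tdist.sf(abs(t), n - 2)


def kruskal_oracle(groups):
    """Tie-corrected H statistic and chi-square p."""
    pooled = [v for g in groups for v in g]
    n = len(pooled)
    ranks = rank_with_ties(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start:start + len(g)]
        h += sum(r) ** 2 / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    # tie correction
    counts = {}
    for v in pooled:
        counts[v] = counts.get(v, 0) + 1
    tie = sum(c ** 3 - c for c in counts.values())
    denom = 1.0 - tie / (n ** 3 - n)
    if denom == 0:
        return 0.0, 1.0
    h /= denom
    from scipy.stats import chi2
    return h, chi2.sf(h, len(groups) - 1)


def dunn_oracle(groups):
    """Pairwise Dunn z and Bonferroni-adjusted p, recomputed from ranks."""
    pooled = [v for g in groups for v in g]
    n = len(pooled)
    ranks = rank_with_ties(pooled)
    mean_ranks, sizes = [], []
    start = 0
    for g in groups:
        mean_ranks.append(sum(ranks[start:start + len(g)]) / len(g))
        sizes.append(len(g))
        start += len(g)
    counts = {}
    for v in pooled:
        counts[v] = counts.get(v, 0) + 1
    tie = sum(c ** 3 - c for c in counts.values())
    var = n * (n + 1) / 12.0 - tie / (12.0 * (n - 1))
    from scipy.stats import norm
    k = len(groups)
    npairs = k * (k - 1) // 2
    out = {}
    for i, j in combinations(range(k), 2):
        se = math.sqrt(var * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se
        out[(i, j)] = (z, min(1.0, 2 * norm.sf(abs(z)) * npairs))
    return out


def mannwhitney_u_oracle(a, b):
    """U of the first sample by direct pair enumeration."""
    u = 0.0
    for x in a:
        for y in b:
            if x > y:
                u += 1.0
            elif x == y:
                u += 0.5
    return u


# ---------------------------------------------------------------------------
# Cox partial-likelihood oracle


def cox_loglik_oracle(beta, times, events, x, ties="efron"):
    """Naive Efron/Breslow partial log-likelihood (loops, no reuse)."""
    times = list(times)
    n = len(times)
    ll = 0.0
    for t in sorted({times[i] for i in range(n) if events[i]}):
        dead = [i for i in range(n) if events[i] and times[i] == t]
        risk = [i for i in range(n) if times[i] >= t]
        d = len(dead)
        s0r = sum(math.exp(beta * x[i]) for i in risk)
        s0d = sum(math.exp(beta * x[i]) for i in dead)
        ll += sum(beta * x[i] for i in dead)
        for l in range(d):
            frac = l / d if ties == "efron" else 0.0
            ll -= math.log(s0r - frac * s0d)
    return ll


def cox_grid_argmax(times, events, x, lo=-5.0, hi=5.0, num=20001, ties="efron"):
    betas = np.linspace(lo, hi, num)
    lls = [cox_loglik_oracle(b, times, events, x, ties) for b in betas]
    return float(betas[int(np.argmax(lls))])


# ---------------------------------------------------------------------------
# brute-force response-criteria oracle


def _vol(scan: ScanRecord, compartment: Compartment, excluded: set[str]) -> float:
    return sum(l.volume_cm3 for l in scan.lesions
               if l.compartment is compartment and l.lesion_id not in excluded)


def brute_force_track(t: PatientTimeline, cfg: CriteriaConfig):
    """Re-derive per-scan labels and the progression day from scratch.

    Recomputes every reference (baseline, nadir, known-lesion set) per scan
    by explicit enumeration over the history instead of incremental updates.
    Returns (labels, progression_day, confirmed_day); labels is a list of
    (scan_day, label string) for scans after baseline.  Non-imaging events
    are not applied.
    """
    if cfg.baseline_rule is BaselineRule.POSTOP:
        window = (t.surgery_day + 1, t.surgery_day + 2)
    else:
        window = (t.rt_end_day + 21, t.rt_end_day + 35)
    base_candidates = [s for s in t.scans if window[0] <= s.scan_day <= window[1]]
    assert base_candidates, "oracle requires a baseline scan"
    baseline = base_candidates[0]

    ce_base_sorted = sorted((l for l in baseline.lesions if l.compartment is Compartment.CE),
                            key=lambda l: -l.volume_cm3)
    excluded = {l.lesion_id for l in ce_base_sorted[5:]}

    known0 = set()
    for s in t.scans:
        if s.scan_day <= baseline.scan_day:
            known0.update((l.compartment.value, l.lesion_id) for l in s.lesions)

    post = [s for s in t.scans if s.scan_day > baseline.scan_day]
    guard_end = t.rt_end_day + round(cfg.early_pd_guard_weeks * 7)
    base_ce = _vol(baseline, Compartment.CE, excluded)
    base_ne = _vol(baseline, Compartment.NE, set())

    labels: list[tuple[int, str]] = []
    # nadir references recomputed per scan: totals of baseline plus every
    # prior post-baseline scan that ended up labelled CR/PR/SD
    plain_scans = [baseline]
    known = set(known0)

    def is_candidate(scan, nadir_ce, nadir_ne, known_now):
        new_meas = [l for l in scan.lesions
                    if (l.compartment.value, l.lesion_id) not in known_now
                    and l.volume_cm3 >= cfg.measurable_min_cm3]
        ce = _vol(scan, Compartment.CE, excluded)
        ne = _vol(scan, Compartment.NE, set())
        if new_meas:
            return True
        if ce >= (1 + cfg.pd_increase_frac) * nadir_ce and \
                ce >= cfg.measurable_min_cm3 and ce > nadir_ce:
            return True
        if ne >= (1 + cfg.ne_pd_increase_frac) * nadir_ne and \
                ne >= cfg.measurable_min_cm3 and ne > nadir_ne:
            return True
        return False

    def plain_label(scan):
        ce = _vol(scan, Compartment.CE, excluded)
        if ce <= cfg.cr_volume_cm3:
            return "CR"
        if base_ce > 0 and ce <= (1 - cfg.pr_decrease_frac) * base_ce:
            return "PR"
        return "SD"

    i = 0
    while i < len(post):
        s = post[i]
        nadir_ce = min(_vol(p, Compartment.CE, excluded) for p in plain_scans)
        nadir_ne = min(_vol(p, Compartment.NE, set()) for p in plain_scans)
        if not is_candidate(s, nadir_ce, nadir_ne, known):
            labels.append((s.scan_day, plain_label(s)))
            plain_scans.append(s)
            i += 1
            continue
        needs_conf = (cfg.confirmation_rule is ConfirmationRule.ALWAYS_REQUIRED
                      or s.scan_day <= guard_end)
        if not needs_conf:
            labels.append((s.scan_day, "PD"))
            return labels, s.scan_day, None
        if i + 1 >= len(post):
            labels.append((s.scan_day, "pPD"))
            return labels, None, None
        sp = post[i + 1]
        s_ce = _vol(s, Compartment.CE, excluded)
        s_ne = _vol(s, Compartment.NE, set())
        sp_ce = _vol(sp, Compartment.CE, excluded)
        sp_ne = _vol(sp, Compartment.NE, set())
        known_plus = known | {(l.compartment.value, l.lesion_id) for l in s.lesions}
        further_new = any((l.compartment.value, l.lesion_id) not in known_plus
                          and l.volume_cm3 >= cfg.measurable_min_cm3
                          for l in sp.lesions)
        grow = lambda now, ref: (now >= (1 + cfg.psp_extra_increase_frac) * ref
                                 and now > ref and now >= cfg.measurable_min_cm3)
        if grow(sp_ce, s_ce) or grow(sp_ne, s_ne) or further_new:
            labels.append((s.scan_day, "PD"))
            labels.append((sp.scan_day, "PD"))
            return labels, s.scan_day, sp.scan_day
        labels.append((s.scan_day, "PsP"))
        known |= {(l.compartment.value, l.lesion_id) for l in sp.lesions
                  if l.volume_cm3 >= cfg.measurable_min_cm3}
        # nadir restarts at the resolving scan
        plain_scans = [sp]
        labels.append((sp.scan_day, plain_label(sp)))
        i += 2
    return labels, None, None
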