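"""Comparative survival statistics for the criteria comparison.

Implements the statistical battery used to compare response criteria:
Spearman correlation between PFS and OS, Kruskal-Wallis with Dunn/Bonferroni
post-hoc tests for between-criteria differences, Mann-Whitney U for
two-group comparisons, and fixed-landmark analysis (8/12 months) with a
single-binary-covariate Cox proportional-hazards model on residual survival.

Rank tests go through scipy.stats; Dunn's post-hoc test and the Cox partial
likelihood (Newton-Raphson, Efron or Breslow tie handling) are implemented
here.  All tests are two-sided.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .endpoints import median_iqr


class DegenerateStratificationError(ValueError):
    """A landmark stratum is empty; the hazard ratio is undefined."""


@dataclass(frozen=True)
class CorrelationResult:
    criterion: str
    rho: float
    p_value: float
    n: int


@dataclass(frozen=True)
class PairwiseComparison:
    pair: tuple[str, str]
    z: float
    p_adjusted: float


@dataclass(frozen=True)
class GroupTestResult:
    statistic: float
    p_value: float
    pairwise: tuple[PairwiseComparison, ...] = ()


@dataclass(frozen=True)
class CoxResult:
    beta: float
    se: float
    hr: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int
    n_events: int
    ties: str = "efron"
    #: True when the partial likelihood is monotone (complete separation:
    #: all events in one group) and the HR diverges.
    monotone: bool = False


@dataclass(frozen=True)
class LandmarkResult:
    landmark_months: float
    criterion: str
    n_included: int
    n_sd: int
    n_pd: int
    median_os_sd: float
    iqr_sd: float
    median_os_pd: float
    iqr_pd: float
    rank_p: float
    hr: float
    ci_low: float
    ci_high: float
    cox_p: float
    monotone: bool = False


# ---------------------------------------------------------------------------
# rank statistics

def spearman_pfs_os(pfs: Sequence[float], os: Sequence[float],
                    criterion: str = "") -> CorrelationResult:
    """Spearman rank correlation (average ranks for ties, t-approximation p)."""
    pfs = np.asarray(pfs, dtype=float)
    os = np.asarray(os, dtype=float)
    if pfs.size != os.size or pfs.size < 3:
        raise ValueError("need paired samples with n >= 3")
    if np.all(pfs == pfs[0]) or np.all(os == os[0]):
        raise ValueError("correlation undefined for a constant vector")
    res = sps.spearmanr(pfs, os)
    return CorrelationResult(criterion, float(res.statistic), float(res.pvalue), int(pfs.size))


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> GroupTestResult:
    """Tie-corrected Kruskal-Wallis H with a chi-square p on k-1 df."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("each group must be nonempty")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        # all observations tied: H is 0 by convention, no evidence of any
        # location difference
        return GroupTestResult(statistic=0.0, p_value=1.0)
    h, p = sps.kruskal(*arrays)
    return GroupTestResult(statistic=float(h), p_value=float(p))


def dunn_bonferroni(groups: Sequence[Sequence[float]],
                    labels: Optional[Sequence[str]] = None) -> tuple[PairwiseComparison, ...]:
    """Dunn's post-hoc z tests on mean ranks, Bonferroni-adjusted.

    z_ij = (Rbar_i - Rbar_j) / sqrt( (N(N+1)/12 - T/(12(N-1))) (1/n_i + 1/n_j) )
    with T = sum over tie groups of (t^3 - t).  Two-sided normal p-values are
    multiplied by the number of pairs and capped at 1.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("each group must be nonempty")
    if labels is None:
        labels = [str(i) for i in range(len(arrays))]
    pooled = np.concatenate(arrays)
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    mean_ranks = []
    start = 0
    for a in arrays:
        mean_ranks.append(ranks[start:start + a.size].mean())
        start += a.size
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts ** 3 - counts))
    variance_scale = n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1))
    n_pairs = len(arrays) * (len(arrays) - 1) // 2
    out = []
    for i, j in combinations(range(len(arrays)), 2):
        denom = math.sqrt(variance_scale * (1.0 / arrays[i].size + 1.0 / arrays[j].size))
        z = (mean_ranks[i] - mean_ranks[j]) / denom if denom > 0 else 0.0
        p = 2.0 * sps.norm.sf(abs(z))
        out.append(PairwiseComparison((labels[i], labels[j]), float(z),
                                      float(min(1.0, p * n_pairs))))
    return tuple(out)


def mann_whitney(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U (normal approximation, tie + continuity
    correction); returns (U of the first sample, p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic",
                           use_continuity=True)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Cox proportional hazards, single binary covariate

def _cox_loglik_parts(beta: float, times: np.ndarray, events: np.ndarray,
                      x: np.ndarray, ties: str) -> tuple[float, float, float]:
    """(log-likelihood, gradient, hessian) of the partial likelihood."""
    theta = np.exp(beta * x)
    order = np.argsort(times, kind="stable")
    times, events, x, theta = times[order], events[order], x[order], theta[order]
    ll = grad = hess = 0.0
    event_times = np.unique(times[events])
    for t in event_times:
        at_risk = times >= t
        dead = (times == t) & events
        d = int(dead.sum())
        s0r = theta[at_risk].sum()
        s1r = (x[at_risk] * theta[at_risk]).sum()
        s2r = (x[at_risk] ** 2 * theta[at_risk]).sum()
        s0d = theta[dead].sum()
        s1d = (x[dead] * theta[dead]).sum()
        s2d = (x[dead] ** 2 * theta[dead]).sum()
        ll += beta * x[dead].sum()
        grad += x[dead].sum()
        for l in range(d):
            frac = l / d if ties == "efron" else 0.0
            den = s0r - frac * s0d
            num1 = s1r - frac * s1d
            num2 = s2r - frac * s2d
            ll -= math.log(den)
            grad_term = num1 / den
            hess += num2 / den - grad_term ** 2
            grad -= grad_term
    return ll, grad, -hess


def cox_binary(times: Sequence[float], events: Sequence[bool],
               group_flags: Sequence[int], ties: str = "efron") -> CoxResult:
    """Fit a Cox model with one binary covariate by Newton-Raphson.

    Maximizes the partial likelihood (Efron tie handling by default,
    Breslow available); converges when |delta beta| < 1e-8 or after 50
    iterations.  Complete separation (all events in one group) yields a
    flagged result with an infinite hazard-ratio marker instead of a
    silently diverging estimate.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError("ties must be 'efron' or 'breslow'")
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    x = np.asarray(group_flags, dtype=float)
    n = times.size
    n_events = int(events.sum())
    if n_events < 1:
        raise ValueError("need at least one event")
    if np.all(x == x[0]):
        raise ValueError("group flag is constant; beta is undefined")
    ex = x[events]
    if np.all(ex == 1.0) or np.all(ex == 0.0):
        sign = 1.0 if ex[0] == 1.0 else -1.0
        return CoxResult(beta=sign * math.inf, se=math.inf, hr=math.inf if sign > 0 else 0.0,
                         ci_low=math.nan, ci_high=math.nan, p_value=math.nan,
                         n=n, n_events=n_events, ties=ties, monotone=True)

    beta = 0.0
    for _ in range(50):
        _, grad, neg_info = _cox_loglik_parts(beta, times, events, x, ties)
        info = -neg_info
        if info <= 0:
            break
        delta = grad / info
        beta += delta
        if abs(beta) > 30:
            return CoxResult(beta=math.copysign(math.inf, beta), se=math.inf,
                             hr=math.inf if beta > 0 else 0.0,
                             ci_low=math.nan, ci_high=math.nan, p_value=math.nan,
                             n=n, n_events=n_events, ties=ties, monotone=True)
        if abs(delta) < 1e-8:
            break
    _, _, neg_info = _cox_loglik_parts(beta, times, events, x, ties)
    se = math.sqrt(1.0 / -neg_info)
    z = beta / se
    ci = 1.959963984540054 * se
    return CoxResult(beta=float(beta), se=float(se), hr=float(math.exp(beta)),
                     ci_low=float(math.exp(beta - ci)), ci_high=float(math.exp(beta + ci)),
                     p_value=float(2.0 * sps.norm.sf(abs(z))),
                     n=n, n_events=n_events, ties=ties)


# ---------------------------------------------------------------------------
# landmark analysis

def landmark_analysis(endpoint_rows: pd.DataFrame, landmark_months: float,
                      criterion: str, ties: str = "efron") -> LandmarkResult:
    """Fixed-landmark comparison of survival by progression status.

    Patients still alive and under observation beyond the landmark
    (``os_months > landmark``) are included; status is PD if progression was
    dated at or before the landmark, otherwise SD (CR/PR count as
    non-progressed).  Residual survival from the landmark carries each
    patient's OS event indicator into a binary-covariate Cox model; group
    medians/IQRs are total OS months among observed deaths, compared with a
    Mann-Whitney test on residual survival.
    """
    if landmark_months <= 0:
        raise ValueError("landmark_months must be positive")
    df = endpoint_rows[endpoint_rows["criterion"] == criterion]
    included = df[df["os_months"] > landmark_months]
    if included.empty:
        raise DegenerateStratificationError(f"no patients beyond {landmark_months} months")
    is_pd = included["pfs_event"].astype(bool) & (included["pfs_months"] <= landmark_months)
    pd_rows = included[is_pd]
    sd_rows = included[~is_pd]
    if pd_rows.empty or sd_rows.empty:
        raise DegenerateStratificationError(
            f"{criterion} at {landmark_months} months: a stratum is empty "
            f"(SD={len(sd_rows)}, PD={len(pd_rows)}); HR undefined")

    sd_obs = sd_rows[sd_rows["os_event"].astype(bool)]["os_months"].to_numpy()
    pd_obs = pd_rows[pd_rows["os_event"].astype(bool)]["os_months"].to_numpy()
    med_sd, iqr_sd = median_iqr(sd_obs)
    med_pd, iqr_pd = median_iqr(pd_obs)
    if sd_obs.size and pd_obs.size:
        _, rank_p = mann_whitney(sd_obs - landmark_months, pd_obs - landmark_months)
    else:
        rank_p = math.nan

    residual = included["os_months"].to_numpy() - landmark_months
    events = included["os_event"].to_numpy(dtype=bool)
    flags = is_pd.to_numpy(dtype=int)
    cox = cox_binary(residual, events, flags, ties=ties)
    return LandmarkResult(
        landmark_months=float(landmark_months), criterion=criterion,
        n_included=int(len(included)), n_sd=int(len(sd_rows)), n_pd=int(len(pd_rows)),
        median_os_sd=med_sd, iqr_sd=iqr_sd, median_os_pd=med_pd, iqr_pd=iqr_pd,
        rank_p=float(rank_p), hr=cox.hr, ci_low=cox.ci_low, ci_high=cox.ci_high,
        cox_p=cox.p_value, monotone=cox.monotone)


def km_curve(times: Sequence[float], events: Sequence[bool]) -> pd.DataFrame:
    """Kaplan-Meier survival curve (time, survival, at-risk) via lifelines."""
    from lifelines import KaplanMeierFitter

    km = KaplanMeierFitter()
    km.fit(np.asarray(times, dtype=float), np.asarray(events, dtype=bool))
    df = km.survival_function_.reset_index()
    df.columns = ["time", "survival"]
    at_risk = km.event_table["at_risk"].reindex(df["time"]).to_numpy()
    df["at_risk"] = at_risk
    return df
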