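"""Seizure-assay and behavior statistics.

Incidence is compared with Fisher's exact test (two-sided by the
sum-of-small-probabilities rule over all tables with the observed margins);
onset and survival are summarized as Kaplan–Meier curves and compared with
the log-rank test, with animals that never reach the endpoint censored at
the end of the 2-h observation window rather than excluded.  Severity uses
the ordinal 1–7 modified Racine scale (7 = death), summarized by
median/IQR and compared with a two-sample rank test.  The three-chamber
sociability readout is the discrimination index
DI(%) = (t_mouse − t_object)/(t_mouse + t_object) × 100.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "OBSERVATION_END_S",
    "FisherResult",
    "fisher_2x2",
    "km_curve",
    "logrank_test",
    "discrimination_index",
    "latency_shift_percent",
    "severity_summary",
    "SeveritySummary",
]

#: kainate-assay observation window (2 h); non-responders are censored here
OBSERVATION_END_S = 7200.0


@dataclass
class FisherResult:
    p: float
    odds_ratio: float  # sample odds ratio ad/bc (inf when bc = 0)


def fisher_2x2(a: int, b: int, c: int, d: int) -> FisherResult:
    """Two-sided Fisher exact test for a 2×2 table [[a, b], [c, d]].

    With both margins fixed, the two-sided p sums the hypergeometric
    probabilities of every table whose probability does not exceed the
    observed table's (the "sum of small p" rule, the common
    statistical-package default).  The sample odds ratio ad/bc is reported.
    """
    for v in (a, b, c, d):
        if int(v) != v or v < 0:
            raise ValueError("counts must be nonnegative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    N = a + b + c + d
    if N == 0:
        raise ValueError("all-zero table")
    r1, c1 = a + b, a + c
    support = np.arange(max(0, c1 - (N - r1)), min(r1, c1) + 1)
    pmf = stats.hypergeom.pmf(support, N, r1, c1)
    p_obs = float(stats.hypergeom.pmf(a, N, r1, c1))
    # relative tolerance absorbs floating-point ties (as in R's fisher.test)
    p = float(pmf[pmf <= p_obs * (1.0 + 1e-7)].sum())
    if b * c == 0:
        odds = np.inf if a * d > 0 else np.nan
    else:
        odds = a * d / (b * c)
    return FisherResult(p=min(p, 1.0), odds_ratio=float(odds))


def km_curve(times: Sequence[float], events: Sequence[bool]) -> pd.DataFrame:
    """Kaplan–Meier product-limit curve.

    Returns step coordinates with columns ``time``, ``survival`` (starting
    at (0, 1)) and ``cumulative_incidence`` = 1 − survival, the scale on
    which seizure-onset curves are plotted.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise ValueError("empty group")
    if (times < 0).any():
        raise ValueError("times must be nonnegative")
    from lifelines import KaplanMeierFitter

    km = KaplanMeierFitter()
    km.fit(times, event_observed=events)
    surv = km.survival_function_
    out = pd.DataFrame({"time": surv.index.to_numpy(dtype=float),
                        "survival": surv.iloc[:, 0].to_numpy()})
    out["cumulative_incidence"] = 1.0 - out["survival"]
    return out


def logrank_test(times_a, events_a, times_b, events_b) -> tuple[float, float]:
    """Log-rank comparison of two survival curves.

    Returns the chi-square statistic (1 df) and its p-value.  Requires at
    least one observed event overall.
    """
    ea, eb = np.asarray(events_a, bool), np.asarray(events_b, bool)
    if ea.sum() + eb.sum() == 0:
        raise ValueError("log-rank test needs at least one event")
    from lifelines.statistics import logrank_test as _lr

    res = _lr(times_a, times_b, event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value)


def discrimination_index(t_mouse, t_object):
    """Three-chamber discrimination index, in percent.

    DI = (t_mouse − t_object)/(t_mouse + t_object) × 100 ∈ [−100, 100];
    positive values mean preference for the novel mouse.  Accepts scalars
    or arrays; a trial with zero total investigation time is an error.
    """
    tm = np.asarray(t_mouse, dtype=float)
    to = np.asarray(t_object, dtype=float)
    if (tm < 0).any() or (to < 0).any():
        raise ValueError("investigation times must be nonnegative")
    total = tm + to
    if (total == 0).any():
        raise ValueError("t_mouse + t_object must be positive")
    di = (tm - to) / total * 100.0
    return float(di) if di.ndim == 0 else di


def latency_shift_percent(latencies_corr: Sequence[Sequence[float]],
                          latencies_dup: Sequence[Sequence[float]]) -> float:
    """Percent change in mean GTCS latency, corrected vs duplication, by trial.

    For each induction trial where both genotypes had a GTCS, the ratio of
    mean latencies (corr / dup) is computed; trials where either group has
    no event are excluded.  The summary is the mean ratio expressed as a
    percent change (+40 means the corrected genotype seized 40% later).
    """
    if len(latencies_corr) != len(latencies_dup):
        raise ValueError("per-trial lists must align")
    ratios = []
    for lc, ld in zip(latencies_corr, latencies_dup):
        lc, ld = np.asarray(lc, float), np.asarray(ld, float)
        if lc.size == 0 or ld.size == 0:
            continue
        md = ld.mean()
        if md == 0:
            raise ValueError("zero mean latency in duplication group")
        ratios.append(lc.mean() / md)
    if not ratios:
        raise ValueError("no trial with events in both genotypes")
    return (float(np.mean(ratios)) - 1.0) * 100.0


@dataclass
class SeveritySummary:
    table: pd.DataFrame  # group, n, median, iqr_low, iqr_high
    p: float | None  # rank-sum p, None when a group is too small
    test_skipped: bool


def severity_summary(table: pd.DataFrame, by: str = "genotype",
                     score_col: str = "racine_1h") -> SeveritySummary:
    """Median/IQR of ordinal severity scores per group plus a rank-sum test.

    The comparison is a two-sided exact Mann–Whitney test (delegated; only
    run for exactly two groups of ≥ 2 animals each — otherwise the
    summaries are returned with the test flagged as skipped).
    """
    groups = []
    for name, sub in table.groupby(by):
        s = sub[score_col].to_numpy()
        q1, med, q3 = np.percentile(s, [25, 50, 75])
        groups.append({"group": name, "n": len(s), "median": med,
                       "iqr_low": q1, "iqr_high": q3})
    summary = pd.DataFrame(groups)
    p = None
    skipped = True
    if len(groups) == 2 and all(g["n"] >= 2 for g in groups):
        a = table.loc[table[by] == groups[0]["group"], score_col]
        b = table.loc[table[by] == groups[1]["group"], score_col]
        p = float(stats.mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue)
        skipped = False
    return SeveritySummary(table=summary, p=p, test_skipped=skipped)
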