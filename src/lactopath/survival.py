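"""Kaplan–Meier estimation, log-rank testing and maximally selected cutpoints.

The continuous marker (e.g. a lactate score) is dichotomized at the cutpoint
that maximizes the two-group log-rank statistic, with the low-group
proportion restricted to a band (default [0.2, 0.8]). Because the cutpoint is
chosen to maximize the statistic, the naive chi-square p-value at the
selected cutpoint is anti-conservative; a permutation-adjusted p-value over
score-label permutations is available.

Survival tables are DataFrames with columns ``time`` (non-negative),
``event`` (0/1) and, for cutpoint analysis, ``score``. At tied times,
censored observations are treated as at risk for the events occurring at
that time (censorings after events, the standard convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats

__all__ = ["km_estimate", "logrank_test", "maxstat_cutpoint", "CutpointResult"]


def _check_records(df: pd.DataFrame, need_score: bool = False) -> pd.DataFrame:
    required = {"time", "event"} | ({"score"} if need_score else set())
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"survival table is missing columns: {sorted(missing)}")
    time = df["time"].to_numpy(dtype=float)
    event = df["event"].to_numpy()
    if len(df) == 0:
        raise ValueError("survival table is empty")
    if np.any(time < 0) or not np.all(np.isfinite(time)):
        raise ValueError("times must be finite and non-negative")
    if not np.isin(event, [0, 1]).all():
        raise ValueError("event indicator must be 0 or 1")
    return df


def km_estimate(records: pd.DataFrame) -> pd.DataFrame:
    """Product-limit (Kaplan–Meier) survival estimate.

    Returns a DataFrame indexed by time with columns ``survival`` (S(t),
    right-continuous, S(0)=1, nonincreasing), ``at_risk``, ``events`` and
    ``censored``.
    """
    _check_records(records)
    kmf = KaplanMeierFitter()
    kmf.fit(records["time"], records["event"])
    table = kmf.event_table
    surv = kmf.survival_function_["KM_estimate"].reindex(table.index)
    return pd.DataFrame(
        {
            "survival": surv.to_numpy(dtype=float),
            "at_risk": table["at_risk"].to_numpy(dtype=int),
            "events": table["observed"].to_numpy(dtype=int),
            "censored": table["censored"].to_numpy(dtype=int),
        },
        index=pd.Index(table.index, name="time"),
    )


def _logrank_chi2(
    time: np.ndarray, event: np.ndarray, in_group1: np.ndarray
) -> float:
    """Two-group log-rank chi-square from the O-E summation over event times.

    ``in_group1`` may be a boolean vector (one grouping) or a boolean matrix
    ``(n, n_groupings)``; a vector of statistics is returned in that case.
    """
    order = np.argsort(time, kind="stable")
    time = time[order]
    event = event[order].astype(bool)
    g1 = np.atleast_2d(in_group1.T).T[order]  # (n, k)

    # distinct event times
    event_times, first_idx = np.unique(time[event], return_index=True)
    n = len(time)
    k = g1.shape[1]
    # at-risk at t: suffix counts of subjects with time >= t
    # suffix sums over the time-sorted order
    g1f = g1.astype(float)
    suffix_g1 = np.vstack([np.cumsum(g1f[::-1], axis=0)[::-1], np.zeros((1, k))])
    o = np.zeros(k)
    e = np.zeros(k)
    v = np.zeros(k)
    for t in event_times:
        i0 = np.searchsorted(time, t, side="left")
        i1 = np.searchsorted(time, t, side="right")
        n_t = n - i0
        d_t = int(event[i0:i1].sum())
        n1_t = suffix_g1[i0]
        d1_t = (g1f[i0:i1] * event[i0:i1, None]).sum(axis=0)
        o += d1_t
        e += d_t * n1_t / n_t
        if n_t > 1:
            v += d_t * (n1_t / n_t) * (1 - n1_t / n_t) * (n_t - d_t) / (n_t - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(v > 0, (o - e) ** 2 / v, 0.0)
    return chi2 if k > 1 else float(chi2[0])


def logrank_test(group1: pd.DataFrame, group2: pd.DataFrame) -> tuple[float, float]:
    """Standard two-group log-rank test.

    Observed and expected event counts are accumulated over the distinct
    event times of the pooled sample; the statistic is chi-square with 1
    degree of freedom. Returns ``(chi_square, p_value)``.
    """
    _check_records(group1)
    _check_records(group2)
    time = np.concatenate([group1["time"], group2["time"]]).astype(float)
    event = np.concatenate([group1["event"], group2["event"]]).astype(int)
    if event.sum() == 0:
        raise ValueError("log-rank test requires at least one event")
    membership = np.zeros(len(time), dtype=bool)
    membership[: len(group1)] = True
    chi2 = _logrank_chi2(time, event, membership)
    return chi2, float(stats.chi2.sf(chi2, df=1))


@dataclass
class CutpointResult:
    """Outcome of a maximally selected log-rank cutpoint search."""

    cutpoint: float
    max_statistic: float  # log-rank chi-square at the cutpoint
    group_sizes: tuple[int, int]  # (n_low: score <= cutpoint, n_high)
    candidate_grid: np.ndarray
    p_value_naive: float
    p_value_permutation: float | None = None


def maxstat_cutpoint(
    records: pd.DataFrame,
    minprop: float = 0.2,
    maxprop: float = 0.8,
    n_permutations: int = 0,
    seed: int | None = None,
) -> CutpointResult:
    """Maximally selected log-rank cutpoint for a continuous score.

    Every distinct score value whose induced low-group ("score <= cutpoint")
    proportion lies in ``[minprop, maxprop]`` is a candidate; the cutpoint
    maximizing the log-rank chi-square is returned, ties broken toward the
    lower cutpoint. ``p_value_naive`` is the unadjusted chi-square tail at
    the maximum (anti-conservative by construction); with
    ``n_permutations > 0`` a permutation-adjusted p-value over score-label
    permutations is also computed.
    """
    _check_records(records, need_score=True)
    if not 0 < minprop <= maxprop < 1:
        raise ValueError("need 0 < minprop <= maxprop < 1")
    time = records["time"].to_numpy(dtype=float)
    event = records["event"].to_numpy(dtype=int)
    score = records["score"].to_numpy(dtype=float)
    n = len(score)
    if event.sum() == 0:
        raise ValueError("cutpoint search requires at least one event")

    uniq = np.unique(score)
    if uniq.size < 2:
        raise ValueError("all scores are tied; no cutpoint exists")
    # low-group proportion induced by each candidate cutpoint
    n_low = np.searchsorted(np.sort(score), uniq, side="right")
    prop = n_low / n
    admissible = (prop >= minprop) & (prop <= maxprop)
    candidates = uniq[admissible]
    if candidates.size == 0:
        raise ValueError(
            f"no cutpoint yields a low-group proportion in [{minprop}, {maxprop}]"
        )

    def max_stat(score_vec: np.ndarray) -> tuple[float, float]:
        membership = score_vec[:, None] <= candidates[None, :]
        chi2 = _logrank_chi2(time, event, membership)
        chi2 = np.atleast_1d(chi2)
        best = int(np.argmax(chi2))  # argmax returns first max -> lower cutpoint
        return float(candidates[best]), float(chi2[best])

    cut, stat = max_stat(score)

    p_perm = None
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        exceed = 0
        for _ in range(n_permutations):
            perm = rng.permutation(score)
            _, s = max_stat(perm)
            if s >= stat:
                exceed += 1
        p_perm = (1.0 + exceed) / (1.0 + n_permutations)

    n_lo = int(np.count_nonzero(score <= cut))
    return CutpointResult(
        cutpoint=cut,
        max_statistic=stat,
        group_sizes=(n_lo, n - n_lo),
        candidate_grid=candidates,
        p_value_naive=float(stats.chi2.sf(stat, df=1)),
        p_value_permutation=p_perm,
    )
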