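"""Independent brute-force reference implementations used by the tests.

Each function evaluates a statistic literally from its definition with
plain Python loops, deliberately sharing no code with the package.
"""

from __future__ import annotations

import numpy as np


def ssgsea_bruteforce(values: dict[str, float], in_set: set[str], alpha: float) -> float:
    """Literal running-sum single-sample enrichment for one sample.

    ``values`` maps gene -> expression. Rank statistic = ascending rank of
    the expression value (1 = lowest); genes walked in descending
    expression order (ties by insertion order).
    """
    genes = list(values)
    # ascending ranks with average ties
    sorted_vals = sorted(values.values())
    ranks = {}
    for g, v in values.items():
        positions = [i + 1 for i, sv in enumerate(sorted_vals) if sv == v]
        ranks[g] = sum(positions) / len(positions)
    order = sorted(genes, key=lambda g: (-values[g], genes.index(g)))
    w_total = sum(abs(ranks[g]) ** alpha for g in order if g in in_set)
    n_out = sum(1 for g in order if g not in in_set)
    score, cum_in, cum_out = 0.0, 0.0, 0.0
    for g in order:
        if g in in_set:
            cum_in += abs(ranks[g]) ** alpha / w_total
        else:
            cum_out += 1.0 / n_out
        score += cum_in - cum_out
    return score


def es_bruteforce(stats: dict[str, float], in_set: set[str], weight: float = 1.0) -> float:
    """Signed maximum deviation of the weighted KS running sum."""
    genes = list(stats)
    order = sorted(genes, key=lambda g: (-stats[g], genes.index(g)))
    w_total = sum(abs(stats[g]) ** weight for g in order if g in in_set)
    n_out = sum(1 for g in order if g not in in_set)
    best, cum_in, cum_out = 0.0, 0.0, 0.0
    for g in order:
        if g in in_set:
            cum_in += abs(stats[g]) ** weight / w_total
        else:
            cum_out += 1.0 / n_out
        dev = cum_in - cum_out
        if abs(dev) > abs(best):
            best = dev
    return best


def logrank_bruteforce(times1, events1, times2, events2) -> float:
    """Two-group log-rank chi-square from the O-E definition."""
    pooled = [(t, e, 0) for t, e in zip(times1, events1)] + [
        (t, e, 1) for t, e in zip(times2, events2)
    ]
    event_times = sorted({t for t, e, _ in pooled if e == 1})
    o = e_exp = v = 0.0
    for t in event_times:
        at_risk = [(tt, ee, g) for tt, ee, g in pooled if tt >= t]
        n_t = len(at_risk)
        d_t = sum(1 for tt, ee, _ in at_risk if tt == t and ee == 1)
        n1_t = sum(1 for _, _, g in at_risk if g == 0)
        d1_t = sum(1 for tt, ee, g in at_risk if tt == t and ee == 1 and g == 0)
        o += d1_t
        e_exp += d_t * n1_t / n_t
        if n_t > 1:
            v += d_t * (n1_t / n_t) * (1 - n1_t / n_t) * (n_t - d_t) / (n_t - 1)
    return (o - e_exp) ** 2 / v if v > 0 else 0.0


def maxstat_bruteforce(times, events, scores, minprop, maxprop):
    """Exhaustive scan over all distinct-score splits; returns (cut, stat)."""
    n = len(scores)
    best_cut, best_stat = None, -1.0
    for c in sorted(set(scores)):
        low = [i for i in range(n) if scores[i] <= c]
        if not minprop <= len(low) / n <= maxprop:
            continue
        high = [i for i in range(n) if scores[i] > c]
        stat = logrank_bruteforce(
            [times[i] for i in low], [events[i] for i in low],
            [times[i] for i in high], [events[i] for i in high],
        )
        if stat > best_stat + 1e-12:
            best_cut, best_stat = c, stat
    return best_cut, best_stat


def auroc_pairs(probs, labels) -> float:
    """Pair-counting Mann-Whitney AUROC with 0.5 credit for ties."""
    pos = [p for p, y in zip(probs, labels) if y == 1]
    neg = [p for p, y in zip(probs, labels) if y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def youden_bruteforce(probs, labels):
    """Exhaustive scan of observed cutoffs; returns (threshold, J)."""
    candidates = sorted(set(probs)) + [max(probs) + 1.0]
    best_thr, best_j = None, -np.inf
    for thr in candidates:
        tp = sum(1 for p, y in zip(probs, labels) if p >= thr and y == 1)
        fn = sum(1 for p, y in zip(probs, labels) if p < thr and y == 1)
        tn = sum(1 for p, y in zip(probs, labels) if p < thr and y == 0)
        fp = sum(1 for p, y in zip(probs, labels) if p >= thr and y == 0)
        j = tp / (tp + fn) + tn / (tn + fp) - 1.0
        if j > best_j + 1e-12:
            best_thr, best_j = thr, j
    return best_thr, best_j


def net_benefit_hand(probs, labels, pt) -> float:
    """Net benefit at one threshold from the confusion counts."""
    n = len(labels)
    tp = sum(1 for p, y in zip(probs, labels) if p >= pt and y == 1)
    fp = sum(1 for p, y in zip(probs, labels) if p >= pt and y == 0)
    return tp / n - (fp / n) * pt / (1 - pt)
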