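"""Gene-set handling, enrichment scoring and lactate-group stratification.

The lactate signature is an ordinary :class:`~lactopath.containers.GeneSet`
read from GMT; nothing here is specific to lactate biology. Scores are
computed per sample with the rank-based single-sample enrichment statistic
(ssGSEA), samples are split into LAC_H / LAC_L tertiles, and per-signature
group differences are summarized as a mean delta with a Wilcoxon rank-sum
p-value.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .containers import (
    LABEL_HIGH,
    LABEL_LOW,
    LABEL_MID,
    GeneSet,
    validate_expression,
)
from .errors import ParseError

__all__ = [
    "read_gmt",
    "write_gmt",
    "ssgsea_scores",
    "preranked_gsea",
    "stratify_tertiles",
    "signature_delta",
]


# ---------------------------------------------------------------------------
# GMT I/O
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read gene sets from a tab-separated GMT file.

    Each non-blank line is ``name<TAB>description<TAB>gene1<TAB>gene2...``.
    Duplicate genes within a line are dropped (first occurrence kept) with a
    warning; a line with fewer than three fields raises :class:`ParseError`
    naming the line number.
    """
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}: line {lineno}: expected name, description and at "
                    f"least one gene (got {len(fields)} fields)"
                )
            name, desc, *genes = fields
            genes = [g for g in genes if g]
            seen: dict[str, None] = {}
            for g in genes:
                if g in seen:
                    continue
                seen[g] = None
            if len(seen) < len(genes):
                warnings.warn(
                    f"{path}: line {lineno}: gene set {name!r} contains "
                    f"{len(genes) - len(seen)} duplicate gene(s); deduplicated",
                    stacklevel=2,
                )
            sets.append(GeneSet(name=name, genes=list(seen), description=desc))
    return sets


def write_gmt(sets: list[GeneSet], path: str | Path) -> None:
    """Write gene sets as GMT; inverse of :func:`read_gmt`."""
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, gs.description, *gs.genes]) + "\n")


# ---------------------------------------------------------------------------
# Single-sample enrichment (ssGSEA)
# ---------------------------------------------------------------------------

def _ssgsea_one_sample(order_stats: np.ndarray, in_set: np.ndarray, alpha: float) -> float:
    """Enrichment score for one sample given genes already in descending order.

    ``order_stats`` holds the absolute rank statistic per position and
    ``in_set`` the set membership per position. The score is the sum over all
    positions of the difference between the weighted in-set ECDF and the
    uniform out-of-set ECDF.
    """
    w = np.where(in_set, np.abs(order_stats) ** alpha, 0.0)
    denom_in = w.sum()
    n_out = np.count_nonzero(~in_set)
    ecdf_in = np.cumsum(w) / denom_in
    ecdf_out = np.cumsum(~in_set) / n_out
    return float(np.sum(ecdf_in - ecdf_out))


def ssgsea_scores(
    expr: pd.DataFrame,
    sets: list[GeneSet] | GeneSet,
    alpha: float = 0.25,
) -> pd.DataFrame:
    """Per-sample single-sample enrichment scores for one or more gene sets.

    For each sample, genes are ranked by expression (descending); the score is
    the running-sum difference between the in-set ECDF weighted by
    ``|rank|**alpha`` and the unweighted out-of-set ECDF, summed over all rank
    positions. The statistic depends on each sample's expression values only
    through their ranks, so it is invariant to strictly monotone transforms
    of a sample's column. No cross-sample rescaling is applied.

    Parameters
    ----------
    expr
        Genes x samples matrix (log-scale or otherwise caller-normalized).
    sets
        Gene set(s) to score. Sets with no gene in ``expr`` are skipped with
        a warning; a set covering every measured gene is an error (the
        out-of-set ECDF would be empty).
    alpha
        Rank-weighting exponent.

    Returns
    -------
    pandas.DataFrame
        Samples x gene-sets score table.
    """
    validate_expression(expr)
    if isinstance(sets, GeneSet):
        sets = [sets]
    gene_index = pd.Index(expr.index)
    n_genes = len(gene_index)

    # Descending-order positions per sample; average ranks give the statistic.
    values = expr.to_numpy(dtype=float)
    # rank 1 = lowest expression; statistic = rank value (higher = more expressed)
    rank_stat = np.apply_along_axis(stats.rankdata, 0, values)

    out: dict[str, np.ndarray] = {}
    for gs in sets:
        member = gene_index.isin(gs.genes)
        n_in = int(member.sum())
        if n_in == 0:
            warnings.warn(
                f"gene set {gs.name!r} shares no genes with the matrix; skipped",
                stacklevel=2,
            )
            continue
        if n_in == n_genes:
            raise ValueError(
                f"gene set {gs.name!r} covers every measured gene; the "
                "out-of-set ECDF is undefined"
            )
        dropped = len(gs) - n_in
        if dropped:
            warnings.warn(
                f"gene set {gs.name!r}: {dropped} gene(s) absent from the "
                "matrix were dropped",
                stacklevel=2,
            )
        scores = np.empty(values.shape[1])
        for j in range(values.shape[1]):
            # stable descending order; ties broken by gene position for determinism
            order = np.lexsort((np.arange(n_genes), -values[:, j]))
            scores[j] = _ssgsea_one_sample(
                rank_stat[order, j], member[order], alpha
            )
        out[gs.name] = scores
    return pd.DataFrame(out, index=expr.columns)


# ---------------------------------------------------------------------------
# Preranked enrichment with permutation significance
# ---------------------------------------------------------------------------

def _running_es(stat_sorted: np.ndarray, in_set: np.ndarray, weight: float) -> float:
    """Signed maximum deviation of the weighted KS running sum (one ranking)."""
    w = np.where(in_set, np.abs(stat_sorted) ** weight, 0.0)
    p_hit = np.cumsum(w) / w.sum()
    p_miss = np.cumsum(~in_set) / np.count_nonzero(~in_set)
    dev = p_hit - p_miss
    return float(dev[np.argmax(np.abs(dev))])


def preranked_gsea(
    ranked_stats: pd.Series,
    gene_set: GeneSet,
    n_perm: int = 1000,
    seed: int | None = None,
    weight: float = 1.0,
) -> tuple[float, float, float]:
    """Preranked enrichment score with gene-label permutation significance.

    ``ranked_stats`` maps genes to a ranking statistic (e.g. a differential
    expression score). ES is the signed maximum deviation of the weighted
    Kolmogorov–Smirnov running sum over genes sorted by decreasing statistic.
    The null is built by permuting set membership over genes; NES divides ES
    by the mean |ES| of the same-sign permutations and the p-value is the
    same-sign permutation tail proportion with +1 smoothing.

    Returns ``(es, nes, p_value)``.
    """
    if n_perm < 10:
        raise ValueError("n_perm must be at least 10")
    values = ranked_stats.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("ranking statistics must be finite")
    genes = pd.Index(ranked_stats.index)
    member = genes.isin(gene_set.genes)
    n_in = int(member.sum())
    n = len(genes)
    if n_in < 2 or n - n_in < 2:
        raise ValueError("need at least 2 in-set and 2 out-of-set genes")

    order = np.lexsort((np.arange(n), -values))
    stat_sorted = values[order]
    in_sorted = member[order]
    es = _running_es(stat_sorted, in_sorted, weight)

    rng = np.random.default_rng(seed)
    # Vectorized permutations of set membership along the fixed ranking.
    w_abs = np.abs(stat_sorted) ** weight
    perm_member = np.zeros((n_perm, n), dtype=bool)
    for b in range(n_perm):
        idx = rng.choice(n, size=n_in, replace=False)
        perm_member[b, idx] = True
    w_perm = np.where(perm_member, w_abs[None, :], 0.0)
    p_hit = np.cumsum(w_perm, axis=1) / w_perm.sum(axis=1, keepdims=True)
    p_miss = np.cumsum(~perm_member, axis=1) / (n - n_in)
    dev = p_hit - p_miss
    arg = np.argmax(np.abs(dev), axis=1)
    es_perm = dev[np.arange(n_perm), arg]

    same_sign = es_perm * np.sign(es) >= 0 if es != 0 else np.ones(n_perm, bool)
    es_null = np.abs(es_perm[same_sign])
    if es_null.size == 0:
        nes = np.nan
        p = 1.0 / (n_perm + 1)
    else:
        nes = es / float(np.mean(es_null)) if np.mean(es_null) > 0 else np.nan
        p = (1.0 + np.count_nonzero(es_null >= abs(es))) / (1.0 + es_null.size)
    return es, float(nes), float(p)


# ---------------------------------------------------------------------------
# Stratification and group deltas
# ---------------------------------------------------------------------------

def stratify_tertiles(scores: pd.Series, fraction: float = 0.33) -> pd.DataFrame:
    """Label the top/bottom ``fraction`` of samples LAC_H / LAC_L.

    ``k = max(1, floor(fraction * n))`` samples with the highest scores are
    labeled LAC_H, the ``k`` lowest LAC_L, everything else MID. Ties at a
    boundary are broken by stable sample-id order (within a tied score,
    lexicographically earlier ids fall in the lower group).

    Returns a DataFrame indexed like ``scores`` with columns ``score`` and
    ``group``.
    """
    n = len(scores)
    if n < 3:
        raise ValueError("need at least 3 samples to stratify")
    if not 0 < fraction <= 0.5:
        raise ValueError("fraction must lie in (0, 0.5]")
    if not np.all(np.isfinite(scores.to_numpy(dtype=float))):
        raise ValueError("scores must be finite")
    k = max(1, int(np.floor(fraction * n)))

    frame = pd.DataFrame(
        {"score": scores.to_numpy(dtype=float), "_sid": scores.index.astype(str)},
        index=scores.index,
    )
    order = frame.sort_values(["score", "_sid"], kind="stable").index
    group = pd.Series(LABEL_MID, index=scores.index, name="group")
    group.loc[order[:k]] = LABEL_LOW
    group.loc[order[-k:]] = LABEL_HIGH
    return pd.DataFrame({"score": frame["score"], "group": group})


def signature_delta(
    scores: pd.DataFrame | pd.Series,
    groups: pd.Series,
    high_minus_low: bool = True,
) -> pd.DataFrame:
    """Mean score difference between LAC_H and LAC_L with rank-sum p-values.

    ``delta = mean(LAC_H) - mean(LAC_L)`` (flip the sign with
    ``high_minus_low=False``, matching the opposite reporting convention).
    The p-value is a two-sided Wilcoxon rank-sum with tie correction and
    continuity correction (normal approximation).

    ``scores`` may be a Series (one signature) or a samples x signatures
    DataFrame; returns one row per signature with columns ``delta`` and
    ``p_value``.
    """
    if isinstance(scores, pd.Series):
        scores = scores.to_frame(scores.name or "signature")
    groups = groups.reindex(scores.index)
    hi_mask = groups == LABEL_HIGH
    lo_mask = groups == LABEL_LOW
    if hi_mask.sum() == 0 or lo_mask.sum() == 0:
        raise ValueError("both LAC_H and LAC_L groups must be non-empty")
    rows = {}
    for name in scores.columns:
        hi = scores.loc[hi_mask, name].to_numpy(dtype=float)
        lo = scores.loc[lo_mask, name].to_numpy(dtype=float)
        delta = float(hi.mean() - lo.mean())
        if not high_minus_low:
            delta = -delta
        res = stats.mannwhitneyu(
            hi, lo, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        rows[name] = {"delta": delta, "p_value": float(res.pvalue)}
    return pd.DataFrame.from_dict(rows, orient="index")
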