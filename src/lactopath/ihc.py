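"""Immunohistochemistry H-score computation and group comparison.

The H-score weights the percentage of cells in each staining-intensity class:
``H = 1*%weak + 2*%moderate + 3*%strong``, ranging from 0 (all negative) to
300 (all strong). Percentages need not sum to 100 — the remainder is the
negative (intensity 0) fraction, which carries zero weight — but a sum above
100 is rejected.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["h_score", "compare_groups"]

_PCT_COLS = ("p_weak", "p_moderate", "p_strong")


def _validate_percentages(w, m, s) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    w, m, s = (np.asarray(x, dtype=float) for x in (w, m, s))
    for name, arr in zip(_PCT_COLS, (w, m, s)):
        if np.any(~np.isfinite(arr)) or np.any(arr < 0) or np.any(arr > 100):
            raise ValueError(f"{name} must lie in [0, 100]")
    total = w + m + s
    if np.any(total > 100 + 1e-9):
        raise ValueError("intensity-class percentages must sum to at most 100")
    return w, m, s


def h_score(p_weak, p_moderate, p_strong) -> float | np.ndarray:
    """Intensity-weighted percentage score in [0, 300].

    Accepts scalars or aligned arrays of percentages. ``(0, 0, 100)`` gives
    the maximum of 300; ``(0, 0, 0)`` (all cells negative) gives 0.
    """
    w, m, s = _validate_percentages(p_weak, p_moderate, p_strong)
    out = 1.0 * w + 2.0 * m + 3.0 * s
    return float(out) if out.ndim == 0 else out


def h_score_table(table: pd.DataFrame) -> pd.Series:
    """Vectorized :func:`h_score` over a table with p_weak/p_moderate/p_strong."""
    missing = set(_PCT_COLS) - set(table.columns)
    if missing:
        raise ValueError(f"intensity table is missing columns: {sorted(missing)}")
    values = h_score(*(table[c] for c in _PCT_COLS))
    return pd.Series(values, index=table.index, name="h_score")


def compare_groups(
    high: pd.DataFrame, low: pd.DataFrame
) -> tuple[float, float, float]:
    """Compare H-scores between predicted-high and predicted-low groups.

    Both inputs are intensity tables (p_weak/p_moderate/p_strong per sample).
    Returns ``(median_high, median_low, p_value)`` with a two-sided Wilcoxon
    rank-sum p-value (normal approximation with tie and continuity
    correction).
    """
    if len(high) < 3 or len(low) < 3:
        raise ValueError("each group needs at least 3 samples")
    hs_high = h_score_table(high).to_numpy()
    hs_low = h_score_table(low).to_numpy()
    res = stats.mannwhitneyu(
        hs_high, hs_low, alternative="two-sided", method="asymptotic",
        use_continuity=True,
    )
    return float(np.median(hs_high)), float(np.median(hs_low)), float(res.pvalue)
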