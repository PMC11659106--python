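"""Nonparametric statistical battery: Mann–Whitney U, Steel–Dwass, χ².

All tests are two-tailed.  Two-group comparisons use the Mann–Whitney U
test (exact enumeration for small tie-free samples, normal approximation
with tie correction otherwise); three or more groups use the Steel–Dwass
all-pairs multiple comparison, in which each pair is ranked jointly on its
own and the standardized rank statistic is referred to the Studentized
range distribution with k groups and infinite degrees of freedom.
"""

from __future__ import annotations

from itertools import combinations
from typing import Dict, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import ValidationError

__all__ = ["mann_whitney_u", "steel_dwass", "chi_square", "ALPHA"]

#: two-tailed significance threshold used throughout
ALPHA = 0.05

_EXACT_MAX_N = 12  # combined size at or below which exact enumeration runs


def _as_sample(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size == 0:
        raise ValidationError(f"group {name!r} is empty")
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"group {name!r} contains non-finite values")
    return arr


def mann_whitney_u(a, b) -> Tuple[float, float]:
    """Two-tailed Mann–Whitney U test; returns (U of the first sample, p).

    Uses the exact null distribution when the combined sample size is at
    most 12 and tie-free, else the tie-corrected normal approximation with
    continuity correction.
    """
    a = _as_sample(a, "a")
    b = _as_sample(b, "b")
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (pooled.size <= _EXACT_MAX_N and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def _pair_z(x: np.ndarray, y: np.ndarray) -> float:
    """Standardized joint-rank statistic for one pair (tie-corrected)."""
    ni, nj = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)  # midranks
    r_i = ranks[:ni].sum()
    n = ni + nj
    expect = ni * (n + 1) / 2.0
    # tie-corrected variance of the rank sum
    var = ni * nj / (n * (n - 1.0)) * (np.sum(ranks ** 2) - n * (n + 1.0) ** 2 / 4.0)
    if var <= 0:  # all observations tied
        return 0.0
    return float((r_i - expect) / np.sqrt(var))


def steel_dwass(groups: Dict[str, Sequence[float]]) -> pd.DataFrame:
    """All-pairs Steel–Dwass comparisons for ≥3 groups.

    For each pair the groups are ranked jointly over that pair only; the
    two-tailed p-value is P(Q ≥ √2·|z|) from the Studentized range
    distribution with k groups and ∞ df.  Returns a tidy table with one
    row per unordered pair.
    """
    if len(groups) < 3:
        raise ValidationError(
            "Steel–Dwass requires >= 3 groups (use mann_whitney_u for two)"
        )
    samples = {name: _as_sample(vals, name) for name, vals in groups.items()}
    k = len(samples)
    rows = []
    for (na, xa), (nb, xb) in combinations(samples.items(), 2):
        z = _pair_z(xa, xb)
        p = float(sps.studentized_range.sf(np.sqrt(2.0) * abs(z), k, np.inf))
        rows.append(
            {
                "group_a": na,
                "group_b": nb,
                "statistic": z,
                "p_value": min(p, 1.0),
                "significant": p < ALPHA,
            }
        )
    return pd.DataFrame(rows)


def chi_square(table) -> Tuple[float, float]:
    """Pearson χ² on a 2×2 count table, 1 df, two-tailed, no continuity
    correction; raises on a zero marginal."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValidationError(f"expected a 2x2 table, got shape {t.shape}")
    if np.any(t < 0) or not np.allclose(t, np.round(t)):
        raise ValidationError("table entries must be non-negative integers")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValidationError("zero marginal in contingency table")
    stat, p, _, _ = sps.chi2_contingency(t, correction=False)
    return float(stat), float(p)


def auto_compare(groups: Dict[str, Sequence[float]]) -> pd.DataFrame:
    """Dispatch: 2 groups → Mann–Whitney, ≥3 → Steel–Dwass; tidy output."""
    if len(groups) < 2:
        raise ValidationError("need at least two groups")
    if len(groups) == 2:
        (na, xa), (nb, xb) = groups.items()
        u, p = mann_whitney_u(xa, xb)
        return pd.DataFrame(
            [{
                "group_a": na, "group_b": nb, "statistic": u,
                "p_value": p, "significant": p < ALPHA,
            }]
        )
    return steel_dwass(groups)
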