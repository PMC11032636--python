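"""Comparisons of typicality across lexical categories.

The category analysis runs Bartlett's homogeneity-of-variance test first;
because rating-derived typicality routinely violates homogeneity, the
omnibus comparison is Welch's heteroskedastic one-way ANOVA (F with
Satterthwaite denominator degrees of freedom) with the omega-squared
effect size, followed by Games-Howell pairwise post hocs, which combine
Welch-type standard errors with the studentized-range distribution.

omega^2 is estimated as ``df1 (F - 1) / (df1 (F - 1) + N)`` applied to the
Welch F — the conventional approximation for heteroskedastic designs; it
is approximate and can be slightly negative for F < 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "GroupSample",
    "BartlettResult",
    "WelchResult",
    "PairwiseResult",
    "bartlett_test",
    "welch_anova",
    "games_howell",
]


@dataclass(frozen=True)
class GroupSample:
    label: str
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))


@dataclass
class BartlettResult:
    chi2: float
    df: int
    p: float


@dataclass
class WelchResult:
    f: float
    df1: int
    df2: float
    p: float
    omega2: float


@dataclass
class PairwiseResult:
    pair: tuple[str, str]
    mean_diff: float
    se: float
    df: float
    q: float
    p_adj: float


def _check(groups: Sequence[GroupSample]) -> list[GroupSample]:
    groups = list(groups)
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for grp in groups:
        if grp.values.size < 2:
            raise ValueError(f"group {grp.label!r} has fewer than 2 observations")
        if np.var(grp.values, ddof=1) <= 0:
            raise ValueError(f"group {grp.label!r} has zero within-group variance")
    return groups


def bartlett_test(groups: Sequence[GroupSample]) -> BartlettResult:
    """Bartlett's chi-square test of equal variances (k - 1 df)."""
    groups = _check(groups)
    chi2, p = stats.bartlett(*[g.values for g in groups])
    return BartlettResult(float(chi2), len(groups) - 1, float(p))


def welch_anova(groups: Sequence[GroupSample]) -> WelchResult:
    """Welch's heteroskedastic one-way ANOVA with omega-squared."""
    groups = _check(groups)
    k = len(groups)
    n = np.array([g.values.size for g in groups], dtype=float)
    mean = np.array([g.values.mean() for g in groups])
    var = np.array([g.values.var(ddof=1) for g in groups])

    w = n / var
    w_sum = w.sum()
    grand = (w * mean).sum() / w_sum
    a = ((w * (mean - grand) ** 2).sum()) / (k - 1)
    lam = ((1.0 - w / w_sum) ** 2 / (n - 1.0)).sum()
    b = 1.0 + 2.0 * (k - 2.0) / (k**2 - 1.0) * lam
    f = a / b
    df1 = k - 1
    df2 = (k**2 - 1.0) / (3.0 * lam)
    p = float(stats.f.sf(f, df1, df2))
    n_total = float(n.sum())
    omega2 = df1 * (f - 1.0) / (df1 * (f - 1.0) + n_total)
    return WelchResult(float(f), df1, float(df2), p, float(omega2))


def games_howell(groups: Sequence[GroupSample]) -> list[PairwiseResult]:
    """Games-Howell pairwise post hocs for unequal variances and ns.

    For each pair the standard error is sqrt(s_i^2/n_i + s_j^2/n_j) with
    Satterthwaite degrees of freedom, the statistic ``q = |diff| sqrt(2) /
    SE``, and the adjusted p-value comes from the studentized-range
    distribution with k groups.  With exactly two groups this reduces to
    the Welch two-sample t-test (q = t sqrt(2)).
    """
    groups = _check(groups)
    k = len(groups)
    results = []
    for gi, gj in combinations(groups, 2):
        ni, nj = gi.values.size, gj.values.size
        vi, vj = gi.values.var(ddof=1), gj.values.var(ddof=1)
        diff = gi.values.mean() - gj.values.mean()
        vin, vjn = vi / ni, vj / nj
        se = np.sqrt(vin + vjn)
        df = (vin + vjn) ** 2 / (vin**2 / (ni - 1) + vjn**2 / (nj - 1))
        q = abs(diff) * np.sqrt(2.0) / se
        p_adj = float(np.clip(stats.studentized_range.sf(q, k, df), 0.0, 1.0))
        results.append(
            PairwiseResult((gi.label, gj.label), float(diff), float(se), float(df),
                           float(q), p_adj)
        )
    return results
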