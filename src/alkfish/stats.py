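"""Exact contingency-table inference for 2xK tables.

Provides Fisher's exact test by full enumeration of margin-consistent
tables (minimum-likelihood two-sided criterion), Pearson's chi-square,
Cramer's V with a 95% confidence interval obtained by inverting the
noncentral chi-square distribution, and add-one (Laplace) smoothing for
degenerate tables.

The noncentral CI follows Smithson's construction: the noncentrality
lambda of the chi-square statistic is bracketed so the observed statistic
sits at the 97.5th / 2.5th percentile of the noncentral distribution, and
each lambda bound maps to a V bound via sqrt((lambda + df) / (n * m))
with m = min(r-1, c-1).  Lambda is clamped at zero; a clamped lower
bound maps to 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize
from scipy import stats as sps

__all__ = [
    "ContingencyTable",
    "AssociationResult",
    "EnumerationCapacityError",
    "laplace_smooth",
    "fisher_exact",
    "chi_square",
    "cramers_v",
    "cramers_v_ci",
    "associate",
    "build_pattern_table",
]

#: Largest column count accepted by the exact enumeration.
MAX_COLUMNS = 4


class EnumerationCapacityError(ValueError):
    """Table shape outside the supported exact-enumeration range."""


@dataclass(frozen=True)
class ContingencyTable:
    """A labelled table of non-negative integer counts."""

    counts: tuple  # tuple of row tuples
    row_labels: tuple = ()
    col_labels: tuple = ()

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if arr.ndim != 2:
            raise ValueError("counts must be two-dimensional")
        if np.any(arr < 0) or not np.issubdtype(arr.dtype, np.integer):
            raise ValueError("counts must be non-negative integers")
        object.__setattr__(
            self, "counts", tuple(tuple(int(x) for x in row) for row in arr)
        )
        if not self.row_labels:
            object.__setattr__(
                self, "row_labels", tuple(f"r{i}" for i in range(arr.shape[0]))
            )
        if not self.col_labels:
            object.__setattr__(
                self, "col_labels", tuple(f"c{j}" for j in range(arr.shape[1]))
            )
        if len(self.row_labels) != arr.shape[0] or len(self.col_labels) != arr.shape[1]:
            raise ValueError("label lengths do not match table shape")

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=np.int64)

    @property
    def n(self) -> int:
        return int(self.array.sum())

    @property
    def shape(self) -> tuple:
        return self.array.shape


@dataclass(frozen=True)
class AssociationResult:
    """Joint outcome of the association analysis on one table."""

    p_value: float
    chi_square: float
    df: int
    cramers_v: float
    v_ci: tuple
    smoothed: bool


def laplace_smooth(table: ContingencyTable) -> tuple:
    """Add one to every cell when a row or column sums to zero.

    Returns ``(table, smoothed)``; the identity (and ``False``) when no
    margin is degenerate.
    """
    arr = table.array
    if np.all(arr.sum(axis=1) > 0) and np.all(arr.sum(axis=0) > 0):
        return table, False
    return (
        ContingencyTable(
            tuple(tuple(int(x) + 1 for x in row) for row in table.counts),
            table.row_labels,
            table.col_labels,
        ),
        True,
    )


def _log_table_prob(row0: Sequence[int], col_sums: Sequence[int], n: int, r0: int) -> float:
    """Log multivariate-hypergeometric probability of a 2xK table given
    margins, parameterized by its first row."""
    lp = -(math.lgamma(n + 1) - math.lgamma(r0 + 1) - math.lgamma(n - r0 + 1))
    for a, c in zip(row0, col_sums):
        lp += math.lgamma(c + 1) - math.lgamma(a + 1) - math.lgamma(c - a + 1)
    return lp


def _iter_first_rows(col_sums: Sequence[int], r0: int):
    """Yield every first row consistent with the margins."""
    k = len(col_sums)

    def rec(j: int, remaining: int, prefix: tuple):
        if j == k - 1:
            if remaining <= col_sums[j]:
                yield prefix + (remaining,)
            return
        tail_cap = sum(col_sums[j + 1:])
        lo = max(0, remaining - tail_cap)
        hi = min(col_sums[j], remaining)
        for a in range(lo, hi + 1):
            yield from rec(j + 1, remaining - a, prefix + (a,))

    yield from rec(0, r0, ())


def fisher_exact(table: ContingencyTable, rel_tol: float = 1e-7) -> float:
    """Two-sided Fisher exact test for a 2xK table by full enumeration.

    The p-value sums the conditional (multivariate hypergeometric)
    probabilities of every margin-consistent table whose probability does
    not exceed that of the observed table (minimum-likelihood criterion,
    with a ``1 + rel_tol`` relative guard against floating-point ties —
    the convention of the standard statistical software).
    """
    arr = table.array
    if arr.shape[0] != 2:
        raise EnumerationCapacityError("exact enumeration supports 2-row tables only")
    if arr.shape[1] > MAX_COLUMNS:
        raise EnumerationCapacityError(
            f"exact enumeration supports at most {MAX_COLUMNS} columns, "
            f"got {arr.shape[1]}"
        )
    col_sums = [int(c) for c in arr.sum(axis=0)]
    n = int(arr.sum())
    r0 = int(arr[0].sum())
    if n == 0:
        raise ValueError("empty table")
    lp_obs = _log_table_prob(arr[0], col_sums, n, r0)
    cutoff = lp_obs + math.log1p(rel_tol)
    terms = [
        math.exp(lp)
        for row0 in _iter_first_rows(col_sums, r0)
        if (lp := _log_table_prob(row0, col_sums, n, r0)) <= cutoff
    ]
    return min(1.0, math.fsum(terms))


def chi_square(table: ContingencyTable) -> tuple:
    """Pearson chi-square statistic and degrees of freedom (no continuity
    correction)."""
    stat, _, df, _ = sps.chi2_contingency(table.array, correction=False)
    return float(stat), int(df)


def _v_denominator(table: ContingencyTable) -> int:
    r, c = table.shape
    return table.n * min(r - 1, c - 1)


def cramers_v(table: ContingencyTable) -> float:
    """Cramer's V: sqrt(chi2 / (n * min(r-1, c-1)))."""
    stat, _ = chi_square(table)
    return math.sqrt(stat / _v_denominator(table))


def _ncx2_cdf(x: float, df: int, lam: float) -> float:
    if lam <= 0:
        return float(sps.chi2.cdf(x, df))
    return float(sps.ncx2.cdf(x, df, lam))


def cramers_v_ci(table: ContingencyTable, level: float = 0.95) -> tuple:
    """Two-sided confidence interval for Cramer's V.

    Inverts the noncentral chi-square distribution at the observed
    statistic: lambda_hi solves ``P(X2_{df,lam} <= chi2_obs) = alpha/2``
    and lambda_lo solves ``P(X2_{df,lam} <= chi2_obs) = 1 - alpha/2``
    (clamped at 0, in which case the lower bound is 0).  Each lambda maps
    to a V bound via ``sqrt((lambda + df) / (n * min(r-1, c-1)))``.
    """
    if not 0 < level < 1:
        raise ValueError("confidence level must be in (0, 1)")
    stat, df = chi_square(table)
    alpha = 1.0 - level
    denom = _v_denominator(table)

    def solve(target: float) -> float:
        # find lam with ncx2.cdf(stat; df, lam) == target; cdf decreases in lam
        f = lambda lam: _ncx2_cdf(stat, df, lam) - target
        if f(0.0) <= 0:
            return 0.0
        hi = max(stat, 1.0)
        while f(hi) > 0:
            hi *= 2.0
            if hi > 1e8:
                raise RuntimeError(
                    f"noncentrality search failed to bracket: cdf({stat}, {df}, "
                    f"{hi}) still above {target}"
                )
        return float(optimize.brentq(f, 0.0, hi, xtol=1e-10, rtol=1e-12))

    lam_lo = solve(1.0 - alpha / 2.0)
    lam_hi = solve(alpha / 2.0)
    lower = 0.0 if lam_lo == 0.0 else math.sqrt((lam_lo + df) / denom)
    upper = math.sqrt((lam_hi + df) / denom) if lam_hi > 0 else 0.0
    return lower, upper


def associate(table: ContingencyTable, level: float = 0.95) -> AssociationResult:
    """Full association analysis with the degenerate-margin smoothing
    policy applied first."""
    table, smoothed = laplace_smooth(table)
    stat, df = chi_square(table)
    return AssociationResult(
        p_value=fisher_exact(table),
        chi_square=stat,
        df=df,
        cramers_v=cramers_v(table),
        v_ci=cramers_v_ci(table, level=level),
        smoothed=smoothed,
    )


def build_pattern_table(samples: Iterable, max_patterns: int = 3) -> ContingencyTable:
    """Cross-tabulate concordance group against pattern-set size.

    ``samples`` yields ``(group, pattern_set_size)`` pairs with group in
    {"discordant", "concordant"}.  Samples with an empty pattern set are
    excluded (logged).  Rows: discordant, concordant; columns: 1..max
    pattern-set sizes.
    """
    import logging

    logger = logging.getLogger(__name__)
    rows = {"discordant": [0] * max_patterns, "concordant": [0] * max_patterns}
    for group, size in samples:
        if group not in rows:
            raise ValueError(f"unknown concordance group {group!r}")
        if size == 0:
            logger.info("sample with empty pattern set excluded from the table")
            continue
        if not 1 <= size <= max_patterns:
            raise ValueError(f"pattern-set size {size} out of range")
        rows[group][size - 1] += 1
    return ContingencyTable(
        (tuple(rows["discordant"]), tuple(rows["concordant"])),
        row_labels=("discordant", "concordant"),
        col_labels=tuple(str(i + 1) for i in range(max_patterns)),
    )
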