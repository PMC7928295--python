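"""Contingency statistics for 2×2 (and r×c) count tables.

Implements the cross-product odds ratio with Haldane–Anscombe correction
and Woolf (logit) 95% CI, Pearson's χ² (optionally Yates-corrected),
Fisher's exact test (two-sided, point-probability method), and a
deterministic test-selection rule (Cochran's criterion: exact test when any
expected count is below 5 or the grand total below 40).

All p-values are two-sided.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "ContingencyTable",
    "ComparisonResult",
    "odds_ratio",
    "chi_square_test",
    "fisher_exact",
    "choose_test",
    "compare_2x2",
]

CHI_SQUARE = "chi_square"
CHI_SQUARE_YATES = "chi_square_yates"
FISHER_EXACT = "fisher_exact"


@dataclass(frozen=True)
class ContingencyTable:
    """An r×c table of non-negative integer counts with optional labels."""

    counts: tuple[tuple[int, ...], ...]
    row_labels: Optional[tuple[str, ...]] = None
    col_labels: Optional[tuple[str, ...]] = None

    @classmethod
    def from_array(cls, a, row_labels=None, col_labels=None) -> "ContingencyTable":
        arr = np.asarray(a)
        if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
            raise ValueError("contingency table must be at least 2x2")
        if np.any(arr < 0) or not np.all(arr == np.round(arr)):
            raise ValueError("counts must be non-negative integers")
        if arr.sum() <= 0:
            raise ValueError("contingency table must have a positive grand total")
        return cls(
            counts=tuple(tuple(int(x) for x in row) for row in arr),
            row_labels=tuple(row_labels) if row_labels else None,
            col_labels=tuple(col_labels) if col_labels else None,
        )

    def to_array(self) -> np.ndarray:
        return np.array(self.counts, dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.counts), len(self.counts[0]))


@dataclass(frozen=True)
class ComparisonResult:
    """Outcome of a 2×2 comparison.

    ``or_ci95`` is a Woolf logit interval (the source tables print no CIs,
    so the interval is an extension and is labelled as such in reports).
    ``haldane`` records whether the +0.5 cell correction was applied to the
    odds ratio because of an empty cell.
    """

    odds_ratio: float
    or_ci95: tuple[float, float]
    statistic: Optional[float]
    dof: Optional[int]
    p_value: float
    test_used: str
    haldane: bool = False

    def __post_init__(self) -> None:
        lo, hi = self.or_ci95
        if not (lo <= self.odds_ratio <= hi):
            raise ValueError("CI does not contain the odds ratio")


def _as_2x2(t) -> np.ndarray:
    arr = t.to_array() if isinstance(t, ContingencyTable) else np.asarray(t, dtype=float)
    if arr.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {arr.shape}")
    return arr


def _check_margins(arr: np.ndarray) -> None:
    if np.any(arr.sum(axis=1) == 0) or np.any(arr.sum(axis=0) == 0):
        raise ValueError("table has an all-zero row or column")


def odds_ratio(t) -> tuple[float, tuple[float, float], bool]:
    """Cross-product odds ratio (a·d)/(b·c) with Woolf 95% CI.

    If any cell is zero the Haldane–Anscombe correction (+0.5 to every
    cell) is applied to both the estimate and the interval; the returned
    flag records the correction.
    """
    arr = _as_2x2(t)
    _check_margins(arr)
    corrected = bool(np.any(arr == 0))
    a, b, c, d = (arr + 0.5 if corrected else arr).ravel()
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo = math.exp(math.log(or_) - 1.96 * se)
    hi = math.exp(math.log(or_) + 1.96 * se)
    return or_, (lo, hi), corrected


def chi_square_test(t, yates: bool = False) -> tuple[float, int, float]:
    """Pearson χ² test of independence on an r×c table.

    Returns (statistic, dof, p).  ``yates`` applies the continuity
    correction (2×2 only; ignored by convention for larger tables, where
    scipy applies none either).
    """
    arr = t.to_array() if isinstance(t, ContingencyTable) else np.asarray(t, dtype=float)
    _check_margins(arr)
    res = sps.chi2_contingency(arr, correction=yates and arr.shape == (2, 2))
    return float(res.statistic), int(res.dof), float(res.pvalue)


def fisher_exact(t) -> float:
    """Two-sided Fisher exact p for a 2×2 table.

    Uses the point-probability definition: the sum of hypergeometric
    probabilities, over all tables with the observed margins, that do not
    exceed the observed table's probability.
    """
    arr = _as_2x2(t)
    return float(sps.fisher_exact(arr, alternative="two-sided")[1])


def expected_counts(t) -> np.ndarray:
    arr = t.to_array() if isinstance(t, ContingencyTable) else np.asarray(t, dtype=float)
    _check_margins(arr)
    return np.outer(arr.sum(axis=1), arr.sum(axis=0)) / arr.sum()


def choose_test(t, yates: bool = False) -> str:
    """Deterministic test selection for a 2×2 table (Cochran's rule).

    Fisher's exact test when any expected count is < 5 or the grand total
    is < 40; otherwise Pearson χ² (Yates-corrected if requested).
    """
    arr = _as_2x2(t)
    if arr.sum() < 40 or np.any(expected_counts(arr) < 5):
        return FISHER_EXACT
    return CHI_SQUARE_YATES if yates else CHI_SQUARE


def compare_2x2(t, yates: bool = False) -> ComparisonResult:
    """Full 2×2 comparison: OR + CI, and the test chosen by Cochran's rule."""
    arr = _as_2x2(t)
    or_, ci, haldane = odds_ratio(arr)
    test = choose_test(arr, yates=yates)
    if test == FISHER_EXACT:
        p = fisher_exact(arr)
        stat: Optional[float] = None
        dof: Optional[int] = None
    else:
        stat, dof, p = chi_square_test(arr, yates=(test == CHI_SQUARE_YATES))
    return ComparisonResult(
        odds_ratio=or_,
        or_ci95=ci,
        statistic=stat,
        dof=dof,
        p_value=p,
        test_used=test,
        haldane=haldane,
    )
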