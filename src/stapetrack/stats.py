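"""Rater-comparison and intensity–amplitude statistics.

The study design compares four raters — the software and three human
observers of decreasing experience — on the same set of applied stimuli.
Each pairwise comparison is a 2x2 contingency table (rater x
detected/undetected) tested with Pearson's chi-square (1 df); the six
pairwise p-values are Bonferroni-adjusted.  Stimulation-intensity versus
motion-vector-length association uses the Pearson correlation with a
two-sided t-test.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

RATERS = ("software", "experienced", "intermediate", "unexperienced")


class DegenerateTableError(ValueError):
    """A contingency-table margin is zero; the chi-square test is undefined."""


@dataclass(frozen=True)
class RaterSummary:
    """Detected/applied counts for one rater."""

    rater: str
    applied: int
    detected: int

    def __post_init__(self) -> None:
        if not 0 <= self.detected <= self.applied:
            raise ValueError("need 0 <= detected <= applied")

    @property
    def rate(self) -> float:
        return self.detected / self.applied


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts [[a, b], [c, d]]: rows are raters, columns detected/undetected."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("grand total must be positive")

    @classmethod
    def from_summaries(cls, s1: RaterSummary, s2: RaterSummary) -> "ContingencyTable2x2":
        return cls(s1.detected, s1.applied - s1.detected, s2.detected, s2.applied - s2.detected)

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int
    electrode: str = ""

    def __post_init__(self) -> None:
        if not -1 - 1e-12 <= self.r <= 1 + 1e-12:
            raise ValueError("r must lie in [-1, 1]")
        if self.n < 3:
            raise ValueError("need at least 3 pairs")


def chi_square_2x2(
    table: ContingencyTable2x2, continuity_correction: bool = False
) -> tuple[float, float]:
    """Pearson chi-square with 1 df on a 2x2 table; two-sided p.

    Yates continuity correction only when requested; the default is the
    plain Pearson statistic.
    """
    arr = table.as_array()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise DegenerateTableError("zero row or column margin")
    stat, p, _, _ = sps.chi2_contingency(arr, correction=continuity_correction)
    return float(stat), float(p)


def pairwise_rater_tests(
    summaries: list[RaterSummary],
    continuity_correction: bool = False,
) -> pd.DataFrame:
    """All pairwise 2x2 chi-square tests with Bonferroni adjustment.

    Every summary must share the same applied total (same stimuli shown to
    every rater).  ``p_adjusted = min(1, m * p_raw)`` where m is the number
    of pairs.
    """
    applied = {s.applied for s in summaries}
    if len(applied) != 1:
        raise ValueError(f"applied totals differ across raters: {sorted(applied)}")
    if len(summaries) < 2:
        raise ValueError("need at least two raters")
    m = len(summaries) * (len(summaries) - 1) // 2
    rows = []
    for s1, s2 in combinations(summaries, 2):
        stat, p = chi_square_2x2(
            ContingencyTable2x2.from_summaries(s1, s2), continuity_correction
        )
        rows.append(
            {
                "rater_a": s1.rater,
                "rater_b": s2.rater,
                "statistic": stat,
                "p_raw": p,
                "p_adjusted": min(1.0, m * p),
            }
        )
    return pd.DataFrame(rows)


def pearson_correlation(levels, amplitudes, electrode: str = "") -> CorrelationResult:
    """Pearson r between stimulation level and motion-vector length."""
    levels = np.asarray(levels, dtype=float)
    amplitudes = np.asarray(amplitudes, dtype=float)
    if len(levels) != len(amplitudes):
        raise ValueError("levels and amplitudes must pair up")
    if len(levels) < 3:
        raise ValueError("need at least 3 pairs")
    if levels.std() == 0 or amplitudes.std() == 0:
        raise ValueError("correlation undefined for zero-variance input")
    res = sps.pearsonr(levels, amplitudes)
    return CorrelationResult(r=float(res.statistic), p=float(res.pvalue), n=len(levels), electrode=electrode)


def summaries_from_counts(df: pd.DataFrame) -> list[RaterSummary]:
    """Sum a per-patient counts table into overall per-rater summaries.

    Expects columns ``applied`` plus one count column per rater name.
    """
    applied = int(df["applied"].sum())
    return [
        RaterSummary(rater=r, applied=applied, detected=int(df[r].sum()))
        for r in RATERS
        if r in df.columns
    ]


def summaries_from_detections(detections: pd.DataFrame) -> list[RaterSummary]:
    """Per-rater summaries from a long-format detection table.

    Expects columns ``rater`` and boolean ``detected``; every rater must
    cover the same stimuli.
    """
    out = []
    for rater, grp in detections.groupby("rater", sort=True):
        out.append(RaterSummary(rater=str(rater), applied=len(grp), detected=int(grp["detected"].sum())))
    return out
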