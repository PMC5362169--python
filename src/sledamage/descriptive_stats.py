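"""Descriptive cohort statistics and two-group comparison tests.

Covers the summaries a cohort report needs: the distribution of the damage
index among affected patients (mean, SD, median, range), percentages with
half-up rounding to one decimal, chi-square / Fisher exact tests on 2x2
tables, and the Mann-Whitney U test for continuous variables.  The test
machinery is delegated to scipy where it exists; the chi-square statistic is
the closed form N(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d)) without continuity
correction unless requested.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import DataError


@dataclass
class SdiSummary:
    mean: float
    sd: float
    median: float
    min: int
    max: int

    @property
    def mean_rounded(self) -> float:
        return round_half_up(self.mean, 1)

    @property
    def sd_rounded(self) -> float:
        return round_half_up(self.sd, 1)


def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal half-up rounding (0.05 -> 0.1), unlike banker's rounding."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def sdi_summary(dist: Mapping[int, int]) -> SdiSummary:
    """Summary statistics of a score -> patient-count distribution.

    Mean is count-weighted; SD uses the n-1 divisor (0 by convention for a
    single patient); the median uses the usual midpoint convention on the
    expanded multiset, computed from cumulative counts.
    """
    items = sorted((int(s), int(c)) for s, c in dist.items() if c > 0)
    if not items or any(c < 0 for _, c in dist.items()):
        raise DataError("distribution must have non-negative counts, at least one positive")
    scores = np.array([s for s, _ in items], dtype=float)
    counts = np.array([c for _, c in items], dtype=float)
    n = counts.sum()
    mean = float((scores * counts).sum() / n)
    if n > 1:
        ss = ((scores - mean) ** 2 * counts).sum()
        sd = float(np.sqrt(ss / (n - 1)))
    else:
        sd = 0.0
    cum = np.cumsum(counts)
    if n % 2 == 1:
        median = float(scores[np.searchsorted(cum, (n + 1) / 2)])
    else:
        lo = float(scores[np.searchsorted(cum, n / 2)])
        hi = float(scores[np.searchsorted(cum, n / 2 + 1)])
        median = (lo + hi) / 2.0
    return SdiSummary(mean=mean, sd=sd, median=median,
                      min=int(scores[0]), max=int(scores[-1]))


def proportion_pct(numerator: int, denominator: int) -> float:
    """100 * numerator / denominator, half-up rounded to one decimal."""
    if denominator <= 0:
        raise DataError("denominator must be positive")
    if not 0 <= numerator <= denominator:
        raise DataError("numerator must lie in [0, denominator]")
    return round_half_up(100.0 * numerator / denominator, 1)


@dataclass
class TwoByTwo:
    """Counts: a/b = group-1 positive/negative, c/d = group-2 positive/negative."""

    a: int
    b: int
    c: int
    d: int

    def validate(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise DataError("counts must be non-negative")
        if self.a + self.b == 0 or self.c + self.d == 0:
            raise DataError("both row sums must be positive")


def two_by_two_test(
    table: TwoByTwo, method: str = "chi_square", continuity: bool = False
) -> tuple[float | None, float]:
    """Chi-square (1 df, no Yates correction by default) or Fisher exact.

    Returns (statistic, p) for chi-square and (None, p) for Fisher, whose
    two-sided p sums hypergeometric probabilities of tables as or more
    extreme at fixed margins.
    """
    table.validate()
    a, b, c, d = table.a, table.b, table.c, table.d
    if method == "chi_square":
        n = a + b + c + d
        r1, r2 = a + b, c + d
        c1, c2 = a + c, b + d
        if min(c1, c2) == 0:
            raise DataError("a column margin is empty; chi-square undefined")
        diff = abs(a * d - b * c)
        if continuity:
            diff = max(diff - n / 2.0, 0.0)
        stat = n * diff**2 / (r1 * r2 * c1 * c2)
        return float(stat), float(stats.chi2.sf(stat, df=1))
    if method == "fisher_exact":
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        return None, float(p)
    raise DataError(f"unknown method {method!r}")


def mann_whitney(sample_a: Sequence[float], sample_b: Sequence[float]) -> tuple[float, float]:
    """Mann-Whitney U (statistic for sample_a) with a two-sided p-value.

    Exact enumeration when the combined sample is small (<= 12) and tie-free;
    otherwise the tie-corrected normal approximation.  Two identical
    constant samples have zero rank variance; p = 1 by convention.
    """
    x = np.asarray(sample_a, dtype=float)
    y = np.asarray(sample_b, dtype=float)
    if x.size == 0 or y.size == 0:
        raise DataError("both samples must be non-empty")
    n, m = x.size, y.size
    ties = np.unique(np.r_[x, y]).size < n + m
    if np.unique(np.r_[x, y]).size == 1:
        return n * m / 2.0, 1.0
    method = "exact" if (n + m <= 12 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    p = float(res.pvalue)
    if np.isnan(p):  # fully degenerate rank variance
        p = 1.0
    return float(res.statistic), p


def group_comparison_table(cohort, cases, controls) -> list[dict]:
    """Per-feature case/control counts, percentages and p-values.

    ``cases`` / ``controls`` are (patient, prefix) selections.  A feature is
    counted positive for a patient if it is 1 at any visit of the full
    series.  Fisher's exact test replaces chi-square whenever an expected
    cell count drops below 5 (the usual applicability rule).
    """
    rows = []
    case_series = [s for s, _ in cases]
    control_series = [s for s, _ in controls]
    n_ca, n_co = len(case_series), len(control_series)
    for name in cohort.codebook:
        ca = sum(
            any(v.feature_flags[name] for v in s.visits) for s in case_series
        )
        co = sum(
            any(v.feature_flags[name] for v in s.visits) for s in control_series
        )
        t = TwoByTwo(ca, n_ca - ca, co, n_co - co)
        n = n_ca + n_co
        expected_min = min(
            (t.a + t.b) * (t.a + t.c) / n,
            (t.a + t.b) * (t.b + t.d) / n,
            (t.c + t.d) * (t.a + t.c) / n,
            (t.c + t.d) * (t.b + t.d) / n,
        ) if n else 0
        method = "fisher_exact" if expected_min < 5 else "chi_square"
        try:
            _, p = two_by_two_test(t, method=method)
        except DataError:
            p = float("nan")
        rows.append(
            {
                "feature": name,
                "cases_positive": ca,
                "cases_pct": proportion_pct(ca, n_ca) if n_ca else float("nan"),
                "controls_positive": co,
                "controls_pct": proportion_pct(co, n_co) if n_co else float("nan"),
                "test": method,
                "p_value": p,
            }
        )
    return rows
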