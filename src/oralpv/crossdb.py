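"""Cross-database comparison of reporting rates.

Per-term odds ratios of one spontaneous-reporting database against another
(Woolf log-normal confidence intervals, no zero-cell correction: a zero
count in the comparator database reports an infinite OR, a zero count in
the index database reports 0, both with undefined interval bounds), plus
chi-square / Fisher comparisons of the databases' covariate marginals.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .icsr import ICSRCollection
from .rates import TermRateRow

logger = logging.getLogger(__name__)

Z95 = 1.96


@dataclass(frozen=True)
class OREstimate:
    """Odds ratio of db1 vs db2 reporting for one term."""

    or_point: float
    ci_low: float
    ci_high: float
    a: int
    b: int
    n1: int
    n2: int
    ci_defined: bool = True

    @property
    def dominance(self) -> str:
        """'db1' if the CI sits above 1, 'db2' if below, else 'indeterminate'."""
        if self.ci_defined and self.ci_low > 1.0:
            return "db1"
        if self.ci_defined and self.ci_high < 1.0:
            return "db2"
        return "indeterminate"


def odds_ratio(a: int, n1: int, b: int, n2: int) -> OREstimate:
    """OR of term reporting in database 1 (a of n1) vs database 2 (b of n2)."""
    if not (0 <= a <= n1 and 0 <= b <= n2) or n1 < 1 or n2 < 1:
        raise ValueError("counts must satisfy 0 <= a <= n1, 0 <= b <= n2, n1, n2 >= 1")
    if a == n1 or b == n2:
        raise ValueError("degenerate table: a term cannot fill a whole database")
    if b == 0 and a > 0:
        return OREstimate(math.inf, math.nan, math.nan, a, b, n1, n2, ci_defined=False)
    if a == 0 and b > 0:
        return OREstimate(0.0, math.nan, math.nan, a, b, n1, n2, ci_defined=False)
    if a == 0 and b == 0:
        return OREstimate(math.nan, math.nan, math.nan, a, b, n1, n2, ci_defined=False)
    point = (a / (n1 - a)) / (b / (n2 - b))
    se = math.sqrt(1 / a + 1 / (n1 - a) + 1 / b + 1 / (n2 - b))
    log_or = math.log(point)
    return OREstimate(
        point,
        math.exp(log_or - Z95 * se),
        math.exp(log_or + Z95 * se),
        a,
        b,
        n1,
        n2,
    )


def cross_db_table(
    rows1: list[TermRateRow], rows2: list[TermRateRow]
) -> list[tuple[str, OREstimate]]:
    """Per-term OR of db1 vs db2 over a shared kept term set."""
    by_term2 = {r.term: r for r in rows2}
    missing = [r.term for r in rows1 if r.term not in by_term2]
    if missing:
        raise ValueError(f"terms absent from db2 rows: {missing}")
    out = []
    for r1 in rows1:
        r2 = by_term2[r1.term]
        out.append((r1.term, odds_ratio(r1.n_cases, r1.n_total, r2.n_cases, r2.n_total)))
    return out


def cross_db_frame(pairs: list[tuple[str, OREstimate]]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "term": [t for t, _ in pairs],
            "n1": [e.a for _, e in pairs],
            "n2": [e.b for _, e in pairs],
            "or": [round(e.or_point, 2) if math.isfinite(e.or_point) else e.or_point for _, e in pairs],
            "ci_low": [round(e.ci_low, 2) if e.ci_defined else np.nan for _, e in pairs],
            "ci_high": [round(e.ci_high, 2) if e.ci_defined else np.nan for _, e in pairs],
            "dominance": [e.dominance for _, e in pairs],
        }
    )


@dataclass(frozen=True)
class CharacteristicTest:
    """2 x k test of one covariate's distribution across the two databases."""

    variable: str
    categories: tuple[str, ...]
    counts_db1: tuple[int, ...]
    counts_db2: tuple[int, ...]
    statistic: float
    df: int
    p_value: float
    method: str


def characteristic_test_from_counts(
    variable: str, counts1: pd.Series, counts2: pd.Series
) -> CharacteristicTest:
    """Chi-square (Fisher fallback for sparse 2x2) on aligned category counts.

    Categories absent from one database count as zero there; the ``missing``
    category is expected to have been excluded upstream.
    """
    cats = sorted(set(counts1.index) | set(counts2.index))
    cats = [c for c in cats if counts1.get(c, 0) + counts2.get(c, 0) > 0]
    if len(cats) < 2:
        raise ValueError(f"variable {variable!r} has <2 informative categories")
    table = np.array(
        [[int(counts1.get(c, 0)) for c in cats], [int(counts2.get(c, 0)) for c in cats]]
    )
    expected = stats.contingency.expected_freq(table)
    method = "chi_square"
    if (expected < 5).any() and table.shape == (2, 2):
        method = "fisher"
        stat, p = stats.fisher_exact(table)
        df = 1
    else:
        if (expected < 5).any():
            logger.warning(
                "%s: expected cell < 5 in a 2x%d table; keeping chi-square", variable, len(cats)
            )
        stat, p, df, _ = stats.chi2_contingency(table, correction=False)
    return CharacteristicTest(
        variable=variable,
        categories=tuple(cats),
        counts_db1=tuple(int(x) for x in table[0]),
        counts_db2=tuple(int(x) for x in table[1]),
        statistic=float(stat),
        df=int(df),
        p_value=float(p),
        method=method,
    )


def compare_characteristics(
    c1: ICSRCollection, c2: ICSRCollection, variable: str
) -> CharacteristicTest:
    """Test one covariate's marginal distribution in db1 vs db2.

    The ``missing`` category is excluded from both margins, matching the
    convention under which the published percentages are computed.
    """
    if c1.n_total == 0 or c2.n_total == 0:
        raise ValueError("both collections must be non-empty")
    counts1 = c1.covariate_counts(variable, include_missing=False)
    counts2 = c2.covariate_counts(variable, include_missing=False)
    return characteristic_test_from_counts(variable, counts1, counts2)
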