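"""Stratified reporting rates for the most-reported terms.

For one term and one stratification variable (sex, 3-level age, year,
vaccine type, schedule) the module tabulates per-stratum case counts,
stratum ICSR denominators and ARRs, and tests homogeneity of the case
proportion across strata.  Records missing the variable are excluded from
both numerator and denominator.  The test is Pearson chi-square without
continuity correction; when any expected cell drops below 5 it falls back
to Fisher's exact test (2x2) or to a Monte-Carlo permutation of the
chi-square statistic with margins fixed (larger tables, fixed seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .icsr import AGE3_LEVELS, MISSING, ICSRCollection
from .rates import TermRateRow, arr

VARIABLES = ("sex", "age3", "year", "vaccine_type", "schedule")
DEFAULT_YEARS = (2021, 2022, 2023)
MC_SAMPLES = 9999


@dataclass(frozen=True)
class Stratum:
    label: str
    n_cases: int
    n_denominator: int

    @property
    def arr(self) -> float:
        return arr(self.n_cases, self.n_denominator)


@dataclass(frozen=True)
class StratumTable:
    term: str
    variable: str
    strata: tuple[Stratum, ...]
    statistic: float
    p_value: float
    method: str  # chi_square | fisher | chi_square_mc


def top_terms(rows: list[TermRateRow], k: int = 20) -> list[str]:
    """The k most-reported terms; ties broken lexicographically."""
    if not rows:
        raise ValueError("no rate rows supplied")
    ranked = sorted(rows, key=lambda r: (-r.n_cases, r.term))
    return [r.term for r in ranked[:k]]


def _stratum_column(collection: ICSRCollection, variable: str, years) -> pd.Series:
    if variable == "age3":
        return collection.age3()
    if variable == "year":
        col = collection.frame["year"].astype(str)
        keep = {str(y) for y in years}
        return col.where(col.isin(keep), MISSING)
    if variable in ("sex", "vaccine_type", "schedule"):
        return collection.frame[variable]
    raise ValueError(f"unknown stratification variable {variable!r}")


def _stratum_order(variable: str, labels: set[str], years) -> list[str]:
    orders = {
        "sex": ("female", "male"),
        "age3": AGE3_LEVELS,
        "year": tuple(str(y) for y in years),
        "vaccine_type": ("mrna", "viral_vector", "protein_subunit", "inactivated"),
        "schedule": ("primer", "booster"),
    }
    return [s for s in orders[variable] if s in labels]


def stratify(
    collection: ICSRCollection,
    term: str,
    variable: str,
    scope: str = "any_position",
    years=DEFAULT_YEARS,
    mc_seed: int = 0,
) -> StratumTable:
    """Per-stratum counts, ARRs and a homogeneity test for one term.

    Strata with zero cases are listed but excluded from the test when more
    than two strata exist (a zero row cannot inform a rate comparison and
    would degenerate the expected counts); with only two strata the test
    keeps both.
    """
    strat = _stratum_column(collection, variable, years)
    informative = strat != MISSING
    labels = set(strat[informative])
    if len(labels) < 2:
        raise ValueError(f"variable {variable!r} has <2 informative strata")
    order = _stratum_order(variable, labels, years)

    case_mask = collection.term_mask(term, scope)
    strata = []
    for label in order:
        in_stratum = (strat == label).to_numpy()
        strata.append(
            Stratum(label, int((case_mask & in_stratum).sum()), int(in_stratum.sum()))
        )

    stat, p, method = stratum_test(strata, mc_seed=mc_seed)
    return StratumTable(term, variable, tuple(strata), stat, p, method)


def stratum_test(strata: list[Stratum], mc_seed: int = 0) -> tuple[float, float, str]:
    """Homogeneity test over a strata x (case, non-case) table."""
    tested = [s for s in strata if s.n_cases > 0] if len(strata) > 2 else list(strata)
    if len(tested) < 2:
        return float("nan"), 1.0, "chi_square"
    table = np.array([[s.n_cases, s.n_denominator - s.n_cases] for s in tested])
    expected = stats.contingency.expected_freq(table)
    if not (expected < 5).any():
        stat, p, _, _ = stats.chi2_contingency(table, correction=False)
        return float(stat), float(p), "chi_square"
    if table.shape[0] == 2:
        _, p = stats.fisher_exact(table)
        stat, _, _, _ = stats.chi2_contingency(table, correction=False)
        return float(stat), float(p), "fisher"
    return _chi_square_mc(table, mc_seed)


def _chi_square_mc(table: np.ndarray, seed: int) -> tuple[float, float, str]:
    # Condition on both margins: redistribute the case total across strata
    # by multivariate hypergeometric draws and compare chi-square statistics.
    stat_obs, _, _, _ = stats.chi2_contingency(table, correction=False)
    denominators = table.sum(axis=1)
    n_cases = int(table[:, 0].sum())
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5A11]))
    draws = rng.multivariate_hypergeometric(denominators, n_cases, size=MC_SAMPLES)
    exp_cases = denominators * n_cases / denominators.sum()
    exp_non = denominators - exp_cases
    non_cases = denominators[None, :] - draws
    with np.errstate(invalid="ignore"):
        stat_sim = ((draws - exp_cases) ** 2 / exp_cases).sum(axis=1) + (
            (non_cases - exp_non) ** 2 / exp_non
        ).sum(axis=1)
    p = (1 + int((stat_sim >= stat_obs - 1e-12).sum())) / (MC_SAMPLES + 1)
    return float(stat_obs), float(p), "chi_square_mc"


def subgroup_frame(tables: list[StratumTable]) -> pd.DataFrame:
    """Long-format view: one row per term x variable x stratum."""
    rows = []
    for t in tables:
        for s in t.strata:
            rows.append(
                {
                    "term": t.term,
                    "variable": t.variable,
                    "stratum": s.label,
                    "n_cases": s.n_cases,
                    "n_denominator": s.n_denominator,
                    "arr": round(s.arr, 3),
                    "p_value": t.p_value,
                    "method": t.method,
                }
            )
    return pd.DataFrame(rows)


def forest_frame(tables: list[StratumTable]) -> pd.DataFrame:
    """Plot-ready long format with per-stratum ARR and log-scale Wald CI."""
    rows = []
    for t in tables:
        for s in t.strata:
            if s.n_cases > 0:
                se = 1.0 / np.sqrt(s.n_cases)  # Poisson approximation on log rate
                low = s.arr * np.exp(-1.96 * se)
                high = s.arr * np.exp(1.96 * se)
            else:
                low = high = np.nan
            rows.append(
                {
                    "term": t.term,
                    "variable": t.variable,
                    "stratum": s.label,
                    "arr": round(s.arr, 3),
                    "ci_low": round(low, 3) if np.isfinite(low) else np.nan,
                    "ci_high": round(high, 3) if np.isfinite(high) else np.nan,
                }
            )
    return pd.DataFrame(rows)
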