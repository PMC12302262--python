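"""Hybrid frequentist + Bayesian signal-of-disproportionate-reporting (SDR) detection.

Within a multi-term spontaneous-reporting database that contains both
COVID-19-vaccine and comparator-vaccine reports, each adverse-event term is
summarised by a 2x2 table

    a = COVID-19 reports with the term      b = COVID-19 reports without it
    c = comparator reports with the term    d = comparator reports without it

and scored with three disproportionality statistics:

* PRR  = (a/(a+b)) / (c/(c+d)), the proportional reporting ratio, with a
  log-scale normal 95% CI, SE = sqrt(1/a - 1/(a+b) + 1/c - 1/(c+d));
* ROR  = ad/bc, the reporting odds ratio, Woolf CI,
  SE = sqrt(1/a + 1/b + 1/c + 1/d);
* IC   = log2((a + 1/2) / (E + 1/2)), the shrinkage information component
  with the expected count E = (a+c)(a+b)/N taken from the table margins
  (the analysis is confined to the vaccine-report database, so the
  within-table margins are the relevant reporting baseline).  Its lower
  2.5th-percentile credibility bound uses the standard two-term
  approximation IC025 = IC - 3.3 (a+1/2)^(-1/2) - 2 (a+1/2)^(-3/2).

A term is a signal (SDR = yes) only when all three agree:
PRR >= 2 with CI lower bound >= 1, ROR >= 2 with CI lower bound >= 1, and
IC > 0 with IC025 > 0.  Terms with too few reports in either vaccine class
for the metrics to be meaningful are disqualified rather than scored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .icsr import ICSRCollection
from .vocab import AETermFrame

Z95 = 1.96


@dataclass(frozen=True)
class ContingencyTable2x2:
    a: int  # term present, covid19
    b: int  # term absent, covid19
    c: int  # term present, comparator
    d: int  # term absent, comparator

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def expected_a(self) -> float:
        """Margin-based expectation of the observed count a."""
        if self.n == 0:
            raise ValueError("empty table")
        return (self.a + self.c) * (self.a + self.b) / self.n


@dataclass(frozen=True)
class MetricCI:
    point: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class SignalMetrics:
    """All disproportionality metrics and the composite SDR call for one term."""

    term: str
    table: ContingencyTable2x2
    prr: MetricCI | None
    ror: MetricCI | None
    ic: float | None
    ic025: float | None
    qualified: bool
    sdr: str  # yes | no | disqualified


def build_2x2(collection: ICSRCollection, term: str, scope: str = "any_position") -> ContingencyTable2x2:
    """Count the term-by-vaccine-class 2x2 table in a multi-term collection."""
    if collection.dialect != "multi_term":
        raise ValueError("disproportionality runs on the multi-term database")
    has_term = collection.term_mask(term, scope)
    covid = (collection.frame["vaccine_class"] == "covid19").to_numpy()
    a = int((has_term & covid).sum())
    c = int((has_term & ~covid).sum())
    return ContingencyTable2x2(a=a, b=int(covid.sum()) - a, c=c, d=int((~covid).sum()) - c)


def prr(t: ContingencyTable2x2) -> MetricCI | None:
    """Proportional reporting ratio with 95% CI; None when undefined (a or c = 0)."""
    if t.a == 0 or t.c == 0:
        return None
    point = (t.a / (t.a + t.b)) / (t.c / (t.c + t.d))
    se = math.sqrt(1 / t.a - 1 / (t.a + t.b) + 1 / t.c - 1 / (t.c + t.d))
    log_p = math.log(point)
    return MetricCI(point, math.exp(log_p - Z95 * se), math.exp(log_p + Z95 * se))


def ror(t: ContingencyTable2x2) -> MetricCI | None:
    """Reporting odds ratio with Woolf 95% CI; None when any cell is zero."""
    if min(t.a, t.b, t.c, t.d) == 0:
        return None
    point = (t.a * t.d) / (t.b * t.c)
    se = math.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)
    log_p = math.log(point)
    return MetricCI(point, math.exp(log_p - Z95 * se), math.exp(log_p + Z95 * se))


def information_component(t: ContingencyTable2x2) -> tuple[float, float]:
    """Shrinkage IC and its IC025 lower credibility bound."""
    e = t.expected_a  # raises on an empty table
    shrunk = t.a + 0.5
    ic = math.log2(shrunk / (e + 0.5))
    ic025 = ic - 3.3 * shrunk ** -0.5 - 2.0 * shrunk ** -1.5
    return ic, ic025


def qualify(t: ContingencyTable2x2, min_covid: int = 3, min_comparator: int = 1) -> bool:
    """Whether the table supports the three metrics at all.

    Requires at least ``min_covid`` exposed cases and ``min_comparator``
    comparator cases; with those present all three metrics are computable
    unless a non-case cell is empty (degenerate arm).
    """
    if t.a < min_covid or t.c < min_comparator:
        return False
    return prr(t) is not None and ror(t) is not None and t.n > 0


def classify_sdr(
    prr_m: MetricCI | None,
    ror_m: MetricCI | None,
    ic: float | None,
    ic025: float | None,
    qualified: bool = True,
) -> str:
    """Composite SDR rule: all of PRR, ROR and IC conditions must hold."""
    if not qualified:
        return "disqualified"
    assert prr_m is not None and ror_m is not None and ic is not None and ic025 is not None
    ok = (
        prr_m.point >= 2.0
        and prr_m.ci_low >= 1.0
        and ror_m.point >= 2.0
        and ror_m.ci_low >= 1.0
        and ic > 0.0
        and ic025 > 0.0
    )
    return "yes" if ok else "no"


def evaluate_term(
    collection: ICSRCollection,
    term: str,
    scope: str = "any_position",
    min_covid: int = 3,
    min_comparator: int = 1,
) -> SignalMetrics:
    t = build_2x2(collection, term, scope)
    q = qualify(t, min_covid, min_comparator)
    if not q:
        return SignalMetrics(term, t, None, None, None, None, False, "disqualified")
    prr_m = prr(t)
    ror_m = ror(t)
    ic, ic025 = information_component(t)
    return SignalMetrics(term, t, prr_m, ror_m, ic, ic025, True, classify_sdr(prr_m, ror_m, ic, ic025))


def signal_table(
    collection: ICSRCollection,
    frame: AETermFrame,
    scope: str = "any_position",
    min_covid: int = 3,
    min_comparator: int = 1,
    terms: list[str] | None = None,
) -> list[SignalMetrics]:
    terms = frame.terms if terms is None else terms
    return [
        evaluate_term(collection, term, scope, min_covid, min_comparator) for term in terms
    ]


def signals_frame(metrics: list[SignalMetrics]) -> pd.DataFrame:
    """Report layout with 2-decimal rounding of every metric."""

    def r2(x: float | None) -> float | None:
        return None if x is None else round(x, 2)

    return pd.DataFrame(
        {
            "term": [m.term for m in metrics],
            "a": [m.table.a for m in metrics],
            "b": [m.table.b for m in metrics],
            "c": [m.table.c for m in metrics],
            "d": [m.table.d for m in metrics],
            "prr": [r2(m.prr.point) if m.prr else None for m in metrics],
            "prr_low": [r2(m.prr.ci_low) if m.prr else None for m in metrics],
            "prr_high": [r2(m.prr.ci_high) if m.prr else None for m in metrics],
            "ror": [r2(m.ror.point) if m.ror else None for m in metrics],
            "ror_low": [r2(m.ror.ci_low) if m.ror else None for m in metrics],
            "ror_high": [r2(m.ror.ci_high) if m.ror else None for m in metrics],
            "ic": [r2(m.ic) for m in metrics],
            "ic025": [r2(m.ic025) for m in metrics],
            "sdr": [m.sdr for m in metrics],
        }
    )
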