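"""Absolute reporting ratios (ARR): cases per 1000 ICSRs, with rare-term trimming."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .icsr import ICSRCollection
from .vocab import AETermFrame


@dataclass(frozen=True)
class TermRateRow:
    term: str
    group: str
    n_cases: int
    n_total: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_cases <= self.n_total:
            raise ValueError(f"{self.term}: n_cases {self.n_cases} outside [0, {self.n_total}]")

    @property
    def arr(self) -> float:
        return arr(self.n_cases, self.n_total)


def arr(n_cases: int, n_total: int) -> float:
    """Reported cases per 1000 ICSRs."""
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    if not 0 <= n_cases <= n_total:
        raise ValueError("n_cases outside [0, n_total]")
    return 1000.0 * n_cases / n_total


def arr_table(
    collection: ICSRCollection, frame: AETermFrame, scope: str = "any_position"
) -> list[TermRateRow]:
    """One ARR row per vocabulary term, sorted by descending count then term."""
    n_total = collection.n_total
    rows = [
        TermRateRow(term, frame.entries[term], collection.term_case_count(term, scope), n_total)
        for term in frame.terms
    ]
    return sorted(rows, key=lambda r: (-r.n_cases, r.term))


def trim_rare(
    rows: list[TermRateRow], min_count: int = 3
) -> tuple[list[TermRateRow], list[TermRateRow]]:
    """Split rows into (kept, trimmed) by the minimum reporting count.

    Terms with fewer than ``min_count`` reports carry too little information
    for rate comparison and are set aside; both outputs keep input order.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    kept = [r for r in rows if r.n_cases >= min_count]
    trimmed = [r for r in rows if r.n_cases < min_count]
    return kept, trimmed


def rates_frame(rows1: list[TermRateRow], rows2: list[TermRateRow] | None = None) -> pd.DataFrame:
    """Tabular view: term, group, counts and 3-decimal ARRs per database."""
    df = pd.DataFrame(
        {
            "term": [r.term for r in rows1],
            "group": [r.group for r in rows1],
            "n_db1": [r.n_cases for r in rows1],
            "arr_db1": [round(r.arr, 3) for r in rows1],
        }
    )
    if rows2 is not None:
        by_term = {r.term: r for r in rows2}
        df["n_db2"] = [by_term[t].n_cases if t in by_term else pd.NA for t in df["term"]]
        df["arr_db2"] = [round(by_term[t].arr, 3) if t in by_term else pd.NA for t in df["term"]]
    return df
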