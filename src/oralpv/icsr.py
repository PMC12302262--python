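"""Data model and I/O for individual case safety report (ICSR) collections.

Two spontaneous-reporting dialects are supported:

* ``single_term`` — one preferred term per report (the "chief complaint"
  convention of the German PEI export);
* ``multi_term`` — up to five preferred terms per report plus a vaccine
  class (COVID-19 vs comparator), as in VAERS-style exports.

Collections are backed by a pandas DataFrame (one row per ICSR, terms in
columns ``term1``..``term5``) so that million-report databases stay cheap;
:class:`ICSRRecord` objects are materialised lazily.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from .vocab import normalize_term

logger = logging.getLogger(__name__)

MISSING = "missing"
SEX_LEVELS = ("female", "male")
AGE_LEVELS = ("under2", "2to6", "7to17", "18to59", "over59")
VACCINE_LEVELS = ("mrna", "viral_vector", "protein_subunit", "inactivated")
SCHEDULE_LEVELS = ("primer", "booster")
VACCINE_CLASSES = ("covid19", "comparator")
DIALECTS = ("single_term", "multi_term")
SCOPES = ("any_position", "primary_only")
MAX_TERMS = 5

#: three-level age regrouping used by the subgroup and regression stages
AGE3_MAP = {
    "under2": "minors",
    "2to6": "minors",
    "7to17": "minors",
    "18to59": "adults",
    "over59": "seniors",
}
AGE3_LEVELS = ("minors", "adults", "seniors")

COVARIATES = ("sex", "age_group", "vaccine_type", "schedule", "year")

_LEVELS = {
    "sex": SEX_LEVELS,
    "age_group": AGE_LEVELS,
    "vaccine_type": VACCINE_LEVELS,
    "schedule": SCHEDULE_LEVELS,
}

_TERM_COLS = tuple(f"term{i}" for i in range(1, MAX_TERMS + 1))
_SINGLE_COLS = ("report_id", "sex", "age_group", "vaccine_type", "schedule", "year", "term")
_MULTI_COLS = (
    "report_id",
    "sex",
    "age_group",
    "vaccine_type",
    "schedule",
    "year",
    "vaccine_class",
) + _TERM_COLS


class FormatError(ValueError):
    """Raised for structurally invalid ICSR tables (columns, empty file)."""


@dataclass(frozen=True)
class ICSRRecord:
    """One safety report: covariates plus an ordered list of preferred terms."""

    report_id: str
    sex: str
    age_group: str
    vaccine_type: str
    schedule: str
    year: int
    vaccine_class: str
    terms: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.terms:
            raise ValueError(f"record {self.report_id!r} has no terms")
        if len(self.terms) > MAX_TERMS:
            raise ValueError(f"record {self.report_id!r} exceeds {MAX_TERMS} terms")


class ICSRCollection:
    """A validated set of ICSRs sharing one reporting dialect."""

    def __init__(self, df: pd.DataFrame, dialect: str):
        if dialect not in DIALECTS:
            raise ValueError(f"unknown dialect {dialect!r}")
        missing_cols = [c for c in ("report_id", *COVARIATES, "vaccine_class", *_TERM_COLS) if c not in df.columns]
        if missing_cols:
            raise ValueError(f"collection frame lacks columns: {missing_cols}")
        if dialect == "single_term" and df[list(_TERM_COLS[1:])].notna().any().any():
            raise ValueError("single-term dialect admits exactly one term per record")
        if df["term1"].isna().any():
            raise ValueError("every record needs at least one term")
        self.dialect = dialect
        if not df.index.equals(pd.RangeIndex(len(df))):
            df = df.reset_index(drop=True)
        self._df = df

    # -- container basics -------------------------------------------------
    @property
    def n_total(self) -> int:
        return len(self._df)

    def __len__(self) -> int:
        return self.n_total

    @property
    def frame(self) -> pd.DataFrame:
        """The backing DataFrame (read-only by convention)."""
        return self._df

    @property
    def records(self) -> Iterator[ICSRRecord]:
        for row in self._df.itertuples(index=False):
            terms = tuple(t for t in (getattr(row, c) for c in _TERM_COLS) if isinstance(t, str))
            yield ICSRRecord(
                report_id=row.report_id,
                sex=row.sex,
                age_group=row.age_group,
                vaccine_type=row.vaccine_type,
                schedule=row.schedule,
                year=int(row.year),
                vaccine_class=row.vaccine_class,
                terms=terms,
            )

    @classmethod
    def from_records(cls, records: list[ICSRRecord], dialect: str) -> "ICSRCollection":
        rows = []
        for r in records:
            row = {
                "report_id": r.report_id,
                "sex": r.sex,
                "age_group": r.age_group,
                "vaccine_type": r.vaccine_type,
                "schedule": r.schedule,
                "year": r.year,
                "vaccine_class": r.vaccine_class,
            }
            for i, col in enumerate(_TERM_COLS):
                row[col] = r.terms[i] if i < len(r.terms) else None
            rows.append(row)
        df = pd.DataFrame(rows, columns=["report_id", *COVARIATES, "vaccine_class", *_TERM_COLS])
        return cls(df, dialect)

    # -- derived columns ---------------------------------------------------
    def age3(self) -> pd.Series:
        """Three-level age regrouping: minors (<18), adults (18-59), seniors (>59)."""
        return self._df["age_group"].map(AGE3_MAP).fillna(MISSING)

    def covariate_counts(self, variable: str, include_missing: bool = True) -> pd.Series:
        """Record counts per category of one covariate (or ``age3``)."""
        if variable == "age3":
            col = self.age3()
        elif variable in COVARIATES or variable == "vaccine_class":
            col = self._df[variable]
        else:
            raise ValueError(f"unknown variable {variable!r}")
        counts = col.value_counts(dropna=False)
        counts.index = counts.index.map(str)
        if not include_missing:
            counts = counts.drop(MISSING, errors="ignore")
        return counts

    # -- term counting -----------------------------------------------------
    def term_mask(self, term: str, scope: str = "any_position") -> np.ndarray:
        if scope not in SCOPES:
            raise ValueError(f"unknown scope {scope!r}")
        term = normalize_term(term)
        if scope == "primary_only" or self.dialect == "single_term":
            return (self._df["term1"] == term).to_numpy()
        mask = np.zeros(self.n_total, dtype=bool)
        for col in _TERM_COLS:
            mask |= (self._df[col] == term).to_numpy()
        return mask

    def term_case_count(self, term: str, scope: str = "any_position") -> int:
        """Number of reports carrying ``term`` (anywhere, or as primary symptom)."""
        return int(self.term_mask(term, scope).sum())

    def term_universe(self) -> list[str]:
        """All distinct preferred terms appearing in the collection."""
        terms: set[str] = set()
        for col in _TERM_COLS:
            terms.update(self._df[col].dropna().unique())
        return sorted(terms)

    def subset(self, mask: np.ndarray) -> "ICSRCollection":
        return ICSRCollection(self._df.loc[mask].reset_index(drop=True), self.dialect)


# ---------------------------------------------------------------------------
# readers / writers

def read_icsr_table(path: str | Path, dialect: str) -> ICSRCollection:
    """Read a dialect CSV into a validated collection.

    Unknown covariate codes fall back to ``missing`` (with a logged warning);
    rows without a usable report id, year or term are rejected and their
    1-based row numbers reported in the log.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    expected = _SINGLE_COLS if dialect == "single_term" else _MULTI_COLS
    try:
        raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file") from None
    for col in expected:
        if col not in raw.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    extra = [c for c in raw.columns if c not in expected]
    if extra:
        raise FormatError(f"{path}: unexpected columns for {dialect} dialect: {extra}")
    if len(raw) == 0:
        raise FormatError(f"{path}: no data rows")

    df = pd.DataFrame({"report_id": raw["report_id"].str.strip()})
    for var, levels in _LEVELS.items():
        col = raw[var].str.strip().str.lower()
        bad = ~col.isin(levels + (MISSING, ""))
        if bad.any():
            logger.warning(
                "%s: %d rows with unknown %s values mapped to missing", path, int(bad.sum()), var
            )
        df[var] = col.where(col.isin(levels), MISSING)
    year = pd.to_numeric(raw["year"].str.strip(), errors="coerce")

    if dialect == "single_term":
        df["vaccine_class"] = "covid19"
        term_lists = raw["term"].map(lambda t: [normalize_term(t)] if t.strip() else [])
    else:
        vc = raw["vaccine_class"].str.strip().str.lower()
        bad_vc = ~vc.isin(VACCINE_CLASSES)
        if bad_vc.any():
            logger.warning("%s: %d rows with unknown vaccine_class treated as covid19", path, int(bad_vc.sum()))
        df["vaccine_class"] = vc.where(vc.isin(VACCINE_CLASSES), "covid19")
        stacked = raw[list(_TERM_COLS)].apply(lambda s: s.str.strip())
        term_lists = stacked.apply(lambda r: [normalize_term(t) for t in r if t], axis=1)

    malformed = (df["report_id"] == "") | year.isna() | (term_lists.str.len() == 0)
    if malformed.any():
        rows = [int(i) + 2 for i in malformed[malformed].index]  # +2: header + 1-based
        logger.warning("%s: rejected %d malformed rows (rows %s)", path, len(rows), rows)
    df["year"] = year.fillna(0).astype(int)
    for i, col in enumerate(_TERM_COLS):
        df[col] = term_lists.map(lambda ts, i=i: ts[i] if i < len(ts) else None)
    df = df.loc[~malformed].reset_index(drop=True)
    if len(df) == 0:
        raise FormatError(f"{path}: no valid rows")
    return ICSRCollection(df, dialect)


def write_icsr_table(collection: ICSRCollection, path: str | Path) -> None:
    """Write a collection back to its dialect CSV layout."""
    df = collection.frame
    if collection.dialect == "single_term":
        out = df[list(_SINGLE_COLS[:-1])].copy()
        out["term"] = df["term1"]
    else:
        out = df[list(_MULTI_COLS)].copy()
        out[list(_TERM_COLS)] = out[list(_TERM_COLS)].fillna("")
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# duplicate merging

def merge_duplicates(collection: ICSRCollection) -> ICSRCollection:
    """Collapse reports sharing a report id into one record.

    Covariate conflicts resolve to the first non-missing value (else the
    first occurrence); term lists are unioned in first-seen order and
    truncated to the dialect bound, keeping the primary term.  Idempotent.
    """
    df = collection.frame
    if df["report_id"].is_unique:
        return collection

    first_idx = ~df["report_id"].duplicated()
    merged = df.loc[first_idx].copy()
    merged_pos = {rid: i for i, rid in enumerate(merged["report_id"])}

    dup_ids = set(df.loc[df["report_id"].duplicated(), "report_id"])
    limit = 1 if collection.dialect == "single_term" else MAX_TERMS
    for rid, chunk in df[df["report_id"].isin(dup_ids)].groupby("report_id", sort=False):
        pos = merged_pos[rid]
        for var in ("sex", "age_group", "vaccine_type", "schedule"):
            vals = [v for v in chunk[var] if v != MISSING]
            if vals:
                merged.iloc[pos, merged.columns.get_loc(var)] = vals[0]
        terms: list[str] = []
        for row in chunk[list(_TERM_COLS)].itertuples(index=False):
            for t in row:
                if isinstance(t, str) and t not in terms:
                    terms.append(t)
        terms = terms[:limit]
        for i, col in enumerate(_TERM_COLS):
            merged.iloc[pos, merged.columns.get_loc(col)] = terms[i] if i < len(terms) else None
    return ICSRCollection(merged.reset_index(drop=True), collection.dialect)
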