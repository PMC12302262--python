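"""Oral adverse-event vocabulary.

Preferred terms (MedDRA-style PT strings) are organised by an
anatomo-physiological framework of the oral cavity: anatomical regions
(lips, palate, tongue, dentition, salivary glands, oral mucosa) plus the
two oral functions (taste, other sensation).  A small list of exclusion
keywords removes terms that contain oral-anatomy words but are not
plausible vaccine adverse events (contraceptives, congenital
malformations, oncology).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

GROUPS = (
    "taste",
    "sensation",
    "lips",
    "palate",
    "tongue",
    "dentition",
    "salivary_glands",
    "oral_mucosa",
)

_WS = re.compile(r"\s+")


def normalize_term(term: str) -> str:
    """Lowercase, trim and collapse internal whitespace of a preferred term."""
    return _WS.sub(" ", term.strip().lower())


@dataclass(frozen=True)
class AETermFrame:
    """Vocabulary of oral AE preferred terms with their anatomical group.

    ``entries`` maps a normalized preferred term to one of :data:`GROUPS`;
    ``exclusion_keywords`` are case-insensitive substrings that veto a term.
    """

    entries: dict[str, str]
    exclusion_keywords: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        for term, group in self.entries.items():
            if group not in GROUPS:
                raise ValueError(f"unknown group {group!r} for term {term!r}")
            if self.is_excluded(term):
                raise ValueError(f"vocabulary entry {term!r} matches an exclusion keyword")

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, term: str) -> bool:
        return normalize_term(term) in self.entries

    def group_of(self, term: str) -> str:
        return self.entries[normalize_term(term)]

    @property
    def terms(self) -> list[str]:
        return list(self.entries)

    def is_excluded(self, term: str) -> bool:
        t = normalize_term(term)
        return any(kw in t for kw in self.exclusion_keywords)

    @classmethod
    def from_csv(cls, path: str | Path, exclusions_path: str | Path | None = None) -> "AETermFrame":
        df = pd.read_csv(path)
        if not {"term", "group"}.issubset(df.columns):
            raise ValueError("term frame CSV requires columns: term, group")
        entries = {normalize_term(t): g for t, g in zip(df["term"], df["group"])}
        keywords: tuple[str, ...] = ()
        if exclusions_path is not None:
            keywords = _read_keywords(Path(exclusions_path).read_text(encoding="utf-8"))
        return cls(entries=entries, exclusion_keywords=keywords)


def _read_keywords(text: str) -> tuple[str, ...]:
    out = []
    for line in text.splitlines():
        line = line.strip().lower()
        if line and not line.startswith("#"):
            out.append(line)
    return tuple(out)


def load_default_frame() -> AETermFrame:
    """The packaged 80-term oral-AE vocabulary (60 tabulated + 20 rare terms)."""
    pkg = resources.files("oralpv.data")
    df = pd.read_csv(pkg / "term_groups.csv")
    keywords = _read_keywords((pkg / "exclusion_keywords.txt").read_text(encoding="utf-8"))
    return AETermFrame(
        entries={normalize_term(t): g for t, g in zip(df["term"], df["group"])},
        exclusion_keywords=keywords,
    )


def classify_oral_terms(term_universe: list[str], frame: AETermFrame) -> list[tuple[str, str]]:
    """Select oral-cavity terms from a term universe.

    Returns ``(term, group)`` pairs for universe terms present in ``frame``,
    dropping any term that matches an exclusion keyword (case-insensitive
    substring).  Output is sorted by term and de-duplicated.
    """
    if not frame.entries:
        raise ValueError("term frame is empty")
    hits: dict[str, str] = {}
    for raw in term_universe:
        term = normalize_term(raw)
        if term in frame.entries and not frame.is_excluded(term):
            hits[term] = frame.entries[term]
    return sorted(hits.items())
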