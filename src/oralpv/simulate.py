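"""Synthetic paired ICSR databases with known ground truth.

The generator emulates the structure of the two real reporting systems the
pipeline targets: a single-term "chief complaint" database (db1, PEI-like)
and a multi-term database with a comparator-vaccine arm (db2, VAERS-like).
Covariates are drawn independently from configurable marginals (with an
explicit ``missing`` category); each oral term is included on a report with
probability logistic(logit(base rate) + covariate log-odds offsets), terms
independently of each other; comparator-arm reports use flat per-term
rates with no covariate effects.  Reports that draw no oral term carry a
generic filler symptom so denominators contain non-cases, as in real
spontaneous-reporting data.

Everything is deterministic given (config, seed).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

from . import reference_data
from .icsr import COVARIATES, ICSRCollection, MISSING
from .vocab import load_default_frame, normalize_term

#: generic non-oral reactogenicity symptoms used as filler terms
FILLER_TERMS = (
    "headache",
    "pyrexia",
    "fatigue",
    "chills",
    "injection site pain",
    "nausea",
    "dizziness",
)

EFFECT_KEYS = ("female", "minors", "seniors", "viral_vector", "protein_subunit", "booster")

_MARGINAL_VARS = ("sex", "age_group", "vaccine_type", "schedule", "year")


class SimConfig(BaseModel):
    """Ground-truth parameters for one paired-database simulation."""

    n_reports_db1: int = Field(ge=1)
    n_reports_db2: int = Field(ge=1)
    covariate_marginals: dict[str, dict[str, dict[str, float]]]
    term_rates: dict[str, float]  # per 1000 reports
    covariate_effects: dict[str, dict[str, float]] = Field(default_factory=dict)
    comparator_fraction: float = Field(default=0.25, ge=0.0, lt=1.0)
    comparator_term_rates: dict[str, float] = Field(default_factory=dict)
    max_terms_db2: int = Field(default=5, ge=1, le=5)
    seed: int = 0

    @field_validator("term_rates", "comparator_term_rates")
    @classmethod
    def _rates_valid(cls, v: dict[str, float]) -> dict[str, float]:
        for term, rate in v.items():
            if not 0.0 <= rate <= 1000.0:
                raise ValueError(f"rate for {term!r} outside [0, 1000] per 1000")
        return {normalize_term(t): r for t, r in v.items()}

    @field_validator("covariate_effects")
    @classmethod
    def _effects_valid(cls, v):
        for term, effects in v.items():
            bad = set(effects) - set(EFFECT_KEYS)
            if bad:
                raise ValueError(f"unknown effect keys for {term!r}: {sorted(bad)}")
        return {normalize_term(t): e for t, e in v.items()}

    @model_validator(mode="after")
    def _marginals_valid(self) -> "SimConfig":
        for db in ("db1", "db2"):
            if db not in self.covariate_marginals:
                raise ValueError(f"covariate_marginals lacks {db!r}")
            for var in _MARGINAL_VARS:
                probs = self.covariate_marginals[db].get(var)
                if not probs:
                    raise ValueError(f"{db}: no marginal for {var!r}")
                vals = np.array(list(probs.values()), dtype=float)
                if (vals < 0).any() or (vals > 1).any():
                    raise ValueError(f"{db}/{var}: probabilities outside [0, 1]")
                if abs(vals.sum() - 1.0) > 1e-9:
                    raise ValueError(f"{db}/{var}: probabilities sum to {vals.sum()}, not 1")
        return self


def _logit(p: float) -> float:
    return float(np.log(p / (1.0 - p)))


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def generate_database(cfg: SimConfig, which: str, seed: int | None = None) -> ICSRCollection:
    """Draw one synthetic database (``db1`` single-term, ``db2`` multi-term)."""
    if which not in ("db1", "db2"):
        raise ValueError(f"which must be db1 or db2, got {which!r}")
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0 if which == "db1" else 1]))
    n = cfg.n_reports_db1 if which == "db1" else cfg.n_reports_db2

    columns: dict[str, np.ndarray] = {
        "report_id": np.char.add(f"{which}-", np.arange(n).astype(str)).astype(object)
    }
    marginals = cfg.covariate_marginals[which]
    for var in _MARGINAL_VARS:
        cats = list(marginals[var])
        probs = np.array([marginals[var][c] for c in cats], dtype=float)
        codes = rng.choice(len(cats), size=n, p=probs / probs.sum())
        if var == "year":
            columns[var] = np.array([int(c) for c in cats])[codes]
        else:
            columns[var] = np.array(cats, dtype=object)[codes]

    if which == "db2" and cfg.comparator_fraction > 0:
        comparator = rng.random(n) < cfg.comparator_fraction
    else:
        comparator = np.zeros(n, dtype=bool)
    columns["vaccine_class"] = np.where(comparator, "comparator", "covid19").astype(object)

    filler = np.array(FILLER_TERMS, dtype=object)[rng.choice(len(FILLER_TERMS), size=n)]
    filler_first = rng.random(n) < 0.5  # whether a non-oral symptom leads the list

    age = columns["age_group"]
    effect_masks = {
        "female": columns["sex"] == "female",
        "minors": (age == "under2") | (age == "2to6") | (age == "7to17"),
        "seniors": age == "over59",
        "viral_vector": columns["vaccine_type"] == "viral_vector",
        "protein_subunit": columns["vaccine_type"] == "protein_subunit",
        "booster": columns["schedule"] == "booster",
    }

    oral_lists: dict[int, list[str]] = {}
    primary = np.full(n, None, dtype=object)
    for term, rate in cfg.term_rates.items():
        base = rate / 1000.0
        u = rng.random(n)  # drawn unconditionally to keep the stream term-aligned
        if base <= 0.0 and not (which == "db2" and cfg.comparator_term_rates.get(term, 0) > 0):
            continue
        if base >= 1.0:
            p = np.full(n, 1.0)
        elif base <= 0.0:
            p = np.zeros(n)
        else:
            eta = np.full(n, _logit(base))
            for key, offset in cfg.covariate_effects.get(term, {}).items():
                eta[effect_masks[key]] += offset
            p = _expit(eta)
        if which == "db2":
            comp_rate = cfg.comparator_term_rates.get(term, rate) / 1000.0
            p = np.where(comparator, comp_rate, p)
        included = np.flatnonzero(u < p)
        if which == "db1":
            sel = included[pd.isnull(primary[included])]
            primary[sel] = term
        else:
            for i in included:
                oral_lists.setdefault(int(i), []).append(term)

    term_cols = {f"term{k}": np.full(n, None, dtype=object) for k in range(1, 6)}
    if which == "db1":
        term_cols["term1"] = np.where(pd.isnull(primary), filler, primary)
    else:
        term_cols["term1"] = filler.astype(object).copy()
        for i, terms in oral_lists.items():
            full = [filler[i], *terms] if filler_first[i] else [*terms, filler[i]]
            full = full[: cfg.max_terms_db2]
            for k, t in enumerate(full):
                term_cols[f"term{k + 1}"][i] = t
    columns.update(term_cols)
    df = pd.DataFrame(
        {c: columns[c] for c in ("report_id", *COVARIATES, "vaccine_class", *term_cols)},
        copy=False,
    )
    dialect = "single_term" if which == "db1" else "multi_term"
    return ICSRCollection(df, dialect)


# ---------------------------------------------------------------------------
# default configuration reproducing the published study conditions

def _marginals_from_reference(database: str) -> dict[str, dict[str, float]]:
    total = reference_data.db_totals()[database]
    out: dict[str, dict[str, float]] = {}
    for var in ("sex", "age_group", "vaccine_type", "schedule"):
        counts = reference_data.marginal_counts(database, var, include_missing=True)
        p_missing = counts.get(MISSING, 0) / total
        non_missing = counts.drop(MISSING, errors="ignore")
        probs = {
            cat: float((c / non_missing.sum()) * (1.0 - p_missing))
            for cat, c in non_missing.items()
        }
        if p_missing > 0:
            probs[MISSING] = float(p_missing)
        out[var] = _close_to_one(probs)
    years = reference_data.marginal_counts(database, "year", include_missing=False)
    out["year"] = _close_to_one({str(y): float(c / years.sum()) for y, c in years.items()})
    return out


def _close_to_one(probs: dict[str, float]) -> dict[str, float]:
    # absorb float residue into the largest category so sums are exactly 1
    top = max(probs, key=probs.get)
    probs[top] += 1.0 - sum(probs.values())
    return probs


RARE_TERM_RATE = 0.001  # per 1000; keeps the 20 rare vocabulary terms below trim


def default_reference_config(seed: int = 0) -> SimConfig:
    """Simulation matched to the published study conditions.

    Marginals reproduce the tabulated covariate distributions of both
    databases (missing explicit, category shares conditional on
    non-missing); per-term base rates are the published single-term-database
    ARRs; the 20 rare vocabulary terms get a sub-trim rate.  The comparator
    arm is 25% of db2 (db2 is scaled so its COVID-19 arm matches the
    published total) with per-term comparator rates equal to base rate /
    published PRR, preserving each term's observed reporting-rate ratio.
    """
    totals = reference_data.db_totals()
    metrics = reference_data.load_term_metrics()
    comparator_fraction = 0.25
    term_rates = {
        t: 1000.0 * n / totals["pei"] for t, n in zip(metrics["term"], metrics["n_pei"])
    }
    for term in load_default_frame().terms:
        term_rates.setdefault(term, RARE_TERM_RATE)
    comparator_rates = {}
    for row in metrics.itertuples(index=False):
        rate = term_rates[row.term]
        comparator_rates[row.term] = rate / row.prr if np.isfinite(row.prr) else rate
    return SimConfig(
        n_reports_db1=totals["pei"],
        n_reports_db2=round(totals["vaers"] / (1.0 - comparator_fraction)),
        covariate_marginals={
            "db1": _marginals_from_reference("pei"),
            "db2": _marginals_from_reference("vaers"),
        },
        term_rates=term_rates,
        comparator_fraction=comparator_fraction,
        comparator_term_rates=comparator_rates,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# config serialization

def save_config(cfg: SimConfig, path: str | Path) -> None:
    path = Path(path)
    payload = cfg.model_dump()
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(payload, sort_keys=False), encoding="utf-8")
    else:
        path.write_text(json.dumps(payload, indent=2), encoding="utf-8")


def load_config(path: str | Path) -> SimConfig:
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    payload = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
    return SimConfig.model_validate(payload)
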