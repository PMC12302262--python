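"""Published reference counts for the PEI / VAERS oral-AE analysis.

The package ships three small CSV transcriptions of the published summary
tables of the national pharmacovigilance analysis of oral adverse events
after COVID-19 vaccination (PEI, Germany, Dec 2020 - Dec 2023; VAERS, USA,
Dec 2020 - Oct 2024):

* ``db_characteristics.csv`` — marginal covariate counts per database,
  including the explicitly tabulated ``missing`` category;
* ``oral_ae_metrics.csv`` — per-term case counts with the published ARR,
  cross-database OR, PRR/ROR/IC metrics and SDR call;
* ``pei_subgroup_counts.csv`` — stratified PEI case counts for the top-20
  terms (sex, 3-level age, year, vaccine type, schedule).

These serve as desk-scale inputs for re-deriving the published numbers;
they are data transcribed from print, not computed by this package.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import numpy as np
import pandas as pd

DATABASES = ("pei", "vaers")


def _data(name: str):
    return resources.files("oralpv.data") / name


@lru_cache(maxsize=None)
def load_db_characteristics() -> pd.DataFrame:
    df = pd.read_csv(_data("db_characteristics.csv"), dtype={"pct_printed": str})
    df["count"] = df["count"].astype(int)
    return df


@lru_cache(maxsize=None)
def db_totals() -> dict[str, int]:
    df = load_db_characteristics()
    rows = df[df["variable"] == "total"]
    return dict(zip(rows["database"], rows["count"]))


def marginal_counts(database: str, variable: str, include_missing: bool = True) -> pd.Series:
    """Category -> count for one covariate in one database."""
    if database not in DATABASES:
        raise ValueError(f"unknown database {database!r}")
    df = load_db_characteristics()
    rows = df[(df["database"] == database) & (df["variable"] == variable)]
    if rows.empty:
        raise ValueError(f"no counts for variable {variable!r} in {database}")
    s = pd.Series(rows["count"].to_numpy(), index=rows["category"].to_numpy())
    if not include_missing:
        s = s.drop("missing", errors="ignore")
    return s


def stratum_denominators(variable: str, database: str = "pei") -> pd.Series:
    """Stratum ICSR totals used as ARR denominators (missing excluded).

    ``age3`` sums the three under-18 brackets into ``minors``.
    """
    if variable == "age3":
        counts = marginal_counts(database, "age_group", include_missing=False)
        return pd.Series(
            {
                "minors": int(counts[["under2", "2to6", "7to17"]].sum()),
                "adults": int(counts["18to59"]),
                "seniors": int(counts["over59"]),
            }
        )
    return marginal_counts(database, variable, include_missing=False)


@lru_cache(maxsize=None)
def load_term_metrics() -> pd.DataFrame:
    """Per-term published counts and metrics (60 tabulated terms).

    The ``or_`` column parses the printed infinity symbol to ``numpy.inf``.
    """
    df = pd.read_csv(_data("oral_ae_metrics.csv"))
    df = df.rename(columns={"or": "or_"})
    df["or_"] = df["or_"].replace("inf", np.inf).astype(float)
    return df


@lru_cache(maxsize=None)
def load_subgroup_counts() -> pd.DataFrame:
    df = pd.read_csv(_data("pei_subgroup_counts.csv"), dtype={"stratum": str, "arr_printed": str})
    df["n_cases"] = df["n_cases"].astype(int)
    return df


def printed_decimal_tolerance(printed: str) -> float:
    """Half a unit in the last printed decimal place (e.g. '0.43' -> 0.005)."""
    if "." not in printed:
        return 0.5
    return 0.5 * 10 ** -len(printed.split(".")[1])
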