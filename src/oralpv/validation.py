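"""Re-derivation of the published summary numbers from the packaged counts.

Every check here recomputes a published quantity (ARR, cross-database OR,
SDR call, covariate percentage, stratified ARR) from raw counts through the
package's own functions and compares it with the printed value at its
printed precision.  This is the substance behind the ``oralpv validate``
command.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from . import reference_data
from .crossdb import odds_ratio
from .rates import arr
from .signals import MetricCI, classify_sdr


def recompute_rate_table() -> pd.DataFrame:
    """Published per-term ARRs recomputed from counts, for both databases."""
    totals = reference_data.db_totals()
    m = reference_data.load_term_metrics()
    out = m[["term", "n_pei", "arr_pei", "n_vaers", "arr_vaers"]].copy()
    out["arr_pei_calc"] = [round(arr(n, totals["pei"]), 3) for n in m["n_pei"]]
    out["arr_vaers_calc"] = [round(arr(n, totals["vaers"]), 3) for n in m["n_vaers"]]
    out["ok"] = (abs(out["arr_pei_calc"] - out["arr_pei"]) < 1e-9) & (
        abs(out["arr_vaers_calc"] - out["arr_vaers"]) < 1e-9
    )
    return out


def recompute_or_table() -> pd.DataFrame:
    """Published cross-database ORs recomputed from counts and totals."""
    totals = reference_data.db_totals()
    m = reference_data.load_term_metrics()
    rows = []
    for r in m.itertuples(index=False):
        est = odds_ratio(int(r.n_pei), totals["pei"], int(r.n_vaers), totals["vaers"])
        calc = round(est.or_point, 2) if math.isfinite(est.or_point) else est.or_point
        ok = calc == r.or_ if math.isfinite(r.or_) else math.isinf(calc)
        if est.ci_defined and np.isfinite(r.or_low):
            ok = ok and round(est.ci_low, 2) == r.or_low and round(est.ci_high, 2) == r.or_high
        rows.append(
            {
                "term": r.term,
                "or_printed": r.or_,
                "or_calc": calc,
                "ci_low_calc": round(est.ci_low, 2) if est.ci_defined else np.nan,
                "ci_high_calc": round(est.ci_high, 2) if est.ci_defined else np.nan,
                "ok": bool(ok),
            }
        )
    return pd.DataFrame(rows)


def classify_printed_metrics() -> pd.DataFrame:
    """SDR rule applied to the published PRR/ROR/IC values, row by row."""
    m = reference_data.load_term_metrics()
    rows = []
    for r in m.itertuples(index=False):
        qualified = not pd.isna(r.prr)
        if qualified:
            sdr = classify_sdr(
                MetricCI(r.prr, r.prr_low, r.prr_high),
                MetricCI(r.ror, r.ror_low, r.ror_high),
                r.ic,
                r.ic025,
            )
        else:
            sdr = classify_sdr(None, None, None, None, qualified=False)
        rows.append({"term": r.term, "sdr_printed": r.sdr, "sdr_calc": sdr, "ok": sdr == r.sdr})
    return pd.DataFrame(rows)


def characteristics_percentages() -> pd.DataFrame:
    """Covariate percentages under the missing-excluded convention vs printed.

    Non-missing categories are expressed as a share of the non-missing
    total; the ``missing`` share uses the full database total.  Printed
    values are compared at their printed precision.
    """
    df = reference_data.load_db_characteristics()
    totals = reference_data.db_totals()
    rows = []
    for (db, var), chunk in df[df["variable"] != "total"].groupby(["database", "variable"]):
        non_missing = chunk.loc[chunk["category"] != "missing", "count"].sum()
        for r in chunk.itertuples(index=False):
            denom = totals[db] if r.category == "missing" else non_missing
            pct = 100.0 * r.count / denom
            printed = r.pct_printed
            if isinstance(printed, str) and printed.startswith("<"):
                ok = pct < float(printed[1:])
                tol = np.nan
            else:
                tol = reference_data.printed_decimal_tolerance(printed)
                ok = abs(pct - float(printed)) <= tol + 1e-12
            rows.append(
                {
                    "database": db,
                    "variable": var,
                    "category": r.category,
                    "pct_calc": pct,
                    "pct_printed": printed,
                    "ok": bool(ok),
                }
            )
    return pd.DataFrame(rows)


def recompute_subgroup_arrs() -> pd.DataFrame:
    """Stratified ARRs for the top terms recomputed from counts and denominators."""
    sub = reference_data.load_subgroup_counts()
    rows = []
    for (variable,), chunk in sub.groupby(["variable"]):
        denoms = reference_data.stratum_denominators(variable)
        for r in chunk.itertuples(index=False):
            calc = arr(int(r.n_cases), int(denoms[r.stratum]))
            tol = reference_data.printed_decimal_tolerance(r.arr_printed)
            rows.append(
                {
                    "term": r.term,
                    "variable": variable,
                    "stratum": r.stratum,
                    "n_cases": r.n_cases,
                    "denominator": int(denoms[r.stratum]),
                    "arr_calc": calc,
                    "arr_printed": r.arr_printed,
                    "ok": abs(calc - float(r.arr_printed)) <= tol + 1e-12,
                }
            )
    return pd.DataFrame(rows)


def validate_all() -> dict[str, pd.DataFrame]:
    """All re-derivation tables, keyed by check name."""
    return {
        "rates": recompute_rate_table(),
        "odds_ratios": recompute_or_table(),
        "sdr_classification": classify_printed_metrics(),
        "characteristics": characteristics_percentages(),
        "subgroup_arrs": recompute_subgroup_arrs(),
    }
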