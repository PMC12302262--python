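"""Per-term multivariable logistic regression.

Outcome: the term was reported on an ICSR (vs not); predictors: sex, age
group (3-level), vaccine type and vaccine schedule, dummy-coded against
the references male / adults 18-59 / mRNA / primer series.  Reports with
any predictor missing are dropped listwise; comparator-vaccine reports are
excluded (the model describes COVID-19-vaccine reporting only).  Predictor
levels with zero cases are unestimable (the MLE diverges) and are recorded
as suppressed instead of entering the design.

The fit is plain maximum likelihood via iteratively reweighted least
squares (IRLS): converged when the largest absolute coefficient change
falls below 1e-8, capped at 100 iterations.  Confidence intervals are Wald
intervals from the observed information.  Quasi-complete separation is
detected (runaway coefficients) and flagged rather than penalised.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .icsr import AGE3_MAP, MISSING, ICSRCollection

Z95 = 1.96
MAX_ITER = 100
TOL = 1e-8
SEPARATION_COEF = 15.0  # |log-odds| beyond this is numerically degenerate

#: contrast name -> (source column, level); order fixes the report layout
CONTRASTS = {
    "female": ("sex", "female"),
    "minors": ("age3", "minors"),
    "seniors": ("age3", "seniors"),
    "viral_vector": ("vaccine_type", "viral_vector"),
    "protein_subunit": ("vaccine_type", "protein_subunit"),
    "inactivated": ("vaccine_type", "inactivated"),
    "booster": ("schedule", "booster"),
}


@dataclass(frozen=True)
class Design:
    term: str
    X: np.ndarray  # n_used x (1 + len(columns)), intercept first
    y: np.ndarray
    columns: tuple[str, ...]
    n_used: int
    suppressed_levels: tuple[str, ...]


@dataclass(frozen=True)
class RegressionFit:
    term: str
    coefficients: dict[str, tuple[float, float]]  # level -> (estimate, se)
    aor: dict[str, tuple[float, float, float] | None]  # level -> (point, lo, hi)
    n_used: int
    converged: bool
    suppressed_levels: tuple[str, ...] = field(default_factory=tuple)
    log_likelihood: float = float("nan")


def build_design(collection: ICSRCollection, term: str, scope: str = "any_position") -> Design:
    """Dummy-coded design matrix for one term's reporting model."""
    df = collection.frame
    y_all = collection.term_mask(term, scope)

    keep = (df["vaccine_class"] == "covid19").to_numpy()
    preds = pd.DataFrame(
        {
            "sex": df["sex"],
            "age3": df["age_group"].map(AGE3_MAP).fillna(MISSING),
            "vaccine_type": df["vaccine_type"],
            "schedule": df["schedule"],
        }
    )
    keep &= (preds != MISSING).all(axis=1).to_numpy()

    y = y_all[keep].astype(float)
    preds = preds.loc[keep]
    if y.sum() == 0:
        raise ValueError(f"term {term!r} has no cases after listwise deletion")

    cols: list[str] = []
    dummies: list[np.ndarray] = []
    suppressed: list[str] = []
    for name, (var, level) in CONTRASTS.items():
        x = (preds[var] == level).to_numpy(dtype=float)
        if x.sum() == 0:
            continue  # level absent from the data: no contrast to report
        if y[x == 1].sum() == 0:
            suppressed.append(name)
            continue
        cols.append(name)
        dummies.append(x)
    X = np.column_stack([np.ones(len(y)), *dummies]) if dummies else np.ones((len(y), 1))
    return Design(term, X, y, tuple(cols), int(len(y)), tuple(suppressed))


def _irls(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, bool, list[float]]:
    beta = np.zeros(X.shape[1])
    ll_path: list[float] = []
    converged = False
    for _ in range(MAX_ITER):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        ll_path.append(float(np.sum(y * np.log(mu + 1e-300) + (1 - y) * np.log(1 - mu + 1e-300))))
        w = mu * (1 - mu)
        # Newton step on the working response; ridge epsilon guards singular XtWX
        xtw = X.T * w
        hess = xtw @ X + 1e-10 * np.eye(X.shape[1])
        grad = X.T @ (y - mu)
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.max(np.abs(step)) < TOL:
            converged = True
            break
    eta = np.clip(X @ beta, -30, 30)
    mu = 1.0 / (1.0 + np.exp(-eta))
    ll_path.append(float(np.sum(y * np.log(mu + 1e-300) + (1 - y) * np.log(1 - mu + 1e-300))))
    w = mu * (1 - mu)
    cov = np.linalg.inv(X.T * w @ X + 1e-10 * np.eye(X.shape[1]))
    se = np.sqrt(np.diag(cov))
    return beta, se, converged, ll_path


def fit_logistic(design: Design) -> RegressionFit:
    """Maximum-likelihood fit of the design; flags separation instead of failing."""
    if design.y.sum() == 0:
        raise ValueError("zero cases in design")
    if design.y.sum() == len(design.y):
        raise ValueError("zero non-cases in design")
    beta, se, converged, ll_path = _irls(design.X, design.y)

    coefficients: dict[str, tuple[float, float]] = {}
    aor: dict[str, tuple[float, float, float] | None] = {}
    separated = False
    for j, name in enumerate(design.columns, start=1):
        est, s = float(beta[j]), float(se[j])
        coefficients[name] = (est, s)
        if abs(est) > SEPARATION_COEF or est + Z95 * s > 700:
            aor[name] = None
            separated = True
        else:
            aor[name] = (np.exp(est), np.exp(est - Z95 * s), np.exp(est + Z95 * s))
    return RegressionFit(
        term=design.term,
        coefficients=coefficients,
        aor=aor,
        n_used=design.n_used,
        converged=converged and not separated,
        suppressed_levels=design.suppressed_levels,
        log_likelihood=ll_path[-1],
    )


def fit_term(collection: ICSRCollection, term: str, scope: str = "any_position") -> RegressionFit:
    return fit_logistic(build_design(collection, term, scope))


def is_significant(ci: tuple[float, float, float]) -> bool:
    return not (ci[1] <= 1.0 <= ci[2])


def aor_frame(fits: list[RegressionFit]) -> pd.DataFrame:
    """Report layout: one row per term, one aOR (CI) column per contrast."""
    report_cols = [c for c in CONTRASTS if c != "inactivated"]
    rows = []
    for f in fits:
        row: dict[str, object] = {"term": f.term, "n_used": f.n_used, "converged": f.converged}
        for name in report_cols:
            ci = f.aor.get(name)
            if name in f.suppressed_levels or ci is None:
                row[name] = "NA"
                row[f"{name}_sig"] = False
            else:
                row[name] = f"{ci[0]:.2f} ({ci[1]:.2f}-{ci[2]:.2f})"
                row[f"{name}_sig"] = is_significant(ci)
        rows.append(row)
    cols = ["term", "n_used", "converged"]
    for name in report_cols:
        cols += [name, f"{name}_sig"]
    return pd.DataFrame(rows, columns=cols)
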