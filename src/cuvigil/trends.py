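"""Reporting-trend Poisson models, exploratory logistic models, descriptives.

The yearly reporting trend for each drug is modelled as a log-link Poisson
regression of annual report counts on calendar year (centered at the span
midpoint); the incidence-rate ratio per year is the exponentiated slope.
With two drugs a drug indicator and Year×Drug interaction quantify
heterogeneity of the temporal dynamics.  Both GLMs are fitted by iteratively
reweighted least squares with a tight convergence tolerance so that exact
log-linear data are reproduced to full precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .case_store import CaseSet

Z95 = 1.959963984540054

AGE_GROUPS = ("<18", "18-64", ">=65", "unknown")


@dataclass
class YearlyCounts:
    """Annual report counts for one drug, gap years zero-filled."""

    drug: str
    series: List[Tuple[int, int]]
    missing_year_reports: int = 0

    def years(self) -> np.ndarray:
        return np.array([y for y, _ in self.series])

    def counts(self) -> np.ndarray:
        return np.array([c for _, c in self.series])


@dataclass
class Term:
    name: str
    estimate: float
    se: float
    p: float

    @property
    def exp_estimate(self) -> float:
        return math.exp(self.estimate)

    @property
    def ci(self) -> Tuple[float, float]:
        return (math.exp(self.estimate - Z95 * self.se),
                math.exp(self.estimate + Z95 * self.se))


@dataclass
class TrendFit:
    terms: Dict[str, Term]
    irr: Dict[str, Tuple[float, Tuple[float, float], float]]  # drug -> (IRR, CI, p)
    interaction: Optional[Term] = None
    converged: bool = True
    n_iter: int = 0


@dataclass
class LogisticFit:
    outcome: str
    terms: Dict[str, Term]
    n_used: int = 0
    n_dropped_missing: int = 0


def aggregate_yearly_counts(cohort: CaseSet, drug: str) -> YearlyCounts:
    """Count reports per receipt year, zero-filling gaps inside the span.

    Reports without a receipt year are counted separately and excluded."""
    years = [r.receipt_year for r in cohort.reports if r.receipt_year is not None]
    missing = cohort.n - len(years)
    if not years:
        return YearlyCounts(drug=drug, series=[], missing_year_reports=missing)
    lo, hi = min(years), max(years)
    counts = {y: 0 for y in range(lo, hi + 1)}
    for y in years:
        counts[y] += 1
    return YearlyCounts(drug=drug, series=sorted(counts.items()),
                        missing_year_reports=missing)


# ---------------------------------------------------------------------------
# IRLS core

def _irls(X: np.ndarray, y: np.ndarray, family: str,
          tol: float = 1e-10, max_iter: int = 100,
          separation_bound: float = 15.0) -> Tuple[np.ndarray, np.ndarray, int]:
    """Iteratively reweighted least squares for Poisson(log) / binomial(logit).

    Returns (coefficients, covariance, iterations).  Convergence is declared
    when the max absolute coefficient change drops below ``tol``.
    """
    n, p = X.shape
    beta = np.zeros(p)
    if family == "poisson":
        beta[0] = math.log(max(y.mean(), 1e-8))
    for it in range(1, max_iter + 1):
        eta = X @ beta
        if family == "poisson":
            mu = np.exp(np.clip(eta, -30, 30))
            w = mu
            z = eta + (y - mu) / np.maximum(mu, 1e-12)
        else:
            mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
            w = mu * (1 - mu)
            w = np.maximum(w, 1e-12)
            z = eta + (y - mu) / w
        WX = X * w[:, None]
        XtWX = X.T @ WX
        beta_new = np.linalg.solve(XtWX, WX.T @ z)
        delta = np.max(np.abs(beta_new - beta))
        beta = beta_new
        if family == "binomial" and np.max(np.abs(beta)) > separation_bound:
            raise ValueError("separation: coefficients diverging on the logit scale")
        if delta < tol:
            cov = np.linalg.inv(XtWX)
            return beta, cov, it
    raise RuntimeError(f"IRLS did not converge in {max_iter} iterations "
                       f"(last change {delta:.3e})")


def _wald_terms(names: Sequence[str], beta: np.ndarray, cov: np.ndarray) -> Dict[str, Term]:
    out = {}
    for j, name in enumerate(names):
        se = math.sqrt(cov[j, j])
        z = beta[j] / se if se > 0 else float("inf")
        p = 2 * stats.norm.sf(abs(z))
        out[name] = Term(name, float(beta[j]), se, float(p))
    return out


def fit_poisson_glm(series: Sequence[YearlyCounts],
                    with_interaction: bool = False) -> TrendFit:
    """Log-link Poisson trend model on one or two yearly count series.

    Year is centered at the midpoint of the pooled span.  With two series and
    ``with_interaction`` the model adds a drug indicator and Year×Drug term;
    the second drug's IRR is exp(year + interaction coefficients).
    """
    series = list(series)
    if not 1 <= len(series) <= 2:
        raise ValueError("supply one or two yearly series")
    for s in series:
        if len(s.series) < 3:
            raise ValueError(f"{s.drug}: need >= 3 yearly observations")
        if s.counts().sum() == 0:
            raise ValueError(f"{s.drug}: all-zero series")

    all_years = np.concatenate([s.years() for s in series]).astype(float)
    center = (all_years.min() + all_years.max()) / 2.0

    rows, y = [], []
    for k, s in enumerate(series):
        for year, count in s.series:
            yr = year - center
            if with_interaction and len(series) == 2:
                rows.append([1.0, yr, float(k), yr * float(k)])
            else:
                rows.append([1.0, yr])
            y.append(float(count))
    X = np.array(rows)
    y = np.array(y)
    names = (["intercept", "year", "drug", "year:drug"]
             if X.shape[1] == 4 else ["intercept", "year"])
    beta, cov, n_iter = _irls(X, y, "poisson")
    terms = _wald_terms(names, beta, cov)

    irr: Dict[str, Tuple[float, Tuple[float, float], float]] = {}
    t_year = terms["year"]
    irr[series[0].drug] = (t_year.exp_estimate, t_year.ci, t_year.p)
    interaction = None
    if "year:drug" in terms:
        interaction = terms["year:drug"]
        # slope for drug 2 = year + interaction; variance by the delta method
        b = beta[names.index("year")] + beta[names.index("year:drug")]
        j1, j2 = names.index("year"), names.index("year:drug")
        var = cov[j1, j1] + cov[j2, j2] + 2 * cov[j1, j2]
        se = math.sqrt(var)
        zval = b / se if se > 0 else float("inf")
        irr[series[1].drug] = (math.exp(b),
                               (math.exp(b - Z95 * se), math.exp(b + Z95 * se)),
                               float(2 * stats.norm.sf(abs(zval))))
    elif len(series) == 2:
        # no interaction: the common slope applies to both drugs
        irr[series[1].drug] = irr[series[0].drug]
    return TrendFit(terms=terms, irr=irr, interaction=interaction, n_iter=n_iter)


def fit_logistic_glm(cases: CaseSet, outcome: str = "serious",
                     covariates: Sequence[str] = ("sex", "age_years")) -> LogisticFit:
    """Exploratory logistic model for seriousness or hospitalization.

    Reference level for sex is female; reports with missing outcome or
    covariates are dropped listwise and counted.
    """
    if outcome not in ("serious", "hospitalization"):
        raise ValueError("outcome must be 'serious' or 'hospitalization'")
    rows, y = [], []
    dropped = 0
    for rep in cases.reports:
        if outcome == "serious":
            resp = rep.serious
        else:
            resp = ("hospitalization" in rep.outcomes) if rep.outcomes else None
        if resp is None:
            dropped += 1
            continue
        row = [1.0]
        ok = True
        for cv in covariates:
            if cv == "sex":
                if rep.sex == "unspecified":
                    ok = False
                    break
                row.append(1.0 if rep.sex == "male" else 0.0)
            elif cv == "age_years":
                if rep.age_years is None:
                    ok = False
                    break
                row.append(float(rep.age_years))
            else:
                raise ValueError(f"unknown covariate {cv!r}")
        if not ok:
            dropped += 1
            continue
        rows.append(row)
        y.append(1.0 if resp else 0.0)
    y = np.array(y)
    if len(y) == 0 or y.min() == y.max():
        raise ValueError("outcome must be observed in both classes")
    X = np.array(rows)
    names = ["intercept"] + ["sex[male]" if c == "sex" else c for c in covariates]
    beta, cov, _ = _irls(X, y, "binomial")
    return LogisticFit(outcome=outcome, terms=_wald_terms(names, beta, cov),
                       n_used=len(y), n_dropped_missing=dropped)


# ---------------------------------------------------------------------------
# descriptive tabulations

def _age_group(age: Optional[float]) -> str:
    if age is None:
        return "unknown"
    if age < 18:
        return "<18"
    if age < 65:
        return "18-64"
    return ">=65"


def tabulate_descriptives(cohorts: Dict[str, CaseSet], dimension: str):
    """Counts per category per drug for one descriptive dimension.

    Dimensions: database/drug, continent, reporter_type, age_group, sex,
    seriousness, outcomes.  Every report falls in exactly one category except
    for the multi-valued outcomes dimension.
    """
    import pandas as pd

    def categories_of(rep):
        if dimension == "database/drug":
            return ["reports"]
        if dimension == "continent":
            return [rep.continent]
        if dimension == "reporter_type":
            return [rep.reporter_type]
        if dimension == "age_group":
            return [_age_group(rep.age_years)]
        if dimension == "sex":
            return [rep.sex]
        if dimension == "seriousness":
            if rep.serious is None:
                return ["unknown"]
            return ["serious" if rep.serious else "non-serious"]
        if dimension == "outcomes":
            return sorted(rep.outcomes) or ["none recorded"]
        raise ValueError(f"unknown dimension {dimension!r}")

    data: Dict[str, Dict[str, int]] = {}
    for drug, cohort in cohorts.items():
        col: Dict[str, int] = {}
        for rep in cohort.reports:
            for cat in categories_of(rep):
                col[cat] = col.get(cat, 0) + 1
        data[drug] = col
    frame = pd.DataFrame(data).fillna(0).astype(int)
    return frame.sort_index()


def period_totals(counts: YearlyCounts, cut_year: int = 2000) -> Tuple[int, int]:
    """Aggregate a yearly series into (pre-cut, cut-and-after) totals."""
    pre = sum(c for y, c in counts.series if y < cut_year)
    post = sum(c for y, c in counts.series if y >= cut_year)
    return pre, post
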