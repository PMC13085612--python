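"""Disproportionality statistics for spontaneous-report signal detection.

Four complementary measures of disproportionate reporting are computed from
each drug–event 2×2 table:

* **ROR** (reporting odds ratio) ``ad/(bc)`` with a Wald log-scale 95% CI;
* **PRR** (proportional reporting ratio) ``[a/(a+b)]/[c/(c+d)]`` with its
  Wald CI and the companion chi-square;
* **IC** (information component), the shrinkage observed/expected measure
  ``log2((a+0.5)/(E+0.5))`` with IC025, the lower 95% credibility bound from
  the Gamma(a+0.5, E+0.5) posterior of the relative reporting rate;
* **EBGM** (empirical-Bayes geometric mean) from the gamma-Poisson shrinker:
  a two-component gamma mixture prior on the latent relative reporting rate
  λ, fitted by marginal maximum likelihood across all tables, yielding the
  posterior geometric mean and the (EB05, EB95) 90% interval per pair.

Tables containing a zero cell get the Haldane–Anscombe +0.5 correction for
ROR/PRR only (and are marked as corrected); IC and EBGM handle zeros
natively through their priors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Set, Tuple

import numpy as np
from scipy import optimize, special, stats

from .contingency import ContingencyTable

Z95 = 1.959963984540054  # two-sided 95% normal quantile

#: classical gamma-Poisson shrinker starting values (alpha1, beta1, alpha2, beta2, P)
CLASSIC_MGPS_START = (0.2, 0.1, 2.0, 4.0, 1.0 / 3.0)


@dataclass(frozen=True)
class Thresholds:
    """Configurable signal criteria (the conventional defaults)."""

    ror_ci_low: float = 1.0
    ror_min_a: int = 3
    prr_min: float = 2.0
    prr_chi2_min: float = 4.0
    prr_min_a: int = 3
    ic025_min: float = 0.0
    eb05_min: float = 2.0


@dataclass(frozen=True)
class MgpsPrior:
    """Two-component gamma mixture prior on the relative reporting rate λ."""

    alpha1: float
    beta1: float
    alpha2: float
    beta2: float
    P: float
    loglik: float = float("nan")

    def __post_init__(self):
        if min(self.alpha1, self.beta1, self.alpha2, self.beta2) <= 0:
            raise ValueError("gamma hyperparameters must be strictly positive")
        if not (0 < self.P < 1):
            raise ValueError("mixing weight must lie in (0, 1)")


#: diffuse default prior used when no fit is requested
DEFAULT_PRIOR = MgpsPrior(*CLASSIC_MGPS_START)


@dataclass
class Chi2Result:
    statistic: float
    df: int
    p: float


@dataclass
class SignalRow:
    """One rendered signal-table record for a drug–event pair."""

    drug: str
    event: str
    a: int
    E: float
    ROR: float
    ROR_CI: Tuple[float, float]
    PRR: float
    PRR_CI: Tuple[float, float]
    chi2: float
    IC: float
    IC025: float
    EBGM: float
    EB05: float
    EB95: float
    corrected: bool = False
    comparator: str = ""
    flags: Set[str] = field(default_factory=set)


def _check_margins(t: ContingencyTable) -> None:
    if t.a + t.b == 0 or t.c + t.d == 0:
        raise ValueError("degenerate margin: empty drug or comparator arm")


def _cells(t: ContingencyTable) -> Tuple[Tuple[float, float, float, float], bool]:
    """Apply the Haldane–Anscombe +0.5 correction when any cell is zero."""
    cells = (t.a, t.b, t.c, t.d)
    if min(cells) == 0:
        return tuple(x + 0.5 for x in cells), True
    return tuple(float(x) for x in cells), False


def compute_ror(t: ContingencyTable) -> Tuple[float, Tuple[float, float], bool]:
    """Reporting odds ratio with 95% Wald CI; returns (ROR, (lo, hi), corrected)."""
    _check_margins(t)
    (a, b, c, d), corrected = _cells(t)
    ror = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    ci = (ror * math.exp(-Z95 * se), ror * math.exp(Z95 * se))
    return ror, ci, corrected


def compute_prr(t: ContingencyTable) -> Tuple[float, Tuple[float, float], bool]:
    """Proportional reporting ratio with 95% Wald CI."""
    _check_margins(t)
    (a, b, c, d), corrected = _cells(t)
    prr = (a / (a + b)) / (c / (c + d))
    se = math.sqrt(1 / a - 1 / (a + b) + 1 / c - 1 / (c + d))
    ci = (prr * math.exp(-Z95 * se), prr * math.exp(Z95 * se))
    return prr, ci, corrected


def compute_chi2_yates(table, correction: bool = True) -> Chi2Result:
    """Pearson chi-square on a 2×2 table (Yates-corrected by default).

    The uncorrected variant (``correction=False``) is the one used in the
    classical PRR signal criterion.
    """
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (arr.sum(0) == 0).any() or (arr.sum(1) == 0).any():
        raise ValueError("degenerate margin: zero row or column total")
    stat, p, df, _ = stats.chi2_contingency(arr, correction=correction)
    return Chi2Result(statistic=float(stat), df=int(df), p=float(p))


# ---------------------------------------------------------------------------
# information component (BCPNN, shrinkage observed/expected form)

def compute_ic(t: ContingencyTable, method: str = "exact") -> Tuple[float, float]:
    """Information component and its lower 95% credibility bound.

    IC = log2((a+0.5)/(E+0.5)).  With ``method='exact'`` (default), IC025 is
    the log2 of the 0.025 quantile of the Gamma(a+0.5, rate E+0.5) posterior;
    ``method='approx'`` uses the closed form
    IC − 3.3(a+0.5)^(−1/2) − 2(a+0.5)^(−3/2).
    """
    a, E = t.a, t.E
    ic = math.log2((a + 0.5) / (E + 0.5))
    if method == "exact":
        q = stats.gamma.ppf(0.025, a + 0.5, scale=1.0 / (E + 0.5))
        ic025 = math.log2(q) if q > 0 else float("-inf")
    elif method == "approx":
        s = a + 0.5
        ic025 = ic - 3.3 * s ** -0.5 - 2.0 * s ** -1.5
    else:
        raise ValueError(f"unknown IC method {method!r}")
    return ic, ic025


# ---------------------------------------------------------------------------
# gamma-Poisson shrinker (MGPS)

def _mixture_logpmf(a, E, theta) -> np.ndarray:
    """Marginal log-likelihood terms: mixture of negative binomials.

    Integrating the Poisson(λE) likelihood over a Gamma(α, β) prior on λ
    gives NB(a; α, β/(β+E)); the marginal is the P-weighted two-component
    mixture.
    """
    a1, b1, a2, b2, p = theta
    l1 = stats.nbinom.logpmf(a, a1, b1 / (b1 + E))
    l2 = stats.nbinom.logpmf(a, a2, b2 / (b2 + E))
    return np.logaddexp(np.log(p) + l1, np.log1p(-p) + l2)


def _unpack(x: np.ndarray) -> Tuple[float, float, float, float, float]:
    return (*np.exp(x[:4]), special.expit(x[4]))


def fit_mgps_prior(tables: Sequence, restarts: int = 5,
                   restart_seed: int = 20260929, min_tables: int = 50) -> MgpsPrior:
    """Fit the five mixture hyperparameters by marginal maximum likelihood.

    ``tables`` may be ContingencyTable objects or raw ``(a, E)`` pairs.
    Optimization runs L-BFGS-B on log/logit-transformed parameters from the
    classical start plus ``restarts − 1`` dispersed seeded starts; the best
    log-likelihood wins (ties go to the earliest restart).
    """
    pairs = [(t.a, t.E) if hasattr(t, "a") else tuple(t) for t in tables]
    pairs = [(a, E) for a, E in pairs if E > 0]
    if len(pairs) < min_tables:
        raise ValueError(
            f"need at least {min_tables} tables with E > 0 (got {len(pairs)})")
    a = np.asarray([p[0] for p in pairs], dtype=float)
    E = np.asarray([p[1] for p in pairs], dtype=float)

    def nll(x):
        with np.errstate(over="ignore", invalid="ignore"):
            v = _mixture_logpmf(a, E, _unpack(x))
        if not np.all(np.isfinite(v)):
            return 1e12
        return -float(v.sum())

    rng = np.random.default_rng(restart_seed)
    starts = [np.array([math.log(CLASSIC_MGPS_START[0]), math.log(CLASSIC_MGPS_START[1]),
                        math.log(CLASSIC_MGPS_START[2]), math.log(CLASSIC_MGPS_START[3]),
                        special.logit(CLASSIC_MGPS_START[4])])]
    for _ in range(max(0, restarts - 1)):
        starts.append(np.concatenate([rng.uniform(-2.5, 2.5, 4),
                                      rng.uniform(-1.5, 1.5, 1)]))

    bounds = [(-12, 12)] * 4 + [(-10, 10)]
    best = None
    for x0 in starts:
        res = optimize.minimize(nll, x0, method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun - 1e-9:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("MGPS fit failed: no restart converged")
    a1, b1, a2, b2, p = _unpack(best.x)
    return MgpsPrior(a1, b1, a2, b2, p, loglik=-float(best.fun))


def posterior_ebgm(t, prior: MgpsPrior) -> Tuple[float, float, float]:
    """EBGM and the 90% posterior interval (EB05, EB95) for one table.

    The posterior on λ is again a two-component gamma mixture with
    components Gamma(αᵢ+a, βᵢ+E) and mixing weight updated by the marginal
    negative-binomial evidence.  EBGM = 2^{E[log2 λ]} using
    E[ln λ] = ψ(shape) − ln(rate) per component; EB05/EB95 solve the mixture
    CDF by bracketed root-finding.
    """
    a, E = (t.a, t.E) if hasattr(t, "a") else tuple(t)
    s1, r1 = prior.alpha1 + a, prior.beta1 + E
    s2, r2 = prior.alpha2 + a, prior.beta2 + E
    l1 = stats.nbinom.logpmf(a, prior.alpha1, prior.beta1 / (prior.beta1 + E))
    l2 = stats.nbinom.logpmf(a, prior.alpha2, prior.beta2 / (prior.beta2 + E))
    w1 = math.log(prior.P) + l1
    w2 = math.log1p(-prior.P) + l2
    m = max(w1, w2)
    q = math.exp(w1 - m) / (math.exp(w1 - m) + math.exp(w2 - m))

    mean_log = q * (special.digamma(s1) - math.log(r1)) \
        + (1 - q) * (special.digamma(s2) - math.log(r2))
    ebgm = math.exp(mean_log)

    def mix_cdf(x):
        return (q * stats.gamma.cdf(x, s1, scale=1 / r1)
                + (1 - q) * stats.gamma.cdf(x, s2, scale=1 / r2))

    def quantile(prob):
        # the mixture quantile lies between the component quantiles; pad the
        # bracket slightly against rounding when the weight collapses
        q1 = stats.gamma.ppf(prob, s1, scale=1 / r1)
        q2 = stats.gamma.ppf(prob, s2, scale=1 / r2)
        lo, hi = min(q1, q2) * (1 - 1e-9), max(q1, q2) * (1 + 1e-9)
        if mix_cdf(lo) >= prob:
            return lo
        if mix_cdf(hi) <= prob:
            return hi
        return optimize.brentq(lambda x: mix_cdf(x) - prob, lo, hi,
                               rtol=1e-10, xtol=1e-300)

    return ebgm, quantile(0.05), quantile(0.95)


# ---------------------------------------------------------------------------
# assembly and evaluation

def evaluate_signals(row: SignalRow, thresholds: Thresholds = Thresholds(),
                     uncorrected_chi2: Optional[float] = None) -> Set[str]:
    """Apply the conventional signal criteria and return the flag set.

    ROR+ : CI lower bound > 1 with a ≥ 3;
    PRR+ : PRR ≥ 2, uncorrected chi-square ≥ 4, a ≥ 3;
    IC+  : IC025 > 0;
    EBGM+: EB05 ≥ 2.
    """
    th = thresholds
    flags = set()
    if row.ROR_CI[0] > th.ror_ci_low and row.a >= th.ror_min_a:
        flags.add("ROR+")
    chi2u = uncorrected_chi2 if uncorrected_chi2 is not None else row.chi2
    if row.PRR >= th.prr_min and chi2u >= th.prr_chi2_min and row.a >= th.prr_min_a:
        flags.add("PRR+")
    if row.IC025 > th.ic025_min:
        flags.add("IC+")
    if row.EB05 >= th.eb05_min:
        flags.add("EBGM+")
    return flags


def compute_signal_row(t: ContingencyTable, prior: MgpsPrior = DEFAULT_PRIOR,
                       thresholds: Thresholds = Thresholds()) -> SignalRow:
    """All four statistics plus flags for one contingency table."""
    ror, ror_ci, corr1 = compute_ror(t)
    prr, prr_ci, corr2 = compute_prr(t)
    try:
        chi2_yates = compute_chi2_yates([[t.a, t.b], [t.c, t.d]], correction=True)
        chi2_plain = compute_chi2_yates([[t.a, t.b], [t.c, t.d]], correction=False)
    except ValueError:  # zero event margin: chi-square undefined, no PRR signal
        chi2_yates = Chi2Result(float("nan"), 1, float("nan"))
        chi2_plain = Chi2Result(float("-inf"), 1, float("nan"))
    ic, ic025 = compute_ic(t)
    ebgm, eb05, eb95 = posterior_ebgm(t, prior)
    row = SignalRow(drug=t.drug, event=t.event, a=t.a, E=t.E,
                    ROR=ror, ROR_CI=ror_ci, PRR=prr, PRR_CI=prr_ci,
                    chi2=chi2_yates.statistic, IC=ic, IC025=ic025,
                    EBGM=ebgm, EB05=eb05, EB95=eb95,
                    corrected=corr1 or corr2, comparator=t.comparator)
    row.flags = evaluate_signals(row, thresholds,
                                 uncorrected_chi2=chi2_plain.statistic)
    return row
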