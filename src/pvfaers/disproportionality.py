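"""Disproportionality statistics for drug-event 2x2 report tables.

Three estimators of reporting disproportionality are computed per
drug-endpoint pair, all from the same report-level 2x2 table

    =============  ==========  ==========
    .              endpoint    no endpoint
    target drug        a           b
    comparator         c           d
    =============  ==========  ==========

* **ROR** — reporting odds ratio ``(a*d)/(b*c)`` with a 95% Wald interval
  ``exp(ln ROR +/- 1.96*sqrt(1/a+1/b+1/c+1/d))``; if any cell is zero the
  Haldane–Anscombe correction (add 0.5 to every cell) is applied first.

* **BCPNN IC** — the information component ``log2((a+0.5)/(E+0.5))`` with
  expected count ``E=(a+b)(a+c)/N``, and the closed-form lower credible
  bound ``IC025 = IC - 3.3*(a+0.5)^-1/2 - 2.0*(a+0.5)^-3/2``.

* **MGPS EBGM** — the multi-item gamma-Poisson shrinker.  Observed counts
  are modelled as ``a ~ Poisson(lambda * E)`` with a two-component gamma
  mixture prior on the relative reporting rate lambda.  The five prior
  hyperparameters are fitted by maximizing the negative-binomial mixture
  marginal likelihood over all tables of the run; the posterior for each
  table is again a gamma mixture, EBGM is the posterior geometric mean
  ``2**E[log2 lambda]`` and EB05/EB95 are posterior quantiles.

A pair is a *signal* only when all three agree: ROR >= 3 with Wald lower
bound > 1, IC025 > 0 and EB05 > 2.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize, special
from scipy import stats as st

from .io_faers import CaseReport
from .term_mapping import CompositeEndpoint, map_endpoints

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class ContingencyTable:
    """Report-level 2x2 counts for one drug-event pair."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be nonnegative")
        if self.n == 0:
            raise ValueError("empty table (N = 0)")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def expected(self) -> float:
        """E = (a+b)(a+c)/N, the count expected under independence."""
        return (self.a + self.b) * (self.a + self.c) / self.n


@dataclass(frozen=True)
class RorResult:
    ror: float
    ci_low: float
    ci_high: float
    corrected: bool


@dataclass(frozen=True)
class IcResult:
    ic: float
    ic025: float
    expected: float


@dataclass(frozen=True)
class MgpsPrior:
    """Hyperparameters of the gamma-mixture prior on lambda.

    ``alpha1, beta1`` and ``alpha2, beta2`` are shape/rate pairs; ``p_mix``
    is the weight of the first component.
    """

    alpha1: float
    beta1: float
    alpha2: float
    beta2: float
    p_mix: float
    loglik: float = float("nan")
    converged: bool = True

    def __post_init__(self) -> None:
        if min(self.alpha1, self.beta1, self.alpha2, self.beta2) <= 0:
            raise ValueError("gamma hyperparameters must be positive")
        if not 0 < self.p_mix < 1:
            raise ValueError("p_mix must lie in (0, 1)")

    @property
    def prior_mean(self) -> float:
        return self.p_mix * self.alpha1 / self.beta1 + (1 - self.p_mix) * self.alpha2 / self.beta2


@dataclass(frozen=True)
class EbgmResult:
    ebgm: float
    eb05: float
    eb95: float
    posterior_weight: float


@dataclass(frozen=True)
class SignalDecision:
    is_signal: bool
    criteria_met: dict


def ror(t: ContingencyTable) -> RorResult:
    """Reporting odds ratio with 95% Wald interval (zero cells corrected)."""
    a, b, c, d = float(t.a), float(t.b), float(t.c), float(t.d)
    corrected = min(a, b, c, d) == 0
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    point = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return RorResult(
        ror=point,
        ci_low=math.exp(math.log(point) - Z_95 * se),
        ci_high=math.exp(math.log(point) + Z_95 * se),
        corrected=corrected,
    )


def bcpnn_ic(t: ContingencyTable) -> IcResult:
    """Shrinkage information component with its closed-form lower bound."""
    e = t.expected
    shrunk = t.a + 0.5
    ic = math.log2(shrunk / (e + 0.5))
    ic025 = ic - 3.3 * shrunk ** -0.5 - 2.0 * shrunk ** -1.5
    return IcResult(ic=ic, ic025=ic025, expected=e)


# ---------------------------------------------------------------------------
# MGPS

MGPS_START = (0.2, 0.1, 2.0, 4.0, 1.0 / 3.0)
_MGPS_BOUNDS = [(1e-6, 50.0)] * 4 + [(1e-6, 1 - 1e-6)]


def _nb_logpmf(n: np.ndarray, alpha: float, beta: float, e: np.ndarray) -> np.ndarray:
    """log of the gamma-Poisson (negative binomial) marginal pmf of a count
    with expectation multiplier ``e`` under a Gamma(alpha, rate beta) prior."""
    return (special.gammaln(alpha + n) - special.gammaln(alpha) - special.gammaln(n + 1)
            + alpha * (np.log(beta) - np.log(beta + e))
            + n * (np.log(e) - np.log(beta + e)))


def _mixture_loglik(theta: Sequence[float], n: np.ndarray, e: np.ndarray) -> float:
    a1, b1, a2, b2, p = theta
    lw = np.stack([
        math.log(p) + _nb_logpmf(n, a1, b1, e),
        math.log1p(-p) + _nb_logpmf(n, a2, b2, e),
    ])
    return float(special.logsumexp(lw, axis=0).sum())


def _as_pairs(tables: Iterable[ContingencyTable] | Iterable[tuple]) -> tuple[np.ndarray, np.ndarray]:
    ns, es = [], []
    for item in tables:
        if isinstance(item, ContingencyTable):
            ns.append(item.a)
            es.append(item.expected)
        else:
            n, e = item
            ns.append(n)
            es.append(e)
    return np.asarray(ns, dtype=float), np.asarray(es, dtype=float)


def fit_mgps_prior(tables: Iterable[ContingencyTable] | Iterable[tuple],
                   start: Sequence[float] = MGPS_START) -> MgpsPrior:
    """Fit the five mixture hyperparameters by marginal maximum likelihood.

    ``tables`` may be :class:`ContingencyTable` objects or raw ``(a, E)``
    pairs.  Box-constrained L-BFGS-B from the classic start point
    ``(0.2, 0.1, 2.0, 4.0, 1/3)``.  With no informative counts (all zero) or
    on optimizer failure the start-point prior is returned flagged
    non-converged.
    """
    n, e = _as_pairs(tables)
    if len(n) < 2 or not np.all(e > 0):
        raise ValueError("need >= 2 tables with positive expected counts")
    if not np.any(n > 0):
        warnings.warn("all observed counts are zero; MGPS prior not identifiable", stacklevel=2)
        return MgpsPrior(*start, loglik=_mixture_loglik(start, n, e), converged=False)

    res = optimize.minimize(
        lambda th: -_mixture_loglik(th, n, e),
        x0=np.asarray(start, dtype=float),
        method="L-BFGS-B",
        bounds=_MGPS_BOUNDS,
    )
    if not res.success:
        warnings.warn(f"MGPS prior fit did not converge: {res.message}", stacklevel=2)
        return MgpsPrior(*start, loglik=_mixture_loglik(start, n, e), converged=False)
    a1, b1, a2, b2, p = (float(v) for v in res.x)
    return MgpsPrior(a1, b1, a2, b2, p, loglik=float(-res.fun), converged=True)


def posterior_mixture_weight(t_a: float, e: float, prior: MgpsPrior) -> float:
    """Posterior probability that lambda came from the first component."""
    n = np.asarray([float(t_a)])
    ee = np.asarray([float(e)])
    lw1 = math.log(prior.p_mix) + float(_nb_logpmf(n, prior.alpha1, prior.beta1, ee)[0])
    lw2 = math.log1p(-prior.p_mix) + float(_nb_logpmf(n, prior.alpha2, prior.beta2, ee)[0])
    m = max(lw1, lw2)
    w1 = math.exp(lw1 - m)
    return w1 / (w1 + math.exp(lw2 - m))


def posterior_cdf(lam: float, t_a: float, e: float, prior: MgpsPrior) -> float:
    """CDF of the posterior gamma mixture of lambda at ``lam``."""
    q = posterior_mixture_weight(t_a, e, prior)
    c1 = st.gamma.cdf(lam, prior.alpha1 + t_a, scale=1.0 / (prior.beta1 + e))
    c2 = st.gamma.cdf(lam, prior.alpha2 + t_a, scale=1.0 / (prior.beta2 + e))
    return q * c1 + (1 - q) * c2


def _posterior_quantile(p: float, t_a: float, e: float, prior: MgpsPrior) -> float:
    lo = min(st.gamma.ppf(p, prior.alpha1 + t_a, scale=1.0 / (prior.beta1 + e)),
             st.gamma.ppf(p, prior.alpha2 + t_a, scale=1.0 / (prior.beta2 + e)))
    hi = max(st.gamma.ppf(p, prior.alpha1 + t_a, scale=1.0 / (prior.beta1 + e)),
             st.gamma.ppf(p, prior.alpha2 + t_a, scale=1.0 / (prior.beta2 + e)))
    lo, hi = max(lo * 0.5, 1e-12), hi * 2 + 1e-12
    f = lambda lam: posterior_cdf(lam, t_a, e, prior) - p
    # widen until the root is bracketed (mixture mass can sit past one
    # component's quantile)
    while f(lo) > 0 and lo > 1e-300:
        lo *= 0.5
    while f(hi) < 0 and hi < 1e300:
        hi *= 2
    # a near-zero shape parameter can push the quantile below double
    # precision; the bracket bound is then the representable answer
    if f(lo) > 0:
        return lo
    if f(hi) < 0:
        return hi
    return float(optimize.brentq(f, lo, hi, xtol=1e-10, rtol=1e-12))


def ebgm(t: ContingencyTable, prior: MgpsPrior) -> EbgmResult:
    """Empirical-Bayes geometric mean and 5th/95th posterior percentiles.

    The posterior is ``Q * Gamma(alpha1+a, beta1+E) + (1-Q) * Gamma(alpha2+a,
    beta2+E)``; ``E[ln lambda]`` uses the digamma closed form and the
    quantiles come from bracketed root-finding on the mixture CDF.
    """
    e = t.expected
    if e <= 0:
        raise ValueError("EBGM undefined for E = 0")
    q = posterior_mixture_weight(t.a, e, prior)
    mean_log = (q * (special.digamma(prior.alpha1 + t.a) - math.log(prior.beta1 + e))
                + (1 - q) * (special.digamma(prior.alpha2 + t.a) - math.log(prior.beta2 + e)))
    return EbgmResult(
        ebgm=math.exp(mean_log),
        eb05=_posterior_quantile(0.05, t.a, e, prior),
        eb95=_posterior_quantile(0.95, t.a, e, prior),
        posterior_weight=q,
    )


# ---------------------------------------------------------------------------
# joint signal criterion


def evaluate_signal(ror_r: RorResult, ic_r: IcResult, ebgm_r: EbgmResult) -> SignalDecision:
    """Joint criterion: ROR >= 3 with Wald lower bound > 1, IC025 > 0 and
    EB05 > 2; a signal requires all three."""
    criteria = {
        "ror_rule": ror_r.ror >= 3 and ror_r.ci_low > 1,
        "ic_rule": ic_r.ic025 > 0,
        "ebgm_rule": ebgm_r.eb05 > 2,
    }
    return SignalDecision(is_signal=all(criteria.values()), criteria_met=criteria)


def build_table(cohort_cases: Sequence[CaseReport], background_cases: Sequence[CaseReport],
                endpoint: CompositeEndpoint) -> ContingencyTable:
    """Report-level 2x2 counts of an endpoint in cohort vs comparator.

    A case counts once per endpoint however many member PTs it lists.
    ``background_cases`` must be disjoint from the cohort.
    """
    eps = (endpoint,)
    a = sum(1 for case in cohort_cases if map_endpoints(case, eps))
    c = sum(1 for case in background_cases if map_endpoints(case, eps))
    return ContingencyTable(a=a, b=len(cohort_cases) - a,
                            c=c, d=len(background_cases) - c)
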