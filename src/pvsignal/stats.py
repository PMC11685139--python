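"""Disproportionality statistics for drug-event signal detection.

Four algorithms are computed on the 2x2 table (a, b, c, d) of a
drug-event pair against the reporting universe (N = a+b+c+d):

* **ROR** — reporting odds ratio ``ad/bc`` with the Woolf (log-scale)
  95% confidence interval.
* **PRR** — proportional reporting ratio ``[a/(a+b)]/[c/(c+d)]`` with
  the Pearson chi-square statistic (no Yates correction).
* **BCPNN IC** — the closed-form Bayesian information component of
  Bate et al.: the posterior expectation of ``log2 P(drug,event) /
  (P(drug)P(event))`` under independent Dirichlet priors, with a
  +/- 2 SD credibility interval.
* **MGPS EBGM** — DuMouchel's multi-item gamma-Poisson shrinker: the
  observed count is Poisson with mean ``lambda * E`` where ``E =
  (a+b)(a+c)/N`` and ``lambda`` follows a two-component gamma mixture
  prior fitted by maximum marginal likelihood across all pairs.  EBGM
  is the posterior geometric mean ``2^{E[log2 lambda | n]}``, EBGM05
  the 5th posterior percentile.

Signal criteria (the conventional thresholds for these algorithms):
ROR: a>=3 and CI floor > 1; PRR: PRR>=2, chi2>=4, a>=3; BCPNN:
IC-2SD > 0; MGPS: EBGM05 > 2.  A PT-level signal requires all four,
a SOC-level signal at least one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, special, stats as sps

from .cohort import ContingencyTable

log = logging.getLogger(__name__)

__all__ = [
    "SignalScores",
    "GPSPrior",
    "ConvergenceError",
    "ror_stat",
    "prr_stat",
    "bcpnn_ic",
    "fit_gps_prior",
    "ebgm_stat",
    "evaluate_signal",
    "score_table",
    "rank_signals",
    "solve_background_count",
]

_Z95 = 1.959963984540054  # two-sided 95% normal quantile
_LN2 = np.log(2.0)

# BCPNN prior constants (Bate 1998): Dirichlet priors on the joint and
# the two margins; gamma is tuned so that IC has prior expectation 0.
_G11, _A1, _B1, _ALPHA, _BETA = 1.0, 1.0, 1.0, 2.0, 2.0


class ConvergenceError(RuntimeError):
    """Prior fit failed to converge; carries the last iterate."""

    def __init__(self, message: str, last_iterate=None, grad_norm=None):
        super().__init__(message)
        self.last_iterate = last_iterate
        self.grad_norm = grad_norm


@dataclass(frozen=True)
class GPSPrior:
    """Two-component gamma mixture prior on the relative reporting rate.

    Component k has shape ``alpha_k`` and rate ``beta_k``; ``w`` is the
    weight of the first component.
    """

    alpha1: float
    beta1: float
    alpha2: float
    beta2: float
    w: float

    def __post_init__(self):
        if min(self.alpha1, self.beta1, self.alpha2, self.beta2) <= 0:
            raise ValueError("gamma shapes and rates must be positive")
        if not 0.0 <= self.w <= 1.0:
            raise ValueError("mixture weight must lie in [0, 1]")

    @property
    def mean(self) -> float:
        """Prior mean of the relative reporting rate."""
        return self.w * self.alpha1 / self.beta1 + (1 - self.w) * self.alpha2 / self.beta2


@dataclass(frozen=True)
class SignalScores:
    """All four disproportionality scores for one drug-event pair."""

    case_count: int
    ror: float
    ror_lo: float
    ror_hi: float
    prr: float
    chi2: float
    ic: float
    ic_lo: float
    ic_hi: float
    ebgm: float
    ebgm05: float

    @property
    def flags(self) -> dict:
        return signal_flags(self)


# ---------------------------------------------------------------------------
# frequentist statistics


def _cells(t: ContingencyTable) -> Tuple[float, float, float, float]:
    """Cells as floats with the Haldane-Anscombe 0.5 applied when bc = 0."""
    a, b, c, d = float(t.a), float(t.b), float(t.c), float(t.d)
    if b * c == 0:
        log.info("zero cell in table (a=%g,b=%g,c=%g,d=%g): adding 0.5 to all cells", a, b, c, d)
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return a, b, c, d


def ror_stat(t: ContingencyTable) -> Tuple[float, float, float]:
    """Reporting odds ratio with its Woolf 95% confidence interval.

    ``ror = ad/bc``; ``CI = exp(ln ror -/+ 1.96 sqrt(1/a+1/b+1/c+1/d))``.
    An a=0 table yields (0, 0, 0) — defined but never a signal.
    """
    a, b, c, d = _cells(t)
    if a == 0:
        return 0.0, 0.0, 0.0
    ror = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return ror, ror * np.exp(-_Z95 * se), ror * np.exp(_Z95 * se)


def prr_stat(t: ContingencyTable) -> Tuple[float, float]:
    """Proportional reporting ratio and Pearson chi-square (no Yates)."""
    a, b, c, d = _cells(t)
    n = a + b + c + d
    prr = (a / (a + b)) / (c / (c + d))
    chi2 = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
    return prr, chi2


def bcpnn_ic(t: ContingencyTable) -> Tuple[float, float, float]:
    """Closed-form Bayesian information component with a +/- 2 SD interval.

    Defined for every non-negative table: the Dirichlet priors
    regularize empty cells, so no continuity correction is needed.
    """
    a = float(t.a)
    n = float(t.n)
    row = a + t.b  # target margin
    col = a + t.c  # event margin
    gamma = _G11 * (n + _ALPHA) * (n + _BETA) / ((row + _A1) * (col + _B1))
    e_ic = np.log2(
        (a + _G11) * (n + _ALPHA) * (n + _BETA) / ((n + gamma) * (row + _A1) * (col + _B1))
    )
    v_ic = (
        (n - a + gamma - _G11) / ((a + _G11) * (1 + n + gamma))
        + (n - row + _ALPHA - _A1) / ((row + _A1) * (1 + n + _ALPHA))
        + (n - col + _BETA - _B1) / ((col + _B1) * (1 + n + _BETA))
    ) / _LN2**2
    sd = np.sqrt(v_ic)
    return float(e_ic), float(e_ic - 2 * sd), float(e_ic + 2 * sd)


# ---------------------------------------------------------------------------
# MGPS / empirical-Bayes gamma-Poisson shrinkage


def _mixture_logpmf(n, e, prior: GPSPrior) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-component and total log marginal P(n | E) (negative binomial)."""
    n = np.asarray(n, dtype=float)
    e = np.asarray(e, dtype=float)
    lp1 = sps.nbinom.logpmf(n, prior.alpha1, prior.beta1 / (prior.beta1 + e))
    lp2 = sps.nbinom.logpmf(n, prior.alpha2, prior.beta2 / (prior.beta2 + e))
    with np.errstate(divide="ignore"):
        lw1, lw2 = np.log(prior.w), np.log1p(-prior.w)
    total = np.logaddexp(lw1 + lp1, lw2 + lp2)
    return lp1, lp2, total


def fit_gps_prior(
    pair_counts: Sequence[Tuple[int, float]],
    init: Tuple[float, float, float, float, float] = (0.2, 0.1, 2.0, 4.0, 1.0 / 3.0),
    max_iter: int = 500,
) -> GPSPrior:
    """Fit the gamma-mixture prior by maximum marginal likelihood.

    Maximizes ``sum_i log P(n_i | E_i, prior)`` where the marginal of a
    gamma-Poisson pair is negative binomial, over all (observed,
    expected) pairs of the database.  Deterministic: bounded
    quasi-Newton from the documented initialization on log-transformed
    shapes/rates and a logit-transformed weight.
    """
    pairs = np.asarray(list(pair_counts), dtype=float)
    if pairs.ndim != 2 or len(pairs) < 2:
        raise ValueError("need at least two (n, E) pairs")
    n, e = pairs[:, 0], pairs[:, 1]
    if np.any(e <= 0):
        raise ValueError("all expected counts must be positive")

    def unpack(theta):
        a1, b1, a2, b2 = np.exp(np.clip(theta[:4], -12.0, 12.0))
        w = special.expit(theta[4])
        return GPSPrior(a1, b1, a2, b2, float(np.clip(w, 1e-12, 1 - 1e-12)))

    def nll(theta):
        prior = unpack(theta)
        _, _, total = _mixture_logpmf(n, e, prior)
        return -float(np.sum(total))

    theta0 = np.concatenate([np.log(init[:4]), [special.logit(init[4])]])
    # bounds keep shapes/rates in (e^-12, e^12); beyond that the marginal
    # is flat and the gamma pmf under/overflows
    res = optimize.minimize(
        nll,
        theta0,
        method="L-BFGS-B",
        bounds=[(-12.0, 12.0)] * 4 + [(-12.0, 12.0)],
        options={"maxiter": max_iter, "ftol": 1e-12, "gtol": 1e-8},
    )
    if res.status == 1:  # iteration cap reached
        raise ConvergenceError(
            f"prior fit did not converge in {max_iter} iterations: {res.message}",
            last_iterate=unpack(res.x),
            grad_norm=float(np.linalg.norm(res.jac)),
        )
    return unpack(res.x)


def _posterior(n: float, e: float, prior: GPSPrior):
    """Posterior mixture: updated weight and the two gamma components."""
    lp1, lp2, total = _mixture_logpmf(n, e, prior)
    with np.errstate(divide="ignore"):
        q1 = np.exp(np.log(prior.w) + lp1 - total) if prior.w > 0 else 0.0
    shapes = (prior.alpha1 + n, prior.alpha2 + n)
    rates = (prior.beta1 + e, prior.beta2 + e)
    return float(q1), shapes, rates


def ebgm_stat(n: int, e: float, prior: GPSPrior, tol: float = 1e-8) -> Tuple[float, float]:
    """EBGM (posterior geometric mean of lambda) and EBGM05 (5th percentile).

    EBGM uses the digamma identity ``E[ln lambda] = psi(shape) -
    ln(rate)`` per gamma component; EBGM05 is found by monotone
    root-finding on the posterior mixture CDF.
    """
    if e <= 0:
        raise ValueError("expected count must be positive")
    q1, (s1, s2), (r1, r2) = _posterior(float(n), float(e), prior)
    mean_log = q1 * (special.digamma(s1) - np.log(r1)) + (1 - q1) * (
        special.digamma(s2) - np.log(r2)
    )
    ebgm = float(np.exp(mean_log))

    def cdf(x):
        return q1 * sps.gamma.cdf(x, s1, scale=1 / r1) + (1 - q1) * sps.gamma.cdf(
            x, s2, scale=1 / r2
        )

    # bracket the 5th percentile between the component quantiles
    lo = 0.5 * min(sps.gamma.ppf(0.05, s1, scale=1 / r1), sps.gamma.ppf(0.05, s2, scale=1 / r2))
    hi = 2.0 * max(sps.gamma.ppf(0.05, s1, scale=1 / r1), sps.gamma.ppf(0.05, s2, scale=1 / r2))
    lo = max(lo, np.finfo(float).tiny)
    f_lo, f_hi = cdf(lo) - 0.05, cdf(hi) - 0.05
    for _ in range(60):  # widen if the mixture mass lies outside
        if f_lo <= 0 <= f_hi:
            break
        if f_lo > 0:
            lo /= 4.0
            f_lo = cdf(lo) - 0.05
        if f_hi < 0:
            hi *= 4.0
            f_hi = cdf(hi) - 0.05
    else:
        raise RuntimeError("could not bracket the 5th posterior percentile")
    ebgm05 = optimize.brentq(lambda x: cdf(x) - 0.05, lo, hi, xtol=tol, rtol=4 * np.finfo(float).eps)
    return ebgm, float(ebgm05)


# ---------------------------------------------------------------------------
# criteria, scoring and ranking


def signal_flags(s: SignalScores) -> dict:
    """Per-algorithm criterion flags (conventional thresholds)."""
    return {
        "ror": s.case_count >= 3 and s.ror_lo > 1.0,
        "prr": s.prr >= 2.0 and s.chi2 >= 4.0 and s.case_count >= 3,
        "bcpnn": s.ic_lo > 0.0,
        "mgps": s.ebgm05 > 2.0,
    }


def evaluate_signal(scores: SignalScores, level: str) -> bool:
    """Combine the four flags: all must fire at PT level, any at SOC level."""
    flags = signal_flags(scores)
    if level == "PT":
        return all(flags.values())
    if level == "SOC":
        return any(flags.values())
    raise ValueError(f"level must be 'PT' or 'SOC', got {level!r}")


def score_pair(t: ContingencyTable, prior: GPSPrior) -> SignalScores:
    """All four algorithms on one 2x2 table."""
    ror, ror_lo, ror_hi = ror_stat(t)
    prr, chi2 = prr_stat(t)
    ic, ic_lo, ic_hi = bcpnn_ic(t)
    ebgm, ebgm05 = ebgm_stat(t.a, t.expected, prior)
    return SignalScores(
        case_count=t.a,
        ror=ror,
        ror_lo=ror_lo,
        ror_hi=ror_hi,
        prr=prr,
        chi2=chi2,
        ic=ic,
        ic_lo=ic_lo,
        ic_hi=ic_hi,
        ebgm=ebgm,
        ebgm05=ebgm05,
    )


def score_table(cont: pd.DataFrame, prior: Optional[GPSPrior] = None) -> pd.DataFrame:
    """Score every term of a contingency DataFrame (columns a, b, c, d).

    If no prior is given, the gamma-mixture prior is fitted to the
    (a, E) pairs of this very table — the empirical-Bayes step that
    shares shrinkage strength across all drug-event pairs.  Returns a
    deterministic, index-sorted DataFrame with point estimates, interval
    bounds, per-algorithm flags and the PT/SOC-level signal columns.
    """
    cont = cont.sort_index()
    n_tot = int(cont[["a", "b", "c", "d"]].iloc[0].sum()) if len(cont) else 0
    e = (cont["a"] + cont["b"]) * (cont["a"] + cont["c"]) / n_tot if len(cont) else cont["a"]
    if prior is None:
        prior = fit_gps_prior(list(zip(cont["a"], e)))
    rows = []
    for term, r in cont.iterrows():
        t = ContingencyTable(int(r["a"]), int(r["b"]), int(r["c"]), int(r["d"]))
        s = score_pair(t, prior)
        flags = s.flags
        rows.append(
            {
                "term": term,
                "a": s.case_count,
                "ror": s.ror,
                "ror_lo": s.ror_lo,
                "ror_hi": s.ror_hi,
                "prr": s.prr,
                "chi2": s.chi2,
                "ic": s.ic,
                "ic_lo": s.ic_lo,
                "ic_hi": s.ic_hi,
                "ebgm": s.ebgm,
                "ebgm05": s.ebgm05,
                "flag_ror": flags["ror"],
                "flag_prr": flags["prr"],
                "flag_bcpnn": flags["bcpnn"],
                "flag_mgps": flags["mgps"],
                "signal_pt": all(flags.values()),
                "signal_soc": any(flags.values()),
            }
        )
    return pd.DataFrame(rows).set_index("term")


def rank_signals(scores: pd.DataFrame, by: str, n: int) -> pd.DataFrame:
    """Top-n signals by frequency (case count) or intensity (ROR CI floor).

    Ties break on the other key, then alphabetically on the term.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    if by == "frequency":
        keys, ascending = ["a", "ror_lo"], [False, False]
    elif by == "intensity":
        keys, ascending = ["ror_lo", "a"], [False, False]
    else:
        raise ValueError(f"by must be 'frequency' or 'intensity', got {by!r}")
    ordered = scores.reset_index().sort_values(
        keys + ["term"], ascending=ascending + [True], kind="mergesort"
    )
    return ordered.set_index("term").head(n)


def solve_background_count(a: float, b: float, ror: float, rest_total: float) -> float:
    """Invert the ROR: the background with-event count c given the margins.

    Solves ``(a d)/(b c) = ror`` under ``c + d = rest_total``:
    ``c = rest_total * r / (1 + r)`` with ``r = a / (b ror)``.  Used to
    reconstruct full 2x2 tables from published (a, ROR, totals).
    """
    if ror <= 0 or rest_total <= 0:
        raise ValueError("ror and rest_total must be positive")
    r = a / (b * ror)
    if r <= 0:
        raise ValueError("infeasible margins: a and b must be positive")
    return rest_total * r / (1.0 + r)
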