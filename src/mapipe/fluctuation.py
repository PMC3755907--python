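"""Luria-Delbruck fluctuation analysis.

Parallel cultures grown from a small inoculum accumulate mutants whose
per-culture count follows the heavy-tailed Luria-Delbruck distribution.  Two
estimators of m (the expected number of mutations per culture) are provided:

- the P0 method, m = -ln(fraction of cultures with zero mutants), with a
  Clopper-Pearson binomial CI on the zero fraction propagated through -ln;
- the MSS maximum-likelihood method, maximising the full likelihood under the
  Lea-Coulson probability recursion
      p_0 = exp(-m),   p_k = (m/k) * sum_{j<k} p_j / (k - j + 1),
  with the Stewart normal approximation on ln m for the CI
  (sigma_ln_m = 1.225 * m^-0.315 / sqrt(C)).

The per-cell-division rate is m / n_final: with n_final >> n_initial the
number of divisions in a culture is ~= n_final.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
import numpy as np
from scipy import optimize, stats

logger = logging.getLogger(__name__)

__all__ = [
    "FluctuationExperiment",
    "FluctuationResult",
    "ld_pmf",
    "ld_pmf_adaptive",
    "p0_estimate",
    "mss_mle",
]


@dataclass(frozen=True)
class FluctuationExperiment:
    mutant_counts: tuple[int, ...]
    n_final: float                 # cells per culture at plating
    n_initial: float = 1.0

    def __post_init__(self):
        counts = tuple(int(c) for c in self.mutant_counts)
        object.__setattr__(self, "mutant_counts", counts)
        if any(c < 0 for c in counts):
            raise ValueError("mutant counts must be non-negative")
        if not self.n_final > self.n_initial >= 1:
            raise ValueError("need n_final > n_initial >= 1")

    @property
    def n_cultures(self) -> int:
        return len(self.mutant_counts)


@dataclass(frozen=True)
class FluctuationResult:
    method: str                    # "P0" | "MSS-MLE"
    m: float                       # expected mutations per culture
    rate: float                    # per-cell-division rate = m / n_final
    ci_low: float
    ci_high: float
    n_cultures: int


def ld_pmf(m: float, k_max: int) -> np.ndarray:
    """Luria-Delbruck probabilities p_0..p_k_max at parameter m.

    Lea-Coulson recursion; the returned vector sums to <= 1, with the deficit
    being the probability of counts above k_max.
    """
    if m < 0:
        raise ValueError("m must be non-negative")
    if k_max < 0:
        raise ValueError("k_max must be >= 0")
    p = np.zeros(k_max + 1)
    p[0] = np.exp(-m)
    if m == 0 or k_max == 0:
        return p
    # weight for term j in p_k is 1/(k - j + 1); recip[i] = 1/(i + 2)
    recip = 1.0 / np.arange(2, k_max + 2, dtype=float)
    for k in range(1, k_max + 1):
        p[k] = m / k * np.dot(p[:k], recip[:k][::-1])
    return p


def ld_pmf_adaptive(m: float, tail_tol: float = 1e-6,
                    k_cap: int = 100_000) -> np.ndarray:
    """pmf extended until the tail mass is below ``tail_tol`` (or k_cap)."""
    k = max(64, int(8 * m) + 8)
    while True:
        p = ld_pmf(m, k)
        if 1.0 - p.sum() < tail_tol or k >= k_cap:
            return p
        k = min(2 * k, k_cap)


def p0_estimate(exp: FluctuationExperiment, conf: float = 0.95) -> FluctuationResult:
    """P0 estimator: m = -ln(zero fraction).

    Requires at least one zero-count culture; with none the estimator is
    undefined (use the MSS MLE instead).  The CI comes from the exact
    binomial CI on the zero fraction.
    """
    counts = np.asarray(exp.mutant_counts)
    c = len(counts)
    z = int((counts == 0).sum())
    if z == 0:
        raise ValueError(
            "no culture had zero mutants: the P0 estimator is undefined; "
            "use mss_mle")
    frac0 = z / c
    m = -np.log(frac0)
    alpha = 1 - conf
    lo_f = stats.beta.ppf(alpha / 2, z, c - z + 1) if z > 0 else 0.0
    hi_f = stats.beta.ppf(1 - alpha / 2, z + 1, c - z) if z < c else 1.0
    # -ln is decreasing: high zero-fraction -> low m
    m_lo = -np.log(hi_f)
    m_hi = -np.log(lo_f)
    nf = exp.n_final
    return FluctuationResult("P0", float(m), float(m / nf),
                             float(max(m_lo, 0.0) / nf), float(m_hi / nf), c)


def _neg_log_lik(log_m: float, uniq: np.ndarray, mult: np.ndarray,
                 n_tail: int, k_max: int) -> float:
    m = np.exp(log_m)
    p = ld_pmf(m, k_max)
    tiny = 1e-300
    ll = float(np.dot(mult, np.log(np.maximum(p[uniq], tiny))))
    if n_tail:
        ll += n_tail * np.log(max(1.0 - p.sum(), tiny))
    return -ll


def mss_mle(exp: FluctuationExperiment, k_cap: int = 10_000,
            conf: float = 0.95) -> FluctuationResult:
    """MSS maximum-likelihood estimate of m from the full count distribution.

    Counts above ``k_cap`` (jackpots) are lumped into a single tail category
    with probability 1 - sum(p_k), the standard numerical-stability device.
    m is found by bounded derivative-free optimisation of the log-likelihood
    over ln m, m in [1e-6, 1e3], relative tolerance 1e-6.
    """
    counts = np.asarray(exp.mutant_counts)
    if len(counts) < 2:
        raise ValueError("need at least two cultures")
    if (counts == 0).all():
        warnings.warn("all counts zero: falling back to the P0 estimator")
        res = p0_estimate(exp, conf)
        return FluctuationResult("MSS-MLE", res.m, res.rate, res.ci_low,
                                 res.ci_high, res.n_cultures)
    retained = counts[counts <= k_cap]
    n_tail = int((counts > k_cap).sum())
    uniq, mult = np.unique(retained, return_counts=True)
    k_max = int(uniq.max()) if len(uniq) else 0
    res = optimize.minimize_scalar(
        _neg_log_lik, bounds=(np.log(1e-6), np.log(1e3)), method="bounded",
        args=(uniq, mult, n_tail, k_max), options={"xatol": 1e-7})
    m = float(np.exp(res.x))
    c = len(counts)
    sigma = 1.225 * m ** (-0.315) / np.sqrt(c)
    z = stats.norm.ppf(0.5 + conf / 2)
    nf = exp.n_final
    return FluctuationResult(
        "MSS-MLE", m, m / nf,
        float(np.exp(np.log(m) - z * sigma) / nf),
        float(np.exp(np.log(m) + z * sigma) / nf), c)
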