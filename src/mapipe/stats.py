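"""Bias, proximity and spectrum-comparison statistics.

- insertion/deletion bias per motif class: Pearson chi-square against a 50:50
  expectation, df=1, no continuity correction (the convention under which the
  published p-values for the C/G and AT/TA classes reproduce exactly);
- repeat-proximity: two-sample Kolmogorov-Smirnov on nearest-neighbour
  distance ECDFs (mutated repeats vs all genomic repeats), asymptotic p;
- between-strain spectrum comparison: Monte-Carlo Fisher-type exact test for
  a 2 x k category table, with the chi-square p reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BiasResult",
    "ProximityResult",
    "indel_bias_test",
    "proximity_ks",
    "cumulative_within",
    "compare_spectra",
    "ecdf",
]


@dataclass(frozen=True)
class BiasResult:
    motif_class: str
    n_ins: int
    n_del: int
    majority_fraction: float
    majority_sign: str
    chi2: float
    p: float
    low_n: bool           # fewer than 5 events: computed but flagged

    @property
    def n(self) -> int:
        return self.n_ins + self.n_del

    @property
    def deletion_fraction(self) -> float:
        return self.n_del / self.n

    @property
    def insertion_fraction(self) -> float:
        return self.n_ins / self.n


def indel_bias_test(n_ins: int, n_del: int, motif_class: str = "") -> BiasResult:
    """Chi-square test of insertion vs deletion counts against 50:50.

    No Yates correction (df=1).  Totals under 5 are flagged low_n: the test is
    still computed but should not be reported as significant on its own.
    """
    n = n_ins + n_del
    if n < 1:
        raise ValueError("need at least one event")
    e = n / 2.0
    chi2 = (n_ins - e) ** 2 / e + (n_del - e) ** 2 / e
    p = float(stats.chi2.sf(chi2, df=1)) if chi2 > 0 else 1.0
    maj = max(n_ins, n_del) / n
    return BiasResult(
        motif_class=motif_class, n_ins=n_ins, n_del=n_del,
        majority_fraction=maj,
        majority_sign="insertion" if n_ins >= n_del else "deletion",
        chi2=float(chi2), p=p, low_n=n < 5)


def ecdf(sample: np.ndarray) -> pd.DataFrame:
    """Right-continuous empirical CDF evaluated at the sorted unique values."""
    x = np.sort(np.asarray(sample, dtype=float))
    xs, counts = np.unique(x, return_counts=True)
    return pd.DataFrame({"x": xs, "cdf": np.cumsum(counts) / len(x)})


@dataclass
class ProximityResult:
    d_mutated: np.ndarray
    d_all: np.ndarray
    ks_D: float
    p: float
    ecdf_mutated: pd.DataFrame = field(repr=False, default=None)
    ecdf_all: pd.DataFrame = field(repr=False, default=None)


def proximity_ks(
    mutated_distances: Sequence[float],
    all_distances: Sequence[float],
) -> ProximityResult:
    """Two-sample KS comparison of nearest-repeat distance distributions.

    D is the sup-difference of the two ECDFs over the pooled support; p is the
    asymptotic Smirnov value with effective n = n1*n2/(n1+n2) (appropriate at
    the sample sizes repeat censuses produce).  NaN distances (single-locus
    chromosomes) are dropped.
    """
    dm = np.asarray(mutated_distances, dtype=float)
    da = np.asarray(all_distances, dtype=float)
    dm, da = dm[~np.isnan(dm)], da[~np.isnan(da)]
    if len(dm) < 2 or len(da) < 2:
        raise ValueError("each sample needs >= 2 defined distances")
    res = stats.ks_2samp(dm, da, alternative="two-sided", method="asymp")
    return ProximityResult(
        d_mutated=dm, d_all=da, ks_D=float(res.statistic), p=float(res.pvalue),
        ecdf_mutated=ecdf(dm), ecdf_all=ecdf(da))


def cumulative_within(distances: Sequence[float], cutoff_bp: float) -> float:
    """Fraction of nearest-neighbour distances <= cutoff (NaN dropped)."""
    d = np.asarray(distances, dtype=float)
    d = d[~np.isnan(d)]
    if len(d) == 0:
        raise ValueError("no defined distances")
    return float((d <= cutoff_bp).mean())


def _log_table_prob(row1: np.ndarray, col_totals: np.ndarray, n1: int) -> float:
    """log P(table | margins) for a 2 x k table under the hypergeometric null:
    prod_j C(c_j, a_j) / C(N, n1), with a_j the row-1 entries."""
    from scipy.special import gammaln

    def lchoose(n, k):
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    return float(np.sum(lchoose(col_totals, row1)) -
                 lchoose(col_totals.sum(), n1))


def compare_spectra(
    counts_a: Sequence[int],
    counts_b: Sequence[int],
    n_mc: int = 100_000,
    seed: int | None = None,
) -> dict:
    """Fisher-type exact comparison of two spectra (2 x k table), Monte Carlo.

    p is the null probability of a margins-fixed table whose hypergeometric
    likelihood is <= that of the observed table (the standard exact-test
    ordering), estimated from ``n_mc`` multivariate-hypergeometric draws; the
    asymptotic chi-square p is reported alongside.  The seed is mandatory for
    reproducibility.
    """
    a = np.asarray(counts_a, dtype=int)
    b = np.asarray(counts_b, dtype=int)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need two equal-length count vectors with k >= 2")
    if a.sum() < 1 or b.sum() < 1:
        raise ValueError("both spectra need at least one event")
    if seed is None:
        raise ValueError("a seed is required for the Monte-Carlo p-value")
    col = a + b
    n1 = int(a.sum())
    obs = _log_table_prob(a, col, n1)
    rng = np.random.default_rng(seed)
    draws = rng.multivariate_hypergeometric(col, n1, size=n_mc)
    from scipy.special import gammaln
    lch = lambda n, k: gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
    logp = lch(col, draws).sum(axis=1) - lch(col.sum(), n1)
    # tolerance guards float ties against the observed likelihood
    p_mc = float((logp <= obs + 1e-9).mean())
    keep = col > 0
    chi2, chi2_p, dof, _ = stats.chi2_contingency(
        np.vstack([a[keep], b[keep]]), correction=False)
    return {"p_mc": p_mc, "n_mc": n_mc, "chi2": float(chi2),
            "chi2_p": float(chi2_p), "df": int(dof)}
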