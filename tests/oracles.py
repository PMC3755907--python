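"""Independent brute-force oracles used to validate the implementation.

These deliberately re-derive results from first principles with naive
algorithms (character-by-character scans, explicit sup over pooled support,
closed forms) and share no code with the package.
"""

from __future__ import annotations

import math

import numpy as np

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _primitive(unit: str) -> bool:
    n = len(unit)
    return not any(n % d == 0 and unit == unit[:d] * (n // d)
                   for d in range(1, n))


def brute_force_repeats(seq: str, min_hpr_len: int = 3, min_units: int = 3,
                        max_unit_len: int = 4) -> set[tuple[int, int, str]]:
    """All maximal perfect tandem repeats as (start, end, unit) triples.

    A tract start is any position where the period-k self-match begins
    (cannot be extended one base left); the tract is grown one character at a
    time and truncated to full units.
    """
    out: set[tuple[int, int, str]] = set()
    n = len(seq)
    for k in range(1, max_unit_len + 1):
        for a in range(n - k):
            if seq[a] != seq[a + k]:
                continue
            if a > 0 and seq[a - 1] == seq[a - 1 + k]:
                continue  # extendable left: not a tract start
            j = a
            while j + k < n and seq[j] == seq[j + k]:
                j += 1
            tract_len = (j + k) - a
            n_units = tract_len // k
            unit = seq[a:a + k]
            if k == 1:
                if tract_len < min_hpr_len:
                    continue
            elif n_units < min_units or not _primitive(unit):
                continue
            out.add((a, a + n_units * k, unit))
    return out


def ks_statistic_brute(x, y) -> float:
    """Two-sample KS D as an explicit sup over the pooled support."""
    x = sorted(x)
    y = sorted(y)
    support = sorted(set(x) | set(y))
    d = 0.0
    for v in support:
        fx = sum(1 for t in x if t <= v) / len(x)
        fy = sum(1 for t in y if t <= v) / len(y)
        d = max(d, abs(fx - fy))
    return d


def chi2_1df_p_closed_form(chi2: float) -> float:
    """P(X > chi2) for 1 df via the normal tail: 2 * (1 - Phi(sqrt(chi2)))."""
    return 2.0 * (1.0 - 0.5 * (1.0 + math.erf(math.sqrt(chi2) / math.sqrt(2.0))))


def nearest_distances_brute(intervals: list[tuple[int, int]]) -> list[float]:
    """All-pairs minimum end-to-start gaps for loci on one chromosome."""
    out = []
    for i, (s1, e1) in enumerate(intervals):
        best = math.inf
        for j, (s2, e2) in enumerate(intervals):
            if i == j:
                continue
            gap = max(0, max(s1, s2) - min(e1, e2))
            best = min(best, gap)
        out.append(best)
    return out


def ols_r2_brute(x, y) -> float:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    b = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
    a = y.mean() - b * x.mean()
    resid = y - (a + b * x)
    ss_res = (resid ** 2).sum()
    ss_tot = ((y - y.mean()) ** 2).sum()
    return 1.0 - ss_res / ss_tot
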