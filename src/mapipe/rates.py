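"""Mutation-rate estimation and spectrum accounting for MA experiments.

Rates are events per opportunity, where opportunity is target size x
generations x lineages (bp-generations for per-bp rates, repeat-generations
for per-repeat rates).  Confidence intervals on event counts are exact
Poisson (Garwood); the repeat-length rate curve is fitted in two regimes, an
exponential increase over 3-8 units (OLS on log10 rate, fold-per-unit =
10^slope) and a linear continuation at >= 9 units.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .classify import ClassifiedMutation
from .repeats import RepeatCensus

logger = logging.getLogger(__name__)

__all__ = [
    "RateEstimate",
    "SpectrumTable",
    "LengthRateCurve",
    "poisson_ci",
    "per_bp_rate",
    "fold_induction",
    "spectrum_table",
    "per_repeat_rate_by_length",
    "fit_regimes",
    "chromosome_size_regression",
    "replication_timing_test",
    "coding_fraction",
    "WILD_TYPE_REFERENCE_RATE",
    "DEFAULT_CALLABLE_GENOME_BP",
    "DEFAULT_GENERATIONS",
]

#: wild-type per-bp per-generation reference rate from the prior literature
WILD_TYPE_REFERENCE_RATE = 3.3e-10
#: callable genome size (bp) consistent with the per-lineage event counts and
#: printed per-bp rates of the source MA experiment
DEFAULT_CALLABLE_GENOME_BP = 1.216e7
DEFAULT_GENERATIONS = 170

SPECTRUM_CATEGORIES = [
    "deletions_at_homopolymers",
    "insertions_at_homopolymers",
    "transitions",
    "transversions",
    "insertions_at_microsatellites",
    "deletions_at_microsatellites",
]


def poisson_ci(events: int, conf: float = 0.95) -> tuple[float, float]:
    """Exact (Garwood) two-sided Poisson CI on a count."""
    a = 1.0 - conf
    lo = 0.0 if events == 0 else stats.chi2.ppf(a / 2, 2 * events) / 2
    hi = stats.chi2.ppf(1 - a / 2, 2 * events + 2) / 2
    return lo, hi


@dataclass(frozen=True)
class RateEstimate:
    events: int
    opportunity: float    # bp-generations or repeat-generations
    rate: float
    ci_low: float
    ci_high: float

    def fold(self, reference_rate: float = WILD_TYPE_REFERENCE_RATE) -> float:
        return fold_induction(self.rate, reference_rate)


def _rate_estimate(events: int, opportunity: float) -> RateEstimate:
    if opportunity <= 0:
        raise ValueError("opportunity must be positive")
    lo, hi = poisson_ci(events)
    return RateEstimate(events, opportunity, events / opportunity,
                        lo / opportunity, hi / opportunity)


def per_bp_rate(
    events: int,
    n_lineages: int,
    generations: float = DEFAULT_GENERATIONS,
    callable_genome_bp: float = DEFAULT_CALLABLE_GENOME_BP,
) -> RateEstimate:
    """Per-bp per-generation rate: events / (lineages x generations x callable bp)."""
    if n_lineages <= 0 or generations <= 0 or callable_genome_bp <= 0:
        raise ValueError("all inputs must be positive")
    return _rate_estimate(events, n_lineages * generations * callable_genome_bp)


def fold_induction(rate: float, reference_rate: float = WILD_TYPE_REFERENCE_RATE) -> float:
    """Ratio of a strain's rate to the wild-type reference rate (unrounded)."""
    if reference_rate <= 0:
        raise ValueError("reference_rate must be positive")
    return rate / reference_rate


@dataclass
class SpectrumTable:
    """Six-category mutation spectrum with subtotals and percentages."""

    counts: pd.Series   # indexed by SPECTRUM_CATEGORIES

    @classmethod
    def from_counts(cls, del_hpr: int, ins_hpr: int, transitions: int,
                    transversions: int, ins_ms: int, del_ms: int) -> "SpectrumTable":
        return cls(pd.Series(
            [del_hpr, ins_hpr, transitions, transversions, ins_ms, del_ms],
            index=SPECTRUM_CATEGORIES, dtype=int))

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def percentages(self) -> pd.Series:
        return 100.0 * self.counts / self.total

    @property
    def subtotals(self) -> pd.Series:
        c = self.counts
        return pd.Series({
            "homopolymer_indels": int(c["deletions_at_homopolymers"]
                                      + c["insertions_at_homopolymers"]),
            "substitutions": int(c["transitions"] + c["transversions"]),
            "microsatellite_indels": int(c["insertions_at_microsatellites"]
                                         + c["deletions_at_microsatellites"]),
        })

    @property
    def subtotal_percentages(self) -> pd.Series:
        return 100.0 * self.subtotals / self.total

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"count": self.counts,
                             "pct_of_total": self.percentages.round(1)})


def spectrum_table(muts: Sequence[ClassifiedMutation]) -> SpectrumTable:
    """Tally classified mutations into the six-category spectrum.

    Indels are split by repeat type (homopolymer vs larger microsatellite);
    indels not assigned to any repeat are excluded from the table with a log
    note (in the source data only two such events existed).  Unclassified
    rows raise.
    """
    counts = dict.fromkeys(SPECTRUM_CATEGORIES, 0)
    bad, unassigned = [], 0
    for m in muts:
        if m.kind == "SNV":
            if m.ts_tv == "transition":
                counts["transitions"] += 1
            elif m.ts_tv == "transversion":
                counts["transversions"] += 1
            else:
                bad.append(m)
        elif m.kind == "indel":
            if m.repeat is None:
                unassigned += 1
                continue
            at_hpr = m.repeat.unit_len == 1
            if m.indel_sign == "deletion":
                counts["deletions_at_homopolymers" if at_hpr
                       else "deletions_at_microsatellites"] += 1
            elif m.indel_sign == "insertion":
                counts["insertions_at_homopolymers" if at_hpr
                       else "insertions_at_microsatellites"] += 1
            else:
                bad.append(m)
        else:
            bad.append(m)
    if bad:
        raise ValueError(f"unclassified records: {bad[:5]}")
    if unassigned:
        logger.info("%d indels not at a censused repeat (excluded from table)",
                    unassigned)
    return SpectrumTable(pd.Series(counts, dtype=int)[SPECTRUM_CATEGORIES])


@dataclass
class LengthRateCurve:
    """Per (motif_class, length) mutation rates with regime fits attached."""

    table: pd.DataFrame  # columns: motif_class, length, events, census, rate, ci_low, ci_high, dropout_flag
    n_lineages: int
    generations: float
    exp_fit: Optional[dict] = None
    lin_fit: Optional[dict] = None


def per_repeat_rate_by_length(
    events_by_class_length: pd.Series,
    census: RepeatCensus,
    n_lineages: int,
    generations: float = DEFAULT_GENERATIONS,
    dropout_len_bp: int = 14,
) -> LengthRateCurve:
    """Rate per repeat per generation for each (motif_class, length).

    ``events_by_class_length`` is a Series indexed by (motif_class, length);
    length is run bp for homopolymers, unit count otherwise.  Rows whose
    repeat tract is >= ``dropout_len_bp`` long are flagged: indel detection
    drops off for long repeats, so those rates are potential underestimates.
    """
    cens = census.by_class_and_length()
    rows = []
    for (cls, length), n_census in cens.items():
        ev = int(events_by_class_length.get((cls, length), 0))
        opp = n_census * n_lineages * generations
        lo, hi = poisson_ci(ev)
        unit_len = len(cls.split("/")[0])
        rows.append({
            "motif_class": cls, "length": int(length), "events": ev,
            "census": int(n_census), "rate": ev / opp,
            "ci_low": lo / opp, "ci_high": hi / opp,
            "dropout_flag": length * unit_len >= dropout_len_bp,
        })
    for (cls, length), ev in events_by_class_length.items():
        if ev > 0 and (cls, length) not in cens.index:
            raise ValueError(
                f"events at ({cls}, L={length}) but census has no such repeats")
    table = pd.DataFrame(rows).sort_values(["motif_class", "length"],
                                           ignore_index=True)
    return LengthRateCurve(table, n_lineages, generations)


def fit_regimes(
    curve: LengthRateCurve,
    motif_class: Optional[str] = None,
    exp_range: tuple[int, int] = (3, 8),
    lin_min_length: int = 9,
) -> LengthRateCurve:
    """Fit the exponential (3-8 units) and linear (>= 9 units) regimes.

    Exponential: OLS of log10(rate) on length over ``exp_range`` (zero-rate
    lengths excluded and reported); fold_per_unit = 10^slope.  Linear: OLS of
    rate on length for length >= ``lin_min_length`` with R^2.  A regime with
    too few informative lengths is marked unavailable rather than fabricated.
    """
    t = curve.table
    if motif_class is not None:
        t = t[t["motif_class"] == motif_class]
    exp_t = t[(t["length"] >= exp_range[0]) & (t["length"] <= exp_range[1])]
    nz = exp_t[exp_t["rate"] > 0]
    excluded = sorted(exp_t.loc[exp_t["rate"] <= 0, "length"].tolist())
    if len(nz) >= 3:
        res = stats.linregress(nz["length"], np.log10(nz["rate"]))
        curve.exp_fit = {
            "slope": res.slope, "intercept": res.intercept,
            "r2": res.rvalue ** 2, "fold_per_unit": 10 ** res.slope,
            "n_lengths": len(nz), "zero_rate_lengths_excluded": excluded,
            "motif_class": motif_class,
        }
    else:
        curve.exp_fit = None
        logger.warning("exponential fit unavailable: %d nonzero lengths", len(nz))
    lin_t = t[(t["length"] >= lin_min_length)]
    if len(lin_t) >= 2 and lin_t["length"].nunique() >= 2:
        res = stats.linregress(lin_t["length"], lin_t["rate"])
        curve.lin_fit = {"slope": res.slope, "intercept": res.intercept,
                         "r2": res.rvalue ** 2, "n_lengths": len(lin_t),
                         "motif_class": motif_class}
    else:
        curve.lin_fit = None
    return curve


def chromosome_size_regression(
    mutation_chroms: Sequence[str],
    chrom_lengths: dict[str, int],
) -> tuple[pd.DataFrame, float]:
    """Mutation count per chromosome regressed on chromosome length (OLS with
    intercept); returns the per-chromosome table and R^2."""
    if len(chrom_lengths) < 3:
        raise ValueError("need >= 3 chromosomes")
    counts = pd.Series(0, index=list(chrom_lengths))
    vc = pd.Series(mutation_chroms).value_counts()
    counts.loc[vc.index.intersection(counts.index)] = vc
    df = pd.DataFrame({"length": pd.Series(chrom_lengths), "count": counts})
    if df["length"].nunique() == 1:
        # equal-length chromosomes: size explains no count variation
        return df, 0.0
    res = stats.linregress(df["length"], df["count"])
    return df, res.rvalue ** 2


def replication_timing_test(
    mutation_positions: pd.DataFrame,   # columns chrom, pos
    timing_bins: pd.DataFrame,          # columns chrom, start, end, bin
) -> dict:
    """Chi-square homogeneity of mutation counts across replication-timing
    bins, with expectation proportional to bin bp.

    Bins with expected count < 1 are merged into the neighbouring (next) bin
    label and the merge is logged.  Returns statistic, df, p and the table.
    """
    bp = timing_bins.assign(bp=timing_bins["end"] - timing_bins["start"]) \
                    .groupby("bin")["bp"].sum().sort_index()
    # assign each mutation to a bin
    obs = pd.Series(0, index=bp.index, dtype=float)
    for chrom, grp in mutation_positions.groupby("chrom"):
        tb = timing_bins[timing_bins["chrom"] == chrom]
        for _, r in tb.iterrows():
            inside = ((grp["pos"] >= r["start"]) & (grp["pos"] < r["end"])).sum()
            obs[r["bin"]] += inside
    total = obs.sum()
    exp = bp / bp.sum() * total
    # merge sparse bins forward
    labels, o, e = list(obs.index), obs.to_numpy(dtype=float), exp.to_numpy(dtype=float)
    i = 0
    while i < len(o):
        if e[i] < 1 and len(o) > 1:
            j = i + 1 if i + 1 < len(o) else i - 1
            logger.info("merging bin %s (expected %.2f) into %s",
                        labels[i], e[i], labels[j])
            o[j] += o[i]
            e[j] += e[i]
            o = np.delete(o, i); e = np.delete(e, i); del labels[i]
        else:
            i += 1
    chi2 = float(((o - e) ** 2 / e).sum())
    df = len(o) - 1
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    return {"chi2": chi2, "df": df, "p": p,
            "table": pd.DataFrame({"bin": labels, "observed": o, "expected": e})}


def coding_fraction(
    muts: Sequence[ClassifiedMutation],
    coding_intervals: pd.DataFrame,     # columns chrom, start, end
) -> dict[str, float]:
    """Fraction of mutations inside coding intervals, split by SNV/indel.

    Intervals are merged per chromosome before the point-in-interval test."""
    merged: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, grp in coding_intervals.groupby("chrom"):
        ivs = grp.sort_values("start")[["start", "end"]].to_numpy()
        out = []
        for s, e in ivs:
            if out and s <= out[-1][1]:
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append([s, e])
        arr = np.array(out)
        merged[chrom] = (arr[:, 0], arr[:, 1])

    def inside(chrom: str, pos: int) -> bool:
        if chrom not in merged:
            return False
        starts, ends = merged[chrom]
        i = np.searchsorted(starts, pos, side="right") - 1
        return i >= 0 and pos < ends[i]

    res = {}
    for kind in ("SNV", "indel"):
        sub = [m for m in muts if m.kind == kind]
        if not sub:
            res[kind] = float("nan")
            continue
        res[kind] = sum(inside(m.call.chrom, m.call.pos) for m in sub) / len(sub)
    return res
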