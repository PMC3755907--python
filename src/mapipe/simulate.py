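"""Synthetic data generation for the whole pipeline.

Three generators make every stage testable offline:

- a genome with a controlled tandem-repeat landscape (each embedded locus is
  maximal by construction, so the census recovers it at exact coordinates);
- mutation-accumulation lineages evolved under length-dependent replication
  slippage (rate(class, L) = base * fold^(L-3), direction by per-class bias,
  run length updated as slippage proceeds) plus uniform single-base
  substitutions, emitted as left-aligned endpoint-vs-ancestor calls under the
  neutral-accumulation model (every surviving mutation fixes);
- fluctuation cultures grown with per-division mutation.

All outputs are bit-reproducible from (seed, config); per-lineage RNG streams
are derived from the master seed by fixed offsets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
import numpy as np
import pandas as pd

from .repeats import (RepeatCensus, RepeatLocus, canonical_motif,
                      find_repeats, revcomp)

logger = logging.getLogger(__name__)

__all__ = [
    "SimConfig",
    "default_repeat_spec",
    "generate_genome",
    "simulate_ma_lines",
    "apply_detection_dropout",
    "simulate_fluctuation",
    "make_coding_intervals",
    "make_timing_bins",
]

CALL_COLUMNS = ["lineage_id", "chrom", "pos", "ref", "alt",
                "span_reads_sample", "span_reads_ancestor",
                "locus_id", "ref_len_bp"]


def default_repeat_spec() -> list[tuple[str, int, int]]:
    """(embedded unit, length, copies) for a 1 Mb genome.

    Lengths are bp for homopolymers and units otherwise.  Copy numbers fall
    ~3-fold per extra unit, mirroring the roughly geometric length spectrum
    of repeats in the yeast genome; relative class abundances mirror the
    strong A/T-homopolymer dominance of the observed mutation counts.
    """
    spec: list[tuple[str, int, int]] = []
    for unit, counts in [
        ("A", [24000, 8000, 2660, 888, 296, 96]),    # A/T HPRs, L = 3..8 bp
        ("C", [300, 100, 34, 12, 4, 2]),             # C/G HPRs
        ("GT", [1200, 400, 134, 44, 14, 6]),         # GT/CA di, L = 3..8 units
        ("AT", [1200, 400, 134, 44, 14, 6]),         # AT/TA di
        ("GA", [120, 40, 14, 4, 0, 0]),              # GA/CT di
        ("AAT", [60, 20, 6, 0, 0, 0]),               # tri
        ("AAC", [60, 20, 6, 0, 0, 0]),               # tri
        ("AAAT", [20, 8, 0, 0, 0, 0]),               # tetra (censused, no curve)
    ]:
        for i, n in enumerate(counts):
            if n:
                spec.append((unit, 3 + i, n))
    return spec


@dataclass
class SimConfig:
    """Study conditions for the synthetic MA experiment."""

    genome_length: int = 1_000_000
    gc_fraction: float = 0.38          # ~yeast genomic GC
    n_chromosomes: int = 1
    repeat_spec: list[tuple[str, int, int]] = field(default_factory=default_repeat_spec)
    snv_rate: float = 4.8e-9           # per bp per generation (MMR-null SBS rate)
    slippage_base_rate: float = 7.5e-7  # per repeat per generation at L = 3
    slippage_fold_per_unit: float = 4.0
    exp_max_length: int = 8            # exponential regime ends here; linear beyond
    bias: dict = field(default_factory=lambda: {
        "A/T": 0.93, "C/G": 0.74, "AT/TA": 0.37, "GT/CA": 0.65})
    default_bias: float = 0.5          # deletion probability for other classes
    n_lineages: int = 16
    generations: int = 170
    bottleneck_interval: int = 21      # metadata only: accumulation is neutral
    dropout_len: int = 14              # bp; detection falls off at long repeats
    dropout_prob: float = 0.5
    coding_fraction: float = 0.74
    cluster_fraction: float = 0.1      # fraction of loci placed as close pairs
    cluster_gap_max: int = 3
    proximal_boost: float = 1.0        # slippage multiplier near a proximal repeat
    proximal_cutoff_bp: int = 3
    multi_unit_prob: float = 0.0       # probability a slippage step is 2 units

    def __post_init__(self):
        for name in ("gc_fraction", "dropout_prob", "cluster_fraction",
                     "coding_fraction", "default_bias", "multi_unit_prob"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.snv_rate < 0 or self.slippage_base_rate < 0:
            raise ValueError("rates must be non-negative")

    def deletion_prob(self, motif_class: str) -> float:
        return self.bias.get(motif_class, self.default_bias)


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_background(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=n, p=p)]


def _pick_base(rng: np.random.Generator, exclude: str) -> str:
    choices = [b for b in "ACGT" if b not in exclude]
    return choices[rng.integers(len(choices))]


def generate_genome(
    config: SimConfig, seed: int
) -> tuple[dict[str, str], RepeatCensus]:
    """Assemble a genome with the configured embedded repeats.

    Each embedded locus is flanked so that its periodicity cannot extend
    (left flank differs from the unit's last base, right flank from its
    first), and a verification pass rewrites any background base that formed
    an unintended census-size repeat overlapping or adjacent to an embedded
    locus.  Returns (sequences, truth census).  ``cluster_fraction`` of the
    loci are placed as close pairs (gap <= cluster_gap_max) so that
    proximity structure exists.
    """
    rng = np.random.default_rng([seed, 11])
    items: list[tuple[str, int]] = []   # (unit, n_units)
    for unit, length, copies in config.repeat_spec:
        n_units = length if len(unit) == 1 else length
        items.extend([(unit, n_units)] * copies)
    if not items:
        return _finalize_chroms(config, rng,
                                [_random_background(rng, config.genome_length,
                                                    config.gc_fraction)], [])
    order = rng.permutation(len(items))
    items = [items[i] for i in order]

    # group into blocks: pairs (clustered) or singletons
    n_pairs = int(config.cluster_fraction * len(items) / 2)
    blocks: list[list[tuple[str, int]]] = []
    i = 0
    for _ in range(n_pairs):
        blocks.append([items[i], items[i + 1]])
        i += 2
    blocks.extend([[it] for it in items[i:]])
    rng.shuffle(blocks)

    def unit_seq(unit: str, n: int) -> str:
        return unit * n

    pieces: list[str] = []   # alternating background gaps and repeat blocks
    truth: list[tuple[int, int, str]] = []  # start, end, unit (global coords later)
    block_strs: list[tuple[str, list[tuple[int, int, str]]]] = []
    for block in blocks:
        s = ""
        loci_local: list[tuple[int, int, str]] = []
        prev_unit = None
        for j, (unit, n) in enumerate(block):
            if j > 0:
                gap = int(rng.integers(0, config.cluster_gap_max + 1))
                # gap 0 is only safe when neither run extends into the other
                if gap == 0 and (unit[0] == prev_unit[0] or
                                 prev_unit[-1] == unit[-1]):
                    gap = 1
                if gap:
                    g0 = _pick_base(rng, prev_unit[0] + unit[-1])
                    fill = (g0 + "".join(
                        _pick_base(rng, "") for _ in range(gap - 1)))
                    # last gap base must not left-extend the next locus
                    if fill[-1] == unit[-1]:
                        fill = fill[:-1] + _pick_base(rng, unit[-1] + prev_unit[0])
                    s += fill
            loci_local.append((len(s), len(s) + len(unit) * n, unit))
            s += unit_seq(unit, n)
            prev_unit = unit
        first_unit, last_unit = block[0][0], block[-1][0]
        left = _pick_base(rng, first_unit[-1])
        right = _pick_base(rng, last_unit[0])
        s = left + s + right
        loci_local = [(a + 1, b + 1, u) for a, b, u in loci_local]
        block_strs.append((s, loci_local))

    total_block = sum(len(s) for s, _ in block_strs)
    n_gaps = len(block_strs) + 1
    spare = config.genome_length - total_block - 2 * n_gaps
    if spare < 0:
        raise ValueError(
            f"embedded repeats ({total_block} bp + spacing) do not fit in "
            f"{config.genome_length} bp")
    gap_lens = rng.multinomial(spare, np.full(n_gaps, 1 / n_gaps)) + 2

    parts: list[np.ndarray] = []
    pos = 0
    for g, (s, loci_local) in zip(gap_lens, block_strs):
        parts.append(_random_background(rng, int(g), config.gc_fraction))
        pos += int(g)
        parts.append(np.frombuffer(s.encode(), dtype=np.uint8))
        for a, b, u in loci_local:
            truth.append((pos + a, pos + b, u))
        pos += len(s)
    parts.append(_random_background(rng, int(gap_lens[-1]), config.gc_fraction))
    genome = np.concatenate(parts)
    return _finalize_chroms(config, rng, [genome], truth)


def _finalize_chroms(config, rng, arrays, truth):
    genome = arrays[0]
    truth.sort()
    # split into chromosomes at repeat-free cut points
    n_chrom = max(1, config.n_chromosomes)
    cuts = [0]
    if n_chrom > 1:
        bounds = np.linspace(0, len(genome), n_chrom + 1).astype(int)[1:-1]
        starts = np.array([t[0] for t in truth]) if truth else np.array([0])
        ends = np.array([t[1] for t in truth]) if truth else np.array([0])
        for b in bounds:
            i = np.searchsorted(ends, b)
            # nudge the cut out of any locus
            if i < len(starts) and starts[i] < b < ends[i]:
                b = int(ends[i])
            cuts.append(int(b))
    cuts.append(len(genome))

    sequences: dict[str, str] = {}
    loci: list[RepeatLocus] = []
    for c in range(len(cuts) - 1):
        name = f"chr{c + 1}"
        lo, hi = cuts[c], cuts[c + 1]
        sequences[name] = genome[lo:hi].tobytes().decode()
        for a, b, u in truth:
            if lo <= a and b <= hi:
                loci.append(RepeatLocus(name, a - lo, b - lo, u,
                                        canonical_motif(u)))
    census = RepeatCensus(loci)
    _repair_unintended(sequences, census, rng)
    return sequences, census


def _repair_unintended(sequences: dict[str, str], truth: RepeatCensus,
                       rng: np.random.Generator, margin: int = 8) -> None:
    """Rewrite background bases that formed a census-size repeat overlapping
    or adjacent (gap <= 1) to an embedded locus."""
    by_chrom: dict[str, list[RepeatLocus]] = {}
    for l in truth:
        by_chrom.setdefault(l.chrom, []).append(l)
    for chrom, loci in by_chrom.items():
        seq = np.frombuffer(sequences[chrom].encode(), dtype=np.uint8).copy()
        protected = np.zeros(len(seq), dtype=bool)
        for l in loci:
            protected[l.start:l.end] = True
        truth_keys = {(l.start, l.end, l.unit) for l in loci}
        t_starts = np.array(sorted(l.start for l in loci))
        t_ends = np.array(sorted(l.end for l in loci))

        def near_truth(a: int, b: int) -> bool:
            # overlaps or within 1 bp of some truth locus
            return bool((np.searchsorted(t_starts, b + 1, side="right")
                         > np.searchsorted(t_ends, a - 1, side="left")))

        def offenders_in(window_seq: str, lo: int) -> list[tuple[int, int]]:
            out = []
            for f in find_repeats({chrom: window_seq}):
                a, b = f.start + lo, f.end + lo
                if (a, b, f.unit) in truth_keys:
                    continue
                if near_truth(a, b):
                    out.append((a, b))
            return out

        todo = offenders_in(seq.tobytes().decode(), 0)
        for _ in range(12):
            if not todo:
                break
            nxt: list[tuple[int, int]] = []
            for a, b in todo:
                idx = [i for i in range(a, b) if not protected[i]]
                if not idx:    # purely inside embedded loci: structural, leave
                    continue
                i = idx[len(idx) // 2]
                seq[i] = ord(_pick_base(rng, chr(seq[i])))
                lo = max(0, a - margin)
                hi = min(len(seq), b + margin)
                nxt.extend(offenders_in(seq[lo:hi].tobytes().decode(), lo))
            todo = sorted(set(nxt))
        sequences[chrom] = seq.tobytes().decode()


def _slippage_rate(config: SimConfig, lengths: np.ndarray) -> np.ndarray:
    """Per-repeat per-generation slippage rate at the current lengths
    (bp for HPRs, units otherwise); repeats shorter than 2 units/bp are inert.

    The rate rises exponentially (base * fold^(L-3)) up to ``exp_max_length``
    units and continues linearly beyond it, mirroring the observed
    exponential-to-linear crossover in repeat instability (a rate law that
    keeps growing exponentially would also make insertion-biased loci ratchet
    away within an experiment)."""
    base, fold = config.slippage_base_rate, config.slippage_fold_per_unit
    lmax = config.exp_max_length
    r_exp = base * fold ** (np.minimum(lengths, lmax) - 3.0)
    r_top = base * fold ** (lmax - 3.0)
    slope = r_top * (1.0 - 1.0 / fold)        # continues the last exponential step
    r = np.where(lengths <= lmax, r_exp, r_top + slope * (lengths - lmax))
    return np.where(lengths >= 2, r, 0.0)


def simulate_ma_lines(
    sequences: dict[str, str],
    truth: RepeatCensus,
    config: SimConfig,
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Evolve MA lineages and emit endpoint calls plus the truth event table.

    Per generation and lineage: SNVs arrive as Poisson(snv_rate * G) at
    uniform positions with a uniform alternative base; each repeat locus
    slips with Poisson(rate(class, current length)), direction drawn from the
    per-class deletion bias, and the length is updated so later generations
    see the new length.  The endpoint VCF-style calls carry the net change
    per locus (left-aligned, anchored).  Returns (calls, truth_events).
    """
    from .repeats import nearest_neighbor_distances

    loci = list(truth)
    n_loci = len(loci)
    L0 = np.array([l.length for l in loci], dtype=float)
    classes = [l.motif_class for l in loci]
    delp = np.array([config.deletion_prob(c) for c in classes])
    boost = np.ones(n_loci)
    if config.proximal_boost != 1.0 and n_loci > 1:
        nn = nearest_neighbor_distances(truth)["nn_distance"].to_numpy()
        boost[np.nan_to_num(nn, nan=np.inf) <= config.proximal_cutoff_bp] = \
            config.proximal_boost

    genome_bp = sum(len(s) for s in sequences.values())
    chrom_names = list(sequences)
    chrom_lens = np.array([len(sequences[c]) for c in chrom_names])
    chrom_offsets = np.concatenate([[0], np.cumsum(chrom_lens)])

    call_rows: list[dict] = []
    event_rows: list[dict] = []
    step = np.array([1, 2])
    step_p = np.array([1 - config.multi_unit_prob, config.multi_unit_prob])

    # slippage rates only depend on integer length: precompute a lookup
    max_l = int(L0.max() if n_loci else 0) + config.generations + 2
    rate_lut = _slippage_rate(config, np.arange(max_l + 1, dtype=float))

    for li in range(config.n_lineages):
        lineage = f"L{li + 1:02d}"
        rng = np.random.default_rng([seed, 1000 + li])
        L = L0.copy()
        net = np.zeros(n_loci, dtype=int)
        for gen in range(1, config.generations + 1):
            lam = rate_lut[np.minimum(L, max_l).astype(int)] * boost
            k = rng.poisson(lam)
            hit = np.flatnonzero(k)
            for i in hit:
                for _ in range(int(k[i])):
                    units = int(rng.choice(step, p=step_p))
                    is_del = rng.random() < delp[i]
                    if is_del:
                        units = -min(units, int(L[i]))
                        if units == 0:
                            continue
                    L[i] += units
                    net[i] += units
                    event_rows.append({
                        "lineage_id": lineage, "locus_id": i,
                        "chrom": loci[i].chrom, "start": loci[i].start,
                        "motif_class": classes[i], "length_at_event": L[i] - units,
                        "generation": gen,
                        "sign": "deletion" if units < 0 else "insertion",
                        "units": units,
                    })
            n_snv = rng.poisson(config.snv_rate * genome_bp)
            if n_snv:
                gpos = rng.integers(0, genome_bp, size=n_snv)
                for gp in gpos:
                    ci = int(np.searchsorted(chrom_offsets, gp, side="right") - 1)
                    chrom = chrom_names[ci]
                    pos = int(gp - chrom_offsets[ci])
                    ref = sequences[chrom][pos]
                    alt = _pick_base(rng, ref)
                    call_rows.append({
                        "lineage_id": lineage, "chrom": chrom, "pos": pos,
                        "ref": ref, "alt": alt, "locus_id": -1,
                        "ref_len_bp": 0, "generation": gen})

        for i in np.flatnonzero(net):
            l = loci[i]
            seq = sequences[l.chrom]
            k = l.unit_len
            d = int(net[i])
            anchor = seq[l.start - 1] if l.start > 0 else seq[l.end]
            if l.start == 0:
                logger.warning("locus at contig start skipped in VCF emission")
                continue
            if d < 0:
                ref = seq[l.start - 1:l.start + (-d) * k]
                alt = anchor
            else:
                ref = anchor
                alt = anchor + l.unit * d
            call_rows.append({
                "lineage_id": lineage, "chrom": l.chrom, "pos": l.start - 1,
                "ref": ref, "alt": alt, "locus_id": i,
                "ref_len_bp": l.length_bp, "generation": -1})

    calls = pd.DataFrame(
        call_rows, columns=["lineage_id", "chrom", "pos", "ref", "alt",
                            "locus_id", "ref_len_bp", "generation"])
    calls["span_reads_sample"] = pd.NA
    calls["span_reads_ancestor"] = pd.NA
    calls = calls.sort_values(["lineage_id", "chrom", "pos"],
                              ignore_index=True)
    # identical SNV arising twice at one site in one lineage: keep first
    calls = calls.drop_duplicates(
        subset=["lineage_id", "chrom", "pos", "ref", "alt"], ignore_index=True)
    events = pd.DataFrame(
        event_rows, columns=["lineage_id", "locus_id", "chrom", "start",
                             "motif_class", "length_at_event", "generation",
                             "sign", "units"])
    return calls, events


def apply_detection_dropout(
    calls: pd.DataFrame,
    config: SimConfig,
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Detection model for indels at long repeats.

    Indel calls at loci whose reference tract is >= ``dropout_len`` bp are
    removed with probability ``dropout_prob`` (spanning reads rarely traverse
    long repeats); every surviving indel receives simulated spanning-read
    counts >= 3 for both the passaged line and the ancestor.  Returns
    (surviving calls, dropped calls) so detection power can be audited.
    """
    rng = np.random.default_rng([seed, 77])
    calls = calls.copy()
    is_indel = calls["ref"].str.len() != calls["alt"].str.len()
    at_long = is_indel & (calls["ref_len_bp"] >= config.dropout_len)
    u = rng.random(len(calls))
    drop = at_long & (u < config.dropout_prob)
    n_ind = int(is_indel.sum())
    spans_s = 3 + rng.poisson(8, size=n_ind)
    spans_a = 3 + rng.poisson(8, size=n_ind)
    calls.loc[is_indel, "span_reads_sample"] = spans_s
    calls.loc[is_indel, "span_reads_ancestor"] = spans_a
    kept = calls[~drop].reset_index(drop=True)
    dropped = calls[drop].reset_index(drop=True)
    if len(dropped):
        logger.info("detection dropout removed %d of %d long-repeat indels",
                    len(dropped), int(at_long.sum()))
    return kept, dropped


def simulate_fluctuation(
    n_initial: float,
    n_final: float,
    per_division_rate: float,
    n_cultures: int,
    seed: int,
    model: str = "division",
) -> np.ndarray:
    """Forward growth-mutation simulation of fluctuation cultures.

    ``model="division"`` (default) simulates asynchronous exponential growth:
    the number of mutations per culture is Binomial(divisions, rate) with
    mutation times uniform over divisions, and each mutant clone expands
    stochastically to a Geometric(s / n_final) final size (s the population
    size at the mutation) - the growth model whose mutant-count law the MSS
    recursion describes.  ``model="synchronous"`` doubles the whole culture
    each generation with Binomial mutation at each division; its clone sizes
    are exact powers of two, a coarser (historically earlier) discretisation.

    Mutants breed true; there is no plating loss or phenotypic lag.
    """
    if n_final > 1e8:
        raise ValueError("population above 1e8; scale the assay down")
    if not n_final > n_initial >= 1:
        raise ValueError("need n_final > n_initial >= 1")
    if not 0 <= per_division_rate <= 1:
        raise ValueError("per-division rate must be a probability")
    rng = np.random.default_rng([seed, 5])
    if per_division_rate == 1.0:
        # every division yields a mutant daughter; only the inoculum stays wt
        return np.full(n_cultures, int(n_final - n_initial), dtype=np.int64)

    if model == "synchronous":
        g = int(round(np.log2(n_final / n_initial)))
        n_wt = np.full(n_cultures, int(n_initial), dtype=np.int64)
        n_mut = np.zeros(n_cultures, dtype=np.int64)
        for _ in range(g):
            new = rng.binomial(n_wt, per_division_rate)
            n_mut = 2 * n_mut + new
            n_wt = 2 * n_wt - new
        return n_mut
    if model != "division":
        raise ValueError(f"unknown model {model!r}")

    divisions = int(n_final - n_initial)
    k = rng.binomial(divisions, per_division_rate, size=n_cultures)
    total = int(k.sum())
    counts = np.zeros(n_cultures, dtype=np.int64)
    if total:
        # population size at each mutation, uniform over divisions
        s = rng.uniform(n_initial, n_final, size=total)
        clones = rng.geometric(np.minimum(s / n_final, 1.0))
        clones = np.minimum(clones, int(n_final))
        owner = np.repeat(np.arange(n_cultures), k)
        np.add.at(counts, owner, clones)
    return counts


def make_coding_intervals(
    genome_lengths: dict[str, int],
    coding_fraction: float,
    seed: int,
    mean_block: int = 1500,
) -> pd.DataFrame:
    """Alternating coding/intergenic blocks covering the given fraction."""
    rng = np.random.default_rng([seed, 31])
    rows = []
    for chrom, glen in genome_lengths.items():
        pos = 0
        while pos < glen:
            cod = int(max(50, rng.exponential(mean_block)))
            gap = int(max(20, rng.exponential(
                mean_block * (1 - coding_fraction) / max(coding_fraction, 1e-9))))
            end = min(pos + cod, glen)
            rows.append({"chrom": chrom, "start": pos, "end": end})
            pos = end + gap
    return pd.DataFrame(rows)


def make_timing_bins(genome_lengths: dict[str, int], n_bins: int) -> pd.DataFrame:
    """Tile each chromosome into contiguous segments assigned round-robin to
    ``n_bins`` replication-timing bins (10-min-interval analogue)."""
    rows = []
    for chrom, glen in genome_lengths.items():
        edges = np.linspace(0, glen, 4 * n_bins + 1).astype(int)
        for i in range(len(edges) - 1):
            rows.append({"chrom": chrom, "start": int(edges[i]),
                         "end": int(edges[i + 1]), "bin": i % n_bins})
    return pd.DataFrame(rows)
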