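"""Classification of fixed mutations from mutation-accumulation endpoints.

Every call is either a single-base substitution (six strand-collapsed
classes, transition/transversion) or an insertion/deletion.  Indels are
left-aligned and assigned to the tandem-repeat locus whose unit they expand
or contract, since slippage acts within a run.  Two upstream filters from the
study design are provided: a spanning-read callability filter for indels at
repeats and removal of mutations shared across many lineages (those arose in
the common ancestor, not during passaging).  A detector flags substitutions
at the junction of two adjacent repeats that are equivalent to a +1/-1 unit
double-slippage (a repeat boundary shift).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .repeats import RepeatCensus, RepeatLocus, find_repeats, _rotations

logger = logging.getLogger(__name__)

__all__ = [
    "MutationCall",
    "ClassifiedMutation",
    "classify_snv",
    "left_align_indel",
    "assign_indel",
    "classify_all",
    "filter_span_coverage",
    "remove_shared_mutations",
    "detect_boundary_shift",
    "SNV_CLASSES",
]

PURINES = {"A", "G"}

# strand-collapsed substitution classes, keyed by (ref, alt)
_SNV_CLASS = {
    ("G", "A"): "G:C>A:T", ("C", "T"): "G:C>A:T",
    ("A", "G"): "A:T>G:C", ("T", "C"): "A:T>G:C",
    ("G", "T"): "G:C>T:A", ("C", "A"): "G:C>T:A",
    ("G", "C"): "G:C>C:G", ("C", "G"): "G:C>C:G",
    ("A", "T"): "A:T>T:A", ("T", "A"): "A:T>T:A",
    ("A", "C"): "A:T>C:G", ("T", "G"): "A:T>C:G",
}

SNV_CLASSES = ["G:C>A:T", "A:T>G:C", "G:C>T:A", "G:C>C:G", "A:T>T:A", "A:T>C:G"]


@dataclass(frozen=True)
class MutationCall:
    """One fixed mutation in one lineage, VCF-style (ref/alt share an anchor
    base for indels).  ``pos`` is 0-based."""

    lineage_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    span_reads_sample: Optional[int] = None
    span_reads_ancestor: Optional[int] = None

    def __post_init__(self):
        if self.ref == self.alt:
            raise ValueError("ref and alt are identical")

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1


@dataclass(frozen=True)
class ClassifiedMutation:
    call: MutationCall
    kind: str                       # "SNV" | "indel"
    snv_class: Optional[str] = None
    ts_tv: Optional[str] = None     # "transition" | "transversion"
    indel_sign: Optional[str] = None  # "insertion" | "deletion"
    repeat: Optional[RepeatLocus] = None
    units_changed: Optional[int] = None
    boundary_shift: bool = False


def classify_snv(ref: str, alt: str) -> tuple[str, str]:
    """(transition|transversion, strand-collapsed class) for a substitution.

    >>> classify_snv("G", "A")
    ('transition', 'G:C>A:T')
    """
    if len(ref) != 1 or len(alt) != 1:
        raise ValueError("multi-base alleles: route through the indel path")
    if ref == alt or ref not in "ACGT" or alt not in "ACGT":
        raise ValueError(f"invalid substitution {ref}>{alt}")
    ts = (ref in PURINES) == (alt in PURINES)
    return ("transition" if ts else "transversion", _SNV_CLASS[(ref, alt)])


def _indel_diff(ref: str, alt: str) -> tuple[int, str, int]:
    """(offset of breakpoint within ref, inserted-or-deleted sequence, sign).

    Sign is +1 for insertion, -1 for deletion.  Requires a pure indel (one
    allele a prefix of the other after the shared anchor)."""
    if len(ref) == len(alt):
        raise ValueError("not an indel")
    # strip common prefix
    p = 0
    while p < min(len(ref), len(alt)) and ref[p] == alt[p]:
        p += 1
    if len(ref) > len(alt):
        if alt[:p] != ref[:p] or ref[len(ref) - (len(alt) - p):] != alt[p:]:
            pass  # complex allele; treat remainder as the diff anyway
        return p, ref[p:p + (len(ref) - len(alt))], -1
    return p, alt[p:p + (len(alt) - len(ref))], +1


def left_align_indel(chrom_seq: str, pos: int, ref: str, alt: str) -> tuple[int, str, int]:
    """Normalise an indel to its leftmost placement.

    Returns ``(breakpoint, diff, sign)`` where the deleted interval is
    ``[breakpoint, breakpoint + len(diff))`` (sign -1) or the insertion point
    is ``breakpoint`` (sign +1).  Positions reported anywhere inside a repeat
    are ambiguous; left alignment makes assignment deterministic.
    """
    off, diff, sign = _indel_diff(ref, alt)
    bp = pos + off
    while bp > 0 and chrom_seq[bp - 1] == diff[-1]:
        diff = diff[-1] + diff[:-1]
        bp -= 1
    return bp, diff, sign


def assign_indel(
    call: MutationCall,
    census: RepeatCensus,
    chrom_seq: str,
) -> tuple[Optional[RepeatLocus], str, Optional[int]]:
    """Assign a left-aligned indel to the repeat locus it expands/contracts.

    The locus must overlap or touch the indel breakpoint (gap 0 - slippage
    acts within the run) and the inserted/deleted sequence must be a whole
    number of units of the locus, up to rotation.  Ties go to the longest
    locus, then the leftmost.  Returns ``(locus or None, sign, units or None)``.
    """
    bp, diff, s = left_align_indel(chrom_seq, call.pos, call.ref, call.alt)
    sign = "insertion" if s > 0 else "deletion"
    lo, hi = bp, bp + (len(diff) if s < 0 else 0)
    best: Optional[RepeatLocus] = None
    for locus in census.overlapping(call.chrom, lo, hi):
        k = locus.unit_len
        if len(diff) % k != 0:
            continue
        d = len(diff) // k
        if diff[:k] * d != diff or diff[:k] not in _rotations(locus.unit):
            continue
        if best is None or (locus.length_bp, -locus.start) > (best.length_bp, -best.start):
            best = locus
    if best is None:
        logger.debug("unassigned %s at %s:%d (%s)", sign, call.chrom, bp, diff)
        return None, sign, None
    return best, sign, s * (len(diff) // best.unit_len)


def classify_all(
    calls: Iterable[MutationCall],
    census: RepeatCensus,
    sequences: dict[str, str],
    flag_boundary_shifts: bool = True,
) -> list[ClassifiedMutation]:
    """Classify a batch of calls (SNV spectrum + indel-to-repeat assignment)."""
    out = []
    for call in calls:
        if call.is_snv:
            ts_tv, cls = classify_snv(call.ref, call.alt)
            bshift = (
                detect_boundary_shift(call, census, sequences[call.chrom])
                if flag_boundary_shifts else False)
            out.append(ClassifiedMutation(
                call=call, kind="SNV", snv_class=cls, ts_tv=ts_tv,
                boundary_shift=bshift))
        else:
            locus, sign, units = assign_indel(call, census, sequences[call.chrom])
            out.append(ClassifiedMutation(
                call=call, kind="indel", indel_sign=sign, repeat=locus,
                units_changed=units))
    return out


def filter_span_coverage(
    muts: Sequence[ClassifiedMutation],
    min_span: int = 3,
) -> list[ClassifiedMutation]:
    """Callability filter for indels at repeats: keep only those where at
    least ``min_span`` reads traversed the full repeat in both the passaged
    line and its ancestor.  SNVs pass unchanged."""
    kept = []
    for m in muts:
        if m.kind != "indel" or m.repeat is None:
            kept.append(m)
            continue
        if m.call.span_reads_sample is None or m.call.span_reads_ancestor is None:
            raise ValueError(
                "span-read filtering requested but span_reads fields are "
                f"missing for {m.call}")
        if m.call.span_reads_sample >= min_span and m.call.span_reads_ancestor >= min_span:
            kept.append(m)
    return kept


def remove_shared_mutations(
    calls: Sequence[MutationCall],
    min_lineages: int = 3,
) -> list[MutationCall]:
    """Drop variants present in >= min_lineages lineages.

    Identical end-point variants recurring across independently passaged
    lineages almost surely predate the passaging (ancestral growth), so they
    are removed from every lineage."""
    key = lambda c: (c.chrom, c.pos, c.ref, c.alt)
    lineages_per_variant: dict[tuple, set] = {}
    for c in calls:
        lineages_per_variant.setdefault(key(c), set()).add(c.lineage_id)
    shared = {k for k, v in lineages_per_variant.items() if len(v) >= min_lineages}
    kept = [c for c in calls if key(c) not in shared]
    if shared:
        logger.info("removed %d shared variants (%d records)",
                    len(shared), len(calls) - len(kept))
    return kept


def _local_loci(seq: str, min_hpr_len: int, min_units: int):
    """Maximal repeats of a short window at relaxed thresholds, as a set of
    (start, end, unit-class) tuples plus the loci themselves."""
    census = find_repeats({"w": seq}, min_hpr_len=min_hpr_len, min_units=min_units)
    return {(l.start, l.end, l.motif_class): l for l in census}


def detect_boundary_shift(
    snv: MutationCall,
    census: RepeatCensus,
    chrom_seq: str,
    window: int = 20,
) -> bool:
    """True iff the substitution is equivalent to a double slippage at a
    repeat junction: one repeat gains exactly one unit while its neighbour
    (gap <= 1 bp) loses one, and nothing else in the local decomposition
    changes.

    The check re-decomposes the +/-``window`` bp context around the SNV into
    maximal repeats before and after applying the substitution (at relaxed
    thresholds, so a census-size run contracting below threshold remains
    visible) and compares the two decompositions.
    """
    if not snv.is_snv:
        raise ValueError("boundary-shift detection applies to SNVs")
    pos = snv.pos
    # candidate junction pairs from the census: gap <= 1 and SNV within the
    # junction neighbourhood [a.end - 1, b.start]
    loci = census.overlapping(snv.chrom, pos - window, pos + window)
    loci.sort(key=lambda l: l.start)
    pairs = []
    for a in loci:
        for b in loci:
            if a is b or not (0 <= b.start - a.end <= 1):
                continue
            if a.end - 1 <= pos <= b.start:
                pairs.append((a, b))
    if not pairs:
        return False
    lo = max(0, min(pos - window, min(a.start - 1 for a, b in pairs)))
    hi = min(len(chrom_seq), max(pos + window + 1, max(b.end + 1 for a, b in pairs)))
    w0 = chrom_seq[lo:hi]
    p = pos - lo
    if w0[p] != snv.ref:
        raise ValueError(
            f"ref mismatch at {snv.chrom}:{snv.pos}: genome has {w0[p]!r}, "
            f"call says {snv.ref!r}")
    w1 = w0[:p] + snv.alt + w0[p + 1:]
    d0 = _local_loci(w0, 2, 2)
    d1 = _local_loci(w1, 2, 2)
    only0 = [d0[k] for k in d0.keys() - d1.keys()]
    only1 = [d1[k] for k in d1.keys() - d0.keys()]
    # ignore loci clipped by the window edge (unreliable in both decompositions)
    edge = lambda l: l.start == 0 or l.end == len(w0)
    only0 = [l for l in only0 if not edge(l)]
    only1 = [l for l in only1 if not edge(l)]
    if len(only0) != 2 or len(only1) != 2:
        return False
    only0.sort(key=lambda l: l.start)
    only1.sort(key=lambda l: l.start)
    (a0, b0), (a1, b1) = only0, only1
    if a0.motif_class != a1.motif_class or b0.motif_class != b1.motif_class:
        return False
    da = a1.n_units - a0.n_units
    db = b1.n_units - b0.n_units
    return (
        {da, db} == {1, -1}
        and a0.start == a1.start and b0.end == b1.end
        and 0 <= b1.start - a1.end <= 1
    )
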