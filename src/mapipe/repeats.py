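"""Census of perfect tandem repeats (homopolymers and microsatellites).

A *homopolymeric run* (HPR) is a mononucleotide tandem repeat (length counted
in bp); a *microsatellite* here is a perfect tandem repeat with a 2-4 bp unit
(length counted in repeat units).  Loci are maximal: the periodicity cannot be
extended by a single base in either direction.  Repeat classes are collapsed
over strand and unit rotation into the field's canonical labels (A/T, C/G,
AT/TA, GT/CA, GA/CT, AAT/TTA, ...), since a tandem tract has no intrinsic
strand or phase.

Coordinates are 0-based half-open throughout; 1-based only at VCF/BED edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "RepeatLocus",
    "RepeatCensus",
    "canonical_motif",
    "find_repeats",
    "nearest_neighbor_distances",
    "revcomp",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# Historical display names for dinucleotide classes: poly(GT) tracts are
# conventionally written GT/CA (likewise GA/CT, AT/TA) even though the
# lexically smallest rotation is AC (resp. AG, AT).
_DI_DISPLAY = {"AC": "GT/CA", "AG": "GA/CT", "AT": "AT/TA", "CG": "CG/GC"}

DEFAULT_MIN_HPR_LEN = 3   # bp; one length class below the smallest mutated run seen (4 bp)
DEFAULT_MIN_UNITS = 3     # full units for unit_len >= 2


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)


def _rotations(unit: str) -> list[str]:
    return [unit[i:] + unit[:i] for i in range(len(unit))]


def _is_primitive(unit: str) -> bool:
    n = len(unit)
    for d in range(1, n):
        if n % d == 0 and unit == unit[:d] * (n // d):
            return False
    return True


def canonical_motif(unit: str) -> str:
    """Canonical strand/rotation-collapsed class label for a repeat unit.

    The representative is the lexically smallest string over all rotations of
    ``unit`` and of its reverse complement; dinucleotides are then mapped to
    their traditional display names (e.g. ``GT/CA``), all other unit lengths
    are written ``rep/complement(rep)``.

    >>> canonical_motif("T")
    'A/T'
    >>> canonical_motif("TG")
    'GT/CA'
    >>> canonical_motif("TTG")
    'AAC/TTG'
    """
    if not 1 <= len(unit) <= 4:
        raise ValueError(f"unit length must be 1-4, got {unit!r}")
    if any(c not in "ACGT" for c in unit):
        raise ValueError(f"unit must contain only A,C,G,T: {unit!r}")
    if not _is_primitive(unit):
        d = next(d for d in range(1, len(unit)) if len(unit) % d == 0
                 and unit == unit[:d] * (len(unit) // d))
        raise ValueError(
            f"unit {unit!r} is not primitive; reduce to unit {unit[:d]!r}")
    rep = min(_rotations(unit) + _rotations(revcomp(unit)))
    if len(rep) == 2:
        return _DI_DISPLAY[rep]
    return f"{rep}/{_complement(rep)}"


@dataclass(frozen=True)
class RepeatLocus:
    """One maximal perfect tandem repeat on the forward strand."""

    chrom: str
    start: int          # 0-based inclusive
    end: int            # 0-based exclusive; end - start == unit_len * n_units
    unit: str           # unit as observed on the forward strand, phase at start
    motif_class: str    # canonical_motif(unit)

    @property
    def unit_len(self) -> int:
        return len(self.unit)

    @property
    def n_units(self) -> int:
        return (self.end - self.start) // len(self.unit)

    @property
    def length_bp(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        """Length on the scale used for rate curves: bp for HPRs, units otherwise."""
        return self.length_bp if self.unit_len == 1 else self.n_units


@dataclass
class RepeatCensus:
    """Ordered collection of repeat loci plus the class/length histogram."""

    loci: list[RepeatLocus] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.loci = sorted(self.loci, key=lambda l: (l.chrom, l.start, l.unit_len))
        self._index: dict | None = None

    def _build_index(self) -> None:
        idx: dict[str, tuple] = {}
        by_chrom: dict[str, list[RepeatLocus]] = {}
        for l in self.loci:
            by_chrom.setdefault(l.chrom, []).append(l)
        for chrom, loci in by_chrom.items():
            starts = np.array([l.start for l in loci])
            maxlen = max(l.length_bp for l in loci)
            idx[chrom] = (starts, maxlen, loci)
        self._index = idx

    def overlapping(self, chrom: str, lo: int, hi: int) -> list[RepeatLocus]:
        """Loci with start <= hi and end >= lo (touching counts) on chrom."""
        if self._index is None:
            self._build_index()
        entry = self._index.get(chrom)
        if entry is None:
            return []
        starts, maxlen, loci = entry
        a = int(np.searchsorted(starts, lo - maxlen, side="left"))
        b = int(np.searchsorted(starts, hi, side="right"))
        return [l for l in loci[a:b] if l.end >= lo and l.start <= hi]

    def __len__(self) -> int:
        return len(self.loci)

    def __iter__(self):
        return iter(self.loci)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [l.chrom for l in self.loci],
                "start": [l.start for l in self.loci],
                "end": [l.end for l in self.loci],
                "unit": [l.unit for l in self.loci],
                "unit_len": [l.unit_len for l in self.loci],
                "n_units": [l.n_units for l in self.loci],
                "length": [l.length for l in self.loci],
                "motif_class": [l.motif_class for l in self.loci],
            }
        )

    def by_class_and_length(self) -> pd.Series:
        """Locus counts indexed by (motif_class, length).

        Length is run length in bp for homopolymers and the unit count for
        unit_len >= 2, matching how rate curves are binned.
        """
        if not self.loci:
            return pd.Series(dtype=int)
        df = self.to_frame()
        return df.groupby(["motif_class", "length"]).size().sort_index()

    def to_bed(self) -> pd.DataFrame:
        """BED6-compatible table (name = motif_class:n_units, score = n_units)."""
        df = self.to_frame()
        return pd.DataFrame(
            {
                "chrom": df["chrom"],
                "start": df["start"],
                "end": df["end"],
                "name": df["motif_class"].str.cat(df["n_units"].astype(str), sep=":"),
                "score": df["n_units"],
                "strand": ".",
            }
        )


def _scan_segment(seg: str, chrom: str, offset: int, min_hpr_len: int,
                  min_units: int, max_unit_len: int) -> list[RepeatLocus]:
    """All maximal perfect tandem repeats in an N-free segment.

    For each period k the boolean array ``s[i] == s[i+k]`` is run-length
    encoded; every maximal True-run [i, i+L) is a maximal periodicity tract
    [i, i+L+k).  The locus keeps only full units, phased at the tract start.
    Tracts whose leading unit is non-primitive are exactly the ones already
    reported at a smaller period and are skipped, which also guarantees that
    an XX "dinucleotide" is only ever reported as a homopolymer.
    """
    out: list[RepeatLocus] = []
    n = len(seg)
    if n < 2:
        return out
    arr = np.frombuffer(seg.encode("ascii"), dtype=np.uint8)
    for k in range(1, max_unit_len + 1):
        if n < 2 * k:
            continue
        eq = arr[k:] == arr[:-k]
        if not eq.any():
            continue
        # run-length encode eq
        bounded = np.concatenate(([False], eq, [False]))
        diff = np.diff(bounded.astype(np.int8))
        run_starts = np.flatnonzero(diff == 1)
        run_ends = np.flatnonzero(diff == -1)
        for i, j in zip(run_starts, run_ends):
            tract_len = int(j - i) + k       # bp of the periodic tract
            n_units = tract_len // k
            if k == 1:
                if tract_len < min_hpr_len:
                    continue
            else:
                if n_units < min_units:
                    continue
            unit = seg[i:i + k]
            if k > 1 and not _is_primitive(unit):
                continue
            out.append(
                RepeatLocus(
                    chrom=chrom,
                    start=offset + int(i),
                    end=offset + int(i) + n_units * k,
                    unit=unit,
                    motif_class=canonical_motif(unit),
                )
            )
    return out


def find_repeats(
    sequences: Mapping[str, str],
    min_hpr_len: int = DEFAULT_MIN_HPR_LEN,
    min_units: int = DEFAULT_MIN_UNITS,
    max_unit_len: int = 4,
) -> RepeatCensus:
    """Census all maximal perfect repeats with unit length 1..max_unit_len.

    Parameters
    ----------
    sequences
        Mapping of sequence name to A/C/G/T/N string (e.g. from FASTA).
        Runs of N split sequences into independently scanned segments and
        never join repeats.
    min_hpr_len
        Minimum homopolymer run length in bp.
    min_units
        Minimum number of full units for unit lengths >= 2.

    Raises
    ------
    ValueError
        If a sequence contains a character outside A,C,G,T,N (position named).
    """
    loci: list[RepeatLocus] = []
    for chrom, seq in sequences.items():
        seq = seq.upper()
        bad = [i for i, c in enumerate(seq) if c not in "ACGTN"]
        if bad:
            raise ValueError(
                f"non-IUPAC character {seq[bad[0]]!r} in sequence "
                f"{chrom!r} at position {bad[0]}")
        # split on N into scan segments
        start = 0
        for part in seq.split("N"):
            if part:
                loci.extend(
                    _scan_segment(part, chrom, start, min_hpr_len,
                                  min_units, max_unit_len))
            start += len(part) + 1
    return RepeatCensus(loci)


def nearest_neighbor_distances(census: RepeatCensus) -> pd.DataFrame:
    """Minimum bp gap from each locus to any other locus on the same chromosome.

    The gap between loci is end-to-start and non-negative: touching or
    overlapping loci are at distance 0.  A chromosome carrying a single locus
    yields NaN, which downstream ECDFs drop.
    """
    df = census.to_frame()
    if df.empty:
        return df.assign(nn_distance=pd.Series(dtype=float))
    dist = np.full(len(df), np.nan)
    for _, idx in df.groupby("chrom").groups.items():
        sub = df.loc[idx]
        order = np.argsort(sub["start"].to_numpy(), kind="stable")
        starts = sub["start"].to_numpy()[order]
        ends = sub["end"].to_numpy()[order]
        m = len(sub)
        if m < 2:
            continue
        d = np.full(m, np.inf)
        # forward: gap to the next locus by start (any closer one overlaps -> 0)
        fwd = np.maximum(0, starts[1:] - ends[:-1])
        d[:-1] = np.minimum(d[:-1], fwd)
        # backward: gap to the running max end among earlier loci
        prev_max_end = np.maximum.accumulate(ends)[:-1]
        bwd = np.maximum(0, starts[1:] - prev_max_end)
        d[1:] = np.minimum(d[1:], bwd)
        dist[np.asarray(idx)[order]] = d
    return df.assign(nn_distance=dist)
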