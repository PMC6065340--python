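"""Base composition and strand-asymmetry (skew) statistics.

AT-skew = (A - T)/(A + T) and GC-skew = (G - C)/(G + C) computed from base
counts, per gene, per region, per codon position, and genome-wide.  Vertebrate
mitogenomes replicate asymmetrically, leaving the two strands with opposite
compositional bias; the skews quantify that bias on whatever strand the counts
were taken from, so a sequence and its reverse complement have skews of equal
magnitude and opposite sign.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass
from typing import Optional

from .annotation_model import MitoGenome, PCG_NAMES

__all__ = [
    "CompositionSummary",
    "SkewRow",
    "SkewProfile",
    "base_composition",
    "at_skew",
    "gc_skew",
    "skew_profile",
    "reverse_complement",
]

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(sequence: str) -> str:
    return sequence.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class CompositionSummary:
    """Exact base counts plus A+T / G+C fractions (N excluded from denominators)."""

    a: int
    c: int
    g: int
    t: int
    n: int

    @property
    def length(self) -> int:
        return self.a + self.c + self.g + self.t + self.n

    @property
    def at_fraction(self) -> float:
        return (self.a + self.t) / (self.a + self.c + self.g + self.t)

    @property
    def gc_fraction(self) -> float:
        return (self.c + self.g) / (self.a + self.c + self.g + self.t)

    def __add__(self, other: "CompositionSummary") -> "CompositionSummary":
        return CompositionSummary(self.a + other.a, self.c + other.c,
                                  self.g + other.g, self.t + other.t,
                                  self.n + other.n)


def base_composition(sequence: str) -> CompositionSummary:
    if not sequence:
        raise ValueError("empty sequence")
    counts = Counter(sequence)
    bad = set(counts) - set("ACGTN")
    if bad:
        raise ValueError(f"non-ACGTN residues {sorted(bad)}")
    return CompositionSummary(counts["A"], counts["C"], counts["G"], counts["T"],
                              counts["N"])


def at_skew(sequence: str) -> float:
    """(A - T)/(A + T); NaN marks an undefined skew (A + T == 0)."""
    comp = base_composition(sequence)
    denom = comp.a + comp.t
    if denom == 0:
        return math.nan
    return (comp.a - comp.t) / denom


def gc_skew(sequence: str) -> float:
    """(G - C)/(G + C); NaN marks an undefined skew (G + C == 0)."""
    comp = base_composition(sequence)
    denom = comp.g + comp.c
    if denom == 0:
        return math.nan
    return (comp.g - comp.c) / denom


@dataclass(frozen=True)
class SkewRow:
    region: str
    at_skew: float
    gc_skew: float
    at_fraction: float
    length: int
    codon_position: Optional[int] = None  # 1/2/3 for per-position PCG rows


@dataclass
class SkewProfile:
    identifier: str
    strand_convention: str
    rows: list[SkewRow]

    def row(self, region: str, codon_position: Optional[int] = None) -> SkewRow:
        for r in self.rows:
            if r.region == region and r.codon_position == codon_position:
                return r
        raise KeyError(region)

    def to_records(self) -> list[dict]:
        return [
            {
                "region": r.region,
                "codon_position": r.codon_position,
                "AT_skew": None if math.isnan(r.at_skew) else r.at_skew,
                "GC_skew": None if math.isnan(r.gc_skew) else r.gc_skew,
                "AT_fraction": r.at_fraction,
                "length": r.length,
            }
            for r in self.rows
        ]


def _region_sequence(genome: MitoGenome, feature, strand_convention: str) -> str:
    seq = genome.subsequence(feature)
    if strand_convention == "coding_strand" and feature.strand == "L":
        seq = reverse_complement(seq)
    return seq


def skew_profile(genome: MitoGenome, strand_convention: str = "coding_strand",
                 by_codon_position: bool = False) -> SkewProfile:
    """Per-region skew table: 13 PCGs, 2 rRNAs, CR, the concatenated PCG set,
    and the whole genome.

    ``strand_convention`` — ``coding_strand`` reverse-complements L-strand
    features before counting (the standard way published per-gene skews are
    reported; ND6 is the one light-strand PCG); ``genome_strand`` counts every
    region on the sequenced strand as-is.
    """
    if genome.sequence is None:
        raise ValueError(f"{genome.identifier} carries no sequence")
    if strand_convention not in ("coding_strand", "genome_strand"):
        raise ValueError(f"unknown strand convention {strand_convention!r}")

    rows: list[SkewRow] = []
    pcg_concat: list[str] = []
    for f in genome.features:
        if f.category not in ("PCG", "rRNA", "control_region"):
            continue
        try:
            seq = _region_sequence(genome, f, strand_convention)
        except ValueError as exc:
            log.warning("skipping region %s: %s", f.name, exc)
            continue
        rows.append(_row(f.name, seq))
        if f.category == "PCG":
            pcg_concat.append(seq)
            if by_codon_position:
                for pos in (1, 2, 3):
                    sub = seq[pos - 1::3]
                    rows.append(_row(f.name, sub, codon_position=pos))
    concat = "".join(pcg_concat)
    if concat:
        rows.append(_row("13PCG", concat))
        if by_codon_position:
            # positions are per-gene frames, so concatenate per-position slices
            for pos in (1, 2, 3):
                sub = "".join(s[pos - 1::3] for s in pcg_concat)
                rows.append(_row("13PCG", sub, codon_position=pos))
    rows.append(_row("Overall", genome.sequence))
    return SkewProfile(genome.identifier, strand_convention, rows)


def _row(region: str, seq: str, codon_position: Optional[int] = None) -> SkewRow:
    comp = base_composition(seq)
    return SkewRow(region=region, at_skew=at_skew(seq), gc_skew=gc_skew(seq),
                   at_fraction=comp.at_fraction, length=len(seq),
                   codon_position=codon_position)


def pcg_order_check(genome: MitoGenome) -> list[str]:
    """Names of any canonical PCGs missing from the annotation."""
    present = {f.name for f in genome.features}
    return [n for n in PCG_NAMES if n not in present]
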