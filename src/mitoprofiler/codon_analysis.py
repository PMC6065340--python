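"""Codon extraction, usage counts, RSCU, and amino-acid frequencies.

Works under the vertebrate mitochondrial genetic code (AGA/AGG are stops,
ATA is Met, TGA is Trp).  Mitochondrial protein-coding genes frequently end on
an incomplete stop codon — a terminal T or TA at the gene boundary, completed
to TAA by polyadenylation of the transcript — so codon extraction pads those
genes and records the padding.

RSCU (relative synonymous codon usage) for codon c in a synonymous family F:

    RSCU(c) = count(c) * |F| / sum_{c' in F} count(c')

i.e. observed over expected count under uniform use within the family; values
sum to the family size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

from Bio.Data import CodonTable

from .annotation_model import Feature, MitoGenome
from .composition_stats import reverse_complement

__all__ = [
    "GeneticCode",
    "VERTEBRATE_MITO",
    "CodingSequence",
    "CodonUsageTable",
    "coding_sequence",
    "classify_codons",
    "codon_usage",
    "rscu",
    "aa_frequencies",
]

_BASES = "TCAG"
ALL_CODONS = tuple(a + b + c for a in _BASES for b in _BASES for c in _BASES)


@dataclass(frozen=True)
class GeneticCode:
    """A 64-entry codon table plus the synonymous-family map."""

    name: str
    forward: dict  # codon -> one-letter amino acid; stops absent
    stops: frozenset

    def __post_init__(self) -> None:
        if len(self.forward) + len(self.stops) != 64:
            raise ValueError("codon table must cover exactly 64 codons")

    def amino_acid(self, codon: str) -> Optional[str]:
        """One-letter amino acid, or None for a stop codon."""
        return self.forward.get(codon)

    def families(self) -> dict:
        """amino acid -> tuple of synonymous codons (stops excluded)."""
        fam: dict[str, list[str]] = {}
        for codon in ALL_CODONS:
            aa = self.forward.get(codon)
            if aa is not None:
                fam.setdefault(aa, []).append(codon)
        return {aa: tuple(codons) for aa, codons in fam.items()}


def _vertebrate_mito() -> GeneticCode:
    table = CodonTable.unambiguous_dna_by_id[2]
    return GeneticCode(name="vertebrate mitochondrial",
                       forward=dict(table.forward_table),
                       stops=frozenset(table.stop_codons))


VERTEBRATE_MITO = _vertebrate_mito()


@dataclass(frozen=True)
class CodingSequence:
    """A codon-ready coding sequence with its padding record."""

    gene: str
    sequence: str  # coding strand, length divisible by 3
    padded: str = ""  # "" | "AA" | "A"

    def __post_init__(self) -> None:
        if len(self.sequence) % 3 != 0:
            raise ValueError(f"{self.gene}: length {len(self.sequence)} not codon-ready")

    @property
    def codons(self) -> list[str]:
        s = self.sequence
        return [s[i:i + 3] for i in range(0, len(s), 3)]


def coding_sequence(genome: MitoGenome, feature: Feature) -> CodingSequence:
    """Extract a PCG's coding-strand sequence, completing incomplete stops.

    L-strand genes are reverse-complemented.  A trailing T (length mod 3 == 1)
    is padded with AA; a trailing TA (length mod 3 == 2) with A; the padding is
    recorded so downstream stop classification can report the incomplete-stop
    token rather than a literal TAA.
    """
    if feature.category != "PCG":
        raise ValueError(f"{feature.name} is not a protein-coding gene")
    seq = genome.subsequence(feature)
    if feature.strand == "L":
        seq = reverse_complement(seq)
    rem = len(seq) % 3
    padded = ""
    if rem == 1 and seq.endswith("T"):
        seq, padded = seq + "AA", "AA"
    elif rem == 2 and seq.endswith("TA"):
        seq, padded = seq + "A", "A"
    elif rem != 0:
        raise ValueError(
            f"{feature.name}: length {len(seq)} is not a codon multiple and the "
            "tail is not an incomplete stop (T/TA)")
    return CodingSequence(gene=feature.name, sequence=seq, padded=padded)


def classify_codons(cds: CodingSequence,
                    code: GeneticCode = VERTEBRATE_MITO) -> tuple[str, str]:
    """(start codon, stop token) for a codon-ready gene.

    The start codon is reported verbatim (GTG/ATA/ATT initiation is common in
    mitogenomes).  The stop token is the terminal codon when it is a genuine
    stop, ``T-``/``TA-`` when the gene was padded, and ``??`` (with no error)
    for an unrecognized terminal codon.
    """
    codons = cds.codons
    start = codons[0]
    if cds.padded == "AA":
        return start, "T-"
    if cds.padded == "A":
        return start, "TA-"
    last = codons[-1]
    if last in code.stops:
        return start, last
    return start, "??"


@dataclass
class CodonUsageTable:
    """Codon counts over a set of coding sequences (stops counted, flagged)."""

    counts: dict = field(default_factory=lambda: {c: 0 for c in ALL_CODONS})
    code: GeneticCode = VERTEBRATE_MITO

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def count(self, codon: str) -> int:
        return self.counts[codon.replace("U", "T")]

    def non_stop_total(self) -> int:
        return sum(n for c, n in self.counts.items() if c not in self.code.stops)

    def family_total(self, amino_acid: str) -> int:
        fams = self.code.families()
        return sum(self.counts[c] for c in fams[amino_acid])

    def max_codon(self) -> tuple[str, int]:
        """(codon, count) of the most used codon; ties break alphabetically."""
        best = min(self.counts, key=lambda c: (-self.counts[c], c))
        return best, self.counts[best]


def codon_usage(coding_sequences: Iterable[CodingSequence],
                code: GeneticCode = VERTEBRATE_MITO,
                count_padded: bool = True) -> CodonUsageTable:
    """Tally codons over all genes.

    Stop codons (including padded, polyadenylation-completed ones when
    ``count_padded``) are included in the counts — published mitogenome codon
    tables print them, asterisked — but are excluded later from RSCU and
    amino-acid frequencies.
    """
    table = CodonUsageTable(code=code)
    for cds in coding_sequences:
        codons = cds.codons
        if cds.padded and not count_padded:
            codons = codons[:-1]
        for codon in codons:
            if set(codon) <= set("ACGT"):
                table.counts[codon] += 1
    return table


def rscu(usage: CodonUsageTable) -> dict:
    """codon -> RSCU value; families with zero total map to NaN."""
    out: dict[str, float] = {}
    for aa, family in usage.code.families().items():
        total = sum(usage.counts[c] for c in family)
        size = len(family)
        for c in family:
            out[c] = math.nan if total == 0 else usage.counts[c] * size / total
    return out


def aa_frequencies(usage: CodonUsageTable) -> dict:
    """amino acid -> percent of non-stop codons."""
    denom = usage.non_stop_total()
    out: dict[str, float] = {}
    for aa, family in usage.code.families().items():
        n = sum(usage.counts[c] for c in family)
        out[aa] = math.nan if denom == 0 else 100.0 * n / denom
    return out


def to_rna(codon: str) -> str:
    return codon.replace("T", "U")


AA_THREE_TO_ONE = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C", "Gln": "Q",
    "Glu": "E", "Gly": "G", "His": "H", "Ile": "I", "Leu": "L", "Lys": "K",
    "Met": "M", "Phe": "F", "Pro": "P", "Ser": "S", "Thr": "T", "Trp": "W",
    "Tyr": "Y", "Val": "V",
}


def load_usage_tsv(path, column: str,
                   code: GeneticCode = VERTEBRATE_MITO) -> CodonUsageTable:
    """Load one species column of a published-style 64-codon count table.

    Expected columns: AminoAcid, Codon (RNA alphabet, stops asterisked), and
    one count column per species.
    """
    import csv

    table = CodonUsageTable(code=code)
    with open(path, encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if column not in (reader.fieldnames or []):
            raise ValueError(f"{path}: no column {column!r} in {reader.fieldnames}")
        n = 0
        for row in reader:
            codon = row["Codon"].rstrip("*").replace("U", "T")
            table.counts[codon] += int(row[column])
            n += 1
    if n != 64:
        raise ValueError(f"{path}: expected 64 codon rows, found {n}")
    return table
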