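"""Validated in-memory model of an annotated mitochondrial genome.

The model mirrors how mitogenome annotation tables are printed in the
comparative literature: one row per element (protein-coding gene, tRNA, rRNA,
replication origin, control region) with strand (H/L), 1-based inclusive
coordinates, printed size, start/stop codons, and the signed spacer to the next
element (negative values are overlaps).  Everything downstream — spacer and
overlap accounting, gene-order signatures, tandem-duplication detection —
operates on this model, never on raw files.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

log = logging.getLogger(__name__)

__all__ = [
    "Feature",
    "MitoGenome",
    "ValidationIssue",
    "ValidationReport",
    "feature_length",
    "intergenic_spacers",
    "gap_overlap_totals",
    "compare_printed_totals",
    "gene_order_signature",
    "find_tandem_duplicates",
    "validate_annotation",
]

#: The 13 mitochondrial protein-coding genes, in the canonical vertebrate order
#: used for concatenation.
PCG_NAMES = (
    "ND1", "ND2", "COX1", "COX2", "ATP8", "ATP6", "COX3",
    "ND3", "ND4L", "ND4", "ND5", "ND6", "CYTB",
)

RRNA_NAMES = ("12S-rRNA", "16S-rRNA")

CATEGORIES = ("PCG", "tRNA", "rRNA", "origin", "control_region")

#: Incomplete stop-codon tokens: a terminal T or TA completed to TAA by
#: post-transcriptional polyadenylation.
INCOMPLETE_STOP_T = "T-"
INCOMPLETE_STOP_TA = "TA-"


def categorize(name: str) -> str:
    """Infer the feature category from a normalized gene name."""
    if name in PCG_NAMES:
        return "PCG"
    if name in RRNA_NAMES:
        return "rRNA"
    if name.startswith("tRNA-"):
        return "tRNA"
    if name == "OL":
        return "origin"
    if name == "CR":
        return "control_region"
    raise ValueError(f"cannot infer category for feature name {name!r}")


@dataclass(frozen=True)
class Feature:
    """One annotated element with 1-based inclusive coordinates."""

    name: str
    category: str
    strand: str  # "H" (heavy) or "L" (light)
    start: int
    stop: int
    start_codon: Optional[str] = None
    stop_codon: Optional[str] = None
    anticodon: Optional[str] = None

    def __post_init__(self) -> None:
        if self.strand not in ("H", "L"):
            raise ValueError(f"strand must be H or L, got {self.strand!r}")
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.start < 1:
            raise ValueError(f"{self.name}: start must be >= 1, got {self.start}")

    @property
    def wraps(self) -> bool:
        """True when the feature crosses the circular junction (stop < start)."""
        return self.stop < self.start


@dataclass
class MitoGenome:
    """A (usually circular) mitochondrial genome plus its ordered features."""

    identifier: str
    length: int
    circular: bool = True
    sequence: Optional[str] = None
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError(
                f"{self.identifier}: declared length {self.length} != "
                f"sequence length {len(self.sequence)}"
            )
        self.features = sorted(self.features, key=_feature_sort_key)

    def feature_by_name(self, name: str) -> Feature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def features_by_category(self, category: str) -> list[Feature]:
        return [f for f in self.features if f.category == category]

    def subsequence(self, feature: Feature) -> str:
        """Extract the genome-strand subsequence of a feature (handles wrap)."""
        if self.sequence is None:
            raise ValueError(f"{self.identifier} carries no sequence")
        if feature.wraps:
            if not self.circular:
                raise ValueError(f"{feature.name}: wrapping feature on a linear genome")
            return self.sequence[feature.start - 1:] + self.sequence[: feature.stop]
        return self.sequence[feature.start - 1: feature.stop]


def _feature_sort_key(f: Feature):
    # Ties at identical starts break by longer feature first, then by name, so
    # gene-order signatures are deterministic.
    return (f.start, -(f.stop - f.start), f.name)


def feature_length(feature: Feature, genome_length: Optional[int] = None,
                   circular: bool = True) -> int:
    """Length in bp of a feature; wrap-around spans need the genome length."""
    if not feature.wraps:
        return feature.stop - feature.start + 1
    if not circular:
        raise ValueError(f"{feature.name}: stop < start on a linear genome")
    if genome_length is None:
        raise ValueError(f"{feature.name}: wrapping feature needs genome_length")
    return (genome_length - feature.start + 1) + feature.stop


def intergenic_spacers(genome: MitoGenome,
                       include_wrap: bool = True) -> list[tuple[str, str, int]]:
    """Signed spacer between each pair of adjacent features.

    Returns (upstream name, downstream name, gap bp) for consecutive features
    ordered by start.  gap = next.start - prev.stop - 1: zero means abutting,
    negative means overlap.  When the genome is circular and ``include_wrap``,
    the pair (last feature, first feature) across the origin is appended.
    """
    feats = genome.features
    if len(feats) < 2:
        return []
    out = []
    for prev, nxt in zip(feats, feats[1:]):
        out.append((prev.name, nxt.name, nxt.start - prev.stop - 1))
    if genome.circular and include_wrap:
        last, first = feats[-1], feats[0]
        # Distance across the junction: bases after `last` to the end, plus
        # bases before `first`.
        wrap_gap = (genome.length - last.stop) + (first.start - 1)
        out.append((last.name, first.name, wrap_gap))
    return out


def gap_overlap_totals(genome: MitoGenome,
                       include_wrap: bool = False) -> tuple[int, int]:
    """(total gap bp, total overlap bp) over adjacent feature pairs.

    The wrap pair is excluded by default: the published per-genome totals are
    reproduced exactly from the linear pair list alone.
    """
    gaps = overlaps = 0
    for _, _, gap in intergenic_spacers(genome, include_wrap=include_wrap):
        if gap > 0:
            gaps += gap
        elif gap < 0:
            overlaps += -gap
    return gaps, overlaps


def compare_printed_totals(genome: MitoGenome, rows) -> Optional[dict]:
    """Compare coordinate-derived gap/overlap totals with the printed column.

    ``rows`` are the RawFeatureRow records the genome was built from; their
    ``printed_intergenic`` column is summed the way a reader would sum the
    published table (positives = gaps, negatives = overlaps), excluding the
    final row whose value belongs to the wrap pair across the origin.  The
    comparison is logged — agreement at INFO, discrepancy at WARNING — and
    returned; published totals are never substituted for the computed ones.
    Returns None when the table carries no printed intergenic column.
    """
    printed = [r.printed_intergenic for r in rows]
    if all(v is None for v in printed):
        return None
    body = printed[:-1]  # last row's spacer wraps back to the first feature
    printed_gaps = sum(v for v in body if v is not None and v > 0)
    printed_overlaps = sum(-v for v in body if v is not None and v < 0)
    gaps, overlaps = gap_overlap_totals(genome)
    result = {
        "identifier": genome.identifier,
        "computed": {"gap_bp": gaps, "overlap_bp": overlaps},
        "printed": {"gap_bp": printed_gaps, "overlap_bp": printed_overlaps},
        "match": (gaps, overlaps) == (printed_gaps, printed_overlaps),
    }
    if result["match"]:
        log.info("%s: printed intergenic totals %d/%d match the "
                 "coordinate-derived totals", genome.identifier, gaps, overlaps)
    else:
        log.warning("%s: printed intergenic totals %d/%d disagree with "
                    "coordinate-derived %d/%d; keeping the computed values",
                    genome.identifier, printed_gaps, printed_overlaps,
                    gaps, overlaps)
    return result


def gene_order_signature(genome: MitoGenome) -> list[tuple[str, str]]:
    """Ordered (name, strand) tokens — the genome's gene-arrangement signature."""
    return [(f.name, f.strand) for f in genome.features]


def compare_signatures(a: Sequence[tuple[str, str]],
                       b: Sequence[tuple[str, str]]) -> Optional[int]:
    """Index of the first difference between two signatures, or None if equal."""
    for i, (x, y) in enumerate(zip(a, b)):
        if x != y:
            return i
    if len(a) != len(b):
        return min(len(a), len(b))
    return None


def _base_name(token: str) -> str:
    """Collapse duplicate-copy numbering (tRNA-Met1/tRNA-Met2 -> tRNA-Met).

    Paralogous copies of a duplicated gene are conventionally numbered; runs of
    adjacent copies of the same underlying gene are what duplication detection
    looks for.  Serine and leucine tRNA isoacceptors (Ser1/Ser2, Leu1/Leu2) are
    distinct genes with different anticodons, never duplicates, so they keep
    their numbering.
    """
    if token in ("tRNA-Ser1", "tRNA-Ser2", "tRNA-Leu1", "tRNA-Leu2"):
        return token
    if token.startswith("tRNA-") and token[-1].isdigit():
        return token[:-1]
    return token


def find_tandem_duplicates(signature: Sequence[tuple[str, str]]
                           ) -> list[tuple[str, int, tuple[str, str]]]:
    """Maximal runs of >=2 adjacent same-gene, same-strand tokens.

    Returns (gene name, copy count, (upstream flank, downstream flank)).  The
    classic case this detects is the tandem tRNA-Met duplication between
    tRNA-Gln and ND2 shared by dicroglossid frogs.
    """
    out = []
    n = len(signature)
    i = 0
    while i < n:
        name, strand = signature[i]
        base = _base_name(name)
        j = i + 1
        while j < n and _base_name(signature[j][0]) == base and signature[j][1] == strand:
            j += 1
        if j - i >= 2:
            up = signature[i - 1][0] if i > 0 else ""
            down = signature[j][0] if j < n else ""
            out.append((base, j - i, (up, down)))
        i = j
    return out


@dataclass(frozen=True)
class ValidationIssue:
    feature: str
    code: str  # "stop_before_start_repaired" | "size_mismatch" | ...
    printed: Optional[int]
    recomputed: Optional[int]
    repaired: bool

    def to_dict(self) -> dict:
        return {
            "feature": self.feature,
            "code": self.code,
            "printed": self.printed,
            "recomputed": self.recomputed,
            "repaired": self.repaired,
        }


@dataclass
class ValidationReport:
    issues: list[ValidationIssue] = field(default_factory=list)

    def __bool__(self) -> bool:
        return bool(self.issues)

    def by_code(self, code: str) -> list[ValidationIssue]:
        return [i for i in self.issues if i.code == code]

    def to_json(self) -> str:
        return json.dumps([i.to_dict() for i in self.issues], indent=2)


def validate_annotation(rows, identifier: str = "genome",
                        circular: bool = True) -> tuple[MitoGenome, ValidationReport]:
    """Build a MitoGenome from raw table rows, reconciling printed values.

    Printed values never silently override coordinates; every reconciliation is
    recorded:

    * ``stop < start`` with a printed size: stop is reconstructed as
      ``start + size - 1`` (an obvious typographical truncation) and the repair
      is recorded.
    * printed size != computed span: a mismatch is recorded, coordinates kept.
    * ``stop < start`` with no printed size is irreparable -> error.

    Genome length is the maximum stop coordinate.
    """
    report = ValidationReport()
    feats: list[Feature] = []
    for row in rows:
        name = row.name
        start, stop = row.start, row.stop
        if stop < start:
            if row.printed_size is None:
                raise ValueError(
                    f"{identifier}/{name}: stop {stop} < start {start} and no "
                    "printed size to repair from"
                )
            repaired_stop = start + row.printed_size - 1
            report.issues.append(ValidationIssue(
                name, "stop_before_start_repaired", stop, repaired_stop, True))
            stop = repaired_stop
        span = stop - start + 1
        if row.printed_size is not None and row.printed_size != span:
            report.issues.append(ValidationIssue(
                name, "size_mismatch", row.printed_size, span, False))
        feats.append(Feature(
            name=name, category=categorize(name), strand=row.strand,
            start=start, stop=stop,
            start_codon=row.start_codon, stop_codon=row.stop_codon,
        ))
    length = max((f.stop for f in feats), default=0)
    genome = MitoGenome(identifier=identifier, length=length, circular=circular,
                        features=feats)
    return genome, report
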