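"""Readers and writers for the external formats the pipeline touches.

Formats: FASTA, GenBank flat files, the tab-separated annotation-table dialect
used by printed mitogenome profiles (gene / strand / from / to / size / start
codon / stop codon / intergenic bp), and aligned-matrix export (FASTA,
relaxed PHYLIP with a partition file, NEXUS with a sets block).  No analysis
logic lives here; everything returns or accepts the in-memory model types.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO

from .annotation_model import Feature, MitoGenome, categorize

__all__ = [
    "SequenceRecord",
    "RawFeatureRow",
    "read_fasta",
    "write_fasta",
    "read_genbank",
    "write_genbank",
    "read_feature_tsv",
    "write_feature_tsv",
    "write_alignment",
    "normalize_gene_name",
    "bundled_path",
]

log = logging.getLogger(__name__)

ALPHABET = set("ACGTN")

# Printed tables use typographic minus/dashes; numeric fields may carry
# thousands separators.
_DASHES = {"−": "-", "–": "-", "—": "-"}


class FormatError(ValueError):
    """Malformed input file."""


@dataclass(frozen=True)
class SequenceRecord:
    """A plain nucleotide sequence over {A,C,G,T,N}."""

    identifier: str
    residues: str
    circular: bool = False

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"{self.identifier}: empty sequence")
        bad = set(self.residues) - ALPHABET
        if bad:
            raise ValueError(f"{self.identifier}: non-ACGTN residues {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class RawFeatureRow:
    """One line of a printed-style annotation table, values kept verbatim."""

    name: str
    strand: str
    start: int
    stop: int
    printed_size: Optional[int] = None
    start_codon: Optional[str] = None
    stop_codon: Optional[str] = None
    printed_intergenic: Optional[int] = None

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"{self.name}: start must be >= 1")
        if self.printed_size is not None and self.printed_size < 1:
            raise ValueError(f"{self.name}: printed size must be >= 1")


# ---------------------------------------------------------------------------
# gene-name normalization (data-driven: a bundled editable TSV)
# ---------------------------------------------------------------------------

def bundled_path(filename: str) -> Path:
    """Path of a data file shipped with the package."""
    return Path(resources.files("mitoprofiler").joinpath("data", filename))


def _load_synonyms() -> dict[str, str]:
    table = {}
    with open(bundled_path("gene_synonyms.tsv"), encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("alias"):
            raise FormatError("gene_synonyms.tsv: missing header")
        for line in fh:
            if not line.strip():
                continue
            alias, canonical = line.rstrip("\n").split("\t")
            table[alias.upper()] = canonical
    return table


_SYNONYMS: Optional[dict[str, str]] = None


def normalize_gene_name(raw: str) -> str:
    """Map a free-form gene label onto its canonical token (COI -> COX1 ...)."""
    global _SYNONYMS
    if _SYNONYMS is None:
        _SYNONYMS = _load_synonyms()
    key = raw.strip().upper()
    key = re.sub(r"\s+", " ", key)
    canonicals = {c.upper(): c for c in _SYNONYMS.values()}
    if key in canonicals:
        return canonicals[key]
    if key in _SYNONYMS:
        return _SYNONYMS[key]
    # Tolerate e.g. "tRNA-Leu 1" / "trnM-1" style spacing and hyphens.
    compact = key.replace(" ", "").replace("(", "").replace(")", "")
    for alias, canonical in _SYNONYMS.items():
        if alias.replace(" ", "").replace("(", "").replace(")", "") == compact:
            return canonical
    raise KeyError(f"unknown gene name {raw!r}; extend data/gene_synonyms.tsv")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> list[SequenceRecord]:
    """Read FASTA; residues upper-cased, unknown letters mapped to N."""
    records = []
    with open(path, encoding="utf-8") as fh:
        header: Optional[str] = None
        chunks: list[str] = []
        lineno = 0
        seen_any = False
        for line in fh:
            lineno += 1
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if header is not None:
                    records.append(_make_record(header, chunks))
                header = line[1:].split()[0] if len(line) > 1 else f"seq{len(records)+1}"
                chunks = []
                seen_any = True
            else:
                if header is None:
                    raise FormatError(f"{path}: sequence before header at line {lineno}")
                chunks.append(line)
        if header is not None:
            records.append(_make_record(header, chunks))
        if not seen_any:
            raise FormatError(f"{path}: empty FASTA file")
    return records


def _make_record(identifier: str, chunks: list[str]) -> SequenceRecord:
    residues = "".join(chunks).upper()
    cleaned = re.sub(r"[^ACGTN]", "N", residues)
    n_bad = sum(a != b for a, b in zip(residues, cleaned))
    if n_bad:
        log.warning("%s: %d non-ACGTN letters mapped to N", identifier, n_bad)
    return SequenceRecord(identifier=identifier, residues=cleaned)


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 70) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(f">{rec.identifier}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# GenBank flat files
# ---------------------------------------------------------------------------

_GB_TYPES = {"CDS", "tRNA", "rRNA", "D-loop", "rep_origin"}


def read_genbank(path) -> MitoGenome:
    """Parse a GenBank flat file into a MitoGenome.

    CDS/tRNA/rRNA/D-loop/rep_origin features are kept; ``complement(a..b)``
    locations map to strand L; coordinates stay 1-based inclusive.  Gene names
    are normalized through the bundled synonym table.  A feature extending
    beyond the sequence is an error unless the record is circular and the
    feature wraps the junction.
    """
    record = SeqIO.read(path, "genbank")
    seq = str(record.seq).upper()
    seq = re.sub(r"[^ACGTN]", "N", seq)
    circular = record.annotations.get("topology", "linear") == "circular"
    length = len(seq)

    seen_met = 0
    feats: list[Feature] = []
    n_blocks = 0
    for gbf in record.features:
        if gbf.type not in _GB_TYPES:
            continue
        n_blocks += 1
        label = _genbank_label(gbf)
        try:
            name = normalize_gene_name(label)
        except KeyError:
            if gbf.type == "D-loop":
                name = "CR"
            elif gbf.type == "rep_origin":
                name = "OL"
            else:
                raise
        # Two tandem copies of the same tRNA share a label in GenBank records;
        # number them in order of appearance.
        if name == "tRNA-Met1":
            seen_met += 1
            if seen_met == 2:
                name = "tRNA-Met2"
            elif seen_met > 2:
                name = f"tRNA-Met{seen_met}"
        start = int(gbf.location.start) + 1  # Biopython is 0-based half-open
        stop = int(gbf.location.end)
        if stop > length:
            raise FormatError(
                f"{record.id}/{name}: coordinate {stop} beyond sequence length {length}")
        strand = "L" if gbf.location.strand == -1 else "H"
        # A wrapping feature comes through as a compound location; fold it back
        # to start > stop on the circle.
        if len(gbf.location.parts) > 1 and circular:
            first, last = gbf.location.parts[0], gbf.location.parts[-1]
            start, stop = int(first.start) + 1, int(last.end)
        feats.append(Feature(
            name=name, category=categorize(name), strand=strand,
            start=start, stop=stop,
            anticodon=gbf.qualifiers.get("anticodon", [None])[0],
        ))
    if n_blocks != len(feats):
        raise FormatError(f"{record.id}: dropped {n_blocks - len(feats)} feature blocks")
    return MitoGenome(identifier=record.id, length=length, circular=circular,
                      sequence=seq, features=feats)


def _genbank_label(gbf) -> str:
    for key in ("gene", "product", "note"):
        if key in gbf.qualifiers:
            return gbf.qualifiers[key][0]
    if gbf.type == "D-loop":
        return "D-loop"
    if gbf.type == "rep_origin":
        return "rep_origin"
    raise FormatError(f"unlabelled {gbf.type} feature at {gbf.location}")


def write_genbank(genome: MitoGenome, path) -> None:
    """Write a minimal GenBank flat file (LOCUS/FEATURES/ORIGIN) for a genome."""
    from Bio.Seq import Seq
    from Bio.SeqFeature import SeqFeature, SimpleLocation
    from Bio.SeqRecord import SeqRecord

    if genome.sequence is None:
        raise ValueError("cannot write GenBank without a sequence")
    rec = SeqRecord(Seq(genome.sequence), id=genome.identifier,
                    name=genome.identifier[:16], description="synthetic mitogenome")
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["topology"] = "circular" if genome.circular else "linear"
    rec.annotations["date"] = "01-JAN-2000"  # fixed: outputs must be byte-stable
    type_of = {"PCG": "CDS", "tRNA": "tRNA", "rRNA": "rRNA",
               "origin": "rep_origin", "control_region": "D-loop"}
    for f in genome.features:
        loc = SimpleLocation(f.start - 1, f.stop, strand=-1 if f.strand == "L" else 1)
        gbf = SeqFeature(loc, type=type_of[f.category])
        gbf.qualifiers["gene"] = [f.name]
        rec.features.append(gbf)
    with open(path, "w", encoding="utf-8") as fh:
        SeqIO.write(rec, fh, "genbank")


# ---------------------------------------------------------------------------
# annotation-table TSV dialect
# ---------------------------------------------------------------------------

_TSV_COLUMNS = ["Gene", "Strand", "From", "To", "Size", "Start", "Stop", "Intergenic"]


def _clean_number(token: str) -> Optional[int]:
    token = token.strip()
    for uni, ascii_ in _DASHES.items():
        token = token.replace(uni, ascii_)
    token = token.replace(",", "")
    if not token:
        return None
    return int(token)


def _clean_stop_codon(token: str) -> Optional[str]:
    token = token.strip()
    for uni, ascii_ in _DASHES.items():
        token = token.replace(uni, ascii_)
    if not token:
        return None
    # "T–" / "T--" / "T-" are all the same incomplete-stop token.
    if re.fullmatch(r"T-+", token):
        return "T-"
    if re.fullmatch(r"TA-+", token):
        return "TA-"
    return token


def read_feature_tsv(path) -> list[RawFeatureRow]:
    """Read the printed-table TSV dialect into raw rows (values verbatim).

    Thousands separators and typographic minus signs in numeric fields are
    accepted; gene names are normalized; the incomplete-stop token is
    canonicalized to ``T-``/``TA-``.
    """
    with open(path, encoding="utf-8") as fh:
        header_line = fh.readline()
        if not header_line.strip():
            raise FormatError(f"{path}: empty file")
        header = [h.strip() for h in header_line.rstrip("\n").split("\t")]
        missing = [c for c in _TSV_COLUMNS if c not in header]
        if missing:
            raise FormatError(
                f"{path}: missing columns {missing}; found {header}")
        idx = {c: header.index(c) for c in _TSV_COLUMNS}
        rows = []
        for line in fh:
            if not line.strip():
                continue
            cells = line.rstrip("\n").split("\t")
            cells += [""] * (len(header) - len(cells))
            get = lambda col: cells[idx[col]]
            rows.append(RawFeatureRow(
                name=normalize_gene_name(get("Gene")),
                strand=get("Strand").strip(),
                start=_clean_number(get("From")),
                stop=_clean_number(get("To")),
                printed_size=_clean_number(get("Size")),
                start_codon=get("Start").strip() or None,
                stop_codon=_clean_stop_codon(get("Stop")),
                printed_intergenic=_clean_number(get("Intergenic")),
            ))
    if not rows:
        raise FormatError(f"{path}: no feature rows")
    return rows


def write_feature_tsv(genome: MitoGenome, path,
                      printed_rows: Optional[list[RawFeatureRow]] = None) -> None:
    """Emit a printed-style annotation table from a genome model."""
    from .annotation_model import feature_length, intergenic_spacers

    spacers = {up: gap for up, _, gap in intergenic_spacers(genome, include_wrap=False)}
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_TSV_COLUMNS) + "\n")
        for f in genome.features:
            size = feature_length(f, genome.length, genome.circular)
            fh.write("\t".join([
                f.name, f.strand, str(f.start), str(f.stop), str(size),
                f.start_codon or "", f.stop_codon or "",
                str(spacers.get(f.name, "")) if f.name in spacers else "",
            ]) + "\n")


# ---------------------------------------------------------------------------
# alignment export
# ---------------------------------------------------------------------------

def write_alignment(alignment, fmt: str, path,
                    partitions: Optional[list[tuple[str, int, int]]] = None) -> None:
    """Write an equal-length matrix as FASTA / relaxed PHYLIP / NEXUS.

    ``alignment`` provides ``.taxa`` and ``.rows`` (see phylo_prep.Alignment),
    or a (taxa, rows) pair.  NEXUS output embeds a sets block with per-gene
    charset lines; PHYLIP output writes ``<path>.partitions`` alongside.
    Output is byte-identical for identical input (no timestamps).
    """
    taxa, rows = _matrix_of(alignment)
    widths = {len(r) for r in rows}
    if len(widths) > 1:
        raise ValueError(f"ragged alignment: row lengths {sorted(widths)}")
    ncol = widths.pop() if widths else 0
    path = Path(path)
    if fmt == "fasta":
        with open(path, "w", encoding="utf-8") as fh:
            for name, row in zip(taxa, rows):
                fh.write(f">{name}\n")
                for i in range(0, ncol, 70):
                    fh.write(row[i:i + 70] + "\n")
    elif fmt == "phylip-relaxed":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f" {len(taxa)} {ncol}\n")
            for name, row in zip(taxa, rows):
                fh.write(f"{name}  {row}\n")
        if partitions:
            with open(path.with_suffix(path.suffix + ".partitions"), "w",
                      encoding="utf-8") as fh:
                for gene, first, last in partitions:
                    fh.write(f"DNA, {gene} = {first}-{last}\n")
    elif fmt == "nexus":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("#NEXUS\n\nBEGIN DATA;\n")
            fh.write(f"  DIMENSIONS NTAX={len(taxa)} NCHAR={ncol};\n")
            fh.write("  FORMAT DATATYPE=DNA MISSING=N GAP=-;\n  MATRIX\n")
            pad = max((len(t) for t in taxa), default=0) + 2
            for name, row in zip(taxa, rows):
                fh.write(f"    {name.ljust(pad)}{row}\n")
            fh.write("  ;\nEND;\n")
            if partitions:
                fh.write("\nBEGIN SETS;\n")
                for gene, first, last in partitions:
                    fh.write(f"  CHARSET {gene} = {first}-{last};\n")
                fh.write("END;\n")
    else:
        raise ValueError(f"unknown alignment format {fmt!r}")


def _matrix_of(alignment) -> tuple[list[str], list[str]]:
    if hasattr(alignment, "taxa") and hasattr(alignment, "rows"):
        return list(alignment.taxa), list(alignment.rows)
    taxa, rows = alignment
    return list(taxa), list(rows)
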