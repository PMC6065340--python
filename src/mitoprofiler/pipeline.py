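"""End-to-end orchestration: one pass per genome, then cross-genome joins.

Per input genome the pipeline emits a validation report, an annotation-table
profile, per-region skew statistics, codon usage/RSCU, and the control-region
architecture; across genomes it compares gene orders, builds the 13-PCG
stop-stripped supermatrix (when gene lengths agree, i.e. pre-aligned input),
classifies its sites, and writes a neighbor-joining tree.  Reports come in
TSV + JSON twins; all outputs are byte-deterministic for identical inputs.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from . import annotation_model as am
from . import codon_analysis as ca
from . import composition_stats as cs
from . import control_region as cr
from . import genome_io as gio
from . import phylo_prep as pp

__all__ = ["RunConfig", "load_genome", "run_genome", "run_all", "compare_profiles"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    inputs: list  # paths: .gb/.gbk GenBank, .tsv feature table, or (fasta, tsv)
    out_dir: Path = Path("mitoprofiler_out")
    strand_convention: str = "coding_strand"
    by_codon_position: bool = False
    min_period: int = 5
    max_period: int = 200
    min_copies: float = 2.5
    min_identity: float = 0.85
    motifs_path: Optional[Path] = None
    alignment_formats: tuple = ("fasta", "phylip-relaxed", "nexus")

    def motifs(self):
        if self.motifs_path is None:
            return cr.default_motifs()
        return cr.load_motifs(self.motifs_path)


def load_genome(source) -> tuple[am.MitoGenome, am.ValidationReport]:
    """Load one input: GenBank file, feature-table TSV, or (fasta, tsv) pair."""
    if isinstance(source, (tuple, list)):
        fasta_path, tsv_path = source
        rows = gio.read_feature_tsv(tsv_path)
        genome, report = am.validate_annotation(rows, identifier=Path(tsv_path).stem)
        am.compare_printed_totals(genome, rows)
        (record,) = gio.read_fasta(fasta_path)
        if len(record.residues) < genome.length:
            raise ValueError(
                f"{fasta_path}: sequence shorter ({len(record.residues)}) than "
                f"annotation extent ({genome.length})")
        return (am.MitoGenome(identifier=record.identifier, length=len(record.residues),
                              circular=True, sequence=record.residues,
                              features=genome.features), report)
    path = Path(source)
    if path.suffix in (".gb", ".gbk", ".genbank"):
        return gio.read_genbank(path), am.ValidationReport()
    if path.suffix == ".tsv":
        rows = gio.read_feature_tsv(path)
        genome, report = am.validate_annotation(rows, identifier=path.stem)
        am.compare_printed_totals(genome, rows)
        return genome, report
    raise ValueError(f"cannot infer input format of {source}")


def _dump_json(obj, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _fmt(x) -> str:
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return "NA"
    if isinstance(x, float):
        return f"{x:.3f}"  # printed precision; JSON keeps full precision
    return str(x)


def run_genome(genome: am.MitoGenome, report: am.ValidationReport,
               config: RunConfig) -> dict:
    """All single-genome stages; writes reports, returns the bundle dict."""
    out = config.out_dir / genome.identifier
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"identifier": genome.identifier, "genome": genome}

    with open(out / "validation.json", "w", encoding="utf-8") as fh:
        fh.write(report.to_json() + "\n")

    gio.write_feature_tsv(genome, out / "features.tsv")
    gaps, overlaps = am.gap_overlap_totals(genome)
    trnas = genome.features_by_category("tRNA")
    bundle["accounting"] = {
        "genome_length": genome.length,
        "gap_bp": gaps,
        "overlap_bp": overlaps,
        "n_features": len(genome.features),
        "n_tRNA": len(trnas),
        "min_tRNA_bp": min((am.feature_length(f, genome.length) for f in trnas),
                           default=None),
        "duplicates": [
            {"name": n, "copies": c, "flanks": list(fl)}
            for n, c, fl in am.find_tandem_duplicates(am.gene_order_signature(genome))
        ],
    }
    _dump_json(bundle["accounting"], out / "accounting.json")

    if genome.sequence is not None:
        profile = cs.skew_profile(genome, config.strand_convention,
                                  config.by_codon_position)
        bundle["skews"] = profile
        _dump_json(profile.to_records(), out / "skews.json")
        with open(out / "skews.tsv", "w", encoding="utf-8") as fh:
            fh.write("Region\tCodonPos\tAT_skew\tGC_skew\tAT_fraction\tLength\n")
            for r in profile.rows:
                fh.write("\t".join([r.region, _fmt(r.codon_position),
                                    _fmt(r.at_skew), _fmt(r.gc_skew),
                                    _fmt(r.at_fraction), str(r.length)]) + "\n")

        cdss = []
        for f in genome.features_by_category("PCG"):
            try:
                cdss.append(ca.coding_sequence(genome, f))
            except ValueError as exc:
                log.warning("codon stage: %s", exc)
        bundle["coding_sequences"] = cdss
        usage = ca.codon_usage(cdss)
        bundle["usage"] = usage
        values = ca.rscu(usage)
        freqs = ca.aa_frequencies(usage)
        _dump_json({"counts": {ca.to_rna(c): n for c, n in usage.counts.items()},
                    "rscu": {ca.to_rna(c): (None if math.isnan(v) else v)
                             for c, v in values.items()},
                    "aa_percent": {aa: (None if math.isnan(v) else v)
                                   for aa, v in freqs.items()}},
                   out / "codons.json")
        with open(out / "codons.tsv", "w", encoding="utf-8") as fh:
            fh.write("Codon\tAminoAcid\tCount\tRSCU\n")
            for codon in ca.ALL_CODONS:
                aa = usage.code.amino_acid(codon)
                fh.write("\t".join([
                    ca.to_rna(codon) + ("*" if aa is None else ""),
                    aa or "Stop", str(usage.counts[codon]),
                    _fmt(values.get(codon)) if aa is not None else "",
                ]) + "\n")

        try:
            arch = cr.cr_architecture(
                genome, config.motifs(), config.min_period, config.max_period,
                config.min_copies, config.min_identity)
            bundle["cr"] = arch
            _dump_json(arch.to_records(), out / "cr.json")
            with open(out / "cr.tsv", "w", encoding="utf-8") as fh:
                fh.write("Feature\tStart\tStop\tLength\n")
                for rec in arch.to_records():
                    fh.write("\t".join([rec["feature"], _fmt(rec["start"]),
                                        _fmt(rec["stop"]), rec["length"]]) + "\n")
        except KeyError:
            log.warning("%s: no control region annotated", genome.identifier)
    return bundle


def run_all(config: RunConfig) -> dict:
    """The full workflow over every input; returns the report bundle set."""
    config.out_dir = Path(config.out_dir)
    config.out_dir.mkdir(parents=True, exist_ok=True)
    bundles = []
    for source in config.inputs:
        genome, report = load_genome(source)
        bundles.append(run_genome(genome, report, config))

    result = {"bundles": bundles}
    if len(bundles) >= 2:
        sigs = {b["identifier"]: am.gene_order_signature(b["genome"])
                for b in bundles}
        ids = [b["identifier"] for b in bundles]
        comparisons = []
        for a, b in zip(ids, ids[1:]):
            diff = am.compare_signatures(sigs[a], sigs[b])
            comparisons.append({"a": a, "b": b,
                                "first_difference_index": diff,
                                "identical": diff is None})
        result["gene_order"] = comparisons
        _dump_json(comparisons, config.out_dir / "gene_order.json")

        compare_profiles(bundles, config.out_dir / "compare.tsv")

        seqed = [b for b in bundles if b["genome"].sequence is not None]
        if len(seqed) >= 2:
            matrix = _build_supermatrix(seqed)
            if matrix is not None:
                result["supermatrix"] = matrix
                for fmt, ext in (("fasta", "fasta"), ("phylip-relaxed", "phy"),
                                 ("nexus", "nex")):
                    if fmt in config.alignment_formats:
                        gio.write_alignment(matrix.alignment, fmt,
                                            config.out_dir / f"supermatrix.{ext}",
                                            partitions=list(matrix.partitions))
                sites = pp.classify_sites(matrix.alignment)
                result["sites"] = sites
                _dump_json(sites.__dict__, config.out_dir / "sitestats.json")
                dm = pp.p_distance(matrix.alignment)
                tree = pp.nj_tree(dm)
                newick = pp.write_newick(tree)
                result["tree"] = tree
                (config.out_dir / "tree.nwk").write_text(newick + "\n",
                                                         encoding="utf-8")
    return result


def _build_supermatrix(bundles) -> Optional[pp.Supermatrix]:
    """Stop-stripped per-gene matrices; None when gene lengths disagree
    (real data would need an external aligner first)."""
    per_gene: dict[str, dict[str, str]] = {}
    for b in bundles:
        for cds in b["coding_sequences"]:
            _, stop_token = ca.classify_codons(cds)
            stripped = pp.strip_stop_codon(cds, stop_token)
            per_gene.setdefault(cds.gene, {})[b["identifier"]] = stripped
    taxa = tuple(sorted(b["identifier"] for b in bundles))
    alignments = {}
    for gene, rows in per_gene.items():
        if set(rows) != set(taxa):
            log.warning("supermatrix: %s missing in some genomes; skipped", gene)
            continue
        if len({len(s) for s in rows.values()}) != 1:
            log.warning("supermatrix: %s lengths differ across genomes "
                        "(unaligned input); skipped", gene)
            continue
        alignments[gene] = pp.Alignment(taxa=taxa,
                                        rows=tuple(rows[t] for t in taxa))
    if not alignments:
        return None
    return pp.concatenate(alignments)


def compare_profiles(bundles, path) -> None:
    """Side-by-side per-gene table across genomes (missing entries marked)."""
    ids = [b["identifier"] for b in bundles]
    rows: dict[str, dict[str, dict]] = {}
    for b in bundles:
        genome = b["genome"]
        skews = b.get("skews")
        for f in genome.features:
            entry = rows.setdefault(f.name, {})
            cell = {"length": am.feature_length(f, genome.length)}
            if skews is not None:
                try:
                    r = skews.row(f.name)
                    cell["AT_skew"] = r.at_skew
                    cell["GC_skew"] = r.gc_skew
                except KeyError:
                    pass
            entry[b["identifier"]] = cell
    order = sorted(rows)
    with open(path, "w", encoding="utf-8") as fh:
        header = ["Gene"]
        for i in ids:
            header += [f"{i}:length", f"{i}:AT_skew", f"{i}:GC_skew"]
        fh.write("\t".join(header) + "\n")
        for gene in order:
            cells = [gene]
            for i in ids:
                cell = rows[gene].get(i)
                if cell is None:
                    cells += ["NA", "NA", "NA"]
                else:
                    cells += [str(cell["length"]), _fmt(cell.get("AT_skew")),
                              _fmt(cell.get("GC_skew"))]
            fh.write("\t".join(cells) + "\n")
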