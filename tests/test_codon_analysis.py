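"""Vertebrate-mitochondrial codon usage, RSCU, and amino-acid frequencies."""

from __future__ import annotations

import math

import pytest

from mitoprofiler import annotation_model as am
from mitoprofiler import codon_analysis as ca
from mitoprofiler.genome_io import bundled_path


# --- the genetic code -------------------------------------------------------

def test_vertebrate_mito_code():
    code = ca.VERTEBRATE_MITO
    assert code.stops == {"TAA", "TAG", "AGA", "AGG"}
    assert code.amino_acid("TGA") == "W"   # not a stop in this code
    assert code.amino_acid("ATA") == "M"   # Met, not Ile
    assert code.amino_acid("AGA") is None  # stop
    assert len(code.forward) == 60


def test_code_families_partition_sense_codons():
    fams = ca.VERTEBRATE_MITO.families()
    assert sum(len(v) for v in fams.values()) == 60
    assert sorted(fams["L"]) == ["CTA", "CTC", "CTG", "CTT", "TTA", "TTG"]


# --- coding-sequence extraction and padding --------------------------------

def pcg(name, start, stop, strand="H", **kw):
    return am.Feature(name=name, category="PCG", strand=strand,
                      start=start, stop=stop, **kw)


def test_coding_sequence_pads_incomplete_stops():
    #           ATG GCA T          (T- stop, padded AA)
    g = am.MitoGenome(identifier="g", length=16, circular=True,
                      sequence="ATGGCATATGGCATAA",
                      features=[pcg("ND2", 1, 7, stop_codon="T-")])
    cds = ca.coding_sequence(g, g.feature_by_name("ND2"))
    assert cds.sequence == "ATGGCATAA"
    assert cds.padded == "AA"
    assert cds.codons[-1] == "TAA"


def test_coding_sequence_pads_ta():
    g = am.MitoGenome(identifier="g", length=16, circular=True,
                      sequence="ATGGCATAGGGCATAA",
                      features=[pcg("COX3", 1, 8, stop_codon="TA-")])
    cds = ca.coding_sequence(g, g.feature_by_name("COX3"))
    assert cds.padded == "A"
    assert len(cds.sequence) == 9 and cds.sequence.endswith("TAA")


def test_coding_sequence_full_stop_no_padding():
    g = am.MitoGenome(identifier="g", length=16, circular=True,
                      sequence="ATGGCATAAGGCATAA",
                      features=[pcg("ND1", 1, 9)])
    cds = ca.coding_sequence(g, g.feature_by_name("ND1"))
    assert cds.padded == ""
    assert ca.classify_codons(cds) == ("ATG", "TAA")


def test_coding_sequence_l_strand_reverse_complements():
    # coding strand ATGTTTTAA on L => genome holds its reverse complement
    from mitoprofiler.composition_stats import reverse_complement
    coding = "ATGTTTTAA"
    g = am.MitoGenome(identifier="g", length=12, circular=True,
                      sequence=reverse_complement(coding) + "AAA",
                      features=[pcg("ND6", 1, 9, strand="L")])
    cds = ca.coding_sequence(g, g.feature_by_name("ND6"))
    assert cds.sequence == coding


def test_coding_sequence_rejects_bad_length():
    g = am.MitoGenome(identifier="g", length=16, circular=True,
                      sequence="ATGGCAAGGGCATAAA",
                      features=[pcg("ND1", 1, 8)])  # 8 bp, tail AG is no stop
    with pytest.raises(ValueError):
        ca.coding_sequence(g, g.feature_by_name("ND1"))


def test_classify_codons_tokens():
    assert ca.classify_codons(ca.CodingSequence("ND1", "ATGAAACAC"))[1] == "??"
    assert ca.classify_codons(
        ca.CodingSequence("ND2", "ATGAAATAA", padded="AA")) == ("ATG", "T-")
    assert ca.classify_codons(
        ca.CodingSequence("COX3", "ATGAAATAA", padded="A")) == ("ATG", "TA-")


# --- usage, RSCU, frequencies ----------------------------------------------

def test_codon_usage_count_padded_toggle():
    cds = ca.CodingSequence("ND2", "ATGAAATAA", padded="AA")
    with_pad = ca.codon_usage([cds], count_padded=True)
    without = ca.codon_usage([cds], count_padded=False)
    assert with_pad.counts["TAA"] == 1
    assert without.counts["TAA"] == 0
    assert with_pad.total - without.total == 1


def test_rscu_uniform_family_is_one():
    # one of each Val codon -> RSCU 1.0 across the family
    seq = "ATG" + "GTT" + "GTC" + "GTA" + "GTG" + "TAA"
    usage = ca.codon_usage([ca.CodingSequence("ND1", seq)])
    values = ca.rscu(usage)
    for codon in ("GTT", "GTC", "GTA", "GTG"):
        assert values[codon] == pytest.approx(1.0)


def test_rscu_family_sums_equal_family_size():
    usage = ca.load_usage_tsv(bundled_path("nanorana_codon_usage.tsv"),
                              "N_parkeri")
    values = ca.rscu(usage)
    for aa, codons in ca.VERTEBRATE_MITO.families().items():
        total = sum(values[c] for c in codons)
        if any(not math.isnan(values[c]) for c in codons):
            assert total == pytest.approx(len(codons))


def test_rscu_empty_family_is_nan():
    usage = ca.codon_usage([ca.CodingSequence("ND1", "ATGTAA")])
    assert math.isnan(ca.rscu(usage)["GTT"])


def test_rscu_excludes_stops():
    usage = ca.codon_usage([ca.CodingSequence("ND1", "ATGTAA")])
    assert "TAA" not in ca.rscu(usage)
    assert usage.counts["TAA"] == 1  # counted in usage, excluded from RSCU


def test_max_codon_tie_breaks_alphabetically():
    usage = ca.codon_usage([ca.CodingSequence("ND1", "ATGGCCTAA"),
                            ca.CodingSequence("ND2", "ATGGCATAA")])
    # GCA and GCC tie at 1; ATG wins outright at 2; ensure deterministic rule
    codon, count = usage.max_codon()
    assert (codon, count) == ("ATG", 2)


def test_aa_frequencies_sum_to_100():
    usage = ca.load_usage_tsv(bundled_path("nanorana_codon_usage.tsv"),
                              "N_ventripunctata")
    freqs = ca.aa_frequencies(usage)
    assert sum(v for v in freqs.values() if not math.isnan(v)) == \
        pytest.approx(100.0)


# --- the published codon table ----------------------------------------------

def test_published_table_ventripunctata_max_codon():
    usage = ca.load_usage_tsv(bundled_path("nanorana_codon_usage.tsv"),
                              "N_ventripunctata")
    assert usage.max_codon() == ("ATT", 204)  # AUU in the RNA alphabet


def test_published_table_parkeri_leu_family_total():
    usage = ca.load_usage_tsv(bundled_path("nanorana_codon_usage.tsv"),
                              "N_parkeri")
    assert usage.family_total("L") == 614


def test_load_usage_tsv_unknown_column():
    with pytest.raises(ValueError):
        ca.load_usage_tsv(bundled_path("nanorana_codon_usage.tsv"), "N_bogus")


def test_to_rna():
    assert ca.to_rna("ATT") == "AUU"


def test_synthetic_genome_all_pcgs_codon_ready(default_synthetic):
    genome, truth = default_synthetic
    planted = {f["name"]: (f["start_codon"], f["stop_codon"])
               for f in truth["features"]}
    for f in genome.features_by_category("PCG"):
        cds = ca.coding_sequence(genome, f)
        start, stop = ca.classify_codons(cds)
        want_start, want_stop = planted[f.name]
        assert start == (want_start or "ATG")
        assert stop == (want_stop or "TAA")
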