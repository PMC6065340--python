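"""Tandem-repeat detection and conserved-motif scanning in the control region."""

from __future__ import annotations

import numpy as np
import pytest

from mitoprofiler import control_region as cr
from mitoprofiler.genome_io import bundled_path

from oracle_repeats import oracle_repeats


def random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


# --- detect_tandem_repeats: worked examples ---------------------------------

def test_perfect_repeat_minimal_example():
    (rec,) = cr.detect_tandem_repeats("ACGTACGTACGT", min_period=2,
                                      max_period=6)
    assert (rec.start, rec.stop, rec.period) == (1, 12, 4)
    assert rec.copy_number == pytest.approx(3.0)
    assert rec.mean_identity == pytest.approx(1.0)
    assert rec.consensus == "ACGT"
    assert rec.decomposition() == "3 x 4"


def test_partial_final_copy_in_decomposition():
    seq = "ACGTACGTACGTAC"  # 3.5 copies of ACGT
    (rec,) = cr.detect_tandem_repeats(seq, min_period=2, max_period=7)
    assert rec.copy_number == pytest.approx(3.5)
    assert rec.decomposition() == "3 x 4 + 2"


def test_no_repeat_in_aperiodic_sequence():
    assert cr.detect_tandem_repeats("ACGTGCATTAGCCTAGGATC", min_period=3,
                                    max_period=8) == []


def test_repeat_with_mutation_still_detected():
    unit = "ACGTTGCAGT"
    seq = unit * 5
    seq = seq[:23] + ("A" if seq[23] != "A" else "C") + seq[24:]
    (rec,) = cr.detect_tandem_repeats(seq, min_period=5, max_period=20)
    assert rec.period == 10
    assert rec.mean_identity < 1.0
    assert abs(rec.copy_number - 5.0) <= 0.3


def test_harmonic_periods_suppressed():
    seq = "ACGTTGCAGT" * 6  # period 10; periods 20/30 must not be reported
    recs = cr.detect_tandem_repeats(seq, min_period=5, max_period=30)
    assert [r.period for r in recs] == [10]


def test_param_validation():
    with pytest.raises(ValueError):
        cr.detect_tandem_repeats("", min_period=2, max_period=4)
    with pytest.raises(ValueError):
        cr.detect_tandem_repeats("ACGTACGT", min_period=5, max_period=4)
    with pytest.raises(ValueError):
        cr.detect_tandem_repeats("ACGTACGT", min_period=2, max_period=40)
    with pytest.raises(ValueError):
        cr.detect_tandem_repeats("ACGTACGT" * 4, min_period=2, max_period=8,
                                 min_identity=0.0)


def test_random_2kb_has_no_calls_and_matches_oracle():
    rng = np.random.default_rng(0)
    seq = random_dna(rng, 2000)
    got = cr.detect_tandem_repeats(seq, min_period=5, max_period=200)
    assert got == []
    assert oracle_repeats(seq, 5, 200, 2.5, 0.85) == []


def test_oracle_equivalence_small_battery():
    """Spot-check the production detector against the brute-force oracle."""
    rng = np.random.default_rng(7)
    for trial in range(30):
        n = int(rng.integers(40, 301))
        seq = random_dna(rng, n)
        if trial % 2 == 0:  # embed a genuine repeat in half the trials
            unit = random_dna(rng, int(rng.integers(5, 15)))
            ins = unit * int(rng.integers(3, 6))
            at = int(rng.integers(0, max(1, n - len(ins))))
            seq = (seq[:at] + ins + seq[at + len(ins):])[:n]
        got = [(r.start, r.stop, r.period, r.copy_number, r.consensus,
                round(r.mean_identity, 9))
               for r in cr.detect_tandem_repeats(seq, 5, min(200, n // 2))]
        want = [(s, e, p, c, cons, round(i, 9))
                for s, e, p, c, cons, i in
                oracle_repeats(seq, 5, min(200, n // 2), 2.5, 0.85)]
        assert got == want, f"trial {trial} diverged from oracle"


# --- motif scanning ----------------------------------------------------------

def test_scan_motifs_exact_and_iupac():
    motifs = [cr.MotifDefinition("TAS", "TACAT"),
              cr.MotifDefinition("CSB-1", "GACATRA")]  # R = A/G
    hits = cr.scan_motifs("AATACATTTGACATGATACAT", motifs)
    by_motif = {}
    for h in hits:
        by_motif.setdefault(h.motif, []).append((h.start, h.stop))
    assert by_motif["TAS"] == [(3, 7), (17, 21)]
    assert by_motif["CSB-1"] == [(10, 16)]


def test_scan_motifs_mismatch_budget():
    strict = [cr.MotifDefinition("M", "AAAAAA", max_mismatches=0)]
    loose = [cr.MotifDefinition("M", "AAAAAA", max_mismatches=1)]
    seq = "CCAAAATACC"
    assert cr.scan_motifs(seq, strict) == []
    (hit,) = cr.scan_motifs(seq, loose)
    assert (hit.start, hit.stop, hit.mismatches) == (3, 8, 1)


def test_scan_motifs_best_per_locus():
    # overlapping placements collapse to the single best (fewest mismatches)
    motifs = [cr.MotifDefinition("M", "AAAA", max_mismatches=1)]
    hits = cr.scan_motifs("TTAAAAATT", motifs)
    assert len(hits) == 1
    assert hits[0].mismatches == 0


def test_motif_definition_rejects_non_iupac():
    with pytest.raises(ValueError):
        cr.MotifDefinition("bad", "ACGTX")


def test_default_motifs_config():
    motifs = cr.default_motifs()
    names = [m.name for m in motifs]
    for expected in ("TAS", "GACAT", "CSB-1", "CSB-2", "CSB-3", "OH"):
        assert expected in names
    assert len(names) == len(set(names))
    # load_motifs round-trips the bundled file
    assert cr.load_motifs(bundled_path("motifs_default.tsv")) == motifs


# --- merged architecture -----------------------------------------------------

def test_cr_architecture_on_synthetic_genome(default_synthetic):
    genome, truth = default_synthetic
    arch = cr.cr_architecture(genome)
    repeats = [e for e in arch.elements if isinstance(e, cr.RepeatRegion)]
    planted = truth["control_region"]["repeats"]
    assert len(repeats) >= 1
    big = max(repeats, key=lambda r: r.span)
    big_truth = max(planted, key=lambda r: r["stop"] - r["start"])
    assert big.period == big_truth["period"]
    assert abs(big.copy_number - big_truth["copies"]) <= 0.3
    # the 5' repeat units each carry a TAS, so nested hits accumulate
    assert arch.nested_tas >= 2
    # every configured motif is either placed or reported absent
    recs = arch.to_records()
    reported = {r["feature"] for r in recs}
    for m in cr.default_motifs():
        assert m.name in reported or any(
            r["feature"] == m.name for r in recs)


def test_cr_architecture_accepts_raw_sequence():
    seq = "ACGTT" * 10 + "TACATGACATA" + "GGCTA" * 3
    arch = cr.cr_architecture(seq, motifs=[cr.MotifDefinition("TAS", "TACAT")],
                              min_period=4, max_period=20)
    kinds = [type(e).__name__ for e in arch.elements]
    assert "RepeatRegion" in kinds and "MotifHit" in kinds
    assert arch.absent_motifs == []


def test_cr_architecture_records_absent_motifs():
    arch = cr.cr_architecture("ACGTGCATTAGCCTAGGATCGT" * 4,
                              motifs=[cr.MotifDefinition("CSB-2", "AAACCCCCC")])
    assert arch.absent_motifs == ["CSB-2"]
    assert any(r["length"] == "absent" for r in arch.to_records())
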