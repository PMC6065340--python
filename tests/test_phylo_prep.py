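"""Supermatrix assembly, site classification, distances, neighbor-joining."""

from __future__ import annotations

import numpy as np
import pytest

from mitoprofiler import phylo_prep as pp
from mitoprofiler.codon_analysis import CodingSequence
from mitoprofiler.phylo_prep import Alignment


# --- stop stripping ----------------------------------------------------------

def test_strip_stop_codon_complete():
    cds = CodingSequence("ND1", "ATGAAATAA")
    assert pp.strip_stop_codon(cds, "TAA") == "ATGAAA"


def test_strip_stop_codon_padded():
    cds = CodingSequence("ND2", "ATGAAATAA", padded="AA")
    assert pp.strip_stop_codon(cds, "T-") == "ATGAAA"
    cds2 = CodingSequence("COX3", "ATGAAATAA", padded="A")
    assert pp.strip_stop_codon(cds2, "TA-") == "ATGAAA"


def test_strip_stop_codon_unrecognized_kept(caplog):
    cds = CodingSequence("ND1", "ATGAAACAC")
    import logging
    with caplog.at_level(logging.WARNING, logger="mitoprofiler.phylo_prep"):
        assert pp.strip_stop_codon(cds, "??") == "ATGAAACAC"
    assert any("no recognized stop" in r.message for r in caplog.records)


# --- alignments and concatenation -------------------------------------------

def test_alignment_validation():
    with pytest.raises(ValueError):
        Alignment(taxa=("a",), rows=("ACG", "ACG"))
    with pytest.raises(ValueError):
        Alignment(taxa=("a", "a"), rows=("ACG", "ACG"))
    with pytest.raises(ValueError):
        Alignment(taxa=("a", "b"), rows=("ACG", "ACGT"))


def test_concatenate_canonical_order_and_tiling():
    taxa = ("x", "y")
    genes = {
        "ND2": Alignment(taxa, ("ACG", "ACG")),
        "ND1": Alignment(taxa, ("TTTGGG", "TTTGGC")),
        "CYTB": Alignment(taxa, ("AAA", "AAA")),
    }
    sm = pp.concatenate(genes)
    # canonical mitogenome PCG order, not dict or alphabetical order
    assert [p[0] for p in sm.partitions] == ["ND1", "ND2", "CYTB"]
    assert sm.partitions == (("ND1", 1, 6), ("ND2", 7, 9), ("CYTB", 10, 12))
    assert sm.alignment.row("x") == "TTTGGGACGAAA"
    assert sm.alignment.ncol == 12


def test_concatenate_rejects_taxa_mismatch():
    genes = {"ND1": Alignment(("x", "y"), ("AAA", "AAA")),
             "ND2": Alignment(("x", "z"), ("CCC", "CCC"))}
    with pytest.raises(ValueError, match="ND2"):
        pp.concatenate(genes)


def test_concatenate_empty_raises():
    with pytest.raises(ValueError):
        pp.concatenate({})


def test_supermatrix_partition_tiling_enforced():
    aln = Alignment(("x", "y"), ("ACGACG", "ACGACG"))
    with pytest.raises(ValueError):
        pp.Supermatrix(alignment=aln, partitions=(("g1", 1, 3), ("g2", 5, 6)))


# --- site classification -----------------------------------------------------

def test_classify_sites_hand_case():
    aln = Alignment(
        taxa=("a", "b", "c", "d"),
        rows=("ACGTA-",
              "ACCTAN",
              "AGCAA-",
              "AGCTGN"))
    # col1 AAAA conserved; col2 CCGG informative; col3 GCCC singleton;
    # col4 TTAT singleton; col5 AAAG singleton; col6 all missing -> conserved
    sc = pp.classify_sites(aln)
    assert (sc.total, sc.conserved, sc.variable) == (6, 2, 4)
    assert sc.parsimony_informative == 1
    assert sc.singleton == 3
    assert sc.all_missing == 1
    assert sc.conserved + sc.variable == sc.total


def test_classify_sites_needs_two_rows():
    with pytest.raises(ValueError):
        pp.classify_sites(Alignment(("a",), ("ACGT",)))


def test_classify_sites_missing_data_excluded():
    # the N row does not create variability on its own
    aln = Alignment(("a", "b", "c"), ("AC", "AC", "NN"))
    sc = pp.classify_sites(aln)
    assert sc.variable == 0


# --- distances ---------------------------------------------------------------

def test_p_distance_basic_and_missing():
    aln = Alignment(("a", "b"), ("ACGTACGT", "ACGTACGA"))
    d = pp.p_distance(aln)
    assert d.distance("a", "b") == pytest.approx(1 / 8)
    # gaps / N excluded pairwise from numerator and denominator
    aln2 = Alignment(("a", "b"), ("ACGT-N", "ACCTAA"))
    assert pp.p_distance(aln2).distance("a", "b") == pytest.approx(1 / 4)


def test_p_distance_symmetric_zero_diagonal():
    aln = Alignment(("a", "b", "c"), ("ACGT", "ACGA", "TCGA"))
    d = pp.p_distance(aln)
    assert np.allclose(d.values, d.values.T)
    assert np.allclose(np.diag(d.values), 0)


# --- neighbor joining --------------------------------------------------------

def additive_matrix():
    """4-taxon additive distances from tree ((A:2,B:3):1,(C:4,D:5));"""
    taxa = ("A", "B", "C", "D")
    vals = np.array([
        [0, 5, 7, 8],
        [5, 0, 8, 9],
        [7, 8, 0, 9],
        [8, 9, 9, 0],
    ], dtype=float)
    return pp.DistanceMatrix(taxa=taxa, values=vals)


def test_nj_recovers_additive_topology_and_lengths():
    tree = pp.nj_tree(additive_matrix())
    assert pp.has_cherry(tree, "A", "B")
    assert pp.has_cherry(tree, "C", "D")
    # NJ is exact on additive matrices: leaf branch lengths recovered
    lengths = {}
    def walk(node):
        if node.is_leaf:
            lengths[node.name] = node.length
        for c in node.children:
            walk(c)
    walk(tree)
    assert lengths == pytest.approx({"A": 2, "B": 3, "C": 4, "D": 5})


def test_nj_matches_skbio_topology():
    """Cross-check the hand-written NJ against scikit-bio on random matrices."""
    from skbio import DistanceMatrix as SkbioDM
    from skbio.tree import nj as skbio_nj
    rng = np.random.default_rng(11)
    for _ in range(5):
        n = 6
        coords = rng.random((n, 3))
        vals = np.sqrt(((coords[:, None] - coords[None]) ** 2).sum(-1))
        taxa = tuple("T%d" % i for i in range(n))
        ours = pp.nj_tree(pp.DistanceMatrix(taxa=taxa, values=vals))
        theirs = skbio_nj(SkbioDM(vals, ids=list(taxa)))
        # compare unrooted topologies via compatible bipartitions
        our_clades = {c for c in ours.clades() if 1 < len(c) < n - 1}
        all_taxa = frozenset(taxa)
        their_clades = set()
        for node in theirs.non_tips():
            tips = frozenset(t.name for t in node.tips())
            if 1 < len(tips) < n - 1:
                their_clades.add(tips)
        norm = lambda cl: {min(c, all_taxa - c, key=sorted) for c in cl}
        assert norm(our_clades) == norm(their_clades)


def test_nj_deterministic_under_ties():
    # a perfectly symmetric matrix: tie-breaking must still give one answer
    vals = np.full((4, 4), 1.0) - np.eye(4)
    dm = pp.DistanceMatrix(taxa=("a", "b", "c", "d"), values=vals)
    t1 = pp.write_newick(pp.nj_tree(dm))
    t2 = pp.write_newick(pp.nj_tree(dm))
    assert t1 == t2


def test_write_newick_format():
    tree = pp.nj_tree(additive_matrix())
    nwk = pp.write_newick(tree)
    assert nwk.endswith(";")
    assert nwk.count("(") == nwk.count(")")
    for t in ("A", "B", "C", "D"):
        assert t in nwk


def test_has_cherry_unrooted_aware():
    # the additive 4-taxon tree has one internal edge, the A+B | C+D split;
    # in the unrooted reading both sides of it count as cherries
    tree = pp.nj_tree(additive_matrix())
    assert pp.has_cherry(tree, "A", "B")
    assert pp.has_cherry(tree, "C", "D")
    assert not pp.has_cherry(tree, "A", "C")
    assert not pp.has_cherry(tree, "B", "D")
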