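"""13-PCG supermatrix preparation, alignment site statistics, and NJ plumbing.

The supermatrix is the concatenation of the 13 protein-coding genes in
canonical order, each with its terminal stop codon (complete or padded)
removed, with recorded per-gene partitions.  Site classification follows the
standard definitions: a column is conserved when it shows one state over the
non-missing rows, variable otherwise, and potentially parsimony-informative
when at least two states are each present in at least two rows.  Distance and
tree routines (p-distance, neighbor-joining, Newick) are provided as sanity
plumbing — model-based inference is expected to run in external tools on the
exported matrices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .annotation_model import PCG_NAMES
from .codon_analysis import CodingSequence, VERTEBRATE_MITO

__all__ = [
    "Alignment",
    "Supermatrix",
    "SiteClassification",
    "DistanceMatrix",
    "TreeNode",
    "strip_stop_codon",
    "concatenate",
    "classify_sites",
    "p_distance",
    "nj_tree",
    "write_newick",
]

log = logging.getLogger(__name__)

MISSING = set("N-")


@dataclass(frozen=True)
class Alignment:
    """Equal-length rows over {A,C,G,T,N,-} with unique taxon names."""

    taxa: tuple
    rows: tuple

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.rows):
            raise ValueError("taxa/rows length mismatch")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon names")
        widths = {len(r) for r in self.rows}
        if len(widths) > 1:
            raise ValueError(f"ragged alignment: widths {sorted(widths)}")

    @property
    def ncol(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, taxon: str) -> str:
        return self.rows[self.taxa.index(taxon)]


@dataclass(frozen=True)
class Supermatrix:
    alignment: Alignment
    partitions: tuple  # (gene, first column, last column), 1-based inclusive

    def __post_init__(self) -> None:
        pos = 1
        for gene, first, last in self.partitions:
            if first != pos or last < first:
                raise ValueError(f"partitions do not tile: {gene} at {first}-{last}")
            pos = last + 1
        if self.partitions and pos - 1 != self.alignment.ncol:
            raise ValueError("partitions do not cover the matrix")


def strip_stop_codon(cds: CodingSequence, stop_token: str) -> str:
    """Remove the terminal stop codon (complete or padded) from a gene.

    Padded genes lose the padding plus the incomplete stop base(s) — a net
    three bases, keeping the result codon-aligned.  A gene whose terminal
    codon is not a recognized stop is returned unchanged with a warning.
    """
    seq = cds.sequence
    if stop_token in ("T-", "TA-") or cds.padded:
        return seq[:-3]
    if stop_token in VERTEBRATE_MITO.stops and seq.endswith(stop_token):
        return seq[:-3]
    log.warning("%s: no recognized stop codon (%r); kept intact", cds.gene, stop_token)
    return seq


def concatenate(gene_alignments: dict) -> Supermatrix:
    """Join per-gene alignments in canonical PCG order into a supermatrix.

    ``gene_alignments`` maps gene name -> Alignment; every gene must cover the
    identical taxon set.  Genes absent from the canonical 13 are appended
    after them in sorted order (normally there are none).
    """
    if not gene_alignments:
        raise ValueError("no gene alignments given")
    order = [g for g in PCG_NAMES if g in gene_alignments]
    order += sorted(set(gene_alignments) - set(PCG_NAMES))
    taxa = gene_alignments[order[0]].taxa
    for gene in order:
        aln = gene_alignments[gene]
        if set(aln.taxa) != set(taxa):
            diff = set(aln.taxa) ^ set(taxa)
            raise ValueError(f"taxa set mismatch at {gene}: {sorted(diff)}")
    parts = []
    rows = {t: [] for t in taxa}
    pos = 1
    for gene in order:
        aln = gene_alignments[gene]
        for t in taxa:
            rows[t].append(aln.row(t))
        parts.append((gene, pos, pos + aln.ncol - 1))
        pos += aln.ncol
    alignment = Alignment(taxa=tuple(taxa),
                          rows=tuple("".join(rows[t]) for t in taxa))
    return Supermatrix(alignment=alignment, partitions=tuple(parts))


@dataclass(frozen=True)
class SiteClassification:
    total: int
    conserved: int
    variable: int
    parsimony_informative: int
    singleton: int
    all_missing: int = 0  # columns with no non-missing state (conserved by convention)

    def __post_init__(self) -> None:
        assert self.conserved + self.variable == self.total
        assert self.parsimony_informative <= self.variable
        assert self.singleton == self.variable - self.parsimony_informative


def classify_sites(alignment: Alignment) -> SiteClassification:
    """Count conserved / variable / parsimony-informative / singleton columns.

    Gaps and N are missing data.  A column with zero or one non-missing row,
    or all-identical non-missing states, is conserved; otherwise variable.  A
    variable column is parsimony-informative when >=2 states each occur in
    >=2 rows, else it is a singleton column.  Columns that are entirely
    missing count as conserved by convention and are tallied separately.
    """
    if len(alignment.rows) < 2:
        raise ValueError("site classification needs >= 2 rows")
    mat = np.array([list(r) for r in alignment.rows])
    total = mat.shape[1]
    conserved = variable = informative = all_missing = 0
    for j in range(total):
        col = mat[:, j]
        states = col[(col != "N") & (col != "-")]
        if states.size == 0:
            all_missing += 1
            conserved += 1
            continue
        uniq, counts = np.unique(states, return_counts=True)
        if len(uniq) == 1:
            conserved += 1
        else:
            variable += 1
            if (counts >= 2).sum() >= 2:
                informative += 1
    if all_missing:
        log.warning("%d entirely-missing columns counted as conserved", all_missing)
    return SiteClassification(
        total=total, conserved=conserved, variable=variable,
        parsimony_informative=informative, singleton=variable - informative,
        all_missing=all_missing)


# ---------------------------------------------------------------------------
# distances and neighbor-joining
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DistanceMatrix:
    taxa: tuple
    values: np.ndarray  # symmetric, zero diagonal

    def distance(self, a: str, b: str) -> float:
        return float(self.values[self.taxa.index(a), self.taxa.index(b)])


def p_distance(alignment: Alignment) -> DistanceMatrix:
    """Proportion of differing sites over shared non-missing columns."""
    mat = np.array([list(r) for r in alignment.rows])
    present = (mat != "N") & (mat != "-")
    n = len(alignment.taxa)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = present[i] & present[j]
            m = int(shared.sum())
            if m == 0:
                raise ValueError(
                    f"no shared columns between {alignment.taxa[i]} and "
                    f"{alignment.taxa[j]}")
            d = float((mat[i, shared] != mat[j, shared]).mean())
            values[i, j] = values[j, i] = d
    return DistanceMatrix(taxa=alignment.taxa, values=values)


@dataclass
class TreeNode:
    """Binary (or multifurcating at the root) tree with branch lengths."""

    name: Optional[str] = None
    length: float = 0.0
    children: list = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaf_names(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        out = []
        for c in self.children:
            out.extend(c.leaf_names())
        return out

    def clades(self) -> list[frozenset]:
        """Leaf sets of every internal edge (for topology comparison)."""
        out = []
        for c in self.children:
            if not c.is_leaf:
                out.append(frozenset(c.leaf_names()))
                out.extend(c.clades())
        return out


def nj_tree(matrix: DistanceMatrix) -> TreeNode:
    """Canonical neighbor-joining (Saitou-Nei, Studier-Keppler Q criterion).

    Ties in the Q matrix break by the lexicographically smallest taxon-name
    pair, making the tree deterministic.  The final join leaves a trifurcating
    root, the conventional unrooted representation.
    """
    nodes = [TreeNode(name=t) for t in matrix.taxa]
    labels = list(matrix.taxa)
    d = matrix.values.astype(float).copy()
    while len(nodes) > 3:
        n = len(nodes)
        totals = d.sum(axis=1)
        best: Optional[tuple] = None
        for i in range(n):
            for j in range(i + 1, n):
                q = (n - 2) * d[i, j] - totals[i] - totals[j]
                key = (q, *sorted((labels[i], labels[j])))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        vi = 0.5 * d[i, j] + (totals[i] - totals[j]) / (2 * (n - 2))
        vj = d[i, j] - vi
        child_i, child_j = nodes[i], nodes[j]
        child_i.length = max(vi, 0.0)
        child_j.length = max(vj, 0.0)
        parent = TreeNode(children=[child_i, child_j])
        new_d = 0.5 * (d[i] + d[j] - d[i, j])
        keep = [k for k in range(n) if k not in (i, j)]
        d2 = np.zeros((len(keep) + 1, len(keep) + 1))
        d2[:-1, :-1] = d[np.ix_(keep, keep)]
        d2[-1, :-1] = d2[:-1, -1] = new_d[keep]
        d = d2
        nodes = [nodes[k] for k in keep] + [parent]
        labels = [labels[k] for k in keep] + ["+".join(sorted(
            child_i.leaf_names() + child_j.leaf_names()))]
    if len(nodes) == 3:
        a, b, c = d[0, 1], d[0, 2], d[1, 2]
        nodes[0].length = max(0.5 * (a + b - c), 0.0)
        nodes[1].length = max(0.5 * (a + c - b), 0.0)
        nodes[2].length = max(0.5 * (b + c - a), 0.0)
    elif len(nodes) == 2:
        nodes[0].length = nodes[1].length = 0.5 * d[0, 1]
    root = TreeNode(children=nodes)
    return root


def write_newick(tree: TreeNode) -> str:
    """Newick string with branch lengths at 6 decimals."""
    def fmt(node: TreeNode, top: bool = False) -> str:
        if node.is_leaf:
            body = node.name
        else:
            body = "(" + ",".join(fmt(c) for c in node.children) + ")"
        if top:
            return body
        return f"{body}:{node.length:.6f}"
    return fmt(tree, top=True) + ";"


def has_cherry(tree: TreeNode, a: str, b: str) -> bool:
    """True when leaves a and b form a two-leaf clade somewhere in the tree."""
    target = frozenset((a, b))

    def visit(node: TreeNode) -> bool:
        if node.is_leaf:
            return False
        leafset = frozenset(node.leaf_names())
        if leafset == target:
            return True
        return any(visit(c) for c in node.children)

    # also check the complement split (unrooted interpretation)
    all_leaves = frozenset(tree.leaf_names())
    if visit(tree):
        return True
    for c in tree.children:
        if not c.is_leaf and all_leaves - frozenset(c.leaf_names()) == target:
            return True
    return False
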