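"""Control-region (D-loop) architecture: tandem-repeat arrays and motifs.

The mitochondrial control region regulates replication and transcription.  In
ranid and dicroglossid frogs it typically carries a 5' tandem-repeat array with
embedded termination-associated sequences (TAS), the heavy-strand replication
origin (O_H), conserved sequence blocks CSB-1/2/3, and — in some lineages —
additional short-period repeat arrays at the 3' side.  This module detects
tandem repeats by periodic self-matching, scans IUPAC-degenerate motifs with a
mismatch budget, and merges both into an ordered architecture report with
coordinates local to the control region (1-based).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .annotation_model import MitoGenome

__all__ = [
    "RepeatRegion",
    "MotifDefinition",
    "MotifHit",
    "CrArchitecture",
    "detect_tandem_repeats",
    "scan_motifs",
    "cr_architecture",
    "load_motifs",
    "default_motifs",
]

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass(frozen=True)
class RepeatRegion:
    """A detected tandem-repeat array (coordinates 1-based inclusive, local)."""

    start: int
    stop: int
    period: int
    copy_number: float  # span / period, one decimal place
    consensus: str
    mean_identity: float  # fraction of bases agreeing with the tiled consensus

    @property
    def span(self) -> int:
        return self.stop - self.start + 1

    def decomposition(self) -> str:
        """Printed-style length decomposition, e.g. '6 x 124 + 62'."""
        full, rem = divmod(self.span, self.period)
        return f"{full} x {self.period} + {rem}" if rem else f"{full} x {self.period}"


@dataclass(frozen=True)
class MotifDefinition:
    name: str
    consensus: str  # IUPAC alphabet
    max_mismatches: int = 0

    def __post_init__(self) -> None:
        bad = set(self.consensus.upper()) - set(IUPAC)
        if bad:
            raise ValueError(f"{self.name}: non-IUPAC symbols {sorted(bad)}")


@dataclass(frozen=True)
class MotifHit:
    motif: str
    start: int
    stop: int
    strand: str
    mismatches: int


@dataclass
class CrArchitecture:
    """Repeat regions and motif hits ordered along the control region."""

    elements: list  # RepeatRegion | MotifHit, ordered by start
    absent_motifs: list[str]  # configured motifs with no hit
    nested_tas: int  # TAS hits lying inside a detected repeat array

    def to_records(self) -> list[dict]:
        recs = []
        for el in self.elements:
            if isinstance(el, RepeatRegion):
                recs.append({
                    "feature": f"{el.copy_number} tandem repeat units",
                    "start": el.start, "stop": el.stop,
                    "length": el.decomposition(),
                    "period": el.period, "identity": round(el.mean_identity, 3),
                    "consensus": el.consensus,
                })
            else:
                recs.append({
                    "feature": el.motif, "start": el.start, "stop": el.stop,
                    "length": str(el.stop - el.start + 1),
                    "mismatches": el.mismatches,
                })
        for name in self.absent_motifs:
            recs.append({"feature": name, "start": None, "stop": None,
                         "length": "absent"})
        return recs


# ---------------------------------------------------------------------------
# tandem-repeat detection
# ---------------------------------------------------------------------------

def detect_tandem_repeats(sequence: str, min_period: int = 5,
                          max_period: int = 200, min_copies: float = 2.5,
                          min_identity: float = 0.85) -> list[RepeatRegion]:
    """Detect tandem-repeat arrays by periodic self-matching.

    For each candidate period p, positions where ``s[i] == s[i+p]`` are scored
    in sliding windows of one period; windows at or above ``min_identity`` seed
    candidate regions, which are merged, trimmed at exact-mismatch edges, and
    extended through exact matches.  Overlapping calls across periods resolve
    by (longer span, then smaller period, then leftmost).  Copy number is
    span/period to one decimal.
    """
    n = len(sequence)
    if n == 0:
        raise ValueError("empty sequence")
    if not (1 <= min_period <= max_period <= n // 2):
        raise ValueError(
            f"need 1 <= min_period <= max_period <= len/2, got "
            f"({min_period}, {max_period}) for length {n}")
    if not 0 < min_identity <= 1:
        raise ValueError("min_identity must be in (0, 1]")

    arr = np.frombuffer(sequence.encode(), dtype=np.uint8)
    candidates: list[RepeatRegion] = []
    for p in range(min_period, max_period + 1):
        m = (arr[:-p] == arr[p:])
        if m.size < p:
            continue
        # windowed identity over one period
        cs = np.concatenate(([0], np.cumsum(m)))
        win = cs[p:] - cs[:-p]  # matches in m[j:j+p]
        seeds = np.flatnonzero(win >= min_identity * p)
        if seeds.size == 0:
            continue
        # merge seed windows that touch or are separated by at most one
        # period of failing windows (a tight mutation cluster knocks out a
        # run of ~p windows without ending the array)
        breaks = np.flatnonzero(np.diff(seeds) > 2 * p)
        groups = np.split(seeds, breaks + 1)
        for g in groups:
            a = int(g[0])            # first matched offset in m-space
            b = int(g[-1]) + p - 1   # last matched offset in m-space
            # sharpen the edges: windowed seeding overshoots into flanking
            # sequence by up to (1 - min_identity) * p, so shrink while a
            # short edge window matches poorly, then drop outright mismatches
            e = min(8, p)
            while b - a + 1 >= e and m[a:a + e].mean() < 0.75:
                a += 1
            while b - a + 1 >= e and m[b - e + 1:b + 1].mean() < 0.75:
                b -= 1
            while a <= b and not m[a]:
                a += 1
            while b >= a and not m[b]:
                b -= 1
            # extend through contiguous exact matches beyond the windows
            while a > 0 and m[a - 1]:
                a -= 1
            while b + 1 < m.size and m[b + 1]:
                b += 1
            if b < a:
                continue
            span = (b + p) - a + 1   # s-space: matched pairs cover [a, b+p]
            # sharpen the boundaries against the consensus unit: self-match
            # windows blur the true edges by up to one period, which is too
            # coarse for single-decimal copy numbers at short periods
            consensus = _phase_consensus(sequence, a, span, p)
            a, span = _refine_edges(arr, a, span, p, consensus)
            copies = round(span / p, 1)
            if copies < min_copies:
                continue
            if span <= p:
                continue
            consensus = _phase_consensus(sequence, a, span, p)
            ident = _consensus_identity(sequence[a:a + span], consensus)
            if ident < min_identity:
                continue
            # suppress harmonics: if a proper divisor of p already explains
            # the region at the identity threshold, the fundamental-period
            # call covers it and this multiple is redundant
            if _is_harmonic(sequence, a, span, p, min_identity, min_period):
                continue
            candidates.append(RepeatRegion(
                start=a + 1, stop=a + span, period=p, copy_number=copies,
                consensus=consensus, mean_identity=ident))

    # resolve overlaps: longer span first, then smaller period, then leftmost
    candidates.sort(key=lambda r: (-r.span, r.period, r.start))
    accepted: list[RepeatRegion] = []
    for cand in candidates:
        if any(_overlap(cand, acc) for acc in accepted):
            continue
        accepted.append(cand)
    accepted.sort(key=lambda r: r.start)
    return accepted


def _refine_edges(arr: np.ndarray, a: int, span: int, p: int,
                  consensus: str) -> tuple[int, int]:
    """Re-derive the array edges by tiling the consensus unit outward.

    From a phase-aligned interior anchor, walk each direction scoring +2 for
    a base that agrees with the tiled consensus and -3 for one that does not
    (X-drop style: stop once the score falls 12 below its running maximum).
    The edge is the outermost position attaining the maximum, so isolated
    in-array mutations are crossed while random flank sequence — whose
    expected score drifts steeply negative — ends the walk within a base or
    two of the true boundary.
    """
    cons = np.frombuffer(consensus.encode(), dtype=np.uint8)
    n = arr.size

    def agree(i: int) -> bool:
        return bool(arr[i] == cons[(i - a) % p])

    def walk(start: int, step: int) -> int:
        edge, best, score, i = start, 0, 0, start
        while 0 <= i < n:
            if agree(i):
                score += 2
                if score >= best:
                    best, edge = score, i
            else:
                score -= 3
                if best - score >= 12:
                    break
            i += step
        return edge

    anchor = a + (span // (2 * p)) * p  # phase-0 interior position
    anchor = min(max(anchor, a), a + span - 1)
    left = walk(anchor, -1)
    right = walk(anchor, +1)
    return left, right - left + 1


def _is_harmonic(sequence: str, a: int, span: int, p: int,
                 min_identity: float, min_period: int) -> bool:
    # only defer to sub-periods that are themselves reportable; a region
    # whose true period lies below min_period is still best described by p
    region = sequence[a:a + span]
    for q in range(min_period, p):
        if p % q != 0 or len(region) <= q:
            continue
        cons_q = _consensus_unit(region, q)
        if _consensus_identity(region, cons_q) >= min_identity:
            return True
    return False


def _overlap(a: RepeatRegion, b: RepeatRegion) -> bool:
    return a.start <= b.stop and b.start <= a.stop


def _phase_consensus(sequence: str, a: int, span: int, p: int) -> str:
    """Consensus unit phase-aligned to position ``a``.

    When the region holds at least three periods the outermost period on
    each side is excluded: the initial window-based boundaries can drag in
    flanking bases, and for low-copy arrays those contaminate the majority
    vote enough to bias the edge refinement outward.
    """
    if span >= 3 * p:
        return _consensus_unit(sequence[a + p:a + span - p], p)
    return _consensus_unit(sequence[a:a + span], p)


def _consensus_identity(region: str, consensus: str) -> float:
    """Fraction of region bases agreeing with the consensus tiled from its
    5' end (the per-copy identity a dot-matrix style report would quote)."""
    p = len(consensus)
    return sum(b == consensus[i % p] for i, b in enumerate(region)) / len(region)


def _consensus_unit(region: str, period: int) -> str:
    """Column-majority consensus over the unit-aligned full copies."""
    n_full = len(region) // period
    if n_full == 0:
        return region[:period]
    cols: list[str] = []
    for j in range(period):
        column = [region[i * period + j] for i in range(n_full)]
        # majority; ties break to the lexicographically smallest base
        best = min(set(column), key=lambda b: (-column.count(b), b))
        cols.append(best)
    return "".join(cols)


# ---------------------------------------------------------------------------
# motif scanning
# ---------------------------------------------------------------------------

def _iupac_match_counts(sequence: str, consensus: str) -> np.ndarray:
    """Mismatch count of the consensus at every offset (IUPAC-aware)."""
    n, k = len(sequence), len(consensus)
    if n < k:
        return np.empty(0, dtype=int)
    arr = np.frombuffer(sequence.encode(), dtype=np.uint8)
    mism = np.zeros(n - k + 1, dtype=int)
    for j, sym in enumerate(consensus.upper()):
        allowed = np.array([ord(b) for b in IUPAC[sym]], dtype=np.uint8)
        ok = np.isin(arr[j:j + n - k + 1], allowed)
        mism += ~ok
    return mism


def scan_motifs(sequence: str,
                motifs: Sequence[MotifDefinition]) -> list[MotifHit]:
    """All motif placements within each motif's mismatch budget.

    Overlapping placements of the same motif collapse to the best per locus
    (fewest mismatches, then leftmost).
    """
    hits: list[MotifHit] = []
    for motif in motifs:
        k = len(motif.consensus)
        mism = _iupac_match_counts(sequence, motif.consensus)
        positions = np.flatnonzero(mism <= motif.max_mismatches)
        # greedy best-per-locus reduction
        order = sorted(positions, key=lambda i: (mism[i], i))
        taken: list[int] = []
        for i in order:
            if any(abs(i - j) < k for j in taken):
                continue
            taken.append(int(i))
        for i in sorted(taken):
            hits.append(MotifHit(motif=motif.name, start=i + 1, stop=i + k,
                                 strand="H", mismatches=int(mism[i])))
    hits.sort(key=lambda h: (h.start, h.motif))
    return hits


def load_motifs(path) -> list[MotifDefinition]:
    """Read a motif config TSV (name / consensus / max_mismatches; # comments)."""
    motifs = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("name\t"):
                continue
            name, consensus, budget = line.split("\t")
            motifs.append(MotifDefinition(name=name, consensus=consensus.upper(),
                                          max_mismatches=int(budget)))
    return motifs


def default_motifs() -> list[MotifDefinition]:
    from .genome_io import bundled_path
    return load_motifs(bundled_path("motifs_default.tsv"))


# ---------------------------------------------------------------------------
# merged architecture
# ---------------------------------------------------------------------------

def cr_architecture(source: Union[MitoGenome, str],
                    motifs: Optional[Sequence[MotifDefinition]] = None,
                    min_period: int = 5, max_period: int = 200,
                    min_copies: float = 2.5,
                    min_identity: float = 0.85) -> CrArchitecture:
    """Ordered repeat+motif report for a control region.

    ``source`` is either a control-region sequence or an annotated genome (its
    CR feature is extracted).  Configured motifs with no hit are reported with
    an explicit absent marker; TAS hits nested inside a repeat array are
    counted (5' arrays in these frogs carry one TAS per repeat unit).
    """
    if isinstance(source, MitoGenome):
        sequence = source.subsequence(source.feature_by_name("CR"))
    else:
        sequence = source
    if motifs is None:
        motifs = default_motifs()
    repeats = (detect_tandem_repeats(sequence, min_period,
                                     min(max_period, len(sequence) // 2),
                                     min_copies, min_identity)
               if len(sequence) >= 2 * min_period else [])
    hits = scan_motifs(sequence, motifs) if sequence else []
    nested_tas = sum(
        1 for h in hits if h.motif == "TAS"
        and any(r.start <= h.start and h.stop <= r.stop for r in repeats))
    found = {h.motif for h in hits}
    absent = [m.name for m in motifs if m.name not in found]
    elements = sorted([*repeats, *hits],
                      key=lambda el: (el.start, 0 if isinstance(el, RepeatRegion) else 1))
    return CrArchitecture(elements=elements, absent_motifs=absent,
                          nested_tas=nested_tas)
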