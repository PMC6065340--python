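"""Synthetic annotated mitogenomes with recorded ground truth.

The generator emits a frog-like circular mitogenome — 13 protein-coding genes,
23 tRNAs (with the dicroglossid tandem tRNA-Met duplication between tRNA-Gln
and ND2), two rRNAs, the light-strand replication origin, and a long control
region — with every measurable signal planted on purpose and written to a
truth record:

* feature coordinates, strands, start codons, and complete/incomplete stops
  (including the characteristic ATP8/ATP6 −7, ND4L/ND4 −7 and ND5/ND6 −15
  overlaps, with the overlapping bases genuinely shared between reading
  frames and strands);
* an A+T-rich base composition and strand skews;
* codon usage sampled from synonymous-family weights (so codon-bias recovery
  is a statistical test, not a tautology);
* a control region assembled from planted tandem-repeat arrays (with embedded
  TAS copies) and motifs (O_H, CSB-1/2/3);
* optional diverged copies for distance/tree tests.

All randomness flows from one seed; identical spec + seed give byte-identical
output.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .annotation_model import Feature, MitoGenome, validate_annotation
from .codon_analysis import ALL_CODONS, VERTEBRATE_MITO
from .composition_stats import reverse_complement
from .genome_io import (SequenceRecord, read_feature_tsv, bundled_path,
                        write_fasta, write_feature_tsv, write_genbank)

__all__ = [
    "PlannedRepeat",
    "PlannedMotif",
    "PlannedSpacer",
    "SyntheticSpec",
    "generate_mitogenome",
    "mutate_population",
    "generate_trio",
    "write_fixture_set",
    "default_layout",
    "default_cr_plan",
]

BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# spec
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlannedRepeat:
    period: int
    copies: float
    mutation_rate: float = 0.02
    embed_tas: bool = False

    @property
    def span(self) -> int:
        return int(round(self.period * self.copies))


@dataclass(frozen=True)
class PlannedMotif:
    name: str
    sequence: str


@dataclass(frozen=True)
class PlannedSpacer:
    length: int


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic mitogenome.

    Defaults emulate the measured profile of a high-altitude dicroglossid
    mitogenome: an 18.4-kb circle with the 40-feature layout, ~59% A+T,
    negative AT/GC skew on the heavy strand, and a 2.9-kb control region with
    a TAS-bearing 6.5 x 124 bp 5' array and short-period 3' arrays.
    """

    seed: int = 0
    layout: Optional[Sequence[Feature]] = None  # None -> default 40-feature layout
    genome_length_target: Optional[int] = None
    at_fraction: float = 0.59
    at_skew: float = -0.066
    gc_skew: float = -0.259
    cr_at_fraction: float = 0.66
    cr_plan: Optional[list] = None  # None -> default plan
    divergence_plan: Optional[list] = None  # [(label, per-site substitution prob)]

    def __post_init__(self) -> None:
        for p in (self.at_fraction, self.cr_at_fraction):
            if not 0 < p < 1:
                raise ValueError("AT fractions must be in (0, 1)")
        for s in (self.at_skew, self.gc_skew):
            if not -1 <= s <= 1:
                raise ValueError("skew targets must be in [-1, 1]")


def default_layout() -> list[Feature]:
    """The 40-feature layout (coordinates of the 18,373-bp reference table,
    after its one documented coordinate repair)."""
    rows = read_feature_tsv(bundled_path("nanorana_ventripunctata_features.tsv"))
    genome, _ = validate_annotation(rows, identifier="layout")
    return list(genome.features)


_TAS = "TATAAGACATCTATGTA"


def default_cr_plan() -> list:
    """Control-region plan: 5' TAS-bearing 124-bp array, O_H, CSB-1/2/3,
    then three short-period 3' arrays, padded to the CR length."""
    from .control_region import default_motifs

    motif = {m.name: m.consensus for m in default_motifs()}
    return [
        PlannedSpacer(20),
        PlannedRepeat(period=124, copies=6.5, mutation_rate=0.02, embed_tas=True),
        PlannedSpacer(700),
        PlannedMotif("OH", motif["OH"]),
        PlannedSpacer(90),
        PlannedMotif("CSB-1", motif["CSB-1"]),
        PlannedSpacer(40),
        PlannedMotif("CSB-2", motif["CSB-2"]),
        PlannedSpacer(20),
        PlannedMotif("CSB-3", motif["CSB-3"]),
        PlannedSpacer(60),
        PlannedRepeat(period=11, copies=10.8, mutation_rate=0.02),
        PlannedSpacer(40),
        PlannedRepeat(period=11, copies=10.9, mutation_rate=0.02),
        PlannedSpacer(30),
        PlannedRepeat(period=10, copies=29.6, mutation_rate=0.02),
    ]


# ---------------------------------------------------------------------------
# base and codon sampling
# ---------------------------------------------------------------------------

def _base_probs(at: float, at_skew: float, gc_skew: float) -> np.ndarray:
    """P(A), P(C), P(G), P(T) realizing the AT fraction and skew targets."""
    gc = 1.0 - at
    pa = at / 2 * (1 + at_skew)
    pt = at / 2 * (1 - at_skew)
    pg = gc / 2 * (1 + gc_skew)
    pc = gc / 2 * (1 - gc_skew)
    return np.array([pa, pc, pg, pt])


def _random_bases(n: int, probs: np.ndarray, rng: np.random.Generator) -> str:
    return "".join(BASES[rng.choice(4, size=n, p=probs)])


def _balanced_unit(period: int, probs: np.ndarray,
                   rng: np.random.Generator) -> str:
    """A random repeat unit whose A+T count is fixed at the expected value.

    Tandem arrays tile one short unit many times, so iid unit sampling would
    let a single unit's composition noise dominate whole-region composition;
    pinning the unit's A+T count (random arrangement, skew-conditional base
    choice) keeps assembled regions on the composition target.
    """
    n_at = int(round(period * (probs[0] + probs[3])))
    at_positions = rng.choice(period, size=n_at, replace=False)
    is_at = np.zeros(period, dtype=bool)
    is_at[at_positions] = True
    p_a = probs[0] / (probs[0] + probs[3])
    p_g = probs[2] / (probs[1] + probs[2])
    out = []
    for flag in is_at:
        if flag:
            out.append("A" if rng.random() < p_a else "T")
        else:
            out.append("G" if rng.random() < p_g else "C")
    return "".join(out)


def _codon_weights(probs: np.ndarray) -> tuple[list, np.ndarray]:
    """Sense codons weighted by the product of base probabilities.

    The AT fraction is nudged up before weighting to offset the exclusion of
    the (A/T-rich) stop codons from the sense-codon pool, so coding regions
    land on the same composition target as the rest of the genome.
    """
    at = probs[0] + probs[3]
    boosted = _base_probs(min(0.95, at + 0.015),
                          (probs[0] - probs[3]) / max(at, 1e-9),
                          (probs[2] - probs[1]) / max(1 - at, 1e-9))
    index = {b: i for i, b in enumerate("ACGT")}
    sense = [c for c in ALL_CODONS if c not in VERTEBRATE_MITO.stops]
    w = np.array([np.prod([boosted[index[b]] for b in c]) for c in sense])
    return sense, w / w.sum()


def _sample_codons(n: int, sense: list, weights: np.ndarray,
                   rng: np.random.Generator) -> list[str]:
    idx = rng.choice(len(sense), size=n, p=weights)
    return [sense[i] for i in idx]


# ---------------------------------------------------------------------------
# protein-coding genes with planted overlap constraints
# ---------------------------------------------------------------------------

# Forced codon plants making the shared-overlap reading frames consistent:
# the upstream gene's tail and the downstream gene's head spell the same
# genome bases.  Derived for the -7 same-strand pattern (frame offset 2) and
# the -15 opposite-strand pattern (both stops inside the overlap).
_TAIL_MINUS7 = ["GCA", "TGC", "TAA"]
_HEAD_MINUS7 = ["ATG", "CTA", "ACA"]
_ND5_TAIL = ["TCT", "GCA", "GCA", "GCA", "TAA"]
_ND6_TAIL = ["TTA", "TGC", "TGC", "TGC", "AGA"]

_OVERLAP_PAIRS = (("ATP8", "ATP6"), ("ND4L", "ND4"))


def _overlap_plants(layout: Sequence[Feature]) -> dict:
    """name -> ("head"|"tail", forced codons) for the planted overlap pairs."""
    by_name = {f.name: f for f in layout}
    plants: dict[str, tuple[str, list[str]]] = {}
    for up, down in _OVERLAP_PAIRS:
        if up in by_name and down in by_name:
            u, d = by_name[up], by_name[down]
            if (u.stop - d.start + 1 == 7 and (d.start - u.start) % 3 == 2
                    and u.stop_codon == "TAA" and d.start_codon == "ATG"):
                plants[up] = ("tail", _TAIL_MINUS7)
                plants[down] = ("head", _HEAD_MINUS7)
    if "ND5" in by_name and "ND6" in by_name:
        u, d = by_name["ND5"], by_name["ND6"]
        if (u.stop - d.start + 1 == 15 and (d.start - u.start) % 3 == 0
                and u.stop_codon == "TAA" and d.stop_codon == "AGA"
                and d.strand == "L"):
            plants["ND5"] = ("tail", _ND5_TAIL)
            plants["ND6"] = ("tail", _ND6_TAIL)
    return plants


def _gen_pcg(feature: Feature, length: int, sense: list, weights: np.ndarray,
             rng: np.random.Generator,
             plant: Optional[tuple] = None) -> str:
    """Coding-strand sequence: start codon, sampled body, planted stop."""
    stop = feature.stop_codon or "TAA"
    if stop == "T-":
        tail, body_len = "T", length - 3 - 1
    elif stop == "TA-":
        tail, body_len = "TA", length - 3 - 2
    else:
        tail, body_len = stop, length - 3 - 3
    if body_len % 3 != 0 or body_len < 0:
        raise ValueError(f"{feature.name}: length {length} incompatible with "
                         f"stop token {stop!r}")
    codons = [feature.start_codon or "ATG"]
    codons += _sample_codons(body_len // 3, sense, weights, rng)
    if tail in VERTEBRATE_MITO.stops:
        codons.append(tail)
        tail = ""
    if plant is not None:
        kind, forced = plant
        if kind == "head":
            codons[:len(forced)] = forced
        else:  # tail plant always includes the stop codon
            codons[-len(forced):] = forced
    seq = "".join(codons) + tail
    assert len(seq) == length, (feature.name, len(seq), length)
    return seq


# ---------------------------------------------------------------------------
# control region assembly
# ---------------------------------------------------------------------------

def _assemble_cr(plan: list, cr_length: int, probs: np.ndarray,
                 rng: np.random.Generator) -> tuple[str, dict]:
    parts: list[str] = []
    truth = {"repeats": [], "motifs": []}
    pos = 0  # 0-based local cursor
    for el in plan:
        if isinstance(el, PlannedSpacer):
            parts.append(_random_bases(el.length, probs, rng))
            pos += el.length
        elif isinstance(el, PlannedMotif):
            parts.append(el.sequence)
            truth["motifs"].append({"name": el.name, "start": pos + 1,
                                    "stop": pos + len(el.sequence)})
            pos += len(el.sequence)
        elif isinstance(el, PlannedRepeat):
            unit = _balanced_unit(el.period, probs, rng)
            tas_offset = None
            if el.embed_tas:
                if el.period < len(_TAS) + 25:
                    raise ValueError("period too short to embed a TAS copy")
                tas_offset = 20
                unit = unit[:tas_offset] + _TAS + unit[tas_offset + len(_TAS):]
            span = el.span
            tiled = (unit * (span // el.period + 1))[:span]
            mutated = _mutate_string(tiled, el.mutation_rate, rng)
            parts.append(mutated)
            rec = {"period": el.period, "copies": round(span / el.period, 1),
                   "start": pos + 1, "stop": pos + span,
                   "mutation_rate": el.mutation_rate, "unit": unit}
            truth["repeats"].append(rec)
            if tas_offset is not None:
                for k in range(span // el.period + 1):
                    s = k * el.period + tas_offset
                    if s + len(_TAS) <= span:
                        truth["motifs"].append({
                            "name": "TAS", "start": pos + s + 1,
                            "stop": pos + s + len(_TAS), "in_repeat": True})
            pos += span
        else:
            raise TypeError(f"unknown CR plan element {el!r}")
    if pos > cr_length:
        raise ValueError(f"CR plan needs {pos} bp but the control region "
                         f"is {cr_length} bp")
    parts.append(_random_bases(cr_length - pos, probs, rng))
    cr = _break_repeat_edges("".join(parts), truth["repeats"], probs, rng)
    truth["motifs"].sort(key=lambda m: m["start"])
    return cr, truth


def _break_repeat_edges(cr: str, repeats: list, probs: np.ndarray,
                        rng: np.random.Generator) -> str:
    """Make planted copy numbers exact: flanking spacer bases that happen to
    continue an array's periodicity would silently lengthen the true repeat,
    so the three spacer bases on each side are redrawn to break the period."""
    seq = list(cr)
    for rec in repeats:
        p = rec["period"]
        start0, stop0 = rec["start"] - 1, rec["stop"] - 1  # 0-based inclusive
        edges = ([(start0 - d, start0 - d + p) for d in (1, 2, 3)]
                 + [(stop0 + d, stop0 + d - p) for d in (1, 2, 3)])
        for i, partner in edges:
            if not (0 <= i < len(seq) and 0 <= partner < len(seq)):
                continue
            while seq[i] == seq[partner]:
                seq[i] = _random_bases(1, probs, rng)
    return "".join(seq)


def _mutate_string(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.array(list(seq))
    hit = rng.random(arr.size) < rate
    idx = np.flatnonzero(hit)
    for i in idx:
        others = [b for b in "ACGT" if b != arr[i]]
        arr[i] = others[rng.integers(3)]
    return "".join(arr)


# ---------------------------------------------------------------------------
# whole-genome generation
# ---------------------------------------------------------------------------

def generate_mitogenome(spec: SyntheticSpec) -> tuple[MitoGenome, dict]:
    """Generate one annotated genome plus its truth record."""
    rng = np.random.default_rng(spec.seed)
    layout = list(spec.layout) if spec.layout is not None else default_layout()
    layout.sort(key=lambda f: f.start)
    length = max(f.stop for f in layout)
    if spec.genome_length_target is not None:
        cr = layout[-1]
        if cr.category != "control_region":
            raise ValueError("length target requires a terminal control region")
        new_stop = spec.genome_length_target
        plan_len = sum(_plan_span(el) for el in (spec.cr_plan or default_cr_plan()))
        if new_stop - cr.start + 1 < plan_len:
            raise ValueError(
                f"layout cannot fit target {spec.genome_length_target}: the CR "
                f"plan needs {plan_len} bp")
        layout[-1] = Feature(cr.name, cr.category, cr.strand, cr.start, new_stop)
        length = new_stop

    # The control region targets its own (higher) AT fraction, so the rest of
    # the genome compensates to keep the genome-wide target honest:
    # at_rest * (1 - w_cr) + cr_at * w_cr = at_fraction.
    cr_len = sum(f.stop - f.start + 1 for f in layout
                 if f.category == "control_region")
    w_cr = cr_len / length
    at_rest = (spec.at_fraction - spec.cr_at_fraction * w_cr) / (1 - w_cr)
    if not 0 < at_rest < 1:
        raise ValueError(
            f"AT targets unachievable: genome {spec.at_fraction} with CR "
            f"{spec.cr_at_fraction} over {w_cr:.0%} of the genome")
    probs = _base_probs(at_rest, spec.at_skew, spec.gc_skew)
    cr_probs = _base_probs(spec.cr_at_fraction, spec.at_skew, spec.gc_skew)
    sense, weights = _codon_weights(probs)
    plants = _overlap_plants(layout)

    genome_arr: list[Optional[str]] = [None] * length
    cr_truth: dict = {}
    for f in layout:
        flen = f.stop - f.start + 1
        if f.category == "PCG":
            seq = _gen_pcg(f, flen, sense, weights, rng, plants.get(f.name))
        elif f.category == "control_region":
            seq, cr_truth = _assemble_cr(spec.cr_plan or default_cr_plan(),
                                         flen, cr_probs, rng)
        else:
            seq = _random_bases(flen, probs, rng)
        if f.strand == "L":
            seq = reverse_complement(seq)
        for k, base in enumerate(seq):
            pos = f.start - 1 + k
            if genome_arr[pos] is None:
                genome_arr[pos] = base  # overlaps keep the first writer's base
    for i in range(length):
        if genome_arr[i] is None:
            genome_arr[i] = _random_bases(1, probs, rng)

    sequence = "".join(genome_arr)
    genome = MitoGenome(identifier=f"synthetic-{spec.seed}", length=length,
                        circular=True, sequence=sequence, features=layout)
    truth = {
        "seed": spec.seed,
        "length": length,
        "at_fraction_target": spec.at_fraction,
        "cr_at_fraction_target": spec.cr_at_fraction,
        "at_skew_target": spec.at_skew,
        "gc_skew_target": spec.gc_skew,
        "codon_bias": "third-position A/T overuse",
        "features": [
            {"name": f.name, "strand": f.strand, "start": f.start,
             "stop": f.stop, "start_codon": f.start_codon,
             "stop_codon": f.stop_codon}
            for f in genome.features
        ],
        "control_region": cr_truth,
    }
    return genome, truth


def _plan_span(el) -> int:
    if isinstance(el, PlannedSpacer):
        return el.length
    if isinstance(el, PlannedMotif):
        return len(el.sequence)
    return el.span


# ---------------------------------------------------------------------------
# diverged copies
# ---------------------------------------------------------------------------

def mutate_population(genome: MitoGenome,
                      divergence_plan: Sequence[tuple],
                      seed: int = 0) -> list[MitoGenome]:
    """Independent per-site substitutions (uniform over the other 3 bases).

    ``divergence_plan`` is a list of (label, per-site substitution probability
    in [0, 0.75)); annotations are carried over unchanged.  Start and stop
    codons of protein-coding genes (including incomplete-stop tails) are kept
    intact so every derived genome stays codon-parseable — substitutions
    there would be annotation changes, not the neutral divergence modelled.
    """
    rng = np.random.default_rng(seed)
    protected = _landmark_mask(genome)
    out = []
    for label, p in divergence_plan:
        if not 0 <= p < 0.75:
            raise ValueError(f"{label}: substitution probability {p} out of range")
        mutated = list(_mutate_string(genome.sequence, p, rng))
        for i in np.flatnonzero(protected):
            mutated[i] = genome.sequence[i]
        out.append(MitoGenome(identifier=label, length=genome.length,
                              circular=genome.circular, sequence="".join(mutated),
                              features=copy.deepcopy(genome.features)))
    return out


def _landmark_mask(genome: MitoGenome) -> np.ndarray:
    """True at genome positions holding a PCG start codon or stop token."""
    mask = np.zeros(genome.length, dtype=bool)
    for f in genome.features:
        if f.category != "PCG":
            continue
        stop_len = {"T-": 1, "TA-": 2}.get(f.stop_codon or "TAA", 3)
        if f.strand == "H":
            head = range(f.start - 1, f.start + 2)
            tail = range(f.stop - stop_len, f.stop)
        else:  # L-strand gene: coding start at genomic stop
            head = range(f.stop - 3, f.stop)
            tail = range(f.start - 1, f.start - 1 + stop_len)
        for i in (*head, *tail):
            mask[i % genome.length] = True
    return mask


def generate_trio(spec: SyntheticSpec, p_close: float = 0.02,
                  p_shared: float = 0.05, p_far: float = 0.10,
                  p_outgroup: float = 0.30) -> tuple[dict, dict]:
    """Four diverged copies with true topology ((A,B),C,O).

    A and B split from a shared ancestor (itself ``p_shared`` from the root);
    C diverges ``p_far`` straight from the root; O is a distant outgroup.
    Mirrors the empirical situation of two closely-related ingroup genomes
    plus a basal congener.
    """
    root, truth = generate_mitogenome(spec)
    rng_seed = spec.seed + 1
    (shared,) = mutate_population(root, [("shared", p_shared)], seed=rng_seed)
    a, b = mutate_population(shared, [("A", p_close), ("B", p_close)],
                             seed=rng_seed + 1)
    c, o = mutate_population(root, [("C", p_far), ("O", p_outgroup)],
                             seed=rng_seed + 2)
    taxa = {"A": a, "B": b, "C": c, "O": o}
    truth = dict(truth)
    truth["trio"] = {"topology": "((A,B),C,O)", "cherry": ["A", "B"],
                     "p_close": p_close, "p_shared": p_shared,
                     "p_far": p_far, "p_outgroup": p_outgroup}
    return taxa, truth


# ---------------------------------------------------------------------------
# fixture battery
# ---------------------------------------------------------------------------

def write_fixture_set(out_dir, seed: int = 0) -> dict:
    """Write the standard three-fixture battery (FASTA + table TSV + GenBank +
    truth JSON each): default genome, repeat-rich CR genome, diverged trio."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = {}

    def emit(tag: str, genome: MitoGenome, truth: dict) -> None:
        base = out_dir / tag
        write_fasta([SequenceRecord(genome.identifier, genome.sequence,
                                    circular=True)], f"{base}.fasta")
        write_feature_tsv(genome, f"{base}.features.tsv")
        write_genbank(genome, f"{base}.gb")
        with open(f"{base}.truth.json", "w", encoding="utf-8") as fh:
            json.dump(truth, fh, indent=2, sort_keys=True)
        written[tag] = genome

    g, t = generate_mitogenome(SyntheticSpec(seed=seed))
    emit("default", g, t)

    rich_plan = default_cr_plan() + [
        PlannedSpacer(30), PlannedRepeat(period=8, copies=16.3, mutation_rate=0.02),
        PlannedSpacer(40), PlannedRepeat(period=8, copies=12.8, mutation_rate=0.02),
    ]
    g2, t2 = generate_mitogenome(SyntheticSpec(seed=seed + 1, cr_plan=rich_plan))
    emit("repeat_rich", g2, t2)

    taxa, t3 = generate_trio(SyntheticSpec(seed=seed + 2))
    for label, genome in taxa.items():
        emit(f"trio_{label}", genome, {**t3, "taxon": label})
    return written
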