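# Methods

Model notes, parameter defaults with rationale, and known limitations.

## Coordinate model

Mitogenomes are circles with 1-based inclusive feature coordinates on the
heavy (H) strand; light-strand (L) features keep H-strand coordinates and are
reverse-complemented on extraction. A feature with `stop < start` wraps the
origin; its length is `length - start + 1 + stop`. The genome length is the
maximum stop over all features (tables carry no explicit length field).

**Intergenic spacers.** For consecutive features the spacer is
`next.start - prev.stop - 1` (positive gap, negative overlap, zero abutment).
Gap/overlap totals sum the positive and the negated negative spacers over
consecutive pairs **excluding** the wrap-around pair (last feature back to the
first): published per-row intergenic columns leave that junction implicit, and
including it would make totals incomparable with them. When an input table
carries a printed intergenic column, its sum is compared against the
coordinate-derived totals and the agreement or discrepancy is **logged**
(`INFO` on match, `WARNING` on mismatch); the computed values are always the
ones reported. For the three bundled tables the printed columns sum exactly to
the computed totals — 134/42, 63/39 and 71/49 bp of gap/overlap respectively.

**Validation and repair.** `validate_annotation` repairs the one documented
class of table defect — a tRNA row with inverted start/stop whose swap yields a
canonical tRNA length (65–75 bp) — and records it
(`stop_before_start_repaired`; the 18,373-bp table's tRNA-His, 69 bp after
repair). Rows whose printed size disagrees with the coordinate span are
recorded as `size_mismatch` without modification. Inverted non-tRNA rows are
irreparable and raise.

## Composition and skew

AT skew = (A−T)/(A+T), GC skew = (G−C)/(G+C); a zero denominator yields NaN,
never an exception. `N` bases are excluded from fractions. Profiles default to
the `coding_strand` convention (L-strand genes reverse-complemented before
measuring, so e.g. ND6 is directly comparable with H-strand genes);
`genome_strand` reports everything as written on the H strand. Skews negate
exactly under reverse complement — a property test, since it is the invariant
the two conventions rely on.

## Codon analysis

The vertebrate mitochondrial code (NCBI table 2: AGA/AGG/TAA/TAG stops,
TGA=Trp, ATA=Met) is taken from Biopython. Genes whose length mod 3 is 1 or 2
must end in T or TA respectively (incomplete stops completed to TAA by
polyadenylation); extraction pads them and records the padding, and stop
classification reports `T-`/`TA-` rather than the padded literal TAA. Usage
tables count stop codons — published 64-row codon tables print them,
asterisked — with `count_padded=True` by default so totals match such tables;
RSCU and amino-acid frequencies always exclude stops. RSCU is
`count * family_size / family_total`, NaN for unobserved families; family sums
equal the family size by construction (property-tested). `max_codon` breaks
count ties alphabetically for determinism.

## Control-region architecture

### Tandem-repeat detection

For each candidate period `p` (default 5–200), the self-match vector
`m[i] = (s[i] == s[i+p])` is scored in sliding windows of one period
(cumulative-sum), and windows at or above `min_identity` (default 0.85) seed
candidate regions. Seeds separated by more than `2p` failing windows split
into separate candidates — a tight cluster of mutations knocks out a run of
~`p` windows without ending an array, so a `1p` split threshold fragments real
arrays. Candidate edges are then sharpened in three stages:

1. **Mini-window trim**: shrink while an edge window of `min(8, p)` self-match
   positions is below 0.75 identity, then drop outright edge mismatches and
   extend through contiguous exact matches (windowed seeding overshoots into
   flanking sequence by up to `(1 - min_identity) * p`).
2. **Phase-aligned consensus**: the repeat unit is the column-majority
   consensus over full copies; when the candidate spans ≥ 3 periods the
   consensus is computed from the interior (`[p, span-p)`, phase-preserved) so
   residual flank contamination cannot bias the majority vote.
3. **Consensus-guided edge walk**: from an interior anchor on a copy boundary,
   walk outward scoring +2 per consensus agreement and −3 per mismatch,
   stopping 12 below the running maximum; the edge is the outermost position
   attaining the maximum (ties accepted outward). This X-drop-style rule
   tolerates a double mutation near an edge (−6, recoverable) while refusing
   to wander into flanking sequence (expected score slope is negative in
   random sequence), which window-granular edges cannot do at single-decimal
   copy-number precision for short periods.

Copy number is `span / period` rounded to one decimal; `mean_identity` is the
fraction of bases agreeing with the tiled consensus (per-copy identity — raw
self-match identity double-counts each mutation, once against each neighbor
copy). Candidates below `min_copies` (default 2.5) or `min_identity` are
dropped. A candidate at period `p` is suppressed as a harmonic when a proper
divisor `q ≥ min_period` of `p` already explains the region at the identity
threshold; divisors below `min_period` do not suppress (a near-period-4 region
with `min_period=5` is still reportable at period 8). Overlapping calls across
periods resolve greedily by longer span, then smaller period, then leftmost.

The test suite verifies the detector against a brute-force oracle
(`tests/oracle_repeats.py`, an independent all-periods reimplementation) and
against planted arrays with known period/copy number at 2% per-unit mutation.
Two honesty notes: (a) roughly a quarter of uniformly random 2-kb sequences
genuinely contain a short qualifying repeat at the default thresholds, so
"random sequence → no call" holds only for seeds where the oracle confirms
absence; (b) residual planted-recovery failures at higher mutation rates are
truth ambiguities (e.g. two substitutions inside a 4-base partial copy make
the shorter array the correct maximal call), not detector defects.

### Motif scanning

Motifs are IUPAC consensus strings with a per-motif mismatch budget, scanned
at every offset (vectorized per consensus symbol); overlapping placements of
one motif collapse to the best per locus (fewest mismatches, then leftmost).
The bundled default set carries the 17-bp anuran TAS consensus and its GACAT
core; the CSB-1/2/3 and O~H~ entries are synthetic placeholder consensus
strings sized to the published feature lengths (28/19/18/72 bp) — the real
conserved-sequence-block alignments are not distributed in machine-readable
form — and are shared with the generator, so they are exact on synthetic data
and replaceable (`--motifs`) for real data.

## Phylogenetic preparation

Per-gene matrices are stop-stripped (padded genes lose padding plus the
incomplete-stop bases — net three — keeping codon alignment) and concatenated
in canonical mitogenome PCG order into a partitioned supermatrix. This assumes
equal per-gene lengths across taxa (true for the synthetic populations, which
model substitutions only); length-variable real data needs an external aligner
first, and the pipeline then reports no supermatrix rather than misaligning.

Site classification treats gaps and N as missing; a column is conserved when
≤1 distinct non-missing state remains (entirely-missing columns count as
conserved and are tallied and logged); a variable column is
parsimony-informative when ≥2 states occur in ≥2 sequences each. Conserved +
variable = total is asserted structurally.

Distances are p-distances over pairwise shared non-missing columns. The NJ
implementation is hand-written (Saitou–Nei with the Studier–Keppler Q
criterion, trifurcating root, 6-decimal Newick) so output is byte-identical
across runs; Q-matrix ties break by the lexicographically smallest taxon-name
pair. scikit-bio's NJ serves as an independent topology oracle in tests on
matrices with distinct Q minima (where tie-breaking cannot differ).

## Synthetic data generator

`generate_mitogenome(SyntheticSpec)` produces an annotated 18,373-bp circle on
the bundled 40-feature layout plus a complete truth record. Defaults emulate
the measured profile of a high-altitude dicroglossid mitogenome: 59% A+T,
heavy-strand AT skew −0.066 and GC skew −0.259, a 66% A+T control region with
a TAS-bearing 6.5 × 124 bp 5′ array, the O~H~/CSB block, and short-period 3′
arrays (2 × period-11, 1 × period-10).

Design points that matter for test validity:

- **AT compensation.** The control region is AT-richer than the rest; drawing
  the whole genome at the target AT fraction would overshoot it. The non-CR
  base distribution is solved from
  `at_rest = (at_target - cr_at * w_cr) / (1 - w_cr)` where `w_cr` is the CR
  length share, so the realized genome-wide AT fraction meets the target
  (within ±0.01 across seeds).
- **Balanced repeat units.** Random repeat units have their A+T count fixed at
  the expected value so a single 124-bp draw cannot skew the CR composition.
- **Flank breaking (fixture well-posedness).** Spacer bases adjacent to a
  planted array can coincidentally continue its periodicity, silently making
  the true copy number larger than the planted one. The generator redraws the
  three flanking bases on each side of every planted array until they break
  the period, so planted copy numbers are true copy numbers. This makes the
  ground truth correct; it does not tune the detector.
- **Landmark protection under divergence.** `mutate_population` never
  substitutes PCG start-codon or stop-token bases: mutating a planted stop
  makes a derived genome unparseable as codons (an annotation change, not
  neutral divergence) and silently drops genes from the supermatrix. The
  realized substitution rate is therefore marginally below the nominal
  per-site probability (~0.5% of sites are protected).
- **Codon-level sampling.** PCG bodies are drawn codon-by-codon from sense
  codons weighted by base probabilities (with third positions inheriting the
  AT enrichment), so no in-frame stop ever interrupts a gene and planted
  start/stop codons are recoverable exactly.

`generate_trio` derives four copies with true topology ((A,B),C,O) at
divergences 0.02 (within the cherry, via a shared 0.05 ancestor), 0.10 and
0.30. Everything is a pure function of the spec seed; the fixture battery is
byte-deterministic.

## Parameter defaults

| Parameter | Default | Rationale |
| --- | --- | --- |
| `min_period` / `max_period` | 5 / 200 | Below 5 bp, homopolymer/dinucleotide slippage dominates; 200 comfortably covers the 124-bp published unit |
| `min_copies` | 2.5 | Two full copies plus a partial — fewer is a duplication, not an array |
| `min_identity` | 0.85 | Tolerates the 2–3% per-unit divergence seen in real CR arrays with margin; random-sequence false calls remain rare and oracle-confirmed |
| `count_padded` | `True` | Published codon tables include completed stops in their totals |
| strand convention | `coding_strand` | Makes ND6 comparable with H-strand genes, the usual presentation |
| trio divergences | 0.02 / 0.05 / 0.10 / 0.30 | Two close ingroup genomes plus a basal congener and an outgroup, mirroring the empirical setting |

## Limitations

- No insertion/deletion model anywhere: the generator mutates by substitution
  only, and the supermatrix path assumes equal gene lengths (no aligner).
- The repeat detector reports one maximal array per locus; it does not model
  nested or higher-order repeat structure beyond harmonic suppression.
- CSB/O~H~ default motifs are placeholders (see above); real-data motif calls
  require a curated motif file.
- GenBank parsing covers the feature types and naming conventions of
  mitogenome records (CDS/tRNA/rRNA/D-loop/rep_origin); exotic annotations
  raise rather than being guessed at.
- Validation repairs only the inverted-tRNA defect class; other coordinate
  errors surface as explicit `size_mismatch` records or hard failures.
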