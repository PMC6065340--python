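# mitoprofiler

Comparative profiling of vertebrate mitochondrial genomes, built around the
three published *Nanorana* (high-altitude dicroglossid frog) mitogenomes:
*N. parkeri* (17,837 bp), *N. ventripunctata* (18,373 bp) and *N. pleskei*
(17,660 bp).

A complete mitogenome paper rests on a handful of quantitative claims: the
coordinate arithmetic of 37–40 annotated features on a circle (gene lengths,
intergenic gaps, overlaps such as the 7-bp ATP8/ATP6 junction), strand-asymmetric
base composition (AT/GC skew), codon usage and RSCU under the vertebrate
mitochondrial code with its incomplete T–/TA– stop codons, the tandem-repeat and
conserved-motif architecture of the control region (TAS, CSB-1/2/3, O~H~), and a
concatenated 13-gene supermatrix for phylogenetics. `mitoprofiler` implements
each of these as a small, testable primitive, bundles the three published
feature/codon tables as machine-readable data, and ships a seeded synthetic
mitogenome generator so every analysis can be validated against planted ground
truth without any network access.

## Quick start

Generate a synthetic fixture battery (deterministic in the seed) and profile it:

```console
$ mitoprofiler simulate --seed 0 --out demo
wrote 6 fixture genomes to demo

$ mitoprofiler profile demo/default.gb | head -5
Region  CodonPos        AT_skew GC_skew AT_fraction
12S-rRNA                -0.083  -0.224  0.5656
16S-rRNA                -0.029  -0.324  0.5637
ND1             -0.054  -0.318  0.5564
ND2             -0.073  -0.376  0.5934
```

Control-region architecture — a TAS-bearing 6.5 × 124 bp 5′ array, the
replication-origin/CSB block, and short-period 3′ arrays:

```console
$ mitoprofiler cr demo/default.gb | head -6
Feature Start   Stop    Length
6.5 tandem repeat units 21      826     6 x 124 + 62
TAS     41      57      17
GACAT   46      50      5
TAS     165     181     17
GACAT   170     174     5
```

Full workflow over a diverged four-taxon set (per-genome reports, gene-order
comparison, stop-stripped 13-gene supermatrix, site statistics, NJ tree):

```console
$ mitoprofiler run-all demo/trio_A.gb demo/trio_B.gb demo/trio_C.gb demo/trio_O.gb --out trio_out
processed 4 genome(s) -> trio_out
$ cat trio_out/tree.nwk
(C:0.084705,O:0.268799,(A:0.019462,B:0.019904):0.053565);
```

The planted topology ((A,B),C,O) is recovered, with branch lengths close to the
simulated divergences (0.02 within the cherry, 0.10 to C, 0.30 to the outgroup).

Published-table accounting needs no sequence — feature tables alone suffice:

```python
>>> from mitoprofiler.genome_io import bundled_path, read_feature_tsv
>>> from mitoprofiler.annotation_model import validate_annotation, gap_overlap_totals
>>> rows = read_feature_tsv(bundled_path("nanorana_ventripunctata_features.tsv"))
>>> genome, report = validate_annotation(rows)
>>> genome.length, gap_overlap_totals(genome)
(18373, (63, 39))
```

## Modules

| Module | Purpose |
| --- | --- |
| `genome_io` | FASTA/GenBank/feature-table/alignment I/O, gene-name normalization |
| `annotation_model` | Circular-coordinate arithmetic, spacers, gap/overlap totals, gene order, validation/repair |
| `composition_stats` | Base composition, AT/GC skew, per-region and per-codon-position profiles |
| `codon_analysis` | Vertebrate-mito codon extraction (incomplete stops), usage, RSCU, amino-acid frequencies |
| `control_region` | Tandem-repeat detection with consensus-refined edges; IUPAC motif scanning |
| `phylo_prep` | Stop-stripped supermatrix, site classification, p-distance, deterministic NJ |
| `synthetic_data` | Seeded mitogenome generator with full truth records, divergence, fixture battery |
| `pipeline` / `cli` | End-to-end orchestration and the `mitoprofiler` command |

## Reproducing results

```bash
pytest -q                                         # full suite, < 1 minute
python scripts/acceptance.py --seed 1 --out acceptance.json
```

`tests/test_acceptance.py` holds one test per guaranteed behaviour:
published-table coordinate and codon accounting, and the property-based
guarantees (skew antisymmetry under reverse complement, RSCU family
normalization, repeat-detector equivalence with a brute-force oracle plus
planted-array recovery, site-count conservation, NJ recovery of the planted
trio, end-to-end byte determinism). One sequence-level test reproduces values
from the deposited records NC_026789 / KY594708 and is skipped unless those
GenBank files are present under `tests/data/accessions/`; fetch them with
`python scripts/fetch_accessions.py` (network required — nothing else depends
on it).

`scripts/acceptance.py` emits the main computed quantities as JSON
(`{"name": {"value": N, "n": size}}`); table-derived values are
seed-independent, synthetic ones derive all randomness from `--seed`.

Method details, parameter defaults and known limitations are documented in
[docs/methods.md](docs/methods.md).
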