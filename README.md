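# ltrarch

Analysis pipeline for LTR retrotransposons that carry an **additional
archaeal-type ribonuclease H (ARH) domain**, exercised end-to-end on
synthetic genomes with planted ground truth.

The pipeline covers six stages:

1. **`ltrarch.synth`** — generates genomes with planted elements: paired long
   terminal repeats of configurable length/divergence, gag/pol ORFs encoding
   domain chains (GAG, PR, RT, RH, ARH, INT), the five ARH placements plus
   ARH-less elements, and intact or degraded D,E,D,D catalytic cores.
   Ground truth (spans, strands, structures, core states) is emitted as
   GFF3/TSV.
2. **`ltrarch.mining`** — recovers elements from raw sequence: PSSM
   construction from amino-acid alignments, six-frame gapless scanning,
   single-linkage hit chaining, seed-and-extend LTR detection with percent
   identity, completeness scoring, and RT-identity preclustering with
   representative selection.
3. **`ltrarch.structure`** — ORF assignment and classification of each chain
   into structural variants S1–S5 (by ARH position relative to RH/RT and ORF
   membership), NO_ARH, or UNKNOWN, plus per-genome frequency tables.
4. **`ltrarch.degradation`** — profile alignment of RH-type domains, readout
   of the four catalytic-core residues, and intact-versus-degraded
   ("tether-like") calls with a severity score.
5. **`ltrarch.phylo`** — progressive alignment, p-distance neighbor-joining
   trees with Felsenstein bootstrap supports, credible-cluster extraction at
   a support threshold (default 95), monophyly testing, the two-of-three
   lineage-removal filter, and generalized Fitch parsimony for the minimal
   structure-rearrangement scenario on a species tree.
6. **`ltrarch.cli` / `ltrarch.pipeline`** — subcommand CLI orchestrating
   simulate → annotate → report with YAML config, seeded determinism and a
   run log of every threshold used.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds one test per acceptance criterion
(structure recovery on a 1 Mb genome, classifier exactness, DEDD severity
identity, NJ/Fitch oracle equivalence, bootstrap monophyly, filter truth
table, LTR identity calibration, strand symmetry).

## CLI

```sh
# generate a synthetic cohort (genomes + truth + profile library)
ltrarch simulate --config config.yaml --out-dir out/

# mine + classify an existing FASTA against a profile directory
ltrarch annotate --config config.yaml --genome out/genomes.fasta \
    --profiles out/profiles --out-dir out/

# full report: frequencies, degradation summary, RT tree with supports,
# lineage filter decisions, parsimony scenario
ltrarch run-all --config config.yaml --out-dir out/ \
    --species-tree species.nwk
```

Minimal config:

```yaml
seed: 1
genomes:
  - genome_id: g1
    length: 200000
    taxon: taxA
    elements:
      - {structure: S1, count: 2, ltr_divergence: 0.02,
         domain_divergence: 0.02, degrade_native_rh: true}
      - {structure: NO_ARH, count: 1}
```

All thresholds (scan bits fraction, chain gap, LTR length/identity, ORF
length, linker tolerance, degradation threshold, bootstrap replicates,
support threshold, …) are config keys with documented defaults; see
`ltrarch/config.py`.

## Conventions

- Coordinates are 0-based half-open on the forward strand everywhere in
  memory; GFF3 output is 1-based inclusive.
- All randomness flows through named integer seeds; identical seeds give
  byte-identical outputs.
- Trees are serialized as newick with bootstrap supports as internal node
  labels.
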