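# evescan

Desk-scale toolkit for discovering **endogenous viral elements (EVEs)** in
host genomes: chunked translated homology search, candidate-locus
construction, frameshift-aware protein reconstruction with degradation
counting, and a six-category reciprocal-evidence classifier.

The pipeline stages:

1. **chunk** — split each contig into fixed-size chunks (default 50 kb) so
   repetitive regions cannot monopolize the hit budget; a per-chunk cap
   (default 1000) limits reported hits.
2. **forward search** — translated search of the chunks against a viral
   protein query set. Engines: an external DIAMOND binary (`external`), a
   pre-computed outfmt-6-style table (`precomputed`), or the **builtin**
   six-frame Smith–Waterman aligner (numba-accelerated, test/desk scale,
   O(m·n) per frame). E-value threshold 1e-5, top 10 hits per query.
3. **remap + merge** — chunk-local coordinates are remapped to contig
   coordinates and hit intervals are merged into candidate loci whenever the
   gap is ≤ 1000 bp (strand-agnostic).
4. **extract + ORFs** — locus sequences (with optional flank) and
   getorf-style ORFs (stop-to-stop by default, ≥ 50 aa).
5. **reciprocal search** — candidate peptides vs a viral database
   (RVDB-style) and a broad database (nr-style); precomputed tables or the
   builtin protein-protein aligner.
6. **reconstruct** — frameshift-aware local alignment of each locus against
   its best-hit protein (a simplified GeneWise: codon, 1/2/4/5-nt
   frameshift-codon, insertion and deletion states) and counting of stop
   codons, insertions, deletions and frameshifts. Introns are not modeled.
7. **classify** — aggregate the reciprocal evidence per locus and apply six
   rules in strict order: `likely-retro`, `likely-host-protein`,
   `bamford-related`, `likely-transposon`, `likely-eve`, `uncertain`.
   Short keywords (gag/pol/env/pro/rt-in) are matched with word boundaries
   by default (`--substring-keywords` restores literal substring matching).

A first-class **simulator** generates every input offline: toy viral
proteins, background genomes with planted degraded inserts (stops,
frameshifts, codon indels, substitutions) plus ground truth, mock
reciprocal hit tables engineered to force each classification rule, and a
mock NCBI taxdump.

## Test

```bash
python -m pytest -q tests/
```

The suite includes dual-implementation oracles (exhaustive path enumeration
for the frameshift aligner, brute-force interval merging, an independently
coded transcription of the classification rules) and property tests
(hypothesis).

## Command line

```bash
# generate a complete synthetic input set with ground truth
evescan simulate --out fixtures --seed 3 --n-proteins 6 --scenario mixed

# run the whole pipeline from a YAML config
evescan run -c parameters.yaml [--stop-after merge] [--resume]

# individual stages
evescan chunk --genome genome.fna --size 50000 --out chunks.fna
evescan search --query viral.faa --genome chunks.fna --engine builtin --out hits.tsv
evescan merge --hits hits.tsv --genome genome.fna --distance 1000 --bed loci.bed --fasta loci.fna
evescan orfs --fasta loci.fna --min-aa 50 --out peptides.faa
evescan reconstruct --protein ref.faa --locus locus.fna --out report.tsv
evescan classify --loci-bed loci.bed --rvdb-hits r.tsv --nr-hits n.tsv --taxdump taxdump/ --out classification.tsv
```

Minimal `parameters.yaml`:

```yaml
query_fasta: fixtures/proteins.faa
genome_list: [fixtures/genome.fna]
taxdump: fixtures/taxdump
rvdb_hits: fixtures/rvdb_hits.tsv   # reciprocal_mode: precomputed (default)
nr_hits: fixtures/nr_hits.tsv
output_dir: out
```

Outputs under `output_dir`: `loci.bed`, `candidate_cdna.fna`,
`candidate_peptides.faa`, `reconstruction.tsv`, `reconstructed_peptides.faa`,
`classification.tsv`, `summary.tsv`, `manifest.json`, plus per-stage hit
tables. Runs are deterministic: identical config + inputs give
byte-identical outputs with the builtin/precomputed engines.

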