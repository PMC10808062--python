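# constraintdepth

A desk-scale toolkit for phylogenetic constraint-depth analysis: fit a
neutral substitution model from designated neutral alignment columns, score
per-base and element-wise departures from the neutral rate with a
likelihood-ratio test (signed −log10 p scores for conservation and
acceleration), segment alignments into conserved elements with a two-state
phylo-HMM, classify elements into constraint-depth categories (primate ~65 Ma
/ mammal ~100 Ma / vertebrate 160–400 Ma) at a 5% FDR with Storey q-values,
scan for ultraconserved elements, and compute the downstream enrichment
statistics (fine-mapped-variant PIP-tail enrichment, length-binned motif
odds-ratio meta-analysis, mutagenesis-effect correlation, assembly
mismatch-rate regression).

Every pipeline input can be generated synthetically with planted ground
truth (`constraintdepth.synthetic_data`), so all stages are testable
offline.

## Package layout

| module | contents |
| --- | --- |
| `alignment_io` | MAF / aligned-FASTA / BED / TSV readers and writers, reference-anchored `AlignmentColumnSet`, clade column extraction |
| `phylogeny` | rooted `Phylogeny` with branch lengths and named clades (Newick via dendropy) |
| `phylo_core` | REV substitution model, transition matrices, vectorized pruning likelihood, EM-style neutral-model fitting, regional window fits |
| `constraint_scan` | per-base / element-wise LRT scores with a free clade scale factor, scale-factor MLE, two-state phylo-HMM segmentation |
| `depth_classify` | Storey q-values, depth-category classification, DHS core windows, nearest-gene assignment |
| `uce_scan` | perfect-column masks (strict / relaxed), UCE run scanning, overlap statistics |
| `enrichment_stats` | PIP-tail enrichment (Fisher exact), motif OR meta-analysis, effect–score correlation, mismatch regression |
| `synthetic_data` | seeded alignment / PIP-table / footprint-table simulators and the default desk-scale scenario |
| `pipeline` + `cli` | end-to-end orchestration with a frozen config and checksummed manifest |

## CLI

```bash
constraintdepth simulate --scenario planted --seed 1 --out sim/
constraintdepth fit-neutral --alignment sim/alignment.maf --reference primate00 \
    --tree sim/tree.nwk --out sim/model.tsv
constraintdepth phylop --alignment sim/alignment.maf --reference primate00 \
    --tree sim/tree.nwk --neutral-model sim/model.tsv --clade primates \
    --elements sim/elements.bed --out sim/scores.tsv
constraintdepth phastcons --alignment sim/alignment.maf --reference primate00 \
    --tree sim/tree.nwk --neutral-model sim/model.tsv \
    --expected-length 45 --target-coverage 0.3 --rho 0.31 --out sim/cons.bed
constraintdepth classify --input sim/pvalues.tsv --alpha 0.05 --out sim/calls.tsv
constraintdepth uce --alignment sim/alignment.maf --reference primate00 \
    --min-length 20 --missing-tolerance 0.01 --out sim/uces.bed
constraintdepth enrich pip|motif|mpra|mismatch --input ... --out ...
constraintdepth run --seed 1 --out run_out/   # full pipeline + manifest.json
```

Defaults mirror the published settings: HMM expected length 45 bp, target
coverage 0.3, conserved scale 0.31; FDR α = 0.05; Storey λ = 0.5; relaxed
UCE missing tolerance 1%.

## File formats

- Coordinates are 0-based half-open internally; conversions happen at I/O
  boundaries only (BED stays bit-identical through a round trip).
- `-` (gap) and `N` are both treated as missing data for likelihoods but are
  stored distinctly; a species absent from a MAF block is `N`.
- Neutral models serialize to a small key-value text file (`pi_*`, `s_*`,
  `tree_scale`).
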