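# cladesig

A tested, reusable pipeline for discovering **clade-specific signature
proteins** (CSPs) and **conserved signature indels** (CSIs) from homology
search results and protein alignments, mapping family origins onto a rooted
reference tree under Dollo parsimony, and building the reference tree itself
by supermatrix neighbour-joining. A first-class synthetic-data module
generates clade-structured benchmark scenarios with machine-readable ground
truth, so every stage is exercisable at desk scale without downloads.

## What it does

| module | purpose |
|---|---|
| `cladesig.tree` | Newick I/O, rooted/unrooted trees, MRCA, outgroup rooting |
| `cladesig.taxa` | taxonomy maps, named clades, clade set-algebra expressions (`ALL-CladeA`, `CladeB+Elongatus`) |
| `cladesig.hits` | BLAST outfmt-6 (12/13-column) ingestion, taxonomic annotation, E-value-ordered per-query hit tables |
| `cladesig.csp` | the CSP decision procedure: presence at `e_presence`, foreign-hit significance at `e_sig` (default 1e-4), E-value-jump (`gap_factor`) and length-ratio checks, plastid/whitelist exceptions, ORFan exclusion, core/partial completeness tiers |
| `cladesig.msa` / `cladesig.csi` | FASTA alignments; scan for clade-diagnostic indel regions with conserved gap-free flanks, polarized by outgroups |
| `cladesig.dollo` | single-gain / minimal-loss placement of presence patterns; per-node gain summaries |
| `cladesig.phylo` | alignment concatenation, Gblocks-style block filtering (gap mode "half"), Kimura protein distances, neighbour-joining, column bootstrap, outgroup rooting |
| `cladesig.simulate` | seeded scenario generator: species-tree template, universal/planted/ORFan families, planted indels with frozen flanks, phenomenological hit tables, truth JSON with self-audit |
| `cladesig.cli` | `cladesig` command: `simulate \| ingest-hits \| call-csps \| scan-csis \| map-gains \| tree \| all` |

## Quick start

```sh
# generate the default synthetic scenario (46 taxa, 180 families) ...
cladesig simulate --outdir scratch/scenario --seed 1

# ... and run everything on it
cladesig all --indir scratch/scenario --outdir scratch/run --seed 1
```

`all` writes `csp_calls.tsv`, `csi_calls.tsv` (+ dash-notation renders),
`presence_matrix.tsv`, `gain_loss.tsv`, `gains_per_node.tsv`, the filtered
supermatrix, distances, bootstrapped NJ trees (unrooted + outgroup-rooted)
and a `report.json` that includes precision/recall against the planted
truth when `truth.json` is present. Omitting `--indir` simulates a fresh
scenario first. Stage parameters come from a flat `key=value` config file
(`--config`), e.g.:

```
csp.e_sig = 1e-4
csp.gap_factor = 1e3
csi.tau = 0
tree.bootstrap_reps = 1000
```

A scenario directory contains only plain-text inputs: `tree.nwk`,
`taxonomy.tsv` (`seq_id<TAB>taxon<TAB>group_tags`), `clades.tsv`
(`clade<TAB>taxon`), `hits.tsv` (13-column tabular hits), `queries.tsv`,
`targets.txt` (one clade expression per line), per-family FASTA MSAs under
`msas/`, `scan_jobs.tsv`, `genes.txt` and optionally `truth.json`. Real
data can be dropped into the same layout.

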