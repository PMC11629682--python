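# mecphage

Phage–host association analysis for microbial electrolysis cell (MEC)
metagenomes, driven by a ground-truthed synthetic community generator so the
whole chain runs at desk scale.

The pipeline implements:

- **Synthetic community generation** (`mecphage.synth`) — multi-contig host
  genomes with planted prophages and CRISPR arrays, VLP/prokaryotic phage
  contigs, per-contig read counts with electrode-specific enrichment, and a
  full ground-truth manifest. Deterministic for a fixed seed.
- **CRISPR detection** (`mecphage.crispr`) — CRT-style seed-and-extend array
  detection (≥3 repeats, repeat length 23–47, spacer length 26–50, repeat
  identity ≥0.9, spacer identity ≤0.62), spacer extraction, GFF3 export.
- **K-mer homology** (`mecphage.homology`) — Mash-style canonical-k-mer
  sketch ANI, prophage-region calling by windowed containment (≥5 kb),
  prophage↔VLP induction matching, and full-length two-strand
  spacer→protospacer matching with bounded mismatches.
- **Dereplication** (`mecphage.derep`) — phage contig filtering (≥5 kb, ≥1
  viral gene), average-linkage species clustering at 95% ANI, representative
  selection, and retention of species with a >70% complete / <10%
  contaminated member.
- **Abundance & affiliation** (`mecphage.abundance`) — species-level relative
  abundances from read counts and the electrode-affiliation rule (mean >0.1%
  on an electrode, mean and max strictly above the tubing/suspension/inoculum
  comparison group).
- **Association network** (`mecphage.network`) — prophage, induced-prophage
  and CRISPR-match edges at species level, GraphML/TSV export, and
  per-category phage abundance summaries.
- **Community diversity** (`mecphage.diversity`) — pairwise Hill-number
  beta-diversity decomposition and local dissimilarity at q ∈ {0, 1, 2},
  PCoA, Mantel permutation tests, prevalence-vs-completeness curves, and the
  shared-fraction transform.
- **IO & orchestration** (`mecphage.io`, `mecphage.pipeline`, `mecphage.cli`)
  — validated FASTA/TSV dataset loading, YAML configs, and the `run-all`
  driver with a machine-readable summary and run log.

## CLI

```bash
# generate a synthetic dataset (optionally overriding generator defaults)
mecphage generate --seed 1 --out data/

# validate any dataset directory against the schema
mecphage validate data/

# run the full analysis
mecphage run-all data/ --out results/

# individual stages
mecphage cluster data/ --out results/
mecphage crispr data/ --out results/
mecphage match data/ --out results/
mecphage abundance data/ --out results/
mecphage affiliate results/ data/
mecphage diversity results/ data/
mecphage prevalence results/ data/
```

`results/summary.json` reports bin/species counts, feature prevalences,
affiliation counts, association counts by evidence type, dissimilarity
medians and Mantel correlations; `results/run_log.json` records the version,
seed and all parameters.

## Dataset layout

A dataset directory contains `bins.fasta` (headers `binID|contigID`),
`phages.fasta`, `bins.tsv`, `phages.tsv` (with per-predictor lifestyle
columns), `counts_prok.tsv`, `counts_vlp.tsv` and `samples.tsv`
(sample → MEC, location ∈ {anode, cathode, tubing, suspension, inoculum,
foam}, dataset ∈ {prokaryotic, VLP}). Synthetic datasets additionally carry
`config.yaml` and a `truth/` directory with the ground-truth tables.
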