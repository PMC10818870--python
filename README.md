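# micronet

Co-occurrence network analysis for two-group 16S amplicon studies.

`micronet` re-implements, as a tested and reusable pipeline, the network
methodology used in gut-microbiome studies that compare a diseased and a
healthy animal group (the canonical design here: 12 diarrheic low-fecal-score
vs 12 non-diarrheic high-fecal-score dairy cows, with rumen and fecal ASV
tables): correlation networks with a random-matrix-theory (RMT) edge
threshold, topology and module-hub (Zi–Pi) summaries, robustness under
simulated species loss, abundance-weighted null-corrected cohesion, the
supporting preprocessing (prevalence filter, rarefaction, alpha diversity)
and group statistics (Wilcoxon + FDR, Spearman screens, PERMANOVA), and the
acid-insoluble-ash digestibility formula. A synthetic-community generator
with planted, recoverable structure makes every stage testable without
external sequencing data.

## The methods in brief

* **Network inference.** Pairwise Pearson correlations `r_ij` of
  log-transformed relative abundances are hard-thresholded at `|r| ≥ s`.
  The cut-off `s` is chosen by scanning a grid and testing the
  nearest-neighbour spacing distribution (NNSD) of the thresholded matrix's
  unfolded eigenvalues: correlated-bulk spectra follow the Gaussian
  orthogonal ensemble (Wigner surmise, `P(d) = (πd/2)e^{−πd²/4}`), decoupled
  modular spectra follow Poisson (`P(d) = e^{−d}`). The selected threshold
  is where the spectrum transitions to sustained Poisson statistics.
* **Topology.** Node/edge counts, average degree `2E/N`, average shortest
  path over connected pairs, greedy-modularity modules, and per-node
  within-module degree z-score `Zi` and participation coefficient
  `Pi = 1 − Σ_m (k_im/k_i)²`, with module hubs at `Zi > 2.5, Pi ≤ 0.62`.
* **Robustness.** The proportion of nodes remaining after removing 50% of
  nodes at random (100 replicates) or the top 3 module hubs, followed by a
  secondary-extinction cascade (a node dies when it loses all links; an
  abundance-weighted cascade rule is available).
* **Cohesion.** Each taxon's connectedness is its average positive (or
  negative) pairwise correlation after subtracting a taxa-shuffle null
  model; each sample's positive (negative) cohesion is the
  abundance-weighted sum `C±_i = Σ_j a_ij · c±_j`.
* **Digestibility.** `ATTD(%) = (1 − (Ad·Nf)/(Af·Nd)) × 100` from the
  acid-insoluble-ash marker concentrations in diet (`Ad`) and feces (`Af`)
  and the nutrient concentrations `Nd`, `Nf`.

## Worked example

Simulate a study-like dataset (two groups of 12, planted correlated taxon
blocks and differential taxa) and run the whole pipeline from one config:

```yaml
# config.yaml
outdir: out
seed: 42
simulate: {n_taxa: 150}
network: {min_eigs: 30}
phenotypes: [fecal_water_content]
```

```text
$ micronet run config.yaml
completed stages: simulate, prep, network, topology, stability, cohesion, stats

$ micronet network --min-eigs 30 --scan-out scan.tsv out/counts.tsv net.graphml
threshold=0.81 reliable=True nodes=36 edges=50

$ micronet topology net.graphml
nodes=36 edges=50 average_degree=2.78 average_distance=1.52 components=7 modules=7 modularity=0.768

$ head -3 out/cohesion.tsv
sample_id       positive        negative        group
LFS_01  0.18840479907334098     -0.18677219789363997    LFS
LFS_02  0.18396177015976914     -0.18746049540926898    LFS
```

Reading the output: the RMT scan settled on `|r| ≥ 0.81`, keeping 36 taxa and
50 edges (average degree 2E/N = 2.78); shortest paths between connected taxa
average 1.52 steps across 7 components. Per-sample positive cohesion ≈ 0.19
means the average sample's taxa carry, abundance-weighted, a mean positive
null-corrected correlation of 0.19 — higher values indicate a more
cooperative community. `out/manifest.json` records every stage parameter,
seed and output checksum; `out/robustness.tsv`, `out/wilcoxon.tsv`,
`out/spearman_fecal_water_content.tsv` and friends hold the per-stage
results. Each subcommand (`prep`, `network`, `stability`, `cohesion`,
`compare`, `correlate`, `permanova`, `attd`) also runs standalone on TSV
inputs.

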