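# Methods

This note documents the models, numerical choices and limitations behind
`micronet`. It is written for users who want to know what each stage
computes and why, and what the synthetic benchmarks do and do not show.

## Study design being emulated

The pipeline targets the common two-group amplicon design: two groups of 12
samples (labelled LFS/HFS for low/high fecal score), ASV count tables from
a denoising pipeline, per-sample phenotypes (fecal score, fecal water
content, fermentation measures), and per-site networks built separately for
each group from that group's samples. Defaults follow that design:
rarefaction depth 8509, prevalence filter at one third of samples
(inclusive), 1000 PERMANOVA permutations, Student's t for robustness and
cohesion comparisons, Wilcoxon rank-sum + Benjamini–Hochberg for per-taxon
abundance comparisons.

## Preprocessing

* **Prevalence filter.** A taxon is kept when it has a nonzero count in at
  least `fraction · n_samples` samples, boundary inclusive (8 of 24 passes
  a 1/3 filter). The filter is re-applied within each group before
  per-group network construction, since each network should only contain
  taxa observed in its own samples.
* **Rarefaction** subsamples without replacement (multivariate
  hypergeometric) to a common depth; samples under the depth are dropped,
  not padded. Deterministic under the stage seed.
* **Alpha diversity.** Shannon (natural-log units by default; the base is
  an argument since denoising pipelines differ), bias-corrected Chao1
  `S_obs + F1(F1−1)/(2(F2+1))`, and Good's coverage `1 − F1/N`. Shannon is
  a richness-evenness composite and Chao1 a richness estimator; the
  implementations follow the standard definitions.
* **Log transform.** Correlations are computed on `ln(relative abundance +
  pseudocount)`. The default pseudocount is half the smallest nonzero
  relative abundance of the whole table: zeros map strictly below every
  observed value and the rule is invariant to the table's scale. A fixed
  pseudocount can be supplied instead.

## RMT threshold selection

For each candidate threshold `s` in a grid (default 0.30–0.95, step 0.01)
the correlation matrix is hard-thresholded (`|r| < s` zeroed, diagonal 1),
all-zero rows dropped, and the eigenvalue spectrum analysed:

1. **Unfolding.** Eigenvalues are mapped through a monotone
   piecewise-cubic (PCHIP) fit to a thinned set of knots on the cumulative
   spectral staircase. The knot count scales as ~n/20 (minimum 4, cap 25):
   the fit must track only the global eigenvalue density — with too many
   knots the curve follows the staircase itself and the spacing
   fluctuations that carry the ensemble signal are destroyed.
2. **NNSD statistics.** Nearest-neighbour spacings are normalized to unit
   mean and histogrammed on [0, 3] with 20 bins. Chi-square statistics are
   computed against the Poisson law `e^{−d}` and the GOE Wigner surmise
   `(πd/2)e^{−πd²/4}`, each truncated/renormalized to the support.
   Adjacent bins are pooled (from the tail inward) to expected counts ≥ 5
   so the chi-square null approximation holds for small spectra; the
   Poisson p-value uses `df = pooled bins − 1`. Without pooling and knot
   scaling the test rejects ~67% of true Poisson spectra at n ≈ 54; with
   them the size is ~5% across spectrum sizes.
3. **Decision rule.** A grid point qualifies when the Poisson fit has
   p > 0.05, its GOE chi-square exceeds its Poisson chi-square, and at
   least `min_eigs` (default 50) nodes survive. Candidates are restricted
   to thresholds **above the last strong Poisson rejection** (p < 1e-3).
   This gate matters when taxa far outnumber samples: the thresholded
   matrix of pure sampling noise passes through a sparse, sub-percolation
   regime whose spectrum is genuinely Poisson (localized states) *below*
   the correlated bulk's rejection hump, and a naive "first qualifying
   threshold" rule stops there, keeping large numbers of noise edges. The
   transition of interest is the one after which the spectrum stays
   Poisson. If no candidate qualifies, the candidate minimizing the
   Poisson chi-square is returned flagged `reliable=False`.

All knobs (grid, `min_eigs`, bins, support, `p_cut`, `strong_cut`,
`n_knots`) are exposed and logged. Negative correlations participate via
`|r|` and are kept as signed edge attributes, as cohesion needs the signs.

## Topology and Zi–Pi roles

Average degree is exactly `2E/N`; average distance is the mean shortest
path over connected node pairs only (thresholded networks are typically
multi-component; the component count is reported alongside). Modules come
from greedy modularity maximization (deterministic CNM); the within-module
degree z-score `Zi` and participation coefficient `Pi` use the classical
cut-offs (module hub: `Zi > 2.5, Pi ≤ 0.62`; connector: `Pi > 0.62`).

## Robustness

Per replicate, `⌊fraction·N⌋` nodes are removed uniformly at random
(default fraction 0.5, 100 replicates), or the top `n_hubs` module hubs are
removed deterministically (ranked by Zi, ties by Pi then id; top-Zi
fallback, flagged, when fewer module hubs exist). Secondary extinctions
follow one of:

* `degree_zero` (default): survivors that lost every link go extinct —
  the plain "proportion of remaining nodes" reading;
* `abundance_threshold`: a survivor dies when the abundance-weighted sum
  of its remaining link strengths falls below `theta` (default 0.5) of its
  original value, iterated to a fixed point — the weighted-cascade variant
  used in parts of the robustness literature.

Robustness is survivors/N. Both rules ship because published pipelines do
not state which they use; with cascades disabled the value is exactly
`1 − fraction` whenever `fraction·N` is integral, which the tests exploit.
Replicate values are kept so groups can be compared with Student's t.

## Cohesion

Connectedness and cohesion follow the null-model recipe: observed Pearson
correlations on relative abundances (no log transform, matching the cited
cohesion method rather than the network pipeline); a null distribution from
independently permuting each taxon's vector across samples (default 200
iterations — null-mean standard error < 0.01 at n = 24); corrected
`r̂ = r_obs − mean(r_null)`. A taxon's positive connectedness `c⁺_j` is the
mean of its *positive* corrected correlations (0 if none), i.e. a
conditional mean, and symmetrically for `c⁻_j`. Sample cohesion is
`C±_i = Σ_j a_ij c±_j`.

A consequence worth knowing: on fully independent data the conditional mean
does not vanish at finite sample size — corrected correlations are centred
at 0 with spread ≈ 1/√(n−1), so `E|c±| ≈ √(2/π)/√(n−1)` (~0.08 at n = 100),
shrinking only as 1/√n. Cohesion contrasts between groups are therefore
meaningful relative to each other, not as absolute zeros. The test suite
verifies the 1/√n decay and the sign contracts (`C⁺ ≥ 0 ≥ C⁻`).

## Group statistics

Wilcoxon rank-sum uses the exact null for combined n ≤ 12 without ties,
otherwise the tie-corrected normal approximation with continuity
correction; BH adjustment is applied across the features of one family
(e.g. one body site) at a time. Spearman screens gate features at ≥50%
prevalence and drop missing phenotype values pairwise. PERMANOVA uses
Anderson's pseudo-F from within/among sums of squared distances with free
label permutations (`p = (1+#{F* ≥ F})/(B+1)`) and an exhaustive
enumeration mode for small two-group designs; Bray–Curtis is the shipped
distance (externally computed matrices, e.g. UniFrac, can be supplied
instead — no tree handling is in scope).

## Synthetic communities

The generator plants recoverable structure in a compositional count model:

* latent log-abundances are Gaussian with per-taxon baseline means
  ~N(0, 1.5²) (log-normal-like abundance spread) and per-sample sd 0.6;
* correlated blocks (default 6 blocks of 10 taxa, exchangeable correlation
  0.8) come from a shared latent factor per block;
* differential taxa (default 10, alternating direction, log2FC 2) receive a
  group mean shift on the latent scale, and are drawn with baseline
  log-abundance ~N(1.0, 0.5) — moderately abundant — so the planted signal
  sits above the multinomial detection limit and is recoverable by design
  (the calibration target: ≥80% FDR-adjusted sensitivity at n = 12+12);
* counts are multinomial at per-sample depths drawn log-normal with mean
  15623 and sd 2217, truncated at 1000 reads (matching the read spread of
  the emulated study);
* presence/absence taxa are masked to zero in one group after count
  realization (so group-A column sums fall short of the sampled depth by
  the masked reads), with presence in the other group guaranteed.

What the generator does **not** emulate: pervasive weak correlation among
"noise" taxa (real gut communities correlate broadly; synthetic noise taxa
are independent, so synthetic per-group networks at 12 samples are far
sparser — tens of nodes — than real ones with hundreds), taxonomic
structure, overdispersion beyond the multinomial, and longitudinal
dependence. Passing recovery tests therefore demonstrates correctness of
the machinery on known ground truth, not expected performance on real
data.

## Problem sizes used in the automated checks

The test suite and `scripts/acceptance.py` use deliberately small problem
sizes chosen for tight oracles: exhaustive removal enumeration on graphs of
≤ 8 nodes against 10,000-replicate Monte-Carlo; full label enumeration for
PERMANOVA at n = 3+3 and Wilcoxon at combined n ≤ 10; 500×500 ensemble
samples for the NNSD discrimination; 150-taxon planted tables at 24 samples
for threshold-scan purity; 20 seeds for sensitivity/module-recovery rates.

## Known limitations

* The RMT decision internals of the original web pipeline (MENAP) are not
  published; this implementation documents and exposes every choice but
  cannot claim threshold-for-threshold agreement with it.
* Compositionality is not corrected (no SparCC/SPIEC-EASI); correlations
  on relative abundances inherit closure effects, exactly as in the
  emulated methodology.
* With 12 samples per group, correlation estimates are noisy and selected
  thresholds are high; single-group networks should be read comparatively.
* Negative digestibility values are possible under marker measurement
  error and are returned unclamped (flagged in logs).
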