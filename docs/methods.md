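# Methods

## Problem and model

`cisclust` asks whether genes that are co-expressed on a chromosome are
also physically close on it. The unit of analysis is one (chromosome,
phenotype) cell: a gene × sample matrix of log2-normalized expression
values restricted to one chromosome, with genes ordered by start
coordinate.

The analysis proceeds in four stages.

**1. Correlation.** The gene–gene Pearson correlation matrix

    C_ij = Cov(g_i, g_j) / (σ_i σ_j)
         = (1/N_s) Σ_s (g_is − μ_i)(g_js − μ_j) / (σ_i σ_j)

is computed over all N_s samples. Variance intermediates use the
population (1/N_s) normalization; the factor cancels in the ratio, so the
matrix is identical to the usual sample Pearson coefficient. Correlation
decay with distance is summarized by a profile: all upper-triangle pairs
are binned into equal-occupancy distance windows (default 50), and within
each window positive (C > 0) and negative (C < 0) values are summarized
separately by median and quartiles. Equal-occupancy rather than
equal-width windows are used because pair density varies strongly with
genomic distance; window boundaries may share a value when ties straddle a
chunk edge.

**2. Random-matrix null and cluster number.** The number of clusters k is
not chosen a priori. An ensemble of n_m = 100 surrogate matrices is built
by shuffling the expression data, recomputing the correlation matrix, and
taking its eigenvalues. The default shuffle permutes each gene's values
independently across samples — the classic time-series shuffle of
random-matrix correlation analysis — which destroys every shared
component, so on unstructured data the surrogate spectrum follows the
Marchenko–Pastur law with ratio q = n_genes/n_samples and support
[(1−√q)², (1+√q)²]. A within-sample shuffle (permuting gene values inside
each sample, preserving each sample's value multiset) is available as an
option; on per-sample-normalized data the two behave alike, but the
within-sample variant lets per-sample mean variation leak into the null as
a spurious common-mode eigenvalue, so it is not the default. k is the
number of empirical eigenvalues strictly exceeding the (1−α) empirical
quantile of the ensemble's per-matrix largest eigenvalues, α = 0.01; α → 0
recovers the strict "above every null maximum" rule. The largest
(global-mode-like) eigenvalue is counted in k; the smallest eigenvalues,
which are the most noise-sensitive, are never used. k = 0 is a legitimate
outcome (a null-like chromosome) and short-circuits clustering with a
logged notice.

**3. Clustering.** Genes are clustered by k-medoids on the dissimilarity
D_ij = 1 − |C_ij|, so strong correlation and strong anticorrelation both
mean "close". The PAM variant used is: k initial medoids drawn uniformly
without replacement; assignment of each gene to its nearest medoid (ties
to the lowest medoid index); then repeated greedy best-swap steps (the
single objective-improving medoid↔non-medoid exchange, ties to the lowest
index pair) until a swap-local optimum. Because initialization is random,
the run is repeated n_r = 100 times (restart r seeded with seed + r) and
the configuration with the minimum mean gene-to-medoid distance is kept.

**4. Spatial statistics.** For each gene in a cluster of size ≥ 2, the
nearest-neighbor distance (NND) is the minimum distance to another gene of
the same cluster, in ordinal rank units by default (genes ranked by start
coordinate; base pairs optional). Singletons are excluded and counted.
NNDs are pooled over clusters per chromosome. Shannon entropy
H = −Σ p(x) log p(x) over the empirical frequencies of distinct NND values
(no binning, natural log by default; base 2 available) measures how spread
the clusters are: localized clustering concentrates NND mass at small
values and lowers H. Phenotypes are compared by the two-sample
Kolmogorov–Smirnov distance D = sup|F_n − F_m| between pooled NND
distributions, computed exactly at the pooled jump points, and by the
entropy difference. The empirical-vs-null correlation comparison is run
piece-wise: per distance window, the KS distance between the window's
empirical correlations and the same window's values pooled over shuffled
surrogate matrices, with permutation p-values (label permutation of the
pooled window, add-one estimator (b+1)/(n_resamples+1)), reported raw and
Benjamini–Hochberg adjusted; an across-window mean p-value is also
emitted for continuity with prior practice but is not itself a test.

## Synthetic data generator

The generator produces the two regimes the method must distinguish, with
closed-form ground truth:

- **blocks** ("cancer-like"): genes are partitioned into n_blocks
  contiguous runs; gene values follow the spiked-covariance factor model
  x = √λ·f_b + √(1−λ)·σ_ε·ε with a per-block, per-sample standard Gaussian
  factor f_b. The population within-block correlation is
  λ/(λ + (1−λ)σ_ε²), equal to the loading λ at the default σ_ε = 1;
  between blocks it is 0. Each factor contributes exactly one eigenvalue
  above the Marchenko–Pastur bulk, so the spectral stage should recover
  k = n_blocks.
- **decay** ("cancer-like", smooth): a Gaussian process over gene
  positions with correlation λ·exp(−d/ξ) + (1−λ)·δ_ij, ξ defaulting to a
  tenth of the chromosome length.
- **control** ("normal-like"): the same factor model but with factor
  membership assigned uniformly at random, independent of position, and a
  fraction (default 0.5) of genes loading negatively — planting
  significant anticorrelations with no distance structure.
- **null**: i.i.d. Gaussian noise.

Gene positions are drawn uniformly without replacement and sorted; a
single master seed spawns independent sub-streams for positions, structure
and noise, so changing the number of samples never moves the genes.
Defaults (150 genes, 300 samples, 5 blocks, loading 0.7) give a clearly
detectable but not trivial structure: spike eigenvalues ≈ 20 against a
bulk edge ≈ 2.9.

What the generator does **not** emulate: count noise (values are
continuous Gaussian surrogates for log expression, not negative-binomial
counts), library-size and composition effects, gene-length/GC biases,
overlapping or hierarchical clusters, and inter-chromosomal structure.
Passing tests therefore demonstrate that the inference machinery recovers
planted intra-chromosomal structure of the stated kinds, not that real
tumor data contain such structure.

## Numerical choices

- Correlations are computed with a numerically symmetric, clipped
  `corrcoef`; zero-variance genes (std within rounding noise of zero,
  relative tolerance 1e-12) are rejected by the correlation stage and
  dropped with a warning at read time.
- Eigenvalues come from the full symmetric eigendecomposition
  (`eigvalsh`), sorted descending; asymmetry beyond 1e-8 is an error.
- The Marchenko–Pastur CDF used for diagnostics integrates the closed-form
  density on a 20001-point grid (trapezoid rule).
- PAM accepts a swap only if it improves the objective by more than 1e-15,
  guaranteeing termination; all tie-breaks are lowest-index, making every
  stage deterministic given its seed.
- KS statistics are exact (evaluated at pooled jump points, ties handled
  by evaluating at the last index of each tie run); permutation p-values
  re-randomize only the group labels against the fixed sorted pool.
- Equal-occupancy windows are contiguous chunks of the sorted pair
  distances; counts differ by at most one.
- Degenerate inputs: fewer than 3 samples, empty samples in a KS test,
  all-singleton clusterings, and k outside 1..N are errors; an empty
  gene set after filtering is an error at read time.

## Reproducibility

One master seed governs a pipeline run. Each stage of each (chromosome,
phenotype) cell derives its seed as
`SeedSequence((master_seed, crc32("stage:chromosome:phenotype")))`, so
adding a chromosome or phenotype never changes another cell's results, and
two runs with the same configuration produce byte-identical tables (all
floats are written with 10 significant digits; the JSON sidecar records
every effective parameter and derived seed, and no timestamps).

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `n_m` | 100 | surrogate matrices in the spectral null ensemble |
| `alpha` | 0.01 | significance level of the deviating-eigenvalue threshold |
| `n_r` | 100 | k-medoids restarts |
| `n_windows` | 50 | equal-occupancy distance windows for profiles and piece-wise KS |
| `n_resamples` | 1000 | permutations per window p-value (0 = statistics only) |
| `metric` | rank | NND distance units (rank or bp) |
| `distance_metric` | bp | pair-distance units for profiles and KS windows |
| `entropy_base` | e | logarithm base of the Shannon entropy |

## Known limitations

- The deviating-eigenvalue count conflates one very strong factor with
  several weak ones only through the quantile threshold; no Tracy–Widom
  correction is applied.
- Eigenvector information is deliberately unused for cluster assignment;
  k-medoids sees only 1 − |C|.
- The piece-wise KS windows are equal-occupancy, so window widths (in bp)
  differ between phenotypes with different gene sets; comparisons across
  phenotypes are by window index, not physical width.
- The across-window mean p-value is reported for continuity but has no
  calibrated interpretation; use the per-window BH-adjusted values.
- Analysis sizes in the test-suite and the reproduction script (100–200
  genes, 300–500 samples, 10–20 replicates) were chosen as the smallest
  problem sizes at which the planted effects are unambiguous.
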