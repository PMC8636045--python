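# cisclust

Intra-chromosomal co-expression clustering and spatial statistics.

`cisclust` is for transcriptomics researchers who want to know whether the
genes that co-express on a chromosome are also physically close on it — a
question that matters because tumor transcriptomes show a *loss of
long-range co-expression*: positive gene–gene correlation decays with
genomic distance in cancer, while in healthy tissue it does not. The
package analyzes whole intra-chromosomal Pearson correlation matrices
without thresholding any interaction.

## Method

For one chromosome and one phenotype, with N genes and N_s samples:

1. **Correlation** — the Pearson matrix
   `C_ij = (1/N_s) Σ_s (g_is − μ_i)(g_js − μ_j) / (σ_i σ_j)`, plus a
   correlation-vs-distance profile (median and quartiles of positive and
   negative correlations per equal-occupancy distance window).
2. **Random-matrix null** — an ensemble of n_m = 100 surrogate matrices
   from shuffled expression values. Unstructured data give the
   Marchenko–Pastur eigenvalue bulk with edge (1 + √(N/N_s))²; the number
   of empirical eigenvalues λ_1 … λ_k above the 99th percentile of the
   ensemble's largest eigenvalues (p < 0.01) fixes the cluster number k.
3. **k-medoids** — PAM clustering on the dissimilarity `D_ij = 1 − |C_ij|`
   (correlation and anticorrelation both mean "close"), best of
   n_r = 100 random restarts by minimum mean gene-to-medoid distance.
4. **Spatial statistics** — per-gene intra-cluster nearest-neighbor
   distance `D_nn,i = min_j |j − i|` over genes ranked by start
   coordinate; Shannon entropy `H = −Σ p(x) log p(x)` of the pooled NND
   distribution (low H = tightly localized clusters); exact two-sample
   Kolmogorov–Smirnov distances `D_KS = sup_x |F_n(x) − F_m(x)|` between
   phenotypes and, piece-wise per distance window, between empirical and
   shuffled-null correlation values with permutation p-values.

A bundled synthetic generator plants known structure — contiguous
correlated blocks or distance-decaying correlation ("cancer-like"),
position-independent signed factors ("control-like") — so every stage can
be validated against ground truth. See `docs/methods.md` for assumptions,
parameter meanings and limitations.

## Worked example

```python
import numpy as np
from cisclust import (
    SyntheticSpec, simulate, pearson_matrix, build_null_ensemble,
    eigen_spectrum, count_deviating_eigenvalues, correlation_to_dissimilarity,
    kmedoids_best, nnd, shannon_entropy,
)

for mode in ("blocks", "control"):
    spec = SyntheticSpec(n_genes=150, n_samples=300, mode=mode,
                         n_blocks=5, loading=0.7, seed=42)
    expr, truth = simulate(spec)
    corr = pearson_matrix(expr)
    ensemble = build_null_ensemble(expr, n_matrices=100, seed=1)
    k = count_deviating_eigenvalues(eigen_spectrum(corr), ensemble, alpha=0.01)
    result = kmedoids_best(correlation_to_dissimilarity(corr), k,
                           n_restarts=100, seed=2)
    dist = nnd(result.labels, expr.genes, metric="rank")
    print(f"{mode}: k = {k}, objective = {result.objective:.4f}, "
          f"median NND = {np.median(dist.per_gene_nnd):.0f}, "
          f"entropy = {shannon_entropy(dist):.4f} nats")
```

prints

```
blocks: k = 5, objective = 0.2690, median NND = 1, entropy = 0.0000 nats
control: k = 5, objective = 0.2728, median NND = 2, entropy = 1.8408 nats
```

Both chromosomes carry five planted factors and the spectral null finds
k = 5 in each. In the cancer-like `blocks` chromosome the clusters are
contiguous runs of genes, so every clustered gene's nearest same-cluster
neighbor is adjacent (NND = 1, entropy 0): co-expression is spatially
tight. In the control-like chromosome the same five clusters are scattered
over the chromosome, spreading the NND distribution (entropy 1.84 nats).
That entropy gap, and the KS distance between the two NND distributions,
are the package's headline statistics for comparing phenotypes.

## Command line

Every stage is exposed as a subcommand of `cisclust`:

```sh
cisclust simulate --mode blocks --n-genes 150 --n-samples 300 --seed 42 --out-prefix sim
cisclust spectra sim.expression.tsv sim.genes.bed --seed 1 --out-prefix sp     # writes k
cisclust correlate sim.expression.tsv sim.genes.bed --out-prefix co
cisclust cluster co.chr1.correlation.tsv --k 5 --seed 2 --out clusters.tsv
cisclust nnd clusters.tsv --out nnd.tsv
cisclust run-all --config run.yaml                                             # end to end
```

Inputs are a tab-separated expression table (rows = genes, columns =
samples, first column `gene_id`) and a BED file of gene coordinates.
Outputs are TSV tables plus a JSON sidecar recording every parameter and
derived seed; reruns with the same config are byte-identical.

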