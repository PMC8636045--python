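"""Spatial-organization statistics of gene clusters.

Three ingredients quantify how clusters sit along a chromosome:

* NND — for each gene in a cluster of size >= 2, the minimum chromosomal
  distance (rank or bp) to another gene of the same cluster, pooled over
  clusters. Tight, contiguous clusters concentrate NND mass at small
  values; position-independent clusters spread it out.
* Shannon entropy of the NND distribution (empirical frequencies over
  distinct values, no binning): low entropy = localized clusters.
* Kolmogorov-Smirnov distance D = sup_x |F_n(x) - F_m(x)| between two
  empirical CDFs, used both to compare NND distributions across phenotypes
  and, piece-wise in distance windows, to compare correlation values
  against a shuffled-data null. Significance is assessed by label
  permutation with an add-one correction, never parametrically.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np

from .correlation import CorrelationMatrix, equal_occupancy_windows
from .io_formats import GeneAnnotation


@dataclass
class NNDDistribution:
    """Pooled intra-cluster nearest-neighbor distances."""

    per_gene_nnd: np.ndarray
    cluster_sizes: list[int]
    n_singletons: int
    metric: str = "rank"

    def __post_init__(self) -> None:
        self.per_gene_nnd = np.asarray(self.per_gene_nnd, dtype=float)

    @property
    def entropy(self) -> float:
        return shannon_entropy(self)

    def cdf(self) -> tuple[np.ndarray, np.ndarray]:
        """Sorted (value, cumulative probability) pairs of the empirical CDF."""
        vals, counts = np.unique(self.per_gene_nnd, return_counts=True)
        return vals, np.cumsum(counts) / counts.sum()


@dataclass
class KSResult:
    statistic: float
    p_value: Optional[float]
    n_a: int
    n_b: int
    n_resamples: Optional[int] = None


@dataclass
class PiecewiseKSResult:
    """Per-distance-window KS of empirical vs null correlation values."""

    windows: list[KSResult]
    d_low: np.ndarray
    d_high: np.ndarray
    mean_p_value: Optional[float]  # across-window average, reported for fidelity
    bh_adjusted: Optional[np.ndarray] = None

    @property
    def statistics(self) -> np.ndarray:
        return np.array([w.statistic for w in self.windows])

    @property
    def p_values(self) -> np.ndarray:
        return np.array(
            [w.p_value if w.p_value is not None else np.nan for w in self.windows]
        )


def nnd(
    labels: Sequence[int],
    genes: Sequence[GeneAnnotation],
    metric: Literal["rank", "bp"] = "rank",
) -> NNDDistribution:
    """Intra-cluster nearest-neighbor distance for every non-singleton gene."""
    labels = np.asarray(labels)
    if len(labels) != len(genes):
        raise ValueError("labels not aligned with genes")
    if metric == "rank":
        pos = np.array([g.rank for g in genes], dtype=float)
    elif metric == "bp":
        pos = np.array([g.start_bp for g in genes], dtype=float)
    else:
        raise ValueError(f"unknown metric {metric!r}")

    out: list[np.ndarray] = []
    sizes: list[int] = []
    n_singletons = 0
    for lab in np.unique(labels):
        members = pos[labels == lab]
        sizes.append(members.size)
        if members.size < 2:
            n_singletons += 1
            continue
        p = np.sort(members)
        gaps = np.diff(p)
        left = np.concatenate([[np.inf], gaps])
        right = np.concatenate([gaps, [np.inf]])
        out.append(np.minimum(left, right))
    if not out:
        raise ValueError("NND undefined: all clusters are singletons")
    return NNDDistribution(
        per_gene_nnd=np.concatenate(out),
        cluster_sizes=sizes,
        n_singletons=n_singletons,
        metric=metric,
    )


def shannon_entropy(
    dist: NNDDistribution | np.ndarray, base: Literal["e", "2"] = "e"
) -> float:
    """H = -sum p(x) log p(x) over empirical frequencies of distinct values."""
    values = dist.per_gene_nnd if isinstance(dist, NNDDistribution) else np.asarray(dist)
    if values.size == 0:
        raise ValueError("entropy of an empty distribution")
    _, counts = np.unique(values, return_counts=True)
    p = counts / counts.sum()
    log = np.log2 if str(base) == "2" else np.log
    return float(max(0.0, -(p * log(p)).sum()))


def ks_distance(sample_a: Sequence[float], sample_b: Sequence[float]) -> KSResult:
    """Exact two-sample KS statistic, evaluated at the pooled jump points."""
    a = np.sort(np.asarray(sample_a, dtype=float))
    b = np.sort(np.asarray(sample_b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise ValueError("empty sample")
    pooled = np.concatenate([a, b])
    fa = np.searchsorted(a, pooled, side="right") / a.size
    fb = np.searchsorted(b, pooled, side="right") / b.size
    return KSResult(
        statistic=float(np.abs(fa - fb).max()),
        p_value=None,
        n_a=int(a.size),
        n_b=int(b.size),
    )


def _ks_stats_by_permutation(
    pooled_sorted: np.ndarray,
    n_a: int,
    n_resamples: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """KS statistics of random splits of a fixed pooled sample.

    Uses the identity KS = max |cumsum(z)| over distinct pooled values, with
    z = +1/n_a for group-a points and -1/n_b for group-b points in sorted
    order; only the labels are re-randomized per resample.
    """
    n = pooled_sorted.size
    n_b = n - n_a
    # last index of each run of tied values (CDFs only jump there)
    is_end = np.concatenate([pooled_sorted[1:] != pooled_sorted[:-1], [True]])
    base = np.full(n, -1.0 / n_b)
    stats = np.empty(n_resamples)
    for r in range(n_resamples):
        z = base.copy()
        z[rng.choice(n, size=n_a, replace=False)] = 1.0 / n_a
        stats[r] = np.abs(np.cumsum(z)[is_end]).max()
    return stats


def ks_permutation_test(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    n_resamples: int = 1000,
    seed: int | np.random.Generator = 0,
) -> KSResult:
    """KS statistic with a permutation p-value, (b + 1) / (n_resamples + 1)."""
    res = ks_distance(sample_a, sample_b)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pooled = np.sort(np.concatenate([np.asarray(sample_a, float), np.asarray(sample_b, float)]))
    null = _ks_stats_by_permutation(pooled, res.n_a, n_resamples, rng)
    b = int(np.sum(null >= res.statistic - 1e-12))
    res.p_value = (b + 1) / (n_resamples + 1)
    res.n_resamples = n_resamples
    return res


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (NaNs passed through)."""
    p = np.asarray(p, dtype=float)
    ok = ~np.isnan(p)
    q = np.full_like(p, np.nan)
    pv = p[ok]
    m = pv.size
    if m:
        order = np.argsort(pv)
        ranked = pv[order] * m / np.arange(1, m + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        adj = np.empty(m)
        adj[order] = np.clip(ranked, 0, 1)
        q[ok] = adj
    return q


def piecewise_ks_vs_null(
    c: CorrelationMatrix,
    null: Sequence[CorrelationMatrix],
    distances: np.ndarray,
    n_windows: int = 50,
    n_resamples: int = 1000,
    seed: int = 0,
) -> PiecewiseKSResult:
    """Window-wise KS of empirical vs pooled-null correlation values.

    Pairs are binned into equal-occupancy distance windows; in each window
    the empirical correlation values are compared against the same window's
    values pooled over the null matrices. n_resamples = 0 skips the
    permutation p-values (statistics only).
    """
    if len(null) == 0:
        raise ValueError("null ensemble is empty")
    iu, ju = np.triu_indices(c.n_genes, k=1)
    d = distances[iu, ju]
    emp = c.values[iu, ju]
    null_vals = np.stack([nm.values[iu, ju] for nm in null])
    windows = equal_occupancy_windows(d, n_windows)
    rng = np.random.default_rng(seed)

    results: list[KSResult] = []
    d_low, d_high = [], []
    for idx in windows:
        d_low.append(float(d[idx].min()))
        d_high.append(float(d[idx].max()))
        a = emp[idx]
        b = null_vals[:, idx].ravel()
        if a.size < 2 or b.size < 2:
            results.append(KSResult(np.nan, None, a.size, b.size))
            continue
        if n_resamples > 0:
            results.append(ks_permutation_test(a, b, n_resamples, rng))
        else:
            results.append(ks_distance(a, b))
    pvals = np.array([r.p_value for r in results if r.p_value is not None])
    return PiecewiseKSResult(
        windows=results,
        d_low=np.array(d_low),
        d_high=np.array(d_high),
        mean_p_value=float(pvals.mean()) if pvals.size else None,
        bh_adjusted=benjamini_hochberg(
            np.array([r.p_value if r.p_value is not None else np.nan for r in results])
        )
        if n_resamples > 0
        else None,
    )


def compare_phenotypes(
    nnd_control: NNDDistribution, nnd_case: NNDDistribution
) -> tuple[KSResult, float]:
    """KS between two pooled NND distributions and the entropy difference.

    Returns (ks, H(control) - H(case)); a positive difference means the
    control's clusters are more spread out along the chromosome.
    """
    ks = ks_distance(nnd_control.per_gene_nnd, nnd_case.per_gene_nnd)
    delta = shannon_entropy(nnd_control) - shannon_entropy(nnd_case)
    return ks, delta
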