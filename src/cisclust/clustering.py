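"""k-medoids (PAM) clustering of genes with the signed-correlation distance.

The dissimilarity between genes i and j is D_ij = 1 - |C_ij|: strong
correlation or anticorrelation both mean "close". PAM here is random
initialization followed by greedy best-swap refinement; because the
initialization is stochastic, the clustering is repeated with many
restarts and the configuration with the minimum mean gene-to-medoid
distance is kept.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .correlation import CorrelationMatrix
from .io_formats import GeneAnnotation

DEFAULT_N_RESTARTS = 100


@dataclass
class DissimilarityMatrix:
    """Symmetric zero-diagonal matrix of 1 - |C| values in [0, 1]."""

    values: np.ndarray
    genes: list[GeneAnnotation]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.genes)
        if self.values.shape != (n, n):
            raise ValueError("dissimilarity matrix shape mismatch")

    @property
    def n_genes(self) -> int:
        return len(self.genes)


@dataclass
class ClusteringResult:
    k: int
    medoids: np.ndarray  # gene indices, ascending
    labels: np.ndarray  # per-gene cluster id in 0..k-1
    objective: float  # mean distance of genes to their medoid
    n_restarts: int = 1
    seed: int = 0


def correlation_to_dissimilarity(c: CorrelationMatrix) -> DissimilarityMatrix:
    """Entrywise D = 1 - |C|, diagonal exactly zero."""
    d = 1.0 - np.abs(c.values)
    np.fill_diagonal(d, 0.0)
    return DissimilarityMatrix(values=np.clip(d, 0.0, 1.0), genes=list(c.genes))


def _assign(d: np.ndarray, medoids: np.ndarray) -> tuple[np.ndarray, float]:
    """Nearest-medoid labels (ties -> lowest medoid index) and mean distance."""
    sub = d[medoids]  # k x N
    labels = np.argmin(sub, axis=0)  # first minimum; medoids sorted ascending
    objective = float(sub[labels, np.arange(d.shape[0])].mean())
    return labels, objective


def kmedoids_once(
    d: DissimilarityMatrix, k: int, seed: int = 0
) -> ClusteringResult:
    """One PAM run: uniform random medoids, then greedy best-swap to a local optimum.

    Each sweep evaluates every (medoid, non-medoid) exchange and applies the
    single best strictly improving one; ties break toward the lowest
    (medoid, candidate) index pair. The objective is non-increasing and the
    run terminates at a swap-local optimum.
    """
    n = d.n_genes
    if k <= 0:
        raise ValueError("k must be positive")
    if k > n:
        raise ValueError(f"k={k} exceeds number of genes {n}")
    rng = np.random.default_rng(seed)
    dv = d.values
    medoids = np.sort(rng.choice(n, size=k, replace=False))
    labels, objective = _assign(dv, medoids)

    while True:
        best_obj = objective
        best_swap = None
        is_medoid = np.zeros(n, dtype=bool)
        is_medoid[medoids] = True
        candidates = np.flatnonzero(~is_medoid)
        if candidates.size == 0:
            break
        for mi in range(k):
            rem = np.delete(medoids, mi)
            if rem.size:
                rem_min = dv[rem].min(axis=0)
            else:
                rem_min = np.full(n, np.inf)
            # objective after replacing medoid mi with each candidate h
            objs = np.minimum(rem_min[None, :], dv[candidates]).mean(axis=1)
            j = int(np.argmin(objs))
            if objs[j] < best_obj - 1e-15:
                best_obj = float(objs[j])
                best_swap = (mi, int(candidates[j]))
        if best_swap is None:
            break
        mi, h = best_swap
        medoids = np.sort(np.concatenate([np.delete(medoids, mi), [h]]))
        labels, objective = _assign(dv, medoids)

    # relabel clusters by medoid order so ids are 0..k-1 and every cluster,
    # including each medoid's own, is non-empty by construction
    return ClusteringResult(
        k=k, medoids=medoids, labels=labels, objective=objective, seed=seed
    )


def kmedoids_best(
    d: DissimilarityMatrix,
    k: int,
    n_restarts: int = DEFAULT_N_RESTARTS,
    seed: int = 0,
) -> ClusteringResult:
    """Best of n_restarts PAM runs by minimum mean gene-to-medoid distance.

    Restart r uses seed + r, so individual restarts can be reproduced; ties
    go to the lowest restart index.
    """
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    best: ClusteringResult | None = None
    for r in range(n_restarts):
        res = kmedoids_once(d, k, seed=seed + r)
        if best is None or res.objective < best.objective:
            best = res
    best.n_restarts = n_restarts
    best.seed = seed
    return best
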