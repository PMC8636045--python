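"""Random-matrix null ensemble and deviating-eigenvalue selection of k.

The null destroys gene-gene correlations while preserving marginal value
distributions. The default axis permutes each gene's values independently
across samples (the classic time-series shuffle of random-matrix
correlation analysis), which removes every shared component — including
any sample-wide mode carried by varying per-sample means — so the ensemble
spectrum follows the Marchenko-Pastur law with ratio q = n_genes /
n_samples and support [(1 - sqrt(q))^2, (1 + sqrt(q))^2]. The "sample"
axis instead permutes gene values within each sample, preserving each
sample's value multiset; on per-sample-normalized data the two coincide in
effect, but the sample axis lets per-sample mean variation leak into the
null as a spurious common mode, so it is offered as an option only.

The number of clusters k is the count of empirical eigenvalues exceeding
the (1 - alpha) quantile of the ensemble's per-matrix largest eigenvalues
(alpha = 0 degenerates to the strict max rule). The smallest eigenvalues,
which are the most noise-sensitive, play no role.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigvalsh

from .correlation import CorrelationMatrix, pearson_matrix
from .io_formats import ExpressionMatrix

DEFAULT_N_MATRICES = 100
DEFAULT_ALPHA = 0.01


@dataclass
class EigenSpectrum:
    """Eigenvalues of a correlation matrix, sorted descending."""

    eigenvalues: np.ndarray
    n_genes: int
    n_samples: int

    def __post_init__(self) -> None:
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)


@dataclass
class NullEnsemble:
    """Spectra of n_matrices shuffled-data correlation matrices."""

    spectra: list[EigenSpectrum]
    seed: int

    @property
    def n_matrices(self) -> int:
        return len(self.spectra)

    @property
    def max_eigenvalues(self) -> np.ndarray:
        return np.array([s.eigenvalues[0] for s in self.spectra])

    def pooled_eigenvalues(self) -> np.ndarray:
        return np.concatenate([s.eigenvalues for s in self.spectra])


def shuffle_expression(
    m: ExpressionMatrix, seed: int | np.random.Generator
) -> ExpressionMatrix:
    """Independently permute the gene values within each sample (column).

    Each column's multiset of values is exactly preserved; gene and sample
    labels are unchanged.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perm = np.argsort(rng.random(m.values.shape), axis=0)
    return ExpressionMatrix(
        genes=list(m.genes),
        samples=list(m.samples),
        values=np.take_along_axis(m.values, perm, axis=0),
        phenotype=m.phenotype,
    )


def shuffle_expression_per_gene(
    m: ExpressionMatrix, seed: int | np.random.Generator
) -> ExpressionMatrix:
    """Variant: permute each gene's values across samples (row-wise).

    Also destroys gene-gene correlation, but preserves per-gene rather than
    per-sample marginals.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perm = np.argsort(rng.random(m.values.shape), axis=1)
    return ExpressionMatrix(
        genes=list(m.genes),
        samples=list(m.samples),
        values=np.take_along_axis(m.values, perm, axis=1),
        phenotype=m.phenotype,
    )


def eigen_spectrum(c: CorrelationMatrix, atol: float = 1e-8) -> EigenSpectrum:
    """Eigenvalues of a symmetric correlation matrix, descending."""
    v = c.values
    if not np.allclose(v, v.T, atol=atol):
        raise ValueError("matrix asymmetric beyond tolerance")
    w = eigvalsh((v + v.T) / 2.0)[::-1]
    return EigenSpectrum(eigenvalues=w, n_genes=c.n_genes, n_samples=-1)


def build_null_ensemble(
    m: ExpressionMatrix,
    n_matrices: int = DEFAULT_N_MATRICES,
    seed: int = 0,
    axis: str = "gene",
) -> NullEnsemble:
    """Shuffle -> correlate -> decompose, n_matrices times.

    axis="gene" (default) permutes each gene across samples; axis="sample"
    permutes within each sample.
    """
    if n_matrices < 1:
        raise ValueError("n_matrices must be >= 1")
    shuffler = {"sample": shuffle_expression, "gene": shuffle_expression_per_gene}[axis]
    spectra = []
    for child in np.random.SeedSequence(seed).spawn(n_matrices):
        rng = np.random.default_rng(child)
        sp = eigen_spectrum(pearson_matrix(shuffler(m, rng)))
        sp.n_samples = m.n_samples
        spectra.append(sp)
    return NullEnsemble(spectra=spectra, seed=seed)


def null_correlation_matrices(
    m: ExpressionMatrix, n_matrices: int, seed: int = 0, axis: str = "gene"
) -> list[CorrelationMatrix]:
    """Correlation matrices of shuffled data (for the piece-wise KS null)."""
    shuffler = {"sample": shuffle_expression, "gene": shuffle_expression_per_gene}[axis]
    out = []
    for child in np.random.SeedSequence(seed).spawn(n_matrices):
        rng = np.random.default_rng(child)
        out.append(pearson_matrix(shuffler(m, rng)))
    return out


def deviating_threshold(ensemble: NullEnsemble, alpha: float = DEFAULT_ALPHA) -> float:
    """(1 - alpha) empirical quantile of the ensemble's largest eigenvalues."""
    if not 0.0 < alpha < 0.5:
        raise ValueError("alpha must lie in (0, 0.5)")
    return float(np.quantile(ensemble.max_eigenvalues, 1.0 - alpha))


def count_deviating_eigenvalues(
    empirical: EigenSpectrum,
    ensemble: NullEnsemble,
    alpha: float = DEFAULT_ALPHA,
) -> int:
    """Number of empirical eigenvalues strictly above the null threshold."""
    thr = deviating_threshold(ensemble, alpha)
    return int(np.sum(empirical.eigenvalues > thr))


def marchenko_pastur_support(q: float) -> tuple[float, float]:
    return (1.0 - np.sqrt(q)) ** 2, (1.0 + np.sqrt(q)) ** 2


def marchenko_pastur_pdf(x: np.ndarray, q: float) -> np.ndarray:
    """Marchenko-Pastur density with ratio q = n_genes / n_samples < 1."""
    a, b = marchenko_pastur_support(q)
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    inside = (x > a) & (x < b)
    xi = x[inside]
    out[inside] = np.sqrt((b - xi) * (xi - a)) / (2.0 * np.pi * q * xi)
    return out


def marchenko_pastur_cdf(x: np.ndarray, q: float, n_grid: int = 20001) -> np.ndarray:
    """Numeric CDF of the MP law on its support (q < 1; no point mass at 0)."""
    a, b = marchenko_pastur_support(q)
    grid = np.linspace(a, b, n_grid)
    pdf = marchenko_pastur_pdf(grid, q)
    cdf = np.concatenate([[0.0], np.cumsum((pdf[1:] + pdf[:-1]) / 2.0 * np.diff(grid))])
    cdf /= cdf[-1]
    return np.interp(np.asarray(x, dtype=float), grid, cdf, left=0.0, right=1.0)
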