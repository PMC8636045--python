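"""Synthetic per-chromosome expression matrices with known correlation structure.

The generator emulates the two regimes the analysis is built to distinguish:

* ``blocks`` — a "cancer-like" chromosome: genes fall into contiguous runs
  that share a latent per-sample factor, so physically close genes are
  strongly co-expressed and the correlation matrix is block diagonal.
* ``decay`` — a "cancer-like" chromosome where positive correlation decays
  smoothly with genomic distance (exponential-kernel Gaussian process).
* ``control`` — a "normal-like" chromosome: factor membership is independent
  of position, and a fraction of genes load negatively, planting significant
  anticorrelations with no distance dependence.
* ``null`` — i.i.d. Gaussian noise, the no-structure reference.

blocks/control use a spiked-covariance (factor) model so the population
correlations are available in closed form (:func:`expected_correlation`)
and the number of eigenvalues deviating from the random-matrix bulk is
known (= number of factors).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .io_formats import ExpressionMatrix, GeneAnnotation

MODES = ("blocks", "decay", "control", "null")


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a simulated chromosome.

    loading is the population within-cluster correlation level in [0, 1]
    (at the default noise_sd = 1); decay_scale_bp is the e-folding distance
    of the decay kernel; neg_fraction is the probability a control-mode gene
    loads negatively on its factor.
    """

    n_genes: int
    n_samples: int
    mode: str = "blocks"
    chromosome_length_bp: int = 100_000_000
    n_blocks: int = 5
    loading: float = 0.7
    decay_scale_bp: Optional[float] = None
    neg_fraction: float = 0.5
    noise_sd: float = 1.0
    seed: int = 0
    chromosome: str = "chr1"
    phenotype: str = ""

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.n_genes < 1 or self.n_samples < 1:
            raise ValueError("n_genes and n_samples must be positive")
        if self.n_genes > self.chromosome_length_bp:
            raise ValueError("more genes than base pairs")
        if not 0.0 <= self.loading <= 1.0:
            raise ValueError("loading must lie in [0, 1]")
        if not 0.0 <= self.neg_fraction <= 1.0:
            raise ValueError("neg_fraction must lie in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.mode == "blocks" and self.n_blocks > self.n_genes:
            raise ValueError("n_blocks cannot exceed n_genes")

    @property
    def decay_scale(self) -> float:
        if self.decay_scale_bp is not None:
            return float(self.decay_scale_bp)
        return self.chromosome_length_bp / 10.0


def _streams(spec: SyntheticSpec) -> tuple[np.random.Generator, ...]:
    """Three independent sub-streams (positions, structure, noise) off one seed.

    Varying n_samples only consumes the noise/structure streams, so gene
    positions are stable across sample sizes for a fixed seed.
    """
    children = np.random.SeedSequence(spec.seed).spawn(3)
    return tuple(np.random.default_rng(c) for c in children)


def _plan(spec: SyntheticSpec):
    """Deterministic layout: positions plus (mode-dependent) factor structure."""
    pos_rng, struct_rng, _ = _streams(spec)
    positions = np.sort(
        pos_rng.choice(spec.chromosome_length_bp, size=spec.n_genes, replace=False)
    )
    assignment = None
    signs = None
    if spec.mode == "blocks":
        assignment = np.concatenate(
            [
                np.full(len(chunk), b, dtype=int)
                for b, chunk in enumerate(
                    np.array_split(np.arange(spec.n_genes), spec.n_blocks)
                )
            ]
        )
        signs = np.ones(spec.n_genes, dtype=int)
    elif spec.mode == "control":
        assignment = struct_rng.integers(0, spec.n_blocks, size=spec.n_genes)
        signs = np.where(
            struct_rng.random(spec.n_genes) < spec.neg_fraction, -1, 1
        )
    return positions, assignment, signs


def _within_factor_correlation(spec: SyntheticSpec) -> float:
    """Population correlation of two genes sharing a factor (positive signs)."""
    lam = spec.loading
    return lam / (lam + (1.0 - lam) * spec.noise_sd**2)


def simulate(spec: SyntheticSpec) -> tuple[ExpressionMatrix, Optional[np.ndarray]]:
    """Draw one expression matrix; returns (matrix, per-gene truth labels or None).

    Truth labels are block ids (blocks mode) or signed factor ids
    ``sign * (factor + 1)`` (control mode); decay and null modes have no
    discrete ground truth.
    """
    positions, assignment, signs = _plan(spec)
    _, _, noise_rng = _streams(spec)
    n, s = spec.n_genes, spec.n_samples
    lam = spec.loading

    if spec.mode == "null":
        values = noise_rng.standard_normal((n, s)) * spec.noise_sd
        truth = None
    elif spec.mode in ("blocks", "control"):
        n_fac = int(assignment.max()) + 1 if assignment.size else 0
        factors = noise_rng.standard_normal((n_fac, s))
        eps = noise_rng.standard_normal((n, s))
        values = (
            np.sqrt(lam) * signs[:, None] * factors[assignment]
            + np.sqrt(1.0 - lam) * spec.noise_sd * eps
        )
        truth = (
            assignment.copy()
            if spec.mode == "blocks"
            else signs * (assignment + 1)
        )
    else:  # decay
        d = np.abs(positions[:, None] - positions[None, :]).astype(float)
        cov = lam * np.exp(-d / spec.decay_scale) + (1.0 - lam) * np.eye(n)
        chol = None
        for jitter in (0.0, 1e-10, 1e-8, 1e-6):
            try:
                chol = np.linalg.cholesky(cov + jitter * np.eye(n))
                break
            except np.linalg.LinAlgError:
                continue
        if chol is None:
            raise ValueError("decay covariance not positive definite after jitter")
        values = chol @ noise_rng.standard_normal((n, s))
        truth = None

    genes = [
        GeneAnnotation(
            gene_id=f"G{i:05d}",
            chromosome=spec.chromosome,
            start_bp=int(p),
            rank=i,
        )
        for i, p in enumerate(positions)
    ]
    matrix = ExpressionMatrix(
        genes=genes,
        samples=[f"S{j:04d}" for j in range(s)],
        values=values,
        phenotype=spec.phenotype or spec.mode,
    )
    return matrix, truth


def expected_correlation(spec: SyntheticSpec, gene_i: int, gene_j: int) -> float:
    """Population correlation between two genes implied by the generative model."""
    if spec.mode == "null":
        raise ValueError("null mode has no correlation structure")
    if gene_i == gene_j:
        return 1.0
    positions, assignment, signs = _plan(spec)
    if spec.mode == "decay":
        d = abs(float(positions[gene_i]) - float(positions[gene_j]))
        return spec.loading * np.exp(-d / spec.decay_scale)
    if assignment[gene_i] != assignment[gene_j]:
        return 0.0
    return signs[gene_i] * signs[gene_j] * _within_factor_correlation(spec)
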