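"""Pearson correlation matrices and correlation-vs-genomic-distance profiles.

The correlation between two genes i and j over N_s samples is

    C_ij = (1/N_s) * sum_s (g_is - mu_i)(g_js - mu_j) / (sigma_i * sigma_j)

with population (1/N_s) normalization of the variance intermediates; the
normalization cancels in the ratio, so the matrix equals the usual sample
Pearson coefficient. Distance profiles summarize the upper-triangle pairs
in equal-occupancy distance windows, positive and negative correlations
separately (median and quartiles per window).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .io_formats import ExpressionMatrix, GeneAnnotation, FLOAT_FMT


@dataclass
class CorrelationMatrix:
    """Symmetric unit-diagonal Pearson matrix over an ordered gene list."""

    genes: list[GeneAnnotation]
    values: np.ndarray
    phenotype: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.genes)
        if self.values.shape != (n, n):
            raise ValueError(f"correlation matrix shape {self.values.shape} != ({n}, {n})")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def to_frame(self) -> pd.DataFrame:
        ids = [g.gene_id for g in self.genes]
        return pd.DataFrame(self.values, index=pd.Index(ids, name="gene_id"), columns=ids)

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", float_format=FLOAT_FMT)


def pearson_matrix(m: ExpressionMatrix) -> CorrelationMatrix:
    """Full gene-gene Pearson correlation matrix of an expression matrix."""
    if m.n_samples < 3:
        raise ValueError("need at least 3 samples for a correlation matrix")
    sd = m.values.std(axis=1)
    # relative tolerance: a constant row's std is rounding noise, not signal
    zero = np.flatnonzero(sd <= 1e-12 * (np.abs(m.values).max(axis=1) + 1.0))
    if zero.size:
        raise ValueError(
            f"zero-variance gene(s): {[m.genes[i].gene_id for i in zero[:5]]}"
        )
    if m.n_genes == 1:
        c = np.ones((1, 1))
    else:
        c = np.corrcoef(m.values)
    c = np.clip((c + c.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(c, 1.0)
    return CorrelationMatrix(genes=list(m.genes), values=c, phenotype=m.phenotype)


def pair_distances(
    genes: Sequence[GeneAnnotation], metric: Literal["bp", "rank"] = "bp"
) -> np.ndarray:
    """Symmetric matrix of pairwise gene distances in base pairs or rank units."""
    if metric == "bp":
        x = np.array([g.start_bp for g in genes], dtype=float)
    elif metric == "rank":
        x = np.array([g.rank for g in genes], dtype=float)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return np.abs(x[:, None] - x[None, :])


def equal_occupancy_windows(
    distances: np.ndarray, n_windows: int
) -> list[np.ndarray]:
    """Split indices of a 1-D distance vector into n_windows equal-count chunks.

    Chunks are contiguous in sorted distance order; counts differ by at most
    one. Ties at a chunk edge stay on the side their sorted position puts
    them, so two adjacent windows can share a boundary value.
    """
    if n_windows < 2:
        raise ValueError("n_windows must be >= 2")
    if distances.size < n_windows:
        raise ValueError(
            f"{distances.size} pairs cannot fill {n_windows} windows"
        )
    order = np.argsort(distances, kind="stable")
    return [np.asarray(c) for c in np.array_split(order, n_windows)]


@dataclass
class DistanceProfile:
    """Per-window summary of correlation vs distance, split by correlation sign."""

    table: pd.DataFrame  # columns: window, d_low_bp, d_high_bp, sign, median, q1, q3, count

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)

    def sign_frame(self, sign: str) -> pd.DataFrame:
        return self.table[self.table["sign"] == sign].reset_index(drop=True)


def distance_profile(
    c: CorrelationMatrix, distances: np.ndarray, n_windows: int = 50
) -> DistanceProfile:
    """Bin upper-triangle pairs into equal-occupancy distance windows.

    Within each window, positive (C > 0) and negative (C < 0) correlations
    are summarized separately by median/q1/q3/count; exact zeros fall in
    neither stratum.
    """
    iu, ju = np.triu_indices(c.n_genes, k=1)
    d = distances[iu, ju]
    v = c.values[iu, ju]
    windows = equal_occupancy_windows(d, n_windows)
    rows = []
    for w, idx in enumerate(windows):
        dw, vw = d[idx], v[idx]
        lo, hi = float(dw.min()), float(dw.max())
        for sign, vals in (("positive", vw[vw > 0]), ("negative", vw[vw < 0])):
            if vals.size:
                q1, med, q3 = np.quantile(vals, [0.25, 0.5, 0.75])
            else:
                q1 = med = q3 = np.nan
            rows.append(
                {
                    "window": w,
                    "d_low": lo,
                    "d_high": hi,
                    "sign": sign,
                    "median": med,
                    "q1": q1,
                    "q3": q3,
                    "count": int(vals.size),
                }
            )
    return DistanceProfile(table=pd.DataFrame(rows))
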