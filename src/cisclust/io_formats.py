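"""Reading and writing of the pipeline's external artifacts.

Expression tables are TSV (rows = genes, columns = samples, first column
``gene_id``); gene coordinates come from BED (0-based half-open; the BED
start column is used verbatim as the gene start). Cluster assignments and
statistics tables are TSV with a JSON sidecar carrying run metadata.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: numeric formatting used for every table we write; round-trips are exact
#: to 10 significant digits.
FLOAT_FMT = "%.10g"


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene's identity and genomic location.

    ``rank`` is the 0-based ordinal position of the gene after sorting by
    ``start_bp`` within its chromosome (ties broken by ``gene_id``).
    """

    gene_id: str
    chromosome: str
    start_bp: int
    rank: int


@dataclass
class ExpressionMatrix:
    """Gene x sample log2 expression values bound to gene annotations.

    May span several chromosomes (ranks are per-chromosome); use
    :meth:`split_by_chromosome` to obtain single-chromosome matrices.
    """

    genes: list[GeneAnnotation]
    samples: list[str]
    values: np.ndarray
    phenotype: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValueError(
                f"values shape {self.values.shape} inconsistent with "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression matrix contains non-finite values")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]

    def chromosomes(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.genes:
            seen.setdefault(g.chromosome, None)
        return list(seen)

    def split_by_chromosome(self) -> dict[str, "ExpressionMatrix"]:
        out: dict[str, ExpressionMatrix] = {}
        for chrom in self.chromosomes():
            idx = [i for i, g in enumerate(self.genes) if g.chromosome == chrom]
            out[chrom] = ExpressionMatrix(
                genes=[self.genes[i] for i in idx],
                samples=list(self.samples),
                values=self.values[idx],
                phenotype=self.phenotype,
            )
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.gene_ids, name="gene_id"),
            columns=self.samples,
        )


def _assign_ranks(genes: Sequence[GeneAnnotation]) -> list[GeneAnnotation]:
    """Sort by (chromosome, start_bp, gene_id) and assign per-chromosome ranks."""
    ordered = sorted(genes, key=lambda g: (g.chromosome, g.start_bp, g.gene_id))
    out: list[GeneAnnotation] = []
    counters: dict[str, int] = {}
    for g in ordered:
        r = counters.get(g.chromosome, 0)
        counters[g.chromosome] = r + 1
        out.append(replace(g, rank=r))
    return out


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED file (chrom, chromStart, chromEnd, name, ...); 4 columns required."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#", dtype={0: str},
    )
    if df.shape[1] < 4:
        raise ValueError(f"BED file {path} needs >= 4 columns (chrom, start, end, name)")
    df = df.iloc[:, :4]
    df.columns = ["chromosome", "start_bp", "end_bp", "gene_id"]
    df["start_bp"] = df["start_bp"].astype(int)
    if (df["start_bp"] < 0).any():
        raise ValueError("negative start coordinate in BED")
    if df["gene_id"].duplicated().any():
        dups = df.loc[df["gene_id"].duplicated(), "gene_id"].tolist()
        raise ValueError(f"duplicate gene ids in BED: {dups[:5]}")
    return df


def read_expression_table(
    path: str | Path,
    annotation_path: str | Path,
    phenotype: str = "",
    drop_zero_variance: bool = True,
) -> ExpressionMatrix:
    """Read an expression TSV plus a BED annotation into an :class:`ExpressionMatrix`.

    Genes present in both files are retained, sorted by (chromosome,
    start_bp, gene_id), and given per-chromosome ranks. Genes missing from
    either file are dropped with a logged count, as are zero-variance genes
    (their Pearson correlation is undefined).
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].tolist()
        raise ValueError(f"duplicate gene ids in expression table: {dups[:5]}")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()].index
            raise ValueError(
                f"non-numeric value in column {col!r}, row {bad[0]!r}"
            )
    if df.isna().any().any():
        row, col = next(zip(*np.nonzero(df.isna().to_numpy())))
        raise ValueError(
            f"missing value at gene {df.index[row]!r}, sample {df.columns[col]!r}"
        )

    bed = read_bed(annotation_path)
    common = df.index.intersection(bed["gene_id"])
    n_dropped = (len(df) - len(common)) + (len(bed) - len(common))
    if n_dropped:
        logger.info(
            "dropped %d genes absent from expression/annotation intersection",
            n_dropped,
        )
    if len(common) == 0:
        raise ValueError("no genes shared between expression table and BED")

    bed = bed.set_index("gene_id").loc[common]
    genes = _assign_ranks(
        [
            GeneAnnotation(gid, str(row.chromosome), int(row.start_bp), rank=-1)
            for gid, row in bed.iterrows()
        ]
    )
    values = df.loc[[g.gene_id for g in genes]].to_numpy(dtype=float)

    if drop_zero_variance:
        keep = values.std(axis=1) > 1e-12 * (np.abs(values).max(axis=1) + 1.0)
        if not keep.all():
            n_zv = int((~keep).sum())
            logger.warning("dropping %d zero-variance genes", n_zv)
            genes = _assign_ranks([g for g, k in zip(genes, keep) if k])
            values = values[keep]
    if len(genes) == 0:
        raise ValueError("no genes left after filtering")

    return ExpressionMatrix(
        genes=genes, samples=[str(c) for c in df.columns], values=values,
        phenotype=phenotype,
    )


def write_expression_table(m: ExpressionMatrix, path: str | Path) -> None:
    m.to_frame().to_csv(path, sep="\t", float_format=FLOAT_FMT)


def write_bed(m: ExpressionMatrix, path: str | Path, gene_span_bp: int = 1) -> None:
    """Write the matrix's annotations as a 4-column BED."""
    with open(path, "w") as fh:
        for g in m.genes:
            fh.write(
                f"{g.chromosome}\t{g.start_bp}\t{g.start_bp + gene_span_bp}"
                f"\t{g.gene_id}\n"
            )


def filter_low_expression(
    m: ExpressionMatrix, threshold: float
) -> ExpressionMatrix:
    """Retain genes whose mean across samples is strictly above ``threshold``.

    The filter is meant for pre-log values (mean expression > 10 on the raw
    scale); apply it before log transformation, or not at all if the input
    is already preprocessed.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    keep = m.values.mean(axis=1) > threshold
    if not keep.all():
        logger.info("low-expression filter removed %d genes", int((~keep).sum()))
    genes = _assign_ranks([g for g, k in zip(m.genes, keep) if k])
    return ExpressionMatrix(
        genes=genes, samples=list(m.samples), values=m.values[keep],
        phenotype=m.phenotype,
    )


def write_cluster_table(result, genes: Sequence[GeneAnnotation], path: str | Path) -> None:
    """Write per-gene cluster assignments as TSV.

    Columns: gene_id, chromosome, start_bp, rank, cluster_id, is_medoid.
    """
    labels = np.asarray(result.labels)
    if len(labels) != len(genes):
        raise ValueError(
            f"label vector length {len(labels)} != gene list length {len(genes)}"
        )
    medoids = set(int(i) for i in result.medoids)
    rows = [
        {
            "gene_id": g.gene_id,
            "chromosome": g.chromosome,
            "start_bp": g.start_bp,
            "rank": g.rank,
            "cluster_id": int(labels[i]),
            "is_medoid": i in medoids,
        }
        for i, g in enumerate(genes)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_cluster_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    expected = {"gene_id", "chromosome", "start_bp", "rank", "cluster_id", "is_medoid"}
    missing = expected - set(df.columns)
    if missing:
        raise ValueError(f"cluster table missing columns: {sorted(missing)}")
    return df


def write_sidecar(path: str | Path, metadata: dict) -> None:
    """Write the JSON sidecar of run metadata (seed, parameters, version)."""
    from cisclust import __version__

    payload = {"tool": "cisclust", "version": __version__, **metadata}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_sidecar(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
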