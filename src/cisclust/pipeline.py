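"""End-to-end orchestration: correlation -> null spectrum -> k -> clustering -> NND.

One run processes every (chromosome, phenotype) cell independently:
Pearson matrix, shuffled-data null ensemble, deviating-eigenvalue count k,
k-medoids clustering (skipped with a notice when k = 0), cluster table and
NND/entropy statistics; then each case phenotype is compared against the
designated control per chromosome (NND KS distance and entropy difference).

Reproducibility: one master seed; each stage of each cell derives its own
seed as SeedSequence((master_seed, crc32("stage:chromosome:phenotype"))),
so adding a chromosome or phenotype never changes another cell's results,
and two runs with the same config produce byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .clustering import (
    ClusteringResult,
    correlation_to_dissimilarity,
    kmedoids_best,
)
from .correlation import distance_profile, pair_distances, pearson_matrix
from .io_formats import (
    ExpressionMatrix,
    FLOAT_FMT,
    read_expression_table,
    write_cluster_table,
    write_sidecar,
)
from .spectral import (
    build_null_ensemble,
    count_deviating_eigenvalues,
    deviating_threshold,
    eigen_spectrum,
    null_correlation_matrices,
)
from .stats import compare_phenotypes, nnd, piecewise_ks_vs_null, shannon_entropy
from .synthetic import SyntheticSpec, simulate

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a full run; defaults follow the method's standard settings."""

    output_dir: str = "cisclust_out"
    seed: int = 0
    n_m: int = 100  # null-ensemble size
    n_r: int = 100  # k-medoids restarts
    alpha: float = 0.01  # deviating-eigenvalue significance level
    n_windows: int = 50
    n_resamples: int = 1000
    n_null_matrices_ks: int = 10  # null correlation matrices kept for piece-wise KS
    metric: str = "rank"  # NND metric: rank | bp
    distance_metric: str = "bp"  # profile/KS distance: bp | rank
    entropy_base: str = "e"
    control_phenotype: str = "control"
    chromosomes: Optional[list[str]] = None  # None = all present
    # real input: {phenotype: expression_tsv}; one shared BED
    expression: dict = field(default_factory=dict)
    bed: Optional[str] = None
    # or synthetic input: {phenotype: SyntheticSpec kwargs}
    synthetic: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def stage_seed(master_seed: int, stage: str, chromosome: str, phenotype: str) -> int:
    """Deterministic per-(stage, cell) seed below 2^31."""
    tag = zlib.crc32(f"{stage}:{chromosome}:{phenotype}".encode())
    ss = np.random.SeedSequence((master_seed, tag))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def _load_inputs(cfg: RunConfig) -> dict[str, dict[str, ExpressionMatrix]]:
    """Return {phenotype: {chromosome: ExpressionMatrix}} plus truth labels."""
    cells: dict[str, dict[str, ExpressionMatrix]] = {}
    if cfg.synthetic and cfg.expression:
        raise ValueError("configure either synthetic or real input, not both")
    if cfg.synthetic:
        for pheno, kwargs in cfg.synthetic.items():
            kwargs = dict(kwargs)
            kwargs.setdefault("seed", stage_seed(cfg.seed, "simulate", kwargs.get("chromosome", "chr1"), pheno))
            spec = SyntheticSpec(phenotype=pheno, **kwargs)
            m, _ = simulate(spec)
            cells[pheno] = m.split_by_chromosome()
    elif cfg.expression:
        if not cfg.bed:
            raise ValueError("real input requires a BED annotation path")
        for pheno, path in cfg.expression.items():
            m = read_expression_table(path, cfg.bed, phenotype=pheno)
            cells[pheno] = m.split_by_chromosome()
    else:
        raise ValueError("no input configured")
    if cfg.chromosomes:
        cells = {
            p: {c: m for c, m in by_chrom.items() if c in cfg.chromosomes}
            for p, by_chrom in cells.items()
        }
    return cells


def analyze_cell(
    m: ExpressionMatrix,
    cfg: RunConfig,
    chromosome: str,
    phenotype: str,
) -> dict:
    """Run the full per-(chromosome, phenotype) analysis; returns a result dict."""
    corr = pearson_matrix(m)
    dist = pair_distances(m.genes, metric=cfg.distance_metric)

    ens_seed = stage_seed(cfg.seed, "null_ensemble", chromosome, phenotype)
    ensemble = build_null_ensemble(m, n_matrices=cfg.n_m, seed=ens_seed)
    spectrum = eigen_spectrum(corr)
    spectrum.n_samples = m.n_samples
    k = count_deviating_eigenvalues(spectrum, ensemble, alpha=cfg.alpha)
    threshold = deviating_threshold(ensemble, alpha=cfg.alpha)

    n_windows = min(cfg.n_windows, max(2, m.n_genes * (m.n_genes - 1) // 2))
    profile = distance_profile(corr, dist, n_windows=n_windows)

    ks_nulls = null_correlation_matrices(
        m, cfg.n_null_matrices_ks,
        seed=stage_seed(cfg.seed, "ks_null", chromosome, phenotype),
    )
    pw = piecewise_ks_vs_null(
        corr, ks_nulls, dist, n_windows=n_windows,
        n_resamples=cfg.n_resamples,
        seed=stage_seed(cfg.seed, "ks_perm", chromosome, phenotype),
    )

    clustering: Optional[ClusteringResult] = None
    nnd_dist = None
    entropy = None
    if k >= 1:
        diss = correlation_to_dissimilarity(corr)
        clustering = kmedoids_best(
            diss, k, n_restarts=cfg.n_r,
            seed=stage_seed(cfg.seed, "kmedoids", chromosome, phenotype),
        )
        try:
            nnd_dist = nnd(clustering.labels, m.genes, metric=cfg.metric)
            entropy = shannon_entropy(nnd_dist, base=cfg.entropy_base)
        except ValueError as exc:  # all clusters singletons
            logger.warning("%s/%s: %s", chromosome, phenotype, exc)
    else:
        logger.info(
            "%s/%s: no deviating eigenvalues (k=0); clustering skipped",
            chromosome, phenotype,
        )
    return {
        "matrix": m,
        "correlation": corr,
        "spectrum": spectrum,
        "threshold": threshold,
        "k": k,
        "profile": profile,
        "piecewise_ks": pw,
        "clustering": clustering,
        "nnd": nnd_dist,
        "entropy": entropy,
    }


def _write_cell(outdir: Path, cell: dict, cfg: RunConfig, chromosome: str, phenotype: str) -> None:
    prefix = outdir / f"{chromosome}.{phenotype}"
    cell["correlation"].write(f"{prefix}.correlation.tsv")
    pd.DataFrame({"eigenvalue": cell["spectrum"].eigenvalues}).to_csv(
        f"{prefix}.spectrum.tsv", sep="\t", index=False, float_format=FLOAT_FMT
    )
    cell["profile"].write(f"{prefix}.profile.tsv")
    pw = cell["piecewise_ks"]
    pd.DataFrame(
        {
            "d_low": pw.d_low,
            "d_high": pw.d_high,
            "ks_statistic": pw.statistics,
            "p_value": pw.p_values,
            "p_bh": pw.bh_adjusted if pw.bh_adjusted is not None else np.nan,
        }
    ).to_csv(f"{prefix}.ks_vs_null.tsv", sep="\t", index=False, float_format=FLOAT_FMT)
    if cell["clustering"] is not None:
        write_cluster_table(
            cell["clustering"], cell["matrix"].genes, f"{prefix}.clusters.tsv"
        )
    if cell["nnd"] is not None:
        pd.DataFrame({"nnd": cell["nnd"].per_gene_nnd}).to_csv(
            f"{prefix}.nnd.tsv", sep="\t", index=False, float_format=FLOAT_FMT
        )


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full analysis; returns {(chromosome, phenotype): cell dict}.

    Failures are isolated per cell: an error in one (chromosome, phenotype)
    is logged and the rest of the run proceeds.
    """
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    inputs = _load_inputs(cfg)

    results: dict[tuple[str, str], dict] = {}
    sidecar: dict = {
        "config": cfg.to_dict(),
        "cells": {},
        "comparisons": {},
    }
    for pheno, by_chrom in inputs.items():
        for chrom, m in by_chrom.items():
            try:
                cell = analyze_cell(m, cfg, chrom, pheno)
            except Exception as exc:
                logger.error("cell %s/%s failed: %s", chrom, pheno, exc)
                continue
            results[(chrom, pheno)] = cell
            _write_cell(outdir, cell, cfg, chrom, pheno)
            sidecar["cells"][f"{chrom}.{pheno}"] = {
                "n_genes": m.n_genes,
                "n_samples": m.n_samples,
                "k": cell["k"],
                "threshold": cell["threshold"],
                "entropy": cell["entropy"],
                "ks_vs_null_mean_p": cell["piecewise_ks"].mean_p_value,
                "seeds": {
                    stage: stage_seed(cfg.seed, stage, chrom, pheno)
                    for stage in ("null_ensemble", "ks_null", "ks_perm", "kmedoids")
                },
            }

    control = cfg.control_phenotype
    comp_rows = []
    for (chrom, pheno), cell in results.items():
        if pheno == control or cell["nnd"] is None:
            continue
        ctrl = results.get((chrom, control))
        if ctrl is None or ctrl["nnd"] is None:
            continue
        ks, delta = compare_phenotypes(ctrl["nnd"], cell["nnd"])
        comp_rows.append(
            {
                "chromosome": chrom,
                "phenotype": pheno,
                "ks_statistic": ks.statistic,
                "delta_entropy": delta,
            }
        )
        sidecar["comparisons"][f"{chrom}.{pheno}"] = {
            "ks_statistic": ks.statistic,
            "delta_entropy": delta,
        }
    if comp_rows:
        pd.DataFrame(comp_rows).to_csv(
            outdir / "phenotype_comparisons.tsv", sep="\t", index=False,
            float_format=FLOAT_FMT,
        )
    write_sidecar(outdir / "run.json", sidecar)
    return results
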