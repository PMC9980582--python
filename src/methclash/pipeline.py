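"""End-to-end orchestration: read -> mask -> matrix -> DMC -> downstream.

The stage order is fixed: masking of genetically confounded cytosines,
matrix assembly under the coverage rule, optional season merging,
differential testing with the dual FDR/effect filter, SNP-proximity
profiling, stretch clustering and gene ranking, PCA and variance
partition.  A single JSON run-summary carries every stage's counts, the
headline percentages recomputed from this run's counts, and the exact
parameters used.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_EVEN, Decimal
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from . import __version__
from .clustering_genes import (
    GeneDmcSummary,
    StretchCluster,
    assign_genes,
    cluster_stretches,
    group_by_cluster_size,
    rank_by_density,
)
from .coverage_matrix import SiteMatrix, build_matrix, filter_min_cov, merge_seasons
from .diff_methylation import DmcSummary, call_dmcs
from .io_formats import (
    ConfigurationError,
    DataError,
    GeneAnnotation,
    MethylationCall,
    SampleInfo,
    SnpRecord,
    read_bismark_cov,
    read_gene_bed,
    read_samples_tsv,
    read_vcf_genotypes,
    write_dmc_table,
)
from .pca_variance import PcaResult, VariancePartition, methylation_pca, variance_partition
from .snp_masking import MaskResult, SsSnpSet, call_subspecies_specific_snps, mask_cytosines
from .snp_proximity import ProximityProfile, enrichment_test, proximity_profile


def format_percent(count: int, total: int, decimals: int) -> str:
    """Render 100*count/total with round-half-even at ``decimals`` places."""
    if total <= 0:
        raise DataError("format_percent needs a positive total")
    quantum = Decimal(1).scaleb(-decimals)
    value = (Decimal(count) * 100 / Decimal(total)).quantize(
        quantum, rounding=ROUND_HALF_EVEN)
    return f"{value:.{decimals}f}"


@dataclass
class Dataset:
    """The pipeline's input bundle (real files or a synthetic study)."""

    samples: list[SampleInfo]
    calls: dict[str, list[MethylationCall]]
    snps: list[SnpRecord]
    genes: list[GeneAnnotation]


def load_dataset(
    cov_paths: Mapping[str, str | Path],
    vcf_path: str | Path,
    bed_path: str | Path,
    samples_path: str | Path,
) -> Dataset:
    """Read a dataset from disk; ``cov_paths`` maps sample_id to cov file."""
    samples = read_samples_tsv(samples_path)
    missing = [s.sample_id for s in samples if s.sample_id not in cov_paths]
    if missing:
        raise ConfigurationError(f"no coverage file given for samples {missing}")
    calls = {s.sample_id: read_bismark_cov(cov_paths[s.sample_id], s.sample_id)
             for s in samples}
    animal_ids = list(dict.fromkeys(s.animal_id for s in samples))
    snps = read_vcf_genotypes(vcf_path, animal_ids)
    genes = read_gene_bed(bed_path)
    return Dataset(samples=samples, calls=calls, snps=snps, genes=genes)


def load_dataset_dir(directory: str | Path) -> Dataset:
    """Read a dataset laid out as by ``synthetic_data.write_dataset``."""
    directory = Path(directory)
    samples = read_samples_tsv(directory / "samples.tsv")
    cov_paths = {s.sample_id: directory / f"{s.sample_id}.cov" for s in samples}
    return load_dataset(cov_paths, directory / "variants.vcf",
                        directory / "genes.bed", directory / "samples.tsv")


@dataclass
class PipelineParams:
    min_cov: int = 10
    destrand: bool = False
    merge_seasons: bool = True
    mask: bool = True
    mask_mode: str = "all"
    fixed_snp_mode: str = "strict"
    fdr: float = 0.05
    min_diff: float = 0.10
    test: str = "qlrt"
    diff_mode: str = "mean_of_fractions"
    max_gap: int = 2000
    require_same_direction: bool = True
    promoter_flank: int = 2000
    proximity_bin_width: int = 10
    proximity_max_dist: int = 100
    seed: Optional[int] = None


@dataclass
class PipelineResult:
    params: PipelineParams
    mask_result: MaskResult
    sssnps: SsSnpSet
    matrix_seasons: SiteMatrix
    matrix_test: SiteMatrix
    dmc_records: list
    dmc_summary: DmcSummary
    profile: Optional[ProximityProfile]
    enrichment: Optional[pd.DataFrame]
    clusters: list[StretchCluster]
    gene_summaries: list[GeneDmcSummary]
    gene_grouping: Optional[dict]
    pca: Optional[PcaResult]
    partition: Optional[VariancePartition]
    summary: dict


def run_pipeline(
    dataset: Dataset,
    params: PipelineParams | None = None,
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Run every stage on an in-memory dataset; optionally write outputs."""
    if params is None:
        params = PipelineParams()
    samples = dataset.samples
    group_assignment = {s.animal_id: s.group for s in samples}

    # --- mask ---------------------------------------------------------
    universe = sorted({(c.chrom, c.pos) for calls in dataset.calls.values()
                       for c in calls})
    if params.mask:
        mask_result = mask_cytosines(universe, dataset.snps, params.mask_mode)
    else:
        mask_result = MaskResult(kept=set(universe), removed_at_snp=set(),
                                 removed_adjacent=set())
    kept = mask_result.kept
    calls = {sid: [c for c in cl if (c.chrom, c.pos) in kept]
             for sid, cl in dataset.calls.items()}

    # --- matrices -----------------------------------------------------
    base = build_matrix(calls, samples, min_cov=0, destrand=params.destrand)
    matrix_seasons = filter_min_cov(base, params.min_cov)
    seasons = {s.season for s in samples}
    if params.merge_seasons and len(seasons) > 1:
        matrix_test = merge_seasons(base, min_cov=params.min_cov)
    else:
        matrix_test = matrix_seasons

    # --- fixed SNPs and DMCs ------------------------------------------
    sssnps = call_subspecies_specific_snps(
        dataset.snps, group_assignment, mode=params.fixed_snp_mode)
    dmc_records, dmc_summary = call_dmcs(
        matrix_test, fdr=params.fdr, min_diff=params.min_diff,
        test=params.test, diff_mode=params.diff_mode)

    dmc_sites = [(r.chrom, r.pos) for r in dmc_records if r.is_dmc]
    mc_sites = [(r.chrom, r.pos) for r in dmc_records if not r.is_dmc]
    profile = enrichment = None
    if dmc_sites and mc_sites:
        profile = proximity_profile(
            dmc_sites, mc_sites, sssnps,
            bin_width=params.proximity_bin_width,
            max_dist=params.proximity_max_dist)
        enrichment = enrichment_test(profile)

    # --- clusters and genes -------------------------------------------
    clusters = cluster_stretches(
        dmc_records, max_gap=params.max_gap,
        require_same_direction=params.require_same_direction)
    gene_summaries = rank_by_density(assign_genes(
        dmc_records, clusters, dataset.genes,
        promoter_flank=params.promoter_flank))
    gene_grouping = (group_by_cluster_size(gene_summaries)
                     if gene_summaries else None)

    # --- PCA and variance partition -----------------------------------
    pca = None
    if matrix_seasons.n_sites >= 2 and matrix_seasons.n_samples >= 2:
        pca = methylation_pca(matrix_seasons)
    partition = None
    try:
        if matrix_seasons.n_sites >= 1:
            partition = variance_partition(matrix_seasons)
    except ConfigurationError:
        partition = None  # single-season designs carry no season stratum

    summary = _build_summary(dataset, params, mask_result, matrix_seasons,
                             matrix_test, dmc_summary, sssnps, clusters,
                             gene_summaries, gene_grouping, pca, partition)
    result = PipelineResult(
        params=params, mask_result=mask_result, sssnps=sssnps,
        matrix_seasons=matrix_seasons, matrix_test=matrix_test,
        dmc_records=dmc_records, dmc_summary=dmc_summary,
        profile=profile, enrichment=enrichment, clusters=clusters,
        gene_summaries=gene_summaries, gene_grouping=gene_grouping,
        pca=pca, partition=partition, summary=summary,
    )
    if outdir is not None:
        write_outputs(result, outdir)
    return result


def _build_summary(dataset, params, mask_result, matrix_seasons, matrix_test,
                   dmc_summary, sssnps, clusters, gene_summaries,
                   gene_grouping, pca, partition) -> dict:
    n_tested = dmc_summary.n_tested
    summary = {
        "tool": "methclash",
        "version": __version__,
        "parameters": dataclasses.asdict(params),
        "stages": {
            "input": {
                "n_samples": len(dataset.samples),
                "n_cytosines": mask_result.n_input,
                "n_variant_records": len(dataset.snps),
                "n_genes": len(dataset.genes),
            },
            "mask": {
                **mask_result.report(),
                "at_snp_discard_percent_str": (
                    format_percent(mask_result.n_removed_at_snp,
                                   mask_result.n_input, 2)
                    if mask_result.n_input else None),
            },
            "matrix": {
                "n_sites_all_samples": matrix_seasons.n_sites,
                "n_sites_tested": matrix_test.n_sites,
                "min_cov": params.min_cov,
            },
            "fixed_snps": {"n_sssnp": len(sssnps)},
            "dmc": {
                **dmc_summary.to_dict(),
                "dmc_percent_str": (
                    format_percent(dmc_summary.n_dmc, n_tested, 2)
                    if n_tested else None),
            },
            "clusters": {
                "n_clusters": len(clusters),
                "largest": max((c.size for c in clusters), default=0),
            },
            "genes": {
                "n_dmg": len(gene_summaries),
                "grouping": gene_grouping,
            },
            "pca": {
                "explained_variance_ratio":
                    pca.explained_variance_ratio[:5].tolist() if pca else None,
            },
            "variance_partition": partition.fractions if partition else None,
        },
    }
    return summary


def write_outputs(result: PipelineResult, outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["dmc"] = outdir / "dmc_table.tsv"
    write_dmc_table(result.dmc_records, paths["dmc"])

    if result.profile is not None:
        prof = result.profile.to_frame()
        if result.enrichment is not None:
            prof = prof.merge(
                result.enrichment[["bin_lo", "odds_ratio", "p_value", "q_value"]],
                on="bin_lo")
        paths["proximity"] = outdir / "snp_proximity.tsv"
        prof.to_csv(paths["proximity"], sep="\t", index=False)

    paths["clusters"] = outdir / "dmc_clusters.bed"
    with open(paths["clusters"], "wt") as out:
        for i, c in enumerate(result.clusters):
            strand = "+" if c.direction >= 0 else "-"
            out.write(f"{c.chrom}\t{c.start - 1}\t{c.end}\tcluster{i + 1}\t"
                      f"{c.size}\t{strand}\n")

    paths["genes"] = outdir / "gene_dmc_summary.tsv"
    pd.DataFrame([{
        "gene_id": s.gene_id, "chrom": s.chrom, "start": s.start,
        "end": s.end, "strand": s.strand, "length": s.length,
        "n_dmc": s.n_dmc, "density_per_kb": s.density_per_kb,
        "largest_cluster_size": s.largest_cluster_size,
        "cluster_count": s.cluster_count,
    } for s in result.gene_summaries]).to_csv(paths["genes"], sep="\t", index=False)

    if result.pca is not None:
        paths["pca"] = outdir / "pca_scores.tsv"
        df = pd.DataFrame(result.pca.scores,
                          columns=[f"PC{i + 1}" for i
                                   in range(result.pca.scores.shape[1])])
        df.insert(0, "sample_id", result.pca.sample_ids)
        df.to_csv(paths["pca"], sep="\t", index=False)

    if result.partition is not None:
        paths["partition"] = outdir / "variance_partition.tsv"
        pd.DataFrame([result.partition.fractions]).to_csv(
            paths["partition"], sep="\t", index=False)

    paths["summary"] = outdir / "run_summary.json"
    paths["summary"].write_text(
        json.dumps(result.summary, indent=2, sort_keys=True) + "\n")
    return paths
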