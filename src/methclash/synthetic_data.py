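"""Synthetic genotype + methylation-count datasets with known truth.

The generator emulates the post-alignment products of a two-subspecies
RRBS + genotyping study: 2 groups of 5 animals, each sampled in two
seasons, beta-binomial methylation counts at CpG sites, subspecies-fixed
SNPs (some of them C->T variants sitting exactly on a CpG cytosine, which
a bisulfite assay reads as a fully unmethylated cytosine), clustered
group-differential sites near genes, and a small season effect.

The per-site success probability for sample *i* (animal *a*, season *t*)
at site *s* is

    pi = clip(baseline_s + effect_s * g_a / 2 + shift_s * g_a / 2
              + ind_{s,a} + seas_{s,t}, 0, 1)

where ``g_a`` is +1/-1 by group, ``effect_s`` is the true differential-
methylation effect (zero outside designated sites), ``shift_s`` a small
breed-wide baseline shift, and the individual and season terms are
zero-mean normal draws (individual effects shared across the two seasons
of an animal).  Coverage is negative-binomial; methylated counts are
binomial given coverage.  At a confounded site, every animal homozygous
for the T allele emits all reads as unmethylated — the bisulfite artifact
the masking stage exists to remove.

Everything is a pure function of (config, seed): identical configs give
byte-identical output files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    ConfigurationError,
    GeneAnnotation,
    MethylationCall,
    SampleInfo,
    SnpRecord,
    write_bismark_cov,
    write_gene_bed,
    write_samples_tsv,
    write_vcf,
)

_BASES = "ACGT"

_CLASS_RANGES = {"lt30": (0.10, 0.30), "30to70": (0.30, 0.70),
                 "gt70": (0.70, 0.95)}


@dataclass
class SimulationConfig:
    """Study-design parameters for the synthetic dataset.

    Defaults mirror the design the pipeline targets: 5 + 5 animals in two
    groups, two seasons (challenge ``C`` and recovery ``R``) with a
    negligible season effect, mean methylation near 0.74, and a variance
    ordering individual > breed > season.
    """

    n_per_group: int = 5
    group_labels: tuple[str, str] = ("A", "N")
    n_seasons: int = 2
    season_labels: tuple[str, ...] = ("C", "R")
    genome: tuple[tuple[str, int], ...] = (("chr1", 1_500_000),
                                           ("chr2", 1_500_000))
    n_cpg_sites: int = 5000
    n_fixed_snps: int = 400
    n_segregating_snps: int = 400
    frac_csnp_confound: float = 0.05
    frac_snp_near_dmc: float = 0.25  # fixed SNPs dropped within 100 bp of a DMC
    n_true_dmc: int = 300
    effect_classes: dict[str, float] = field(
        default_factory=lambda: {"lt30": 0.45, "30to70": 0.35, "gt70": 0.20})
    cluster_geometry: tuple[int, int, int] = (20, 6, 500)  # clusters, sites, max gap
    n_genes: int = 60
    gene_length: int = 5000
    promoter_margin: int = 500  # cluster offset into the gene body
    coverage_mean: float = 30.0
    coverage_dispersion: float = 8.0  # NB size; var = mu + mu^2/size
    methylation_beta_params: tuple[float, float] = (7.4, 2.6)  # mean 0.74
    breed_effect_sd: float = 0.03
    individual_effect_sd: float = 0.08
    season_effect_sd: float = 0.01
    segregating_maf: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_group < 2 or self.n_seasons < 1:
            raise ConfigurationError("need >=2 animals per group, >=1 season")
        for name in ("n_cpg_sites", "n_fixed_snps", "n_segregating_snps",
                     "n_true_dmc", "n_genes"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if not 0 <= self.frac_csnp_confound <= 1:
            raise ConfigurationError("frac_csnp_confound must be in [0, 1]")
        total = sum(self.effect_classes.values())
        if self.effect_classes and abs(total - 1.0) > 1e-9:
            raise ConfigurationError("effect_classes mixture must sum to 1")
        if set(self.effect_classes) - set(_CLASS_RANGES):
            raise ConfigurationError(
                f"unknown effect classes {set(self.effect_classes) - set(_CLASS_RANGES)}")
        genome_len = sum(length for _, length in self.genome)
        if self.n_cpg_sites * 2 + 10 > genome_len:
            raise ConfigurationError(
                f"{self.n_cpg_sites} CpG sites do not fit a "
                f"{genome_len} bp genome")
        if self.n_true_dmc > self.n_cpg_sites:
            raise ConfigurationError("n_true_dmc exceeds n_cpg_sites")

    def animals(self) -> list[tuple[str, str]]:
        """(animal_id, group) pairs, e.g. A1..A5 then N1..N5."""
        out = []
        for g in self.group_labels:
            out += [(f"{g}{i + 1}", g) for i in range(self.n_per_group)]
        return out

    def samples(self) -> list[SampleInfo]:
        return [
            SampleInfo(f"{animal}_{season}", animal, group, season)
            for animal, group in self.animals()
            for season in self.season_labels[: self.n_seasons]
        ]

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=2, default=list)


@dataclass
class TruthTable:
    """Ground truth for a simulated dataset.

    ``sites`` has one row per CpG cytosine: baseline methylation, signed
    group effect (group1 - group2 in true methylation fraction), effect
    class, cluster id (-1 for none), breed baseline shift, nearest
    fixed-SNP distance (-1 when no fixed SNP shares the chromosome), and
    the confound flag with the T-homozygous group.  Confounded sites have
    group effect 0: their apparent difference is purely genetic.
    """

    sites: pd.DataFrame
    snps: pd.DataFrame
    snp_records: list[SnpRecord]
    genes: list[GeneAnnotation]
    samples: list[SampleInfo]
    config: SimulationConfig

    def confounded_sites(self) -> set[tuple[str, int]]:
        df = self.sites[self.sites.is_csnp_confounded]
        return set(zip(df.chrom, df.pos.astype(int)))

    def true_dmc_sites(self) -> set[tuple[str, int]]:
        df = self.sites[self.sites.group_effect.abs() >= 0.10]
        return set(zip(df.chrom, df.pos.astype(int)))

    def true_clusters(self) -> dict[int, pd.DataFrame]:
        df = self.sites[self.sites.cluster_id >= 0]
        return {int(cid): sub.sort_values("pos")
                for cid, sub in df.groupby("cluster_id")}


def _genome_offsets(genome: Sequence[tuple[str, int]]):
    """Map a linear coordinate over the concatenated genome to (chrom, pos)."""
    chroms, lengths = zip(*genome)
    bounds = np.concatenate([[0], np.cumsum(lengths)])
    return chroms, bounds


def _linear_to_site(linear: np.ndarray, chroms, bounds):
    idx = np.searchsorted(bounds, linear, side="right") - 1
    pos = linear - bounds[idx] + 1
    return idx, pos


def generate_truth(config: SimulationConfig) -> TruthTable:
    """Lay out CpG sites, effects, clusters, SNPs, genes and genotypes."""
    config.validate()
    rng = np.random.default_rng([config.seed, 0])
    chroms, bounds = _genome_offsets(config.genome)
    genome_len = int(bounds[-1])

    n_clusters, sites_per_cluster, max_gap = config.cluster_geometry
    n_clustered = min(config.n_true_dmc, n_clusters * sites_per_cluster)
    n_clusters_used = n_clustered // sites_per_cluster if sites_per_cluster else 0
    n_clustered = n_clusters_used * sites_per_cluster
    n_scattered_dmc = config.n_true_dmc - n_clustered

    # CpG positions live on an even-coordinate grid so two cytosines are
    # never adjacent and never coincide; non-confound SNPs go on odd
    # coordinates, so they can flank but not hit a CpG by accident.
    grid = np.arange(2, genome_len - 2, 2, dtype=np.int64)

    # clusters: runs of sites with intra-gaps < max_gap, round-robined
    # over chromosomes, each slotted into its own non-overlapping window
    cluster_linear: dict[int, np.ndarray] = {}
    if n_clusters_used:
        span = sites_per_cluster * max_gap + 100
        by_chrom: dict[int, list[int]] = {}
        for cid in range(n_clusters_used):
            by_chrom.setdefault(cid % len(chroms), []).append(cid)
        for ci, cids in by_chrom.items():
            clen = config.genome[ci][1]
            n_slots = clen // (span * 3)
            if n_slots < len(cids):
                raise ConfigurationError(
                    f"{len(cids)} clusters of span {span} bp do not fit "
                    f"chromosome {chroms[ci]} ({clen} bp)")
            slots = np.sort(rng.choice(n_slots, size=len(cids), replace=False))
            window = clen // n_slots
            for slot, cid in zip(slots, cids):
                start_lin = int(bounds[ci]) + int(slot) * window + 2
                gaps = rng.integers(1, max(max_gap // 2, 2),
                                    size=sites_per_cluster - 1)
                cluster_linear[cid] = start_lin + np.concatenate(
                    [[0], np.cumsum(gaps * 2)])
    clustered = (np.concatenate([cluster_linear[c] for c in sorted(cluster_linear)])
                 if cluster_linear else np.empty(0, dtype=np.int64))

    taken = set(clustered.tolist())
    free_grid = grid[~np.isin(grid, clustered)]
    n_rest = config.n_cpg_sites - clustered.size
    rest = rng.choice(free_grid, size=n_rest, replace=False)
    linear_all = np.concatenate([clustered, rest])

    cluster_ids = np.full(config.n_cpg_sites, -1, dtype=np.int64)
    for cid in sorted(cluster_linear):
        start = cid * sites_per_cluster
        cluster_ids[start:start + cluster_linear[cid].size] = cid

    order = np.argsort(linear_all, kind="stable")
    linear_all = linear_all[order]
    cluster_ids = cluster_ids[order]
    chrom_idx, pos = _linear_to_site(linear_all, chroms, bounds)

    # effects: clustered sites first (shared sign and class per cluster),
    # then scattered singles at random non-cluster sites
    effects = np.zeros(config.n_cpg_sites)
    classes = np.array(["none"] * config.n_cpg_sites, dtype=object)
    class_names = list(config.effect_classes)
    class_probs = np.array([config.effect_classes[c] for c in class_names])
    for cid in range(n_clusters_used):
        members = np.flatnonzero(cluster_ids == cid)
        cname = rng.choice(class_names, p=class_probs)
        lo, hi = _CLASS_RANGES[cname]
        sign = rng.choice([-1.0, 1.0])
        mags = rng.uniform(lo, min(hi, 0.95), size=members.size)
        effects[members] = sign * mags
        classes[members] = cname
    if n_scattered_dmc:
        candidates = np.flatnonzero(cluster_ids < 0)
        chosen = rng.choice(candidates, size=n_scattered_dmc, replace=False)
        for i in chosen:
            cname = rng.choice(class_names, p=class_probs)
            lo, hi = _CLASS_RANGES[cname]
            effects[i] = rng.choice([-1.0, 1.0]) * rng.uniform(lo, min(hi, 0.95))
            classes[i] = cname

    # baselines: Beta(a, b) everywhere, but effect sites draw a midpoint
    # leaving room for +-effect/2 so clamping never erodes the class
    a, b = config.methylation_beta_params
    baseline = rng.beta(a, b, size=config.n_cpg_sites)
    effect_mask = effects != 0
    half = np.abs(effects[effect_mask]) / 2
    baseline[effect_mask] = rng.uniform(half + 0.02, 1.0 - half - 0.02)

    breed_shift = rng.normal(0.0, config.breed_effect_sd, size=config.n_cpg_sites)

    # --- SNPs ---------------------------------------------------------
    animals = config.animals()
    g1, g2 = config.group_labels
    n_confound = int(round(config.frac_csnp_confound * config.n_fixed_snps))
    n_confound = min(n_confound, int((~effect_mask).sum()))
    n_near = int(round(config.frac_snp_near_dmc * config.n_fixed_snps))
    n_near = min(n_near, config.n_fixed_snps - n_confound, config.n_true_dmc)
    n_far = config.n_fixed_snps - n_confound - n_near

    snp_rows = []
    snp_records: list[SnpRecord] = []

    def _fixed_record(chrom: str, p: int, ref: str, alt: str, alt_group: str):
        gts = {}
        for a_id, grp in animals:
            allele = alt if grp == alt_group else ref
            gts[a_id] = (allele, allele)
        snp_records.append(SnpRecord(chrom, int(p), ref, (alt,), gts, True))
        snp_rows.append((chrom, int(p), ref, alt, "fixed", alt_group))

    # confounded c-SNPs: C->T exactly on a (non-effect) CpG cytosine
    confound_flags = np.zeros(config.n_cpg_sites, dtype=bool)
    confound_group = np.array([""] * config.n_cpg_sites, dtype=object)
    if n_confound:
        candidates = np.flatnonzero(~effect_mask)
        chosen = rng.choice(candidates, size=n_confound, replace=False)
        for i in chosen:
            alt_group = str(rng.choice([g1, g2]))
            confound_flags[i] = True
            confound_group[i] = alt_group
            _fixed_record(chroms[chrom_idx[i]], int(pos[i]), "C", "T", alt_group)

    used_positions = {(chroms[chrom_idx[i]], int(pos[i]))
                      for i in range(config.n_cpg_sites)}
    used_positions |= {(r.chrom, r.pos) for r in snp_records}

    def _fresh_odd_positions(n: int) -> list[tuple[str, int]]:
        out: list[tuple[str, int]] = []
        while len(out) < n:
            lin = int(rng.integers(3, genome_len - 3))
            lin |= 1  # odd linear coordinate
            idx, p = _linear_to_site(np.array([lin]), chroms, bounds)
            site = (chroms[idx[0]], int(p[0]))
            if site not in used_positions:
                used_positions.add(site)
                out.append(site)
        return out

    # fixed SNPs seeded near true DMCs (odd offsets 3..99 bp, so they
    # flank the cytosine without masking it)
    if n_near:
        dmc_idx = np.flatnonzero(effect_mask)
        chosen = rng.choice(dmc_idx, size=n_near, replace=False)
        for i in chosen:
            offset = int(rng.choice(np.arange(3, 100, 2)))
            side = int(rng.choice([-1, 1]))
            p = int(pos[i]) + side * offset
            site = (chroms[chrom_idx[i]], p)
            if p < 1 or site in used_positions:
                n_far += 1
                continue
            used_positions.add(site)
            ref, alt = rng.choice(list(_BASES), size=2, replace=False)
            _fixed_record(site[0], p, str(ref), str(alt), str(rng.choice([g1, g2])))

    for chrom, p in _fresh_odd_positions(n_far):
        ref, alt = rng.choice(list(_BASES), size=2, replace=False)
        _fixed_record(chrom, p, str(ref), str(alt), str(rng.choice([g1, g2])))

    # segregating SNPs: Hardy-Weinberg genotypes at the configured
    # frequency, independently per group; resampled until polymorphic
    for chrom, p in _fresh_odd_positions(config.n_segregating_snps):
        ref, alt = rng.choice(list(_BASES), size=2, replace=False)
        ref, alt = str(ref), str(alt)
        while True:
            gts = {}
            any_alt = False
            for a_id, _grp in animals:
                pair = tuple(
                    alt if rng.random() < config.segregating_maf else ref
                    for _ in range(2))
                gts[a_id] = pair
                any_alt |= alt in pair
            if any_alt:
                break
        snp_records.append(SnpRecord(chrom, p, ref, (alt,), gts, True))
        snp_rows.append((chrom, p, ref, alt, "segregating", ""))

    # --- genes: one per cluster first, the rest uniform ---------------
    genes: list[GeneAnnotation] = []
    chrom_len = dict(config.genome)
    for cid in range(min(n_clusters_used, config.n_genes)):
        members = np.flatnonzero(cluster_ids == cid)
        c = chroms[chrom_idx[members[0]]]
        lo = int(pos[members].min())
        start = max(1, lo - config.promoter_margin)
        end = min(chrom_len[c], start + config.gene_length - 1)
        strand = str(rng.choice(["+", "-"]))
        genes.append(GeneAnnotation(c, start, end, strand, f"GENE{cid + 1:04d}"))
    for j in range(len(genes), config.n_genes):
        c = str(rng.choice(chroms))
        start = int(rng.integers(1, max(chrom_len[c] - config.gene_length, 2)))
        strand = str(rng.choice(["+", "-"]))
        genes.append(GeneAnnotation(c, start, start + config.gene_length - 1,
                                    strand, f"GENE{j + 1:04d}"))

    # nearest fixed-SNP distance per cytosine (truth bookkeeping)
    fixed_by_chrom: dict[str, np.ndarray] = {}
    snps_df = pd.DataFrame(snp_rows, columns=["chrom", "pos", "ref", "alt",
                                              "kind", "alt_group"])
    for chrom, sub in snps_df[snps_df.kind == "fixed"].groupby("chrom"):
        fixed_by_chrom[chrom] = np.sort(sub.pos.to_numpy(dtype=np.int64))
    nearest = np.full(config.n_cpg_sites, -1, dtype=np.int64)
    for i in range(config.n_cpg_sites):
        arr = fixed_by_chrom.get(chroms[chrom_idx[i]])
        if arr is None or arr.size == 0:
            continue
        j = np.searchsorted(arr, pos[i])
        best = np.inf
        for k in (j - 1, j):
            if 0 <= k < arr.size:
                best = min(best, abs(int(arr[k]) - int(pos[i])))
        nearest[i] = int(best)

    sites = pd.DataFrame({
        "chrom": [chroms[i] for i in chrom_idx],
        "pos": pos.astype(np.int64),
        "strand": "+",
        "baseline": baseline,
        "group_effect": effects,
        "diff_class": classes,
        "cluster_id": cluster_ids,
        "breed_shift": breed_shift,
        "nearest_fixed_snp_dist": nearest,
        "is_csnp_confounded": confound_flags,
        "csnp_alt_group": confound_group,
    }).sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)

    return TruthTable(sites=sites, snps=snps_df, snp_records=snp_records,
                      genes=genes, samples=config.samples(), config=config)


@dataclass
class SyntheticDataset:
    """In-memory rendering of one simulated study."""

    samples: list[SampleInfo]
    calls: dict[str, list[MethylationCall]]
    snps: list[SnpRecord]
    genes: list[GeneAnnotation]
    truth: TruthTable


def simulate_counts(truth: TruthTable, config: SimulationConfig) -> SyntheticDataset:
    """Draw coverage and methylated counts for every sample and season."""
    rng = np.random.default_rng([config.seed, 1])
    sites = truth.sites
    n_sites = len(sites)
    animals = config.animals()
    n_animals = len(animals)
    seasons = list(config.season_labels[: config.n_seasons])
    g1 = config.group_labels[0]
    gsign = np.array([1.0 if grp == g1 else -1.0 for _, grp in animals])

    baseline = sites.baseline.to_numpy()
    effect = sites.group_effect.to_numpy()
    shift = sites.breed_shift.to_numpy()
    ind = rng.normal(0.0, config.individual_effect_sd, size=(n_sites, n_animals))
    seas = rng.normal(0.0, config.season_effect_sd, size=(n_sites, len(seasons)))

    confound = sites.is_csnp_confounded.to_numpy()
    conf_group = sites.csnp_alt_group.to_numpy()
    artifact = np.zeros((n_sites, n_animals), dtype=bool)
    for j, (_aid, grp) in enumerate(animals):
        artifact[:, j] = confound & (conf_group == grp)

    size = config.coverage_dispersion
    p_nb = size / (size + config.coverage_mean)

    calls: dict[str, list[MethylationCall]] = {}
    chrom_arr = sites.chrom.to_numpy()
    pos_arr = sites.pos.to_numpy()
    strand_arr = sites.strand.to_numpy()
    for t, season in enumerate(seasons):
        pi = np.clip(
            baseline[:, None]
            + (effect[:, None] + shift[:, None]) * gsign[None, :] / 2.0
            + ind + seas[:, t][:, None],
            0.0, 1.0,
        )
        cov = rng.negative_binomial(size, p_nb, size=(n_sites, n_animals))
        meth = rng.binomial(cov, pi)
        meth[artifact] = 0  # T-homozygotes read fully unmethylated
        for j, (animal, _grp) in enumerate(animals):
            sample_id = f"{animal}_{season}"
            calls[sample_id] = [
                MethylationCall(chrom_arr[i], int(pos_arr[i]), strand_arr[i],
                                int(meth[i, j]), int(cov[i, j] - meth[i, j]))
                for i in range(n_sites)
            ]

    return SyntheticDataset(samples=config.samples(), calls=calls,
                            snps=truth.snp_records, genes=truth.genes,
                            truth=truth)


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Convenience: generate_truth then simulate_counts."""
    return simulate_counts(generate_truth(config), config)


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write the dataset in the exact dialects the readers consume.

    Produces one Bismark-cov file per sample, a VCF, a gene BED, a sample
    sheet, truth TSVs and the config as JSON; returns the paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for s in dataset.samples:
        p = outdir / f"{s.sample_id}.cov"
        write_bismark_cov(dataset.calls[s.sample_id], p)
        paths[f"cov:{s.sample_id}"] = p
    animal_ids = []
    for s in dataset.samples:
        if s.animal_id not in animal_ids:
            animal_ids.append(s.animal_id)
    paths["vcf"] = outdir / "variants.vcf"
    write_vcf(dataset.snps, animal_ids, paths["vcf"],
              contigs=dataset.truth.config.genome)
    paths["bed"] = outdir / "genes.bed"
    write_gene_bed(dataset.genes, paths["bed"])
    paths["samples"] = outdir / "samples.tsv"
    write_samples_tsv(dataset.samples, paths["samples"])
    paths["truth_sites"] = outdir / "truth_sites.tsv"
    dataset.truth.sites.to_csv(paths["truth_sites"], sep="\t", index=False)
    paths["truth_snps"] = outdir / "truth_snps.tsv"
    dataset.truth.snps.to_csv(paths["truth_snps"], sep="\t", index=False)
    paths["config"] = outdir / "config.json"
    paths["config"].write_text(dataset.truth.config.to_json() + "\n")
    return paths
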