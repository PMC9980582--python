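"""DMC stretch clustering, gene assignment, density ranking and grouping.

A *stretch* is a run of two or more direction-concordant DMCs whose
consecutive gaps stay below ``max_gap`` (default 2000 bp).  Stretches and
individual DMCs are attached to genes through the gene body plus an
upstream promoter flank; genes are ranked by DMC density (DMCs per kb of
gene length) and grouped by the size of their largest stretch — the
inputs a downstream gene-set enrichment would consume.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .diff_methylation import bh_adjust
from .io_formats import DataError, DmcRecord, GeneAnnotation


@dataclass(frozen=True)
class StretchCluster:
    chrom: str
    positions: tuple[int, ...]  # sorted member DMC positions
    direction: int  # +1 / -1 sign of (group1 - group2); 0 if mixed (flag off)

    @property
    def start(self) -> int:
        return self.positions[0]

    @property
    def end(self) -> int:
        return self.positions[-1]

    @property
    def size(self) -> int:
        return len(self.positions)

    @property
    def max_internal_gap(self) -> int:
        return int(max(np.diff(self.positions))) if self.size > 1 else 0


@dataclass
class GeneDmcSummary:
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    length: int
    n_dmc: int
    largest_cluster_size: int
    cluster_count: int

    @property
    def density_per_kb(self) -> float:
        return 1000.0 * self.n_dmc / self.length


def cluster_stretches(
    dmcs: Sequence[DmcRecord],
    max_gap: int = 2000,
    require_same_direction: bool = True,
) -> list[StretchCluster]:
    """Single linear sweep over position-sorted DMCs.

    A run breaks when the chromosome changes, the gap to the previous DMC
    reaches ``max_gap``, or (with the direction flag on) the sign of the
    group difference flips.  Runs of length 1 are not clusters.
    """
    recs = sorted((r for r in dmcs if r.is_dmc), key=lambda r: (r.chrom, r.pos))
    clusters: list[StretchCluster] = []
    run: list[DmcRecord] = []

    def _flush() -> None:
        if len(run) >= 2:
            direction = run[0].direction if require_same_direction else int(
                np.sign(sum(r.direction for r in run)))
            clusters.append(StretchCluster(
                chrom=run[0].chrom,
                positions=tuple(r.pos for r in run),
                direction=direction,
            ))

    for r in recs:
        if run and (
            r.chrom != run[-1].chrom
            or r.pos - run[-1].pos >= max_gap
            or (require_same_direction and r.direction != run[-1].direction)
        ):
            _flush()
            run = []
        run.append(r)
    _flush()
    return clusters


def _gene_window(gene: GeneAnnotation, promoter_flank: int) -> tuple[int, int]:
    """Gene body plus an upstream promoter flank (strand-aware)."""
    if gene.strand == "-":
        return gene.start, gene.end + promoter_flank
    return max(1, gene.start - promoter_flank), gene.end


def assign_genes(
    dmcs: Sequence[DmcRecord],
    clusters: Sequence[StretchCluster],
    genes: Sequence[GeneAnnotation],
    promoter_flank: int = 2000,
) -> list[GeneDmcSummary]:
    """Attach DMCs and stretches to genes; one per gene with >=1 DMC.

    A DMC belongs to a gene when its position lies in the gene window; a
    cluster belongs to every gene any of its members touches.  Overlapping
    genes each receive shared DMCs.
    """
    dmc_pos: dict[str, np.ndarray] = {}
    for chrom, sub in pd.DataFrame(
        [(r.chrom, r.pos) for r in dmcs if r.is_dmc], columns=["chrom", "pos"]
    ).groupby("chrom"):
        dmc_pos[chrom] = np.sort(sub.pos.to_numpy(dtype=np.int64))

    summaries: list[GeneDmcSummary] = []
    for gene in genes:
        lo, hi = _gene_window(gene, promoter_flank)
        pos = dmc_pos.get(gene.chrom)
        n_dmc = 0
        if pos is not None:
            n_dmc = int(np.searchsorted(pos, hi, side="right")
                        - np.searchsorted(pos, lo, side="left"))
        if n_dmc == 0:
            continue
        sizes = [c.size for c in clusters
                 if c.chrom == gene.chrom
                 and any(lo <= p <= hi for p in c.positions)]
        summaries.append(GeneDmcSummary(
            gene_id=gene.gene_id, chrom=gene.chrom, start=gene.start,
            end=gene.end, strand=gene.strand, length=gene.length,
            n_dmc=n_dmc, largest_cluster_size=max(sizes, default=0),
            cluster_count=len(sizes),
        ))
    return summaries


def rank_by_density(summaries: Sequence[GeneDmcSummary]) -> list[GeneDmcSummary]:
    """Descending DMC density (per kb); ties by n_dmc then gene_id."""
    return sorted(summaries,
                  key=lambda s: (-s.density_per_kb, -s.n_dmc, s.gene_id))


def group_by_cluster_size(
    summaries: Sequence[GeneDmcSummary],
    total_dmg_count: int | None = None,
    key: str = "largest_cluster_size",
) -> dict:
    """Count genes whose largest stretch reaches >=2, >=3 and >3 DMCs.

    Percentages (one decimal, round-half-even) are taken over
    ``total_dmg_count``, defaulting to the number of summaries (all genes
    hit by any DMC).  ``key='cluster_count'`` switches to counting
    stretches per gene instead of the largest stretch's size.
    """
    if key not in ("largest_cluster_size", "cluster_count"):
        raise DataError(f"unknown grouping key {key!r}")
    if total_dmg_count is None:
        total_dmg_count = len(summaries)
    if total_dmg_count == 0:
        raise DataError("total_dmg_count is 0; percentages undefined")
    values = [getattr(s, key) for s in summaries]
    counts = {
        "ge2": sum(v >= 2 for v in values),
        "ge3": sum(v >= 3 for v in values),
        "gt3": sum(v > 3 for v in values),
    }
    return {
        "counts": counts,
        "percentages": {k: round(100.0 * v / total_dmg_count, 1)
                        for k, v in counts.items()},
        "total_dmg_count": total_dmg_count,
    }


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT gene-set file (set name, description, member genes)."""
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise DataError(f"GMT line with <3 fields: {line[:50]!r}")
        sets[fields[0]] = set(fields[2:])
    return sets


def geneset_enrichment(
    gene_list: Iterable[str],
    gene_sets: Mapping[str, set[str]],
    universe: Iterable[str],
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation test per gene set.

    P(X >= k) with N = |universe|, K = |set ∩ universe|, n = |list|; BH
    adjustment across sets.  Sets with no universe overlap are skipped
    with a warning.
    """
    genes = set(gene_list)
    uni = set(universe)
    if not genes:
        raise DataError("empty gene list")
    if not genes <= uni:
        raise DataError("gene list is not contained in the universe")
    rows = []
    for name, members in gene_sets.items():
        K = len(members & uni)
        if K == 0:
            warnings.warn(f"gene set {name!r} has no overlap with the universe",
                          stacklevel=2)
            continue
        k = len(members & genes)
        p = float(stats.hypergeom.sf(k - 1, len(uni), K, len(genes)))
        rows.append((name, K, k, min(p, 1.0)))
    df = pd.DataFrame(rows, columns=["gene_set", "set_size_in_universe",
                                     "overlap", "p_value"])
    if len(df):
        df["q_value"] = bh_adjust(df["p_value"].to_numpy())
    else:
        df["q_value"] = pd.Series(dtype=float)
    return df
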