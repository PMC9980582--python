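"""Figure analogues: PCA scatter, SNP-proximity bars, per-gene profiles."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .coverage_matrix import SiteMatrix
from .io_formats import GeneAnnotation
from .pca_variance import PcaResult
from .snp_proximity import ProximityProfile


def plot_pca(pca: PcaResult, samples, path: str | Path) -> None:
    """PC1/PC2 scatter coloured by group, marker by season."""
    groups = sorted({s.group for s in samples})
    seasons = sorted({s.season for s in samples})
    colors = dict(zip(groups, ["#1f77b4", "#d62728", "#2ca02c", "#9467bd"]))
    markers = dict(zip(seasons, "osD^v"))
    fig, ax = plt.subplots(figsize=(5, 4))
    for s, (x, y) in zip(samples, pca.scores[:, :2]):
        ax.scatter(x, y, c=colors[s.group], marker=markers[s.season],
                   label=f"{s.group}/{s.season}")
        ax.annotate(s.sample_id, (x, y), fontsize=6, alpha=0.7)
    handles, labels = ax.get_legend_handles_labels()
    seen = dict(zip(labels, handles))
    ax.legend(seen.values(), seen.keys(), fontsize=7)
    evr = pca.explained_variance_ratio
    ax.set_xlabel(f"PC1 ({100 * evr[0]:.1f}%)")
    if len(evr) > 1:
        ax.set_ylabel(f"PC2 ({100 * evr[1]:.1f}%)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_proximity(profile: ProximityProfile, path: str | Path) -> None:
    """Grouped bars: proportion of DMCs and MCs per nearest-ssSNP bin."""
    x = np.arange(len(profile.bins))
    width = 0.4
    fig, ax = plt.subplots(figsize=(6, 3.5))
    ax.bar(x - width / 2, profile.dmc_props, width, label="DMC")
    ax.bar(x + width / 2, profile.mc_props, width, label="MC")
    ax.set_xticks(x)
    ax.set_xticklabels([f"{lo}-{hi}" for lo, hi in profile.bins],
                       rotation=45, fontsize=7)
    ax.set_xlabel("distance to nearest ssSNP (bp)")
    ax.set_ylabel("proportion of set")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_gene_profile(matrix: SiteMatrix, gene: GeneAnnotation,
                      path: str | Path, flank: int = 2000) -> None:
    """Group-mean methylation along one gene (body plus flank)."""
    groups = sorted({s.group for s in matrix.samples})
    in_gene = ((matrix.sites.chrom == gene.chrom)
               & (matrix.sites.pos >= gene.start - flank)
               & (matrix.sites.pos <= gene.end + flank)).to_numpy()
    pos = matrix.sites.pos.to_numpy()[in_gene]
    P = matrix.P[in_gene]
    fig, ax = plt.subplots(figsize=(6, 3))
    for g in groups:
        mask = matrix.group_mask(g)
        ax.plot(pos, P[:, mask].mean(axis=1), marker=".", lw=0.8, label=g)
    ax.axvspan(gene.start, gene.end, alpha=0.1, color="grey")
    ax.set_title(gene.gene_id, fontsize=9)
    ax.set_xlabel("position (bp)")
    ax.set_ylabel("mean methylation")
    ax.set_ylim(-0.02, 1.02)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
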