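"""Assemble per-sample methylation calls into aligned site x sample matrices.

The unit of analysis is the individual cytosine (strand-specific), and a
site is retained only when its coverage reaches ``min_cov`` in EVERY
sample — a site absent from one sample's file counts as coverage 0 there
and is dropped.  Optional destranding merges the two symmetric cytosines
of a CpG dyad (minus-strand counts fold onto the plus-strand position one
base upstream) before the filter is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import DataError, MethylationCall, SampleInfo

SITE_COLUMNS = ["chrom", "pos", "strand"]


@dataclass
class SiteMatrix:
    """Aligned count matrices over the retained cytosines.

    ``M`` and ``U`` are (n_sites, n_samples) integer arrays of methylated
    and unmethylated read counts; ``P = M / (M + U)`` is defined everywhere
    because every retained cell has coverage >= ``min_cov``.
    """

    sites: pd.DataFrame  # columns chrom, pos, strand; sorted by (chrom, pos)
    samples: list[SampleInfo]
    M: np.ndarray
    U: np.ndarray
    min_cov: int = 10

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def coverage(self) -> np.ndarray:
        return self.M + self.U

    @property
    def P(self) -> np.ndarray:
        cov = self.coverage
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(cov > 0, self.M / np.maximum(cov, 1), np.nan)

    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def group_mask(self, group: str) -> np.ndarray:
        return np.array([s.group == group for s in self.samples])

    def site_keys(self) -> list[tuple[str, int]]:
        return list(zip(self.sites["chrom"], self.sites["pos"].astype(int)))


def _calls_to_frame(calls: Sequence[MethylationCall], sample_id: str,
                    destrand: bool) -> pd.DataFrame:
    rows = []
    for c in calls:
        pos, strand = c.pos, c.strand
        if destrand and strand == "-":
            pos, strand = c.pos - 1, "+"
        rows.append((c.chrom, pos, strand, c.n_meth, c.n_unmeth))
    df = pd.DataFrame(rows, columns=SITE_COLUMNS + ["M", "U"])
    if destrand:
        df = df.groupby(SITE_COLUMNS, as_index=False)[["M", "U"]].sum()
    elif df.duplicated(SITE_COLUMNS).any():
        dup = df[df.duplicated(SITE_COLUMNS)].iloc[0]
        raise DataError(
            f"sample {sample_id!r}: duplicate call at "
            f"{dup.chrom}:{dup.pos}({dup.strand})"
        )
    return df


def build_matrix(
    calls: Mapping[str, Sequence[MethylationCall]],
    samples: Sequence[SampleInfo],
    min_cov: int = 10,
    destrand: bool = False,
) -> SiteMatrix:
    """Align calls across samples and keep sites covered >= min_cov in all.

    ``calls`` maps sample_id to that sample's (already masked) calls; every
    sample in ``samples`` must have an entry (possibly empty).
    """
    missing = [s.sample_id for s in samples if s.sample_id not in calls]
    if missing:
        raise DataError(f"no methylation calls supplied for samples {missing}")
    if not samples:
        raise DataError("no samples supplied")

    frames = []
    for s in samples:
        df = _calls_to_frame(calls[s.sample_id], s.sample_id, destrand)
        df = df.rename(columns={"M": f"M::{s.sample_id}", "U": f"U::{s.sample_id}"})
        frames.append(df.set_index(SITE_COLUMNS))
    wide = pd.concat(frames, axis=1, join="outer")
    wide = wide.astype(float).fillna(0).astype(np.int64)
    wide = wide.reset_index().sort_values(["chrom", "pos"], kind="mergesort")

    M = wide[[f"M::{s.sample_id}" for s in samples]].to_numpy()
    U = wide[[f"U::{s.sample_id}" for s in samples]].to_numpy()
    keep = ((M + U) >= min_cov).all(axis=1)
    sites = wide.loc[keep, SITE_COLUMNS].reset_index(drop=True)
    return SiteMatrix(sites=sites, samples=list(samples),
                      M=M[keep], U=U[keep], min_cov=min_cov)


def filter_min_cov(matrix: SiteMatrix, min_cov: int) -> SiteMatrix:
    """Keep only sites with coverage >= min_cov in every sample."""
    keep = (matrix.coverage >= min_cov).all(axis=1)
    return SiteMatrix(
        sites=matrix.sites.loc[keep].reset_index(drop=True),
        samples=list(matrix.samples),
        M=matrix.M[keep], U=matrix.U[keep], min_cov=min_cov,
    )


def merge_seasons(matrix: SiteMatrix, min_cov: int | None = None) -> SiteMatrix:
    """Sum counts across seasons per animal and re-apply the coverage rule.

    The merged matrix has one column per animal (season label ``merged``);
    the coverage filter (``min_cov``, defaulting to the input matrix's) is
    re-applied on the merged counts, so a site under-covered within each
    season can enter the merged matrix when the input was built unfiltered.
    """
    if min_cov is None:
        min_cov = matrix.min_cov
    animals: list[str] = []
    for s in matrix.samples:
        if s.animal_id not in animals:
            animals.append(s.animal_id)
    cols = {a: [i for i, s in enumerate(matrix.samples) if s.animal_id == a]
            for a in animals}
    merged_samples = []
    for a in animals:
        first = matrix.samples[cols[a][0]]
        merged_samples.append(replace(first, sample_id=a, season="merged"))
    M = np.column_stack([matrix.M[:, cols[a]].sum(axis=1) for a in animals])
    U = np.column_stack([matrix.U[:, cols[a]].sum(axis=1) for a in animals])
    keep = ((M + U) >= min_cov).all(axis=1)
    return SiteMatrix(
        sites=matrix.sites.loc[keep].reset_index(drop=True),
        samples=merged_samples, M=M[keep], U=U[keep], min_cov=min_cov,
    )
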