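"""Subspecies-specific SNP calling and genetic masking of cytosines.

A bisulfite experiment cannot distinguish a genomic C->T polymorphism from
an unmethylated cytosine: both read as T.  Cytosines sitting on (or
immediately adjacent to) a variant position are therefore removed from the
methylation dataset before differential testing.  Masking uses the union of
ALL detected variants in either group, regardless of fixation; fixation
between the groups matters only for the separate SNP-proximity analysis,
which uses the strict fixed-difference caller below.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .io_formats import ConfigurationError, SnpRecord

Site = tuple[str, int]


@dataclass(frozen=True)
class SsSnpSet:
    """Sorted positions, per chromosome, of SNVs fixed for alternative
    bases between the two groups (every sample homozygous, the two groups
    carrying different alleles)."""

    positions: dict[str, np.ndarray]

    def __len__(self) -> int:
        return int(sum(arr.size for arr in self.positions.values()))

    def chrom(self, chrom: str) -> np.ndarray:
        return self.positions.get(chrom, np.empty(0, dtype=np.int64))


@dataclass
class MaskResult:
    """Partition of the input cytosines by the SNP mask.

    The three sets are disjoint and their union is the input set;
    ``removed_adjacent`` holds cytosines exactly 1 bp from a variant that
    are not themselves on a variant.
    """

    kept: set[Site]
    removed_at_snp: set[Site]
    removed_adjacent: set[Site]

    @property
    def n_kept(self) -> int:
        return len(self.kept)

    @property
    def n_removed_at_snp(self) -> int:
        return len(self.removed_at_snp)

    @property
    def n_removed_adjacent(self) -> int:
        return len(self.removed_adjacent)

    @property
    def n_input(self) -> int:
        return self.n_kept + self.n_removed_at_snp + self.n_removed_adjacent

    def discard_percent(self) -> float:
        """Percentage of input cytosines sitting directly on a variant."""
        if self.n_input == 0:
            return 0.0
        return 100.0 * self.n_removed_at_snp / self.n_input

    def report(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_kept": self.n_kept,
            "n_removed_at_snp": self.n_removed_at_snp,
            "n_removed_adjacent": self.n_removed_adjacent,
            "at_snp_discard_percent": self.discard_percent(),
        }


def _is_hom(pair: tuple[Optional[str], Optional[str]]) -> bool:
    a, b = pair
    return a is not None and a == b


def call_subspecies_specific_snps(
    snps: Iterable[SnpRecord],
    group_assignment: Mapping[str, str],
    mode: str = "strict",
    min_called_per_group: int = 1,
) -> SsSnpSet:
    """Call positions fixed for alternative bases between the two groups.

    A position qualifies iff it is an SNV, every sample of group 1 is
    homozygous for one allele, every sample of group 2 homozygous for a
    different allele, and (in the default ``strict`` mode) no genotype is
    missing.  ``lenient`` mode instead requires at least
    ``min_called_per_group`` called homozygotes per group, all concordant.
    """
    if mode not in ("strict", "lenient"):
        raise ConfigurationError(f"unknown fixed-SNP calling mode {mode!r}")
    groups = sorted(set(group_assignment.values()))
    if len(groups) != 2:
        raise ConfigurationError(
            f"need exactly two groups, got {groups!r}"
        )
    members = {g: [s for s, gg in group_assignment.items() if gg == g]
               for g in groups}
    for g, mem in members.items():
        if not mem:
            raise ConfigurationError(f"group {g!r} has no samples")

    by_chrom: dict[str, list[int]] = {}
    for rec in snps:
        if not rec.is_snv:
            continue
        fixed_allele: dict[str, Optional[str]] = {}
        ok = True
        for g in groups:
            allele: Optional[str] = None
            n_called = 0
            for s in members[g]:
                pair = rec.genotypes.get(s, (None, None))
                if pair[0] is None and pair[1] is None:
                    if mode == "strict":
                        ok = False
                        break
                    continue
                if not _is_hom(pair):
                    ok = False
                    break
                if allele is None:
                    allele = pair[0]
                elif allele != pair[0]:
                    ok = False
                    break
                n_called += 1
            if not ok:
                break
            if allele is None or n_called < (min_called_per_group
                                             if mode == "lenient" else len(members[g])):
                ok = False
                break
            fixed_allele[g] = allele
        if ok and fixed_allele[groups[0]] != fixed_allele[groups[1]]:
            by_chrom.setdefault(rec.chrom, []).append(rec.pos)

    return SsSnpSet({
        chrom: np.unique(np.asarray(pos, dtype=np.int64))
        for chrom, pos in by_chrom.items()
    })


def mask_cytosines(
    cytosines: Iterable[Site],
    variants: Iterable[SnpRecord],
    mask_mode: str = "all",
) -> MaskResult:
    """Partition cytosines into kept / on-a-variant / +-1 bp from a variant.

    ``mask_mode='all'`` (default) masks against every variant record;
    ``'ct_only'`` restricts to SNVs whose REF/ALT pair involves C and T on
    either strand (C/T or G/A), for sensitivity analysis.
    """
    if mask_mode not in ("all", "ct_only"):
        raise ConfigurationError(f"unknown mask_mode {mask_mode!r}")

    var_by_chrom: dict[str, set[int]] = {}
    for rec in variants:
        if mask_mode == "ct_only":
            if not rec.is_snv:
                continue
            pairs = {frozenset((rec.ref_allele, alt)) for alt in rec.alt_alleles}
            if frozenset("CT") not in pairs and frozenset("GA") not in pairs:
                continue
        var_by_chrom.setdefault(rec.chrom, set()).add(rec.pos)

    kept: set[Site] = set()
    at_snp: set[Site] = set()
    adjacent: set[Site] = set()
    for site in cytosines:
        chrom, pos = site
        vs = var_by_chrom.get(chrom)
        if vs is None:
            kept.add(site)
        elif pos in vs:
            at_snp.add(site)
        elif (pos - 1) in vs or (pos + 1) in vs:
            adjacent.add(site)
        else:
            kept.add(site)
    return MaskResult(kept=kept, removed_at_snp=at_snp, removed_adjacent=adjacent)
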