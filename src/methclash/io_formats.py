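"""Readers and writers for the standard formats the pipeline touches.

Internal coordinate convention is 1-based inclusive throughout, matching
both the Bismark coverage dialect and VCF.  BED input is converted on read
(``start + 1``, ``end``); that conversion is the only off-by-one boundary in
the package.

The methylation-percentage column of Bismark coverage files is never
trusted: methylation fractions are always recomputed from the two count
columns, which are the primitive data.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
import pysam


class ParseError(ValueError):
    """A line of an input file could not be interpreted."""


class ConfigurationError(ValueError):
    """The requested analysis configuration is inconsistent with the data."""


class DataError(ValueError):
    """Structurally valid input that violates a pipeline precondition."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MethylationCall:
    """One sample's methylated/unmethylated read counts at a cytosine."""

    chrom: str
    pos: int  # 1-based
    strand: str  # '+', '-' or '.' when unknown
    n_meth: int
    n_unmeth: int

    @property
    def coverage(self) -> int:
        return self.n_meth + self.n_unmeth

    @property
    def fraction(self) -> Optional[float]:
        """Methylation fraction; ``None`` at zero coverage."""
        cov = self.coverage
        if cov == 0:
            return None
        return self.n_meth / cov


@dataclass(frozen=True)
class SnpRecord:
    """A genotyped variant position with per-sample unordered allele pairs.

    ``genotypes`` maps sample id to a pair of allele strings; missing
    alleles are ``None``.  ``is_snv`` is False for indels and
    multi-nucleotide variants, which are kept (anchored at POS) for
    cytosine masking but never qualify as subspecies-specific SNPs.
    """

    chrom: str
    pos: int  # 1-based anchor position
    ref_allele: str
    alt_alleles: tuple[str, ...]
    genotypes: dict[str, tuple[Optional[str], Optional[str]]]
    is_snv: bool = True


@dataclass(frozen=True)
class GeneAnnotation:
    chrom: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    strand: str
    gene_id: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ParseError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class SampleInfo:
    """Sample metadata: which animal, which group (breed), which season."""

    sample_id: str
    animal_id: str
    group: str
    season: str


@dataclass(frozen=True)
class DmcRecord:
    """A tested cytosine with its differential-methylation verdict.

    ``is_dmc`` holds iff q_value <= fdr AND abs_meth_diff >= min_diff (the
    dual filter); ``diff_class`` partitions DMCs into ``lt30`` (<30%),
    ``30to70`` (30-70%, boundaries inclusive) and ``gt70`` (>70%) by
    absolute methylation difference, and is ``none`` for non-DMCs.
    """

    chrom: str
    pos: int
    strand: str
    mean_meth_g1: float
    mean_meth_g2: float
    abs_meth_diff: float
    p_value: float
    q_value: float
    is_dmc: bool
    diff_class: str  # 'lt30' | '30to70' | 'gt70' | 'none'

    @property
    def direction(self) -> int:
        """Sign of (group1 - group2) mean methylation; 0 when equal."""
        d = self.mean_meth_g1 - self.mean_meth_g2
        return (d > 0) - (d < 0)


# ---------------------------------------------------------------------------
# Bismark coverage
# ---------------------------------------------------------------------------

def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_bismark_cov(path: str | Path, sample_id: str = "") -> list[MethylationCall]:
    """Read a Bismark coverage file (``chrom start end meth% n_meth n_unmeth``).

    Coordinates are 1-based with start == end.  The methylation-% column is
    ignored; an optional 7th column is taken as strand.  Zero-coverage lines
    are retained (coverage filtering happens downstream).
    """
    calls: list[MethylationCall] = []
    label = f" in sample {sample_id!r}" if sample_id else ""
    with _open_text(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(
                    f"{path}:{lineno}{label}: expected >=6 tab-separated "
                    f"columns, got {len(fields)}"
                )
            chrom, start, _end, _pct, m, u = fields[:6]
            try:
                pos = int(start)
                n_meth = int(m)
                n_unmeth = int(u)
            except ValueError as exc:
                raise ParseError(
                    f"{path}:{lineno}{label}: non-integer coordinate or "
                    f"count column: {exc}"
                ) from None
            if pos < 1 or n_meth < 0 or n_unmeth < 0:
                raise ParseError(
                    f"{path}:{lineno}{label}: negative count or position < 1"
                )
            strand = fields[6] if len(fields) >= 7 and fields[6] in "+-" else "."
            calls.append(MethylationCall(chrom, pos, strand, n_meth, n_unmeth))
    return calls


def write_bismark_cov(calls: Iterable[MethylationCall], path: str | Path) -> None:
    """Write calls in the 6-column Bismark coverage dialect (plus strand)."""
    with open(path, "wt") as out:
        for c in sorted(calls, key=lambda c: (c.chrom, c.pos)):
            pct = 0.0 if c.coverage == 0 else 100.0 * c.n_meth / c.coverage
            cols = [c.chrom, str(c.pos), str(c.pos), f"{pct:.6g}",
                    str(c.n_meth), str(c.n_unmeth)]
            if c.strand in "+-":
                cols.append(c.strand)
            out.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf_genotypes(path: str | Path, sample_ids: Sequence[str]) -> list[SnpRecord]:
    """Read per-sample genotypes from a VCF, keeping variant positions only.

    Records where every requested sample is homozygous reference are
    dropped.  Indels and MNVs are reduced to their anchor position and
    flagged ``is_snv=False``.
    """
    records: list[SnpRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        present = set(vcf.header.samples)
        missing = [s for s in sample_ids if s not in present]
        if missing:
            raise ConfigurationError(
                f"samples {missing} requested but absent from VCF header of {path}"
            )
        for rec in vcf.fetch() if vcf.index is not None else vcf:
            alts = tuple(a for a in (rec.alts or ()) if a is not None)
            if not alts:
                continue
            genotypes: dict[str, tuple[Optional[str], Optional[str]]] = {}
            any_nonref = False
            for s in sample_ids:
                alleles = rec.samples[s].alleles
                if alleles is None or len(alleles) == 0:
                    pair: tuple[Optional[str], Optional[str]] = (None, None)
                else:
                    pair = tuple(alleles[:2])  # type: ignore[assignment]
                    if len(pair) == 1:
                        pair = (pair[0], pair[0])
                genotypes[s] = pair
                if any(a is not None and a != rec.ref for a in pair):
                    any_nonref = True
            if not any_nonref:
                continue
            is_snv = len(rec.ref) == 1 and all(len(a) == 1 for a in alts)
            records.append(
                SnpRecord(rec.chrom, rec.pos, rec.ref, alts, genotypes, is_snv)
            )
    return records


def write_vcf(records: Iterable[SnpRecord], sample_ids: Sequence[str],
              path: str | Path, contigs: Sequence[tuple[str, int]] = ()) -> None:
    """Write SnpRecords as a minimal plain-text VCF 4.2 with GT fields."""
    with open(path, "wt") as out:
        out.write("##fileformat=VCFv4.2\n")
        for chrom, length in contigs:
            out.write(f"##contig=<ID={chrom},length={length}>\n")
        out.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        out.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                  + "\t".join(sample_ids) + "\n")
        for rec in sorted(records, key=lambda r: (r.chrom, r.pos)):
            allele_index = {rec.ref_allele: 0}
            for i, a in enumerate(rec.alt_alleles, start=1):
                allele_index[a] = i
            gts = []
            for s in sample_ids:
                pair = rec.genotypes.get(s, (None, None))
                gts.append("/".join(
                    "." if a is None else str(allele_index[a]) for a in pair
                ))
            out.write("\t".join([
                rec.chrom, str(rec.pos), ".", rec.ref_allele,
                ",".join(rec.alt_alleles), ".", "PASS", ".", "GT", *gts,
            ]) + "\n")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_gene_bed(path: str | Path) -> list[GeneAnnotation]:
    """Read BED4/BED6 gene intervals, converting to 1-based inclusive."""
    genes: list[GeneAnnotation] = []
    with _open_text(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: expected >=4 BED columns")
            chrom, start0, end0, name = fields[:4]
            try:
                start = int(start0)
                end = int(end0)
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from None
            if end <= start:
                raise ParseError(f"{path}:{lineno}: end {end} <= start {start}")
            strand = fields[5] if len(fields) >= 6 and fields[5] in "+-" else "."
            genes.append(GeneAnnotation(chrom, start + 1, end, strand, name))
    return genes


def write_gene_bed(genes: Iterable[GeneAnnotation], path: str | Path) -> None:
    with open(path, "wt") as out:
        for g in sorted(genes, key=lambda g: (g.chrom, g.start)):
            out.write(f"{g.chrom}\t{g.start - 1}\t{g.end}\t{g.gene_id}\t0\t"
                      f"{g.strand if g.strand in '+-' else '.'}\n")


# ---------------------------------------------------------------------------
# sample sheets and DMC tables
# ---------------------------------------------------------------------------

_SAMPLE_COLUMNS = ["sample_id", "animal_id", "group", "season"]


def read_samples_tsv(path: str | Path) -> list[SampleInfo]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing sample-sheet columns {missing}")
    return [SampleInfo(*row) for row in df[_SAMPLE_COLUMNS].itertuples(index=False)]


def write_samples_tsv(samples: Iterable[SampleInfo], path: str | Path) -> None:
    pd.DataFrame(
        [(s.sample_id, s.animal_id, s.group, s.season) for s in samples],
        columns=_SAMPLE_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


_DMC_COLUMNS = ["chrom", "pos", "strand", "mean_meth_g1", "mean_meth_g2",
                "abs_meth_diff", "p_value", "q_value", "is_dmc", "diff_class"]


def dmc_records_to_frame(records: Sequence[DmcRecord]) -> pd.DataFrame:
    df = pd.DataFrame([vars(r) for r in records], columns=_DMC_COLUMNS)
    return df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def write_dmc_table(records: Sequence[DmcRecord], path: str | Path) -> None:
    """Write tested cytosines as a TSV sorted by (chrom, pos)."""
    dmc_records_to_frame(records).to_csv(path, sep="\t", index=False)


def read_dmc_table(path: str | Path) -> list[DmcRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "diff_class": str})
    return [
        DmcRecord(
            chrom=row.chrom, pos=int(row.pos), strand=str(row.strand),
            mean_meth_g1=float(row.mean_meth_g1),
            mean_meth_g2=float(row.mean_meth_g2),
            abs_meth_diff=float(row.abs_meth_diff),
            p_value=float(row.p_value), q_value=float(row.q_value),
            is_dmc=bool(row.is_dmc), diff_class=str(row.diff_class),
        )
        for row in df.itertuples(index=False)
    ]
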