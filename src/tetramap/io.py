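"""Input/output containers and text formats for GBS read-depth data.

The central container is :class:`ReadCountMatrix`, a pair of aligned
markers x individuals pandas DataFrames holding per-allele read depths.
Two on-disk dialects are supported:

* a TSV with one row per marker, one column per individual, and each
  cell the string ``"xA,xB"``;
* a minimal VCF in which depths travel in the per-sample ``AD`` FORMAT
  field (read back through pysam).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ReadCountMatrix",
    "read_counts_tsv",
    "write_counts_tsv",
    "read_counts_vcf",
    "write_counts_vcf",
    "read_genotypes_tsv",
    "write_genotypes_tsv",
]


@dataclasses.dataclass
class ReadCountMatrix:
    """Per-marker, per-individual allele read depths for a biallelic SNP set.

    Attributes
    ----------
    x_a, x_b
        Integer DataFrames of identical shape; rows are marker ids,
        columns are individual ids. ``x_a`` counts reads supporting the
        alternate allele A, ``x_b`` the reference allele B.
    """

    x_a: pd.DataFrame
    x_b: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.x_a.index.equals(self.x_b.index) or not self.x_a.columns.equals(
            self.x_b.columns
        ):
            raise ValueError("x_a and x_b must share index and columns")
        if (self.x_a.to_numpy() < 0).any() or (self.x_b.to_numpy() < 0).any():
            raise ValueError("read counts must be non-negative")

    @property
    def markers(self) -> pd.Index:
        return self.x_a.index

    @property
    def individuals(self) -> pd.Index:
        return self.x_a.columns

    @property
    def total(self) -> pd.DataFrame:
        """Total depth N = x_a + x_b."""
        return self.x_a + self.x_b

    def subset_individuals(self, columns: Iterable[str]) -> "ReadCountMatrix":
        cols = list(columns)
        return ReadCountMatrix(self.x_a[cols].copy(), self.x_b[cols].copy())


def write_counts_tsv(reads: ReadCountMatrix, path: str | Path) -> None:
    """Write a ReadCountMatrix as a marker x individual TSV of "xA,xB" cells."""
    xa = reads.x_a.astype(int).astype(str)
    xb = reads.x_b.astype(int).astype(str)
    cells = xa + "," + xb
    cells.index.name = "marker"
    cells.to_csv(path, sep="\t")


def read_counts_tsv(path: str | Path) -> ReadCountMatrix:
    """Read the "xA,xB" TSV dialect produced by :func:`write_counts_tsv`."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    xa = df.map(lambda s: int(s.split(",")[0]))
    xb = df.map(lambda s: int(s.split(",")[1]))
    return ReadCountMatrix(xa, xb)


def write_counts_vcf(
    reads: ReadCountMatrix,
    path: str | Path,
    marker_info: pd.DataFrame | None = None,
) -> None:
    """Write a minimal VCF carrying depths in the AD FORMAT field.

    ``marker_info``, if given, must be indexed by marker id with columns
    ``chromosome`` and (optionally) ``cM``; genetic positions are scaled
    to integer bp-like coordinates for the POS column. Without it all
    markers go on a single placeholder contig in input order. Genotypes
    are emitted as ``./.`` — calling is downstream of this container.
    """
    markers = list(reads.markers)
    if marker_info is not None:
        chroms = [str(marker_info.loc[m, "chromosome"]) for m in markers]
        if "cM" in marker_info.columns:
            pos = [int(round(float(marker_info.loc[m, "cM"]) * 1e4)) + 1 for m in markers]
        else:
            pos = list(range(1, len(markers) + 1))
    else:
        chroms = ["un"] * len(markers)
        pos = list(range(1, len(markers) + 1))

    samples = list(reads.individuals)
    xa = reads.x_a.to_numpy(dtype=int)
    xb = reads.x_b.to_numpy(dtype=int)

    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=NS,Number=1,Type=Integer,Description="Number of samples">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description='
            '"Allelic depths (ref B first, alt A second)">\n'
        )
        for contig in dict.fromkeys(chroms):
            fh.write(f"##contig=<ID={contig}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for i, marker in enumerate(markers):
            cells = "\t".join(
                f"./.:{xb[i, j]},{xa[i, j]}" for j in range(len(samples))
            )
            fh.write(
                f"{chroms[i]}\t{pos[i]}\t{marker}\tC\tT\t.\t.\tNS={len(samples)}\tGT:AD\t{cells}\n"
            )


def read_counts_vcf(path: str | Path) -> ReadCountMatrix:
    """Read allele depths from the AD FORMAT field of a VCF.

    AD is interpreted as (ref, alt) = (x_b, x_a); multi-allelic records
    are rejected. Missing AD entries become zero depth.
    """
    import pysam

    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        markers: list[str] = []
        rows_a: list[list[int]] = []
        rows_b: list[list[int]] = []
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                raise ValueError(
                    f"record {rec.id or rec.pos}: expected exactly one ALT allele"
                )
            markers.append(rec.id if rec.id else f"{rec.chrom}_{rec.pos}")
            xa_row, xb_row = [], []
            for s in samples:
                ad = rec.samples[s].get("AD")
                if ad is None or ad[0] is None:
                    xb_row.append(0)
                    xa_row.append(0)
                else:
                    xb_row.append(int(ad[0]))
                    xa_row.append(int(ad[1]))
            rows_a.append(xa_row)
            rows_b.append(xb_row)
    xa = pd.DataFrame(rows_a, index=markers, columns=samples)
    xb = pd.DataFrame(rows_b, index=markers, columns=samples)
    return ReadCountMatrix(xa, xb)


def write_genotypes_tsv(calls: pd.DataFrame, path: str | Path) -> None:
    """Write a genotype-call matrix (values AA/BB/AB/NA) as TSV."""
    out = calls.copy()
    out.index.name = "marker"
    out.to_csv(path, sep="\t")


def read_genotypes_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    bad = set(np.unique(df.to_numpy())) - {"AA", "BB", "AB", "NA"}
    if bad:
        raise ValueError(f"unexpected genotype codes: {sorted(bad)}")
    return df
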