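"""Readers and writers for genotype matrices, genetic maps, and metadata.

Supported genotype formats:

* ``csv`` — rows are samples, columns are SNPs, cells in ``{0, 1, NA}``;
  the first column holds the sample id.
* ``vcf`` — plain-text VCF with a ``GT`` field; haploid calls (``0``/``1``)
  or homozygous diploid calls (``0/0``, ``1/1``) are accepted.  Heterozygous
  calls are set missing (inbred lines carry one haploid copy) and counted in
  a warning; non-biallelic sites are skipped with a warning.

The genetic map is a 3-column TSV ``snp_id, chrom, cm``; metadata is a CSV
with header ``sample_id, role, subpop_id, country, year, state``.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from haplopaint.data_model.types import (
    MISSING,
    GeneticMap,
    GenotypeMatrix,
    SampleMetadata,
    ValidationError,
)


class ParseError(ValueError):
    """Raised when an input file does not parse in the declared dialect."""


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def read_genotypes(path: str | Path, format: str = "csv") -> GenotypeMatrix:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "csv":
        return _read_genotypes_csv(path)
    if format == "vcf":
        return _read_genotypes_vcf(path)
    raise ValueError(f"unknown genotype format {format!r} (expected csv or vcf)")


def write_genotypes(
    g: GenotypeMatrix, path: str | Path, format: str = "csv"
) -> None:
    path = Path(path)
    if format == "csv":
        _write_genotypes_csv(g, path)
    elif format == "vcf":
        _write_genotypes_vcf(g, path)
    else:
        raise ValueError(f"unknown genotype format {format!r} (expected csv or vcf)")


def _read_genotypes_csv(path: Path) -> GenotypeMatrix:
    try:
        df = pd.read_csv(path, index_col=0, dtype=str)
    except Exception as exc:
        raise ParseError(f"{path}: not parseable as genotype CSV: {exc}") from exc
    calls = np.full(df.shape, MISSING, dtype=np.int8)
    values = df.to_numpy()
    for code, val in ((0, "0"), (1, "1")):
        calls[values == val] = code
    known = (values == "0") | (values == "1")
    na = pd.isna(values) | np.isin(values, ("NA", "na", "", "."))
    bad = ~known & ~na
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ParseError(
            f"{path}: line {i + 2}: invalid cell {values[i, j]!r} "
            f"for SNP {df.columns[j]!r} (expected 0/1/NA)"
        )
    return GenotypeMatrix(list(df.index.astype(str)), list(df.columns.astype(str)), calls)


def _write_genotypes_csv(g: GenotypeMatrix, path: Path) -> None:
    values = g.calls.astype(object)
    values[g.calls == MISSING] = "NA"
    df = pd.DataFrame(values, index=g.sample_ids, columns=g.snp_ids)
    df.index.name = "sample_id"
    df.to_csv(path)


def _read_genotypes_vcf(path: Path) -> GenotypeMatrix:
    try:
        vf = pysam.VariantFile(str(path))
    except Exception as exc:
        raise ParseError(f"{path}: not parseable as VCF: {exc}") from exc
    samples = list(vf.header.samples)
    snp_ids: list[str] = []
    rows: list[np.ndarray] = []
    n_het = 0
    n_skipped = 0
    for rec in vf.fetch() if vf.index is not None else vf:
        alts = rec.alts or ()
        if len(alts) != 1:
            n_skipped += 1
            continue
        row = np.full(len(samples), MISSING, dtype=np.int8)
        for i, s in enumerate(samples):
            alleles = rec.samples[s].get("GT", (None,))
            calls = {a for a in alleles if a is not None}
            if not calls:
                continue
            if len(calls) > 1:  # heterozygous: not representable haploid
                n_het += 1
                continue
            row[i] = calls.pop()
        snp_ids.append(rec.id if rec.id not in (None, ".") else f"{rec.chrom}:{rec.pos}")
        rows.append(row)
    vf.close()
    if n_skipped:
        warnings.warn(f"{path}: skipped {n_skipped} non-biallelic site(s)", stacklevel=2)
    if n_het:
        warnings.warn(
            f"{path}: set {n_het} heterozygous call(s) missing (haploid coding)",
            stacklevel=2,
        )
    calls = (
        np.stack(rows, axis=1) if rows else np.empty((len(samples), 0), dtype=np.int8)
    )
    return GenotypeMatrix([str(s) for s in samples], snp_ids, calls)


def _write_genotypes_vcf(g: GenotypeMatrix, path: Path) -> None:
    # Minimal haploid single-contig VCF; positions are sequential ranks.
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##contig=<ID=1>\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.sample_ids)
            + "\n"
        )
        code = {0: "0", 1: "1", MISSING: "."}
        for j, snp in enumerate(g.snp_ids):
            gts = "\t".join(code[int(c)] for c in g.calls[:, j])
            fh.write(f"1\t{j + 1}\t{snp}\tA\tT\t.\tPASS\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# map and metadata
# ---------------------------------------------------------------------------

def read_map(path: str | Path) -> GeneticMap:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "chrom": str})
    except Exception as exc:
        raise ParseError(f"{path}: not parseable as map TSV: {exc}") from exc
    required = {"snp_id", "chrom", "cm"}
    if not required.issubset(df.columns):
        raise ValidationError(
            f"{path}: map requires columns {sorted(required)}, got {list(df.columns)}"
        )
    return GeneticMap(df.set_index("snp_id"))


def write_map(gmap: GeneticMap, path: str | Path) -> None:
    out = gmap.table.reset_index()
    out.columns = ["snp_id", "chrom", "cm"]
    out.to_csv(path, sep="\t", index=False)


def read_metadata(path: str | Path) -> SampleMetadata:
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={"sample_id": str, "state": str, "country": str})
    except Exception as exc:
        raise ParseError(f"{path}: not parseable as metadata CSV: {exc}") from exc
    if "sample_id" not in df.columns or "role" not in df.columns:
        raise ValidationError(
            f"{path}: metadata requires columns sample_id and role"
        )
    return SampleMetadata(df.set_index("sample_id"))


def write_metadata(metadata: SampleMetadata, path: str | Path) -> None:
    out = metadata.table.reset_index()
    out = out.rename(columns={out.columns[0]: "sample_id"})
    out.to_csv(path, index=False)
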