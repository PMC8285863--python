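"""Readers and writers for the four input table formats.

GWAS summary statistics come in PLINK association-output style (CHR, BP,
SNP, P, BETA and optionally PHE for multi-phenotype files); cis-eQTL
summary statistics follow the GTEx portal export (SNP.Id, Gene.Symbol,
P.value, NES, Tissue, optional N); gene coordinates carry Gene, CHR,
Start, Stop, Build; pairwise LD follows PLINK ``--r2`` output (BP_A,
SNP_A, BP_B, SNP_B, R2, with CHR_A/CHR_B optional).

All readers sniff the delimiter (comma, tab, or whitespace) and match
header names case-insensitively with dots and underscores interchangeable,
since GTEx and PLINK dialects differ. Canonical in-memory form is a pandas
DataFrame with lower-case column names: ``chrom, bp, snp, p_gwas, beta``
for GWAS; ``snp, gene, p_eqtl, nes, tissue, n`` for eQTL; ``gene, chrom,
start, stop, build`` for genes; ``bp_a, snp_a, bp_b, snp_b, r2`` for LD.

Coordinates are 1-based inclusive throughout (PLINK/GTEx convention).
"""
from __future__ import annotations

import logging
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Set, Union

import numpy as np
import pandas as pd

from .errors import EmptyInputError, SchemaError, ValidationError

logger = logging.getLogger("eqtplot")

#: Floor applied to p-values of exactly zero so -log10 stays finite.
P_FLOOR = 1e-300

PathLike = Union[str, Path]

GWAS_COLUMNS = {"chr": "chrom", "bp": "bp", "snp": "snp", "p": "p_gwas",
                "beta": "beta", "phe": "phe"}
EQTL_COLUMNS = {"snp_id": "snp", "gene_symbol": "gene", "p_value": "p_eqtl",
                "nes": "nes", "tissue": "tissue", "n": "n"}
GENES_COLUMNS = {"gene": "gene", "chr": "chrom", "start": "start",
                 "stop": "stop", "build": "build"}
LD_COLUMNS = {"chr_a": "chr_a", "bp_a": "bp_a", "snp_a": "snp_a",
              "chr_b": "chr_b", "bp_b": "bp_b", "snp_b": "snp_b",
              "r2": "r2"}


def _sniff_sep(path: PathLike) -> str:
    with open(path) as fh:
        first = fh.readline()
    if "\t" in first:
        return "\t"
    if "," in first:
        return ","
    return r"\s+"


def _normalize(name: str) -> str:
    return name.strip().lower().replace(".", "_")


def _read_table(path: PathLike, colmap: dict, required: Iterable[str],
                kind: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"{kind} file not found: {path}")
    df = pd.read_csv(path, sep=_sniff_sep(path),
                     float_precision="round_trip")
    df.columns = [_normalize(c) for c in df.columns]
    df = df.rename(columns=colmap)
    keep = [c for c in colmap.values() if c in df.columns]
    df = df[keep]
    for col in required:
        if col not in df.columns:
            # report the column under its documented external header
            external = {v: k for k, v in colmap.items()}[col].upper()
            raise SchemaError(f"{kind} table is missing required column "
                              f"{external!r} ({path})")
    return df


def _clamp_p(df: pd.DataFrame, col: str, kind: str) -> pd.DataFrame:
    """Clamp p == 0 to P_FLOOR (warn); reject p outside [0, 1]."""
    bad = df[(df[col] < 0) | (df[col] > 1)]
    if len(bad):
        raise ValidationError(
            f"{kind}: {len(bad)} rows with p-value outside [0, 1] "
            f"(first offending value {bad[col].iloc[0]!r})")
    n_zero = int((df[col] == 0).sum())
    if n_zero:
        logger.warning("%s: clamped %d zero p-values to %.0e", kind, n_zero,
                       P_FLOOR)
        df = df.copy()
        df.loc[df[col] == 0, col] = P_FLOOR
    return df


def _drop_missing(df: pd.DataFrame, cols: list[str], kind: str) -> pd.DataFrame:
    """Drop rows with missing values in ``cols``; non-numeric text errors."""
    finite = np.ones(len(df), dtype=bool)
    for col in cols:
        values = df[col]
        if values.dtype == object:
            present = values.notna() & (values.astype(str).str.strip() != "")
            try:
                pd.to_numeric(values[present])
            except (TypeError, ValueError) as exc:
                raise SchemaError(
                    f"{kind}: column {col!r} contains non-numeric data: {exc}")
        finite &= np.isfinite(pd.to_numeric(df[col], errors="coerce"))
    n_drop = int((~finite).sum())
    if n_drop:
        logger.warning("%s: dropped %d rows with missing/non-finite %s",
                       kind, n_drop, "/".join(cols))
    return df.loc[finite]


def read_gwas(path: PathLike, trait: str) -> pd.DataFrame:
    """Read GWAS summary statistics, filtered to ``trait`` when PHE exists.

    Rows with missing or non-finite P or BETA are dropped with a logged
    count. The returned frame carries ``.attrs["trait"]``.
    """
    df = _read_table(path, GWAS_COLUMNS,
                     ["chrom", "bp", "snp", "p_gwas", "beta"], "GWAS")
    if "phe" in df.columns:
        df = df[df["phe"].astype(str) == trait].drop(columns="phe")
        if len(df) == 0:
            raise EmptyInputError(
                f"no GWAS rows remain after filtering to trait {trait!r}")
    df = _drop_missing(df, ["p_gwas", "beta"], "GWAS")
    df = df.astype({"chrom": "int64", "bp": "int64", "snp": str,
                    "p_gwas": float, "beta": float})
    _check(df["bp"].ge(1).all(), "GWAS: BP positions must be >= 1")
    _check(df["chrom"].gt(0).all(), "GWAS: CHR must be a positive integer")
    _check(df["snp"].str.len().gt(0).all(), "GWAS: empty SNP identifier")
    df = _clamp_p(df, "p_gwas", "GWAS")
    df = df.reset_index(drop=True)
    df.attrs["trait"] = trait
    return df


def read_eqtl(path: PathLike) -> pd.DataFrame:
    """Read cis-eQTL summary statistics; all tissues are retained.

    Duplicate (SNP, gene, tissue) rows are rejected. The optional N column
    (sample size, needed for meta-analysis collapsing) is kept when present.
    """
    df = _read_table(path, EQTL_COLUMNS,
                     ["snp", "gene", "p_eqtl", "nes", "tissue"], "eQTL")
    df = _drop_missing(df, ["p_eqtl", "nes"], "eQTL")
    try:
        df = df.astype({"snp": str, "gene": str, "p_eqtl": float,
                        "nes": float, "tissue": str})
    except (TypeError, ValueError) as exc:
        raise SchemaError(f"eQTL: non-numeric P.value/NES column: {exc}")
    if "n" in df.columns:
        n = pd.to_numeric(df["n"], errors="coerce")
        _check((n.isna() | (n >= 1)).all(), "eQTL: N must be a positive integer")
        df["n"] = n
    dup = df.duplicated(subset=["snp", "gene", "tissue"])
    if dup.any():
        first = df.loc[dup, ["snp", "gene", "tissue"]].iloc[0]
        raise ValidationError(
            "eQTL: duplicate (SNP, gene, tissue) rows; first offending "
            f"triple ({first['snp']}, {first['gene']}, {first['tissue']})")
    _check(df["gene"].str.len().gt(0).all(), "eQTL: empty gene symbol")
    _check(df["tissue"].str.len().gt(0).all(), "eQTL: empty tissue label")
    df = _clamp_p(df, "p_eqtl", "eQTL")
    return df.reset_index(drop=True)


def read_genes(path: Optional[PathLike] = None, gbuild: str = "hg19") -> pd.DataFrame:
    """Read gene coordinates filtered to the requested genome build.

    Without a path, a small bundled gene table is used (a subset of
    protein-coding genes for hg19 and hg38, sufficient for examples and
    tests; pass a full table for real analyses).
    """
    if gbuild not in ("hg19", "hg38"):
        raise ValidationError(f"gbuild must be hg19 or hg38, got {gbuild!r}")
    if path is None:
        with resources.as_file(
                resources.files("eqtplot.data") / "genes_default.tsv") as p:
            df = _read_table(p, GENES_COLUMNS,
                             ["gene", "chrom", "start", "stop", "build"],
                             "Genes")
    else:
        df = _read_table(path, GENES_COLUMNS,
                         ["gene", "chrom", "start", "stop", "build"], "Genes")
    df = df.astype({"gene": str, "chrom": "int64", "start": "int64",
                    "stop": "int64", "build": str})
    bad = df[df["start"] > df["stop"]]
    if len(bad):
        raise ValidationError(
            f"Genes: Start > Stop for gene {bad['gene'].iloc[0]!r}")
    dup = df.duplicated(subset=["gene", "build"])
    if dup.any():
        raise ValidationError(
            f"Genes: duplicate (gene, build) entry {df.loc[dup, 'gene'].iloc[0]!r}")
    df = df[df["build"] == gbuild].reset_index(drop=True)
    if len(df) == 0:
        raise EmptyInputError(f"gene table has no rows for build {gbuild!r}")
    return df


def read_ld(path: PathLike, gwas_snps: Set[str]) -> pd.DataFrame:
    """Read PLINK ``--r2``-style pairwise LD.

    Pairs with either endpoint absent from ``gwas_snps`` are dropped (only
    variants present in the GWAS table can carry LD information here), and
    symmetric duplicates (a,b)/(b,a) are deduplicated keeping the first.
    """
    df = _read_table(path, LD_COLUMNS,
                     ["bp_a", "snp_a", "bp_b", "snp_b", "r2"], "LD")
    df = df.astype({"bp_a": "int64", "snp_a": str, "bp_b": "int64",
                    "snp_b": str, "r2": float})
    if ((df["r2"] < 0) | (df["r2"] > 1)).any():
        bad = df.loc[(df["r2"] < 0) | (df["r2"] > 1), "r2"].iloc[0]
        raise ValidationError(f"LD: R2 value {bad} outside [0, 1]")
    _check((df["snp_a"] != df["snp_b"]).all(), "LD: self-pair (SNP_A == SNP_B)")
    n_before = len(df)
    df = df[df["snp_a"].isin(gwas_snps) & df["snp_b"].isin(gwas_snps)]
    n_drop = n_before - len(df)
    if n_drop:
        logger.info("LD: dropped %d pairs with an endpoint absent from the "
                    "GWAS table", n_drop)
    key = df.apply(lambda r: tuple(sorted((r["snp_a"], r["snp_b"]))), axis=1) \
        if len(df) else pd.Series([], dtype=object)
    df = df.loc[~key.duplicated()] if len(df) else df
    if len(df) == 0:
        logger.warning("LD: no pairs remain after GWAS-variant restriction; "
                        "LD panels will be disabled")
    return df[["bp_a", "snp_a", "bp_b", "snp_b", "r2"]].reset_index(drop=True)


def _check(cond: bool, message: str) -> None:
    if not bool(cond):
        raise ValidationError(message)


# ---------------------------------------------------------------------------
# canonical TSV writers (headers in the documented external dialects)

def write_gwas(df: pd.DataFrame, path: PathLike, trait: Optional[str] = None) -> None:
    out = df.rename(columns={"chrom": "CHR", "bp": "BP", "snp": "SNP",
                             "p_gwas": "P", "beta": "BETA", "phe": "PHE"})
    out.to_csv(path, sep="\t", index=False)


def write_eqtl(df: pd.DataFrame, path: PathLike) -> None:
    out = df.rename(columns={"snp": "SNP.Id", "gene": "Gene.Symbol",
                             "p_eqtl": "P.value", "nes": "NES",
                             "tissue": "Tissue", "n": "N"})
    out.to_csv(path, sep="\t", index=False)


def write_genes(df: pd.DataFrame, path: PathLike) -> None:
    out = df.rename(columns={"gene": "Gene", "chrom": "CHR", "start": "Start",
                             "stop": "Stop", "build": "Build"})
    out.to_csv(path, sep="\t", index=False)


def write_ld(df: pd.DataFrame, path: PathLike) -> None:
    out = df.rename(columns={"bp_a": "BP_A", "snp_a": "SNP_A",
                             "bp_b": "BP_B", "snp_b": "SNP_B", "r2": "R2"})
    out.to_csv(path, sep="\t", index=False)
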