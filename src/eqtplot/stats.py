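"""Colocalization statistics: enrichment, P-P correlation, rankings.

Two summary statistics quantify colocalization at a locus. The enrichment
test asks whether trait-significant variants are enriched for eQTLs of the
candidate gene, via a two-sided Fisher exact test on the 2x2 table of
(GWAS-significant vs not) x (eQTL vs not). The P-P correlation measures
how the two significance profiles track each other across variants: a
Pearson correlation of ``-log10 p_eqtl`` against ``-log10 p_gwas``,
together with a least-squares line for display. The log scale is what the
scatter axes use, and correlating the raw probabilities would be dominated
by the mass of near-1 p-values.

Gene and tissue rankings repeat the P-P correlation across a list of
candidate genes (with tissue collapsing) or across individual tissues (no
collapsing) and order results by significance of the correlation.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import AnalysisConfig
from .errors import UnknownGeneError, ValidationError
from .locus import (CONGRUOUS, INCONGRUOUS, build_locus_table,
                    collapse_tissues, define_locus)

logger = logging.getLogger("eqtplot")


@dataclass(frozen=True)
class EnrichmentResult:
    """2x2 Fisher summary of eQTL enrichment among GWAS-significant variants.

    ``a``: GWAS-significant eQTLs, ``b``: GWAS-significant non-eQTLs,
    ``c``: non-significant eQTLs, ``d``: non-significant non-eQTLs.
    """

    a: int
    b: int
    c: int
    d: int
    fisher_p: float
    stratum: str = "all"
    degenerate: bool = False

    @property
    def proportion_sig(self) -> float:
        return self.a / (self.a + self.b) if (self.a + self.b) else float("nan")

    @property
    def proportion_nonsig(self) -> float:
        return self.c / (self.c + self.d) if (self.c + self.d) else float("nan")


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson summary of the P-P relationship on -log10 coordinates."""

    n_points: int
    pearson_r: float
    p_correlation: float
    slope: float
    intercept: float
    stratum: str = "all"

    @property
    def defined(self) -> bool:
        return self.n_points >= 3 and np.isfinite(self.pearson_r)


@dataclass(frozen=True)
class RankingEntry:
    key: str
    pearson_r: float
    p_correlation: float
    n_points: int

    @property
    def defined(self) -> bool:
        return np.isfinite(self.p_correlation)

    def format(self, label: str) -> str:
        if not self.defined:
            return (f"eQTL analysis for {label} {self.key}: insufficient "
                    f"data ({self.n_points} qualifying variants)")
        return (f"eQTL analysis for {label} {self.key}: Pearson correlation: "
                f"{self.pearson_r:.3g}, p-value: {self.p_correlation:.3g}")


def _stratum_mask(locus_table: pd.DataFrame, stratum: str) -> pd.DataFrame:
    """Restrict eQTL status to one congruence class.

    eQTLs of the *other* class are excluded from consideration; non-eQTL
    variants are unchanged and remain the comparison group.
    """
    if stratum == "all":
        return locus_table
    if stratum not in (CONGRUOUS, INCONGRUOUS):
        raise ValidationError(f"unknown stratum {stratum!r}")
    keep = (~locus_table["has_eqtl"]) \
        | (locus_table["congruence_class"] == stratum)
    return locus_table[keep]


def enrichment_test(locus_table: pd.DataFrame,
                    stratum: str = "all") -> EnrichmentResult:
    """Two-sided Fisher exact test for eQTL enrichment among significant hits.

    With an empty margin (no GWAS-significant variants, or none
    non-significant) the test is undefined; the result is flagged
    degenerate with p reported as 1.
    """
    sub = _stratum_mask(locus_table, stratum)
    sig = sub["gwas_significant"].to_numpy(bool)
    eqtl = sub["has_eqtl"].to_numpy(bool)
    a = int(np.sum(sig & eqtl))
    b = int(np.sum(sig & ~eqtl))
    c = int(np.sum(~sig & eqtl))
    d = int(np.sum(~sig & ~eqtl))
    if (a + b) == 0 or (c + d) == 0:
        logger.warning("enrichment (%s): empty margin (a+b=%d, c+d=%d); "
                       "test degenerate, p = 1", stratum, a + b, c + d)
        return EnrichmentResult(a, b, c, d, 1.0, stratum, degenerate=True)
    _, p = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return EnrichmentResult(a, b, c, d, float(p), stratum)


def pp_points(locus_table: pd.DataFrame, stratum: str = "all") -> pd.DataFrame:
    """Qualifying eQTL variants as P-P coordinates.

    Returns columns ``snp, x, y`` with ``x = -log10 p_eqtl`` and
    ``y = -log10 p_gwas``. Variants failing the eQTL significance
    threshold never reach this table (they carry ``has_eqtl = False``).
    """
    sub = locus_table[locus_table["has_eqtl"]]
    if stratum != "all":
        sub = sub[sub["congruence_class"] == stratum]
    return pd.DataFrame({
        "snp": sub["snp"].to_numpy(),
        "x": -np.log10(sub["p_eqtl"].to_numpy(float)),
        "y": -np.log10(sub["p_gwas"].to_numpy(float)),
    })


def pp_correlation(locus_table: pd.DataFrame,
                   stratum: str = "all") -> CorrelationResult:
    """Pearson r, its p-value, and the best-fit line on P-P coordinates.

    Fewer than 3 qualifying points (or zero variance on an axis) yields an
    undefined, flagged result rather than an exception.
    """
    pts = pp_points(locus_table, stratum)
    n = len(pts)
    if n < 3 or pts["x"].nunique() < 2 or pts["y"].nunique() < 2:
        logger.warning("P-P correlation (%s): only %d qualifying points; "
                       "correlation undefined", stratum, n)
        return CorrelationResult(n, float("nan"), float("nan"),
                                 float("nan"), float("nan"), stratum)
    r, p = sps.pearsonr(pts["x"], pts["y"])
    slope, intercept = np.polyfit(pts["x"], pts["y"], 1)
    return CorrelationResult(n, float(r), float(p), float(slope),
                             float(intercept), stratum)


def select_lead_variant(pp: pd.DataFrame,
                        user_lead: Optional[str] = None,
                        gwas_snps: Optional[set] = None,
                        ld_snps: Optional[set] = None) -> str:
    """Pick the lead variant for LD coloring of the P-P plot.

    A user-specified lead must appear in both the GWAS and LD tables.
    Otherwise the lead is the upper-right-most point — the variant
    maximizing ``x + y`` (ties: larger y, then lexicographic SNP id).
    """
    if user_lead is not None:
        if gwas_snps is not None and user_lead not in gwas_snps:
            raise ValidationError(
                f"lead SNP {user_lead!r} absent from the GWAS table")
        if ld_snps is not None and user_lead not in ld_snps:
            raise ValidationError(
                f"lead SNP {user_lead!r} absent from the LD table")
        return user_lead
    if len(pp) == 0:
        raise ValidationError("cannot select a lead variant from zero points")
    ranked = pp.assign(_sum=pp["x"] + pp["y"]).sort_values(
        ["_sum", "y", "snp"], ascending=[False, False, True],
        kind="mergesort")
    return str(ranked["snp"].iloc[0])


def _sort_rankings(entries: list[RankingEntry]) -> list[RankingEntry]:
    # ascending p; undefined entries last; ties: |r| descending, then name
    return sorted(entries, key=lambda e: (
        not e.defined,
        e.p_correlation if e.defined else float("inf"),
        -(abs(e.pearson_r) if e.defined else 0.0),
        e.key))


def rank_genes(gwas: pd.DataFrame, eqtl: pd.DataFrame,
               gene_list: Sequence[str], genes_table: pd.DataFrame,
               config: AnalysisConfig) -> list[RankingEntry]:
    """P-P correlation across candidate genes, ordered by significance.

    For each gene the locus is defined, eQTL data for that gene is
    collapsed per the configured tissue selector and method, and the
    correlation (all variants, no congruence split) is computed. Genes
    with too few qualifying variants are flagged and placed last.
    """
    missing = [g for g in gene_list if g not in set(genes_table["gene"])]
    if missing:
        raise UnknownGeneError(f"gene(s) {missing} not in the gene table")
    entries = []
    for gene in gene_list:
        locus = define_locus(gene, genes_table, config.range_kb)
        collapsed = collapse_tissues(eqtl[eqtl["gene"] == gene],
                                     config.tissue, config.collapse_method,
                                     config.assume_equal_n)
        table = build_locus_table(gwas, collapsed, locus, config)
        res = pp_correlation(table, "all")
        entries.append(RankingEntry(gene, res.pearson_r, res.p_correlation,
                                    res.n_points))
    return _sort_rankings(entries)


def rank_tissues(gwas: pd.DataFrame, eqtl: pd.DataFrame, gene: str,
                 tissue_list: Union[str, Sequence[str]],
                 genes_table: pd.DataFrame,
                 config: AnalysisConfig) -> list[RankingEntry]:
    """P-P correlation across tissues for one gene, ordered by significance.

    ``"all"`` considers every tissue present in the eQTL table. No
    collapsing: each tissue is analyzed on its own records.
    """
    locus = define_locus(gene, genes_table, config.range_kb)
    gene_eqtl = eqtl[eqtl["gene"] == gene]
    if isinstance(tissue_list, str) and tissue_list == "all":
        tissues = sorted(gene_eqtl["tissue"].unique())
    elif isinstance(tissue_list, str):
        tissues = [tissue_list]
    else:
        tissues = list(tissue_list)
    entries = []
    for tissue in tissues:
        collapsed = collapse_tissues(gene_eqtl, tissue, "min")
        table = build_locus_table(gwas, collapsed, locus, config)
        res = pp_correlation(table, "all")
        entries.append(RankingEntry(tissue, res.pearson_r, res.p_correlation,
                                    res.n_points))
    return _sort_rankings(entries)


def rankings_to_frame(entries: Sequence[RankingEntry],
                      key_name: str) -> pd.DataFrame:
    """Tabular (TSV-writable) form of a ranking."""
    return pd.DataFrame({
        key_name: [e.key for e in entries],
        "pearson_r": [e.pearson_r for e in entries],
        "p_correlation": [e.p_correlation for e in entries],
        "n_points": [e.n_points for e in entries],
    })
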