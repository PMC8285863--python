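"""Locus definition, tissue collapsing, congruence, and the variant table.

The locus of interest (LOI) is the candidate gene's coordinates extended by
a flanking window on either side. Within it, GWAS variants are joined with
the gene's (possibly tissue-collapsed) cis-eQTL records into one row per
variant — the unit every downstream statistic and panel consumes.

Tissue collapsing turns a multi-tissue eQTL table into one record per
variant. ``min`` keeps the p-value and effect size of the single most
significant tissue (a PanTissue/MultiTissue view of the strongest effect,
agnostic of tissue); ``median``/``mean`` summarize p and NES element-wise;
``meta`` combines p-values across tissues with a sample-size-weighted
Z-test (Stouffer), in which case no combined NES is defined.

Direction-of-effect congruence compares the sign of the GWAS effect (beta)
with the sign of the eQTL effect (NES): a variant associated with increased
expression *and* an increase in the trait is congruous; opposite nonzero
signs are incongruous. Either effect being exactly zero leaves the class
undefined (``not_applicable``).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .config import AnalysisConfig
from .errors import (EmptyInputError, MetaSampleSizeError, UnknownGeneError,
                     UnknownTissueError, ValidationError)

logger = logging.getLogger("eqtplot")

CONGRUOUS = "congruous"
INCONGRUOUS = "incongruous"
NOT_APPLICABLE = "not_applicable"


@dataclass(frozen=True)
class Locus:
    """The analysis window: gene bounds extended by ``range_kb`` kilobases."""

    gene: str
    chrom: int
    start_bp: int
    stop_bp: int

    def contains(self, bp) -> "np.ndarray":
        """1-based inclusive membership test."""
        return (np.asarray(bp) >= self.start_bp) & (np.asarray(bp) <= self.stop_bp)


def define_locus(gene: str, genes_table: pd.DataFrame,
                 range_kb: float = 200.0) -> Locus:
    """Locate ``gene`` in the coordinate table and extend by the flank.

    The lower bound is floored at position 1.
    """
    hit = genes_table[genes_table["gene"] == gene]
    if len(hit) == 0:
        available = sorted(genes_table["gene"].unique())
        lo = max(0, np.searchsorted(available, gene) - 3)
        nearby = ", ".join(available[lo:lo + 6])
        raise UnknownGeneError(
            f"gene {gene!r} not found in the gene table for this build; "
            f"alphabetically nearby symbols: {nearby}")
    row = hit.iloc[0]
    flank = int(round(range_kb * 1000))
    return Locus(gene=gene, chrom=int(row["chrom"]),
                 start_bp=max(1, int(row["start"]) - flank),
                 stop_bp=int(row["stop"]) + flank)


def weighted_z_meta(p_values: Sequence[float], nes_signs: Sequence[float],
                    sample_sizes: Optional[Sequence[float]] = None,
                    assume_equal_n: bool = False) -> float:
    """Sample-size-weighted Z-test (Stouffer) combining two-sided p-values.

    Each study contributes a signed Z, ``z_i = sign(nes_i) *
    Phi^-1(1 - p_i / 2)``, weighted by ``w_i = sqrt(n_i)``; the combined
    statistic is ``Z = sum(w_i z_i) / sqrt(sum(w_i^2))`` and the returned
    p-value is ``2 * (1 - Phi(|Z|))``. Signing by the effect direction
    means studies with opposite directions cancel rather than reinforce.
    """
    p = np.asarray(p_values, dtype=float)
    signs = np.sign(np.asarray(nes_signs, dtype=float))
    if np.any((p <= 0) | (p > 1)):
        raise ValidationError("meta-analysis p-values must lie in (0, 1]")
    if sample_sizes is None or np.any(~np.isfinite(
            np.asarray(sample_sizes, dtype=float))):
        if not assume_equal_n:
            raise MetaSampleSizeError(
                "meta collapse requires a sample size (N) for every eQTL "
                "record; pass assume_equal_n=True to treat all tissues as "
                "equally sized")
        n = np.ones_like(p)
    else:
        n = np.asarray(sample_sizes, dtype=float)
    w = np.sqrt(n)
    z = signs * stats.norm.isf(p / 2.0)
    Z = float(np.sum(w * z) / np.sqrt(np.sum(w * w)))
    return float(min(1.0, 2.0 * stats.norm.sf(abs(Z))))


def classify_congruence(beta: float, nes: float) -> str:
    """Direction-of-effect class for one variant (see module docstring)."""
    if not (np.isfinite(beta) and np.isfinite(nes)):
        raise ValidationError("classify_congruence requires finite beta and NES")
    prod = beta * nes
    if prod > 0:
        return CONGRUOUS
    if prod < 0:
        return INCONGRUOUS
    return NOT_APPLICABLE


def _select_tissues(eqtl: pd.DataFrame,
                    tissue: Union[str, Sequence[str]]) -> pd.DataFrame:
    if isinstance(tissue, str):
        names = None if tissue == "all" else [tissue]
    else:
        names = list(tissue)
    if names is None:
        return eqtl
    present = set(eqtl["tissue"].unique())
    missing = [t for t in names if t not in present]
    if missing:
        raise UnknownTissueError(
            f"tissue(s) {missing} not present in the eQTL table; available: "
            f"{sorted(present)}")
    return eqtl[eqtl["tissue"].isin(names)]


def collapse_tissues(eqtl: pd.DataFrame,
                     tissue: Union[str, Sequence[str]] = "all",
                     method: str = "min",
                     assume_equal_n: bool = False) -> pd.DataFrame:
    """Collapse a single gene's eQTL records to one row per variant.

    Returns columns ``snp, p_eqtl, nes, source_tissue, method``; under
    ``meta`` the NES column is NaN and ``source_tissue`` is ``"combined"``.
    Only tissues with a record for a given variant enter its summary.
    """
    if method not in ("min", "median", "mean", "meta"):
        raise ValidationError(f"unknown collapse method {method!r}")
    sub = _select_tissues(eqtl, tissue)
    if len(sub) == 0:
        return pd.DataFrame(columns=["snp", "p_eqtl", "nes", "source_tissue",
                                     "method"])
    if method == "min":
        # smallest p; ties broken by larger |NES|, then tissue name
        ranked = sub.assign(_absnes=sub["nes"].abs()).sort_values(
            ["snp", "p_eqtl", "_absnes", "tissue"],
            ascending=[True, True, False, True], kind="mergesort")
        out = ranked.groupby("snp", as_index=False).first()
        out = out.rename(columns={"tissue": "source_tissue"})
        out = out[["snp", "p_eqtl", "nes", "source_tissue"]]
    elif method in ("median", "mean"):
        agg = sub.groupby("snp", as_index=False).agg(
            p_eqtl=("p_eqtl", method), nes=("nes", method))
        agg["source_tissue"] = "combined"
        out = agg
    else:  # meta
        if "n" not in sub.columns and not assume_equal_n:
            raise MetaSampleSizeError(
                "meta collapse requires an N column in the eQTL table; "
                "pass assume_equal_n=True to assume equal sample sizes")
        records = []
        for snp, grp in sub.groupby("snp"):
            n = grp["n"].to_numpy(float) if "n" in grp.columns else None
            p = weighted_z_meta(grp["p_eqtl"].to_numpy(),
                                grp["nes"].to_numpy(), n,
                                assume_equal_n=assume_equal_n)
            records.append((snp, p))
        out = pd.DataFrame(records, columns=["snp", "p_eqtl"])
        out["nes"] = np.nan
        out["source_tissue"] = "combined"
    out["method"] = method
    return out.sort_values("snp", kind="mergesort").reset_index(drop=True)


def build_locus_table(gwas: pd.DataFrame, collapsed_eqtl: pd.DataFrame,
                      locus: Locus, config: AnalysisConfig) -> pd.DataFrame:
    """Join GWAS variants in the locus with collapsed eQTL annotation.

    Every GWAS variant inside the locus appears exactly once. A variant is
    an eQTL for the gene (``has_eqtl``) when a record matched by SNP id
    exists and its p-value passes ``sigpvalue_eqtl`` (<=); GWAS
    significance uses strict ``<`` on ``sigpvalue_gwas``. In congruence
    mode each qualifying eQTL variant carries a direction-of-effect class.
    """
    inside = gwas[(gwas["chrom"] == locus.chrom)
                  & locus.contains(gwas["bp"].to_numpy())]
    if len(inside) == 0:
        raise EmptyInputError(
            f"no GWAS variants fall inside the locus {locus.gene} "
            f"(chr{locus.chrom}:{locus.start_bp}-{locus.stop_bp})")
    cols = collapsed_eqtl[["snp", "p_eqtl", "nes"]] if len(collapsed_eqtl) \
        else pd.DataFrame(columns=["snp", "p_eqtl", "nes"])
    merged = inside.merge(cols, on="snp", how="left", validate="one_to_one")
    merged["has_eqtl"] = merged["p_eqtl"].notna() \
        & (merged["p_eqtl"] <= config.sigpvalue_eqtl)
    merged.loc[~merged["has_eqtl"], ["p_eqtl", "nes"]] = np.nan
    merged["gwas_significant"] = merged["p_gwas"] < config.sigpvalue_gwas

    classes = np.full(len(merged), NOT_APPLICABLE, dtype=object)
    if config.congruence:
        n_zero = 0
        for i, (ok, beta, nes) in enumerate(zip(
                merged["has_eqtl"], merged["beta"], merged["nes"])):
            if ok and np.isfinite(nes):
                cls = classify_congruence(beta, nes)
                classes[i] = cls
                n_zero += cls == NOT_APPLICABLE
        if n_zero:
            logger.warning("congruence: %d eQTL variants with beta*NES == 0 "
                           "excluded from the congruous/incongruous split",
                           n_zero)
    merged["congruence_class"] = classes
    return merged.sort_values("bp", kind="mergesort").reset_index(drop=True)


def export_locus_table(locus_table: pd.DataFrame, path) -> None:
    """Write the per-variant analysis table as TSV (documented columns)."""
    locus_table.to_csv(path, sep="\t", index=False)
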