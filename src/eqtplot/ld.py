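"""Locus LD filtering, heatmap variant selection, and the R^2 matrix.

Pairwise LD (squared genotype correlation, as produced by PLINK ``--r2``)
is consumed, never computed. Heatmap variants are chosen in two steps:
pairs are restricted to qualifying eQTL variants inside the locus with
``r2 > r2min`` (strict), then variants must be in LD with at least
``ldmin`` other variants to be drawn — a degree filter that thins dense
loci down to the most informative variants.

Unobserved pairs are treated as R^2 = 0 throughout (both in the matrix
and in lead-variant coloring), which is the natural reading of a PLINK
output that omits pairs below its reporting threshold.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

logger = logging.getLogger("eqtplot")


@dataclass
class LdContext:
    """Filtered variant set and symmetric R^2 matrix for the heatmap."""

    kept_variants: List[str]          # ordered by bp
    positions: List[int]              # bp of each kept variant
    r2_matrix: np.ndarray             # symmetric, unit diagonal
    lead_snp: Optional[str] = None
    lead_r2: Dict[str, float] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.kept_variants)


def filter_ld_pairs(ld_pairs: pd.DataFrame,
                    locus_eqtl_variants: Sequence[str],
                    r2min: float = 0.1) -> pd.DataFrame:
    """Pairs with both endpoints among the locus eQTL variants and r2 > r2min."""
    if not (0 <= r2min <= 1):
        raise ValidationError("r2min must lie in [0, 1]")
    allowed = set(locus_eqtl_variants)
    keep = (ld_pairs["snp_a"].isin(allowed)
            & ld_pairs["snp_b"].isin(allowed)
            & (ld_pairs["r2"] > r2min))
    return ld_pairs[keep].reset_index(drop=True)


def degree_filter(filtered_pairs: pd.DataFrame,
                  locus_eqtl_variants: Sequence[str],
                  ldmin: int = 10) -> List[str]:
    """Variants in LD with at least ``ldmin`` others (degree in the pair graph).

    Variants incident to no retained pair have degree 0, so they pass only
    when ``ldmin == 0``.
    """
    if ldmin < 0:
        raise ValidationError("ldmin must be >= 0")
    degree = {v: 0 for v in locus_eqtl_variants}
    for a, b in zip(filtered_pairs["snp_a"], filtered_pairs["snp_b"]):
        if a in degree:
            degree[a] += 1
        if b in degree:
            degree[b] += 1
    return [v for v in locus_eqtl_variants if degree[v] >= ldmin]


def build_r2_matrix(kept_variants: Sequence[str],
                    positions: Dict[str, int],
                    filtered_pairs: pd.DataFrame) -> LdContext:
    """Symmetric R^2 matrix over the kept variants, ordered by position.

    Unit diagonal; unobserved pairs are 0. Conflicting duplicate R^2
    values for one pair raise an error.
    """
    if len(kept_variants) == 0:
        raise ValidationError("cannot build an R^2 matrix over zero variants")
    order = sorted(kept_variants, key=lambda v: (positions[v], v))
    idx = {v: i for i, v in enumerate(order)}
    n = len(order)
    mat = np.zeros((n, n))
    np.fill_diagonal(mat, 1.0)
    seen: Dict[tuple, float] = {}
    for a, b, r2 in zip(filtered_pairs["snp_a"], filtered_pairs["snp_b"],
                        filtered_pairs["r2"]):
        if a not in idx or b not in idx:
            continue
        key = tuple(sorted((a, b)))
        if key in seen and not np.isclose(seen[key], r2):
            raise ValidationError(
                f"conflicting R^2 values for pair {key}: {seen[key]} vs {r2}")
        seen[key] = float(r2)
        i, j = idx[a], idx[b]
        mat[i, j] = mat[j, i] = float(r2)
    return LdContext(kept_variants=order,
                     positions=[int(positions[v]) for v in order],
                     r2_matrix=mat)


def lead_r2_annotation(ld_pairs: pd.DataFrame, lead_snp: str,
                       pp_variants: Sequence[str]) -> Dict[str, float]:
    """R^2 with the lead variant for every P-P point (lead -> 1, absent -> 0)."""
    r2 = {v: 0.0 for v in pp_variants}
    for a, b, val in zip(ld_pairs["snp_a"], ld_pairs["snp_b"],
                         ld_pairs["r2"]):
        other = b if a == lead_snp else (a if b == lead_snp else None)
        if other is not None and other in r2:
            r2[other] = max(r2[other], float(val))
    r2[lead_snp] = 1.0
    return r2


def build_ld_context(ld_pairs: pd.DataFrame, locus_table: pd.DataFrame,
                     r2min: float = 0.1, ldmin: int = 10) -> Optional[LdContext]:
    """Full LD pipeline for one locus; None when nothing survives filtering.

    Consumes the per-variant locus table to identify qualifying eQTL
    variants and their positions. Degree counting uses the
    locus-restricted, r2-thresholded pair set.
    """
    eqtl_variants = locus_table.loc[locus_table["has_eqtl"], "snp"].tolist()
    positions = dict(zip(locus_table["snp"], locus_table["bp"].astype(int)))
    pairs = filter_ld_pairs(ld_pairs, eqtl_variants, r2min)
    kept = degree_filter(pairs, eqtl_variants, ldmin)
    if len(kept) < 2:
        logger.warning("LD: %d variant(s) survive r2min=%.3g / ldmin=%d "
                       "filtering; LD heatmap disabled", len(kept), r2min,
                       ldmin)
        return None
    return build_r2_matrix(kept, positions, pairs)
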