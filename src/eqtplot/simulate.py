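"""Synthetic loci with block LD structure and shared or distinct causal variants.

The generator emulates the statistical structure the analysis assumes: a
locus of equally spaced variants organized into LD blocks with AR(1)
correlation decay (genotype correlation ``rho^|i-j|`` within a block, zero
across blocks), a single causal variant for the trait and a single causal
variant per gene-expression signal. Summary statistics follow the standard
single-causal-variant approximation: the expected Z-score of every variant
is the causal Z attenuated by its genotype correlation with the causal
variant, plus unit normal noise. Effect sizes are recovered as
``z / sqrt(N)``, giving GTEx-like NES magnitudes (O(0.1-1)) at eQTL sample
sizes of a few hundred and UK-Biobank-scale betas for the trait.

When ``shared_causal`` is true the expression and trait signals are driven
by the same variant (colocalization); otherwise the expression causal
variant sits in a different LD block, producing overlapping but
non-colocalizing signals. Pairwise LD is emitted as ``r^2 = rho^(2|i-j|)``
for within-block pairs.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from . import io as tables_io

#: GTEx-like default tissue panel with sample sizes.
DEFAULT_TISSUES = {"Whole_Blood": 670, "Liver": 208, "Adipose_Subcutaneous": 581}


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of the synthetic locus (see module docstring for the model)."""

    n_variants: int = 300
    n_blocks: int = 3
    rho: float = 0.9                      # within-block AR(1) correlation
    lambda_g: float = 12.0                # causal GWAS Z-score
    lambda_e: float = 10.0                # causal eQTL Z-score
    shared_causal: bool = True
    eqtl_sign: int = 1                    # sign of the causal eQTL effect
    tissues: Dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_TISSUES))
    gwas_n: int = 300000
    gene: str = "GENE1"
    trait: str = "TRAIT"
    chrom: int = 11
    start_bp: int = 66_000_000
    spacing_bp: int = 1000
    build: str = "hg19"
    r2_floor: float = 0.01                # LD pairs below this are not emitted
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.rho < 1):
            raise ValueError("rho must lie in (0, 1)")
        if self.lambda_g < 0 or self.lambda_e < 0:
            raise ValueError("signal strengths must be >= 0")
        if self.n_blocks < 1 or self.n_variants < self.n_blocks:
            raise ValueError("need at least one variant per block")


def _block_index(params: SimulationParams) -> np.ndarray:
    return np.arange(params.n_variants) * params.n_blocks // params.n_variants


def _correlation_to(params: SimulationParams, causal: int) -> np.ndarray:
    """Genotype correlation of every variant with the causal variant."""
    blocks = _block_index(params)
    i = np.arange(params.n_variants)
    r = np.where(blocks == blocks[causal],
                 params.rho ** np.abs(i - causal), 0.0)
    return r


def _causal_indices(params: SimulationParams) -> Tuple[int, int]:
    blocks = _block_index(params)
    centers = [int(np.flatnonzero(blocks == b).mean())
               for b in range(params.n_blocks)]
    central = params.n_blocks // 2
    causal_g = centers[central]
    causal_e = causal_g if params.shared_causal else centers[0]
    return causal_g, causal_e


def _two_sided_p(z: np.ndarray) -> np.ndarray:
    return np.clip(2.0 * stats.norm.sf(np.abs(z)), tables_io.P_FLOOR, 1.0)


def simulate_locus(params: SimulationParams
                   ) -> Tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame,
                              pd.DataFrame]:
    """Generate (gwas, eqtl, genes, ld_pairs) tables for one synthetic locus.

    Deterministic for a fixed seed: identical params yield identical
    tables. The gene record spans the central LD block.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_variants
    bp = params.start_bp + params.spacing_bp * np.arange(n)
    snp = np.array([f"rs{params.start_bp // 1000 + i:d}_{i:04d}"
                    for i in range(n)])
    blocks = _block_index(params)
    causal_g, causal_e = _causal_indices(params)

    z_g = params.lambda_g * _correlation_to(params, causal_g) \
        + rng.standard_normal(n)
    gwas = pd.DataFrame({
        "chrom": params.chrom, "bp": bp, "snp": snp,
        "p_gwas": _two_sided_p(z_g),
        "beta": z_g / np.sqrt(params.gwas_n),
    })
    gwas.attrs["trait"] = params.trait

    r_e = _correlation_to(params, causal_e)
    frames = []
    for tissue, n_samples in params.tissues.items():
        z_t = params.eqtl_sign * params.lambda_e * r_e \
            + rng.standard_normal(n)
        frames.append(pd.DataFrame({
            "snp": snp, "gene": params.gene,
            "p_eqtl": _two_sided_p(z_t),
            "nes": z_t / np.sqrt(n_samples),
            "tissue": tissue, "n": n_samples,
        }))
    eqtl = pd.concat(frames, ignore_index=True)

    central = params.n_blocks // 2
    in_central = np.flatnonzero(blocks == central)
    genes = pd.DataFrame({
        "gene": [params.gene], "chrom": [params.chrom],
        "start": [int(bp[in_central[0]])], "stop": [int(bp[in_central[-1]])],
        "build": [params.build],
    })

    ld = _emit_ld_pairs(params, bp, snp, blocks)
    return gwas, eqtl, genes, ld


def _emit_ld_pairs(params: SimulationParams, bp: np.ndarray, snp: np.ndarray,
                   blocks: np.ndarray) -> pd.DataFrame:
    rows = []
    r2_decay = params.rho ** 2
    # max distance at which r2 still clears the floor
    max_d = int(np.floor(np.log(params.r2_floor) / np.log(r2_decay))) \
        if params.r2_floor > 0 else params.n_variants
    for i in range(params.n_variants):
        for j in range(i + 1, min(i + max_d + 1, params.n_variants)):
            if blocks[i] != blocks[j]:
                break
            r2 = r2_decay ** (j - i)
            if r2 >= params.r2_floor:
                rows.append((int(bp[i]), snp[i], int(bp[j]), snp[j], r2))
    return pd.DataFrame(rows, columns=["bp_a", "snp_a", "bp_b", "snp_b",
                                       "r2"])


def write_fixture_set(tables: Tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame,
                                    pd.DataFrame],
                      out_dir, params: Optional[SimulationParams] = None,
                      include_ld: bool = True) -> Dict[str, Path]:
    """Write the four tables in the exact dialects the readers accept.

    Returns the mapping of table name to path. The LD file is omitted when
    ``include_ld`` is false or the LD table is empty; a params manifest is
    written when ``params`` is given.
    """
    gwas, eqtl, genes, ld = tables
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, Path] = {}
    tables_io.write_gwas(gwas, out_dir / "gwas.tsv")
    paths["gwas"] = out_dir / "gwas.tsv"
    tables_io.write_eqtl(eqtl, out_dir / "eqtl.tsv")
    paths["eqtl"] = out_dir / "eqtl.tsv"
    tables_io.write_genes(genes, out_dir / "genes.tsv")
    paths["genes"] = out_dir / "genes.tsv"
    if include_ld and len(ld):
        tables_io.write_ld(ld, out_dir / "ld.tsv")
        paths["ld"] = out_dir / "ld.tsv"
    if params is not None:
        manifest = dataclasses.asdict(params)
        (out_dir / "params.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        paths["params"] = out_dir / "params.json"
    return paths
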