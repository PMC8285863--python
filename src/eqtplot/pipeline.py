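"""End-to-end orchestration of one gene-trait colocalization analysis."""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import pandas as pd
from matplotlib.figure import Figure

from . import plotting
from .config import AnalysisConfig, tissue_label
from .ld import LdContext, build_ld_context, lead_r2_annotation
from .locus import (CONGRUOUS, INCONGRUOUS, Locus, build_locus_table,
                    collapse_tissues, define_locus)
from .stats import (CorrelationResult, EnrichmentResult, enrichment_test,
                    pp_correlation, pp_points, select_lead_variant)

logger = logging.getLogger("eqtplot")


@dataclass
class AnalysisResult:
    """Everything one analysis computed, plus the rendered figure."""

    locus: Locus
    locus_table: pd.DataFrame
    enrichment: List[EnrichmentResult]
    correlations: Dict[str, CorrelationResult]
    ld_context: Optional[LdContext] = None
    lead_snps: Dict[str, str] = field(default_factory=dict)
    figure: Optional[Figure] = None
    panels: Dict[str, object] = field(default_factory=dict)
    output_path: Optional[Path] = None
    layout: str = "basic"


def run_analysis(gwas: pd.DataFrame, eqtl: pd.DataFrame,
                 genes_table: pd.DataFrame, config: AnalysisConfig,
                 ld_pairs: Optional[pd.DataFrame] = None,
                 out_dir: str = ".", fmt: str = "png",
                 render: bool = True) -> AnalysisResult:
    """Run locus definition, collapsing, statistics, LD, and rendering.

    ``config.gene`` must name a single gene present in ``genes_table``.
    When the LD table is supplied but nothing survives filtering, the
    figure falls back to the no-LD layout with a logged warning.
    """
    gene = config.gene if isinstance(config.gene, str) else config.gene[0]
    locus = define_locus(gene, genes_table, config.range_kb)
    collapsed = collapse_tissues(eqtl[eqtl["gene"] == gene], config.tissue,
                                 config.collapse_method,
                                 config.assume_equal_n)
    table = build_locus_table(gwas, collapsed, locus, config)
    table.attrs["trait"] = gwas.attrs.get("trait", config.trait or "")

    strata = [CONGRUOUS, INCONGRUOUS] if config.congruence else ["all"]
    enrichment = [enrichment_test(table, s) for s in strata]
    correlations = {s: pp_correlation(table, s)
                    for s in (["all"] + strata if config.congruence
                              else ["all"])}

    ld_supplied = ld_pairs is not None and len(ld_pairs) > 0
    ld_context = None
    lead_snps: Dict[str, str] = {}
    lead_r2: Dict[str, Dict[str, float]] = {}
    if ld_supplied:
        ld_context = build_ld_context(ld_pairs, table, config.r2min,
                                      config.ldmin)
        if ld_context is None:
            ld_supplied = False
            logger.warning("falling back to the no-LD layout")
        else:
            ld_snp_set = set(ld_pairs["snp_a"]) | set(ld_pairs["snp_b"])
            gwas_snp_set = set(gwas["snp"])
            pp_strata = strata if config.congruence else ["all"]
            for s in pp_strata:
                pts = pp_points(table, s)
                if len(pts) == 0:
                    continue
                # a user-specified lead applies to the single P-P panel;
                # per-stratum panels each auto-select their own lead
                user_lead = config.lead_snp if s == "all" else None
                lead = select_lead_variant(
                    pts, user_lead,
                    gwas_snps=gwas_snp_set if user_lead else None,
                    ld_snps=ld_snp_set if user_lead else None)
                lead_snps[s] = lead
                lead_r2[s] = lead_r2_annotation(ld_pairs, lead,
                                                pts["snp"].tolist())

    result = AnalysisResult(locus=locus, locus_table=table,
                            enrichment=enrichment,
                            correlations=correlations,
                            ld_context=ld_context, lead_snps=lead_snps)
    if not render:
        return result

    spec = plotting.FigureSpec.resolve(config, ld_supplied)
    fig, panels = plotting.compose_figure(spec)
    meta = config.collapse_method == "meta" and not (
        isinstance(config.tissue, str) and config.tissue != "all")
    plotting.render_main_panel(panels["main"], table, locus, config,
                               lead_snps=list(lead_snps.values()), meta=meta)
    plotting.render_gene_track(panels["gene_track"], genes_table, locus,
                               config.genometrackheight)
    if "ld_heatmap" in panels and ld_context is not None:
        plotting.render_ld_heatmap(panels["ld_heatmap"], ld_context, locus,
                                   spec.ldcolor)
    plotting.render_enrichment_panel(panels["enrichment"], enrichment)

    if spec.layout == "ld_congruence":
        for key, stratum in (("pp_congruous", CONGRUOUS),
                             ("pp_incongruous", INCONGRUOUS)):
            pts = pp_points(table, stratum)
            plotting.render_pp_panel(panels[key], pts,
                                     correlations[stratum], config,
                                     lead_snp=lead_snps.get(stratum),
                                     lead_r2=lead_r2.get(stratum))
            panels[key].set_title(stratum, fontsize=9)
    elif spec.layout == "ld":
        pts = pp_points(table, "all")
        plotting.render_pp_panel(panels["pp"], pts, correlations["all"],
                                 config, lead_snp=lead_snps.get("all"),
                                 lead_r2=lead_r2.get("all"))
    else:
        if config.congruence:
            by_stratum = {s: (pp_points(table, s), correlations[s])
                          for s in (CONGRUOUS, INCONGRUOUS)}
            plotting.render_pp_panel(panels["pp"], pp_points(table, "all"),
                                     correlations["all"], config,
                                     pp_by_stratum=by_stratum)
        else:
            plotting.render_pp_panel(panels["pp"], pp_points(table, "all"),
                                     correlations["all"], config)

    trait = gwas.attrs.get("trait", config.trait or "trait")
    path = plotting.save_figure(fig, out_dir, locus.gene, trait,
                                tissue_label(config.tissue),
                                config.congruence, ld_supplied,
                                saveplot=config.saveplot, fmt=fmt)
    result.figure = fig
    result.panels = panels
    result.output_path = path
    result.layout = spec.layout
    return result
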