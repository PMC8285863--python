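"""Panel rendering and figure composition.

Three layouts, chosen purely by what data is supplied:

* ``basic`` — no LD: main colocalization panel (A), gene track (B),
  enrichment bars (C), P-P scatter (D).
* ``ld`` — LD supplied: A, B, LD heatmap (C), enrichment (D), P-P with
  R^2-to-lead coloring (E).
* ``ld_congruence`` — LD plus the direction-of-effect split: A-D as in
  ``ld``, then separate congruous (E) and incongruous (F) P-P panels,
  each with its own lead variant.

The main panel is a regional association plot: position along x,
``-log10 p_GWAS`` along y. Variants without qualifying eQTL evidence are
grey squares; eQTL variants are triangles pointing up or down with the
GWAS direction of effect, sized by |NES| and filled by ``-log10 p_eQTL``
(a single sequential ramp by default; blue for congruous and red for
incongruous variants when the split is on). The main panel, gene track,
and heatmap share identical x-limits.

Rendering is deterministic at fixed dpi (Agg backend, pinned defaults);
repeated runs produce byte-identical PNG buffers.
"""
from __future__ import annotations

import io as _io
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Optional, Sequence

import matplotlib
matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib.collections import PolyCollection
from matplotlib.figure import Figure
from matplotlib.gridspec import GridSpec

from .config import AnalysisConfig
from .ld import LdContext
from .locus import CONGRUOUS, INCONGRUOUS, Locus
from .stats import CorrelationResult, EnrichmentResult

logger = logging.getLogger("eqtplot")

GREY = "0.55"
CMAP_DEFAULT = "viridis"
CMAP_CONGRUOUS = "Blues"
CMAP_INCONGRUOUS = "Reds"
LEAD_COLOR = "#2ca02c"

#: figure height as a fraction of width, per layout
ASPECT = {"basic": 0.75, "ld": 0.9, "ld_congruence": 0.9}


@dataclass(frozen=True)
class FigureSpec:
    """Geometry and options resolved for one figure."""

    layout: str                      # basic | ld | ld_congruence
    width: float
    dpi: int
    genometrackheight: float
    ldcolor: str = "color"

    @staticmethod
    def resolve(config: AnalysisConfig, ld_supplied: bool) -> "FigureSpec":
        if ld_supplied and config.congruence:
            layout = "ld_congruence"
        elif ld_supplied:
            layout = "ld"
        else:
            layout = "basic"
        return FigureSpec(layout=layout,
                          width=config.resolved_width(ld_supplied),
                          dpi=config.res,
                          genometrackheight=config.genometrackheight,
                          ldcolor=config.ldcolor)


def _nes_sizes(nes: np.ndarray, limits: Optional[tuple],
               meta: bool) -> np.ndarray:
    """Marker areas (pt^2) from |NES|; constant under meta collapsing."""
    if meta or np.all(~np.isfinite(nes)):
        return np.full(len(nes), 60.0)
    mag = np.abs(nes)
    lo, hi = (limits if limits is not None
              else (float(np.nanmin(mag)), float(np.nanmax(mag))))
    if hi <= lo:
        return np.full(len(nes), 60.0)
    frac = np.clip((mag - lo) / (hi - lo), 0, 1)
    return 20.0 + 180.0 * frac


def render_main_panel(ax, locus_table: pd.DataFrame, locus: Locus,
                      config: AnalysisConfig,
                      lead_snps: Sequence[str] = (),
                      meta: bool = False) -> None:
    """Regional association panel with eQTL coloring (panel A)."""
    y = -np.log10(locus_table["p_gwas"].to_numpy(float))
    x = locus_table["bp"].to_numpy(float)
    non = ~locus_table["has_eqtl"].to_numpy(bool)
    ax.scatter(x[non], y[non], marker="s", s=18, c=GREY, linewidths=0,
               label="no eQTL", zorder=2)

    def _triangles(mask: np.ndarray, cmap: str, label: str) -> None:
        if not mask.any():
            return
        sub = locus_table[mask]
        color = -np.log10(sub["p_eqtl"].to_numpy(float))
        sizes = _nes_sizes(sub["nes"].to_numpy(float),
                           config.nes_size_limits, meta)
        up = sub["beta"].to_numpy(float) >= 0
        for marker, sel in (("^", up), ("v", ~up)):
            if sel.any():
                sc = ax.scatter(sub["bp"].to_numpy(float)[sel],
                                -np.log10(sub["p_gwas"].to_numpy(float))[sel],
                                marker=marker, s=sizes[sel], c=color[sel],
                                cmap=cmap, vmin=0,
                                vmax=max(1.0, float(color.max())),
                                edgecolors="none", zorder=3)
        fig = ax.get_figure()
        cb = fig.colorbar(sc, ax=ax, pad=0.01, fraction=0.04)
        cb.set_label(f"-log10 P_eQTL ({label})" if label else "-log10 P_eQTL")

    has = locus_table["has_eqtl"].to_numpy(bool)
    if config.congruence:
        cls = locus_table["congruence_class"].to_numpy(object)
        _triangles(has & (cls == CONGRUOUS), CMAP_CONGRUOUS, "congruous")
        _triangles(has & (cls == INCONGRUOUS), CMAP_INCONGRUOUS, "incongruous")
    else:
        _triangles(has, CMAP_DEFAULT, "")

    ax.axhline(-np.log10(config.sigpvalue_gwas), color="red", lw=1.0,
               zorder=1)
    for snp in lead_snps:
        hit = locus_table[locus_table["snp"] == snp]
        if len(hit):
            ax.annotate(snp,
                        (float(hit["bp"].iloc[0]),
                         float(-np.log10(hit["p_gwas"].iloc[0]))),
                        textcoords="offset points", xytext=(4, 6),
                        fontsize=8)
    ax.set_xlim(locus.start_bp, locus.stop_bp)
    if config.ylima is not None:
        ax.set_ylim(top=config.ylima)
    ax.set_ylabel(r"-log10 P_GWAS")
    trait = locus_table.attrs.get("trait", "")
    ax.set_title(f"{locus.gene} eQTLs and {trait} associations "
                 f"(chr{locus.chrom})".strip(), fontsize=10)


def render_gene_track(ax, genes_table: pd.DataFrame, locus: Locus,
                      height_weight: float = 2.0) -> None:
    """Gene-body track sharing the main panel's x-axis (panel B)."""
    overlapping = genes_table[(genes_table["chrom"] == locus.chrom)
                              & (genes_table["start"] <= locus.stop_bp)
                              & (genes_table["stop"] >= locus.start_bp)]
    lanes: list[int] = []  # rightmost occupied bp per lane
    for _, row in overlapping.sort_values("start").iterrows():
        start = max(int(row["start"]), locus.start_bp)
        stop = min(int(row["stop"]), locus.stop_bp)
        lane = next((k for k, right in enumerate(lanes) if start > right),
                    len(lanes))
        if lane == len(lanes):
            lanes.append(stop)
        else:
            lanes[lane] = stop
        ax.broken_barh([(start, max(stop - start, 1))], (lane, 0.6),
                       facecolors="#4878a8")
        ax.text(start, lane + 0.75, row["gene"], fontsize=7, va="bottom")
    ax.set_xlim(locus.start_bp, locus.stop_bp)
    ax.set_ylim(-0.5, max(len(lanes), 1) + 0.8)
    ax.set_yticks([])
    ax.set_xlabel(f"chr{locus.chrom} position (bp)")


def render_ld_heatmap(ax, ld_context: LdContext, locus: Locus,
                      ldcolor: str = "color") -> bool:
    """Triangular pairwise-R^2 heatmap mapped to the shared x-axis (panel C).

    Cells are drawn as diamonds below a row of connector lines that tie
    each heatmap column to the variant's true chromosomal position.
    Returns False (panel skipped) with fewer than two variants.
    """
    n = ld_context.n
    if n < 2:
        logger.warning("LD heatmap skipped: fewer than 2 kept variants")
        return False
    span = locus.stop_bp - locus.start_bp
    s = span / n
    cols = locus.start_bp + s * (np.arange(n) + 0.5)
    verts, vals = [], []
    for i in range(n):
        for j in range(i, n):
            xc = (cols[i] + cols[j]) / 2.0
            yc = -(j - i) * 0.5 - 1.0
            verts.append([(xc - s / 2, yc), (xc, yc + 0.5),
                          (xc + s / 2, yc), (xc, yc - 0.5)])
            vals.append(ld_context.r2_matrix[i, j])
    cmap = "Greys" if ldcolor == "black" else CMAP_DEFAULT
    pc = PolyCollection(verts, array=np.array(vals), cmap=cmap,
                        edgecolors="none", clim=(0, 1))
    ax.add_collection(pc)
    top = 1.5
    for pos, col in zip(ld_context.positions, cols):
        ax.plot([pos, col], [top, -0.5], color="0.4", lw=0.4)
    ax.set_xlim(locus.start_bp, locus.stop_bp)
    ax.set_ylim(-(n - 1) * 0.5 - 2.0, top)
    ax.set_yticks([])
    fig = ax.get_figure()
    cb = fig.colorbar(pc, ax=ax, pad=0.01, fraction=0.04)
    cb.set_label(r"pairwise $R^2$")
    return True


def render_enrichment_panel(ax, results: Sequence[EnrichmentResult]) -> None:
    """Proportion-eQTL bars for significant vs non-significant variants."""
    groups = list(results)
    width = 0.35
    centers = np.arange(2)  # significant, non-significant
    palette = {"all": "#4878a8", CONGRUOUS: "#3b6fb5", INCONGRUOUS: "#c44e52"}
    for k, res in enumerate(groups):
        offset = (k - (len(groups) - 1) / 2) * width
        props = [res.proportion_sig, res.proportion_nonsig]
        props = [0.0 if not np.isfinite(v) else v for v in props]
        ax.bar(centers + offset, props, width * 0.9,
               color=palette.get(res.stratum, "#4878a8"),
               label=res.stratum if res.stratum != "all" else None)
        ptxt = "n.s." if res.degenerate else f"p = {res.fisher_p:.2g}"
        ax.text(float(centers[0] + offset), props[0] + 0.02,
                ptxt, ha="center", fontsize=7)
    ax.set_xticks(centers)
    ax.set_xticklabels(["GWAS significant", "not significant"], fontsize=8)
    ax.set_ylabel("proportion eQTL")
    ax.set_ylim(0, 1.15)
    if len(groups) > 1:
        ax.legend(fontsize=7)


def _annotate_corr(ax, res: CorrelationResult, y_frac: float,
                   color: str = "black") -> None:
    if res.defined:
        txt = f"r = {res.pearson_r:.3f}, p = {res.p_correlation:.3g}"
    else:
        txt = f"r undefined (n = {res.n_points})"
    ax.text(0.03, y_frac, txt, transform=ax.transAxes, fontsize=8,
            color=color)


def render_pp_panel(ax, pp: pd.DataFrame, result: CorrelationResult,
                    config: AnalysisConfig,
                    lead_snp: Optional[str] = None,
                    lead_r2: Optional[Dict[str, float]] = None,
                    pp_by_stratum: Optional[dict] = None) -> None:
    """P-P scatter with best-fit line and correlation annotation.

    With LD, points are filled by R^2 to the lead variant and the lead is
    a green diamond. In congruence mode without LD both strata are
    superimposed (blue congruous, red incongruous) with per-stratum lines.
    """
    if pp_by_stratum is not None:
        for frac, (stratum, (pts, res)) in zip(
                (0.94, 0.87), sorted(pp_by_stratum.items())):
            color = "#3b6fb5" if stratum == CONGRUOUS else "#c44e52"
            ax.scatter(pts["x"], pts["y"], s=16, c=color, alpha=0.8,
                       linewidths=0, label=stratum)
            _draw_fit(ax, pts, res, color)
            _annotate_corr(ax, res, frac, color)
        ax.legend(fontsize=7, loc="lower right")
    elif lead_r2 is not None and lead_snp is not None:
        colors = np.array([lead_r2.get(s, 0.0) for s in pp["snp"]])
        others = pp["snp"].to_numpy() != lead_snp
        sc = ax.scatter(pp["x"][others], pp["y"][others], s=18,
                        c=colors[others], cmap=CMAP_DEFAULT, vmin=0, vmax=1,
                        linewidths=0)
        lead_pt = pp[pp["snp"] == lead_snp]
        if len(lead_pt):
            ax.scatter(lead_pt["x"], lead_pt["y"], marker="D", s=55,
                       c=LEAD_COLOR, edgecolors="black", linewidths=0.5,
                       zorder=4)
            ax.annotate(lead_snp, (float(lead_pt["x"].iloc[0]),
                                   float(lead_pt["y"].iloc[0])),
                        textcoords="offset points", xytext=(5, 5), fontsize=7)
        cb = ax.get_figure().colorbar(sc, ax=ax, pad=0.01, fraction=0.05)
        cb.set_label(r"$R^2$ with lead")
        _draw_fit(ax, pp, result)
        _annotate_corr(ax, result, 0.94)
    else:
        ax.scatter(pp["x"], pp["y"], s=18, c="#4878a8", linewidths=0)
        _draw_fit(ax, pp, result)
        _annotate_corr(ax, result, 0.94)
    if config.xlimd is not None:
        ax.set_xlim(right=config.xlimd)
    if config.ylimd is not None:
        ax.set_ylim(top=config.ylimd)
    ax.set_xlabel(r"-log10 P_eQTL")
    ax.set_ylabel(r"-log10 P_GWAS")


def _draw_fit(ax, pts: pd.DataFrame, res: CorrelationResult,
              color: str = "black") -> None:
    if res.defined and len(pts):
        xs = np.linspace(float(pts["x"].min()), float(pts["x"].max()), 2)
        ax.plot(xs, res.slope * xs + res.intercept, color=color, lw=1.0)


def compose_figure(spec: FigureSpec) -> tuple[Figure, Dict[str, "plt.Axes"]]:
    """Create the figure and named panel axes for a layout.

    Returns the figure and a dict of panels keyed ``main, gene_track,
    [ld_heatmap,] enrichment, pp`` (or ``pp_congruous``/``pp_incongruous``
    for the congruence layout).
    """
    height = spec.width * ASPECT[spec.layout]
    fig = Figure(figsize=(spec.width, height), dpi=spec.dpi)
    panels: Dict[str, plt.Axes] = {}
    gth = max(spec.genometrackheight, 0.5)
    if spec.layout == "basic":
        gs = GridSpec(3, 2, figure=fig, height_ratios=[6, gth, 4],
                      hspace=0.35, wspace=0.3)
        panels["main"] = fig.add_subplot(gs[0, :])
        panels["gene_track"] = fig.add_subplot(gs[1, :])
        panels["enrichment"] = fig.add_subplot(gs[2, 0])
        panels["pp"] = fig.add_subplot(gs[2, 1])
    elif spec.layout == "ld":
        gs = GridSpec(4, 2, figure=fig, height_ratios=[6, gth, 4, 4],
                      hspace=0.4, wspace=0.3)
        panels["main"] = fig.add_subplot(gs[0, :])
        panels["gene_track"] = fig.add_subplot(gs[1, :])
        panels["ld_heatmap"] = fig.add_subplot(gs[2, :])
        panels["enrichment"] = fig.add_subplot(gs[3, 0])
        panels["pp"] = fig.add_subplot(gs[3, 1])
    elif spec.layout == "ld_congruence":
        gs = GridSpec(4, 3, figure=fig, height_ratios=[6, gth, 4, 4],
                      hspace=0.4, wspace=0.35)
        panels["main"] = fig.add_subplot(gs[0, :])
        panels["gene_track"] = fig.add_subplot(gs[1, :])
        panels["ld_heatmap"] = fig.add_subplot(gs[2, :])
        panels["enrichment"] = fig.add_subplot(gs[3, 0])
        panels["pp_congruous"] = fig.add_subplot(gs[3, 1])
        panels["pp_incongruous"] = fig.add_subplot(gs[3, 2])
    else:
        raise ValueError(f"unknown layout {spec.layout!r}")
    return fig, panels


def output_filename(gene: str, trait: str, tissue_label: str,
                    congruence: bool, ld_supplied: bool,
                    fmt: str = "png") -> str:
    """Dot-separated output name: gene.trait.tissue.<congruence>.<ld>.eQTpLot.fmt."""
    cong = "Congruent" if congruence else "NoCongruence"
    ld = "LD" if ld_supplied else "NoLD"
    return f"{gene}.{trait}.{tissue_label}.{cong}.{ld}.eQTpLot.{fmt}"


def save_figure(fig: Figure, out_dir, gene: str, trait: str,
                tissue_label: str, congruence: bool, ld_supplied: bool,
                saveplot: bool = True, fmt: str = "png") -> Optional[Path]:
    """Write the composed figure; returns the path (None when saveplot off)."""
    if not saveplot:
        return None
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / output_filename(gene, trait, tissue_label, congruence,
                                     ld_supplied, fmt)
    fig.savefig(path, format=fmt, dpi=fig.dpi)
    return path


def figure_png_bytes(fig: Figure) -> bytes:
    """PNG buffer of the figure (used for determinism checks)."""
    buf = _io.BytesIO()
    fig.savefig(buf, format="png", dpi=fig.dpi)
    return buf.getvalue()
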