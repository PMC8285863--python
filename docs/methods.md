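# Methods

## Scope and data model

`eqtplot` integrates two sets of summary statistics — per-variant GWAS
associations and per-variant × gene × tissue cis-eQTL associations — at a
single locus of interest (LOI), defined as the candidate gene's
coordinates extended by `range_kb` kilobases on each side (default 200;
the lower bound is floored at position 1). Coordinates are 1-based
inclusive throughout, following PLINK and GTEx conventions; LOI
membership is `start ≤ bp ≤ stop`. Variants are matched between tables
purely by SNP identifier: no allele columns exist in these schemas, so
the package assumes GWAS β and eQTL NES are reported relative to the
same (alternative) allele for each variant. If the two sources used
different effect alleles for a variant, its congruence class will be
flipped; users combining heterogeneous sources should harmonize alleles
upstream.

## Input handling

Delimiters (comma, tab, whitespace) are sniffed from the header line,
and header names are matched case-insensitively with dots and
underscores interchangeable, since GTEx exports and PLINK outputs
disagree on dialect. Rows lacking P/BETA (GWAS) or P.value/NES (eQTL)
are dropped with a logged count. P-values of exactly 0 are clamped to
1e-300 with a warning so −log₁₀ axes stay finite. Duplicate
(SNP, gene, tissue) eQTL rows and out-of-range values are hard errors:
validation never silently repairs data beyond the two documented cases
above. LD pairs are restricted to variants present in the GWAS table,
and symmetric duplicates keep the first occurrence.

A small bundled gene-coordinate table (a hand-assembled subset of
protein-coding genes on both hg19 and hg38, with approximate RefSeq
bounds) backs `read_genes` when no table is supplied; it is sufficient
for examples and tests, and real analyses should pass a complete table.

## Tissue collapsing

PanTissue (`tissue="all"`) and MultiTissue (a tissue list) analyses
collapse each variant's eQTL records across the selected tissues. Only
tissues with a record for that variant contribute. Methods:

* `min` (default): the p-value **and** NES of the single most
  significant tissue, so each variant shows its strongest effect,
  agnostic of tissue. Ties on p are broken by larger |NES|, then by
  tissue name, making the result deterministic.
* `median` / `mean`: element-wise summary of both p and NES across the
  selected tissues. Summarizing p-values this way is a display
  convention, not a calibrated combined test.
* `meta`: a sample-size-weighted Z-test (Stouffer). Each tissue
  contributes zᵢ = sign(NESᵢ)·Φ⁻¹(1 − pᵢ/2) with weight wᵢ = √nᵢ;
  Z = Σwᵢzᵢ / √(Σwᵢ²) and the combined two-sided p is 2·(1 − Φ(|Z|)).
  No combined NES is defined, so the main panel draws all variants at a
  fixed size. The classical weighted Z-test is directionless; signing
  each zᵢ by the effect direction is this package's choice, made so that
  tissues with opposing effects cancel rather than reinforce —
  consistent with the congruence semantics elsewhere. Sample sizes must
  be present in the `N` column; `assume_equal_n=True` (CLI
  `--assume-equal-n`) permits an equal-weight combination, which can
  misestimate when tissue panels differ in size.

## Per-variant classification

A variant *qualifies* as an eQTL when a collapsed record exists and
p_eQTL ≤ `sigpvalue_eqtl` (default 0.05). GWAS significance uses strict
`<` on `sigpvalue_gwas` (default 5×10⁻⁸), mirroring the threshold's role
as a plotted cut line. The two comparisons are deliberately fixed to one
convention each and documented here; equality cases are vanishingly rare
in practice.

In congruence mode, qualifying eQTL variants are classed congruous when
sign(β) = sign(NES) with both nonzero, incongruous for opposite nonzero
signs; β·NES = 0 leaves the class undefined and the variant is excluded
from the split with a logged warning.

## Statistics

**Enrichment.** A two-sided Fisher exact test (point-probability rule,
as implemented in scipy) on the 2×2 table: a = GWAS-significant eQTLs,
b = GWAS-significant non-eQTLs, c = non-significant eQTLs,
d = non-significant non-eQTLs. When a margin is empty (for instance, no
GWAS-significant variants at all) the test is undefined; the result is
flagged degenerate and p is reported as 1 with a warning rather than
raising. In congruence mode two separate tests are run — congruous
eQTLs vs non-eQTLs, incongruous eQTLs vs non-eQTLs — with eQTLs of the
other class excluded from each table and the non-eQTL comparison group
shared.

**P–P correlation.** Pearson's r between −log₁₀ p_eQTL and −log₁₀
p_GWAS over qualifying eQTL variants (those failing `sigpvalue_eqtl`
are excluded), with the p-value of correlation from the usual t
transform on n − 2 degrees of freedom, and an ordinary least-squares
line for display. The log scale matches the plotted axes; correlating
raw probabilities would be dominated by the mass of near-1 p-values.
Fewer than 3 points, or zero variance on either axis, yields a flagged
undefined result.

**Lead variant.** For LD coloring, the lead is the user-specified SNP
(required to be present in both the GWAS and LD tables) or else the
upper-right-most P–P point: the variant maximizing
(−log₁₀ p_eQTL + −log₁₀ p_GWAS), ties broken by the larger GWAS
coordinate, then lexicographic SNP id. In congruence mode each P–P
panel selects its own lead.

**Rankings.** `rank_genes` repeats locus definition, collapsing, and
P–P correlation per gene; `rank_tissues` does the same per tissue with
no collapsing. Entries sort ascending by correlation p-value; undefined
entries go last; ties sort by |r| descending, then name, so the order
is fully deterministic.

## LD filtering and the heatmap

Pairs are restricted to qualifying eQTL variants inside the LOI with
R² > `r2min` (default 0.1, strict — the boundary convention adopted and
documented here), then variants must be in LD with at least `ldmin`
(default 10) others to be drawn. Degree counting uses the
locus-restricted, thresholded pair set. The R² matrix is symmetric with
unit diagonal; pairs absent from the input are treated as R² = 0, the
natural reading of PLINK output that omits sub-threshold pairs.
Conflicting duplicate R² values for one pair are an error. Congruence
mode does not change LD filtering — the heatmap always shows all
qualifying eQTL variants. When fewer than two variants survive, the LD
panels are skipped and the figure falls back to the no-LD layout with a
logged warning.

## Figure composition

Layout is a pure function of the inputs: 4 panels without LD (main,
gene track, enrichment, P–P), 5 with LD (adding the heatmap and
lead-variant P–P coloring), 6 with LD and congruence (separate
congruous and incongruous P–P panels). Width defaults to 12 in
(14 with LD); height is width × 0.75 (basic) or × 0.9 (LD layouts),
fixed constants chosen to keep panel aspect ratios stable. The gene
track height weight is `genometrackheight` (default 2). Gene bodies are
drawn from the supplied coordinate table only (no transcript/exon
models, no remote annotation). The heatmap columns are evenly spaced
with connector lines to each variant's true chromosomal position, and
the main panel, gene track, and heatmap share identical x-limits.

Marker sizes scale linearly in |NES| between the observed (or
`nes_size_limits`-fixed) extremes; under `meta` collapse all markers are
one size. Color ramps are perceptually uniform: viridis for the default
single-scale mode and the heatmap (greyscale with `ldcolor="black"`),
blue/red sequential ramps for congruous/incongruous. Output files are
named `<gene>.<trait>.<tissue>.<Congruent|NoCongruence>.<LD|NoLD>.eQTpLot.<fmt>`
with dot-separated tokens; PNG (default, `res` dpi, default 300), PDF,
and SVG are supported. Rendering is deterministic: the Agg backend with
default settings produces byte-identical PNG buffers on repeat.

## Synthetic data

The generator (`eqtplot.simulate`) emulates the structure the analysis
assumes, not real genomes. A locus of `n_variants` (default 300) equally
spaced variants is divided into `n_blocks` (default 3) LD blocks with
AR(1) genotype correlation ρ^|i−j| within a block (ρ = 0.9) and zero
across blocks. Under the standard single-causal-variant approximation,
every variant's expected Z-score is the causal Z attenuated by its
correlation with the causal variant: z = λ·r(·, causal) + ε with ε
standard normal, λ_g = 12 for the trait and λ_e = 10 per tissue —
strengths typical of a clearly genome-wide-significant locus with
well-powered cis-eQTLs. Two-sided p-values follow, and effect sizes are
z/√N with N = 300 000 for the GWAS (biobank scale) and GTEx-like tissue
sample sizes (670/581/208), giving NES magnitudes of order 0.1–1.
`shared_causal=True` drives expression and trait through the same
variant (the colocalization condition); otherwise the expression causal
variant moves to a different block. Pairwise LD is emitted as
r² = ρ^(2|i−j|) for within-block pairs above a floor of 0.01, and the
gene record spans the central block.

What the generator does **not** model: allele frequencies and their
effect on power, imputation artifacts, correlated noise between GWAS
and eQTL samples (sample overlap), multiple causal variants, and
cross-block LD leakage. Passing tests therefore demonstrate that the
statistics respond correctly to presence/absence of colocalization
under idealized LD, not that the method is calibrated on real data.

## Numerical choices and degenerate inputs

Zero p-values clamp to 1e-300; meta-analysis p-values are capped at 1;
undefined correlations and degenerate Fisher tests return flagged
results instead of raising so that rankings and figures degrade
gracefully; empty LD intersections disable LD panels rather than
failing the run. Sorts use stable (mergesort) ordering everywhere a
tie-break is documented, so outputs are reproducible across runs and
platforms.

## Problem sizes

The test suite and the acceptance script run on the generator's default
locus (300 variants, 3 blocks, 3 tissues) with 25–50 replicates for the
paired shared-vs-distinct comparisons — sizes at which the paired
contrast in P–P correlation and enrichment is already decisive, as the
replicate fractions they report show.
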