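"""Analysis configuration with the tool's documented defaults.

The defaults encode the standard conventions of regional eQTL-GWAS
colocalization analysis: genome-wide significance at 5e-8 for the trait
association, nominal 0.05 for eQTL qualification, a 200 kb flank around the
candidate gene, PanTissue collapsing by minimum p-value, and LD-heatmap
thinning at R^2 > 0.1 with a minimum degree of 10.
"""
from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Optional, Sequence, Union

from .errors import ValidationError

TissueSelector = Union[str, Sequence[str]]

VALID_COLLAPSE_METHODS = ("min", "median", "mean", "meta")
VALID_BUILDS = ("hg19", "hg38")
VALID_LDCOLORS = ("color", "black")


@dataclass
class AnalysisConfig:
    """Resolved options for one gene-trait colocalization analysis.

    Parameters mirror the tool's command line: significance thresholds,
    locus flank size, tissue collapsing, LD filtering, and rendering
    options. ``width`` defaults to 12 inches, or 14 when LD data is
    supplied (resolved by :meth:`resolved_width`).
    """

    gene: Optional[Union[str, Sequence[str]]] = None
    trait: Optional[str] = None
    tissue: TissueSelector = "all"
    sigpvalue_gwas: float = 5e-8
    sigpvalue_eqtl: float = 0.05
    range_kb: float = 200.0
    congruence: bool = False
    collapse_method: str = "min"
    assume_equal_n: bool = False
    r2min: float = 0.1
    ldmin: int = 10
    lead_snp: Optional[str] = None
    gbuild: str = "hg19"
    # rendering
    genometrackheight: float = 2.0
    ldcolor: str = "color"
    nes_size_limits: Optional[tuple[float, float]] = None
    res: int = 300
    width: Optional[float] = None
    xlimd: Optional[float] = None
    ylima: Optional[float] = None
    ylimd: Optional[float] = None
    saveplot: bool = True
    getplot: bool = True
    # list modes
    gene_list: bool = False
    tissue_list: bool = False

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not (0 < self.sigpvalue_gwas <= 1):
            raise ValidationError("sigpvalue_gwas must lie in (0, 1]")
        if not (0 < self.sigpvalue_eqtl <= 1):
            raise ValidationError("sigpvalue_eqtl must lie in (0, 1]")
        if self.range_kb < 0:
            raise ValidationError("range_kb must be >= 0")
        if not (0 <= self.r2min <= 1):
            raise ValidationError("r2min must lie in [0, 1]")
        if self.ldmin < 0:
            raise ValidationError("ldmin must be >= 0")
        if self.collapse_method not in VALID_COLLAPSE_METHODS:
            raise ValidationError(
                f"collapse_method must be one of {VALID_COLLAPSE_METHODS}, "
                f"got {self.collapse_method!r}"
            )
        if self.gbuild not in VALID_BUILDS:
            raise ValidationError(f"gbuild must be one of {VALID_BUILDS}")
        if self.ldcolor not in VALID_LDCOLORS:
            raise ValidationError(f"ldcolor must be one of {VALID_LDCOLORS}")

    def resolved_width(self, ld_supplied: bool) -> float:
        """Figure width in inches: user override, else 12 (14 with LD)."""
        if self.width is not None:
            return float(self.width)
        return 14.0 if ld_supplied else 12.0

    def with_overrides(self, **kwargs) -> "AnalysisConfig":
        """Return a copy with the given fields replaced (and re-validated)."""
        return replace(self, **kwargs)

    @classmethod
    def from_layers(cls, *layers: dict) -> "AnalysisConfig":
        """Build a config from precedence-ordered dicts (later wins).

        Used by the CLI to merge defaults < YAML config file < command-line
        flags; ``None`` values in a layer are treated as "not set".
        """
        known = {f.name for f in fields(cls)}
        merged: dict = {}
        for layer in layers:
            for key, value in layer.items():
                if key not in known:
                    raise ValidationError(f"unknown configuration key {key!r}")
                if value is not None:
                    merged[key] = value
        return cls(**merged)


def tissue_label(tissue: TissueSelector) -> str:
    """Filename token for the tissue selector.

    ``"all"`` means PanTissue collapsing, a list means MultiTissue, and a
    single name is used verbatim.
    """
    if isinstance(tissue, str):
        return "PanTissue" if tissue == "all" else tissue
    return "MultiTissue"
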