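"""Typed exceptions raised by input validation and analysis steps."""


class EqtplotError(Exception):
    """Base class for all package errors."""


class SchemaError(EqtplotError):
    """An input table is missing a required column or has a wrong dtype."""


class ValidationError(EqtplotError):
    """An input table violates a value-level invariant (duplicates, ranges)."""


class EmptyInputError(EqtplotError):
    """A filter step left zero rows where at least one is required."""


class UnknownGeneError(EqtplotError):
    """The requested gene is absent from the gene-coordinate table."""


class UnknownTissueError(EqtplotError):
    """A named tissue does not occur in the eQTL table."""


class MetaSampleSizeError(EqtplotError):
    """Sample sizes are required for meta-analysis collapse but absent.

    Pass ``assume_equal_n=True`` to meta-analyze assuming identical sample
    sizes across tissues (may yield inaccurate combined estimates).
    """
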