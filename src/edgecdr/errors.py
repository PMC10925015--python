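"""Exception hierarchy shared across the package."""


class EdgecdrError(Exception):
    """Base class for all package errors."""


class ParseError(EdgecdrError):
    """SMILES string is syntactically or chemically invalid."""


class SchemaError(EdgecdrError):
    """An atom falls outside the feature schema's element list."""


class UnknownCharError(EdgecdrError):
    """A character is absent from the tokenizer vocabulary's alphabet."""


class LeakageError(EdgecdrError):
    """Augmentation was requested for a non-training record."""


class ShapeError(EdgecdrError):
    """Tensor dimensions are inconsistent with the declared parameters."""


class DataError(EdgecdrError):
    """A dataset references drugs or cell lines that cannot be resolved."""


class DegenerateInputError(EdgecdrError):
    """Metric input is degenerate (e.g. constant ground-truth vector)."""


class InfeasibleSplitError(EdgecdrError):
    """A blind split cannot reach the requested fraction within tolerance."""


class PoolExhaustedError(EdgecdrError):
    """More distinct drugs requested than the built-in pool provides."""


class EmptyIntersectionError(EdgecdrError):
    """No genes survive intersecting the omics matrices with the gene list."""
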