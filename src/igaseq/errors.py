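"""Exception hierarchy shared across the package.

Each class maps onto one failure mode of the pipeline's contracts; the CLI
translates them into stable exit codes (usage 2, data validation 3,
insufficient data 4).
"""


class IgaSeqError(ValueError):
    """Base class for all package-specific errors."""


class FormatError(IgaSeqError):
    """A file's contents violate the expected dialect (bad cell, bad header)."""


class JoinError(IgaSeqError):
    """Count table and sample metadata (or taxonomy) do not line up."""


class ParameterError(IgaSeqError):
    """A function argument is outside its documented domain."""


class SelectionError(IgaSeqError):
    """A requested fraction/age/group slice is absent from the data."""


class DegenerateSampleError(IgaSeqError):
    """A sample has zero total counts and no pseudocount to rescue it."""


class InsufficientDataError(IgaSeqError):
    """Too few samples or groups to run the requested statistic."""


class DesignError(IgaSeqError):
    """An ANOVA design cell is empty or otherwise unusable."""
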