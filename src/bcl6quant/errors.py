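"""Exception hierarchy shared across the package."""


class BCL6QuantError(Exception):
    """Base class for all package-specific errors."""


class InputError(BCL6QuantError):
    """An input file or table is missing, unreadable, or malformed."""


class UnsupportedFormatError(InputError):
    """The input decodes, but into a representation the pipeline rejects
    (e.g. more than 8 bits per channel)."""


class ContractError(BCL6QuantError, ValueError):
    """An argument violates a documented precondition."""


class DegenerateInputError(ContractError):
    """The input is formally valid but the operation is undefined on it
    (constant image for automatic thresholding, zero-mass distribution
    for percentiles, zero-variance regression input, ...)."""


class GenerationError(BCL6QuantError):
    """Synthetic-slide generation failed (e.g. object placement could not
    satisfy the non-overlap constraint within the attempt budget)."""


class NoSectionsIncludedError(BCL6QuantError):
    """Every section of a cohort fell below the minimum-gland inclusion
    rule, so no group-level analysis is possible."""


class FitWarning(UserWarning):
    """A curve fit did not converge; moment-based estimates are returned."""
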