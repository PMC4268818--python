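"""Exception hierarchy for groupphylo.

The CLI maps these onto exit codes: model violations (exit 2), log
saturation (exit 3), malformed input (exit 4).
"""


class GroupPhyloError(Exception):
    """Base class for all groupphylo errors."""


class InvalidGroupError(GroupPhyloError, ValueError):
    """Group specification is not a valid product of cyclic factors."""


class DomainError(GroupPhyloError, ValueError):
    """An argument is outside the domain of the operation (bad element,
    out-of-range symbol, identity-keyed rate, negative rate, ...)."""


class InputFormatError(GroupPhyloError, ValueError):
    """A file or config could not be parsed into the expected structure."""


class ModelViolationError(GroupPhyloError):
    """Input data is inconsistent with a group-based stationary model
    (mass on provably-vanishing spectral components, channel disagreement,
    large imaginary residue)."""


class SaturationError(GroupPhyloError):
    """A spectral component is at or below machine zero, so the logarithm
    step is undefined: edge rates too large, or degenerate data."""
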