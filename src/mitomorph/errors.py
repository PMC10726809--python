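"""Exception types shared across the package."""


class FormatError(ValueError):
    """An input file does not conform to the expected on-disk format."""


class ValidationError(ValueError):
    """An in-memory object violates a structural precondition."""


class BoundsError(ValueError):
    """Geometry falls outside the target grid."""


class DomainError(ValueError):
    """A numeric argument is outside the mathematical domain of an operation."""


class DegenerateDataError(ValueError):
    """Data admit no meaningful test statistic (e.g. zero variance everywhere)."""


class CapacityError(RuntimeError):
    """A randomized placement could not be completed within the retry budget."""


class MissingLabelError(KeyError):
    """A requested object label is absent from a label image or volume."""
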