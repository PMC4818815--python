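"""Exception hierarchy for coopfs."""


class CoopfsError(Exception):
    """Base class for all coopfs errors."""


class DatasetError(CoopfsError):
    """A dataset violates the loading contract."""


class MissingValueError(DatasetError):
    """An expression cell is missing (NA/empty)."""


class NonNumericError(DatasetError):
    """An expression cell could not be parsed as a number."""


class MissingLabelColumnError(DatasetError):
    """The named label column is absent from the file."""


class TooFewClassesError(DatasetError):
    """Fewer than two distinct class labels."""


class ClassTooSmallError(DatasetError):
    """A class has fewer than two samples."""


class DuplicateIdentifierError(DatasetError):
    """Feature or sample identifiers are not unique."""


class ConstantClassError(CoopfsError):
    """The class vector is constant; relevance scores are undefined."""


class ConfigError(CoopfsError):
    """Invalid or unknown configuration key/value."""
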