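"""Exception hierarchy shared across the pipeline stages."""


class DinosarcError(Exception):
    """Base class for all package-specific errors."""


class FormatError(DinosarcError, ValueError):
    """Input data has the wrong shape, channel count, or dimensionality."""


class ParameterError(DinosarcError, ValueError):
    """A tunable parameter is outside its valid range."""


class DomainError(DinosarcError, ValueError):
    """An operation was applied to input outside its mathematical domain
    (e.g. an empty field-of-view mask)."""


class DataError(DinosarcError, ValueError):
    """Evaluation inputs are inconsistent (e.g. an abnormal image without a
    ground-truth mask)."""
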