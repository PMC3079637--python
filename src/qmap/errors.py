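"""Exception hierarchy shared across the package."""


class QmapError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(QmapError, ValueError):
    """An argument or data invariant was violated."""


class FormatError(QmapError, ValueError):
    """An input file does not conform to the expected dialect."""


class EstimationError(QmapError, RuntimeError):
    """Matrix approximation cannot proceed (e.g. no observed values)."""
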