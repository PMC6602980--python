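"""Exception hierarchy shared across the package."""


class HrvError(Exception):
    """Base class for all errors raised by poincare_hrv."""


class FormatError(HrvError):
    """A file does not conform to the expected on-disk format."""


class ValidationError(HrvError):
    """A value or data structure violates a type invariant."""


class OrderingError(ValidationError):
    """Samples or beats were supplied out of time order."""


class InsufficientDataError(HrvError):
    """Not enough data to perform the requested computation."""


class EmptySeriesError(InsufficientDataError):
    """A series contains no usable samples at all."""


class WindowRangeError(HrvError):
    """A requested time window falls outside the recording."""


class UnsupportedConfigError(HrvError):
    """A configuration is valid in general but unsupported by this operation."""
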