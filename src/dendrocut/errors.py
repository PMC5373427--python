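"""Exception hierarchy shared across the package."""


class DendrocutError(Exception):
    """Base class for all package-specific errors."""


class InputError(DendrocutError, ValueError):
    """Invalid data or parameter supplied by the caller."""


class ParseError(InputError):
    """A matrix file could not be parsed as a rectangular numeric table."""


class InsufficientMergesError(InputError):
    """An estimator was given fewer merge heights than it requires."""


class ResamplingError(DendrocutError):
    """Too many resampling replicates failed to produce an estimate."""
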