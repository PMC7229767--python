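"""Exception hierarchy shared across the package."""


class RichsimError(Exception):
    """Base class for all package errors."""


class ParameterError(RichsimError, ValueError):
    """A model or distribution parameter is outside its valid range."""


class FormatError(RichsimError, ValueError):
    """An input file or table violates the expected dialect."""


class EstimatorDomainError(RichsimError, ValueError):
    """An estimator was asked for outside its domain (e.g. too few sampling units)."""
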