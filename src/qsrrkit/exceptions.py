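"""Exception hierarchy for qsrrkit."""


class QSRRError(Exception):
    """Base class for all qsrrkit errors."""


class ConfigurationError(QSRRError, ValueError):
    """An invalid configuration value; the message names the offending field."""


class ValidationError(QSRRError, ValueError):
    """Invalid data passed to an operation (shape, names, missing values)."""


class UnsupportedMethodError(QSRRError, TypeError):
    """An operation was requested for an algorithm that cannot provide it."""
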