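"""Exception hierarchy shared across the package."""


class CentelineError(Exception):
    """Base class for all package-specific errors."""


class InvalidIntervalError(CentelineError, ValueError):
    """A genomic interval violates 1 <= start <= end <= chromosome length."""


class ParseError(CentelineError, ValueError):
    """A file record could not be parsed; the message names the offending line."""


class ConfigError(CentelineError, ValueError):
    """A simulation or pipeline configuration is inconsistent."""


class StageError(CentelineError, RuntimeError):
    """A pipeline stage failed; the message names the stage."""
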