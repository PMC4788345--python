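"""Exception hierarchy shared across the toolkit."""


class AncfreqError(Exception):
    """Base class for all package-specific errors."""


class FormatError(AncfreqError):
    """Structural problem in an input file (dimension mismatch, bad header)."""


class ValueRangeError(AncfreqError):
    """A genotype or parameter value outside its legal range."""


class LabelError(AncfreqError):
    """Unknown or inconsistent panel label."""


class ConfigError(AncfreqError):
    """Invalid run or simulation configuration."""


class ConstraintError(AncfreqError):
    """A model constraint violated (e.g. window wider than reference count)."""


class NumericalError(AncfreqError):
    """Numerical failure (singular matrix, non-finite state)."""
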