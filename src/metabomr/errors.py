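"""Exception hierarchy shared across the package."""


class MetaboMRError(Exception):
    """Base class for all package errors."""


class InputError(MetaboMRError, ValueError):
    """Invalid argument values (bad counts, thresholds out of range, ...)."""


class FormatError(MetaboMRError, ValueError):
    """Malformed input files (missing columns, empty tables)."""


class EmptyHarmonizationError(MetaboMRError):
    """No overlapping SNPs survive exposure/outcome harmonization."""


class DegenerateInputError(MetaboMRError, ValueError):
    """Inputs that make a statistic undefined (zero SD, n <= k+1, bx = 0)."""
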