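"""Exception hierarchy.

``InputError`` covers unreadable/malformed/invalid inputs (CLI exit code 2),
``AnalysisError`` covers failures of the analysis itself, e.g. a sample with
zero usable reads (exit code 3).
"""


class PolarcallError(Exception):
    """Base class for all package-specific errors."""


class InputError(PolarcallError):
    """Input file or parameter is missing, malformed, or out of range."""


class AnalysisError(PolarcallError):
    """The analysis cannot proceed on this data (e.g. zero surviving reads)."""
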