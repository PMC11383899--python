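"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: ParseError -> 2, AnalysisError -> 3.
"""


class ChemoscreenError(Exception):
    """Base class for all package errors."""


class ParseError(ChemoscreenError, ValueError):
    """A file or configuration failed schema validation."""


class AnalysisError(ChemoscreenError, ValueError):
    """An analysis precondition was violated (bad group sizes, missing data...)."""
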