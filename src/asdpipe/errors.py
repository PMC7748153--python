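"""Exception hierarchy shared across the package.

Every parse / validation failure maps to a distinct subclass so callers
(and tests) can discriminate failure modes without string matching.
"""


class AsdPipeError(Exception):
    """Base class for all package errors."""


class ParseError(AsdPipeError, ValueError):
    """A file could not be parsed into the requested domain type."""


class MissingColumnError(ParseError):
    """A required column is absent from a delimited input file."""


class NonNumericValueError(ParseError):
    """A cell expected to hold a number could not be converted."""


class DuplicateGeneError(ParseError):
    """The same gene symbol (after normalization) appears more than once."""


class DuplicateNameError(ParseError):
    """Two genesets in one collection share a name."""


class NegativeExpressionError(ParseError):
    """An expression matrix cell holds a negative TPM value."""


class MissingValueError(ParseError):
    """An expression matrix has empty cells and fill_missing was not requested."""


class InvalidSymbolError(AsdPipeError, ValueError):
    """A gene symbol is empty or contains internal whitespace."""


class ConfigError(AsdPipeError, ValueError):
    """A pipeline configuration is invalid; carries the full error list."""

    def __init__(self, errors: list[str]):
        self.errors = list(errors)
        super().__init__("; ".join(self.errors))
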