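"""Exception hierarchy shared across the package."""


class IlncsimError(Exception):
    """Base class for all package-specific errors."""


class GraphError(IlncsimError):
    """The disease hierarchy is structurally invalid (cycle, unreachable node, ...)."""


class UnknownTermError(IlncsimError, KeyError):
    """A disease term was requested that the DAG / table does not contain."""

    def __str__(self) -> str:  # KeyError quotes its message; keep it readable
        return Exception.__str__(self)


class InputFormatError(IlncsimError):
    """An input file could not be parsed (malformed record, wrong column count, ...)."""
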