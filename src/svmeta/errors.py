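"""Exception hierarchy for svmeta."""


class SVMetaError(Exception):
    """Base class for all svmeta errors."""


class ValidationError(SVMetaError):
    """Invalid domain value (bad coordinates, empty sources, bad config)."""


class ContractError(SVMetaError):
    """An operation was invoked with inputs violating its precondition."""


class ParseError(SVMetaError):
    """A file could not be parsed; the message names the file and line."""

    def __init__(self, path, lineno, message):
        self.path = str(path)
        self.lineno = lineno
        super().__init__(f"{self.path}: line {lineno}: {message}")


class CapacityError(SVMetaError):
    """The simulated genome is too small to place the requested variants."""
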