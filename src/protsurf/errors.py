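"""Exception hierarchy shared across the package."""


class ProtsurfError(Exception):
    """Base class for all package errors."""


class ParseError(ProtsurfError):
    """A coordinate file could not be read or is malformed."""


class EmptyStructureError(ProtsurfError):
    """A parsed file contains no polymer residues."""


class LookupError_(ProtsurfError):
    """A chain or residue referenced by key does not exist."""


class ConfigurationError(ProtsurfError):
    """Invalid parameter, missing radius/reference entry, or bad config."""


class ParameterError(ProtsurfError):
    """A numeric parameter is outside its allowed range."""


class FormattingError(ProtsurfError):
    """A value cannot be represented in a fixed-width PDB column."""


class ValidationError(ProtsurfError):
    """An external track references residues absent from the model."""

    def __init__(self, message: str, offenders: list | None = None):
        super().__init__(message)
        self.offenders = offenders or []


class GenerationError(ProtsurfError):
    """A synthetic-structure request is infeasible."""


class EmptyInputError(ProtsurfError):
    """An operation that requires a non-empty input got an empty one."""


class FetchError(ProtsurfError):
    """A structure could not be found locally nor retrieved remotely."""
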