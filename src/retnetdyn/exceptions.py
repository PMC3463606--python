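"""Exception types shared across the package."""


class RetnetdynError(Exception):
    """Base class for all package errors."""


class ParseError(RetnetdynError, ValueError):
    """A malformed input file (bad row, wrong column count, ...)."""


class TypeConflictError(RetnetdynError, ValueError):
    """An identifier appears as a regulator in both the TF and miRNA files."""


class ParameterError(RetnetdynError, ValueError):
    """An argument is outside its documented domain."""


class UnknownEntityError(RetnetdynError, KeyError):
    """A node / entity / time-point id is not present in the container."""


class ConstantProfileError(RetnetdynError, ValueError):
    """Pearson correlation requested for a constant expression profile."""


class EmptyInputError(RetnetdynError, ValueError):
    """An operation received an effectively empty input set."""
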