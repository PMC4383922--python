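"""Exception hierarchy shared across the toolkit.

Parse errors carry file/line context; validation errors describe rejected
values (sequences, counts, spec fields).  The CLI maps ParseError and
ValidationError to exit code 3 and missing-input/usage problems to 2.
"""


class MirfuncError(Exception):
    """Base class for all package errors."""


class ParseError(MirfuncError):
    """A file could not be parsed; message names the offending line/record."""


class ValidationError(MirfuncError):
    """An input value violates a documented constraint."""


class AlphabetError(ValidationError):
    """A sequence contains characters outside the nucleotide alphabet."""


class LengthError(ValidationError):
    """A sequence falls outside its permitted length range."""


class FixtureSpecError(ValidationError):
    """A synthetic-fixture spec is internally contradictory."""
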