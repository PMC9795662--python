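"""Exception hierarchy shared across the package."""


class RepoError(Exception):
    """Base class for all genorepo errors."""


class NotFoundError(RepoError):
    """A genome, organism, tag, taxon, annotation or file could not be found."""


class AmbiguityError(RepoError):
    """More than one candidate matched where exactly one was required."""


class DuplicateError(RepoError):
    """An identifier that must be unique already exists."""


class ParseError(RepoError):
    """A file could not be parsed; message carries line/position context."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)
        self.line = line


class InvalidInputError(RepoError):
    """A precondition on operation inputs was violated (domain, arity, disjointness)."""
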