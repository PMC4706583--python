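"""Exception hierarchy shared across the package."""


class ClandivError(Exception):
    """Base class for all package errors."""


class InputError(ClandivError):
    """Malformed or inconsistent user input (files, tables, configs)."""


class AlignmentShapeError(InputError):
    """Sequences in one alignment do not share a common aligned length."""


class ConfigError(ClandivError):
    """Invalid simulation or run configuration."""


class NewickParseError(InputError):
    """Malformed Newick text; carries the approximate offending position."""

    def __init__(self, message: str, position: int | None = None):
        self.position = position
        if position is not None:
            message = f"{message} (near position {position})"
        super().__init__(message)
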