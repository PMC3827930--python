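"""Exception hierarchy shared by all pipeline stages."""


class LipmineError(Exception):
    """Base class for all errors raised by this package."""


class ConstraintError(LipmineError, ValueError):
    """A generator/spec constraint is violated; message names the field."""


class InputError(LipmineError, ValueError):
    """Invalid input data (empty sequence, missing residue, bad matrix...)."""


class ConfigurationError(LipmineError, ValueError):
    """Invalid stage configuration (empty keyword list, overlapping thresholds...)."""


class FeatureError(LipmineError, ValueError):
    """A required sequence feature is undefined (e.g. lid without a Cys pair)."""


class ParseError(InputError):
    """Malformed structured text (PDB, FASTA); carries a line number when known."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class JoinError(LipmineError, ValueError):
    """Stage outputs disagree on candidate identifiers; message lists orphans."""
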