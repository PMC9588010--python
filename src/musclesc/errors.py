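"""Exception hierarchy for the pipeline."""


class MuscleSCError(Exception):
    """Base class for all package errors."""


class FormatError(MuscleSCError):
    """A file is missing or does not parse as the expected format."""


class IntegrityError(MuscleSCError):
    """A file parses but violates its own declared structure."""


class ValidationError(MuscleSCError, ValueError):
    """A parameter or design value is outside its legal range."""


class EmptyResultError(MuscleSCError):
    """An operation produced an empty matrix where data is required."""
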