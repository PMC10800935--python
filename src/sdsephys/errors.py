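"""Exception hierarchy shared across the package.

All user-input problems derive from :class:`ValidationError` so the CLI can
map them to a distinct exit code; everything else is a runtime failure.
"""


class ValidationError(ValueError):
    """Invalid configuration, table contents, or operation preconditions."""


class FormatError(ValidationError):
    """A file does not conform to its declared on-disk format."""


class UnitError(ValidationError):
    """An operation received a signal in the wrong physical units."""


class FitError(RuntimeError):
    """A numerical fit could not be performed."""
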