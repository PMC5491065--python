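"""Exception hierarchy for otopattern.

All library errors derive from :class:`OtopatternError` so callers can catch
one base class; the three subclasses distinguish malformed files, contract
violations on otherwise well-formed data, and illegal pipeline-stage
transitions.
"""


class OtopatternError(Exception):
    """Base class for all otopattern errors."""


class FormatError(OtopatternError):
    """A file does not conform to its expected on-disk dialect."""


class ValidationError(OtopatternError):
    """Well-formed input violates a documented contract (e.g. negative
    signal, duplicate sample id, unknown group label)."""


class StageError(OtopatternError):
    """An operation was applied to an expression matrix at the wrong
    processing stage or scale."""


class ConfigError(OtopatternError):
    """A simulation or pipeline configuration is internally inconsistent."""
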