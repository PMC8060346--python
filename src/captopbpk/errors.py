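"""Exception hierarchy shared across the pipeline."""


class CaptoPBPKError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CaptoPBPKError):
    """A config file, table or spec is missing, malformed or inconsistent."""


class DomainError(CaptoPBPKError, ValueError):
    """An input is outside the mathematical domain of an operation."""


class ValidationError(CaptoPBPKError, ValueError):
    """A domain object violates one of its invariants."""


class DataIntegrityError(CaptoPBPKError):
    """A packaged data file does not match its frozen checksum."""


class AlignmentError(CaptoPBPKError):
    """Profiles expected on a common sampling schedule are misaligned."""


class SimulationError(CaptoPBPKError):
    """The ODE solver failed for a subject."""
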