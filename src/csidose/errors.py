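"""Exception hierarchy shared by all csidose modules."""


class CsidoseError(Exception):
    """Base class for all csidose-specific errors."""


class ValidationError(CsidoseError, ValueError):
    """An input object violates a structural invariant (bad DVH, bad units, ...)."""


class DomainError(CsidoseError, ValueError):
    """A mathematically undefined request (e.g. negative-a EUD on a zero-dose bin)."""


class ConfigurationError(CsidoseError):
    """Mismatched or unknown configuration (modality mismatch, unknown method, ...)."""


class InconsistencyError(ValidationError):
    """Mutually contradictory inputs (same EUD mapped to two different NTCPs)."""
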