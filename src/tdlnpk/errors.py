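"""Exception hierarchy for tdlnpk."""


class TdlnpkError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(TdlnpkError, ValueError):
    """A physical parameter is outside its admissible range."""


class ContractError(TdlnpkError, ValueError):
    """An operation was called with inputs that violate its contract."""


class IntegrationError(TdlnpkError, RuntimeError):
    """The ODE solver failed; carries a diagnostic state snapshot."""

    def __init__(self, message: str, snapshot=None):
        super().__init__(message)
        self.snapshot = snapshot


class UnknownStudyError(TdlnpkError, KeyError):
    """Requested study id is not in the registry."""
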