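"""Exception hierarchy for costkit."""


class CostkitError(Exception):
    """Base class for all costkit errors."""


class DomainError(CostkitError, ValueError):
    """An argument is outside the mathematical domain of an operation."""


class FormatError(CostkitError, ValueError):
    """A ledger file is malformed (missing field, bad enum, unparsable number)."""


class LedgerValidationError(CostkitError, ValueError):
    """A ledger failed validation where a valid ledger is a precondition."""


class ConfigurationError(CostkitError, ValueError):
    """An analysis references a component or setting the ledger cannot resolve."""
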