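"""Exception hierarchy.

All package errors derive from :class:`HarvestLedgerError` so callers can
catch everything the pipeline may raise with a single handler.
"""


class HarvestLedgerError(Exception):
    """Base class for all errors raised by harvestledger."""


class SchemaError(HarvestLedgerError):
    """An input table is missing a mandatory column or is malformed."""


class ValidationError(HarvestLedgerError):
    """A record violates a domain invariant (signs, pools, linkage)."""


class DomainError(HarvestLedgerError, ValueError):
    """A scalar argument is outside the mathematical domain of an operation."""


class EstimationError(HarvestLedgerError):
    """A density/AGB estimate cannot be formed from the available records."""


class DensityLookupError(EstimationError):
    """No species-level match in the wood-density reference table."""


class ConfigurationError(HarvestLedgerError):
    """A configuration file or object is invalid or incomplete."""


class PairingError(HarvestLedgerError):
    """Reference and estimate records cannot be matched one-to-one."""
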