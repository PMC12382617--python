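"""Exception hierarchy for :mod:`ebeamkin`.

All package-specific errors derive from :class:`EbeamKinError` so callers can
catch everything the library raises with a single clause.
"""


class EbeamKinError(Exception):
    """Base class for all ebeamkin errors."""


class FormatError(EbeamKinError, ValueError):
    """A file does not conform to the expected dialect (e.g. missing column)."""


class ValidationError(EbeamKinError, ValueError):
    """Data violate an invariant (duplicate keys, negative dose/area, ...)."""


class DomainError(EbeamKinError, ValueError):
    """An argument is outside the physical domain (e.g. negative dose)."""


class InsufficientDataError(EbeamKinError, ValueError):
    """Not enough observations (distinct doses, baseline rows) to fit."""


class NoSignalError(EbeamKinError, ValueError):
    """A degradation-product series is identically zero."""


class UnidentifiableError(EbeamKinError, ValueError):
    """The requested quantity is not identifiable from the given design."""


class ConvergenceError(EbeamKinError, RuntimeError):
    """The optimizer failed to converge; the message carries diagnostics."""


class LedgerError(EbeamKinError, ValueError):
    """The pathway/energetics ledger file fails schema validation."""
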