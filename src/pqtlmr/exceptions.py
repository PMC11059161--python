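"""Exception hierarchy.

Everything raised deliberately by the package derives from :class:`PqtlMrError`
so callers (notably the discovery pipeline, which must tolerate per-pair
failures) can catch one base class.
"""


class PqtlMrError(Exception):
    """Base class for all package errors."""


class SummaryFormatError(PqtlMrError):
    """A summary-statistics file is malformed (e.g. a mandatory column is missing)."""


class EmptyInputError(PqtlMrError):
    """An input that must contain at least one record is empty."""


class MissingLdError(PqtlMrError):
    """A variant required for an LD lookup is absent from the LD panel."""


class ConfigurationError(PqtlMrError):
    """Inconsistent configuration (e.g. gene and region on different chromosomes)."""


class DegenerateInstrumentError(PqtlMrError):
    """The exposure effect of an instrument is zero; the Wald ratio is undefined."""


class InsufficientInstrumentsError(PqtlMrError):
    """Fewer instruments than the estimator requires."""


class EmptyOverlapError(PqtlMrError):
    """Two regions share no variants after harmonization."""


class InsufficientTraitsError(PqtlMrError):
    """Multi-trait colocalization needs at least two traits."""


class InvalidParameterError(PqtlMrError):
    """A numeric parameter is outside its valid domain."""


class ContractViolationError(PqtlMrError):
    """An internal decision-rule contract was violated (e.g. coloc supplied for a null MR)."""
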