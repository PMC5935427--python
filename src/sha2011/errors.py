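"""Exception hierarchy shared across the accounting pipeline.

Every stage raises a distinct subclass so that the orchestrator (and the
CLI) can abort with a stage-tagged message instead of a bare traceback.
"""


class Sha2011Error(Exception):
    """Base class for all package errors."""


class ConfigurationError(Sha2011Error):
    """Invalid generator or pipeline configuration; names the offending field."""


class SchemaError(Sha2011Error):
    """An input file is structurally unusable (missing columns/keys)."""


class SamplingError(Sha2011Error):
    """A survey sampling plan requests more units than exist."""


class ClassificationError(Sha2011Error):
    """An ICD-10 code, chapter label or age cannot be classified."""


class EstimationError(Sha2011Error):
    """A coefficient cannot be estimated (empty survey, zero denominator)."""


class AccountsError(Sha2011Error):
    """Internal inconsistency in the accounts cube (e.g. a negative cell)."""


class ReportingError(Sha2011Error):
    """A table cannot be rendered (e.g. an unmapped provider stratum)."""
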