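"""Exception hierarchy for cellkin.

Every error raised on purpose by this package derives from
:class:`CellkinError`, so callers (notably the CLI) can catch one type
and exit with a named, nonzero status.
"""


class CellkinError(Exception):
    """Base class for all cellkin errors."""


class SchemaError(CellkinError):
    """A CSV or config file does not match the expected schema."""


class DataValidationError(CellkinError):
    """A value violates a domain-type invariant (e.g. negative count)."""


class DuplicateRecordError(DataValidationError):
    """Two rows describe the same (line, condition, replicate, time)."""


class ConfigError(CellkinError):
    """Invalid or incomplete configuration."""


class PairingError(CellkinError):
    """Measurements that must share group labels do not."""


class FitError(CellkinError):
    """Too few usable points (or degenerate design) for a regression."""


class ComparisonError(CellkinError):
    """A statistical comparison cannot be formed from the given fits."""


class StatTestError(CellkinError):
    """Inputs violate the preconditions of a hypothesis test."""


class BootstrapError(CellkinError):
    """A resampler raised during a bootstrap loop."""


class ReconciliationError(CellkinError):
    """No usable replicate remains for growth-curve reconciliation."""


class GenerationError(CellkinError):
    """Synthetic scenario configuration is invalid."""
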