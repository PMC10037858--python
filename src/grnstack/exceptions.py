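"""Exception hierarchy for grnstack.

Every error raised by the package derives from :class:`GrnStackError` so
callers (and the CLI) can catch package failures uniformly.
"""


class GrnStackError(Exception):
    """Base class for all grnstack errors."""


class FormatError(GrnStackError):
    """A file violates the expected tabular format (e.g. duplicate gene ids)."""


class GrnParseError(GrnStackError):
    """A cell or line could not be parsed."""


class ConsistencyError(GrnStackError):
    """Cross-file identifiers disagree (e.g. TF absent from the matrix)."""


class GrnValidationError(GrnStackError):
    """A value violates a domain invariant (self-edge, NaN score, ...)."""


class InsufficientDataError(GrnStackError):
    """Too few samples/trajectories for the requested operation."""


class GrnUsageError(GrnStackError):
    """The operation was called on data it does not apply to."""


class NumericalError(GrnStackError):
    """A numerical step failed (singular matrix, non-finite result)."""


class ConfigError(GrnStackError):
    """Invalid configuration value."""


class SimulationError(GrnStackError):
    """The ODE integration blew up or produced non-finite values."""


class SplitError(GrnStackError):
    """A train/test regulator partition could not be formed."""


class DegenerateTrainingError(GrnStackError):
    """Training labels contain a single class."""


class ContractError(GrnStackError):
    """Feature columns do not match what a fitted model expects."""


class TuningError(GrnStackError):
    """Hyper-parameter search had no usable fold/combination."""


class UndefinedMetricError(GrnStackError):
    """Metric undefined for the given labels (e.g. AUPRC with no positives)."""


class EmptyTableError(GrnStackError):
    """No level-1 method produced a score column."""


class BenchmarkError(GrnStackError):
    """The repeated-split benchmark could not be completed."""
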