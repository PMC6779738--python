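"""Exception hierarchy shared across the package.

Data problems (malformed inputs, violated invariants) raise :class:`DataError`;
statistics that are mathematically undefined on the given input raise
:class:`UndefinedStatisticError` so callers can distinguish "bad file" from
"no variation". MCMC non-convergence is its own class because the pipeline
treats it as a per-cell soft failure.
"""


class StockshiftError(Exception):
    """Base class for all package errors."""


class DataError(StockshiftError):
    """Malformed or inconsistent input data."""


class EmptyPartitionError(DataError):
    """A year/size partition selected zero records; downstream statistics refuse it."""


class UndefinedStatisticError(StockshiftError):
    """The requested statistic is undefined on this input (e.g. zero variance)."""


class ConvergenceError(StockshiftError):
    """MCMC chains failed the Gelman-Rubin convergence criterion."""
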