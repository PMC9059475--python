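"""Exception hierarchy shared by all analysis stages.

Undefined metrics raise rather than return 0, because 0 is a legal value
for several indices (SMI in particular).
"""


class OsteomechError(Exception):
    """Base class for all package errors."""


class ParameterError(OsteomechError, ValueError):
    """Invalid or infeasible input parameters."""


class RangeError(OsteomechError, ValueError):
    """A requested region lies outside the data extent."""


class DataError(OsteomechError, ValueError):
    """Input data violate a structural precondition (e.g. non-monotone displacement)."""


class UndefinedMetricError(OsteomechError):
    """The requested metric is undefined for this input (e.g. empty phase)."""


class InsufficientDataError(OsteomechError):
    """Too few samples/points to perform the requested fit or test."""


class NoContactError(OsteomechError):
    """Force never rises above the baseline: no indenter contact detected."""


class FitFailureError(OsteomechError):
    """A model fit produced a physically inadmissible result."""


class AnalysisFailureError(OsteomechError):
    """A curve-analysis step could not identify the required feature."""


class ConfigurationError(OsteomechError, ValueError):
    """Missing or inconsistent configuration (e.g. unmapped material label)."""


class SolverError(OsteomechError):
    """The finite-element system could not be solved."""


class ComparisonError(OsteomechError, ValueError):
    """Two results are not commensurable (e.g. different applied loads)."""
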