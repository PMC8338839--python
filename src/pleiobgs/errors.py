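"""Exception hierarchy.

Three broad classes map to distinct CLI exit codes: configuration problems
(bad column mappings, missing prevalence entries), format problems (malformed
input files), and numerical problems (non-convergence, degenerate designs).
"""


class PleiobgsError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PleiobgsError):
    """A required setting, column mapping or lookup entry is missing or invalid."""


class FormatError(PleiobgsError):
    """An input file violates its format contract (coordinates, sorting, numerics)."""


class NumericalError(PleiobgsError):
    """A numerical routine failed to converge or was handed an infeasible problem."""


class InsufficientDataError(NumericalError):
    """Too few observations for the requested fit."""


class DegenerateDesignError(NumericalError):
    """A regression design with no usable variation (constant predictor)."""


class CollinearityError(DegenerateDesignError):
    """A rank-deficient multi-predictor design (one predictor affine in another)."""
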