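"""Exception hierarchy shared across the package."""


class NormBenchError(Exception):
    """Base class for all package errors."""


class IdentifierError(NormBenchError):
    """Duplicate or malformed marker/sample identifiers."""


class DomainError(NormBenchError):
    """Values outside the valid domain (negative counts, bad fractions...)."""


class DegenerateLibraryError(NormBenchError):
    """A sample with zero total counts."""


class AlignmentError(NormBenchError):
    """Benchmark/test matrices or annotations cannot be aligned."""


class DegenerateDesignError(NormBenchError):
    """A group left with fewer than two samples."""


class DegeneratePercentileError(NormBenchError):
    """A sample whose scaling percentile is zero."""


class NoReferenceError(NormBenchError):
    """Median-of-ratios has no marker positive in every sample."""


class ConvergenceError(NormBenchError):
    """An iterative estimator lost its working set."""


class RankError(NormBenchError):
    """Requested number of latent factors is infeasible."""


class ControlError(NormBenchError):
    """Control marker set invalid or disjoint from the matrix."""


class DegenerateCenteringError(NormBenchError):
    """Replicate-based centering removed all variation."""


class IncompatibilityError(NormBenchError):
    """A normalization output the chosen DE backend cannot absorb."""


class InfeasibleAnchorError(NormBenchError):
    """A cluster is smaller than the requested number of anchor samples."""
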