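"""Exception hierarchy shared across the analysis modules."""


class HybridBracketError(Exception):
    """Base class for all package errors."""


class ParameterError(HybridBracketError, ValueError):
    """A model or operation parameter is outside its valid range."""


class InputError(HybridBracketError, ValueError):
    """Input data violate a structural precondition (labels, shapes, ranges)."""


class FormatError(HybridBracketError, ValueError):
    """A file or alignment violates its format contract (e.g. codon frame)."""


class SaturationError(HybridBracketError, ArithmeticError):
    """A distance correction is undefined because divergence is saturated."""


class DegenerateCompositionError(HybridBracketError, ArithmeticError):
    """Base composition makes a distance formula degenerate (theta in {0, 1})."""


class DegeneracyError(HybridBracketError, ValueError):
    """A landmark configuration or geometry is rank-deficient/degenerate."""


class NonIdentifiableError(HybridBracketError, ValueError):
    """The requested estimate is not identifiable from the given data."""


class CoverageError(HybridBracketError, ValueError):
    """A required group/position has no observations."""


class UndefinedStatisticError(HybridBracketError, ArithmeticError):
    """A statistic's denominator is zero everywhere."""


class JackknifeError(HybridBracketError, ValueError):
    """Too few resampling blocks for a jackknife standard error."""
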