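"""Exception hierarchy.

Fitting routines raise typed errors for scalar calls; map-level drivers catch
them and mask out the offending pixel instead, so whole-map computation always
completes.
"""


class PseudoMRError(Exception):
    """Base class for all package errors."""


class DomainError(PseudoMRError, ValueError):
    """A physical parameter is outside its valid domain (e.g. T1 <= 0)."""


class StructuralError(PseudoMRError, ValueError):
    """Shapes, masks, or series structure are inconsistent."""


class EmptyMaskError(StructuralError):
    """An operation that needs at least one in-mask pixel received none."""


class DegenerateFitError(PseudoMRError):
    """The data admit no informative fit (constant signals, zero design, ...)."""


class FitConvergenceError(PseudoMRError):
    """Nonlinear least squares failed to converge within the iteration budget."""


class InsufficientDataError(PseudoMRError):
    """Too few usable points remain after exclusions to identify the model."""


class DegenerateGeometryError(PseudoMRError):
    """Scattered (mu, sigma) nodes are collinear; triangulation is impossible."""


class FormatError(PseudoMRError):
    """An image file could not be read or its format was ambiguous."""


class ConfigError(PseudoMRError):
    """A pipeline configuration is missing or has invalid fields."""
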