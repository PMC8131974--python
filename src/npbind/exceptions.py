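"""Exceptions and warning categories shared across the package."""


class FitError(ValueError):
    """A regression could not be performed (too few usable points, or the
    data transform excluded everything).  The message names the cause."""


class NoPeakError(ValueError):
    """A spectral window contains no resolvable extremum."""


class NonPhysicalWarning(UserWarning):
    """A fitted quantity fell outside its physically meaningful range
    (e.g. accessible fraction theta not in (0, 1])."""


class ExcludedPointsWarning(UserWarning):
    """Data points were dropped before a fit (fluorescence enhancement,
    zero-quencher rows under a log/reciprocal transform)."""


class UnitDependenceWarning(UserWarning):
    """A result depends on the concentration units of the equilibrium
    constant supplied (van't Hoff intercept entropies)."""


class DegenerateFitWarning(UserWarning):
    """The fit is formally defined but carries no information
    (e.g. no quenching at all: every F equals F0)."""
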