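"""Exception hierarchy shared across the fluxpattern stages."""


class FluxPatternError(Exception):
    """Base class for all package-specific errors."""


class DimensionError(FluxPatternError):
    """Structural-model dimensions are infeasible (e.g. L too small)."""


class SimulationError(FluxPatternError):
    """Cohort simulation failed (e.g. simplex repair rate too high)."""


class ScreenConfigError(FluxPatternError):
    """An association screen was configured so that nothing survives filtering."""


class CollinearityError(FluxPatternError):
    """Predictor of interest is collinear with the covariates."""


class SampleSizeError(FluxPatternError):
    """Too few usable samples for the requested regression."""


class DegeneratePatternError(FluxPatternError):
    """Pattern regression is degenerate (zero-variance in silico statistics)."""


class StateError(FluxPatternError):
    """A stage was invoked before its prerequisites were computed."""


class StoichiometryConflictError(FluxPatternError):
    """Two reconstructions define the same reaction id with different stoichiometry."""


class MissingModelError(FluxPatternError):
    """A microbe with positive abundance has no reconstruction."""


class InfeasibleModelError(FluxPatternError):
    """The community LP has no feasible flux distribution."""


class ModelConstructionError(FluxPatternError):
    """The community LP is unbounded or otherwise ill-posed."""


class FormatError(FluxPatternError):
    """An input table violates the expected layout."""


class ValidationError(FluxPatternError):
    """A reconstruction or config file violates its schema."""
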