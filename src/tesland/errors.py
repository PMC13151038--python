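"""Exception hierarchy shared across the package."""


class TeslandError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(TeslandError, ValueError):
    """An input table is missing a required column."""


class ValidationError(TeslandError, ValueError):
    """Input values violate a documented invariant (e.g. land-cover sums)."""


class StructureError(TeslandError, ValueError):
    """Inputs are structurally malformed (ragged grid, misaligned arrays)."""


class DomainError(TeslandError, ValueError):
    """A scalar argument lies outside its mathematical domain."""


class FitError(TeslandError, ValueError):
    """A regression cannot be performed (too few points, degenerate data)."""


class DegenerateSeriesError(FitError):
    """A growth series has zero maximum and cannot be normalized."""


class BuildInfeasibleError(TeslandError, ValueError):
    """A scenario is provably infeasible before any solve is attempted."""


class SolveError(TeslandError, RuntimeError):
    """The optimizer failed to return a usable solution."""


class InfeasibleError(SolveError):
    """The model is infeasible; the message names the suspect constraint family."""


class SequencingError(TeslandError, ValueError):
    """Scenarios were requested in an order that breaks a data dependency."""
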