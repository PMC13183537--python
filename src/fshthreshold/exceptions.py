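"""Exception hierarchy for cohort validation and model fitting."""


class FshThresholdError(Exception):
    """Base class for all package errors."""


class SchemaError(FshThresholdError):
    """Input table violates the cycle-record schema."""


class EmptyInputError(FshThresholdError):
    """An operation received an empty cohort or file."""


class ConfigurationError(FshThresholdError):
    """Invalid policy, simulation, or run configuration."""


class TertileError(FshThresholdError):
    """Tertile assignment impossible (too few distinct values)."""


class AmbiguityError(FshThresholdError):
    """Duplicate (patient, cycle) pairs make the first cycle ambiguous."""


class CollinearityError(FshThresholdError):
    """Rank-deficient design matrix."""

    def __init__(self, message, aliased=None):
        super().__init__(message)
        self.aliased = list(aliased) if aliased else []


class ConvergenceError(FshThresholdError):
    """GEE coefficient/correlation alternation failed to converge."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace


class SearchError(FshThresholdError):
    """Breakpoint search had no admissible candidate."""


class BootstrapError(FshThresholdError):
    """Too many bootstrap replicates failed."""

    def __init__(self, message, failures=None):
        super().__init__(message)
        self.failures = failures or []


class ComparisonError(FshThresholdError):
    """Nested models were fitted on different rows."""


class FoldError(FshThresholdError):
    """A cross-validation fold has no evaluable cycles."""


class BasisError(FshThresholdError):
    """Spline basis cannot be built (too few distinct exposure values)."""


class StratumError(FshThresholdError):
    """Invalid stratum definition."""
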