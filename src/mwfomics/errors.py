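"""Exception hierarchy for the mwfomics pipeline."""


class MwfomicsError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(MwfomicsError):
    """A simulation or run configuration violates its invariants."""


class ParameterError(MwfomicsError):
    """An analysis parameter is outside its valid range."""


class InputError(MwfomicsError):
    """An input table, volume, or identifier is malformed or inconsistent."""


class SingularDesignError(InputError):
    """Design matrix is rank deficient.

    Attributes
    ----------
    columns : list of str
        Names of the columns implicated in the rank deficiency.
    """

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(
            "design matrix is rank deficient; offending columns: "
            + ", ".join(map(str, self.columns))
        )


class InsufficientDataError(InputError):
    """Fewer observations than model parameters."""


class EmptyJoinError(InputError):
    """Two tables that must share keys have an empty intersection."""


class DegenerateInputError(InputError):
    """An input has zero variance where variation is required."""


class InsufficientRegionsError(InputError):
    """Fewer than the minimum number of regions for a correlation."""


class UndefinedStabilityError(InputError):
    """Differential stability requested with fewer than two donors."""
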