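"""Exception hierarchy shared across the package."""


class LaiprojError(Exception):
    """Base class for all package-specific errors."""


class FormatError(LaiprojError):
    """A file does not have the expected structure (variable, dims, ...)."""


class AlignmentError(LaiprojError):
    """Grids, time indexes or factor sets of two objects do not match."""


class ArgumentError(LaiprojError, ValueError):
    """An argument violates a documented precondition."""


class EmptyRegionError(LaiprojError):
    """A regional reduction found no eligible (unmasked, vegetated) cells."""


class DegenerateObservationsError(LaiprojError):
    """Observations are constant; R^2 (and hence DISO) is undefined."""


class SampleSizeError(LaiprojError):
    """Too few paired samples for the requested statistic or fit."""


class ContractError(LaiprojError):
    """A fitted model was used outside its fit-time contract."""
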