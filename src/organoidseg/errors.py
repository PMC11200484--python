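"""Exception hierarchy used across the package."""


class OrganoidSegError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(OrganoidSegError, ValueError):
    """A numerical parameter is outside its admissible range."""


class ContractError(OrganoidSegError, ValueError):
    """An operation was called with inconsistent arguments (shape mismatch etc.)."""


class DegenerateRegionError(OrganoidSegError):
    """One of the two regions carries (almost) no smoothed weight."""


class NumericalInstabilityError(OrganoidSegError):
    """The level-set field became non-finite during evolution."""

    def __init__(self, iteration: int):
        self.iteration = iteration
        super().__init__(f"level-set field became non-finite at iteration {iteration}")


class InitializationError(OrganoidSegError):
    """Automatic initial-contour generation failed for the given seed point."""


class PhantomSpecError(OrganoidSegError, ValueError):
    """A phantom specification violates one of its invariants."""


class ImageIOError(OrganoidSegError, OSError):
    """Reading or writing an image/config file failed."""
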