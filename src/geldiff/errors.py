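"""Exception hierarchy shared across the package."""


class GeldiffError(Exception):
    """Base class for all package errors."""


class ParameterError(GeldiffError, ValueError):
    """A model parameter violates its physical constraints."""


class DomainError(GeldiffError, ValueError):
    """An evaluation point lies outside the physical domain (r < 0, t < 0)."""


class ConfigError(GeldiffError, ValueError):
    """A configuration file or table is malformed or incomplete."""


class NumericsError(GeldiffError, RuntimeError):
    """A numerical routine failed to reach its accuracy target or blew up."""


class GeometryError(GeldiffError, ValueError):
    """An image-geometry request cannot be satisfied (e.g. empty annulus)."""


class DegenerateInputError(GeldiffError, ValueError):
    """Input carries no information for the requested operation."""


class FitError(GeldiffError, RuntimeError):
    """A least-squares fit failed or the data cannot constrain the model."""


class BootstrapError(GeldiffError, RuntimeError):
    """Too many bootstrap refits failed to produce a trustworthy interval."""
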