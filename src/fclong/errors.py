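"""Exception hierarchy shared across the package."""


class FclongError(Exception):
    """Base class for all package-specific errors."""


class FormatError(FclongError, ValueError):
    """A tabular input (atlas, manifest, FC file) violates its format contract."""


class GeometryError(FclongError, ValueError):
    """An image geometry (affine, grid) is unusable, e.g. a singular affine."""


class ConfigError(FclongError, ValueError):
    """A configuration object is internally inconsistent or infeasible."""


class DataError(FclongError, ValueError):
    """Input data violate a precondition (too few frames, empty cohort, ...)."""
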