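"""Exception hierarchy shared across the package."""


class LaminarError(Exception):
    """Base class for all package-specific errors."""


class SpecError(LaminarError, ValueError):
    """A simulation or analysis specification is invalid."""


class GeometryError(LaminarError, ValueError):
    """Boundary contours or trace geometry are degenerate."""


class BoundsError(LaminarError, ValueError):
    """A requested sample position falls outside the image raster."""


class NoAdmissibleSplitError(LaminarError, ValueError):
    """The quartic second derivative has no two real roots strictly inside (0, 1).

    Carries the root diagnostics so callers can report why the laminar
    subdivision failed for a given profile.
    """

    def __init__(self, message: str, roots=None, coeffs=None):
        super().__init__(message)
        self.roots = roots
        self.coeffs = coeffs


class SchemaError(LaminarError, KeyError):
    """A required input table column is missing."""
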