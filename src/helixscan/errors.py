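"""Package-wide exception types."""


class HelixscanError(Exception):
    """Base class for all helixscan errors."""


class InvalidLengthError(HelixscanError, ValueError):
    """Chain too short for the requested operation."""


class SingularGeometryError(HelixscanError, ValueError):
    """Two residues (near-)overlap; angles and contacts are undefined."""


class ShapeMismatchError(HelixscanError, ValueError):
    """Index set or array shape inconsistent with the conformation."""


class SingularGradientError(HelixscanError, ArithmeticError):
    """dRMSD gradient requested at R = 0 where dR/dx is undefined."""


class InvalidConfigError(HelixscanError, ValueError):
    """Malformed sampling or analysis configuration."""


class UnknownResidueError(HelixscanError, KeyError):
    """Residue type without a packaged reference entry."""


class DisconnectedHistogramError(HelixscanError, RuntimeError):
    """Umbrella windows whose histograms do not overlap; WHAM cannot join them."""


class WhamConvergenceError(HelixscanError, RuntimeError):
    """Self-consistent WHAM iteration exceeded max_iter."""


class EmptyProfileError(HelixscanError, ValueError):
    """No usable (non-missing) entries in a shift table or profile."""


class UndefinedReferenceError(HelixscanError, ValueError):
    """Reference propensity non-positive over a requested region."""
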