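"""Exception hierarchy shared across the package."""


class PhonoramanError(Exception):
    """Base class for all package errors."""


class InvalidStructureError(PhonoramanError):
    """Structure violates an invariant (degenerate lattice, bad masses, ...)."""


class CifParseError(PhonoramanError):
    """Malformed CIF input; the message names the offending item."""


class InconsistentSymmetryError(PhonoramanError):
    """A symmetry operation does not map the structure (or its molecules) onto itself."""


class ForceFieldError(PhonoramanError):
    """Force-field specification problem (bad indices, non-positive constants, ...)."""


class ParameterError(PhonoramanError):
    """Invalid numerical parameter (step sizes, tolerances, amplitudes)."""


class ForceConstantsParseError(PhonoramanError):
    """Malformed FORCE_CONSTANTS file; the message carries a line number."""


class AmbiguousAssignmentError(PhonoramanError):
    """A mode's character vector matches no irrep within the residual tolerance."""


class CorrelationError(PhonoramanError):
    """No consistent parent-to-subgroup irrep mapping exists."""


class ModeNotImaginaryError(PhonoramanError):
    """Eigenvector following requested on a mode with a real frequency."""


class DescentError(PhonoramanError):
    """Saddle descent failed to lower the energy."""


class WindowError(PhonoramanError):
    """Spectral window outside the spectrum grid, or inconsistent map grids."""


class ConfigError(PhonoramanError):
    """Invalid analysis configuration (references, windows, spectrum grids)."""
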