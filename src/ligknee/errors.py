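"""Exception hierarchy shared across the package."""


class LigKneeError(Exception):
    """Base class for all package-specific errors."""


class InvalidMaterialError(LigKneeError):
    """Material coefficients violate their admissible bounds."""


class InvalidDeformationError(LigKneeError):
    """Deformation gradient is singular, non-finite, or not volume-preserving."""


class UnderDeterminedError(LigKneeError):
    """Fewer data points than free coefficients in a fit."""


class SingularPoseError(LigKneeError):
    """Joint coordinate system degenerates (floating axis undefined)."""


class DegenerateGeometryError(LigKneeError):
    """Coincident endpoints or otherwise unusable line-element geometry."""


class ConfigError(LigKneeError):
    """Model configuration is incomplete or inconsistent."""


class SolverError(LigKneeError):
    """Equilibrium solve failed to converge.

    Carries the last residual norm so callers can report how far the
    solve was from equilibrium.
    """

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class UndefinedCorrelationError(LigKneeError):
    """Pearson correlation requested on a zero-variance sequence."""


class CorridorRangeError(LigKneeError):
    """Prediction abscissa falls outside the corridor's abscissa range."""


class CaseMismatchError(LigKneeError):
    """Load-case names do not match across report inputs."""
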