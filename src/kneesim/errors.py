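"""Exception hierarchy shared across the package."""


class KneesimError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(KneesimError, ValueError):
    """A model or protocol parameter violates its constraints.

    The message names the offending field.
    """

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")


class ValidationError(KneesimError, ValueError):
    """An input (series, trace, argument) fails a precondition."""


class SingularityError(KneesimError, ValueError):
    """Joint coordinate decomposition is undefined (ad/abduction near +/-90 deg)."""


class StlFormatError(KneesimError, ValueError):
    """A malformed STL file; carries the byte offset where parsing failed."""

    def __init__(self, message: str, byte_offset: int = 0):
        self.byte_offset = byte_offset
        super().__init__(f"{message} (byte offset {byte_offset})")


class DegenerateGeometryError(KneesimError, ValueError):
    """A direction or frame cannot be constructed (e.g. coincident attachments)."""


class SettlingError(KneesimError, RuntimeError):
    """Static-equilibrium settling failed to converge; carries the residual."""

    def __init__(self, message: str, residual: float):
        self.residual = residual
        super().__init__(f"{message} (residual {residual:.3e})")


class SimulationError(KneesimError, RuntimeError):
    """Squat simulation failed (divergence, deep penetration); carries sample index."""

    def __init__(self, message: str, sample: int):
        self.sample = sample
        super().__init__(f"{message} (sample {sample})")


class CalibrationError(KneesimError, RuntimeError):
    """Every trial point of a calibration failed to simulate."""
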