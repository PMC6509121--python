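"""Exception hierarchy.

All package errors derive from :class:`CartimechError` so callers can catch
domain failures without swallowing programming errors.
"""


class CartimechError(Exception):
    """Base class for all cartimech errors."""


class DomainError(CartimechError, ValueError):
    """An input lies outside the mathematical domain of an operation."""


class UnidentifiableFitError(CartimechError, ValueError):
    """A signal series carries no information about the sought parameter
    (e.g. all-equal magnitudes, vanishing amplitude)."""


class CalibrationError(CartimechError, ValueError):
    """Relaxation-time-vs-composition calibration cannot be established
    (degenerate or non-monotone training data)."""


class SaturationError(CartimechError, ValueError):
    """The mixture saturation condition would leave a non-positive
    proteoglycan fraction somewhere."""


class NormalizationError(CartimechError, ValueError):
    """A weight set violates the per-constituent normalization condition."""


class CompactionError(CartimechError, ValueError):
    """Volume ratio at or below the compaction point J -> phi_s: all fluid
    expelled, osmotic pressure diverges."""


class SolverError(CartimechError, RuntimeError):
    """Equilibrium solver failed to converge; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class ConfigurationError(CartimechError, ValueError):
    """Invalid run configuration (missing files, empty mask, bad options)."""


class FormatError(CartimechError, ValueError):
    """File content inconsistent with the expected on-disk format."""
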