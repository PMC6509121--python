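"""Per-pixel relaxometry: signal models, nonlinear fits and parameter maps.

Four magnitude signal models are supported, one per quantitative MRI
modality:

* ``T1`` — inversion recovery, ``|A[1 - 2 exp(-TI/T1) + exp(-TR/T1)]|``
* ``T1rho`` — spin-lock decay, ``A exp(-TSL/T1rho)``
* ``T2`` — multi-spin-echo decay with offset, ``A exp(-TE/T2) + B``
* ``T2star`` — multi-gradient-echo decay, ``A exp(-TE/T2*)``

Times are in milliseconds, magnitudes in arbitrary units.  For the T2 and
T2* models only echoes with ``TE <= te_cutoff_ms`` (default 60 ms) enter the
fit, which suppresses mis-fits from late, noise-dominated echoes.  Fit
quality is reported as the adjusted coefficient of determination.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from scipy.optimize import least_squares

from .errors import ConfigurationError, DomainError, UnidentifiableFitError

MODALITIES = ("T1", "T1rho", "T2", "T2star")

#: Free parameters per model: (amplitude, relaxation time[, offset]).
_N_FREE = {"T1": 2, "T1rho": 2, "T2": 3, "T2star": 2}

#: Sentinel quality for fits that did not converge.
FAILED_FIT_QUALITY = -np.inf

LN2 = float(np.log(2.0))


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AcquisitionProtocol:
    """Timing protocol of one quantitative sequence.

    ``timing_values_ms`` are inversion times (T1), spin-lock durations
    (T1rho) or echo times (T2/T2*).  ``tr_ms`` is required for the T1
    inversion-recovery model.
    """

    modality: str
    timing_values_ms: tuple[float, ...]
    tr_ms: float | None = None
    te_cutoff_ms: float = 60.0

    def __post_init__(self):
        if self.modality not in MODALITIES:
            raise DomainError(f"unknown modality {self.modality!r}")
        t = np.asarray(self.timing_values_ms, dtype=float)
        object.__setattr__(self, "timing_values_ms", tuple(t.tolist()))
        if t.size < 2 or np.any(np.diff(t) <= 0):
            raise DomainError("timing values must be strictly increasing")
        min_allowed = 0.0 if self.modality == "T1rho" else np.nextafter(0.0, 1.0)
        if t[0] < min_allowed:
            raise DomainError("timing values must be positive "
                              "(a zero spin-lock time is allowed for T1rho)")
        if self.modality == "T1":
            if self.tr_ms is None:
                raise DomainError("T1 inversion recovery requires tr_ms")
            if self.tr_ms <= t[-1]:
                raise DomainError("repetition time must exceed the longest "
                                  "inversion time")

    @property
    def timings(self) -> np.ndarray:
        return np.asarray(self.timing_values_ms, dtype=float)

    def effective_timings(self) -> np.ndarray:
        """Timings actually used by a fit (echo-time cutoff for T2/T2*)."""
        t = self.timings
        if self.modality in ("T2", "T2star"):
            return t[t <= self.te_cutoff_ms]
        return t

    @classmethod
    def default(cls, modality: str) -> "AcquisitionProtocol":
        """Scanner-protocol timing grids used throughout the package.

        T1: TI = 150...1500 ms at TR = 3000 ms; T1rho: spin-lock 0-40 ms;
        T2: TE = n*8.38 ms (n = 1-12); T2*: TE = 3.9 + n*9.6 ms (n = 1-14).
        """
        if modality == "T1":
            return cls("T1", (150.0, 300.0, 500.0, 800.0, 1000.0, 1500.0),
                       tr_ms=3000.0)
        if modality == "T1rho":
            return cls("T1rho", (0.0, 10.0, 20.0, 30.0, 40.0), tr_ms=30.0)
        if modality == "T2":
            return cls("T2", tuple(8.38 * n for n in range(1, 13)),
                       tr_ms=1500.0)
        if modality == "T2star":
            return cls("T2star", tuple(3.9 + 9.6 * n for n in range(1, 15)),
                       tr_ms=700.0)
        raise DomainError(f"unknown modality {modality!r}")


@dataclass(frozen=True)
class SignalSeries:
    """One pixel's magnitudes sampled at the protocol timings."""

    timings_ms: tuple[float, ...]
    magnitudes: tuple[float, ...]

    def __post_init__(self):
        t = np.asarray(self.timings_ms, dtype=float)
        m = np.asarray(self.magnitudes, dtype=float)
        if t.shape != m.shape:
            raise DomainError("timings and magnitudes must have equal length")
        if np.any(m < 0):
            raise DomainError("magnitude MR data must be non-negative")
        object.__setattr__(self, "timings_ms", tuple(t.tolist()))
        object.__setattr__(self, "magnitudes", tuple(m.tolist()))

    @property
    def t(self) -> np.ndarray:
        return np.asarray(self.timings_ms, dtype=float)

    @property
    def y(self) -> np.ndarray:
        return np.asarray(self.magnitudes, dtype=float)


@dataclass(frozen=True)
class SignalModelFit:
    """Estimated (relaxation time, amplitude[, offset]) with fit quality."""

    modality: str
    relaxation_time_ms: float
    amplitude: float
    offset: float = 0.0
    adjusted_r2: float = 1.0

    def __post_init__(self):
        if self.modality not in MODALITIES:
            raise DomainError(f"unknown modality {self.modality!r}")
        if not self.relaxation_time_ms > 0:
            raise DomainError("relaxation time must be positive")
        if self.adjusted_r2 > 1.0 + 1e-12:
            raise DomainError("adjusted R^2 cannot exceed 1")


@dataclass
class ParameterMap:
    """2-D relaxation-time map with per-pixel fit quality and mask.

    ``values`` are in ms and defined (finite, positive) wherever ``mask``
    is true and the fit converged; elsewhere NaN with
    ``quality = -inf`` flagging failed fits inside the mask.
    """

    modality: str
    values: np.ndarray
    quality: np.ndarray
    mask: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.quality = np.asarray(self.quality, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if not (self.values.shape == self.quality.shape == self.mask.shape):
            raise DomainError("values, quality and mask shapes must agree")
        if self.values.ndim != 2:
            raise DomainError("parameter maps are 2-D")

    def valid(self) -> np.ndarray:
        """Pixels inside the mask whose fit converged."""
        return self.mask & np.isfinite(self.values) & (self.values > 0)


# --------------------------------------------------------------------------
# forward models
# --------------------------------------------------------------------------

def _predict(modality: str, t: np.ndarray, relaxation_time: float,
             amplitude: float, offset: float, tr_ms: float | None) -> np.ndarray:
    if relaxation_time <= 0:
        raise DomainError("relaxation time must be positive")
    if modality == "T1":
        return np.abs(amplitude * (1.0 - 2.0 * np.exp(-t / relaxation_time)
                                   + np.exp(-tr_ms / relaxation_time)))
    if modality in ("T1rho", "T2star"):
        return amplitude * np.exp(-t / relaxation_time)
    if modality == "T2":
        return amplitude * np.exp(-t / relaxation_time) + offset
    raise DomainError(f"unknown modality {modality!r}")


def model_signal(fit: SignalModelFit,
                 protocol: AcquisitionProtocol) -> SignalSeries:
    """Model-predicted magnitudes at the protocol timings.

    The T1 model returns the absolute value (magnitude inversion recovery),
    so the predicted signal vanishes at the null point TI = T1*ln 2 when
    TR >> T1.
    """
    if fit.modality != protocol.modality:
        raise DomainError(
            f"fit modality {fit.modality!r} does not match protocol "
            f"{protocol.modality!r}")
    y = _predict(fit.modality, protocol.timings, fit.relaxation_time_ms,
                 fit.amplitude, fit.offset, protocol.tr_ms)
    return SignalSeries(protocol.timing_values_ms, tuple(np.maximum(y, 0.0)))


# --------------------------------------------------------------------------
# per-series fitting
# --------------------------------------------------------------------------

def _initial_guess(modality: str, t: np.ndarray, y: np.ndarray,
                   tr_ms: float | None):
    if modality == "T1":
        # Null-point heuristic: the magnitude minimum sits near TI = T1*ln2.
        t1_0 = max(t[int(np.argmin(y))] / LN2, 1.0)
        return np.array([np.max(y), t1_0])
    # Log-linearized decay for the exponential models.
    offset0 = 0.0
    if modality == "T2":
        offset0 = 0.5 * float(np.min(y))
    yy = np.maximum(y - offset0, 1e-12 * max(float(np.max(y)), 1.0))
    # Ignore zero-time points in the slope estimate denominator guard.
    slope, intercept = np.polyfit(t, np.log(yy), 1)
    tau0 = -1.0 / slope if slope < -1e-12 else float(np.max(t[t > 0]))
    amp0 = float(np.exp(intercept))
    if modality == "T2":
        return np.array([amp0, max(tau0, 1e-2), offset0])
    return np.array([amp0, max(tau0, 1e-2)])


def fit_signal_model(series: SignalSeries, protocol: AcquisitionProtocol,
                     modality: str | None = None) -> SignalModelFit:
    """Nonlinear least-squares fit of one signal series.

    Applies the echo-time cutoff for T2/T2* before fitting, requires at
    least (free parameters + 1) remaining points, and reports the adjusted
    coefficient of determination 1 - (1-R^2)(n-1)/(n-p-1).  A degenerate
    series (all-equal magnitudes or vanishing amplitude) raises
    :class:`UnidentifiableFitError`; an optimizer failure returns a flagged
    fit with ``adjusted_r2 = -inf`` rather than raising.
    """
    modality = modality or protocol.modality
    if modality != protocol.modality:
        raise DomainError("modality disagrees with protocol")
    t = series.t
    y = series.y
    if modality in ("T2", "T2star"):
        keep = t <= protocol.te_cutoff_ms
        t, y = t[keep], y[keep]
    p = _N_FREE[modality]
    n = t.size
    if n < p + 1:
        raise DomainError(
            f"need at least {p + 1} timing points after the echo-time "
            f"cutoff, got {n}")
    if np.ptp(y) < 1e-12 * max(float(np.max(y)), 1.0) or np.max(y) <= 0:
        raise UnidentifiableFitError(
            "signal series carries no decay information")

    x0 = _initial_guess(modality, t, y, protocol.tr_ms)
    lo = np.array([0.0, 1e-3] + ([-np.inf] if p == 3 else []))
    hi = np.array([np.inf, 1e7] + ([np.inf] if p == 3 else []))
    x0 = np.clip(x0, lo + 1e-12, None)

    def resid(x):
        offset = x[2] if p == 3 else 0.0
        return _predict(modality, t, x[1], x[0], offset, protocol.tr_ms) - y

    try:
        res = least_squares(resid, x0, bounds=(lo, hi), method="trf",
                            xtol=1e-14, ftol=1e-14, gtol=1e-14)
    except Exception:
        res = None
    if res is None or not res.success or not np.isfinite(res.cost):
        return SignalModelFit(modality, relaxation_time_ms=1.0,
                              amplitude=0.0, offset=0.0,
                              adjusted_r2=FAILED_FIT_QUALITY)
    amp, tau = float(res.x[0]), float(res.x[1])
    offset = float(res.x[2]) if p == 3 else 0.0
    if amp < 1e-10 * max(float(np.max(y)), 1.0):
        raise UnidentifiableFitError("fitted amplitude is numerically zero")
    ss_res = float(np.sum(res.fun ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    return SignalModelFit(modality, relaxation_time_ms=tau, amplitude=amp,
                          offset=offset, adjusted_r2=min(adj, 1.0))


# --------------------------------------------------------------------------
# map building
# --------------------------------------------------------------------------

def erode_mask(mask: np.ndarray, radius: int = 1) -> np.ndarray:
    """4-connected binary erosion; boundary-pixel exclusion against partial
    volume effects.  Erosion is skipped (with a warning) when it would
    empty the mask."""
    mask = np.asarray(mask, dtype=bool)
    if radius <= 0:
        return mask
    structure = ndimage.generate_binary_structure(2, 1)  # 4-connected
    eroded = ndimage.binary_erosion(mask, structure=structure,
                                    iterations=radius, border_value=0)
    if not eroded.any():
        warnings.warn("boundary erosion would empty the mask; retaining the "
                      "un-eroded mask", stacklevel=2)
        return mask
    return eroded


def build_parameter_map(image_stack: np.ndarray,
                        protocol: AcquisitionProtocol,
                        mask: np.ndarray,
                        erosion_radius: int = 1,
                        min_adjusted_r2: float | None = None) -> ParameterMap:
    """Fit every masked pixel of a (timing, row, col) stack.

    The mask is eroded by ``erosion_radius`` pixels first (boundary
    exclusion).  Pixels whose fit fails are flagged with ``-inf`` quality;
    an optional adjusted-R^2 threshold additionally masks poor fits.
    """
    stack = np.asarray(image_stack, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if stack.ndim != 3:
        raise DomainError("image stack must be (timing, row, col)")
    if stack.shape[0] != len(protocol.timing_values_ms):
        raise DomainError("stack depth disagrees with protocol timings")
    if stack.shape[1:] != mask.shape:
        raise DomainError("stack and mask shapes disagree")
    if not mask.any():
        raise ConfigurationError("mask is empty")
    fit_mask = erode_mask(mask, erosion_radius)

    values = np.full(mask.shape, np.nan)
    quality = np.full(mask.shape, np.nan)
    for r, c in zip(*np.nonzero(fit_mask)):
        series = SignalSeries(protocol.timing_values_ms,
                              tuple(stack[:, r, c]))
        try:
            fit = fit_signal_model(series, protocol)
        except (UnidentifiableFitError, DomainError):
            quality[r, c] = FAILED_FIT_QUALITY
            continue
        if fit.adjusted_r2 == FAILED_FIT_QUALITY:
            quality[r, c] = FAILED_FIT_QUALITY
            continue
        values[r, c] = fit.relaxation_time_ms
        quality[r, c] = fit.adjusted_r2
    if min_adjusted_r2 is not None:
        poor = quality < min_adjusted_r2
        values[poor] = np.nan
        fit_mask = fit_mask & ~poor
    return ParameterMap(protocol.modality, values, quality, fit_mask)
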