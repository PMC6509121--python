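"""qMRI-to-composition conversion.

Relaxation-time maps are converted into depth-resolved volume fractions of
fluid (f), collagen (co) and proteoglycan (pg) in four steps:

1. an exponential calibration ``Tx(phi) = a*exp(b*phi) + c`` between each
   relaxation time Tx and the constituent fraction phi, inverted in a
   clamped (total, continuous, monotone) form;
2. a rational depth profile
   ``phi(z) = (alpha z^3 + beta z^2 + gamma z + delta) / (eps z + 1)``
   per (modality, constituent) over normalized depth z in [0, 1]
   (z = 0 at the articular surface, z = 1 at the osteochondral interface);
3. a weighted combination ``Phi_xi(z) = sum_x w_Tx^xi * phi_xi^Tx(z)`` with
   weights normalized to 1 per constituent;
4. closure by saturation: ``Phi_pg = 1 - Phi_f - Phi_co``, required to stay
   at least ``delta_tol`` (default 1e-6) everywhere.

The idealized depth-dependent mean composition (high fluid / low solids at
the surface, the reverse at depth) is shipped as a configurable default
profile table; see :func:`wilson_reference_profile`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares, lsq_linear

from .errors import (CalibrationError, DomainError, NormalizationError,
                     SaturationError)
from .relaxometry import MODALITIES, ParameterMap

CONSTITUENTS = ("f", "co")

#: Minimal admissible proteoglycan fraction (saturation guard).
DELTA_TOL = 1e-6


# --------------------------------------------------------------------------
# idealized reference composition profiles
# --------------------------------------------------------------------------

#: Default endpoint values of the idealized mean composition profiles
#: (implementation defaults, overridable; the literature model they emulate
#: is published as a figure, not as formulas).
_FLUID_SURFACE, _FLUID_DEEP = 0.85, 0.70
_CO_SURFACE, _CO_DEEP = 0.10, 0.25


def wilson_reference_profile(z, table: dict | None = None):
    """Idealized mean volume fractions (phi_f, phi_co, phi_pg) at depth z.

    z = 0 is the articular surface, z = 1 the osteochondral interface.
    Defaults: fluid 0.85 -> 0.70 (monotone decreasing, quadratic), collagen
    0.10 -> 0.25 (monotone increasing, quadratic), proteoglycan the
    remainder.  ``table`` may supply arrays ``z``, ``phi_f``, ``phi_co``
    to override the default curves (linear interpolation).
    """
    z = np.asarray(z, dtype=float)
    if np.any(z < 0) or np.any(z > 1) or np.any(~np.isfinite(z)):
        raise DomainError("normalized depth must lie in [0, 1]")
    if table is not None:
        zt = np.asarray(table["z"], dtype=float)
        phi_f = np.interp(z, zt, np.asarray(table["phi_f"], dtype=float))
        phi_co = np.interp(z, zt, np.asarray(table["phi_co"], dtype=float))
    else:
        phi_f = _FLUID_SURFACE + (_FLUID_DEEP - _FLUID_SURFACE) * z ** 2
        phi_co = _CO_SURFACE + (_CO_DEEP - _CO_SURFACE) * z ** 2
    phi_pg = 1.0 - phi_f - phi_co
    if np.any(phi_pg <= 0):
        raise DomainError("reference profile leaves no proteoglycan fraction")
    return phi_f, phi_co, phi_pg


# --------------------------------------------------------------------------
# exponential calibration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ExponentialCalibration:
    """Monotone map Tx(phi) = a*exp(b*phi) + c with clamped inverse.

    The inverse phi(Tx) = ln((Tx - c)/a)/b is continuously extended by the
    constant fraction values ``l`` (below the lower relaxation-time bound of
    definition) and ``u`` (above the upper bound), making it a total,
    continuous, monotone function of the relaxation time.
    """

    constituent: str
    modality: str
    a: float          # ms
    b: float          # dimensionless
    c: float          # ms
    phi_lo: float     # fraction domain endpoints used in the calibration
    phi_hi: float

    def __post_init__(self):
        if self.constituent not in CONSTITUENTS:
            raise DomainError(f"unknown constituent {self.constituent!r}")
        if self.modality not in MODALITIES:
            raise DomainError(f"unknown modality {self.modality!r}")
        if self.a == 0 or self.b == 0:
            raise CalibrationError("a and b must be nonzero")
        if not 0 <= self.phi_lo < self.phi_hi <= 1:
            raise DomainError("fraction domain must satisfy 0<=lo<hi<=1")

    def forward(self, phi):
        """Tx(phi) in ms."""
        return self.a * np.exp(self.b * np.asarray(phi, dtype=float)) + self.c

    @property
    def increasing(self) -> bool:
        """True when Tx grows with phi (sign of a*b)."""
        return self.a * self.b > 0

    @property
    def tx_bounds(self) -> tuple[float, float]:
        """(lower, upper) relaxation-time bounds of definition."""
        t0 = float(self.forward(self.phi_lo))
        t1 = float(self.forward(self.phi_hi))
        return (t0, t1) if t0 < t1 else (t1, t0)

    @property
    def clamp_values(self) -> tuple[float, float]:
        """(l, u): fractions returned at/below the lower and at/above the
        upper relaxation-time bound."""
        if self.increasing:
            return self.phi_lo, self.phi_hi
        return self.phi_hi, self.phi_lo


def calibrate_exponential(profile_pairs, constituent: str,
                          modality: str) -> ExponentialCalibration:
    """Least-squares (a, b, c) for Tx(phi) = a*exp(b*phi) + c.

    ``profile_pairs`` is a sequence of (phi, Tx) pairs; at least four are
    required and the phi values must span a nondegenerate interval.
    Degenerate data (constant Tx, hence unidentifiable b) raise
    :class:`CalibrationError`.
    """
    pairs = np.asarray(list(profile_pairs), dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2 or pairs.shape[0] < 4:
        raise DomainError("need at least four (phi, Tx) pairs")
    phi, tx = pairs[:, 0], pairs[:, 1]
    if np.ptp(phi) < 1e-6:
        raise DomainError("phi values span a degenerate interval")
    scale = max(float(np.max(np.abs(tx))), 1.0)
    if np.ptp(tx) < 1e-9 * scale:
        raise CalibrationError("constant relaxation times: b unidentifiable")

    slope = np.polyfit(phi, tx, 1)[0]
    sgn = 1.0 if slope >= 0 else -1.0
    c0 = float(np.min(tx) - 0.5 * np.ptp(tx)) if sgn > 0 \
        else float(np.max(tx) + 0.5 * np.ptp(tx))
    yy = np.maximum(sgn * (tx - c0), 1e-9 * scale)
    b0, ln_a0 = np.polyfit(phi, np.log(yy), 1)
    x0 = np.array([sgn * np.exp(ln_a0), b0, c0])

    def resid(x):
        return x[0] * np.exp(np.clip(x[1] * phi, -500, 500)) + x[2] - tx

    res = least_squares(resid, x0, xtol=1e-15, ftol=1e-15, gtol=1e-15)
    a, b, c = (float(v) for v in res.x)
    if abs(a) < 1e-12 * scale or abs(b) < 1e-8:
        raise CalibrationError("degenerate calibration (a or b ~ 0)")
    return ExponentialCalibration(constituent, modality, a, b, c,
                                  phi_lo=float(np.min(phi)),
                                  phi_hi=float(np.max(phi)))


def invert_calibration(cal: ExponentialCalibration, tx_value):
    """Constituent fraction phi(Tx); total, continuous and monotone.

    Inside the calibration domain this is the exact inverse
    ``ln((Tx - c)/a)/b``; outside it returns the clamp constants.
    """
    tx = np.asarray(tx_value, dtype=float)
    if np.any(np.isnan(tx)):
        raise DomainError("NaN relaxation time")
    lo, hi = cal.tx_bounds
    l, u = cal.clamp_values
    # Clamp into the closed domain, then invert analytically.
    txc = np.clip(tx, lo, hi)
    arg = (txc - cal.c) / cal.a
    phi = np.where(arg > 0, np.log(np.maximum(arg, 1e-300)) / cal.b, np.nan)
    phi = np.where(tx <= lo, l, phi)
    phi = np.where(tx >= hi, u, phi)
    phi = np.clip(phi, min(l, u), max(l, u))
    return float(phi) if np.isscalar(tx_value) else phi


# --------------------------------------------------------------------------
# rational depth profiles
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RationalDepthFit:
    """phi(z) = (alpha z^3 + beta z^2 + gamma z + delta) / (eps z + kappa).

    kappa is fixed to 1 (gauge: numerator and denominator share a scale).
    Evaluation clips to [0, 1] (fractions).
    """

    alpha: float = 0.0
    beta: float = 0.0
    gamma: float = 0.0
    delta: float = 0.0
    eps: float = 0.0
    kappa: float = 1.0

    def __post_init__(self):
        # Linear denominator: positivity on [0, 1] is an endpoint check.
        if self.kappa <= 0 or self.eps + self.kappa <= 0:
            raise DomainError("denominator must be positive on [0, 1]")

    def __call__(self, z):
        z = np.asarray(z, dtype=float)
        num = ((self.alpha * z + self.beta) * z + self.gamma) * z + self.delta
        val = num / (self.eps * z + self.kappa)
        return np.clip(val, 0.0, 1.0)

    @classmethod
    def constant(cls, value: float) -> "RationalDepthFit":
        return cls(delta=float(value))


def fit_depth_profile(z, phi) -> RationalDepthFit:
    """Least-squares rational depth fit with the kappa = 1 gauge.

    Multiplying through by the denominator makes the problem linear:
    ``phi = alpha z^3 + beta z^2 + gamma z + delta - eps*(z*phi)``.
    If the unconstrained optimum places a denominator root inside [0, 1]
    the fit is repeated with eps bounded away from -1 and a warning is
    issued.
    """
    z = np.asarray(z, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if z.shape != phi.shape or z.size < 7:
        raise DomainError("need at least seven (z, phi) samples")
    if np.min(z) > 0.25 or np.max(z) < 0.75:
        raise DomainError("samples must span the depth interval [0, 1]")
    design = np.column_stack([z ** 3, z ** 2, z, np.ones_like(z), -z * phi])
    coeffs, *_ = np.linalg.lstsq(design, phi, rcond=None)
    if 1.0 + coeffs[4] <= 1e-6:  # root of (eps*z + 1) inside [0, 1]
        warnings.warn("denominator root inside [0, 1]; refitting with a "
                      "bounded slope", stacklevel=2)
        res = lsq_linear(design, phi,
                         bounds=([-np.inf] * 4 + [-0.95], [np.inf] * 5))
        coeffs = res.x
    return RationalDepthFit(*(float(v) for v in coeffs))


# --------------------------------------------------------------------------
# weights and composition fields
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class WeightSet:
    """Per-constituent weights of each modality's contribution (sum to 1)."""

    fluid: tuple[float, float, float, float]    # (T1, T1rho, T2, T2star)
    collagen: tuple[float, float, float, float]
    tol: float = 1e-8

    def __post_init__(self):
        for name, row in (("fluid", self.fluid), ("collagen", self.collagen)):
            row = tuple(float(v) for v in row)
            object.__setattr__(self, name, row)
            if len(row) != len(MODALITIES):
                raise NormalizationError(f"{name} weights need "
                                         f"{len(MODALITIES)} entries")
            if any(w < -self.tol or w > 1 + self.tol for w in row):
                raise NormalizationError(f"{name} weights must lie in [0,1]")
            if abs(sum(row) - 1.0) > self.tol:
                raise NormalizationError(
                    f"{name} weights sum to {sum(row):.10f}, expected 1")

    def row(self, constituent: str) -> np.ndarray:
        if constituent == "f":
            return np.asarray(self.fluid)
        if constituent == "co":
            return np.asarray(self.collagen)
        raise DomainError(f"unknown constituent {constituent!r}")

    @classmethod
    def default(cls) -> "WeightSet":
        """Globally identified weights: fluid dominated by T1/T1rho,
        collagen by T1/T2*."""
        return cls(fluid=(0.41, 0.42, 0.16, 0.01),
                   collagen=(0.31, 0.12, 0.11, 0.46))


@dataclass
class CompositionField:
    """Depth-resolved volume fractions on a normalized-depth grid.

    Invariants: Phi_pg + Phi_f + Phi_co = 1 at every grid point (tolerance
    1e-10), Phi_pg >= delta_tol, all fractions within [0, 1].
    """

    z: np.ndarray
    phi_f: np.ndarray
    phi_co: np.ndarray
    phi_pg: np.ndarray
    delta_tol: float = DELTA_TOL

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=float)
        self.phi_f = np.asarray(self.phi_f, dtype=float)
        self.phi_co = np.asarray(self.phi_co, dtype=float)
        self.phi_pg = np.asarray(self.phi_pg, dtype=float)
        if not (self.z.shape == self.phi_f.shape == self.phi_co.shape
                == self.phi_pg.shape):
            raise DomainError("grid and fraction arrays must share a shape")
        if np.any(self.z < 0) or np.any(self.z > 1) or \
                np.any(np.diff(self.z) <= 0):
            raise DomainError("z grid must be increasing within [0, 1]")
        closure = self.phi_f + self.phi_co + self.phi_pg
        if np.max(np.abs(closure - 1.0)) > 1e-10:
            raise SaturationError("fractions do not sum to 1")
        if np.any(self.phi_pg < self.delta_tol):
            zbad = self.z[int(np.argmin(self.phi_pg))]
            raise SaturationError(
                f"proteoglycan fraction below {self.delta_tol:g} "
                f"at z = {zbad:.4f}")
        for arr in (self.phi_f, self.phi_co, self.phi_pg):
            if np.any(arr < 0) or np.any(arr > 1):
                raise SaturationError("fractions must lie in [0, 1]")

    @property
    def phi_s(self) -> np.ndarray:
        """Solid fraction 1 - Phi_f."""
        return 1.0 - self.phi_f

    def at(self, z):
        """(phi_f, phi_co, phi_pg) linearly interpolated at depth z."""
        z = np.asarray(z, dtype=float)
        f = np.interp(z, self.z, self.phi_f)
        co = np.interp(z, self.z, self.phi_co)
        return f, co, 1.0 - f - co

    @classmethod
    def from_reference(cls, z_grid=None, table: dict | None = None,
                       delta_tol: float = DELTA_TOL) -> "CompositionField":
        """Field sampled from the idealized reference profiles."""
        z = np.linspace(0.0, 1.0, 101) if z_grid is None \
            else np.asarray(z_grid, dtype=float)
        f, co, pg = wilson_reference_profile(z, table)
        return cls(z, f, co, pg, delta_tol)


def combine_fractions(fits: dict, weights: WeightSet, z_grid,
                      delta_tol: float = DELTA_TOL) -> CompositionField:
    """Weighted combination of per-modality depth profiles.

    ``fits`` maps constituent ('f', 'co') to a dict of modality ->
    :class:`RationalDepthFit`.  The proteoglycan fraction is the saturation
    remainder; a value below ``delta_tol`` anywhere raises
    :class:`SaturationError` naming the offending depth.
    """
    z = np.asarray(z_grid, dtype=float)
    combined = {}
    for xi in CONSTITUENTS:
        w = weights.row(xi)
        profiles = fits[xi]
        missing = [m for m in MODALITIES if m not in profiles]
        if missing:
            raise DomainError(f"missing depth fits for {missing}")
        combined[xi] = sum(w[i] * profiles[m](z)
                           for i, m in enumerate(MODALITIES))
    phi_pg = 1.0 - combined["f"] - combined["co"]
    return CompositionField(z, combined["f"], combined["co"], phi_pg,
                            delta_tol)


# --------------------------------------------------------------------------
# depth profiles from parameter maps
# --------------------------------------------------------------------------

def depth_profile_from_map(pmap: ParameterMap, n_bins: int = 20,
                           depth_axis: int = 0):
    """Depth-binned mean relaxation times with per-column normalization.

    Each mask column along ``depth_axis`` is normalized so its first masked
    pixel is z = 0 (articular surface) and its last is z = 1; all valid
    pixels are then pooled into ``n_bins`` equal depth bins and averaged.
    Returns (bin-center z, mean Tx) for the nonempty bins.
    """
    valid = pmap.valid()
    vals = pmap.values if depth_axis == 0 else pmap.values.T
    vmask = valid if depth_axis == 0 else valid.T
    zs, ys = [], []
    for col in range(vals.shape[1]):
        rows = np.nonzero(vmask[:, col])[0]
        if rows.size < 2:
            continue
        z = (rows - rows[0]) / (rows[-1] - rows[0])
        zs.append(z)
        ys.append(vals[rows, col])
    if not zs:
        raise DomainError("no mask column holds two or more valid pixels")
    z = np.concatenate(zs)
    y = np.concatenate(ys)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(z, edges) - 1, 0, n_bins - 1)
    centers, means = [], []
    for b in range(n_bins):
        sel = idx == b
        if sel.any():
            centers.append(0.5 * (edges[b] + edges[b + 1]))
            means.append(float(np.mean(y[sel])))
    return np.asarray(centers), np.asarray(means)


def composition_from_maps(maps: dict, weights: WeightSet | None = None,
                          n_bins: int = 20, z_grid=None,
                          reference_table: dict | None = None,
                          delta_tol: float = DELTA_TOL):
    """Full map-to-composition pipeline.

    For every modality map: bin by normalized depth, pair the bin means
    with the idealized reference fractions at the same depths, calibrate
    the exponential relation, invert it bin-wise, and fit the rational
    depth profile.  The per-modality profiles are then combined with the
    weight set.  Returns (CompositionField, per-constituent profile fits).
    """
    weights = weights or WeightSet.default()
    fits: dict[str, dict] = {xi: {} for xi in CONSTITUENTS}
    for modality in MODALITIES:
        if modality not in maps:
            raise DomainError(f"missing parameter map for {modality}")
        zb, txb = depth_profile_from_map(maps[modality], n_bins=n_bins)
        ref = wilson_reference_profile(zb, reference_table)
        for xi, phi_ref in zip(CONSTITUENTS, ref[:2]):
            cal = calibrate_exponential(zip(phi_ref, txb), xi, modality)
            phi_hat = invert_calibration(cal, txb)
            fits[xi][modality] = fit_depth_profile(zb, phi_hat)
    z = np.linspace(0.0, 1.0, 101) if z_grid is None \
        else np.asarray(z_grid, dtype=float)
    return combine_fractions(fits, weights, z, delta_tol), fits
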