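"""Global inverse identification of material parameters and qMRI weights.

All samples are fitted simultaneously with one shared parameter set (the
"global" set): candidate weights re-derive each sample's composition from
its per-modality depth profiles, the forward column solver predicts the
relaxed stress at the measured strain levels, and the bound-constrained
least-squares objective sums per-sample-normalized squared residuals

    sum_s || y_s - f_s(theta) ||^2 / || y_s ||^2

so stiff samples do not dominate.  The per-constituent weight
normalization (rows summing to 1) holds by construction: one weight per
row is eliminated and negative excursions are clipped, renormalized and
penalized.  Goodness of fit is reported per sample as the squared Pearson
correlation R^2 (scale invariant) and the relative approximated error
Omega = 100*||y - f||/||y|| (captures magnitude error that R^2 ignores).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

from .column import build_column, solve_equilibrium
from .composition import CONSTITUENTS, WeightSet, combine_fractions
from .constitutive import MaterialParameters
from .errors import (CompactionError, ConfigurationError, DomainError,
                     NormalizationError, SaturationError, SolverError)
from .relaxometry import MODALITIES

logger = logging.getLogger(__name__)

#: Residual magnitude assigned when the forward model fails under a
#: candidate parameter set (compaction, saturation, solver failure).
PENALTY_RESIDUAL = 1e3

MATERIAL_NAMES = ("k1", "k2", "k3", "a0", "a1", "w")

DEFAULT_BOUNDS = {
    "k1": (0.01, 10.0), "k2": (1.0, 200.0), "k3": (1.0, 100.0),
    "a0": (0.01, 5.0), "a1": (0.5, 20.0), "w": (0.0, 1.0),
}


# --------------------------------------------------------------------------
# goodness-of-fit metrics
# --------------------------------------------------------------------------

def r_squared(y, f) -> float:
    """Squared Pearson correlation between measured y and modelled f.

    Scale invariant (f = 2y still gives 1); magnitude error is captured by
    :func:`relative_error_omega` instead.
    """
    y = np.asarray(y, dtype=float)
    f = np.asarray(f, dtype=float)
    if y.shape != f.shape or y.size < 3:
        raise DomainError("need at least three paired values")
    if np.ptp(y) == 0:
        raise DomainError("correlation undefined for constant measurements")
    if np.ptp(f) == 0:
        return 0.0
    r = np.corrcoef(y, f)[0, 1]
    return float(r * r)


def relative_error_omega(y, f) -> float:
    """Relative approximated error Omega = 100*||y - f||/||y|| [percent]."""
    y = np.asarray(y, dtype=float)
    f = np.asarray(f, dtype=float)
    ny = float(np.linalg.norm(y))
    if ny == 0:
        raise DomainError("zero measurement vector")
    return float(100.0 * np.linalg.norm(y - f) / ny)


# --------------------------------------------------------------------------
# parameter set and sample container
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GlobalParameterSet:
    """Material constants plus the per-constituent modality weights."""

    material: MaterialParameters
    weights: WeightSet

    @classmethod
    def default(cls) -> "GlobalParameterSet":
        return cls(MaterialParameters.default(), WeightSet.default())


@dataclass(frozen=True)
class SampleData:
    """One sample's model input: per-modality depth profiles, the measured
    relaxed stress curve (compressive magnitudes, MPa) and geometry."""

    name: str
    profile_fits: dict          # constituent -> modality -> RationalDepthFit
    strains: tuple[float, ...]
    stress_mpa: tuple[float, ...]
    thickness_mm: float
    n_layers: int = 12

    def __post_init__(self):
        e = np.asarray(self.strains, dtype=float)
        s = np.asarray(self.stress_mpa, dtype=float)
        if e.shape != s.shape or e.size < 3:
            raise DomainError("need at least three strain/stress pairs")
        object.__setattr__(self, "strains", tuple(e.tolist()))
        object.__setattr__(self, "stress_mpa", tuple(s.tolist()))


@dataclass
class FitReport:
    """Outcome of the global optimization."""

    objective: float
    r2: dict
    omega: dict
    n_evaluations: int
    n_starts: int
    success: bool
    message: str


# --------------------------------------------------------------------------
# forward prediction and objective
# --------------------------------------------------------------------------

_Z_GRID = np.linspace(0.0, 1.0, 61)


def predict_sample(sample: SampleData, theta: GlobalParameterSet
                   ) -> np.ndarray:
    """Modelled compressive stress magnitudes at the sample's strains."""
    comp = combine_fractions(sample.profile_fits, theta.weights, _Z_GRID)
    mesh = build_column(comp, theta.material, sample.thickness_mm,
                        n_layers=sample.n_layers)
    out = np.empty(len(sample.strains))
    warm = None
    strains = np.asarray(sample.strains)
    for k, eps in enumerate(strains):
        s, lam = solve_equilibrium(mesh, eps, warm_start=warm)
        out[k] = -s
        if k + 1 < strains.size:
            warm = lam * (1.0 - strains[k + 1]) / (1.0 - eps)
    return out


def _sample_residual(sample: SampleData, theta: GlobalParameterSet
                     ) -> np.ndarray:
    y = np.asarray(sample.stress_mpa)
    ny = float(np.linalg.norm(y))
    try:
        fpred = predict_sample(sample, theta)
    except (CompactionError, SaturationError, SolverError, DomainError) as e:
        logger.warning("forward model failed for sample %s: %s",
                       sample.name, e)
        return np.full(y.size, PENALTY_RESIDUAL)
    return (fpred - y) / ny


def objective(samples, theta: GlobalParameterSet) -> float:
    """Sum over samples of per-sample-normalized squared residuals.

    Zero iff the model curves equal the measurements at every protocol
    strain.  Weight rows violating the normalization condition raise
    before any simulation.
    """
    # WeightSet construction already enforces the normalization condition;
    # re-validate defensively for externally constructed sets.
    for xi in CONSTITUENTS:
        if abs(float(np.sum(theta.weights.row(xi))) - 1.0) > 1e-8:
            raise NormalizationError("weight rows must sum to 1")
    return float(sum(np.sum(_sample_residual(s, theta) ** 2)
                     for s in samples))


# --------------------------------------------------------------------------
# optimizer
# --------------------------------------------------------------------------

class _Packing:
    """Maps a free-parameter vector to a feasible GlobalParameterSet.

    Weight rows are parametrized by all but one modality (the one with the
    largest starting weight); the eliminated weight is the closure
    1 - sum(others).  Negative excursions are clipped and renormalized
    (keeping the row sum at exactly 1) and penalized in the residual.
    """

    def __init__(self, theta0: GlobalParameterSet, free_material,
                 free_weights: bool, bounds: dict):
        self.free_material = tuple(free_material)
        self.free_weights = bool(free_weights)
        self.theta0 = theta0
        self.elim = {}
        names, lo, hi, x0 = [], [], [], []
        for n in self.free_material:
            if n not in MATERIAL_NAMES:
                raise ConfigurationError(f"unknown material parameter {n!r}")
            b = bounds.get(n, DEFAULT_BOUNDS[n])
            names.append(n)
            lo.append(b[0])
            hi.append(b[1])
            x0.append(getattr(theta0.material, n))
        if self.free_weights:
            for xi in CONSTITUENTS:
                row = theta0.weights.row(xi)
                self.elim[xi] = int(np.argmax(row))
                for i, m in enumerate(MODALITIES):
                    if i == self.elim[xi]:
                        continue
                    names.append(f"w_{m}_{xi}")
                    lo.append(0.0)
                    hi.append(1.0)
                    x0.append(float(row[i]))
        self.names = names
        self.lo = np.asarray(lo)
        self.hi = np.asarray(hi)
        self.x0 = np.clip(np.asarray(x0), self.lo, self.hi)

    def unpack(self, x) -> tuple[GlobalParameterSet, float]:
        """(theta, infeasibility penalty)."""
        x = np.asarray(x, dtype=float)
        kw = {n: getattr(self.theta0.material, n) for n in MATERIAL_NAMES}
        j = 0
        for n in self.free_material:
            kw[n] = float(x[j])
            j += 1
        penalty = 0.0
        rows = {"f": np.asarray(self.theta0.weights.row("f")),
                "co": np.asarray(self.theta0.weights.row("co"))}
        if self.free_weights:
            for xi in CONSTITUENTS:
                row = np.empty(len(MODALITIES))
                for i in range(len(MODALITIES)):
                    if i == self.elim[xi]:
                        continue
                    row[i] = x[j]
                    j += 1
                row[self.elim[xi]] = 1.0 - np.sum(
                    np.delete(row, self.elim[xi]))
                if row[self.elim[xi]] < 0.0:
                    penalty += -row[self.elim[xi]]
                    row[self.elim[xi]] = 0.0
                    row = row / np.sum(row)
                rows[xi] = row
        weights = WeightSet(fluid=tuple(rows["f"]),
                            collagen=tuple(rows["co"]))
        return GlobalParameterSet(MaterialParameters(**kw), weights), penalty


def optimize_global(samples, theta0: GlobalParameterSet | None = None,
                    bounds: dict | None = None,
                    free_material=("k1", "a0"), free_weights: bool = True,
                    n_starts: int = 3, seed: int = 0,
                    max_nfev: int | None = 400
                    ) -> tuple[GlobalParameterSet, FitReport]:
    """Bound-constrained global fit over all samples simultaneously.

    Trust-region least squares on the free material constants and weight
    rows, multi-started (``n_starts`` seeded restarts, best-of selection).
    The returned set always satisfies the weight normalization and all
    bounds.  An infeasible starting set (non-finite objective) raises
    :class:`ConfigurationError`.
    """
    samples = list(samples)
    if not samples:
        raise ConfigurationError("no samples")
    theta0 = theta0 or GlobalParameterSet.default()
    pack = _Packing(theta0, free_material, free_weights, bounds or {})
    n_eval = 0

    def resid(x):
        nonlocal n_eval
        n_eval += 1
        theta, penalty = pack.unpack(x)
        parts = [_sample_residual(s, theta) for s in samples]
        parts.append(np.array([10.0 * penalty]))
        return np.concatenate(parts)

    r0 = resid(pack.x0)
    if not np.all(np.isfinite(r0)):
        raise ConfigurationError("starting parameter set is infeasible")

    rng = np.random.default_rng(seed)
    starts = [pack.x0]
    for _ in range(max(0, n_starts - 1)):
        starts.append(rng.uniform(pack.lo, pack.hi))

    best = None
    for x_start in starts:
        res = least_squares(resid, x_start, bounds=(pack.lo, pack.hi),
                            method="trf", x_scale="jac",
                            xtol=1e-9, ftol=1e-9, gtol=1e-9,
                            max_nfev=max_nfev)
        if best is None or res.cost < best.cost:
            best = res
    theta, _ = pack.unpack(best.x)
    r2, omega = {}, {}
    for s in samples:
        y = np.asarray(s.stress_mpa)
        try:
            fpred = predict_sample(s, theta)
            r2[s.name] = r_squared(y, fpred)
            omega[s.name] = relative_error_omega(y, fpred)
        except (CompactionError, SaturationError, SolverError) as e:
            r2[s.name] = float("nan")
            omega[s.name] = float("nan")
            logger.warning("diagnostics failed for sample %s: %s", s.name, e)
    report = FitReport(objective=float(2.0 * best.cost), r2=r2, omega=omega,
                       n_evaluations=n_eval, n_starts=len(starts),
                       success=bool(best.success), message=str(best.message))
    return theta, report


def parameter_sweep(samples, theta: GlobalParameterSet, name: str,
                    values) -> np.ndarray:
    """1-D objective profile over one material constant (identifiability
    diagnostic for partially confounded parameters such as k1 vs the
    collagen weighting)."""
    out = np.empty(len(list(values)))
    for i, v in enumerate(values):
        mat = replace(theta.material, **{name: float(v)})
        out[i] = objective(samples, GlobalParameterSet(mat, theta.weights))
    return out
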