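"""Depth-discretized equilibrium solver for confined compression.

The confined-compression test (rigid impermeable lateral wall, porous
piston) is idealized as a series column of N layers stacked from the
articular surface to the bone.  Each layer deforms as
``F = diag(1, 1, lambda_i)`` (zero lateral strain), so ``J = lambda_i`` and
the nominal and Cauchy axial stresses coincide.  At equilibrium the axial
stress is uniform through depth and the thickness-weighted compressive
strains sum to the applied strain:

    sigma_zz(lambda_i; layer i) = s   for all i,
    sum_i t_i (1 - lambda_i) = eps.

The solver runs a damped Newton iteration on (lambda_1..lambda_N, s) with
a vectorized closed-form axial-stress kernel, warm-started across the
loading protocol, and falls back to a robust nested root bracketing when
Newton fails.  Only relaxed (time-independent) states are computed; ramp
rates in the protocol are metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .composition import CompositionField
from .constitutive import (COMPACTION_GUARD, PHI_CO_FLOOR, FiberArchitecture,
                           LocalComposition, MaterialParameters,
                           arcade_directions, cauchy_stress,
                           default_theta_profile, make_kinematics)
from .errors import CompactionError, DomainError, SaturationError, SolverError

_EXP_CLIP = 500.0


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LoadingProtocol:
    """Strain levels of the stepwise confined-compression protocol.

    Default: 20 ramps of 1 % to a total strain of 20 %; the ramp rate
    (1 %/min) is metadata only — the equilibrium solve is rate independent.
    """

    strain_levels: tuple[float, ...] = tuple(
        float(e) for e in np.arange(1, 21) / 100.0)
    strain_rate_pct_per_min: float = 1.0

    def __post_init__(self):
        e = np.asarray(self.strain_levels, dtype=float)
        if e.size == 0 or np.any(e <= 0) or np.any(np.diff(e) <= 0):
            raise DomainError("strain levels must be positive and strictly "
                              "increasing")
        if e[-1] >= 1.0:
            raise DomainError("strain levels must stay below 100 %")
        object.__setattr__(self, "strain_levels", tuple(e.tolist()))


@dataclass(frozen=True)
class Layer:
    """One depth layer of the column."""

    z_mid: float
    thickness_fraction: float
    composition: LocalComposition
    theta: float  # arcade inclination from the surface plane [rad]
    architecture: FiberArchitecture


@dataclass(frozen=True)
class ColumnMesh:
    """Layered sample column, ordered surface -> bone."""

    layers: tuple[Layer, ...]
    thickness_mm: float
    params: MaterialParameters

    def __post_init__(self):
        if not self.layers:
            raise DomainError("column needs at least one layer")
        t = sum(l.thickness_fraction for l in self.layers)
        if abs(t - 1.0) > 1e-10:
            raise DomainError("thickness fractions must sum to 1")
        if self.thickness_mm <= 0:
            raise DomainError("sample thickness must be positive")

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    def arrays(self):
        """(t_frac, phi_f, phi_co, phi_pg, theta) as vectors over layers."""
        g = lambda f: np.array([f(l) for l in self.layers])
        return (g(lambda l: l.thickness_fraction),
                g(lambda l: l.composition.phi_f),
                g(lambda l: l.composition.phi_co),
                g(lambda l: l.composition.phi_pg),
                g(lambda l: l.theta))

    @property
    def max_phi_s(self) -> float:
        return max(l.composition.phi_s for l in self.layers)


@dataclass(frozen=True)
class EquilibriumSolution:
    """Relaxed stress-strain curve with per-layer stretches.

    ``stress_mpa`` is the compressive nominal stress magnitude (force per
    referential area, positive in compression); ``lambdas[k, i]`` is the
    axial stretch of layer i at strain level k.
    """

    strains: np.ndarray
    stress_mpa: np.ndarray
    lambdas: np.ndarray
    thickness_mm: float

    def __post_init__(self):
        object.__setattr__(self, "strains",
                           np.asarray(self.strains, dtype=float))
        object.__setattr__(self, "stress_mpa",
                           np.asarray(self.stress_mpa, dtype=float))
        object.__setattr__(self, "lambdas",
                           np.asarray(self.lambdas, dtype=float))


# --------------------------------------------------------------------------
# column construction
# --------------------------------------------------------------------------

def _pl_average(zg: np.ndarray, vals: np.ndarray, z0: float,
                z1: float) -> float:
    """Exact average of the piecewise-linear interpolant over [z0, z1]."""
    inner = zg[(zg > z0) & (zg < z1)]
    pts = np.concatenate([[z0], inner, [z1]])
    return float(np.trapezoid(np.interp(pts, zg, vals), pts) / (z1 - z0))


def build_column(comp: CompositionField, params: MaterialParameters,
                 thickness_mm: float, n_layers: int = 20,
                 theta_profile=None) -> ColumnMesh:
    """Discretize a composition field into uniform layers.

    Layer compositions are exact averages of the field's piecewise-linear
    interpolant; fiber architectures are evaluated at layer midpoints.
    A proteoglycan fraction below the field's ``delta_tol`` in any layer
    raises :class:`SaturationError`.
    """
    if n_layers < 1:
        raise DomainError("need at least one layer")
    edges = np.linspace(0.0, 1.0, n_layers + 1)
    layers = []
    for i in range(n_layers):
        z0, z1 = edges[i], edges[i + 1]
        f = _pl_average(comp.z, comp.phi_f, z0, z1)
        co = _pl_average(comp.z, comp.phi_co, z0, z1)
        pg = 1.0 - f - co
        if pg < comp.delta_tol:
            raise SaturationError(
                f"layer {i} proteoglycan fraction {pg:.3g} below tolerance")
        z_mid = 0.5 * (z0 + z1)
        theta = float((theta_profile or default_theta_profile)(z_mid))
        arch = arcade_directions(z_mid, dispersion=params.w,
                                 theta_profile=theta_profile)
        layers.append(Layer(z_mid=z_mid, thickness_fraction=1.0 / n_layers,
                            composition=LocalComposition(f, co, pg),
                            theta=theta, architecture=arch))
    return ColumnMesh(tuple(layers), thickness_mm, params)


# --------------------------------------------------------------------------
# axial stress
# --------------------------------------------------------------------------

def layer_axial_stress(layer: Layer, lam: float,
                       params: MaterialParameters,
                       method: str = "energy") -> float:
    """Nominal axial stress [MPa] of one layer at F = diag(1, 1, lam).

    Under confined kinematics J = lam, so nominal and Cauchy axial
    components coincide; compressive states are negative.
    """
    state = make_kinematics(np.diag([1.0, 1.0, float(lam)]))
    st = cauchy_stress(state, layer.composition, layer.architecture, params,
                       method=method)
    return float(st.sigma[2, 2])


def axial_stress_batch(lam: np.ndarray, phi_f: np.ndarray,
                       phi_co: np.ndarray, phi_pg: np.ndarray,
                       theta: np.ndarray, params: MaterialParameters,
                       n_families: int = 8) -> np.ndarray:
    """Vectorized closed-form sigma_zz over layers at F = diag(1, 1, lam).

    Under the diagonal confined deformation all equiangular families of a
    layer share the same invariants, so the family sum collapses to a
    multiplier; this kernel is algebraically identical to
    :func:`layer_axial_stress` and is cross-checked against it in tests.
    """
    lam = np.asarray(lam, dtype=float)
    phi_s = 1.0 - phi_f
    if np.any(lam <= phi_s + COMPACTION_GUARD):
        i = int(np.argmax(phi_s + COMPACTION_GUARD - lam))
        raise CompactionError(
            f"layer {i}: lambda = {lam[i]:.6g} at or below the compaction "
            f"point {phi_s[i]:.6g}")
    w = params.w
    a = lam ** (-2.0 / 3.0)        # in-plane isochoric stretch^2
    b = lam ** (4.0 / 3.0)         # axial isochoric stretch^2
    Pt = 2.0 * w / 3.0 + (1.0 - w) * np.cos(theta) ** 2   # Lt_xx + Lt_yy
    Qt = w / 3.0 + (1.0 - w) * np.sin(theta) ** 2         # Lt_zz
    i4 = a * Pt + b * Qt
    kk = Pt / a + Qt / b
    k2t = phi_co * params.k2
    k3t = phi_co * params.k3
    fib = phi_co > PHI_CO_FLOOR
    fp = np.where(fib, np.exp(np.clip(np.where(fib, k2t, 1.0) * (i4 - 1.0),
                                      -_EXP_CLIP, _EXP_CLIP)), 0.0)
    gp = np.where(fib, kk ** np.where(fib, k3t - 1.0, 0.0), 0.0)
    pref = np.where(fib, phi_co * params.k1 * n_families, 0.0)
    s_zz = phi_pg * params.a0 + pref * (fp * Qt + gp * (kk / b - Qt / b ** 2))
    s_xxyy = 2.0 * phi_pg * params.a0 + pref * (
        fp * Pt + gp * (2.0 * kk / a - Pt / a ** 2))
    sc = a * s_xxyy + b * s_zz
    a1t = phi_f * params.a1
    pi = params.a0 * ((1.0 - phi_s) / (lam - phi_s)) ** (2.0 * a1t) - params.a0
    return 2.0 * lam ** (1.0 / 3.0) * (s_zz - sc / (3.0 * b)) - pi


def _mesh_stress_fn(mesh: ColumnMesh):
    t, f, co, pg, th = mesh.arrays()
    p = mesh.params

    def stress(lam):
        return axial_stress_batch(lam, f, co, pg, th, p)

    return t, 1.0 - f, stress


# --------------------------------------------------------------------------
# equilibrium solve
# --------------------------------------------------------------------------

def solve_equilibrium(mesh: ColumnMesh, applied_strain: float,
                      warm_start: np.ndarray | None = None,
                      max_iter: int = 60, tol: float = 1e-11):
    """Equilibrium of the layered column at one applied strain.

    Returns ``(s, lam)``: the uniform signed nominal axial stress [MPa,
    negative in compression] and the per-layer axial stretches.  Raises
    :class:`CompactionError` for inadmissible strains and
    :class:`SolverError` (with diagnostics) if neither Newton nor the
    bracketing fallback converges.
    """
    eps = float(applied_strain)
    if eps < 0:
        raise DomainError("applied strain must be non-negative")
    t, phi_s, stress = _mesh_stress_fn(mesh)
    if eps >= 1.0 - mesh.max_phi_s - 1e-6:
        raise CompactionError(
            f"applied strain {eps:.4g} beyond the admissible bound "
            f"{1.0 - mesh.max_phi_s:.4g}")
    if eps == 0.0:
        return 0.0, np.ones(mesh.n_layers)

    lam = np.array(warm_start, dtype=float) if warm_start is not None \
        else np.full(mesh.n_layers, 1.0 - eps)
    lam = np.clip(lam, phi_s + 1e-6, 1.0)
    s = float(np.dot(t, stress(lam)))
    h = 1e-7
    lo = phi_s + 1e-8

    def residual(lam, s):
        r = stress(lam) - s
        rc = float(np.dot(t, 1.0 - lam)) - eps
        return r, rc

    r, rc = residual(lam, s)
    norm = max(np.max(np.abs(r)), abs(rc))
    converged = False
    for _ in range(max_iter):
        if norm < tol:
            converged = True
            break
        d = (stress(np.minimum(lam + h, 1.0 + 1e3 * h))
             - stress(np.maximum(lam - h, lo))) / (
            np.minimum(lam + h, 1.0 + 1e3 * h) - np.maximum(lam - h, lo))
        d = np.where(np.abs(d) < 1e-300, 1e-300, d)
        ds = (rc + np.dot(t, r / d)) / np.dot(t, 1.0 / d)
        dlam = (ds - r) / d
        alpha = 1.0
        for _ in range(12):
            lam_new = np.clip(lam + alpha * dlam, lo + 1e-12, 1.0 + 1e-9)
            s_new = s + alpha * ds
            r_new, rc_new = residual(lam_new, s_new)
            norm_new = max(np.max(np.abs(r_new)), abs(rc_new))
            if norm_new < norm or norm_new < tol:
                lam, s, r, rc, norm = lam_new, s_new, r_new, rc_new, norm_new
                break
            alpha *= 0.5
        else:
            break
    if converged or norm < tol:
        return float(s), lam

    # Robust fallback: bracketed root finding, outer on the shared stress.
    def lam_of_s(si):
        out = np.empty(mesh.n_layers)
        for i in range(mesh.n_layers):
            def fi(x, i=i):
                xi = np.array([x])
                return float(stress_one(xi, i)) - si
            out[i] = brentq(fi, lo[i] + 1e-9, 1.0, xtol=1e-14, rtol=1e-15)
        return out

    tt, ff, cc, pp, hh = mesh.arrays()

    def stress_one(x, i):
        return axial_stress_batch(x, ff[i:i + 1], cc[i:i + 1], pp[i:i + 1],
                                  hh[i:i + 1], mesh.params)[0]

    def gap(si):
        return float(np.dot(t, 1.0 - lam_of_s(si))) - eps

    s_hi, s_lo = 0.0, -1.0
    for _ in range(80):
        if gap(s_lo) > 0:
            break
        s_lo *= 2.0
    else:
        raise SolverError("could not bracket the equilibrium stress",
                          {"strain": eps, "norm": norm})
    try:
        s = brentq(gap, s_lo, s_hi, xtol=1e-14, rtol=1e-15)
    except Exception as exc:  # pragma: no cover - diagnostics path
        raise SolverError("equilibrium solve failed",
                          {"strain": eps, "norm": norm}) from exc
    return float(s), lam_of_s(s)


def simulate_protocol(mesh: ColumnMesh,
                      protocol: LoadingProtocol | None = None
                      ) -> EquilibriumSolution:
    """Relaxed stress-strain curve over the loading protocol.

    Solutions are warm-started from the previous strain level; the
    returned stresses are compressive magnitudes, nondecreasing in strain.
    """
    protocol = protocol or LoadingProtocol()
    strains = np.asarray(protocol.strain_levels)
    stresses = np.empty_like(strains)
    lambdas = np.empty((strains.size, mesh.n_layers))
    warm = None
    for k, eps in enumerate(strains):
        s, lam = solve_equilibrium(mesh, eps, warm_start=warm)
        stresses[k] = -s
        lambdas[k] = lam
        if k + 1 < strains.size:
            # Scale stretches toward the next level's mean compression.
            warm = lam * (1.0 - strains[k + 1]) / (1.0 - eps)
    return EquilibriumSolution(strains=strains, stress_mpa=stresses,
                               lambdas=lambdas,
                               thickness_mm=mesh.thickness_mm)


def stiffness_at(solution: EquilibriumSolution, eps0: float = 0.15,
                 kind: str = "tangent") -> float:
    """Stiffness E [MPa] at strain eps0.

    ``tangent`` (default): central-difference slope d sigma/d eps of the
    compressive curve, interpolated at eps0 from adjacent protocol points.
    ``secant``: sigma(eps0)/eps0.  Raises :class:`DomainError` when the
    curve does not bracket eps0.
    """
    e = solution.strains
    sig = solution.stress_mpa
    if e.size < 2 or not (e[0] <= eps0 <= e[-1]):
        raise DomainError(f"curve does not bracket eps = {eps0}")
    if kind == "secant":
        return float(np.interp(eps0, e, sig) / eps0)
    if kind != "tangent":
        raise DomainError(f"unknown stiffness definition {kind!r}")
    slopes = np.gradient(sig, e)
    return float(np.interp(eps0, e, slopes))
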