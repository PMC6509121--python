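"""Anisotropic fiber-reinforced constitutive model with osmotic swelling.

The tissue is treated as a biphasic mixture at equilibrium: an isochoric
solid-matrix energy (collagen fibril network + isotropic proteoglycan
matrix) plus a volumetric osmotic contribution diverging at the compaction
point J -> Phi_s.  Kinematics use the multiplicative volumetric/isochoric
split, F = J^(1/3) F_bar, C_bar = J^(-2/3) C with det(C_bar) = 1.

Fibril network (per fiber family i, summed over a Benninghoff-arcade set of
eight equiangular families)::

    Psi_co = sum_i k1 [ (1/k2t) exp{k2t (I4_i - 1)} + (1/k3t)(K_i^k3t - 1) ]
    k2t = Phi_co*k2,  k3t = Phi_co*k3

with the dispersion-weighted structure tensor
``Lt_i = (w/3) I + (1 - w) m_i (x) m_i`` and invariants
``I4_i = tr(C_bar Lt_i)`` (generalized-structure-tensor form) and
``K_i = tr(cof(C_bar) Lt_i)`` (tube-contraction term, active in
compression).  Taking the tension invariant through the *weighted* tensor
is what renders the reference configuration exactly stress free for any
dispersion w and makes the w = 1 limit exactly isotropic; the package also
exposes the unweighted invariant (``weighted_i4=False``) and the published
closed-form fibril stress (``method='printed'``), which coincide with the
energy-consistent stress at the reference but drop deformation-dependent
terms of d(K_i)/d(C_bar) away from it.

Proteoglycan matrix: neo-Hookean, ``Psi_pg = a0 (I1_bar - 3)``.

Osmotic multiplier::

    pi(J) = a0 ((1 - Phi_s)/(J - Phi_s))^(2*a1t) + pi0,   a1t = Phi_f*a1

with ``pi0 = -a0`` so that pi(1) = 0 (stress-free reference).  The Cauchy
stress assembles as ``sigma = J^-1 F S F^T`` with
``S = 2 J^(-2/3)[S_bar - (1/3)(S_bar:C_bar) C_bar^-1] - pi J C^-1``, so the
osmotic contribution is the pure pressure ``-pi I``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import CompactionError, DomainError

#: Fibril contribution is dropped below this collagen fraction (the stress
#: scales with Phi_co; the 1/k2t energy constant would overflow instead).
PHI_CO_FLOOR = 1e-8

#: Guard distance above the compaction point.
COMPACTION_GUARD = 1e-9

_EXP_CLIP = 500.0


# --------------------------------------------------------------------------
# parameters and local composition
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MaterialParameters:
    """Global constitutive parameter set.

    k1 [MPa] fibril stress scale; k2, k3 [-] fibril nonlinearity exponents
    (tension/compression); a0 [MPa] proteoglycan-matrix stiffness and
    osmotic scale; a1 [-] osmotic compressibility exponent; w [-] fiber
    dispersion weight (0 = ideal alignment, 1 = isotropic).
    """

    k1: float = 0.6
    k2: float = 50.0
    k3: float = 25.0
    a0: float = 0.35
    a1: float = 5.0
    w: float = 0.3

    def __post_init__(self):
        if not (self.k1 > 0 and self.a0 > 0):
            raise DomainError("k1 and a0 must be positive")
        if not (self.k2 > 0 and self.k3 > 0 and self.a1 > 0):
            raise DomainError("k2, k3 and a1 must be positive")
        if not 0.0 <= self.w <= 1.0:
            raise DomainError("dispersion weight w must lie in [0, 1]")

    @classmethod
    def default(cls) -> "MaterialParameters":
        return cls()


@dataclass(frozen=True)
class LocalComposition:
    """Volume fractions at a material point (sum to 1; Phi_s = 1 - Phi_f)."""

    phi_f: float
    phi_co: float
    phi_pg: float

    def __post_init__(self):
        for v in (self.phi_f, self.phi_co, self.phi_pg):
            if not 0.0 <= v <= 1.0:
                raise DomainError("fractions must lie in [0, 1]")
        if abs(self.phi_f + self.phi_co + self.phi_pg - 1.0) > 1e-8:
            raise DomainError("fractions must sum to 1")

    @property
    def phi_s(self) -> float:
        return 1.0 - self.phi_f

    def effective(self, params: MaterialParameters):
        """(k2t, k3t, a1t) = (Phi_co*k2, Phi_co*k3, Phi_f*a1)."""
        return (self.phi_co * params.k2, self.phi_co * params.k3,
                self.phi_f * params.a1)


# --------------------------------------------------------------------------
# kinematics
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DeformationState:
    F: np.ndarray
    J: float
    C: np.ndarray
    C_bar: np.ndarray


def make_kinematics(F: np.ndarray) -> DeformationState:
    """Volumetric/isochoric split of a deformation gradient."""
    F = np.asarray(F, dtype=float)
    if F.shape != (3, 3):
        raise DomainError("F must be 3x3")
    J = float(np.linalg.det(F))
    if J <= 0:
        raise DomainError("det F must be positive (inverted element)")
    C = F.T @ F
    C_bar = J ** (-2.0 / 3.0) * C
    return DeformationState(F=F, J=J, C=C, C_bar=C_bar)


# --------------------------------------------------------------------------
# fiber architecture
# --------------------------------------------------------------------------

def structural_tensor(m: np.ndarray, w: float) -> np.ndarray:
    """Dispersion-weighted structure tensor (w/3) I + (1-w) m (x) m.

    Unit trace for any w; w = 0 is ideal alignment (rank-one), w = 1 the
    isotropic limit I/3.
    """
    m = np.asarray(m, dtype=float)
    if abs(np.linalg.norm(m) - 1.0) > 1e-9:
        raise DomainError("fiber direction must be a unit vector")
    if not 0.0 <= w <= 1.0:
        raise DomainError("dispersion weight must lie in [0, 1]")
    return (w / 3.0) * np.eye(3) + (1.0 - w) * np.outer(m, m)


def default_theta_profile(z):
    """Arcade inclination from the surface plane: 0 at the articular
    surface (tangential zone) to 90 degrees at the bone (radial zone)."""
    return 0.5 * np.pi * np.asarray(z, dtype=float)


@dataclass(frozen=True)
class FiberArchitecture:
    """Equiangular fiber families at one depth with shared dispersion."""

    directions: np.ndarray      # (n, 3) unit vectors
    dispersion: float

    def __post_init__(self):
        d = np.asarray(self.directions, dtype=float)
        if d.ndim != 2 or d.shape[1] != 3:
            raise DomainError("directions must be (n, 3)")
        norms = np.linalg.norm(d, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-9):
            raise DomainError("fiber directions must be unit vectors")
        object.__setattr__(self, "directions", d)

    @property
    def n_families(self) -> int:
        return self.directions.shape[0]

    @property
    def plain_tensors(self) -> np.ndarray:
        """L_i = m_i (x) m_i, shape (n, 3, 3)."""
        return np.einsum("ni,nj->nij", self.directions, self.directions)

    @property
    def weighted_tensors(self) -> np.ndarray:
        """Lt_i = (w/3) I + (1-w) L_i, shape (n, 3, 3); unit trace."""
        w = self.dispersion
        return (w / 3.0) * np.eye(3)[None] + (1.0 - w) * self.plain_tensors


def arcade_directions(z: float, n_families: int = 8, dispersion: float = 0.3,
                      theta_profile=None) -> FiberArchitecture:
    """Benninghoff-arcade fiber families at normalized depth z.

    ``n_families`` unit vectors at equiangular azimuths, each inclined
    ``theta(z)`` from the surface plane; the default profile is linear,
    theta = 90deg * z, i.e. in-plane fibers at the surface and a radial
    bundle at the bone.
    """
    if not 0.0 <= z <= 1.0:
        raise DomainError("normalized depth must lie in [0, 1]")
    theta = float((theta_profile or default_theta_profile)(z))
    azimuths = 2.0 * np.pi * np.arange(n_families) / n_families
    d = np.column_stack([np.cos(theta) * np.cos(azimuths),
                         np.cos(theta) * np.sin(azimuths),
                         np.full(n_families, np.sin(theta))])
    d /= np.linalg.norm(d, axis=1, keepdims=True)
    return FiberArchitecture(directions=d, dispersion=dispersion)


# --------------------------------------------------------------------------
# invariants and energies
# --------------------------------------------------------------------------

def invariants(state: DeformationState, arch: FiberArchitecture,
               weighted_i4: bool = True):
    """(I1_bar, I4_i list, K_i list) of the isochoric deformation.

    ``I4_i`` uses the dispersion-weighted structure tensors by default (the
    energy's definition); pass ``weighted_i4=False`` for the plain
    rank-one tensors.  ``K_i = tr(cof(C_bar) Lt_i)`` always uses the
    weighted tensors.
    """
    C_bar = state.C_bar
    i1 = float(np.trace(C_bar))
    L4 = arch.weighted_tensors if weighted_i4 else arch.plain_tensors
    i4 = np.einsum("ij,nji->n", C_bar, L4)
    cof = np.linalg.det(C_bar) * np.linalg.inv(C_bar).T
    k = np.einsum("ij,nji->n", cof, arch.weighted_tensors)
    return i1, i4, k


def free_energy(state: DeformationState, comp: LocalComposition,
                arch: FiberArchitecture, params: MaterialParameters) -> float:
    """Isochoric free energy density [MPa].

    Phi_co * sum_i k1[(1/k2t) exp{k2t(I4_i-1)} + (1/k3t)(K_i^k3t - 1)]
    + Phi_pg * a0 (I1_bar - 3); the fibril sum is dropped for vanishing
    collagen content (its stress scales with Phi_co).
    """
    i1, i4, k = invariants(state, arch)
    psi = comp.phi_pg * params.a0 * (i1 - 3.0)
    if comp.phi_co > PHI_CO_FLOOR:
        k2t, k3t, _ = comp.effective(params)
        if k2t <= 0 or k3t <= 0:
            raise DomainError("effective fibril exponents must be positive")
        fib = (np.exp(np.clip(k2t * (i4 - 1.0), -_EXP_CLIP, _EXP_CLIP))
               / k2t + (k ** k3t - 1.0) / k3t)
        psi += comp.phi_co * params.k1 * float(np.sum(fib))
    return float(psi)


def osmotic_pressure(J: float, comp: LocalComposition,
                     params: MaterialParameters) -> float:
    """Osmotic multiplier pi(J) [MPa]; zero at J = 1, diverging at the
    compaction point J -> Phi_s."""
    phi_s = comp.phi_s
    if J <= phi_s + COMPACTION_GUARD:
        raise CompactionError(
            f"J = {J:.6g} at or below the compaction point Phi_s = "
            f"{phi_s:.6g}")
    a1t = comp.phi_f * params.a1
    return params.a0 * ((1.0 - phi_s) / (J - phi_s)) ** (2.0 * a1t) - params.a0


def osmotic_energy(J: float, comp: LocalComposition,
                   params: MaterialParameters) -> float:
    """Volumetric potential with -d(Psi_pi)/dJ = pi and Psi_pi(1) = 0."""
    phi_s = comp.phi_s
    if J <= phi_s + COMPACTION_GUARD:
        raise CompactionError("J at or below the compaction point")
    a1t = comp.phi_f * params.a1
    e = 2.0 * a1t
    fl = 1.0 - phi_s
    if abs(e - 1.0) < 1e-9:
        integral = params.a0 * fl * (np.log(J - phi_s) - np.log(fl))
    else:
        integral = params.a0 * fl ** e * (
            (J - phi_s) ** (1.0 - e) - fl ** (1.0 - e)) / (1.0 - e)
    return float(-(integral - params.a0 * (J - 1.0)))


def total_energy(state: DeformationState, comp: LocalComposition,
                 arch: FiberArchitecture,
                 params: MaterialParameters) -> float:
    """Isochoric + osmotic energy density [MPa] at the relaxed state."""
    return free_energy(state, comp, arch, params) + \
        osmotic_energy(state.J, comp, params)


# --------------------------------------------------------------------------
# stress
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class StressState:
    """Cauchy stress with its isochoric 2nd Piola-Kirchhoff contribution
    and the osmotic multiplier."""

    sigma: np.ndarray   # MPa
    S_bar: np.ndarray   # MPa
    pi: float           # MPa
    pi0: float          # MPa


def _fibril_sbar(state, comp, arch, params, method: str) -> np.ndarray:
    """S_bar = dPsi_bar/dC_bar (exact for 'energy'; published closed form
    for 'printed')."""
    _, i4, k = invariants(state, arch)
    S = comp.phi_pg * params.a0 * np.eye(3)
    if comp.phi_co <= PHI_CO_FLOOR:
        return S
    k2t, k3t, _ = comp.effective(params)
    fp = np.exp(np.clip(k2t * (i4 - 1.0), -_EXP_CLIP, _EXP_CLIP))
    gp = k ** (k3t - 1.0)
    Lt = arch.weighted_tensors
    if method == "printed":
        term = (fp - gp)[:, None, None] * Lt \
            + (gp * k)[:, None, None] * np.eye(3)[None]
        return S + comp.phi_co * params.k1 * term.sum(axis=0)
    # Energy-consistent: d(K_i)/dC_bar = K_i C_bar^-1
    #                    - det(C_bar) C_bar^-1 Lt_i C_bar^-1.
    Cb_inv = np.linalg.inv(state.C_bar)
    det_cb = float(np.linalg.det(state.C_bar))
    dk = (k[:, None, None] * Cb_inv[None]
          - det_cb * np.einsum("ij,njk,kl->nil", Cb_inv, Lt, Cb_inv))
    term = fp[:, None, None] * Lt + gp[:, None, None] * dk
    return S + comp.phi_co * params.k1 * term.sum(axis=0)


def cauchy_stress(state: DeformationState, comp: LocalComposition,
                  arch: FiberArchitecture, params: MaterialParameters,
                  method: str = "energy") -> StressState:
    """Cauchy stress [MPa] at a relaxed material point.

    ``method='energy'`` (default) uses the exact derivative of the
    implemented free energy; ``method='printed'`` uses the published
    closed-form fibril stress, which agrees at the reference configuration
    but neglects deformation-dependent terms away from it.  The reference
    F = I is exactly stress free: the deviatoric projection annihilates
    the (isotropic) S_bar at identity and pi(1) = 0.
    """
    if method not in ("energy", "printed"):
        raise DomainError(f"unknown stress method {method!r}")
    J, C, C_bar, F = state.J, state.C, state.C_bar, state.F
    pi = osmotic_pressure(J, comp, params)
    S_bar = _fibril_sbar(state, comp, arch, params, method)
    Cb_inv = np.linalg.inv(C_bar)
    sc = float(np.einsum("ij,ji->", S_bar, C_bar))
    S_iso = 2.0 * J ** (-2.0 / 3.0) * (S_bar - (sc / 3.0) * Cb_inv)
    C_inv = np.linalg.inv(C)
    S_total = S_iso - pi * J * C_inv
    sigma = (F @ S_total @ F.T) / J
    sigma = 0.5 * (sigma + sigma.T)
    return StressState(sigma=sigma, S_bar=S_bar, pi=pi, pi0=-params.a0)
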