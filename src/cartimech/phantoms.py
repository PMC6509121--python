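"""Synthetic phantoms: qMRI stacks, composition fields and stress curves.

Every other module is testable without any acquisition: the generators
forward-simulate magnitude image stacks from known depth-graded relaxation
profiles on the scanner timing grids, and relaxed confined-compression
curves from a known global parameter set, returning the generating truth
alongside for recovery scoring.  All generators are deterministic under a
fixed seed.

Noise models: ``gaussian`` adds zero-mean noise to the magnitudes (clipped
at zero); ``rician`` applies two-channel Gaussian noise before taking the
magnitude, reproducing the positive bias of low-SNR magnitude MR data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .column import LoadingProtocol, build_column, simulate_protocol
from .composition import (CompositionField, RationalDepthFit, WeightSet,
                          combine_fractions, wilson_reference_profile)
from .constitutive import MaterialParameters
from .errors import ConfigurationError, DomainError, SaturationError
from .inverse import GlobalParameterSet, SampleData
from .relaxometry import (MODALITIES, AcquisitionProtocol, ParameterMap,
                          SignalModelFit, model_signal)

#: Depth-graded truth relaxation times (surface -> bone, ms), linear in z.
DEFAULT_RELAXATION_PROFILES = {
    "T1": (900.0, 600.0),
    "T1rho": (60.0, 35.0),
    "T2": (80.0, 45.0),
    "T2star": (45.0, 25.0),
}


@dataclass(frozen=True)
class PhantomSpec:
    """Generator settings for synthetic stacks and samples."""

    shape: tuple[int, int] = (64, 64)
    depth_axis: int = 0                      # depth runs along rows
    relaxation_profiles: dict = field(
        default_factory=lambda: dict(DEFAULT_RELAXATION_PROFILES))
    amplitude: float = 1.0
    noise: str = "none"                      # none | gaussian | rician
    sigma: float = 0.0
    seed: int | None = None
    material: GlobalParameterSet = field(
        default_factory=GlobalParameterSet.default)
    thickness_mm: float = 4.2
    n_layers: int = 12
    profile_jitter: float = 0.06
    stress_noise: float = 0.0
    protocol: LoadingProtocol = field(default_factory=LoadingProtocol)

    def __post_init__(self):
        if self.noise not in ("none", "gaussian", "rician"):
            raise ConfigurationError(f"unknown noise model {self.noise!r}")
        if self.sigma < 0 or self.stress_noise < 0:
            raise ConfigurationError("noise levels must be non-negative")
        if (self.noise != "none" or self.stress_noise > 0) \
                and self.seed is None:
            raise ConfigurationError("a seed is mandatory when noise is on")
        for m, (lo, hi) in self.relaxation_profiles.items():
            if m not in MODALITIES or lo <= 0 or hi <= 0:
                raise ConfigurationError("relaxation profiles must be "
                                         "positive and per known modality")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


# --------------------------------------------------------------------------
# qMRI stacks
# --------------------------------------------------------------------------

def _apply_noise(clean: np.ndarray, spec: PhantomSpec,
                 rng: np.random.Generator) -> np.ndarray:
    if spec.noise == "none" or spec.sigma == 0.0:
        return clean
    if spec.noise == "gaussian":
        return np.maximum(clean + rng.normal(0.0, spec.sigma, clean.shape),
                          0.0)
    # rician: magnitude of two-channel Gaussian noise
    re = clean + rng.normal(0.0, spec.sigma, clean.shape)
    im = rng.normal(0.0, spec.sigma, clean.shape)
    return np.hypot(re, im)


def phantom_qmri_stack(spec: PhantomSpec):
    """Forward-simulated magnitude stacks with truth maps and mask.

    Returns ``(stacks, truth_maps, mask)``: per modality a
    (timing, row, col) stack simulated from the depth-graded truth
    relaxation profile via the signal models, the truth
    :class:`ParameterMap`, and a shared tissue mask (full frame minus a
    one-pixel border, depth normalized over the masked rows).
    """
    h, w = spec.shape
    if h < 5 or w < 5:
        raise ConfigurationError("phantom frames must be at least 5x5")
    mask = np.zeros(spec.shape, dtype=bool)
    mask[1:h - 1, 1:w - 1] = True
    rows = np.arange(1, h - 1)
    z = (rows - rows[0]) / (rows[-1] - rows[0])
    rng = spec.rng()
    stacks, truths = {}, {}
    for modality in MODALITIES:
        lo, hi = spec.relaxation_profiles[modality]
        tz = lo + (hi - lo) * z
        protocol = AcquisitionProtocol.default(modality)
        truth = np.full(spec.shape, np.nan)
        stack = np.zeros((len(protocol.timing_values_ms),) + spec.shape)
        for r, tval in zip(rows, tz):
            fit = SignalModelFit(modality, relaxation_time_ms=float(tval),
                                 amplitude=spec.amplitude)
            series = model_signal(fit, protocol)
            stack[:, r, 1:w - 1] = np.asarray(series.magnitudes)[:, None]
            truth[r, 1:w - 1] = tval
        stacks[modality] = _apply_noise(stack, spec, rng)
        truths[modality] = ParameterMap(modality, truth,
                                        np.where(mask, 1.0, np.nan), mask)
    if spec.depth_axis == 1:
        stacks = {m: s.transpose(0, 2, 1) for m, s in stacks.items()}
        truths = {m: ParameterMap(m, t.values.T, t.quality.T, t.mask.T)
                  for m, t in truths.items()}
        mask = mask.T
    return stacks, truths, mask


# --------------------------------------------------------------------------
# mechanical samples
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PhantomSample:
    """A synthetic sample: its model inputs, the measured-looking curve and
    the generating truth."""

    name: str
    profile_fits: dict
    composition: CompositionField
    strains: tuple[float, ...]
    stress_truth_mpa: tuple[float, ...]
    stress_measured_mpa: tuple[float, ...]
    theta_truth: GlobalParameterSet
    thickness_mm: float
    n_layers: int

    def as_sample_data(self) -> SampleData:
        return SampleData(name=self.name, profile_fits=self.profile_fits,
                          strains=self.strains,
                          stress_mpa=self.stress_measured_mpa,
                          thickness_mm=self.thickness_mm,
                          n_layers=self.n_layers)


def _perturbed_profiles(rng: np.random.Generator, jitter: float):
    """Per-modality constituent depth profiles: the idealized reference
    curves plus a smooth quadratic perturbation, fitted by the rational
    depth model.  Perturbations are shrunk until the weighted combination
    stays saturated for every admissible weight set."""
    zg = np.linspace(0.0, 1.0, 21)
    ref_f, ref_co, _ = wilson_reference_profile(zg)
    ref = {"f": ref_f, "co": ref_co}
    from .composition import fit_depth_profile
    for attempt in range(8):
        amp = jitter * 0.5 ** attempt
        fits = {"f": {}, "co": {}}
        ok = True
        for xi in ("f", "co"):
            for m in MODALITIES:
                c0, c1 = rng.uniform(-amp, amp, 2)
                # Quadratic perturbation pinned to zero at z = 1, where the
                # reference profiles leave the smallest saturation margin.
                pert = c0 + c1 * zg - (c0 + c1) * zg ** 2
                phi = np.clip(ref[xi] + pert, 0.02, 0.95)
                fits[xi][m] = fit_depth_profile(zg, phi)
        # saturation check under the extreme single-modality weights
        zchk = np.linspace(0.0, 1.0, 41)
        total = max(float(np.max(fits["f"][mf](zchk) + fits["co"][mc](zchk)))
                    for mf in MODALITIES for mc in MODALITIES)
        if total < 1.0 - 2e-3:
            return fits
    raise SaturationError("could not generate admissible phantom profiles")


def phantom_sample(spec: PhantomSpec, index: int = 0) -> PhantomSample:
    """One synthetic sample: composition from perturbed per-modality depth
    profiles combined with the truth weights, and its relaxed
    confined-compression curve under the truth material constants
    (optional multiplicative measurement noise)."""
    seed = spec.seed if spec.seed is not None else 0
    rng = np.random.default_rng((seed, index))
    fits = _perturbed_profiles(rng, spec.profile_jitter)
    comp = combine_fractions(fits, spec.material.weights,
                             np.linspace(0.0, 1.0, 61))
    mesh = build_column(comp, spec.material.material, spec.thickness_mm,
                        n_layers=spec.n_layers)
    sol = simulate_protocol(mesh, spec.protocol)
    clean = sol.stress_mpa
    measured = clean.copy()
    if spec.stress_noise > 0:
        measured = clean * (1.0 + spec.stress_noise
                            * rng.normal(0.0, 1.0, clean.shape))
        measured = np.maximum(measured, 1e-6)
    return PhantomSample(name=f"phantom-{index}", profile_fits=fits,
                         composition=comp,
                         strains=tuple(sol.strains.tolist()),
                         stress_truth_mpa=tuple(clean.tolist()),
                         stress_measured_mpa=tuple(measured.tolist()),
                         theta_truth=spec.material,
                         thickness_mm=spec.thickness_mm,
                         n_layers=spec.n_layers)


def make_recovery_samples(n_samples: int = 3, stress_noise: float = 0.02,
                          seed: int = 0,
                          theta: GlobalParameterSet | None = None,
                          n_layers: int = 12):
    """Synthetic multi-sample recovery study inputs.

    Returns ``(samples, theta_truth)`` where each sample carries its own
    perturbed depth profiles and a noisy measured curve generated under
    the shared truth parameter set.
    """
    theta = theta or GlobalParameterSet.default()
    spec = PhantomSpec(material=theta, stress_noise=stress_noise, seed=seed,
                       n_layers=n_layers)
    samples = [phantom_sample(spec, index=i).as_sample_data()
               for i in range(n_samples)]
    return samples, theta
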