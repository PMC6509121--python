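"""Constitutive model: kinematics, architecture, energies and stress."""

import numpy as np
import pytest

from cartimech import (CompactionError, DomainError, LocalComposition,
                       MaterialParameters, arcade_directions, cauchy_stress,
                       free_energy, invariants, make_kinematics,
                       osmotic_pressure, structural_tensor, total_energy)
from cartimech.constitutive import osmotic_energy

from conftest import random_admissible_composition


def random_state(rng, scale=0.06):
    F = np.eye(3) + scale * rng.standard_normal((3, 3))
    if np.linalg.det(F) <= 0:
        F = np.eye(3)
    return make_kinematics(F)


def fd_cauchy(F, comp, arch, params, h=1e-6):
    """Independent central-difference stress oracle: sigma = J^-1 P F^T
    with P = dPsi/dF."""
    F = np.asarray(F, dtype=float)
    P = np.zeros((3, 3))
    for i in range(3):
        for j in range(3):
            Fp, Fm = F.copy(), F.copy()
            Fp[i, j] += h
            Fm[i, j] -= h
            P[i, j] = (total_energy(make_kinematics(Fp), comp, arch, params)
                       - total_energy(make_kinematics(Fm), comp, arch,
                                      params)) / (2 * h)
    return P @ F.T / np.linalg.det(F)


class TestKinematics:
    def test_identity(self):
        st = make_kinematics(np.eye(3))
        assert st.J == 1.0
        assert np.allclose(st.C_bar, np.eye(3))

    def test_confined_compression_closed_form(self):
        st = make_kinematics(np.diag([1.0, 1.0, 0.85]))
        assert st.J == pytest.approx(0.85, abs=1e-14)
        expected = 0.85 ** (-2 / 3) * np.diag([1.0, 1.0, 0.85 ** 2])
        assert np.allclose(st.C_bar, expected, atol=1e-14)

    def test_isochoric_part_unimodular(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            st = random_state(rng, scale=0.2)
            assert abs(np.linalg.det(st.C_bar) - 1.0) < 1e-10

    def test_inverted_element_rejected(self):
        with pytest.raises(DomainError):
            make_kinematics(np.diag([1.0, 1.0, -0.5]))


class TestArchitecture:
    def test_deep_zone_radial_bundle(self):
        arch = arcade_directions(1.0)
        assert np.allclose(arch.directions, [[0, 0, 1]] * 8, atol=1e-12)

    def test_surface_zone_in_plane(self):
        arch = arcade_directions(0.0)
        assert np.allclose(arch.directions[:, 2], 0.0, atol=1e-12)
        az = np.degrees(np.arctan2(arch.directions[:, 1],
                                   arch.directions[:, 0])) % 360
        assert np.allclose(sorted(az), np.arange(0, 360, 45), atol=1e-9)

    def test_unit_vectors_at_any_depth(self):
        for z in (0.0, 0.3, 0.77, 1.0):
            arch = arcade_directions(z)
            assert np.allclose(np.linalg.norm(arch.directions, axis=1), 1.0)

    def test_depth_domain(self):
        with pytest.raises(DomainError):
            arcade_directions(1.2)

    def test_structural_tensor_limits_and_trace(self):
        m = np.array([1.0, 0.0, 0.0])
        assert np.allclose(structural_tensor(m, 0.0), np.outer(m, m))
        assert np.allclose(structural_tensor(m, 1.0), np.eye(3) / 3)
        rng = np.random.default_rng(2)
        for _ in range(10):
            v = rng.standard_normal(3)
            v /= np.linalg.norm(v)
            L = structural_tensor(v, rng.uniform(0, 1))
            assert np.trace(L) == pytest.approx(1.0, abs=1e-12)
        with pytest.raises(DomainError):
            structural_tensor(np.array([1.0, 1.0, 0.0]), 0.3)


class TestInvariants:
    def test_identity_values(self):
        st = make_kinematics(np.eye(3))
        arch = arcade_directions(0.4, dispersion=0.3)
        i1, i4, k = invariants(st, arch)
        assert i1 == pytest.approx(3.0)
        assert np.allclose(i4, 1.0) and np.allclose(k, 1.0)

    def test_uniaxial_stretch_aligned_family(self):
        """With ideal alignment, I4 is the squared stretch along the
        fiber."""
        lam = 1.08
        F = np.diag([lam, lam ** -0.5, lam ** -0.5])  # isochoric
        st = make_kinematics(F)
        arch = arcade_directions(0.0, dispersion=0.0)  # m_1 = e_x
        _, i4, _ = invariants(st, arch)
        assert i4[0] == pytest.approx(lam ** 2, rel=1e-12)

    def test_cofactor_invariant_matches_inverse_oracle(self):
        """K = tr(cof(C) Lt) equals tr(det(C) C^-1 Lt) computed through an
        explicit matrix inverse."""
        rng = np.random.default_rng(4)
        arch = arcade_directions(0.6, dispersion=0.3)
        for _ in range(10):
            st = random_state(rng, scale=0.15)
            _, _, k = invariants(st, arch)
            Cb = st.C_bar
            oracle = [np.trace(np.linalg.det(Cb) * np.linalg.inv(Cb) @ Lt)
                      for Lt in arch.weighted_tensors]
            assert np.allclose(k, oracle, rtol=1e-10)

    def test_unweighted_option_uses_plain_tensors(self):
        st = make_kinematics(np.diag([1.1, 1.1 ** -0.5, 1.1 ** -0.5]))
        arch = arcade_directions(0.0, dispersion=0.5)
        _, i4w, _ = invariants(st, arch, weighted_i4=True)
        _, i4p, _ = invariants(st, arch, weighted_i4=False)
        assert not np.allclose(i4w, i4p)
        assert i4p[0] == pytest.approx(st.C_bar[0, 0], rel=1e-12)


class TestEnergies:
    def test_reference_energy_constant(self, params, mid_composition,
                                       mid_arch):
        """At the identity the fibril energy reduces to the sum of the
        1/k2t constants; the neo-Hookean term vanishes."""
        st = make_kinematics(np.eye(3))
        k2t = mid_composition.phi_co * params.k2
        expected = mid_composition.phi_co * 8 * params.k1 / k2t
        assert free_energy(st, mid_composition, mid_arch, params) == \
            pytest.approx(expected, rel=1e-12)

    def test_collagen_free_limit(self, params):
        comp = LocalComposition(0.8, 0.0, 0.2)
        arch = arcade_directions(0.5, dispersion=params.w)
        st = make_kinematics(np.diag([1.05, 1.0, 1.0 / 1.05]))
        i1 = np.trace(st.C_bar)
        assert free_energy(st, comp, arch, params) == \
            pytest.approx(comp.phi_pg * params.a0 * (i1 - 3.0), rel=1e-12)

    def test_energy_matches_scalar_reimplementation(self, params):
        """Term-by-term scalar oracle, written independently of the
        vectorized implementation."""
        rng = np.random.default_rng(6)
        comp = LocalComposition(0.75, 0.18, 0.07)
        arch = arcade_directions(0.35, dispersion=params.w)
        for _ in range(5):
            st = random_state(rng)
            Cb = st.C_bar
            k2t = comp.phi_co * params.k2
            k3t = comp.phi_co * params.k3
            acc = 0.0
            for m in arch.directions:
                Lt = (params.w / 3) * np.eye(3) + \
                    (1 - params.w) * np.outer(m, m)
                i4 = float(np.trace(Cb @ Lt))
                cof = np.linalg.det(Cb) * np.linalg.inv(Cb)
                kk = float(np.trace(cof @ Lt))
                acc += params.k1 * (np.exp(k2t * (i4 - 1)) / k2t
                                    + (kk ** k3t - 1) / k3t)
            oracle = comp.phi_co * acc + \
                comp.phi_pg * params.a0 * (np.trace(Cb) - 3.0)
            assert free_energy(st, comp, arch, params) == \
                pytest.approx(oracle, rel=1e-12)


class TestOsmoticPressure:
    def test_stress_free_reference(self, params, mid_composition):
        assert osmotic_pressure(1.0, mid_composition, params) == \
            pytest.approx(0.0, abs=1e-14)

    def test_divergence_toward_compaction(self, params, mid_composition):
        J = mid_composition.phi_s + 1e-9 + 1e-12
        with pytest.raises(CompactionError):
            osmotic_pressure(mid_composition.phi_s + 1e-10,
                             mid_composition, params)
        # just above the guard: enormous pressure
        assert osmotic_pressure(mid_composition.phi_s + 1e-6,
                                mid_composition, params) > 1e6 * params.a0

    def test_hand_evaluated_value(self):
        """Direct scalar evaluation of the swelling relation with the
        global parameter set at 10 % volume loss."""
        params = MaterialParameters(a0=0.35, a1=5.0)
        comp = LocalComposition(0.75, 0.18, 0.07)
        expected = 0.35 * ((1 - 0.25) / (0.9 - 0.25)) ** (2 * 0.75 * 5) - 0.35
        assert osmotic_pressure(0.9, comp, params) == \
            pytest.approx(expected, rel=1e-12)

    def test_monotone_decreasing_in_volume(self, params, mid_composition):
        J = np.linspace(mid_composition.phi_s + 0.05, 1.0, 40)
        pi = [osmotic_pressure(j, mid_composition, params) for j in J]
        assert np.all(np.diff(pi) < 0)

    def test_energy_consistent_with_pressure(self, params, mid_composition):
        h = 1e-7
        for J in (0.9, 0.95, 0.99):
            fd = -(osmotic_energy(J + h, mid_composition, params)
                   - osmotic_energy(J - h, mid_composition, params)) / (2 * h)
            assert fd == pytest.approx(
                osmotic_pressure(J, mid_composition, params), rel=1e-6)


class TestCauchyStress:
    def test_stress_free_reference(self, params):
        rng = np.random.default_rng(7)
        st = make_kinematics(np.eye(3))
        for _ in range(10):
            comp = random_admissible_composition(rng)
            arch = arcade_directions(rng.uniform(0, 1), dispersion=params.w)
            sigma = cauchy_stress(st, comp, arch, params).sigma
            assert np.max(np.abs(sigma)) < 1e-9

    def test_energy_stress_consistency(self, params):
        rng = np.random.default_rng(9)
        comp = LocalComposition(0.75, 0.18, 0.07)
        for _ in range(15):
            arch = arcade_directions(rng.uniform(0, 1), dispersion=params.w)
            st = random_state(rng)
            if st.J <= comp.phi_s + 0.05:
                continue
            sig = cauchy_stress(st, comp, arch, params).sigma
            oracle = fd_cauchy(st.F, comp, arch, params)
            denom = max(np.max(np.abs(sig)), 1e-6)
            assert np.max(np.abs(sig - oracle)) / denom < 1e-5

    def test_objectivity(self, params, mid_composition):
        rng = np.random.default_rng(10)
        arch = arcade_directions(0.45, dispersion=params.w)
        for _ in range(5):
            A = rng.standard_normal((3, 3))
            Q, _ = np.linalg.qr(A)
            if np.linalg.det(Q) < 0:
                Q[:, 0] *= -1
            st = random_state(rng)
            s_rot = cauchy_stress(make_kinematics(Q @ st.F),
                                  mid_composition, arch, params).sigma
            s_ref = cauchy_stress(st, mid_composition, arch, params).sigma
            assert np.max(np.abs(s_rot - Q @ s_ref @ Q.T)) < 1e-9

    def test_confined_compression_monotone(self, params, mid_composition):
        arch = arcade_directions(0.5, dispersion=params.w)
        lams = np.linspace(0.99, 0.75, 15)
        szz = [cauchy_stress(make_kinematics(np.diag([1, 1, l])),
                             mid_composition, arch, params).sigma[2, 2]
               for l in lams]
        assert np.all(np.diff(szz) < 0)  # more compression, more negative
        assert szz[0] < 0

    def test_isotropic_limit_azimuth_invariant(self, mid_composition):
        """At w = 1 the response is independent of fiber azimuths."""
        params = MaterialParameters(w=1.0)
        st = make_kinematics(np.diag([1.0, 1.0, 0.85]))
        s1 = cauchy_stress(st, mid_composition,
                           arcade_directions(0.2, dispersion=1.0),
                           params).sigma
        s2 = cauchy_stress(st, mid_composition,
                           arcade_directions(0.9, dispersion=1.0),
                           params).sigma
        assert np.max(np.abs(s1 - s2)) < 1e-12

    def test_printed_stress_agrees_at_reference_only(self, params,
                                                     mid_composition):
        """The published closed-form fibril stress coincides with the
        energy-consistent stress at F = I but deviates under load (it
        drops deformation-dependent derivative terms); the discrepancy is
        surfaced here rather than silently resolved."""
        arch = arcade_directions(0.5, dispersion=params.w)
        st0 = make_kinematics(np.eye(3))
        s_e = cauchy_stress(st0, mid_composition, arch, params,
                            method="energy").sigma
        s_p = cauchy_stress(st0, mid_composition, arch, params,
                            method="printed").sigma
        assert np.max(np.abs(s_e - s_p)) < 1e-12
        st = make_kinematics(np.diag([1.0, 1.0, 0.85]))
        s_e = cauchy_stress(st, mid_composition, arch, params,
                            method="energy").sigma
        s_p = cauchy_stress(st, mid_composition, arch, params,
                            method="printed").sigma
        assert np.max(np.abs(s_e - s_p)) > 1e-3

    def test_compaction_propagates(self, params, mid_composition):
        arch = arcade_directions(0.5, dispersion=params.w)
        st = make_kinematics(np.diag([1.0, 1.0,
                                      mid_composition.phi_s * 0.99]))
        with pytest.raises(CompactionError):
            cauchy_stress(st, mid_composition, arch, params)


def test_material_parameter_validation():
    with pytest.raises(DomainError):
        MaterialParameters(k1=-1.0)
    with pytest.raises(DomainError):
        MaterialParameters(w=1.5)
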