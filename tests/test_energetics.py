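"""Pair energies, GB solvation, SASA, entropy, full decomposition."""

import math

import numpy as np
import pytest

from samnp import constants as C
from samnp.energetics import (
    BindingOptions, EnergyDecomposition, SingularityError,
    binding_free_energy, gb_polar_solvation, harmonic_oscillator_entropy,
    hct_born_radii, mm_pair_energy, polarity_split, quasiharmonic_entropy,
    sasa_nonpolar, shrake_rupley_sasa,
)
from samnp.geometry import random_rotation
from samnp.topology import TopologyBuilder
from samnp.trajectory import Trajectory


def _ion_topology(charges, sigmas=None, epsilons=None, element="NA"):
    tb = TopologyBuilder()
    n = len(charges)
    sigmas = sigmas or [3.0] * n
    epsilons = epsilons or [0.5] * n
    for q, s, e in zip(charges, sigmas, epsilons):
        tb.add_molecule("ion", [element], [q], [s], [e])
    return tb.build()


class TestPairEnergies:
    def test_coulomb_closed_form(self):
        topo = _ion_topology([1.0, -1.0])
        frame = np.array([[0.0, 0.0, 0.0], [3.32, 0.0, 0.0]])
        e_ele, _ = mm_pair_energy(frame, topo, [0], [1])
        assert e_ele == pytest.approx(-C.COULOMB_CONSTANT / 3.32, rel=1e-12)
        assert e_ele == pytest.approx(-100.02, abs=0.01)

    def test_lj_zero_crossing_and_minimum(self):
        topo = _ion_topology([0.0, 0.0])
        frame = np.array([[0.0, 0.0, 0.0], [3.0, 0.0, 0.0]])
        _, e_vdw = mm_pair_energy(frame, topo, [0], [1])
        assert abs(e_vdw) < 1e-12
        frame[1, 0] = 3.0 * 2 ** (1 / 6)
        _, e_vdw = mm_pair_energy(frame, topo, [0], [1])
        assert e_vdw == pytest.approx(-0.5, rel=1e-12)  # -eps = -sqrt(.5*.5)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(50)
        n = 40
        charges = rng.uniform(-1, 1, size=n).tolist()
        sigmas = rng.uniform(2.5, 3.8, size=n).tolist()
        epsilons = rng.uniform(0.05, 0.3, size=n).tolist()
        topo = _ion_topology(charges, sigmas, epsilons)
        frame = rng.uniform(0, 20, size=(n, 3))
        a, b = np.arange(15), np.arange(15, 40)
        e_ele, e_vdw = mm_pair_energy(frame, topo, a, b)
        oe = ov = 0.0
        for i in a:
            for j in b:
                r = np.linalg.norm(frame[i] - frame[j])
                oe += C.COULOMB_CONSTANT * charges[i] * charges[j] / r
                sig = 0.5 * (sigmas[i] + sigmas[j])
                eps = math.sqrt(epsilons[i] * epsilons[j])
                ov += 4 * eps * ((sig / r) ** 12 - (sig / r) ** 6)
        assert e_ele == pytest.approx(oe, rel=1e-10)
        assert e_vdw == pytest.approx(ov, rel=1e-10)

    def test_overlapping_atoms_raise(self):
        topo = _ion_topology([1.0, 1.0])
        frame = np.zeros((2, 3))
        with pytest.raises(SingularityError):
            mm_pair_energy(frame, topo, [0], [1])

    def test_overlapping_selections_rejected(self):
        topo = _ion_topology([1.0, 1.0])
        with pytest.raises(ValueError, match="disjoint"):
            mm_pair_energy(np.zeros((2, 3)), topo, [0, 1], [1])


class TestGeneralizedBorn:
    def test_single_ion_born_formula(self):
        radii = hct_born_radii(np.zeros((1, 3)), np.array([2.0]),
                               np.array([0.8]))
        assert radii[0] == pytest.approx(2.0, rel=1e-12)
        topo = _ion_topology([1.0])
        got = gb_polar_solvation(np.zeros((1, 3)), topo, [0])
        born = (
            -0.5 * C.COULOMB_CONSTANT * (1.0 - 1.0 / 78.5)
            / C.INTRINSIC_RADII["NA"]
        )
        assert got == pytest.approx(born, rel=1e-6)

    def test_born_reference_value(self):
        """q = 1e in a 2.0 Å cavity, eps 78.5: ΔG ≈ -81.96 kcal/mol."""
        expected = -(C.COULOMB_CONSTANT / 2.0) * (1 - 1 / 78.5) / 2.0
        assert expected == pytest.approx(-81.96, abs=0.01)

    def test_zero_charges_zero_energy(self):
        topo = _ion_topology([0.0, 0.0])
        frame = np.array([[0.0, 0.0, 0.0], [4.0, 0.0, 0.0]])
        assert gb_polar_solvation(frame, topo, [0, 1]) == 0.0

    def test_far_pair_sums_individual_born(self):
        topo = _ion_topology([1.0, -1.0])
        frame = np.array([[0.0, 0.0, 0.0], [2.0e4, 0.0, 0.0]])
        got = gb_polar_solvation(frame, topo, [0, 1])
        single = -0.5 * C.COULOMB_CONSTANT * (1 - 1 / 78.5) / C.INTRINSIC_RADII["NA"]
        assert got == pytest.approx(2 * single, rel=1e-3)

    def test_descreening_shrinks_effective_radius_inverse(self):
        # a close neighbour descreens: effective radius grows
        pos = np.array([[0.0, 0.0, 0.0], [3.0, 0.0, 0.0]])
        radii = hct_born_radii(pos, np.array([1.5, 1.5]), np.array([0.8, 0.8]))
        assert np.all(radii > 1.5)


class TestSASA:
    def test_isolated_sphere_analytic_area(self):
        areas = shrake_rupley_sasa(np.zeros((1, 3)), np.array([2.0]))
        assert areas[0] == pytest.approx(4 * np.pi * 3.4**2, rel=1e-9)

    def test_buried_atom_contributes_zero(self):
        # small atom at the center of a large enclosing sphere
        pos = np.array([[0.0, 0.0, 0.0], [0.1, 0.0, 0.0]])
        radii = np.array([8.0, 1.2])
        areas = shrake_rupley_sasa(pos, radii)
        assert areas[1] == 0.0

    def test_two_overlapping_spheres_match_cap_formula(self):
        r = 2.0 + 1.4  # solvent-expanded radius
        d = 2.5
        pos = np.array([[0.0, 0.0, 0.0], [d, 0.0, 0.0]])
        areas = shrake_rupley_sasa(pos, np.array([2.0, 2.0]))
        # exact exposed area of two equal intersecting spheres
        h = r - d / 2.0  # cap height hidden on each sphere
        exact_each = 4 * np.pi * r**2 - 2 * np.pi * r * h
        assert areas[0] == pytest.approx(exact_each, rel=0.01)
        assert areas[1] == pytest.approx(exact_each, rel=0.01)

    def test_nonpolar_energy_formula(self):
        topo = _ion_topology([0.0])
        got = sasa_nonpolar(np.zeros((1, 3)), topo, [0])
        r = C.INTRINSIC_RADII["NA"] + 1.4
        assert got == pytest.approx(
            C.SASA_GAMMA * 4 * np.pi * r**2 + C.SASA_BETA, rel=1e-9
        )


class TestQuasiharmonicEntropy:
    def _carbon_topology(self):
        tb = TopologyBuilder()
        tb.add_molecule("analyte", ["C"], [0.0], [3.4], [0.09])
        return tb.build()

    def test_frozen_selection_zero_entropy(self):
        topo = self._carbon_topology()
        traj = Trajectory(np.zeros((100, 1, 3)), np.arange(100.0))
        s = quasiharmonic_entropy(traj, topo, [0], remove_rigid_body=False)
        assert s == 0.0

    def test_1d_oscillator_matches_analytic(self):
        topo = self._carbon_topology()
        omega = 1.0e13  # rad/s
        kt_j = 1.380649e-23 * 300.0
        lam = kt_j / omega**2 / 1.66053906660e-47  # amu Å²
        sigma = math.sqrt(lam / 12.011)
        rng = np.random.default_rng(60)
        x = np.zeros((10_000, 1, 3))
        x[:, 0, 0] = rng.normal(scale=sigma, size=10_000)
        traj = Trajectory(x, np.arange(10_000.0))
        got = quasiharmonic_entropy(traj, topo, [0], remove_rigid_body=False)
        expected = -300.0 * harmonic_oscillator_entropy(omega, 300.0)
        assert got == pytest.approx(expected, rel=0.02)

    def test_entropy_increases_with_temperature(self):
        topo = self._carbon_topology()
        rng = np.random.default_rng(61)
        x = np.zeros((2000, 1, 3))
        x[:, 0, :] = rng.normal(scale=0.3, size=(2000, 3))
        traj = Trajectory(x, np.arange(2000.0))
        s300 = -quasiharmonic_entropy(traj, topo, [0], temperature=300.0,
                                      remove_rigid_body=False) / 300.0
        s600 = -quasiharmonic_entropy(traj, topo, [0], temperature=600.0,
                                      remove_rigid_body=False) / 600.0
        assert s600 > s300

    def test_insufficient_frames_raise(self):
        topo = self._carbon_topology()
        traj = Trajectory(np.zeros((10, 1, 3)), np.arange(10.0))
        with pytest.raises(ValueError, match="frames"):
            quasiharmonic_entropy(traj, topo, [0])


class TestBindingFreeEnergy:
    def _two_particle(self, separation, q=(1.0, -1.0)):
        topo = _ion_topology(list(q))
        coords = np.zeros((3, 2, 3))
        coords[:, 1, 0] = separation
        traj = Trajectory(coords, np.arange(3) * 0.1)
        return topo, traj

    def test_empty_ligand_all_terms_zero(self):
        topo, traj = self._two_particle(5.0)
        d = binding_free_energy(traj, topo, np.array([0, 1]),
                                np.array([], dtype=int))
        assert d.enthalpy == 0.0 and d.g_bind == 0.0 and d.e_ele == 0.0

    def test_two_particle_hand_oracle(self):
        """ΔE_ele Coulomb; ΔG terms recomputed term-by-term by hand."""
        sep = 6.0
        topo, traj = self._two_particle(sep)
        d = binding_free_energy(traj, topo, np.array([0]), np.array([1]))
        frame = traj.coords[0]
        assert d.e_ele == pytest.approx(-C.COULOMB_CONSTANT / sep, rel=1e-10)
        gb_hand = (
            gb_polar_solvation(frame, topo, [0, 1])
            - gb_polar_solvation(frame, topo, [0])
            - gb_polar_solvation(frame, topo, [1])
        )
        np_hand = (
            sasa_nonpolar(frame, topo, [0, 1])
            - sasa_nonpolar(frame, topo, [0])
            - sasa_nonpolar(frame, topo, [1])
        )
        assert d.g_polar == pytest.approx(gb_hand, abs=1e-10)
        assert d.g_nonpolar == pytest.approx(np_hand, abs=1e-10)
        assert d.enthalpy == pytest.approx(
            d.e_ele + d.e_vdw + gb_hand + np_hand, abs=1e-10
        )

    def test_bookkeeping_identities_on_random_runs(self, system_small):
        from samnp.synthetic import SyntheticSpec, generate

        spec = SyntheticSpec(n_frames=3, seed=80, water_density=0.0,
                             analyte_bound_fraction=1.0)
        traj, _ = generate(system_small, spec)
        topo = traj.topology
        receptor = np.arange(system_small.model.n_atoms)
        ligand = topo.molecules_of_kind("analyte")[0]
        d = binding_free_energy(traj, topo, receptor, ligand,
                                BindingOptions(sasa_points=240))
        d.check_identities(tol=1e-10)

    def test_rigid_motion_invariance(self):
        topo, traj = self._two_particle(5.0)
        d0 = binding_free_energy(traj, topo, np.array([0]), np.array([1]))
        rot = random_rotation(np.random.default_rng(5))
        shifted = Trajectory(
            traj.coords @ rot.T + np.array([7.0, -3.0, 11.0]),
            traj.times,
        )
        d1 = binding_free_energy(shifted, topo, np.array([0]), np.array([1]))
        for attr in ("e_ele", "e_vdw", "g_polar"):
            assert getattr(d0, attr) == pytest.approx(
                getattr(d1, attr), abs=1e-8
            )
        # the SASA term uses a fixed spherical quadrature, so it is
        # rotation-invariant only to the quadrature resolution
        assert d0.g_nonpolar == pytest.approx(d1.g_nonpolar, abs=0.02)
        assert d0.enthalpy == pytest.approx(d1.enthalpy, abs=0.02)

    def test_asymptotic_decoupling(self):
        topo, traj = self._two_particle(100.0)
        d = binding_free_energy(traj, topo, np.array([0]), np.array([1]))
        assert abs(d.e_ele) < 3.5   # Coulomb tail ~ k_e/100
        assert abs(d.e_vdw) < 1e-6
        assert abs(d.g_polar + d.e_ele) < 0.2  # GB cancels the Coulomb tail
        assert abs(d.g_nonpolar + C.SASA_BETA) < 1e-9  # only the offset left

    def test_bound_attractive_complex_negative_enthalpy(self, system_small):
        from samnp.synthetic import SyntheticSpec, generate

        spec = SyntheticSpec(n_frames=3, seed=81, water_density=0.0,
                             analyte_bound_fraction=1.0)
        traj, _ = generate(system_small, spec)
        topo = traj.topology
        receptor = np.arange(system_small.model.n_atoms)
        ligand = topo.molecules_of_kind("analyte")[0]
        d = binding_free_energy(traj, topo, receptor, ligand,
                                BindingOptions(sasa_points=240))
        assert d.enthalpy < 0.0

    def test_replica_averaging(self):
        topo, t1 = self._two_particle(5.0)
        _, t2 = self._two_particle(7.0)
        d1 = binding_free_energy(t1, topo, np.array([0]), np.array([1]))
        d2 = binding_free_energy(t2, topo, np.array([0]), np.array([1]))
        both = binding_free_energy([t1, t2], topo, np.array([0]),
                                   np.array([1]))
        assert both.n_replicas == 2
        assert both.e_ele == pytest.approx(0.5 * (d1.e_ele + d2.e_ele),
                                           rel=1e-12)

    def test_overlapping_selections_rejected(self):
        topo, traj = self._two_particle(5.0)
        with pytest.raises(ValueError, match="overlap"):
            binding_free_energy(traj, topo, np.array([0, 1]), np.array([1]))


class TestPolaritySplit:
    def test_zero_decomposition(self):
        d = EnergyDecomposition(0, 0, 0, 0, 0, 0, 0, 0, 0, 0)
        assert polarity_split(d) == (0.0, 0.0)

    def test_split_sums_to_enthalpy(self):
        rng = np.random.default_rng(70)
        for _ in range(20):
            e_ele, e_vdw, g_p, g_np = rng.normal(size=4) * 10
            e_mm = e_ele + e_vdw
            g_solv = g_p + g_np
            d = EnergyDecomposition(
                e_int=0.0, e_ele=e_ele, e_vdw=e_vdw, e_mm=e_mm,
                g_polar=g_p, g_nonpolar=g_np, g_solv=g_solv,
                enthalpy=e_mm + g_solv, minus_t_ds=0.0,
                g_bind=e_mm + g_solv,
            )
            h_pol, h_nonpol = polarity_split(d)
            assert h_pol + h_nonpol == pytest.approx(d.enthalpy, abs=1e-10)

    def test_charges_only_split(self):
        # no LJ parameters: the nonpolar side carries only the SASA terms
        topo = _ion_topology([1.0, -1.0], epsilons=[0.0, 0.0])
        coords = np.zeros((2, 2, 3))
        coords[:, 1, 0] = 5.0
        traj = Trajectory(coords, np.arange(2) * 0.1)
        d = binding_free_energy(traj, topo, np.array([0]), np.array([1]))
        h_pol, h_nonpol = polarity_split(d)
        assert d.e_vdw == 0.0
        assert h_nonpol == pytest.approx(d.g_nonpolar, abs=1e-12)
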