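"""Contacts, persistence, bridges, hydrogen bonds, overlap, orientation."""

import math

import numpy as np
import pytest

from samnp.interactions import (
    contact_series, contacting_molecules, hydrogen_bonds, parallel_orientation,
    plane_axis_angle, radial_overlap, salt_bridges, water_bridges,
)
from samnp.synthetic import SyntheticSpec, generate
from samnp.topology import TopologyBuilder
from samnp.trajectory import Trajectory


def _point_topology(n, element="C", charge=0.0):
    tb = TopologyBuilder()
    for _ in range(n):
        tb.add_molecule("analyte", [element], [charge], [3.4], [0.09])
    return tb.build()


class TestContactSeries:
    def _traj(self, coords, box=None):
        coords = np.asarray(coords, float)
        return Trajectory(coords, np.arange(len(coords)) * 0.1, box=box)

    def test_fixed_near_analyte_always_true(self):
        coords = np.zeros((4, 2, 3))
        coords[:, 1, 0] = 3.0
        traj = self._traj(coords)
        s = contact_series(traj, [np.array([1])], np.array([0]), cutoff=5.0)
        assert s.all()

    def test_fixed_far_analyte_always_false(self):
        coords = np.zeros((4, 2, 3))
        coords[:, 1, 0] = 8.0
        traj = self._traj(coords)
        s = contact_series(traj, [np.array([1])], np.array([0]), cutoff=5.0)
        assert not s.any()

    def test_matches_brute_force_random_walk(self):
        rng = np.random.default_rng(12)
        n_mono, n_analytes, atoms_per = 20, 5, 3
        n_atoms = n_mono + n_analytes * atoms_per
        coords = np.cumsum(
            rng.normal(scale=0.7, size=(50, n_atoms, 3)), axis=0
        ) + rng.uniform(-10, 10, size=(1, n_atoms, 3))
        box = np.array([25.0, 25.0, 25.0])
        traj = self._traj(coords, box=box)
        mono = np.arange(n_mono)
        sels = [
            n_mono + atoms_per * a + np.arange(atoms_per)
            for a in range(n_analytes)
        ]
        s = contact_series(traj, sels, mono, cutoff=5.0)
        for f in range(traj.n_frames):
            for a, sel in enumerate(sels):
                dmin = np.inf
                for i in sel:
                    for j in mono:
                        d = coords[f, i] - coords[f, j]
                        d -= box * np.round(d / box)
                        dmin = min(dmin, float(np.linalg.norm(d)))
                assert s[f, a] == (dmin < 5.0)

    def test_periodic_agrees_with_direct_for_large_box(self):
        rng = np.random.default_rng(13)
        coords = rng.uniform(-5, 5, size=(10, 12, 3))
        big = np.array([80.0, 80.0, 80.0])
        t_boxed = self._traj(coords, box=big)
        t_free = self._traj(coords)
        sels = [np.array([10]), np.array([11])]
        mono = np.arange(10)
        assert np.array_equal(
            contact_series(t_boxed, sels, mono, 5.0),
            contact_series(t_free, sels, mono, 5.0),
        )

    def test_empty_selection_rejected(self):
        traj = self._traj(np.zeros((2, 3, 3)))
        with pytest.raises(ValueError):
            contact_series(traj, [np.array([0])], np.array([], dtype=int))


class TestContactingMolecules:
    def test_short_run_does_not_qualify(self):
        # 8 ns of contact at 0.1 ns/frame, then off
        series = np.zeros((200, 1), bool)
        series[:80, 0] = True
        count, recs = contacting_molecules(series, dt=0.1, min_duration=10.0)
        assert count == 0 and not recs[0].qualifies

    def test_exactly_threshold_does_not_qualify(self):
        """'Longer than' is strict: a run of exactly 10 ns does not count."""
        series = np.zeros((150, 1), bool)
        series[:100, 0] = True  # 100 frames * 0.1 ns = 10 ns
        count, _ = contacting_molecules(series, dt=0.1, min_duration=10.0)
        assert count == 0
        series[:101, 0] = True
        count, _ = contacting_molecules(series, dt=0.1, min_duration=10.0)
        assert count == 1

    def test_permanent_contact_qualifies(self):
        series = np.ones((4000, 1), bool)
        count, recs = contacting_molecules(series, dt=0.1, min_duration=10.0)
        assert count == 1 and recs[0].qualifies
        assert recs[0].intervals == [(0.0, 400.0)]

    def test_planted_long_and_short_binders(self):
        """19 molecules with 50 ns bouts, 11 with 2 ns bouts -> count 19."""
        n_frames = 1000
        series = np.zeros((n_frames, 30), bool)
        for a in range(19):
            series[100 : 100 + 500, a] = True  # 50 ns
        for a in range(19, 30):
            series[100 : 100 + 20, a] = True  # 2 ns
        count, _ = contacting_molecules(series, dt=0.1, min_duration=10.0)
        assert count == 19

    def test_monotone_in_min_duration(self):
        rng = np.random.default_rng(3)
        series = rng.uniform(size=(400, 10)) < 0.7
        counts = [
            contacting_molecules(series, dt=0.1, min_duration=m)[0]
            for m in (0.5, 1.0, 2.0, 5.0, 10.0)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_monotone_in_cutoff(self):
        rng = np.random.default_rng(4)
        coords = rng.uniform(-8, 8, size=(30, 12, 3))
        traj = Trajectory(coords, np.arange(30) * 0.1)
        mono = np.arange(8)
        sels = [np.array([8 + a]) for a in range(4)]
        prev = None
        for cutoff in (2.0, 4.0, 6.0, 10.0):
            s = contact_series(traj, sels, mono, cutoff)
            c = contacting_molecules(s, dt=0.1, min_duration=0.5)[0]
            if prev is not None:
                assert c >= prev
            prev = c


class TestSaltBridges:
    def test_single_pair_inside_cutoff(self):
        frame = np.array([[0.0, 0.0, 0.0], [3.5, 0.0, 0.0]])
        assert salt_bridges(frame, np.array([0]), np.array([1])) == 1

    def test_single_pair_outside_cutoff(self):
        frame = np.array([[0.0, 0.0, 0.0], [4.5, 0.0, 0.0]])
        assert salt_bridges(frame, np.array([0]), np.array([1])) == 0

    def test_matches_brute_force(self):
        rng = np.random.default_rng(21)
        frame = rng.uniform(0, 12, size=(40, 3))
        cat = np.arange(15)
        ani = np.arange(15, 40)
        expected = sum(
            1
            for i in cat
            for j in ani
            if np.linalg.norm(frame[i] - frame[j]) <= 4.0
        )
        assert salt_bridges(frame, cat, ani) == expected


class TestHydrogenBonds:
    def _oh_topology(self):
        tb = TopologyBuilder()
        tb.add_molecule("water", ["O", "H", "H"], [-0.8, 0.4, 0.4],
                        [3.15, 1.0, 1.0], [0.15, 0.0, 0.0],
                        bonds=[(0, 1), (0, 2)])
        tb.add_molecule("analyte", ["O"], [-0.4], [3.0], [0.21])
        return tb.build()

    def test_ideal_linear_geometry(self):
        topo = self._oh_topology()
        frame = np.array(
            [[0, 0, 0], [0.96, 0, 0], [-0.3, 0.9, 0], [2.8, 0, 0]], float
        )
        hb = hydrogen_bonds(frame, topo, np.array([0]), np.array([3]))
        assert hb == [(0, 1, 3)]

    def test_bent_geometry_rejected(self):
        topo = self._oh_topology()
        # acceptor at 90 degrees from one O-H bond and nearly collinear
        # (angle ~ 0) with the other: neither hydrogen qualifies
        frame = np.array(
            [[0, 0, 0], [0.96, 0, 0], [-0.3, 0.9, 0], [0.96, -2.5, 0]], float
        )
        hb = hydrogen_bonds(frame, topo, np.array([0]), np.array([3]))
        assert hb == []

    def test_donor_without_hydrogen_raises(self):
        topo = self._oh_topology()
        frame = np.zeros((4, 3))
        with pytest.raises(ValueError, match="donor atom 3"):
            hydrogen_bonds(frame, topo, np.array([3]), np.array([0]))

    def test_water_cluster_matches_brute_force(self):
        rng = np.random.default_rng(30)
        tb = TopologyBuilder()
        n_w = 20
        for _ in range(n_w):
            tb.add_molecule("water", ["O", "H", "H"], [-0.8, 0.4, 0.4],
                            [3.15, 1.0, 1.0], [0.15, 0.0, 0.0],
                            bonds=[(0, 1), (0, 2)])
        topo = tb.build()
        frame = np.zeros((3 * n_w, 3))
        from samnp.model_builder import water_molecule

        for w in range(n_w):
            frame[3 * w : 3 * w + 3] = water_molecule(
                rng.uniform(0, 8, size=3), rng
            )
        donors = np.arange(0, 3 * n_w, 3)
        acceptors = donors.copy()
        got = set(hydrogen_bonds(frame, topo, donors, acceptors))
        expected = set()
        for d in donors:
            for a in acceptors:
                if a == d or np.linalg.norm(frame[a] - frame[d]) > 3.5:
                    continue
                for h in (d + 1, d + 2):
                    v1, v2 = frame[d] - frame[h], frame[a] - frame[h]
                    cosv = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
                    if math.degrees(math.acos(np.clip(cosv, -1, 1))) >= 120.0:
                        expected.add((d, h, a))
        assert got == expected


class TestWaterBridges:
    def _bridge_topology(self):
        tb = TopologyBuilder()
        tb.add_molecule("ligand", ["O"], [-0.5], [3.0], [0.21],
                        flags={0: "sulfonate_oxygen"})
        tb.add_molecule("analyte", ["N", "H"], [0.6, 0.4], [3.25, 1.0],
                        [0.17, 0.0], flags={0: "ammonium_nitrogen"},
                        bonds=[(0, 1)])
        tb.add_molecule("water", ["O", "H", "H"], [-0.8, 0.4, 0.4],
                        [3.15, 1.0, 1.0], [0.15, 0.0, 0.0],
                        bonds=[(0, 1), (0, 2)])
        return tb.build()

    def test_ideal_double_linked_water(self):
        topo = self._bridge_topology()
        # sulfonate O at origin; water O at 2.8 with one H pointing back at
        # it; ammonium N at 5.6 with its H pointing at the water oxygen
        frame = np.array(
            [
                [0.0, 0.0, 0.0],        # sulfonate O
                [5.6, 0.0, 0.0],        # ammonium N
                [4.6, 0.0, 0.0],        # N-H toward water
                [2.8, 0.0, 0.0],        # water O
                [1.84, 0.0, 0.0],       # water H toward sulfonate
                [3.1, 0.95, 0.0],       # other water H
            ]
        )
        n = water_bridges(frame, topo, np.array([0]), np.array([1]))
        assert n == 1

    def test_single_sided_water_not_a_bridge(self):
        topo = self._bridge_topology()
        frame = np.array(
            [
                [0.0, 0.0, 0.0],
                [20.0, 0.0, 0.0],   # ammonium far away
                [19.0, 0.0, 0.0],
                [2.8, 0.0, 0.0],
                [1.84, 0.0, 0.0],
                [3.1, 0.95, 0.0],
            ]
        )
        assert water_bridges(frame, topo, np.array([0]), np.array([1])) == 0

    def test_layer_matches_brute_force(self):
        rng = np.random.default_rng(31)
        tb = TopologyBuilder()
        tb.add_molecule("ligand", ["O", "O", "O"], [-0.5] * 3, [3.0] * 3,
                        [0.21] * 3,
                        flags={i: "sulfonate_oxygen" for i in range(3)})
        tb.add_molecule("analyte", ["N", "H", "H", "H"], [0.25, 0.25, 0.25, 0.25],
                        [3.25, 1.0, 1.0, 1.0], [0.17, 0.0, 0.0, 0.0],
                        flags={0: "ammonium_nitrogen"},
                        bonds=[(0, 1), (0, 2), (0, 3)])
        n_w = 40
        for _ in range(n_w):
            tb.add_molecule("water", ["O", "H", "H"], [-0.8, 0.4, 0.4],
                            [3.15, 1.0, 1.0], [0.15, 0.0, 0.0],
                            bonds=[(0, 1), (0, 2)])
        topo = tb.build()
        from samnp.model_builder import water_molecule

        frame = np.zeros((topo.n_atoms, 3))
        frame[:3] = rng.uniform(0, 6, size=(3, 3))
        frame[3] = rng.uniform(0, 6, size=3)
        for k, h in enumerate((4, 5, 6)):
            frame[h] = frame[3] + 1.01 * np.eye(3)[k]
        for w in range(n_w):
            frame[7 + 3 * w : 10 + 3 * w] = water_molecule(
                rng.uniform(0, 7, size=3), rng
            )
        sulf = np.arange(3)
        amm = np.array([3])
        got = water_bridges(frame, topo, sulf, amm)
        # independent double scan
        expected = 0
        for w in range(n_w):
            o_w = 7 + 3 * w
            to_s = bool(hydrogen_bonds(frame, topo, np.array([o_w]), sulf))
            to_n = bool(hydrogen_bonds(frame, topo, amm, np.array([o_w])))
            expected += int(to_s and to_n)
        assert got == expected


class TestRadialOverlap:
    def _traj_from_radii(self, ra, rb):
        rng = np.random.default_rng(40)
        def shell(radii):
            d = rng.normal(size=(len(radii), 3))
            d /= np.linalg.norm(d, axis=1, keepdims=True)
            return d * np.asarray(radii)[:, None]
        coords = np.vstack([shell(ra), shell(rb)])[None, :, :]
        traj = Trajectory(coords, np.array([0.0]))
        return traj, np.arange(len(ra)), len(ra) + np.arange(len(rb))

    def test_identical_groups_full_overlap(self):
        rng = np.random.default_rng(41)
        radii = rng.uniform(5, 10, size=400)
        traj, ga, gb = self._traj_from_radii(radii, radii)
        assert radial_overlap(traj, ga, gb) == pytest.approx(1.0, abs=1e-9)

    def test_disjoint_shells_zero_overlap(self):
        rng = np.random.default_rng(42)
        traj, ga, gb = self._traj_from_radii(
            rng.uniform(5, 10, size=300), rng.uniform(20, 25, size=300)
        )
        assert radial_overlap(traj, ga, gb) == 0.0

    def test_gaussian_overlap_matches_closed_form(self):
        rng = np.random.default_rng(43)
        n = 40_000
        ra = rng.normal(15.0, 1.0, size=n)
        rb = rng.normal(17.0, 1.0, size=n)
        traj, ga, gb = self._traj_from_radii(ra, rb)
        got = radial_overlap(traj, ga, gb, bin_width=0.25)
        # equal-sigma Gaussians: overlap = 2*Phi(-|mu1-mu2|/(2*sigma))
        from scipy.stats import norm

        expected = 2.0 * norm.cdf(-abs(17.0 - 15.0) / 2.0)
        assert abs(got - expected) < 0.02


class TestParallelOrientation:
    def test_plane_containing_axis_is_zero(self):
        ring = np.array(
            [[math.cos(a), 0.0, math.sin(a)] for a in np.linspace(0, 5, 6)]
        )
        axis_pts = np.column_stack(
            [np.zeros(5), np.zeros(5), np.arange(5.0)]
        )
        assert plane_axis_angle(ring, axis_pts) < 1e-6

    def test_normal_parallel_axis_is_ninety(self):
        ring = np.array(
            [[math.cos(a), math.sin(a), 0.0] for a in np.linspace(0, 5, 6)]
        )
        axis_pts = np.column_stack(
            [np.zeros(5), np.zeros(5), np.arange(5.0)]
        )
        assert abs(plane_axis_angle(ring, axis_pts) - 90.0) < 1e-5

    def test_collinear_plane_atoms_raise(self):
        pts = np.column_stack([np.arange(4.0), np.zeros(4), np.zeros(4)])
        with pytest.raises(ValueError, match="collinear"):
            plane_axis_angle(pts, pts)

    def test_generator_parallel_packing_median(self, system_small):
        spec = SyntheticSpec(n_frames=10, seed=51, water_density=0.0,
                             analyte_bound_fraction=0.9)
        traj, _ = generate(system_small, spec)
        dist = parallel_orientation(traj, traj.topology, system_small.model)
        assert len(dist.angles) > 0
        assert dist.median <= 20.0
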