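"""Synthetic trajectories with planted, recorded ground truth.

The generator is an emulator of trajectory *statistics*, not a physics
engine: ligand directors are drawn from a von Mises-Fisher mixture whose
component count and concentration set the monolayer morphology (bundled
vs. isotropic shell), analytes alternate bound/unbound states with
exponential dwell times and are placed by scripted geometry, and water is
distributed uniformly around the particle then thinned inside the planted
bundle cones by a controllable penetration factor.  Everything the
analyses later estimate (bundle membership, bound intervals, water
exclusion cones) is recorded exactly, so parameter-recovery tests have an
unambiguous reference.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import constants as C
from .geometry import rotation_between, sample_vmf, unit
from .model_builder import SimulationSystem, thomson_points, water_molecule
from .templates import _LJ
from .topology import Topology, TopologyBuilder
from .trajectory import Trajectory

_Z = np.array([0.0, 0.0, 1.0])


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic run.

    Defaults emulate the reference scenario: 0.1 ns frame spacing (so the
    10 ns persistence rule spans 100 frames), two opposite bundles, 30
    analytes with ~20 ns mean bound residence, and bulk-density water in
    the monolayer shell.
    """

    n_frames: int = 100
    dt: float = 0.1                      # ns / frame
    bundle_count: int = 2                # k; 0 = isotropic shell
    bundle_kappa: float = 200.0          # vMF concentration of directors
    analyte_bound_fraction: float = 0.6  # stationary bound probability
    mean_residence: float = 20.0         # ns, mean bound dwell
    contact_distance_bound: float = 4.0  # Å, bound analytes closer than this
    contact_distance_unbound: float = 8.0  # Å, unbound analytes beyond this
    water_penetration: float = 1.0       # 0 = water excluded from bundle cones
    cone_half_angle: float = 40.0        # degrees, bundle water-exclusion cone
    thermal_jitter: float = 0.1          # Å, per-atom Gaussian noise
    water_density: float = C.WATER_NUMBER_DENSITY  # molecules / Å³ in the shell
    seed: int = 0

    def validate(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be positive")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.bundle_count < 0:
            raise ValueError("bundle_count must be >= 0")
        for name in ("analyte_bound_fraction", "water_penetration"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.contact_distance_bound >= self.contact_distance_unbound:
            raise ValueError(
                "contact_distance_bound must be smaller than "
                "contact_distance_unbound"
            )
        if self.mean_residence <= 0:
            raise ValueError("mean_residence must be positive")


@dataclass
class GroundTruth:
    """Exact planted state of a synthetic trajectory."""

    bundle_axes: np.ndarray                     # (k, 3) unit vectors
    bundle_assignment: np.ndarray               # (n_frames, n_ligands), -1 = free
    bound_intervals: list[list[tuple[float, float]]]  # per analyte, ns
    water_cones: list[tuple[np.ndarray, float]]  # (axis, half-angle deg)
    total_time: float                            # n_frames * dt, ns

    def bound_at(self, t: float) -> np.ndarray:
        """Boolean planted bound state of every analyte at time ``t`` (ns)."""
        out = np.zeros(len(self.bound_intervals), bool)
        for i, intervals in enumerate(self.bound_intervals):
            out[i] = any(a <= t < b for a, b in intervals)
        return out

    def bound_counts(self, times: np.ndarray) -> np.ndarray:
        return np.array([int(self.bound_at(t).sum()) for t in times])

    def to_json(self, path: str | Path) -> None:
        payload = {
            "bundle_axes": self.bundle_axes.tolist(),
            "bundle_assignment": self.bundle_assignment.tolist(),
            "bound_intervals": [
                [[float(a), float(b)] for a, b in iv] for iv in self.bound_intervals
            ],
            "water_cones": [
                {"axis": np.asarray(ax).tolist(), "half_angle_deg": float(ha)}
                for ax, ha in self.water_cones
            ],
            "total_time": self.total_time,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            bundle_axes=np.array(d["bundle_axes"], float).reshape(-1, 3),
            bundle_assignment=np.array(d["bundle_assignment"], int),
            bound_intervals=[
                [(float(a), float(b)) for a, b in iv] for iv in d["bound_intervals"]
            ],
            water_cones=[
                (np.array(c["axis"], float), float(c["half_angle_deg"]))
                for c in d["water_cones"]
            ],
            total_time=float(d["total_time"]),
        )


# ----------------------------------------------------------------------
# residence-time machinery
# ----------------------------------------------------------------------

def sample_residence_intervals(rng: np.random.Generator, total_time: float,
                               bound_fraction: float,
                               mean_residence: float) -> list[tuple[float, float]]:
    """Alternating exponential bound/unbound intervals over [0, total_time].

    The unbound mean is set so the stationary bound probability equals
    ``bound_fraction``; the initial state is drawn from that stationary
    probability.  Returns the bound intervals, clipped to the window.
    """
    if bound_fraction <= 0.0:
        return []
    if bound_fraction >= 1.0:
        return [(0.0, total_time)]
    mean_unbound = mean_residence * (1.0 - bound_fraction) / bound_fraction
    t = 0.0
    bound = rng.uniform() < bound_fraction
    intervals: list[tuple[float, float]] = []
    while t < total_time:
        dur = rng.exponential(mean_residence if bound else mean_unbound)
        if bound:
            intervals.append((t, min(t + dur, total_time)))
        t += dur
        bound = not bound
    return intervals


def estimate_mean_residence(intervals_per_analyte: list[list[tuple[float, float]]],
                            total_time: float) -> float:
    """Censored maximum-likelihood estimate of the mean bound dwell time.

    For exponential dwell times right-censored at the window end the MLE
    is total bound time divided by the number of completed bouts.  A bout
    starting exactly at t=0 counts as complete (the generator draws full
    dwell times from the start of the window), only bouts cut off at
    ``total_time`` are censored.
    """
    total = 0.0
    completed = 0
    for intervals in intervals_per_analyte:
        for a, b in intervals:
            total += b - a
            if b < total_time:
                completed += 1
    if completed == 0:
        raise ValueError("no completed bound bouts; window too short")
    return total / completed


# ----------------------------------------------------------------------
# generator
# ----------------------------------------------------------------------

def generate(system: SimulationSystem,
             spec: SyntheticSpec) -> tuple[Trajectory, GroundTruth]:
    """Generate a synthetic trajectory for ``system`` under ``spec``.

    Fully reproducible per ``spec.seed``.  The returned trajectory carries
    its own topology (core + ligands + analytes + generator water +
    neutralizing ions); water and ion counts are chosen by the generator,
    independent of any water in ``system``.
    """
    spec.validate()
    model = system.model
    n_lig = len(model.ligands)
    if n_lig == 0:
        raise ValueError("system has no ligands to animate")
    seeds = np.random.SeedSequence(spec.seed).spawn(5)
    rng_dir = np.random.default_rng(seeds[0])
    rng_analyte = np.random.default_rng(seeds[1])
    rng_water = np.random.default_rng(seeds[2])
    rng_jitter = np.random.default_rng(seeds[3])
    rng_axes = np.random.default_rng(seeds[4])

    anchors = np.array([l.coords[l.template.anchor_index] for l in model.ligands])
    anchor_dirs = unit(anchors - model.core.center)
    chain_len = model.ligands[0].template.axis_length()
    r_surf = model.core.surface_radius()

    # --- planted bundle structure --------------------------------------
    k = spec.bundle_count
    if k > 0:
        axes = thomson_points(k, int(rng_axes.integers(2**31)))
        assignment = np.argmax(anchor_dirs @ axes.T, axis=1)
    else:
        axes = np.empty((0, 3))
        assignment = np.full(n_lig, -1)
    mean_dirs = axes[assignment] if k > 0 else anchor_dirs

    cones: list[tuple[np.ndarray, float]] = []
    if k > 0 and spec.water_penetration < 1.0:
        cones = [(axes[c], spec.cone_half_angle) for c in range(k)]

    # --- analyte state timelines ---------------------------------------
    n_analytes = system.n_analytes
    total_time = spec.n_frames * spec.dt
    intervals = [
        sample_residence_intervals(
            rng_analyte, total_time, spec.analyte_bound_fraction,
            spec.mean_residence,
        )
        for _ in range(n_analytes)
    ]

    # per-bout host ligand and lateral azimuth (deterministic per bout)
    bout_host = [
        [int(rng_analyte.integers(n_lig)) for _ in iv] for iv in intervals
    ]
    bout_phase = [
        [float(rng_analyte.uniform(0.0, 2.0 * np.pi)) for _ in iv]
        for iv in intervals
    ]

    # --- static water and ions -----------------------------------------
    r_mono = float(
        np.linalg.norm(
            np.vstack([l.coords for l in model.ligands]) - model.core.center,
            axis=1,
        ).max()
    )
    waters = _shell_water(
        rng_water, model.core.center, r_surf + 1.0, r_mono + 4.0,
        spec.water_density, cones, spec.water_penetration,
    )
    q = model.formal_charge()
    if system.analyte_template is not None:
        q += n_analytes * system.analyte_template.formal_charge
    n_ions = abs(int(round(q)))
    ion_species = "NA" if q < 0 else "CL"
    ion_pos = np.empty((0, 3))
    if n_ions:
        d = unit(rng_water.normal(size=(n_ions, 3)))
        r = rng_water.uniform(r_mono + 6.0, r_mono + 10.0, size=n_ions)
        ion_pos = model.core.center + d * r[:, None]

    topology = _assemble_topology(system, len(waters), ion_species, n_ions, q)
    elements = topology.elements

    # --- frames ---------------------------------------------------------
    lig_templates = [l.template for l in model.ligands]
    lig_refs = [
        t.coords - t.coords[t.anchor_index] for t in lig_templates
    ]
    mono_heavy_sel = topology.select(kind="ligand", heavy=True)
    mono_all_sel = topology.select(kind="ligand")
    analyte_tpl = system.analyte_template
    if analyte_tpl is not None:
        a_ref = analyte_tpl.coords - analyte_tpl.coords.mean(axis=0)
        a_heavy = analyte_tpl.heavy_indices()
        a_half = float(np.linalg.norm(a_ref, axis=1).max())

    n_atoms = topology.n_atoms
    coords = np.empty((spec.n_frames, n_atoms, 3))
    times = np.arange(spec.n_frames) * spec.dt
    truth_assignment = np.tile(assignment, (spec.n_frames, 1))

    n_core = model.core.n_atoms
    for f in range(spec.n_frames):
        t = times[f]
        frame = np.empty((n_atoms, 3))
        frame[:n_core] = model.core.positions
        # ligands
        off = n_core
        directors = np.empty((n_lig, 3))
        for i in range(n_lig):
            d = sample_vmf(mean_dirs[i], spec.bundle_kappa, 1, rng_dir)[0]
            directors[i] = d
            rot = rotation_between(_Z, d)
            lig = anchors[i] + lig_refs[i] @ rot.T
            if spec.thermal_jitter > 0:
                noise = rng_jitter.normal(
                    scale=spec.thermal_jitter, size=lig.shape
                )
                noise[lig_templates[i].anchor_index] = 0.0
                lig = lig + noise
            frame[off : off + len(lig)] = lig
            off += len(lig)
        lig_heavy_now = frame[mono_heavy_sel]
        from scipy.spatial import cKDTree

        tree_all = cKDTree(np.vstack([frame[mono_all_sel], frame[:n_core]]))
        tree_heavy = cKDTree(lig_heavy_now)
        # analytes
        for ai in range(n_analytes):
            bout = _which_bout(intervals[ai], t)
            if bout is not None:
                host = bout_host[ai][bout]
                phase = bout_phase[ai][bout]
                pos = _place_bound(
                    a_ref, a_heavy, frame, n_core, model, host,
                    directors[host], phase, tree_all, tree_heavy,
                    target=min(3.0, 0.75 * spec.contact_distance_bound),
                    bound_limit=spec.contact_distance_bound,
                )
            else:
                pos = _place_unbound(
                    rng_analyte, a_ref, a_heavy, system.box, lig_heavy_now,
                    model.core.center, r_mono, a_half,
                    spec.contact_distance_unbound,
                )
            frame[off : off + len(pos)] = pos
            off += len(pos)
        # water (static base + jitter) and ions (static)
        if len(waters):
            w = waters.reshape(-1, 3)
            if spec.thermal_jitter > 0:
                w = w + rng_jitter.normal(scale=spec.thermal_jitter, size=w.shape)
            frame[off : off + len(w)] = w
            off += len(w)
        if n_ions:
            frame[off : off + n_ions] = ion_pos
            off += n_ions
        coords[f] = frame

    traj = Trajectory(
        coords=coords, times=times, elements=elements,
        box=system.box.copy() if system.box is not None else None,
        topology=topology,
    )
    truth = GroundTruth(
        bundle_axes=axes,
        bundle_assignment=truth_assignment,
        bound_intervals=intervals,
        water_cones=cones,
        total_time=total_time,
    )
    return traj, truth


def _which_bout(intervals: list[tuple[float, float]], t: float) -> int | None:
    for b, (a, e) in enumerate(intervals):
        if a <= t < e:
            return b
    return None


def _place_bound(a_ref, a_heavy, frame, n_core, model, host, director, phase,
                 tree_all, tree_heavy, target: float,
                 bound_limit: float) -> np.ndarray:
    """Scripted bound placement: parallel to the host chain, ``target`` Å off.

    The analyte long axis is aligned with the host director.  A lateral
    line search (azimuth ``phase`` around the chain, then fallback
    azimuths) looks for the closest standoff where the all-atom minimum
    distance to the monolayer+core is at least ``target_lo`` while the
    heavy-atom minimum stays strictly below ``bound_limit``.  If no
    lateral slot exists (densely packed shell), the analyte is parked
    just beyond the host chain tip along the director, which always
    satisfies both conditions.
    """
    lig = model.ligands[host]
    off = model.ligand_atom_offset(host)
    chain = frame[off : off + lig.template.n_atoms]
    mid = chain.mean(axis=0)
    rot = rotation_between(_Z, director)
    body = a_ref @ rot.T
    target_lo = 0.85 * target
    # lateral frame around the director
    ref = np.array([1.0, 0.0, 0.0])
    if abs(director[0]) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(director, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(director, e1)
    for k in range(9):
        az = phase + k * (2.0 * np.pi / 9.0)
        perp = np.cos(az) * e1 + np.sin(az) * e2
        a_width = float(np.abs(body @ perp).max())
        for t in np.arange(a_width + 1.0, a_width + 9.0, 0.5):
            pos = mid + perp * t + body
            d_all = tree_all.query(pos)[0].min()
            if d_all < target_lo:
                continue
            d_heavy = tree_heavy.query(pos[a_heavy])[0].min()
            if d_heavy < bound_limit:
                return pos
            break  # moving further out only increases d_heavy
    # fallback: park just beyond the host chain tip, along the director
    tip = chain[lig.template.terminal_index]
    low = float((body @ director).min())
    return tip + director * (target - low) + body


def _place_unbound(rng, a_ref, a_heavy, box, mono_heavy, center, r_mono,
                   a_half, unbound_cutoff) -> np.ndarray:
    """Random free placement farther than ``unbound_cutoff`` from the shell.

    All analyte atoms stay inside the box and the *minimum-image* distance
    to every monolayer heavy atom exceeds the cutoff, so periodic and
    direct contact analyses agree on the planted state.
    """
    for _ in range(400):
        rot = rotation_between(_Z, unit(rng.normal(size=3)))
        body = a_ref @ rot.T
        if box is not None:
            centre = rng.uniform(-box / 2.0 + a_half + 0.5,
                                 box / 2.0 - a_half - 0.5)
        else:
            d = unit(rng.normal(size=3))
            centre = center + d * (
                r_mono + unbound_cutoff + a_half + 2.0 + rng.uniform(0.0, 4.0)
            )
        pos = centre + body
        diff = pos[a_heavy][:, None, :] - mono_heavy[None, :, :]
        if box is not None:
            diff -= box * np.round(diff / box)
        if np.linalg.norm(diff, axis=-1).min() > unbound_cutoff + 0.3:
            return pos
    raise ValueError(
        "could not place an unbound analyte farther than "
        f"{unbound_cutoff} Å from the monolayer inside the box; "
        "increase the solvent padding or reduce contact_distance_unbound"
    )


def _shell_water(rng, center, r_in, r_out, density, cones,
                 penetration) -> np.ndarray:
    """Uniform water in a spherical shell, thinned inside the bundle cones."""
    volume = 4.0 / 3.0 * np.pi * (r_out**3 - r_in**3)
    n = int(round(density * volume))
    if n == 0:
        return np.empty((0, 3, 3))
    u = rng.uniform(size=n)
    radii = (u * (r_out**3 - r_in**3) + r_in**3) ** (1.0 / 3.0)
    dirs = unit(rng.normal(size=(n, 3)))
    keep = np.ones(n, bool)
    for axis, half_angle in cones:
        inside = dirs @ axis > np.cos(np.radians(half_angle))
        thin = rng.uniform(size=n) >= penetration
        keep &= ~(inside & thin)
    sites = center + dirs[keep] * radii[keep, None]
    return np.array([water_molecule(s, rng) for s in sites])


def _assemble_topology(system: SimulationSystem, n_waters: int,
                       ion_species: str, n_ions: int, q: float) -> Topology:
    from .model_builder import _WATER_CHARGES, _WATER_EPS, _WATER_SIGMA

    tb = TopologyBuilder()
    model = system.model
    sig_au, eps_au = _LJ["AU"]
    n_au = model.core.n_atoms
    tb.add_molecule(
        "core", ["AU"] * n_au, [0.0] * n_au, [sig_au] * n_au, [eps_au] * n_au,
        bonds=list(model.core.bond_pairs),
    )
    for l in model.ligands:
        t = l.template
        tb.add_molecule(
            "ligand", t.elements, [a.charge for a in t.atoms],
            [a.sigma for a in t.atoms], [a.epsilon for a in t.atoms],
            flags=t.group_flags, bonds=[(i, j) for i, j, _ in t.bonds],
        )
    if system.analyte_template is not None:
        t = system.analyte_template
        for _ in range(system.n_analytes):
            tb.add_molecule(
                "analyte", t.elements, [a.charge for a in t.atoms],
                [a.sigma for a in t.atoms], [a.epsilon for a in t.atoms],
                flags=t.group_flags, bonds=[(i, j) for i, j, _ in t.bonds],
            )
    for _ in range(n_waters):
        tb.add_molecule(
            "water", ["O", "H", "H"], list(_WATER_CHARGES),
            list(_WATER_SIGMA), list(_WATER_EPS), bonds=[(0, 1), (0, 2)],
        )
    q_ion = 1.0 if q < 0 else -1.0
    for _ in range(n_ions):
        sig, eps = _LJ[ion_species]
        tb.add_molecule("ion", [ion_species], [q_ion], [sig], [eps])
    return tb.build()
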