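"""Analyte-monolayer interaction statistics.

Implements the contact bookkeeping used to characterize recognition on the
monolayer: per-frame analyte contacts (0.5 nm heavy-atom rule), persistent
contacting molecules (maximal runs longer than a duration threshold, 10 ns
by default, strictly greater, no gap tolerance), salt bridges, geometric
hydrogen bonds, water bridges, radial-distribution overlap of functional
groups, and the analyte-ring / ligand-backbone parallel-orientation angle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import constants as C
from .topology import Topology
from .trajectory import Trajectory


def _pair_distances(a: np.ndarray, b: np.ndarray,
                    box: np.ndarray | None = None) -> np.ndarray:
    """All pairwise distances between point sets, minimum-image if boxed."""
    diff = a[:, None, :] - b[None, :, :]
    if box is not None:
        diff -= box * np.round(diff / box)
    return np.linalg.norm(diff, axis=-1)


# ----------------------------------------------------------------------
# contacts and persistence
# ----------------------------------------------------------------------

@dataclass
class ContactRecord:
    """Contact history of one analyte molecule."""

    analyte: int
    intervals: list[tuple[float, float]]  # (start ns, end ns), sorted
    qualifies: bool                       # any interval longer than threshold


def contact_series(traj: Trajectory, analyte_selections: list[np.ndarray],
                   monolayer_selection: np.ndarray,
                   cutoff: float = C.CONTACT_CUTOFF,
                   use_box: bool = True) -> np.ndarray:
    """(n_frames, n_analytes) boolean: analyte within ``cutoff`` of monolayer.

    True at frame t iff the minimum heavy-atom distance from the analyte to
    the monolayer selection is strictly below ``cutoff``; distances are
    minimum-image when the trajectory has a box and ``use_box``.
    """
    if len(monolayer_selection) == 0:
        raise ValueError("monolayer selection resolves to zero atoms")
    if any(len(s) == 0 for s in analyte_selections):
        raise ValueError("an analyte selection resolves to zero atoms")
    box = traj.box if use_box else None
    out = np.zeros((traj.n_frames, len(analyte_selections)), bool)
    for f in range(traj.n_frames):
        mono = traj.coords[f][monolayer_selection]
        for a, sel in enumerate(analyte_selections):
            d = _pair_distances(traj.coords[f][sel], mono, box)
            out[f, a] = bool(d.min() < cutoff)
    return out


def _runs(series: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of consecutive True as (start, length) in frames."""
    runs = []
    start = None
    for i, v in enumerate(series):
        if v and start is None:
            start = i
        elif not v and start is not None:
            runs.append((start, i - start))
            start = None
    if start is not None:
        runs.append((start, len(series) - start))
    return runs


def contacting_molecules(series: np.ndarray, dt: float,
                         min_duration: float = C.MIN_CONTACT_DURATION
                         ) -> tuple[int, list[ContactRecord]]:
    """Count molecules with at least one contact run strictly longer than
    ``min_duration`` (ns).

    ``series`` is (n_frames, n_analytes) boolean with frame spacing ``dt``
    ns; a run of m frames covers m·dt ns.  No gap tolerance: a single
    broken frame ends the run.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    records = []
    count = 0
    for a in range(series.shape[1]):
        runs = _runs(series[:, a])
        intervals = [(s * dt, (s + l) * dt) for s, l in runs]
        qualifies = any(l * dt > min_duration for _, l in runs)
        count += int(qualifies)
        records.append(
            ContactRecord(analyte=a, intervals=intervals, qualifies=qualifies)
        )
    return count, records


# ----------------------------------------------------------------------
# bridges and hydrogen bonds
# ----------------------------------------------------------------------

def salt_bridges(frame: np.ndarray, cation_atoms: np.ndarray,
                 anion_atoms: np.ndarray,
                 d_cut: float = C.SALT_BRIDGE_CUTOFF,
                 box: np.ndarray | None = None) -> int:
    """Count of (N⁺, O⁻) pairs within ``d_cut`` Å, each pair once."""
    if len(cation_atoms) == 0 or len(anion_atoms) == 0:
        return 0
    d = _pair_distances(frame[cation_atoms], frame[anion_atoms], box)
    return int((d <= d_cut).sum())


def hydrogen_bonds(frame: np.ndarray, topology: Topology,
                   donors: np.ndarray, acceptors: np.ndarray,
                   d_da: float = C.HBOND_DA_CUTOFF,
                   angle_min: float = C.HBOND_ANGLE_MIN
                   ) -> list[tuple[int, int, int]]:
    """Geometric hydrogen bonds as (donor, hydrogen, acceptor) triples.

    Criteria: donor-acceptor distance ≤ ``d_da`` Å and donor-H-acceptor
    angle ≥ ``angle_min`` degrees.  Every donor must carry at least one
    topology-bonded hydrogen.
    """
    out = []
    cos_min = np.cos(np.radians(angle_min))
    acceptors = np.asarray(acceptors, int)
    for d_idx in np.asarray(donors, int):
        hydrogens = topology.attached_hydrogens(int(d_idx))
        if not hydrogens:
            raise ValueError(
                f"donor atom {d_idx} ({topology.elements[d_idx]}) has no "
                "attached hydrogen in the topology"
            )
        for a_idx in acceptors:
            if a_idx == d_idx:
                continue
            r_da = np.linalg.norm(frame[a_idx] - frame[d_idx])
            if r_da > d_da:
                continue
            for h_idx in hydrogens:
                v1 = frame[d_idx] - frame[h_idx]
                v2 = frame[a_idx] - frame[h_idx]
                n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
                if n1 < 1e-9 or n2 < 1e-9:
                    continue
                # angle >= angle_min  <=>  cos(angle) <= cos(angle_min)
                if float(v1 @ v2) / (n1 * n2) <= cos_min + 1e-12:
                    out.append((int(d_idx), int(h_idx), int(a_idx)))
    return out


def water_bridges(frame: np.ndarray, topology: Topology,
                  sulfonate_oxygens: np.ndarray,
                  ammonium_nitrogens: np.ndarray,
                  d_da: float = C.HBOND_DA_CUTOFF,
                  angle_min: float = C.HBOND_ANGLE_MIN) -> int:
    """Waters simultaneously hydrogen-bonded to both functional groups.

    A water counts when it is H-bonded (as donor or acceptor) to at least
    one sulfonate oxygen and at least one ammonium-nitrogen group member
    (the nitrogen as acceptor side is approximated by its N-H donors
    toward the water oxygen).
    """
    count = 0
    sulf = set(int(i) for i in sulfonate_oxygens)
    waters = topology.molecules_of_kind("water")
    if not waters:
        return 0
    if len(sulfonate_oxygens) == 0 or len(ammonium_nitrogens) == 0:
        return 0
    # distance prefilter: the full angular check only runs on waters whose
    # oxygen is within the D-A cutoff of both groups
    from scipy.spatial import cKDTree

    o_positions = np.array([frame[int(w[0])] for w in waters])
    near_s = cKDTree(frame[np.asarray(sulfonate_oxygens, int)])
    near_n = cKDTree(frame[np.asarray(ammonium_nitrogens, int)])
    close = (near_s.query(o_positions)[0] <= d_da) & (
        near_n.query(o_positions)[0] <= d_da
    )
    for water_atoms, is_close in zip(waters, close):
        if not is_close:
            continue
        o_w = int(water_atoms[0])
        # water as donor toward sulfonate oxygens
        hb_s = hydrogen_bonds(
            frame, topology, np.array([o_w]), np.asarray(sulfonate_oxygens, int),
            d_da, angle_min,
        )
        linked_s = any(a in sulf for _, _, a in hb_s)
        # ammonium N-H donors toward the water oxygen
        linked_n = False
        for n_idx in np.asarray(ammonium_nitrogens, int):
            hb_n = hydrogen_bonds(
                frame, topology, np.array([n_idx]), np.array([o_w]),
                d_da, angle_min,
            )
            if hb_n:
                linked_n = True
                break
        if linked_s and linked_n:
            count += 1
    return count


@dataclass
class BridgeCounts:
    """Per-frame bridge statistics and their pooled ensemble average."""

    salt: np.ndarray          # (n_frames,)
    hbonds: np.ndarray        # (n_frames,)
    water: np.ndarray         # (n_frames,)
    mean_total: float         # mean over frames of salt + water bridges
    se_total: float

    @classmethod
    def from_series(cls, salt, hbonds, water) -> "BridgeCounts":
        from .monolayer import block_mean_se

        salt = np.asarray(salt, int)
        hbonds = np.asarray(hbonds, int)
        water = np.asarray(water, int)
        mean, se = block_mean_se((salt + water).astype(float))
        return cls(salt=salt, hbonds=hbonds, water=water,
                   mean_total=mean, se_total=se)


def bridge_series(traj: Trajectory, topology: Topology,
                  d_salt: float = C.SALT_BRIDGE_CUTOFF,
                  d_da: float = C.HBOND_DA_CUTOFF,
                  angle_min: float = C.HBOND_ANGLE_MIN) -> BridgeCounts:
    """Salt/hydrogen/water-bridge counts for every frame of ``traj``.

    Uses the topology's functional-group flags: sulfonate oxygens on the
    monolayer side, ammonium nitrogens on the analyte side.
    """
    o_sulf = topology.select(flag="sulfonate_oxygen")
    n_amm = topology.select(flag="ammonium_nitrogen")
    salt, hb, wb = [], [], []
    for f in range(traj.n_frames):
        frame = traj.coords[f]
        salt.append(salt_bridges(frame, n_amm, o_sulf, d_salt))
        hb.append(
            len(hydrogen_bonds(frame, topology, n_amm, o_sulf, d_da, angle_min))
            if len(n_amm) else 0
        )
        wb.append(water_bridges(frame, topology, o_sulf, n_amm, d_da, angle_min))
    return BridgeCounts.from_series(salt, hb, wb)


# ----------------------------------------------------------------------
# radial overlap
# ----------------------------------------------------------------------

def radial_overlap(traj: Trajectory, group_a: np.ndarray, group_b: np.ndarray,
                   center: np.ndarray | None = None,
                   bin_width: float = 0.5) -> float:
    """Overlap coefficient of two radial distributions in [0, 1].

    Radial distances are measured from ``center`` (default origin), pooled
    over frames, histogrammed on a shared grid with ``bin_width`` Å, and
    the overlap is Σ min(p_A, p_B)·Δr of the normalized densities.
    """
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("both groups must be non-empty")
    if center is None:
        center = np.zeros(3)
    ra = np.linalg.norm(
        traj.coords[:, group_a, :] - center, axis=-1
    ).ravel()
    rb = np.linalg.norm(
        traj.coords[:, group_b, :] - center, axis=-1
    ).ravel()
    r_max = max(ra.max(), rb.max()) + bin_width
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    pa, _ = np.histogram(ra, bins=edges, density=True)
    pb, _ = np.histogram(rb, bins=edges, density=True)
    return float(np.minimum(pa, pb).sum() * bin_width)


# ----------------------------------------------------------------------
# parallel orientation
# ----------------------------------------------------------------------

def plane_axis_angle(plane_points: np.ndarray, axis_points: np.ndarray) -> float:
    """Angle (degrees) between a best-fit plane and a principal axis.

    0° when the axis lies in the plane, 90° when it is along the normal.
    """
    p = np.asarray(plane_points, float)
    if len(p) < 3:
        raise ValueError("plane needs at least 3 atoms")
    pc = p - p.mean(axis=0)
    _, sv, vt = np.linalg.svd(pc)
    if sv[1] < 1e-9 * max(sv[0], 1.0):
        raise ValueError("plane atoms are collinear")
    normal = vt[2]
    a = np.asarray(axis_points, float)
    ac = a - a.mean(axis=0)
    _, _, avt = np.linalg.svd(ac)
    axis = avt[0]
    s = abs(float(normal @ axis))
    return float(np.degrees(np.arcsin(np.clip(s, 0.0, 1.0))))


@dataclass
class OrientationDistribution:
    angles: np.ndarray        # pooled per-(bound analyte, frame) angles, deg
    median: float
    hist: np.ndarray
    bin_edges: np.ndarray


def parallel_orientation(traj: Trajectory, topology: Topology,
                         model, contact_cutoff: float = C.CONTACT_CUTOFF,
                         n_bins: int = 18) -> OrientationDistribution:
    """Ring-plane vs nearest-ligand-backbone angle of bound analytes.

    For every frame and every analyte within ``contact_cutoff`` of the
    monolayer, computes the angle between the analyte's aromatic best-fit
    plane and the principal axis of the nearest ligand's heavy-atom
    backbone; 0° means the ring plane contains the chain axis (parallel
    packing).
    """
    analyte_mols = topology.molecules_of_kind("analyte")
    if not analyte_mols:
        raise ValueError("no analytes in topology")
    heavy = topology.is_heavy()
    mono_sel = topology.select(kind="ligand", heavy=True)
    ligand_mols = topology.molecules_of_kind("ligand")
    angles = []
    for f in range(traj.n_frames):
        frame = traj.coords[f]
        for mol in analyte_mols:
            ring = [
                i for i in mol
                if topology.flags.get(int(i)) == "aromatic_carbon"
            ]
            if len(ring) < 3:
                continue
            a_heavy = mol[heavy[mol]]
            d = _pair_distances(frame[a_heavy], frame[mono_sel])
            if d.min() >= contact_cutoff:
                continue
            # nearest ligand = the one owning the closest monolayer atom
            closest_atom = mono_sel[np.unravel_index(np.argmin(d), d.shape)[1]]
            lig_mol = next(
                lm for lm in ligand_mols if closest_atom in lm
            )
            lig_heavy = lig_mol[heavy[lig_mol]]
            angles.append(
                plane_axis_angle(frame[ring], frame[lig_heavy])
            )
    angles = np.array(angles)
    if len(angles) == 0:
        return OrientationDistribution(
            angles=angles, median=float("nan"),
            hist=np.zeros(n_bins), bin_edges=np.linspace(0, 90, n_bins + 1),
        )
    hist, edges = np.histogram(angles, bins=n_bins, range=(0.0, 90.0))
    return OrientationDistribution(
        angles=angles, median=float(np.median(angles)),
        hist=hist, bin_edges=edges,
    )
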