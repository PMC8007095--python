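"""Monolayer morphology: directors, bundles, free chains, shell shape.

A ligand's *director* is the unit vector from its sulfur anchor to its
terminal heavy atom.  Bundles are detected on a graph whose nodes are
ligands and whose edges require both director alignment (angle below a
cutoff) and spatial proximity (minimum inter-chain heavy-atom distance
below a cutoff); connected components of at least ``min_size`` chains are
bundles, smaller components are free chains.  Shell shape is summarized by
the gyration tensor of the monolayer heavy atoms: eigenvalues
λ1 ≥ λ2 ≥ λ3, asphericity b = λ1 − (λ2+λ3)/2, acylindricity c = λ2 − λ3,
and relative shape anisotropy κ² = (b² + ¾c²) / (λ1+λ2+λ3)².
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from . import constants as C
from .model_builder import NanoparticleModel
from .trajectory import Trajectory


@dataclass
class BundleAssignment:
    """Per-frame partition of ligands into bundles and free chains."""

    labels: np.ndarray        # (n_frames, n_ligands); bundle id or -1 = free
    n_bundles: np.ndarray     # (n_frames,)
    n_free: np.ndarray        # (n_frames,)

    @property
    def n_frames(self) -> int:
        return len(self.n_bundles)

    def mean_bundles(self) -> tuple[float, float]:
        """Ensemble mean bundle count with block-averaged standard error."""
        return block_mean_se(self.n_bundles.astype(float))

    def mean_free(self) -> tuple[float, float]:
        return block_mean_se(self.n_free.astype(float))


@dataclass
class ShellShape:
    """Gyration-tensor shape descriptors of the monolayer shell (Å², Å)."""

    eigenvalues: np.ndarray   # λ1 ≥ λ2 ≥ λ3, Å²
    rg: float                 # radius of gyration, Å
    asphericity: float        # b, Å²
    acylindricity: float      # c, Å²
    kappa2: float             # relative shape anisotropy, dimensionless


def block_mean_se(x: np.ndarray, n_blocks: int = 5) -> tuple[float, float]:
    """Mean and block-averaged standard error of a per-frame series."""
    x = np.asarray(x, float)
    mean = float(x.mean())
    if len(x) < n_blocks:
        return mean, float("nan")
    blocks = np.array_split(x, n_blocks)
    bm = np.array([b.mean() for b in blocks])
    se = float(bm.std(ddof=1) / np.sqrt(n_blocks))
    return mean, se


# ----------------------------------------------------------------------
# directors
# ----------------------------------------------------------------------

def ligand_directors(frame: np.ndarray, model: NanoparticleModel) -> np.ndarray:
    """Unit vectors sulfur → terminal heavy atom for every ligand in ``frame``.

    ``frame`` must hold all model atoms in build order (core first).
    """
    out = np.empty((len(model.ligands), 3))
    for i, lig in enumerate(model.ligands):
        off = model.ligand_atom_offset(i)
        s = frame[off + lig.template.anchor_index]
        t = frame[off + lig.template.terminal_index]
        v = t - s
        n = np.linalg.norm(v)
        if n < 1e-9:
            raise ValueError(
                f"ligand {i}: sulfur and terminal atom coincide; "
                "director undefined"
            )
        out[i] = v / n
    return out


# ----------------------------------------------------------------------
# bundle detection
# ----------------------------------------------------------------------

def _chain_heavy_coords(frame: np.ndarray,
                        model: NanoparticleModel) -> list[np.ndarray]:
    coords = []
    for i, lig in enumerate(model.ligands):
        off = model.ligand_atom_offset(i)
        heavy = lig.template.heavy_indices()
        coords.append(frame[off + heavy])
    return coords


def detect_bundles_frame(directors: np.ndarray,
                         chain_coords: list[np.ndarray],
                         angle_cutoff: float = C.BUNDLE_ANGLE_CUTOFF,
                         distance_cutoff: float = C.BUNDLE_DISTANCE_CUTOFF,
                         min_size: int = C.BUNDLE_MIN_SIZE) -> np.ndarray:
    """Bundle labels for one frame; -1 marks free chains.

    Edge rule: director angle ≤ ``angle_cutoff`` degrees AND minimum
    heavy-atom distance between the two chains ≤ ``distance_cutoff`` Å.
    Bundle ids are assigned in order of each component's lowest ligand
    index, which makes the labelling invariant under relabeling up to
    permutation and deterministic.
    """
    if angle_cutoff <= 0 or distance_cutoff <= 0:
        raise ValueError("cutoffs must be positive")
    n = len(directors)
    cos_cut = np.cos(np.radians(angle_cutoff))
    g = nx.Graph()
    g.add_nodes_from(range(n))
    trees = [cKDTree(c) for c in chain_coords]
    for i in range(n):
        for j in range(i + 1, n):
            if float(directors[i] @ directors[j]) < cos_cut - 1e-12:
                continue
            dmin = trees[i].query(chain_coords[j])[0].min()
            if dmin <= distance_cutoff:
                g.add_edge(i, j)
    labels = np.full(n, -1, int)
    components = sorted(
        (sorted(comp) for comp in nx.connected_components(g)),
        key=lambda comp: comp[0],
    )
    next_id = 0
    for comp in components:
        if len(comp) >= min_size:
            labels[comp] = next_id
            next_id += 1
    return labels


def detect_bundles(traj: Trajectory, model: NanoparticleModel,
                   angle_cutoff: float = C.BUNDLE_ANGLE_CUTOFF,
                   distance_cutoff: float = C.BUNDLE_DISTANCE_CUTOFF,
                   min_size: int = C.BUNDLE_MIN_SIZE) -> BundleAssignment:
    """Detect bundles in every frame of ``traj``."""
    n_lig = len(model.ligands)
    labels = np.empty((traj.n_frames, n_lig), int)
    for f in range(traj.n_frames):
        frame = traj.coords[f]
        dirs = ligand_directors(frame, model)
        chains = _chain_heavy_coords(frame, model)
        labels[f] = detect_bundles_frame(
            dirs, chains, angle_cutoff, distance_cutoff, min_size
        )
    n_bundles = np.array([len(set(l[l >= 0])) for l in labels])
    n_free = np.array([(l < 0).sum() for l in labels])
    return BundleAssignment(labels=labels, n_bundles=n_bundles, n_free=n_free)


# ----------------------------------------------------------------------
# shell shape
# ----------------------------------------------------------------------

def shell_shape(coords: np.ndarray) -> ShellShape:
    """Gyration-tensor shape descriptors of a point selection.

    Requires at least 3 non-collinear points; all descriptors are about
    the selection centroid and invariant under rigid motion.
    """
    coords = np.asarray(coords, float)
    if len(coords) < 3:
        raise ValueError("shell_shape needs at least 3 atoms")
    centered = coords - coords.mean(axis=0)
    s = centered.T @ centered / len(centered)
    lam = np.sort(np.linalg.eigvalsh(s))[::-1]
    if lam[1] < 1e-12 * max(lam[0], 1.0):
        raise ValueError("selection is collinear; shape undefined")
    b = lam[0] - 0.5 * (lam[1] + lam[2])
    c = lam[1] - lam[2]
    tr = lam.sum()
    kappa2 = (b * b + 0.75 * c * c) / (tr * tr) if tr > 0 else 0.0
    return ShellShape(
        eigenvalues=lam,
        rg=float(np.sqrt(tr)),
        asphericity=float(b),
        acylindricity=float(c),
        kappa2=float(kappa2),
    )


def shell_shape_series(traj: Trajectory, selection: np.ndarray) -> list[ShellShape]:
    """Shell shape of ``selection`` in every frame."""
    return [shell_shape(traj.coords[f][selection]) for f in range(traj.n_frames)]


# ----------------------------------------------------------------------
# paired bundle-count change
# ----------------------------------------------------------------------

@dataclass
class BundleCountChange:
    mean_first: float
    mean_second: float
    delta: float                  # mean_first - mean_second
    ci_low: float
    ci_high: float
    degenerate: bool              # single-frame inputs: CI is a point


def bundle_count_change(traj_first: Trajectory, traj_second: Trajectory,
                        model: NanoparticleModel,
                        angle_cutoff: float = C.BUNDLE_ANGLE_CUTOFF,
                        distance_cutoff: float = C.BUNDLE_DISTANCE_CUTOFF,
                        min_size: int = C.BUNDLE_MIN_SIZE,
                        n_boot: int = 10_000, seed: int = 0,
                        ci_level: float = 0.95) -> BundleCountChange:
    """Change in mean bundle count between two trajectories.

    Both trajectories are analyzed with identical cutoffs; the difference
    (first − second, e.g. unbound − bound) gets a seeded bootstrap
    percentile confidence interval over frames.  Single-frame inputs
    degenerate to a point estimate and are flagged.
    """
    n_lig = len(model.ligands)
    if traj_first.n_atoms < n_lig or traj_second.n_atoms < n_lig:
        raise ValueError("trajectory does not contain all model ligand atoms")
    a = detect_bundles(traj_first, model, angle_cutoff, distance_cutoff, min_size)
    b = detect_bundles(traj_second, model, angle_cutoff, distance_cutoff, min_size)
    xa = a.n_bundles.astype(float)
    xb = b.n_bundles.astype(float)
    delta = float(xa.mean() - xb.mean())
    degenerate = len(xa) < 2 or len(xb) < 2
    if degenerate:
        lo = hi = delta
    else:
        rng = np.random.default_rng(seed)
        boots = np.empty(n_boot)
        for k in range(n_boot):
            boots[k] = (
                xa[rng.integers(len(xa), size=len(xa))].mean()
                - xb[rng.integers(len(xb), size=len(xb))].mean()
            )
        alpha = (1.0 - ci_level) / 2.0
        lo, hi = np.quantile(boots, [alpha, 1.0 - alpha])
    return BundleCountChange(
        mean_first=float(xa.mean()), mean_second=float(xb.mean()),
        delta=delta, ci_low=float(lo), ci_high=float(hi),
        degenerate=degenerate,
    )
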