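"""Interfacial hydration maps on spherical probe surfaces.

For a probe sphere centered on the gold core at a chosen distance from the
gold surface, each (φ, cos θ) cell records how often the atom radially
closest to the probe surface *within that cell's angular footprint* is a
water oxygen (indicator 1) rather than a thiol carbon (indicator 0),
averaged over frames.  Cells that never receive a candidate atom are
undefined, not zero.  The equal-area grid is uniform in φ and cos θ
(default 72 × 36, i.e. 5° azimuthal resolution).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import spherical_angles
from .model_builder import NanoparticleModel
from .topology import Topology
from .trajectory import Trajectory


@dataclass
class HydrationMap:
    """Water-closest fraction per (φ, cos θ) cell at one probe distance."""

    probe_distance: float     # Å from the gold surface
    probe_radius: float       # Å from the core center
    values: np.ndarray        # (n_phi, n_costheta); NaN = undefined cell
    frames_counted: np.ndarray  # (n_phi, n_costheta) int

    @property
    def n_phi(self) -> int:
        return self.values.shape[0]

    @property
    def n_costheta(self) -> int:
        return self.values.shape[1]

    def defined(self) -> np.ndarray:
        return ~np.isnan(self.values)

    def defined_values(self) -> np.ndarray:
        return self.values[self.defined()]


def _candidate_sets(topology: Topology):
    water_o = topology.select(kind="water")
    water_o = np.array(
        [i for i in water_o if topology.elements[i].upper() == "O"], int
    )
    thiol_c = np.array(
        [
            i
            for i in topology.select(kind="ligand")
            if topology.elements[i].upper() == "C"
        ],
        int,
    )
    return water_o, thiol_c


def hydration_map(traj: Trajectory, model: NanoparticleModel,
                  probe_distance: float, n_phi: int = 72,
                  n_costheta: int = 36,
                  topology: Topology | None = None,
                  radial_window: float = 5.0) -> HydrationMap:
    """Closest-atom (water O vs thiol C) indicator map at one probe distance.

    Per frame and per cell, among the water oxygens and thiol carbons whose
    (φ, cos θ) falls in the cell, the atom minimizing
    |radial distance − probe radius| is selected; the cell accumulates 1
    for a water oxygen and 0 for a thiol carbon.  The probe radius is the
    mean radial position of surface gold atoms plus ``probe_distance``.
    Only atoms within ``radial_window`` Å of the probe radius are
    candidates, which keeps the map local: atoms far from the probe shell
    can never populate (or alter) a cell.
    """
    topology = topology or traj.topology
    if topology is None:
        raise ValueError("a topology is required to classify atoms")
    probe_radius = model.core.surface_radius() + probe_distance
    if probe_radius <= 0:
        raise ValueError("probe radius must be positive")
    water_o, thiol_c = _candidate_sets(topology)
    if len(water_o) == 0 and len(thiol_c) == 0:
        raise ValueError(
            "no water oxygens or thiol carbons found; check the topology "
            "selections"
        )
    candidates = np.concatenate([water_o, thiol_c])
    is_water = np.concatenate(
        [np.ones(len(water_o), bool), np.zeros(len(thiol_c), bool)]
    )
    center = model.core.center

    acc = np.zeros((n_phi, n_costheta))
    cnt = np.zeros((n_phi, n_costheta), int)
    for f in range(traj.n_frames):
        pos = traj.coords[f][candidates]
        r, phi, cos_t = spherical_angles(pos, center)
        in_window = np.abs(r - probe_radius) <= radial_window
        r, phi, cos_t = r[in_window], phi[in_window], cos_t[in_window]
        frame_is_water = is_water[in_window]
        i_phi = np.clip(
            ((phi + np.pi) / (2.0 * np.pi) * n_phi).astype(int), 0, n_phi - 1
        )
        i_ct = np.clip(
            ((cos_t + 1.0) / 2.0 * n_costheta).astype(int), 0, n_costheta - 1
        )
        score = np.abs(r - probe_radius)
        flat = i_phi * n_costheta + i_ct
        # per-cell argmin of |r - probe_radius|; ties broken deterministically
        # by candidate order (water oxygens first)
        order = np.lexsort((np.arange(len(flat)), score))
        cell_of = flat[order]
        first = np.full(n_phi * n_costheta, -1, int)
        seen = np.zeros(n_phi * n_costheta, bool)
        for idx, cell in zip(order, cell_of):
            if not seen[cell]:
                seen[cell] = True
                first[cell] = idx
        hit = np.flatnonzero(seen)
        ip, ic = hit // n_costheta, hit % n_costheta
        acc[ip, ic] += frame_is_water[first[hit]].astype(float)
        cnt[ip, ic] += 1

    values = np.full((n_phi, n_costheta), np.nan)
    mask = cnt > 0
    values[mask] = acc[mask] / cnt[mask]
    if not mask.any():
        raise ValueError(
            "no cell received a candidate atom at this probe distance; "
            "check the selections and probe distance"
        )
    return HydrationMap(
        probe_distance=float(probe_distance),
        probe_radius=float(probe_radius),
        values=values, frames_counted=cnt,
    )


def map_series(traj: Trajectory, model: NanoparticleModel,
               distances: list[float], n_phi: int = 72, n_costheta: int = 36,
               topology: Topology | None = None) -> list[HydrationMap]:
    """One hydration map per probe distance (shared grid)."""
    if list(distances) != sorted(distances):
        raise ValueError("distances must be sorted ascending")
    return [
        hydration_map(traj, model, d, n_phi, n_costheta, topology)
        for d in distances
    ]


def heterogeneity(hmap: HydrationMap) -> tuple[float, float]:
    """(fraction of defined cells below 0.5, std of defined cells)."""
    vals = hmap.defined_values()
    if len(vals) == 0:
        raise ValueError("all cells undefined; no heterogeneity statistic")
    return float((vals < 0.5).mean()), float(vals.std())


def plot_map_panels(maps: list[HydrationMap], path: str) -> None:
    """Panel figure of hydration maps (φ on x, cos θ on y), one per distance."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(maps)
    ncols = min(n, 2)
    nrows = (n + ncols - 1) // ncols
    fig, axes = plt.subplots(
        nrows, ncols, figsize=(5.0 * ncols, 3.2 * nrows), squeeze=False
    )
    for k, hmap in enumerate(maps):
        ax = axes[k // ncols][k % ncols]
        im = ax.imshow(
            hmap.values.T, origin="lower", aspect="auto",
            extent=[-180, 180, -1, 1], vmin=0, vmax=1, cmap="RdBu",
        )
        ax.set_xlabel("azimuthal angle φ (deg)")
        ax.set_ylabel("cos θ")
        ax.set_title(f"probe {hmap.probe_distance:g} Å")
        fig.colorbar(im, ax=ax, label="water-closest fraction")
    for k in range(n, nrows * ncols):
        axes[k // ncols][k % ncols].axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
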