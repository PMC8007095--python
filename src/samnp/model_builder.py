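"""Rule-based construction of SAM-protected gold nanoparticle systems.

The build follows explicit geometric rules: an icosahedral (Mackay) gold
cluster carved to the requested atom count, Au-Au bonds at a 2.90 Å cutoff,
thiolate sulfurs spread uniformly over the surface by electrostatic-repulsion
(Thomson-style) minimization and tied to distinct surface gold atoms within
3.3 Å, ligands grafted radially in the all-trans conformation, and a solvated
box with analytes, jittered-lattice water and neutralizing counterions.  All
Au-Au and Au-S bonds are harmonic restraints with a single spring constant
(50000 kJ mol⁻¹ nm⁻² by default).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment, minimize
from scipy.spatial import cKDTree

from . import constants as C
from .geometry import random_rotation, rotation_between, unit
from .templates import _LJ, MoleculeTemplate
from .topology import Topology, TopologyBuilder


class CapacityError(ValueError):
    """Requested cluster size exceeds the supported icosahedral lattice."""


class PlacementError(RuntimeError):
    """A geometric placement could not be satisfied."""


class BuildError(RuntimeError):
    """Model assembly failed after deterministic recovery attempts."""


# ----------------------------------------------------------------------
# gold core
# ----------------------------------------------------------------------

@dataclass
class GoldCore:
    """Icosahedral gold cluster: positions (Å), Au-Au bond pairs, center."""

    positions: np.ndarray
    bond_pairs: list[tuple[int, int]]
    center: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, float)
        self.center = np.asarray(self.center, float)

    @property
    def n_atoms(self) -> int:
        return len(self.positions)

    def surface_indices(self) -> np.ndarray:
        """Atoms with fewer than 12 lattice neighbours (the cluster surface)."""
        counts = np.zeros(self.n_atoms, int)
        for i, j in self.bond_pairs:
            counts[i] += 1
            counts[j] += 1
        return np.flatnonzero(counts < 12)

    def surface_radius(self) -> float:
        """Mean radial distance of surface atoms from the center."""
        surf = self.surface_indices()
        return float(
            np.linalg.norm(self.positions[surf] - self.center, axis=1).mean()
        )


_MAX_SHELLS = 8  # 2869 atoms; plenty beyond the 144-atom default


def _icosahedron_vertices() -> np.ndarray:
    """12 vertices of a regular icosahedron scaled to edge length 1."""
    phi = (1.0 + math.sqrt(5.0)) / 2.0
    raw = []
    for a in (-1.0, 1.0):
        for b in (-phi, phi):
            raw.append([0.0, a, b])
            raw.append([a, b, 0.0])
            raw.append([b, 0.0, a])
    v = np.array(raw) / 2.0  # edge length = 1
    return v


def _icosahedron_faces(vertices: np.ndarray) -> list[tuple[int, int, int]]:
    """The 20 triangular faces, found as nearest-neighbour triples."""
    n = len(vertices)
    d = np.linalg.norm(vertices[:, None] - vertices[None, :], axis=-1)
    edge = d[d > 1e-9].min()
    adj = (d < edge * 1.01) & (d > 1e-9)
    faces = []
    for i in range(n):
        for j in range(i + 1, n):
            if not adj[i, j]:
                continue
            for k in range(j + 1, n):
                if adj[i, k] and adj[j, k]:
                    faces.append((i, j, k))
    assert len(faces) == 20
    return faces


def mackay_cluster(n_shells: int, spacing: float = C.AU_NN_SPACING) -> np.ndarray:
    """All lattice points of an ``n_shells``-shell Mackay icosahedron.

    Shell ``s`` carries 10 s² + 2 points; nearest neighbours along the
    icosahedron edges are ``spacing`` apart.
    """
    verts = _icosahedron_vertices() * spacing
    faces = _icosahedron_faces(verts)
    points = {(0.0, 0.0, 0.0)}
    for s in range(1, n_shells + 1):
        for (i, j, k) in faces:
            for a in range(s + 1):
                for b in range(s + 1 - a):
                    c = s - a - b
                    p = (a * verts[i] + b * verts[j] + c * verts[k])
                    points.add(tuple(np.round(p, 6)))
    return np.array(sorted(points))


def build_gold_core(n_atoms: int, seed: int = 0,
                    spacing: float = C.AU_NN_SPACING,
                    bond_cutoff: float = C.AU_AU_BOND_CUTOFF) -> GoldCore:
    """Carve an ``n_atoms`` icosahedral gold cluster from the Mackay lattice.

    The atoms closest to the lattice centroid are kept (ties broken by
    lexicographic coordinate order), the result is re-centered on its
    centroid, and the Au-Au bond network is populated at ``bond_cutoff``.
    Deterministic; ``seed`` is accepted for interface uniformity.
    """
    if n_atoms < 1:
        raise ValueError("n_atoms must be positive")
    n_shells = 0
    while 1 + sum(10 * s * s + 2 for s in range(1, n_shells + 1)) < n_atoms:
        n_shells += 1
        if n_shells > _MAX_SHELLS:
            cap = 1 + sum(10 * s * s + 2 for s in range(1, _MAX_SHELLS + 1))
            raise CapacityError(
                f"n_atoms={n_atoms} exceeds the supported lattice "
                f"({_MAX_SHELLS} shells, {cap} atoms)"
            )
    lattice = mackay_cluster(n_shells, spacing)
    dist = np.linalg.norm(lattice, axis=1)
    order = np.lexsort(
        (lattice[:, 2], lattice[:, 1], lattice[:, 0], np.round(dist, 6))
    )
    kept = lattice[order[:n_atoms]]
    kept = kept - kept.mean(axis=0)
    pairs = bond_network(kept, bond_cutoff)
    return GoldCore(positions=kept, bond_pairs=pairs, center=np.zeros(3))


def bond_network(positions: np.ndarray, cutoff: float) -> list[tuple[int, int]]:
    """All index pairs at Euclidean distance ≤ cutoff, lower index first."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    positions = np.asarray(positions, float)
    if len(positions) < 2:
        return []
    tree = cKDTree(positions)
    pairs = tree.query_pairs(r=cutoff, output_type="ndarray")
    return sorted((int(min(i, j)), int(max(i, j))) for i, j in pairs)


# ----------------------------------------------------------------------
# anchor placement (Thomson-style repulsion minimization)
# ----------------------------------------------------------------------

def thomson_points(n: int, seed: int, n_restarts: int = 3,
                   maxiter: int = 3000) -> np.ndarray:
    """``n`` unit vectors minimizing the 1/r Coulomb energy on the sphere.

    L-BFGS on free 3n coordinates with the energy evaluated on normalized
    points; several seeded restarts, lowest energy kept.  Deterministic per
    seed.
    """
    if n < 1:
        raise ValueError("need at least one point")
    if n == 1:
        return np.array([[0.0, 0.0, 1.0]])

    def energy_grad(x: np.ndarray):
        p = x.reshape(n, 3)
        norms = np.linalg.norm(p, axis=1, keepdims=True)
        u = p / norms
        diff = u[:, None, :] - u[None, :, :]
        d = np.linalg.norm(diff, axis=-1)
        np.fill_diagonal(d, np.inf)
        e = 0.5 * (1.0 / d).sum()
        g_u = -(diff / d[:, :, None] ** 3).sum(axis=1)
        # project through the normalization u = p/|p|
        g = (g_u - (g_u * u).sum(axis=1, keepdims=True) * u) / norms
        return e, g.ravel()

    best_e, best = np.inf, None
    for child in np.random.SeedSequence(seed).spawn(n_restarts):
        rng = np.random.default_rng(child)
        x0 = rng.normal(size=(n, 3))
        x0 /= np.linalg.norm(x0, axis=1, keepdims=True)
        res = minimize(
            energy_grad, x0.ravel(), jac=True, method="L-BFGS-B",
            options={"maxiter": maxiter, "ftol": 1e-15, "gtol": 1e-10},
        )
        if res.fun < best_e:
            best_e, best = res.fun, res.x
    return unit(best.reshape(n, 3))


@dataclass
class AnchorSet:
    """Relaxed sulfur anchor sites matched to distinct surface gold atoms."""

    positions: np.ndarray    # (n, 3) sulfur coordinates, Å
    gold_indices: np.ndarray  # (n,) matched gold atom per anchor
    directions: np.ndarray   # (n, 3) outward unit vectors

    @property
    def n(self) -> int:
        return len(self.positions)


def place_anchors(core: GoldCore, n_ligands: int, seed: int = 0,
                  s_au_cutoff: float = C.AU_S_BOND_CUTOFF,
                  bond_length: float = C.AU_S_BOND_LENGTH) -> AnchorSet:
    """Spread ``n_ligands`` sulfur sites uniformly over the core surface.

    Directions come from Thomson-style repulsion minimization on the sphere;
    each is then assigned a distinct surface gold atom by optimal one-to-one
    matching on angular separation, and the sulfur is placed ``bond_length``
    beyond that gold's radial distance along its relaxed direction.
    """
    surface = core.surface_indices()
    if n_ligands > len(surface):
        raise PlacementError(
            f"{n_ligands} ligands requested but only {len(surface)} "
            "surface gold atoms available"
        )
    dirs = thomson_points(n_ligands, seed)
    gold_pos = core.positions[surface] - core.center
    gold_dirs = unit(gold_pos)
    cost = -(dirs @ gold_dirs.T)  # maximize alignment
    rows, cols = linear_sum_assignment(cost)
    gold_idx = np.empty(n_ligands, int)
    positions = np.empty((n_ligands, 3))
    for i, jcol in zip(rows, cols):
        g_global = surface[jcol]
        r_g = np.linalg.norm(gold_pos[jcol])
        pos = core.center + dirs[i] * (r_g + bond_length)
        d = np.linalg.norm(pos - core.positions[g_global])
        if d > s_au_cutoff:
            raise PlacementError(
                f"anchor {i} at direction {np.round(dirs[i], 3)} has no gold "
                f"within {s_au_cutoff} Å (closest match {d:.2f} Å)"
            )
        gold_idx[i] = g_global
        positions[i] = pos
    return AnchorSet(positions=positions, gold_indices=gold_idx, directions=dirs)


# ----------------------------------------------------------------------
# ligand grafting
# ----------------------------------------------------------------------

@dataclass
class PlacedLigand:
    template: MoleculeTemplate
    coords: np.ndarray       # (n_atoms, 3) Å
    anchor_gold: int         # core atom index of the bonded gold
    direction: np.ndarray    # outward unit vector at build time


@dataclass
class NanoparticleModel:
    """Assembled SAM-AuNP: core, grafted ligands, harmonic bond network."""

    core: GoldCore
    ligands: list[PlacedLigand]
    spring_k: float = C.SPRING_K_KJ_MOL_NM2
    au_s_bonds: list[tuple[int, int, float]] = field(default_factory=list)
    au_au_bonds: list[tuple[int, int, float]] = field(default_factory=list)

    @property
    def n_atoms(self) -> int:
        return self.core.n_atoms + sum(l.template.n_atoms for l in self.ligands)

    def ligand_atom_offset(self, i: int) -> int:
        """Global index of the first atom of ligand ``i``."""
        off = self.core.n_atoms
        for l in self.ligands[:i]:
            off += l.template.n_atoms
        return off

    def positions(self) -> np.ndarray:
        parts = [self.core.positions] + [l.coords for l in self.ligands]
        return np.vstack(parts) if parts else np.empty((0, 3))

    def elements(self) -> list[str]:
        out = ["AU"] * self.core.n_atoms
        for l in self.ligands:
            out.extend(l.template.elements)
        return out

    def formal_charge(self) -> int:
        return sum(l.template.formal_charge for l in self.ligands)

    def topology(self) -> Topology:
        tb = TopologyBuilder()
        sig_au, eps_au = _LJ["AU"]
        n_au = self.core.n_atoms
        tb.add_molecule(
            "core", ["AU"] * n_au, [0.0] * n_au, [sig_au] * n_au,
            [eps_au] * n_au, bonds=list(self.core.bond_pairs),
        )
        for l in self.ligands:
            t = l.template
            tb.add_molecule(
                "ligand", t.elements, [a.charge for a in t.atoms],
                [a.sigma for a in t.atoms], [a.epsilon for a in t.atoms],
                flags=t.group_flags, bonds=[(i, j) for i, j, _ in t.bonds],
            )
        return tb.build()

    def to_json(self, path) -> None:
        """Serialize the full model (core, ligand placements, bonds)."""
        import json
        from pathlib import Path

        payload = {
            "spring_k": self.spring_k,
            "core": {
                "positions": self.core.positions.tolist(),
                "bond_pairs": [[int(i), int(j)] for i, j in self.core.bond_pairs],
                "center": self.core.center.tolist(),
            },
            "ligands": [
                {
                    "template": l.template.to_dict(),
                    "coords": l.coords.tolist(),
                    "anchor_gold": int(l.anchor_gold),
                    "direction": l.direction.tolist(),
                }
                for l in self.ligands
            ],
            "au_s_bonds": [[int(a), int(b), float(k)] for a, b, k in self.au_s_bonds],
            "au_au_bonds": [[int(a), int(b), float(k)] for a, b, k in self.au_au_bonds],
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path) -> "NanoparticleModel":
        import json
        from pathlib import Path

        from .templates import MoleculeTemplate

        d = json.loads(Path(path).read_text())
        core = GoldCore(
            positions=np.array(d["core"]["positions"]),
            bond_pairs=[(int(i), int(j)) for i, j in d["core"]["bond_pairs"]],
            center=np.array(d["core"]["center"]),
        )
        ligands = [
            PlacedLigand(
                template=MoleculeTemplate.from_dict(l["template"]),
                coords=np.array(l["coords"]),
                anchor_gold=int(l["anchor_gold"]),
                direction=np.array(l["direction"]),
            )
            for l in d["ligands"]
        ]
        model = cls(core=core, ligands=ligands, spring_k=float(d["spring_k"]))
        model.au_s_bonds = [(int(a), int(b), float(k)) for a, b, k in d["au_s_bonds"]]
        model.au_au_bonds = [(int(a), int(b), float(k)) for a, b, k in d["au_au_bonds"]]
        return model

    def validate(self) -> None:
        """Raise if any structural invariant is violated."""
        pos = self.positions()
        for s_idx, g_idx, k in self.au_s_bonds:
            d = np.linalg.norm(pos[s_idx] - self.core.positions[g_idx])
            if d > C.AU_S_BOND_CUTOFF + 1e-9:
                raise BuildError(f"Au-S bond {s_idx}-{g_idx} too long: {d:.3f} Å")
            if k != self.spring_k:
                raise BuildError("inconsistent Au-S spring constant")
        for i, j, k in self.au_au_bonds:
            d = np.linalg.norm(self.core.positions[i] - self.core.positions[j])
            if d > C.AU_AU_BOND_CUTOFF + 1e-9:
                raise BuildError(f"Au-Au bond {i}-{j} too long: {d:.3f} Å")
        sulfur_bonds: dict[int, int] = {}
        for s_idx, _, _ in self.au_s_bonds:
            sulfur_bonds[s_idx] = sulfur_bonds.get(s_idx, 0) + 1
        for i, l in enumerate(self.ligands):
            s_global = self.ligand_atom_offset(i) + l.template.anchor_index
            if sulfur_bonds.get(s_global, 0) != 1:
                raise BuildError(f"ligand {i}: sulfur must have exactly one Au-S bond")


def graft_ligands(core: GoldCore, template: MoleculeTemplate,
                  anchors: AnchorSet,
                  spring_k: float = C.SPRING_K_KJ_MOL_NM2,
                  clash_distance: float = C.CLASH_DISTANCE) -> NanoparticleModel:
    """Graft one ligand per anchor, all-trans, along the outward radial axis.

    Inter-ligand heavy-atom clashes below ``clash_distance`` trigger a
    deterministic torsional back-off (15° spins of the later chain about its
    own axis); if no rotation resolves the clash the build fails.
    """
    if template.kind != "ligand":
        raise ValueError(f"template {template.name} is not a ligand")
    ref = template.coords - template.coords[template.anchor_index]
    heavy_local = template.heavy_indices()

    def _frame(i: int) -> np.ndarray:
        """Rotation taking the template frame onto the anchor frame.

        The chain axis goes to the outward direction; the azimuth is fixed
        by the nearest neighbouring anchor direction, which makes the
        whole build equivariant under rigid rotation of core + anchors.
        """
        u = anchors.directions[i]
        if anchors.n == 1:
            return rotation_between(np.array([0.0, 0.0, 1.0]), u)
        dots = anchors.directions @ u
        dots[i] = -np.inf
        v = anchors.directions[int(np.argmax(dots))]
        x_axis = v - (v @ u) * u
        norm = np.linalg.norm(x_axis)
        if norm < 1e-9:  # neighbour antipodal/parallel: fall back
            return rotation_between(np.array([0.0, 0.0, 1.0]), u)
        x_axis = x_axis / norm
        y_axis = np.cross(u, x_axis)
        return np.column_stack([x_axis, y_axis, u])

    placed: list[PlacedLigand] = []
    placed_heavy: list[np.ndarray] = []
    for i in range(anchors.n):
        u = anchors.directions[i]
        rot = _frame(i)
        coords = anchors.positions[i] + ref @ rot.T
        if placed_heavy:
            others = np.vstack(placed_heavy)
            tree = cKDTree(others)
            best = coords
            ok = False
            for step in range(24):
                if step:
                    spin = rot @ _spin_z(math.radians(15.0 * step))
                    cand = anchors.positions[i] + ref @ spin.T
                else:
                    cand = coords
                dmin = tree.query(cand[heavy_local])[0].min()
                if dmin >= clash_distance:
                    best, ok = cand, True
                    if step:
                        warnings.warn(
                            f"ligand {i}: clash resolved by {15 * step}° "
                            "torsional back-off",
                            stacklevel=2,
                        )
                    break
            if not ok:
                raise BuildError(
                    f"ligand {i}: heavy-atom clash below {clash_distance} Å "
                    "persists after torsional back-off"
                )
            coords = best
        placed.append(
            PlacedLigand(
                template=template, coords=coords,
                anchor_gold=int(anchors.gold_indices[i]), direction=u.copy(),
            )
        )
        placed_heavy.append(coords[heavy_local])

    model = NanoparticleModel(core=core, ligands=placed, spring_k=spring_k)
    model.au_au_bonds = [(i, j, spring_k) for i, j in core.bond_pairs]
    for i, l in enumerate(placed):
        s_global = model.ligand_atom_offset(i) + template.anchor_index
        model.au_s_bonds.append((s_global, l.anchor_gold, spring_k))
    model.validate()
    return model


def _spin_z(angle: float) -> np.ndarray:
    c, s = math.cos(angle), math.sin(angle)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


# ----------------------------------------------------------------------
# solvated simulation system
# ----------------------------------------------------------------------

_WATER_CHARGES = (-0.834, 0.417, 0.417)   # TIP3P-like
_WATER_SIGMA = (3.1507, 1.069, 1.069)
_WATER_EPS = (0.1521, 0.0, 0.0)


def water_molecule(o_pos: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Rigid 3-site water (O, H, H) at ``o_pos`` with random orientation."""
    half = math.radians(C.WATER_HOH_ANGLE) / 2.0
    local = np.array(
        [
            [0.0, 0.0, 0.0],
            [C.WATER_OH_LENGTH * math.sin(half), 0.0, C.WATER_OH_LENGTH * math.cos(half)],
            [-C.WATER_OH_LENGTH * math.sin(half), 0.0, C.WATER_OH_LENGTH * math.cos(half)],
        ]
    )
    rot = random_rotation(rng)
    return o_pos + local @ rot.T


@dataclass
class SimulationSystem:
    """Solvated model: nanoparticle, analytes, 3-site water, counterions."""

    model: NanoparticleModel
    analyte_template: MoleculeTemplate | None
    analyte_coords: list[np.ndarray]
    water_coords: np.ndarray          # (n_waters, 3, 3): O, H, H
    ion_elements: list[str]
    ion_charges: np.ndarray
    ion_coords: np.ndarray
    box: np.ndarray                   # (3,) box lengths, Å; centered at origin

    @property
    def n_analytes(self) -> int:
        return len(self.analyte_coords)

    @property
    def n_waters(self) -> int:
        return len(self.water_coords)

    def total_charge(self) -> float:
        q = self.model.formal_charge()
        if self.analyte_template is not None:
            q += self.n_analytes * self.analyte_template.formal_charge
        return float(q + np.sum(self.ion_charges))

    def solute_positions(self) -> np.ndarray:
        parts = [self.model.positions()] + list(self.analyte_coords)
        return np.vstack(parts)

    def all_positions(self) -> np.ndarray:
        parts = [self.model.positions()] + list(self.analyte_coords)
        if self.n_waters:
            parts.append(self.water_coords.reshape(-1, 3))
        if len(self.ion_coords):
            parts.append(self.ion_coords)
        return np.vstack(parts)

    def topology(self) -> Topology:
        tb = TopologyBuilder()
        sig_au, eps_au = _LJ["AU"]
        n_au = self.model.core.n_atoms
        tb.add_molecule(
            "core", ["AU"] * n_au, [0.0] * n_au, [sig_au] * n_au,
            [eps_au] * n_au, bonds=list(self.model.core.bond_pairs),
        )
        for l in self.model.ligands:
            t = l.template
            tb.add_molecule(
                "ligand", t.elements, [a.charge for a in t.atoms],
                [a.sigma for a in t.atoms], [a.epsilon for a in t.atoms],
                flags=t.group_flags, bonds=[(i, j) for i, j, _ in t.bonds],
            )
        if self.analyte_template is not None:
            t = self.analyte_template
            for _ in range(self.n_analytes):
                tb.add_molecule(
                    "analyte", t.elements, [a.charge for a in t.atoms],
                    [a.sigma for a in t.atoms], [a.epsilon for a in t.atoms],
                    flags=t.group_flags, bonds=[(i, j) for i, j, _ in t.bonds],
                )
        for _ in range(self.n_waters):
            tb.add_molecule(
                "water", ["O", "H", "H"], list(_WATER_CHARGES),
                list(_WATER_SIGMA), list(_WATER_EPS), bonds=[(0, 1), (0, 2)],
            )
        for e, q in zip(self.ion_elements, self.ion_charges):
            sig, eps = _LJ[e.upper()]
            tb.add_molecule("ion", [e], [float(q)], [sig], [eps])
        return tb.build()


def build_system(model: NanoparticleModel,
                 analyte: MoleculeTemplate | None = None,
                 n_analytes: int = 0,
                 padding: float = C.SOLVENT_PADDING,
                 seed: int = 0, *,
                 water: bool = True,
                 water_density: float = C.WATER_NUMBER_DENSITY,
                 water_exclusion: float = 2.6,
                 clash_distance: float = C.CLASH_DISTANCE,
                 max_retries: int = C.MAX_PLACEMENT_RETRIES) -> SimulationSystem:
    """Solvate ``model`` with analytes, lattice water and neutralizing ions.

    Analytes are dropped at uniformly random positions/orientations in a
    shell just outside the monolayer envelope, rejecting heavy-atom clashes
    below ``clash_distance``; the box leaves at least ``padding`` Å between
    every solute atom and each face; water oxygens sit on a jittered cubic
    lattice at ``water_density`` outside ``water_exclusion`` of solute heavy
    atoms; monovalent counterions replace water sites until the total charge
    is exactly zero.
    """
    if padding <= 0:
        raise ValueError("padding must be positive")
    if n_analytes < 0:
        raise ValueError("n_analytes must be non-negative")
    if n_analytes > 0 and analyte is None:
        raise ValueError("analyte template required when n_analytes > 0")
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    model_pos = model.positions()
    model_heavy = model_pos[
        [i for i, e in enumerate(model.elements()) if e.upper() != "H"]
    ]
    r_env = float(np.linalg.norm(model_pos - model.core.center, axis=1).max())

    # --- analytes ------------------------------------------------------
    analyte_coords: list[np.ndarray] = []
    solute_heavy = [model_heavy]
    if n_analytes:
        heavy_local = analyte.heavy_indices()
        centered = analyte.coords - analyte.coords.mean(axis=0)
        for k in range(n_analytes):
            ok = False
            for _ in range(max_retries):
                direction = unit(rng.normal(size=3))
                radius = rng.uniform(r_env + 2.0, r_env + 10.0)
                rot = random_rotation(rng)
                cand = model.core.center + direction * radius + centered @ rot.T
                tree = cKDTree(np.vstack(solute_heavy))
                if tree.query(cand[heavy_local])[0].min() >= clash_distance:
                    ok = True
                    break
            if not ok:
                raise PlacementError(
                    f"analyte {k}: no clash-free placement in {max_retries} tries"
                )
            analyte_coords.append(cand)
            solute_heavy.append(cand[heavy_local])

    solute = np.vstack([model_pos] + analyte_coords)
    box = 2.0 * (np.abs(solute).max(axis=0) + padding)

    # --- water on a jittered lattice -----------------------------------
    water_coords = np.empty((0, 3, 3))
    if water:
        a = water_density ** (-1.0 / 3.0)
        grids = [np.arange(-b / 2.0 + a / 2.0, b / 2.0 - a / 4.0, a) for b in box]
        gx, gy, gz = np.meshgrid(*grids, indexing="ij")
        sites = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
        sites = sites + rng.uniform(-0.3, 0.3, size=sites.shape)
        sites = sites[np.all(np.abs(sites) < box / 2.0 - 0.5, axis=1)]
        tree = cKDTree(np.vstack(solute_heavy))
        keep = tree.query(sites)[0] >= water_exclusion
        sites = sites[keep]
        water_coords = np.array([water_molecule(s, rng) for s in sites])

    # --- neutralizing counterions --------------------------------------
    q_solute = model.formal_charge()
    if analyte is not None:
        q_solute += n_analytes * analyte.formal_charge
    n_ions = abs(int(round(q_solute)))
    ion_elements: list[str] = []
    ion_charges = np.zeros(n_ions)
    ion_coords = np.empty((0, 3))
    if n_ions:
        species, q_ion = ("NA", 1.0) if q_solute < 0 else ("CL", -1.0)
        ion_elements = [species] * n_ions
        ion_charges[:] = q_ion
        if len(water_coords) >= n_ions:
            # replace random water sites with ions
            chosen = rng.choice(len(water_coords), size=n_ions, replace=False)
            ion_coords = water_coords[chosen, 0, :].copy()
            water_coords = np.delete(water_coords, chosen, axis=0)
        else:
            placed = []
            tree = cKDTree(np.vstack(solute_heavy))
            for k in range(n_ions):
                ok = False
                for _ in range(max_retries):
                    cand = rng.uniform(-box / 2.0 + 1.0, box / 2.0 - 1.0)
                    if tree.query(cand)[0] >= water_exclusion and all(
                        np.linalg.norm(cand - p) >= water_exclusion for p in placed
                    ):
                        ok = True
                        break
                if not ok:
                    raise PlacementError(f"ion {k}: no placement found")
                placed.append(cand)
            ion_coords = np.array(placed)

    system = SimulationSystem(
        model=model,
        analyte_template=analyte,
        analyte_coords=analyte_coords,
        water_coords=water_coords,
        ion_elements=ion_elements,
        ion_charges=ion_charges,
        ion_coords=ion_coords,
        box=box,
    )
    if abs(system.total_charge()) > 1e-9:
        raise BuildError(
            f"system charge {system.total_charge()} after ion addition"
        )
    return system
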