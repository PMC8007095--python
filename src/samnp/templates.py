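"""Ligand and analyte molecular templates.

A template carries everything the builder and the energetics need about one
molecule species: elements, partial charges, Lennard-Jones parameters,
connectivity, functional-group flags, and a reference geometry in the
all-trans extended conformation (anchor at the origin, chain axis along +z).

The bundled templates (S1-S3 thiolate ligands, A1-A4 / AN1-AN2 analytes) are
simplified synthetic topologies: linear heavy-atom chains for ligands, an
explicit planar six-ring for aromatic analytes, hydrogens only on
hydrogen-bond donors.  Partial charges are formal charges localized on the
charged group, not fitted values; they are meant to exercise the analysis
machinery, and every file is plain JSON the user can edit.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

VALID_FLAGS = {
    "sulfonate_oxygen",
    "ammonium_nitrogen",
    "carboxylate_oxygen",
    "aromatic_carbon",
    "heavy",
    "hydrogen",
}

# generic per-element LJ parameters (sigma Å, epsilon kcal/mol)
_LJ = {
    "H": (1.069, 0.0157),
    "C": (3.40, 0.09),
    "N": (3.25, 0.17),
    "O": (3.00, 0.21),
    "S": (3.60, 0.25),
    "AU": (2.95, 0.039),
    "NA": (2.44, 0.0874),
    "CL": (4.40, 0.10),
}

_BOND_CC = 1.54
_BOND_CS = 1.81
_BOND_SO = 1.46
_BOND_CN = 1.48
_BOND_NH = 1.01
_BOND_CO2 = 1.26  # carboxylate C-O
_BOND_AROM = 1.40
_ANGLE_BACKBONE = 111.0  # degrees, tetrahedral-ish chain angle


@dataclass
class TemplateAtom:
    element: str
    charge: float
    sigma: float
    epsilon: float


@dataclass
class MoleculeTemplate:
    """Species-level description of one molecule (ligand or analyte)."""

    name: str
    kind: str  # "ligand" | "analyte"
    atoms: list[TemplateAtom]
    coords: np.ndarray  # (n, 3) reference geometry, Å
    bonds: list[tuple[int, int, float]]  # (i, j, ideal length Å)
    formal_charge: int
    anchor_index: int | None  # sulfur anchor for ligands, None for analytes
    terminal_index: int
    group_flags: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, float)
        n = len(self.atoms)
        if self.coords.shape != (n, 3):
            raise ValueError(
                f"template {self.name}: {n} atoms but coords shape {self.coords.shape}"
            )
        for idx, flag in self.group_flags.items():
            if not (0 <= idx < n):
                raise ValueError(f"template {self.name}: flag index {idx} out of range")
            if flag not in VALID_FLAGS:
                raise ValueError(f"template {self.name}: unknown flag {flag!r}")
        if self.kind == "ligand":
            if self.anchor_index is None:
                raise ValueError(f"ligand template {self.name} needs an anchor")
            if self.atoms[self.anchor_index].element != "S":
                raise ValueError(
                    f"ligand template {self.name}: anchor atom must be sulfur"
                )
        net = sum(a.charge for a in self.atoms)
        if abs(net - self.formal_charge) > 1e-6:
            raise ValueError(
                f"template {self.name}: partial charges sum to {net}, "
                f"declared formal charge {self.formal_charge}"
            )

    # ------------------------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    def heavy_indices(self) -> np.ndarray:
        return np.array(
            [i for i, a in enumerate(self.atoms) if a.element != "H"], dtype=int
        )

    def flagged(self, flag: str) -> np.ndarray:
        return np.array(
            sorted(i for i, f in self.group_flags.items() if f == flag), dtype=int
        )

    def axis_length(self) -> float:
        """Extent of the reference geometry along the chain axis (+z)."""
        z = self.coords[:, 2]
        return float(z.max() - z.min())

    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "kind": self.kind,
            "formal_charge": self.formal_charge,
            "anchor_index": self.anchor_index,
            "terminal_index": self.terminal_index,
            "atoms": [
                {
                    "element": a.element,
                    "charge": a.charge,
                    "sigma": a.sigma,
                    "epsilon": a.epsilon,
                    "x": float(x),
                    "y": float(y),
                    "z": float(z),
                }
                for a, (x, y, z) in zip(self.atoms, self.coords)
            ],
            "bonds": [[int(i), int(j), float(r0)] for i, j, r0 in self.bonds],
            "group_flags": {str(i): f for i, f in self.group_flags.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MoleculeTemplate":
        atoms = [
            TemplateAtom(a["element"], a["charge"], a["sigma"], a["epsilon"])
            for a in d["atoms"]
        ]
        coords = np.array([[a["x"], a["y"], a["z"]] for a in d["atoms"]], float)
        return cls(
            name=d["name"],
            kind=d["kind"],
            atoms=atoms,
            coords=coords,
            bonds=[(int(i), int(j), float(r)) for i, j, r in d["bonds"]],
            formal_charge=int(d["formal_charge"]),
            anchor_index=d["anchor_index"],
            terminal_index=int(d["terminal_index"]),
            group_flags={int(i): f for i, f in d["group_flags"].items()},
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "MoleculeTemplate":
        return cls.from_dict(json.loads(Path(path).read_text()))


# Aliases used throughout: a ligand has a sulfur anchor, an analyte does not.
LigandTemplate = MoleculeTemplate
AnalyteTemplate = MoleculeTemplate


# ----------------------------------------------------------------------
# geometry builders
# ----------------------------------------------------------------------

def alltrans_chain(n_atoms: int, bond: float = _BOND_CC,
                   angle: float = _ANGLE_BACKBONE) -> np.ndarray:
    """All-trans zig-zag backbone of ``n_atoms`` sites starting at the origin.

    The chain axis is +z; the zig-zag lies in the x-z plane.  Consecutive
    sites are ``bond`` apart with the internal angle ``angle`` (degrees) at
    every vertex.
    """
    half = math.radians(angle) / 2.0
    dz = bond * math.sin(half)
    dx = bond * math.cos(half)
    coords = np.zeros((n_atoms, 3))
    for k in range(n_atoms):
        coords[k, 2] = k * dz
        coords[k, 0] = dx if (k % 2 == 1) else 0.0
    return coords


def alltrans_extension(n_bonds: int, bond: float = _BOND_CC,
                       angle: float = _ANGLE_BACKBONE) -> float:
    """Closed-form axial extension of an all-trans chain of ``n_bonds`` bonds."""
    return n_bonds * bond * math.sin(math.radians(angle) / 2.0)


def _atom(element: str, charge: float = 0.0) -> TemplateAtom:
    sigma, eps = _LJ[element.upper()]
    return TemplateAtom(element, charge, sigma, eps)


def _chain_bonds(n: int, bond: float) -> list[tuple[int, int, float]]:
    return [(i, i + 1, bond) for i in range(n - 1)]


def make_ligand_template(name: str, n_aliphatic: int, n_aromatic: int,
                         head: str) -> MoleculeTemplate:
    """Build a simplified thiolate-ligand template.

    The backbone is S followed by ``n_aliphatic`` aliphatic and
    ``n_aromatic`` aromatic-flagged carbons; ``head`` is ``"sulfonate"``
    (terminal SO3⁻, formal charge -1) or ``"hydroxyl"`` (terminal OH-like
    oxygen, neutral).
    """
    n_backbone = 1 + n_aliphatic + n_aromatic
    coords = list(alltrans_chain(n_backbone))
    atoms = [_atom("S")] + [_atom("C") for _ in range(n_aliphatic + n_aromatic)]
    bonds = _chain_bonds(n_backbone, _BOND_CC)
    bonds[0] = (0, 1, _BOND_CS)
    flags: dict[int, str] = {}
    for k in range(n_aromatic):
        flags[1 + n_aliphatic + k] = "aromatic_carbon"

    last = n_backbone - 1
    tip = coords[last]
    half = math.radians(_ANGLE_BACKBONE) / 2.0
    dz = _BOND_CC * math.sin(half)

    if head == "sulfonate":
        # sulfonate sulfur continues the chain axis; three oxygens tripod out
        s_idx = len(atoms)
        atoms.append(_atom("S", 0.5))
        coords.append(tip + np.array([0.0, 0.0, _BOND_CS * math.sin(half) + 0.4]))
        bonds.append((last, s_idx, _BOND_CS))
        tilt = math.radians(70.0)
        for k in range(3):
            az = 2.0 * math.pi * k / 3.0
            o_idx = len(atoms)
            atoms.append(_atom("O", -0.5))
            coords.append(
                coords[s_idx]
                + _BOND_SO
                * np.array(
                    [
                        math.sin(tilt) * math.cos(az),
                        math.sin(tilt) * math.sin(az),
                        math.cos(tilt),
                    ]
                )
            )
            bonds.append((s_idx, o_idx, _BOND_SO))
            flags[o_idx] = "sulfonate_oxygen"
        formal = -1
        terminal = s_idx
    elif head == "hydroxyl":
        o_idx = len(atoms)
        atoms.append(_atom("O", -0.4))
        coords.append(tip + np.array([0.0, 0.0, dz]))
        bonds.append((last, o_idx, 1.43))
        h_idx = len(atoms)
        atoms.append(_atom("H", 0.4))
        coords.append(coords[o_idx] + np.array([0.6, 0.0, 0.75]))
        bonds.append((o_idx, h_idx, 0.97))
        flags[h_idx] = "hydrogen"
        formal = 0
        terminal = o_idx
    else:  # pragma: no cover - guarded by callers
        raise ValueError(f"unknown ligand head {head!r}")

    return MoleculeTemplate(
        name=name,
        kind="ligand",
        atoms=atoms,
        coords=np.array(coords),
        bonds=bonds,
        formal_charge=formal,
        anchor_index=0,
        terminal_index=terminal,
        group_flags=flags,
    )


def _hex_ring(center_z: float, radius: float = _BOND_AROM) -> np.ndarray:
    """Planar six-ring in the x-z plane (its plane contains the +z long axis)."""
    pts = []
    for k in range(6):
        a = math.pi / 2.0 + k * math.pi / 3.0
        pts.append([radius * math.cos(a), 0.0, center_z + radius * math.sin(a)])
    return np.array(pts)


def make_analyte_template(name: str, head: str, tail_carbons: int,
                          ring: bool = True) -> MoleculeTemplate:
    """Build a simplified analyte template with its long axis along +z.

    ``head`` selects the charged group at the top of the molecule:
    ``"ammonium"`` (+1), ``"carboxylate"`` (-1) or ``"zwitterion"``
    (ammonium + carboxylate, net 0).  ``ring`` adds an aromatic six-ring
    whose plane contains the long axis, mid-molecule.
    """
    atoms: list[TemplateAtom] = []
    coords: list[np.ndarray] = []
    bonds: list[tuple[int, int, float]] = []
    flags: dict[int, str] = {}

    half = math.radians(_ANGLE_BACKBONE) / 2.0
    dz = _BOND_CC * math.sin(half)

    # tail (bottom, along -z from origin)
    tail = alltrans_chain(max(tail_carbons, 1))
    tail[:, 2] -= tail[-1, 2]  # last tail atom at z=0
    for p in tail:
        atoms.append(_atom("C"))
        coords.append(p)
    bonds.extend(_chain_bonds(len(tail), _BOND_CC))
    top = len(atoms) - 1  # index of current topmost backbone atom
    z = 0.0

    if ring:
        ring_coords = _hex_ring(z + _BOND_AROM + dz)
        ring_start = len(atoms)
        for p in ring_coords:
            atoms.append(_atom("C"))
            coords.append(p)
            flags[len(atoms) - 1] = "aromatic_carbon"
        for k in range(6):
            bonds.append(
                (ring_start + k, ring_start + (k + 1) % 6, _BOND_AROM)
            )
        # bottom ring atom (k=3 is at angle 270°, lowest z) links to the tail
        bonds.append((top, ring_start + 3, _BOND_CC))
        top = ring_start  # top ring atom (k=0, highest z)
        z = coords[ring_start][2]

    formal = 0
    if head in ("ammonium", "zwitterion"):
        n_idx = len(atoms)
        atoms.append(_atom("N", 1.0 - 3 * 0.25))
        coords.append(np.array([0.0, 0.0, z + _BOND_CN]))
        bonds.append((top, n_idx, _BOND_CN))
        flags[n_idx] = "ammonium_nitrogen"
        tilt = math.radians(68.0)
        for k in range(3):
            az = 2.0 * math.pi * k / 3.0
            h_idx = len(atoms)
            atoms.append(_atom("H", 0.25))
            coords.append(
                coords[n_idx]
                + _BOND_NH
                * np.array(
                    [
                        math.sin(tilt) * math.cos(az),
                        math.sin(tilt) * math.sin(az),
                        math.cos(tilt),
                    ]
                )
            )
            bonds.append((n_idx, h_idx, _BOND_NH))
        formal += 1
    if head in ("carboxylate", "zwitterion"):
        # carboxylate goes on the bottom for the zwitterion, on top otherwise
        if head == "carboxylate":
            c_anchor, c_z, direction = top, z + _BOND_CC, 1.0
        else:
            c_anchor, c_z, direction = 0, coords[0][2] - _BOND_CC, -1.0
        c_idx = len(atoms)
        atoms.append(_atom("C", 0.2))
        coords.append(np.array([0.0, 0.0, c_z]))
        bonds.append((c_anchor, c_idx, _BOND_CC))
        for k, sx in enumerate((1.0, -1.0)):
            o_idx = len(atoms)
            atoms.append(_atom("O", -0.6))
            coords.append(
                coords[c_idx]
                + np.array([sx * _BOND_CO2 * 0.83, 0.0, direction * _BOND_CO2 * 0.56])
            )
            bonds.append((c_idx, o_idx, _BOND_CO2))
            flags[o_idx] = "carboxylate_oxygen"
        formal -= 1
    if head not in ("ammonium", "carboxylate", "zwitterion"):
        raise ValueError(f"unknown analyte head {head!r}")

    coords_arr = np.array(coords)
    terminal = int(np.argmax(coords_arr[:, 2]))
    return MoleculeTemplate(
        name=name,
        kind="analyte",
        atoms=atoms,
        coords=coords_arr,
        bonds=bonds,
        formal_charge=formal,
        anchor_index=None,
        terminal_index=terminal,
        group_flags=flags,
    )


# ----------------------------------------------------------------------
# bundled template registry
# ----------------------------------------------------------------------

def _builtin_builders() -> dict[str, MoleculeTemplate]:
    return {
        "S1": make_ligand_template("S1", n_aliphatic=8, n_aromatic=3, head="sulfonate"),
        "S2": make_ligand_template("S2", n_aliphatic=6, n_aromatic=0, head="sulfonate"),
        "S3": make_ligand_template("S3", n_aliphatic=8, n_aromatic=0, head="hydroxyl"),
        "A1": make_analyte_template("A1", head="ammonium", tail_carbons=4, ring=True),
        "A2": make_analyte_template("A2", head="ammonium", tail_carbons=2, ring=True),
        "A3": make_analyte_template("A3", head="ammonium", tail_carbons=3, ring=False),
        "A4": make_analyte_template("A4", head="zwitterion", tail_carbons=2, ring=True),
        "AN1": make_analyte_template("AN1", head="carboxylate", tail_carbons=2, ring=True),
        "AN2": make_analyte_template("AN2", head="carboxylate", tail_carbons=4, ring=True),
    }


BUILTIN_NAMES = ("S1", "S2", "S3", "A1", "A2", "A3", "A4", "AN1", "AN2")


def builtin_template(name: str) -> MoleculeTemplate:
    """Load a bundled template by name (falls back to the in-code builder)."""
    if name not in BUILTIN_NAMES:
        raise KeyError(f"no bundled template {name!r}; choose from {BUILTIN_NAMES}")
    try:
        ref = resources.files(__package__) / "templates" / f"{name}.json"
        return MoleculeTemplate.from_dict(json.loads(ref.read_text()))
    except (FileNotFoundError, ModuleNotFoundError):
        return _builtin_builders()[name]


def write_builtin_templates(directory: str | Path) -> list[Path]:
    """Regenerate the bundled template JSON files into ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for name, tpl in _builtin_builders().items():
        path = directory / f"{name}.json"
        tpl.save(path)
        written.append(path)
    return written
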