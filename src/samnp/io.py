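"""Structure readers/writers and the JSON topology dialect.

PDB and single-frame XYZ are parsed strictly: malformed or truncated
records raise :class:`ParseError` carrying the offending line number
rather than returning a silent partial structure.  Coordinates are Å
everywhere; PDB occupancy/B-factor are written as 1.00/0.00.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .topology import Topology


class ParseError(ValueError):
    """Malformed structure file; message includes the line number."""


_RESNAME_BY_KIND = {
    "core": "AUC",
    "ligand": "LIG",
    "analyte": "ANA",
    "water": "HOH",
    "ion": "ION",
}


@dataclass
class Structure:
    """Minimal structure: elements, coordinates, optional metadata."""

    elements: list[str]
    coords: np.ndarray
    resids: list[int] = field(default_factory=list)
    resnames: list[str] = field(default_factory=list)
    box: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, float)
        n = len(self.elements)
        if self.coords.shape != (n, 3):
            raise ValueError("one coordinate triple per element required")
        if not self.resids:
            self.resids = [1] * n
        if not self.resnames:
            self.resnames = ["MOL"] * n

    @property
    def n_atoms(self) -> int:
        return len(self.elements)


def structure_from_topology(topology: Topology,
                            coords: np.ndarray) -> Structure:
    """Structure with residue numbering taken from molecule membership."""
    resids = [int(m) + 1 for m in topology.mol_ids]
    resnames = [
        _RESNAME_BY_KIND[topology.mol_kinds[m]] for m in topology.mol_ids
    ]
    return Structure(
        elements=list(topology.elements), coords=np.asarray(coords, float),
        resids=resids, resnames=resnames,
    )


# ----------------------------------------------------------------------
# readers
# ----------------------------------------------------------------------

def read_structure(path: str | Path, fmt: str | None = None) -> Structure:
    """Read a PDB or single-frame XYZ structure (format from extension)."""
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt == "pdb":
        return _read_pdb(path)
    if fmt == "xyz":
        return _read_xyz_structure(path)
    raise ValueError(f"unsupported structure format {fmt!r}")


def _read_pdb(path: Path) -> Structure:
    elements, coords, resids, resnames = [], [], [], []
    box = None
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        record = line[:6].strip()
        if record == "CRYST1":
            try:
                box = np.array(
                    [float(line[6:15]), float(line[15:24]), float(line[24:33])]
                )
            except (ValueError, IndexError) as exc:
                raise ParseError(f"{path}: line {lineno}: bad CRYST1") from exc
        if record not in ("ATOM", "HETATM"):
            continue
        if len(line) < 54:
            raise ParseError(
                f"{path}: line {lineno}: truncated atom record "
                f"({len(line)} characters)"
            )
        try:
            x = float(line[30:38])
            y = float(line[38:46])
            z = float(line[46:54])
            resid = int(line[22:26])
        except ValueError as exc:
            raise ParseError(
                f"{path}: line {lineno}: unparseable atom record"
            ) from exc
        element = line[76:78].strip() if len(line) >= 78 else ""
        if not element:
            name = line[12:16].strip()
            element = "".join(c for c in name if c.isalpha())[:2]
            if len(element) == 2 and element[1].islower() is False:
                element = element[0]
        if not element:
            raise ParseError(f"{path}: line {lineno}: no element")
        elements.append(element)
        coords.append([x, y, z])
        resids.append(resid)
        resnames.append(line[17:20].strip() or "MOL")
    if not elements:
        raise ParseError(f"{path}: no atom records found")
    return Structure(
        elements=elements, coords=np.array(coords), resids=resids,
        resnames=resnames, box=box,
    )


def _read_xyz_structure(path: Path) -> Structure:
    lines = path.read_text().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file")
    try:
        n = int(lines[0].strip())
    except ValueError as exc:
        raise ParseError(f"{path}: line 1: expected atom count") from exc
    body = lines[2 : 2 + n]
    if len(body) < n:
        raise ParseError(
            f"{path}: truncated: {n} atoms declared, {len(body)} records found"
        )
    elements, coords = [], []
    for k, line in enumerate(body):
        toks = line.split()
        if len(toks) < 4:
            raise ParseError(f"{path}: line {k + 3}: malformed atom record")
        try:
            coords.append([float(toks[1]), float(toks[2]), float(toks[3])])
        except ValueError as exc:
            raise ParseError(
                f"{path}: line {k + 3}: unparseable coordinates"
            ) from exc
        elements.append(toks[0])
    return Structure(elements=elements, coords=np.array(coords))


# ----------------------------------------------------------------------
# writers
# ----------------------------------------------------------------------

def write_pdb(structure: Structure, path: str | Path) -> None:
    """Write a PDB file (occupancy 1.00, B-factor 0.00)."""
    with open(path, "w") as fh:
        if structure.box is not None:
            b = structure.box
            fh.write(
                f"CRYST1{b[0]:9.3f}{b[1]:9.3f}{b[2]:9.3f}"
                f"{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1           1\n"
            )
        for i, (e, (x, y, z)) in enumerate(
            zip(structure.elements, structure.coords), start=1
        ):
            name = e[:4].upper()
            resname = structure.resnames[i - 1][:3]
            resid = structure.resids[i - 1] % 10000
            fh.write(
                f"ATOM  {i % 100000:5d} {name:<4s} {resname:<3s} A"
                f"{resid:4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
                f"{1.0:6.2f}{0.0:6.2f}          {e[:2].upper():>2s}\n"
            )
        fh.write("END\n")


def write_xyz_structure(structure: Structure, path: str | Path,
                        comment: str = "") -> None:
    with open(path, "w") as fh:
        fh.write(f"{structure.n_atoms}\n{comment}\n")
        for e, (x, y, z) in zip(structure.elements, structure.coords):
            fh.write(f"{e:<2s} {x:14.6f} {y:14.6f} {z:14.6f}\n")


def write_topology_json(model, path: str | Path) -> None:
    """Write a nanoparticle model in the JSON topology dialect.

    ``atoms`` carry element/charge/LJ/flags; ``bonds`` carry the harmonic
    Au-Au and Au-S restraints with the spring constant in kJ mol⁻¹ nm⁻²
    and the built bond length as r0, plus the chemical template bonds
    (spring constant null).
    """
    topo = model.topology()
    pos = model.positions()
    atoms = []
    for i in range(topo.n_atoms):
        atoms.append(
            {
                "element": topo.elements[i],
                "charge": float(topo.charges[i]),
                "sigma": float(topo.sigmas[i]),
                "epsilon": float(topo.epsilons[i]),
                "flags": [topo.flags[i]] if i in topo.flags else [],
            }
        )
    bonds = []
    for i, j, k in model.au_au_bonds + model.au_s_bonds:
        bonds.append(
            {
                "i": int(i), "j": int(j),
                "k_spring_kj_mol_nm2": float(k),
                "r0_A": float(np.linalg.norm(pos[i] - pos[j])),
            }
        )
    n_core = model.core.n_atoms
    off = n_core
    for lig in model.ligands:
        for i, j, r0 in lig.template.bonds:
            bonds.append(
                {
                    "i": off + int(i), "j": off + int(j),
                    "k_spring_kj_mol_nm2": None, "r0_A": float(r0),
                }
            )
        off += lig.template.n_atoms
    payload = {"atoms": atoms, "bonds": bonds}
    Path(path).write_text(json.dumps(payload))
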