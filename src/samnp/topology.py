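"""Flat per-atom topology shared by all analyses.

A :class:`Topology` is the atom table for one assembled system: element,
partial charge, LJ parameters, mass, molecule membership (id and kind), the
functional-group flags inherited from the templates, and the bond list.
Analyses address atoms through index selections produced by
:meth:`Topology.select`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import ATOMIC_MASSES, INTRINSIC_RADII

MOL_KINDS = ("core", "ligand", "analyte", "water", "ion")


@dataclass
class Topology:
    elements: list[str]
    charges: np.ndarray
    sigmas: np.ndarray
    epsilons: np.ndarray
    mol_ids: np.ndarray      # integer molecule id per atom
    mol_kinds: list[str]     # kind per molecule id
    flags: dict[int, str] = field(default_factory=dict)
    bonds: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.charges = np.asarray(self.charges, float)
        self.sigmas = np.asarray(self.sigmas, float)
        self.epsilons = np.asarray(self.epsilons, float)
        self.mol_ids = np.asarray(self.mol_ids, int)
        n = len(self.elements)
        for arr in (self.charges, self.sigmas, self.epsilons, self.mol_ids):
            if len(arr) != n:
                raise ValueError("topology arrays must all have one entry per atom")

    # ------------------------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def masses(self) -> np.ndarray:
        return np.array([ATOMIC_MASSES[e.upper()] for e in self.elements])

    @property
    def intrinsic_radii(self) -> np.ndarray:
        try:
            return np.array([INTRINSIC_RADII[e.upper()] for e in self.elements])
        except KeyError as exc:  # pragma: no cover - element tables are complete
            raise KeyError(f"no intrinsic radius for element {exc}") from None

    def is_heavy(self) -> np.ndarray:
        return np.array([e.upper() != "H" for e in self.elements])

    def total_charge(self) -> float:
        return float(self.charges.sum())

    # ------------------------------------------------------------------
    def select(self, kind: str | None = None, flag: str | None = None,
               mol_index: int | None = None, heavy: bool = False) -> np.ndarray:
        """Atom indices matching all given criteria.

        ``kind`` filters by molecule kind, ``flag`` by functional-group flag,
        ``mol_index`` by the i-th molecule *of that kind* (requires ``kind``),
        ``heavy`` drops hydrogens.
        """
        mask = np.ones(self.n_atoms, bool)
        if kind is not None:
            if kind not in MOL_KINDS:
                raise ValueError(f"unknown molecule kind {kind!r}")
            kind_of_atom = np.array([self.mol_kinds[m] for m in self.mol_ids])
            mask &= kind_of_atom == kind
            if mol_index is not None:
                ids_of_kind = [
                    i for i, k in enumerate(self.mol_kinds) if k == kind
                ]
                mask &= self.mol_ids == ids_of_kind[mol_index]
        elif mol_index is not None:
            raise ValueError("mol_index requires kind")
        if flag is not None:
            flagged = np.zeros(self.n_atoms, bool)
            for i, f in self.flags.items():
                if f == flag:
                    flagged[i] = True
            mask &= flagged
        if heavy:
            mask &= self.is_heavy()
        return np.flatnonzero(mask)

    def molecules_of_kind(self, kind: str) -> list[np.ndarray]:
        """Atom-index arrays, one per molecule of ``kind``, in molecule order."""
        out = []
        for mid, k in enumerate(self.mol_kinds):
            if k == kind:
                out.append(np.flatnonzero(self.mol_ids == mid))
        return out

    def to_dict(self) -> dict:
        return {
            "elements": list(self.elements),
            "charges": self.charges.tolist(),
            "sigmas": self.sigmas.tolist(),
            "epsilons": self.epsilons.tolist(),
            "mol_ids": self.mol_ids.tolist(),
            "mol_kinds": list(self.mol_kinds),
            "flags": {str(i): f for i, f in self.flags.items()},
            "bonds": [[int(i), int(j)] for i, j in self.bonds],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Topology":
        return cls(
            elements=list(d["elements"]),
            charges=np.array(d["charges"]),
            sigmas=np.array(d["sigmas"]),
            epsilons=np.array(d["epsilons"]),
            mol_ids=np.array(d["mol_ids"], int),
            mol_kinds=list(d["mol_kinds"]),
            flags={int(i): f for i, f in d["flags"].items()},
            bonds=[(int(i), int(j)) for i, j in d["bonds"]],
        )

    def attached_hydrogens(self, index: int) -> list[int]:
        """Indices of hydrogen atoms bonded to atom ``index``."""
        out = []
        for i, j in self.bonds:
            if i == index and self.elements[j].upper() == "H":
                out.append(j)
            elif j == index and self.elements[i].upper() == "H":
                out.append(i)
        return out


class TopologyBuilder:
    """Incremental assembly of a :class:`Topology`, one molecule at a time."""

    def __init__(self) -> None:
        self._elements: list[str] = []
        self._charges: list[float] = []
        self._sigmas: list[float] = []
        self._epsilons: list[float] = []
        self._mol_ids: list[int] = []
        self._mol_kinds: list[str] = []
        self._flags: dict[int, str] = {}
        self._bonds: list[tuple[int, int]] = []

    def add_molecule(self, kind: str, elements: list[str], charges, sigmas,
                     epsilons, flags: dict[int, str] | None = None,
                     bonds: list[tuple[int, int]] | None = None) -> int:
        """Append one molecule; returns the global index of its first atom."""
        if kind not in MOL_KINDS:
            raise ValueError(f"unknown molecule kind {kind!r}")
        offset = len(self._elements)
        mid = len(self._mol_kinds)
        self._mol_kinds.append(kind)
        self._elements.extend(elements)
        self._charges.extend(float(q) for q in charges)
        self._sigmas.extend(float(s) for s in sigmas)
        self._epsilons.extend(float(e) for e in epsilons)
        self._mol_ids.extend([mid] * len(elements))
        if flags:
            for i, f in flags.items():
                self._flags[offset + int(i)] = f
        if bonds:
            for i, j in bonds:
                self._bonds.append((offset + int(i), offset + int(j)))
        return offset

    def build(self) -> Topology:
        return Topology(
            elements=list(self._elements),
            charges=np.array(self._charges),
            sigmas=np.array(self._sigmas),
            epsilons=np.array(self._epsilons),
            mol_ids=np.array(self._mol_ids, int),
            mol_kinds=list(self._mol_kinds),
            flags=dict(self._flags),
            bonds=list(self._bonds),
        )
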