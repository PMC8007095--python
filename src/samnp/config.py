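"""Run configuration: every stage's parameters with printed defaults."""

from __future__ import annotations

from dataclasses import dataclass, asdict, field
from pathlib import Path

import yaml

from . import constants as C


@dataclass
class RunConfig:
    """Parameters of the full build → synthesize → analyze pipeline.

    Defaults reproduce the reference construction: a 144-atom icosahedral
    core carrying 50 ligands, 30 analyte copies, 20 Å solvent padding, the
    0.5 nm / 10 ns contact rule, and 300 K.
    """

    # construction
    core_atoms: int = C.N_CORE_ATOMS
    n_ligands: int = C.N_LIGANDS
    ligand: str = "S1"
    analyte: str = "A1"
    n_analytes: int = C.N_ANALYTES
    padding: float = C.SOLVENT_PADDING
    au_au_cutoff: float = C.AU_AU_BOND_CUTOFF
    au_s_cutoff: float = C.AU_S_BOND_CUTOFF
    spring_k: float = C.SPRING_K_KJ_MOL_NM2
    # synthetic trajectory
    n_frames: int = 100
    dt: float = 0.1
    bundle_count: int = 2
    bundle_kappa: float = 200.0
    analyte_bound_fraction: float = 0.6
    mean_residence: float = 20.0
    water_penetration: float = 0.2
    water_density: float = C.WATER_NUMBER_DENSITY
    # analysis
    contact_cutoff: float = C.CONTACT_CUTOFF
    min_contact_duration: float = C.MIN_CONTACT_DURATION
    bundle_angle_cutoff: float = C.BUNDLE_ANGLE_CUTOFF
    bundle_distance_cutoff: float = C.BUNDLE_DISTANCE_CUTOFF
    bundle_min_size: int = C.BUNDLE_MIN_SIZE
    hydration_distances: list = field(default_factory=lambda: [4.0, 6.0, 8.0, 10.0])
    temperature: float = C.TEMPERATURE
    energy_frames: int = 10
    # bookkeeping
    seed: int = 0
    output_dir: str = "samnp_out"

    def validate(self) -> None:
        positive = (
            "core_atoms", "n_ligands", "padding", "au_au_cutoff",
            "au_s_cutoff", "spring_k", "n_frames", "dt", "contact_cutoff",
            "min_contact_duration", "bundle_angle_cutoff",
            "bundle_distance_cutoff", "temperature",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"config: {name} must be positive")
        if self.n_analytes < 0:
            raise ValueError("config: n_analytes must be >= 0")
        if not 0.0 <= self.water_penetration <= 1.0:
            raise ValueError("config: water_penetration must be in [0, 1]")
        if any(d <= 0 for d in self.hydration_distances):
            raise ValueError("config: hydration distances must be positive")

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"config: unknown keys {sorted(unknown)}")
        return cls(**data)
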