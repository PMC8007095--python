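"""Shared fixtures: one reference build reused across the suite."""

from __future__ import annotations

import numpy as np
import pytest

from samnp.model_builder import (
    build_gold_core, build_system, graft_ligands, place_anchors,
)
from samnp.synthetic import SyntheticSpec, generate
from samnp.templates import builtin_template


@pytest.fixture(scope="session")
def core144():
    return build_gold_core(144)


@pytest.fixture(scope="session")
def model50(core144):
    anchors = place_anchors(core144, 50, seed=11)
    return graft_ligands(core144, builtin_template("S1"), anchors)


@pytest.fixture(scope="session")
def system_small(model50):
    """Unsolvated complex system with a handful of analytes."""
    return build_system(
        model50, builtin_template("A1"), n_analytes=6, padding=8.0,
        seed=13, water=False,
    )


@pytest.fixture(scope="session")
def reference_run(system_small):
    """One synthetic trajectory shared by analysis tests (k=2 bundles)."""
    spec = SyntheticSpec(
        n_frames=30, dt=0.1, bundle_count=2, bundle_kappa=200.0,
        water_penetration=0.2, water_density=0.01, seed=17,
    )
    traj, truth = generate(system_small, spec)
    return spec, traj, truth


def rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)
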