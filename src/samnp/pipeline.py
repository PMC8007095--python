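"""End-to-end pipeline: build → synthesize → analyze → report.

Each stage draws its randomness from a child of the master seed (numpy
``SeedSequence.spawn``), so the whole run is reproducible from one
integer and individual stages can be re-run in isolation.  Any stage
error aborts the run with the stage name attached.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig
from .energetics import BindingOptions, binding_free_energy, polarity_split
from .hydration import heterogeneity, map_series
from .interactions import bridge_series, contact_series, contacting_molecules
from .model_builder import build_gold_core, build_system, graft_ligands, place_anchors
from .monolayer import block_mean_se, detect_bundles, shell_shape_series
from .synthetic import SyntheticSpec, generate
from .templates import builtin_template
from .trajectory import Trajectory

log = logging.getLogger("samnp")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def stage_seeds(master_seed: int, n: int = 8) -> list[int]:
    """Derive per-stage child seeds (< 2³¹) from one master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(child.generate_state(1)[0] % (2**31)) for child in ss.spawn(n)]


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        log.info("stage %s: start", name)
        try:
            out = fn(*args, **kwargs)
        except Exception as exc:
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        log.info("stage %s: done", name)
        return out

    return wrap


def run_pipeline(config: RunConfig,
                 output_dir: str | Path | None = None) -> dict:
    """Run the full pipeline and write the JSON + CSV report bundle.

    Returns the report dictionary; files go to ``output_dir`` (default
    from the config).  Fully deterministic per ``config.seed``.
    """
    config.validate()
    out = Path(output_dir or config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    report: dict = {"config": config.to_dict(), "seeds": seeds}

    # --- build ----------------------------------------------------------
    def _build():
        core = build_gold_core(config.core_atoms)
        anchors = place_anchors(
            core, config.n_ligands, seed=seeds[0],
            s_au_cutoff=config.au_s_cutoff,
        )
        ligand = builtin_template(config.ligand)
        model = graft_ligands(core, ligand, anchors, spring_k=config.spring_k)
        return model

    model = _stage("build")(_build)
    report["build"] = {
        "n_core_atoms": model.core.n_atoms,
        "n_ligands": len(model.ligands),
        "n_atoms": model.n_atoms,
        "formal_charge": model.formal_charge(),
        "n_au_au_bonds": len(model.au_au_bonds),
        "n_au_s_bonds": len(model.au_s_bonds),
    }

    # --- system ---------------------------------------------------------
    def _system():
        analyte = builtin_template(config.analyte) if config.n_analytes else None
        return build_system(
            model, analyte, config.n_analytes, config.padding,
            seed=seeds[1], water=False,
        )

    system = _stage("system")(_system)
    report["system"] = {
        "n_analytes": system.n_analytes,
        "box_A": system.box.tolist(),
        "total_charge": system.total_charge(),
    }

    # --- synthesize -----------------------------------------------------
    def _synth():
        spec = SyntheticSpec(
            n_frames=config.n_frames, dt=config.dt,
            bundle_count=config.bundle_count,
            bundle_kappa=config.bundle_kappa,
            analyte_bound_fraction=config.analyte_bound_fraction,
            mean_residence=config.mean_residence,
            water_penetration=config.water_penetration,
            water_density=config.water_density,
            seed=seeds[2],
        )
        return generate(system, spec)

    traj, truth = _stage("synthesize")(_synth)
    topo = traj.topology
    report["synthetic"] = {
        "n_frames": traj.n_frames,
        "dt_ns": traj.dt,
        "n_atoms": traj.n_atoms,
        "planted_bundles": int(config.bundle_count),
        "planted_mean_residence_ns": config.mean_residence,
    }

    # --- contacts -------------------------------------------------------
    def _contacts():
        mono = topo.select(kind="ligand", heavy=True)
        analyte_sels = [
            mol[topo.is_heavy()[mol]]
            for mol in topo.molecules_of_kind("analyte")
        ]
        series = contact_series(
            traj, analyte_sels, mono, cutoff=config.contact_cutoff
        )
        count, records = contacting_molecules(
            series, dt=config.dt, min_duration=config.min_contact_duration
        )
        return series, count, records

    if config.n_analytes:
        series, count, records = _stage("contacts")(_contacts)
        report["contacts"] = {
            "n_contacting": count,
            "mean_bound_per_frame": float(series.sum(axis=1).mean()),
            "planted_bound_per_frame": float(
                np.mean(truth.bound_counts(traj.times))
            ),
        }
        pd.DataFrame(
            {
                "frame": np.arange(traj.n_frames),
                "time_ns": traj.times,
                "n_in_contact": series.sum(axis=1),
            }
        ).to_csv(out / "contacts.csv", index=False)

        # --- bridges ----------------------------------------------------
        bridges = _stage("bridges")(lambda: bridge_series(traj, topo))
        report["bridges"] = {
            "mean_salt_plus_water": bridges.mean_total,
            "se_salt_plus_water": bridges.se_total,
            "mean_salt": float(bridges.salt.mean()),
            "mean_water": float(bridges.water.mean()),
            "mean_hbonds": float(bridges.hbonds.mean()),
        }

    # --- monolayer morphology ------------------------------------------
    def _bundles():
        ba = detect_bundles(
            traj, model, config.bundle_angle_cutoff,
            config.bundle_distance_cutoff, config.bundle_min_size,
        )
        lig_sel = topo.select(kind="ligand", heavy=True)
        shapes = shell_shape_series(traj, lig_sel)
        return ba, shapes

    ba, shapes = _stage("bundles")(_bundles)
    mean_b, se_b = ba.mean_bundles()
    mean_f, _ = ba.mean_free()
    report["monolayer"] = {
        "mean_n_bundles": mean_b,
        "se_n_bundles": se_b,
        "mean_n_free": mean_f,
        "mean_kappa2": float(np.mean([s.kappa2 for s in shapes])),
        "mean_asphericity_A2": float(np.mean([s.asphericity for s in shapes])),
        "mean_rg_A": float(np.mean([s.rg for s in shapes])),
    }
    pd.DataFrame(
        {
            "frame": np.arange(traj.n_frames),
            "n_bundles": ba.n_bundles,
            "n_free": ba.n_free,
            "lambda1_A2": [s.eigenvalues[0] for s in shapes],
            "lambda2_A2": [s.eigenvalues[1] for s in shapes],
            "lambda3_A2": [s.eigenvalues[2] for s in shapes],
            "asphericity_A2": [s.asphericity for s in shapes],
            "kappa2": [s.kappa2 for s in shapes],
        }
    ).to_csv(out / "bundles.csv", index=False)

    # --- hydration ------------------------------------------------------
    def _hydration():
        return map_series(
            traj, model, list(config.hydration_distances), topology=topo
        )

    maps = _stage("hydration")(_hydration)
    hyd = []
    rows = []
    for m in maps:
        frac_low, spread = heterogeneity(m)
        hyd.append(
            {
                "probe_distance_A": m.probe_distance,
                "fraction_cells_below_half": frac_low,
                "std_defined_cells": spread,
                "mean_defined": float(np.nanmean(m.values)),
            }
        )
        for ip in range(m.n_phi):
            for ic in range(m.n_costheta):
                if not np.isnan(m.values[ip, ic]):
                    rows.append(
                        (m.probe_distance, ip, ic, m.values[ip, ic],
                         m.frames_counted[ip, ic])
                    )
    report["hydration"] = hyd
    pd.DataFrame(
        rows,
        columns=["distance_A", "phi_bin", "costheta_bin", "value", "n_frames"],
    ).to_csv(out / "hydration.csv", index=False)

    # --- energetics -----------------------------------------------------
    if config.n_analytes:
        def _energy():
            step = max(1, traj.n_frames // config.energy_frames)
            sub = Trajectory(
                coords=traj.coords[::step], times=traj.times[::step],
                elements=traj.elements, box=traj.box, topology=topo,
            )
            receptor = np.arange(model.n_atoms)
            ligand_sel = topo.molecules_of_kind("analyte")[0]
            decomp = binding_free_energy(
                sub, topo, receptor, ligand_sel,
                BindingOptions(temperature=config.temperature),
            )
            return decomp

        decomp = _stage("energy")(_energy)
        h_pol, h_nonpol = polarity_split(decomp)
        report["energy"] = decomp.as_dict()
        report["energy"]["dH_pol"] = h_pol
        report["energy"]["dH_nonpol"] = h_nonpol

    (out / "report.json").write_text(json.dumps(report, indent=1))
    return report
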