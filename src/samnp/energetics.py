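"""End-point binding-energy decomposition (MM + continuum solvation).

Single-trajectory end-point bookkeeping: for each complex frame the
receptor and ligand conformations are the complex's own, so the internal
(bonded) energy change ΔE_int is identically zero and the molecular-
mechanics change ΔE_MM reduces to the inter-selection electrostatic and
van der Waals terms.  Polar solvation uses a generalized-Born model
(HCT effective radii, Still pairwise formula); nonpolar solvation is the
linear SASA model γ·SASA + β with Shrake-Rupley areas.  The decomposition
identities

    ΔE_MM = ΔE_int + ΔE_ele + ΔE_vdW
    ΔG_solv = ΔG_p_solv + ΔG_np_solv
    ΔH = ΔE_MM + ΔG_solv
    ΔG_b = ΔH + (−TΔS)

hold exactly by construction.  Solute entropy is a quasi-harmonic
estimate from the mass-weighted covariance of fluctuations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from . import constants as C
from .geometry import fibonacci_sphere, kabsch
from .topology import Topology
from .trajectory import Trajectory


class SingularityError(ValueError):
    """Two selected atoms (near-)coincide; pair energies diverge."""


# ----------------------------------------------------------------------
# molecular-mechanics pair energies
# ----------------------------------------------------------------------

def mm_pair_energy(frame: np.ndarray, topology: Topology,
                   selection_a: np.ndarray, selection_b: np.ndarray
                   ) -> tuple[float, float]:
    """Inter-selection Coulomb and Lennard-Jones energies (kcal/mol).

    E_ele = Σ k_e q_i q_j / r_ij over all cross pairs
    (k_e = 332.0637 kcal Å mol⁻¹ e⁻²); E_vdW uses 4ε[(σ/r)¹² − (σ/r)⁶]
    with Lorentz-Berthelot combination and no cutoff.
    """
    a = np.asarray(selection_a, int)
    b = np.asarray(selection_b, int)
    if len(a) == 0 or len(b) == 0:
        return 0.0, 0.0
    if np.intersect1d(a, b).size:
        raise ValueError("selections must be disjoint")
    ra = frame[a]
    rb = frame[b]
    d = np.linalg.norm(ra[:, None, :] - rb[None, :, :], axis=-1)
    if d.min() < 1e-6:
        raise SingularityError(
            f"overlapping atoms at distance {d.min():.2e} Å between selections"
        )
    qq = np.outer(topology.charges[a], topology.charges[b])
    e_ele = float(C.COULOMB_CONSTANT * (qq / d).sum())
    sig = 0.5 * (topology.sigmas[a][:, None] + topology.sigmas[b][None, :])
    eps = np.sqrt(
        np.outer(topology.epsilons[a], topology.epsilons[b])
    )
    sr6 = (sig / d) ** 6
    e_vdw = float((4.0 * eps * (sr6 * sr6 - sr6)).sum())
    return e_ele, e_vdw


# ----------------------------------------------------------------------
# generalized Born (HCT radii, Still pairwise energy)
# ----------------------------------------------------------------------

def hct_born_radii(positions: np.ndarray, radii: np.ndarray,
                   scales: np.ndarray, offset: float = 0.0) -> np.ndarray:
    """Effective Born radii by Hawkins-Cramer-Truhlar pairwise descreening."""
    pos = np.asarray(positions, float)
    rho = np.asarray(radii, float) - offset
    n = len(pos)
    if n == 1:
        return rho.copy()
    r = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    np.fill_diagonal(r, np.inf)
    sj = (np.asarray(scales, float) * rho)[None, :]   # descreener radius of j
    rho_i = rho[:, None]
    active = r + sj > rho_i                           # j not engulfed by i
    with np.errstate(divide="ignore", invalid="ignore"):
        lo = np.maximum(rho_i, np.abs(r - sj))
        hi = r + sj
        term = 0.5 * (
            1.0 / lo
            - 1.0 / hi
            + 0.25 * (r - sj * sj / r) * (1.0 / hi**2 - 1.0 / lo**2)
            + 0.5 * np.log(lo / hi) / r
        )
        # atom i strictly inside j's descreening sphere
        inside = sj > rho_i + r
        term = term + np.where(inside, 1.0 / rho_i - 1.0 / lo, 0.0)
    term = np.where(active & np.isfinite(term), term, 0.0)
    integral = term.sum(axis=1)
    inv_eff = np.maximum(1.0 / rho - integral, 1e-6)
    return 1.0 / inv_eff


def gb_polar_solvation(frame: np.ndarray, topology: Topology,
                       selection: np.ndarray,
                       eps_solvent: float = C.EPSILON_SOLVENT,
                       eps_solute: float = C.EPSILON_SOLUTE,
                       offset: float = 0.0) -> float:
    """Still-style generalized-Born polar solvation energy (kcal/mol).

    ΔG = −(k_e/2)(1/ε_in − 1/ε_solv) Σ_ij q_i q_j / f_ij with
    f_ij = sqrt(r² + R_i R_j exp(−r²/(4 R_i R_j))) and HCT effective Born
    radii R; the single-atom limit is the Born ion formula.
    """
    sel = np.asarray(selection, int)
    if len(sel) == 0:
        return 0.0
    q = topology.charges[sel]
    if np.all(q == 0.0):
        return 0.0
    pos = frame[sel]
    try:
        radii = topology.intrinsic_radii[sel]
    except KeyError as exc:
        raise KeyError(f"missing intrinsic radius: {exc}") from None
    scales = np.array(
        [
            C.HCT_SCALE.get(topology.elements[i].upper(), C.HCT_SCALE_DEFAULT)
            for i in sel
        ]
    )
    eff = hct_born_radii(pos, radii, scales, offset)
    d2 = ((pos[:, None, :] - pos[None, :, :]) ** 2).sum(-1)
    rr = np.outer(eff, eff)
    f = np.sqrt(d2 + rr * np.exp(-d2 / (4.0 * rr)))
    tau = 1.0 / eps_solute - 1.0 / eps_solvent
    return float(-0.5 * C.COULOMB_CONSTANT * tau * (np.outer(q, q) / f).sum())


# ----------------------------------------------------------------------
# SASA nonpolar solvation (Shrake-Rupley)
# ----------------------------------------------------------------------

def shrake_rupley_sasa(positions: np.ndarray, radii: np.ndarray,
                       probe: float = C.SASA_PROBE_RADIUS,
                       n_points: int = C.SASA_N_POINTS) -> np.ndarray:
    """Per-atom solvent-accessible surface area (Å²).

    Deterministic golden-spiral test points; a point survives if it lies
    outside every neighbour's solvent-expanded sphere.
    """
    pos = np.asarray(positions, float)
    rad = np.asarray(radii, float) + probe
    n = len(pos)
    sphere = fibonacci_sphere(n_points)
    areas = np.zeros(n)
    if n == 0:
        return areas
    tree = cKDTree(pos)
    r_max = rad.max()
    for i in range(n):
        pts = pos[i] + rad[i] * sphere
        neighbours = [
            j for j in tree.query_ball_point(pos[i], rad[i] + r_max)
            if j != i
        ]
        accessible = np.ones(n_points, bool)
        for j in neighbours:
            d2 = ((pts - pos[j]) ** 2).sum(1)
            accessible &= d2 > rad[j] ** 2
        areas[i] = accessible.mean() * 4.0 * np.pi * rad[i] ** 2
    return areas


def sasa_nonpolar(frame: np.ndarray, topology: Topology,
                  selection: np.ndarray,
                  gamma: float = C.SASA_GAMMA, beta: float = C.SASA_BETA,
                  probe: float = C.SASA_PROBE_RADIUS,
                  n_points: int = C.SASA_N_POINTS) -> float:
    """Nonpolar solvation ΔG_np = γ·SASA + β (kcal/mol)."""
    sel = np.asarray(selection, int)
    if len(sel) == 0:
        return 0.0
    areas = shrake_rupley_sasa(
        frame[sel], topology.intrinsic_radii[sel], probe, n_points
    )
    return gamma * float(areas.sum()) + beta


# ----------------------------------------------------------------------
# quasi-harmonic entropy
# ----------------------------------------------------------------------

# unit helpers for ω = sqrt(k_B T / λ) with λ in amu Å²
_KB_J = 1.380649e-23
_HBAR_J = 1.054571817e-34
_AMU_A2 = 1.66053906660e-27 * 1e-20  # kg m²
_KCAL_PER_J_MOL = 1.0 / 4184.0
_AVOGADRO = 6.02214076e23


def quasiharmonic_entropy(traj: Trajectory, topology: Topology,
                          selection: np.ndarray,
                          temperature: float = C.TEMPERATURE,
                          remove_rigid_body: bool = True) -> float:
    """Quasi-harmonic −T·S of a selection over a trajectory (kcal/mol).

    Frames are superposed on the first frame (mass-weighted, optional) to
    remove rigid-body motion; the mass-weighted covariance eigenvalues λ
    define mode frequencies ω = sqrt(k_B T / λ) whose quantum harmonic-
    oscillator entropies are summed.  Zero-variance (rigid) modes are
    excluded.  Requires at least 10 frames per selected degree of freedom.
    """
    sel = np.asarray(selection, int)
    n_dof = 3 * len(sel)
    required = 10 * n_dof
    if traj.n_frames < required:
        raise ValueError(
            f"quasi-harmonic entropy needs >= {required} frames for "
            f"{n_dof} degrees of freedom; got {traj.n_frames}"
        )
    masses = topology.masses[sel]
    x = traj.coords[:, sel, :].astype(float)
    ref = x[0]
    if remove_rigid_body:
        x = np.array([kabsch(f, ref, weights=masses) for f in x])
    flat = x.reshape(len(x), -1)
    w = np.repeat(np.sqrt(masses), 3)
    q = (flat - flat.mean(0)) * w
    cov = q.T @ q / len(q)
    lam = np.linalg.eigvalsh(cov)  # amu Å²
    tol = max(lam.max(), 0.0) * 1e-8 + 1e-12
    lam = lam[lam > tol]
    if len(lam) == 0:
        return 0.0
    s_total = 0.0  # kcal/mol/K
    kt_j = _KB_J * temperature
    for l in lam:
        omega = math.sqrt(kt_j / (l * _AMU_A2))  # 1/s
        xfac = _HBAR_J * omega / kt_j
        if xfac > 500:
            continue
        s_mode = C.KB_KCAL * (
            xfac / math.expm1(xfac) - math.log1p(-math.exp(-xfac))
        )
        s_total += s_mode
    return -temperature * s_total


def harmonic_oscillator_entropy(omega: float,
                                temperature: float = C.TEMPERATURE) -> float:
    """Analytic quantum harmonic-oscillator entropy (kcal/mol/K).

    ``omega`` in rad/s.  Reference for validating the quasi-harmonic
    estimator.
    """
    x = _HBAR_J * omega / (_KB_J * temperature)
    return C.KB_KCAL * (x / math.expm1(x) - math.log1p(-math.exp(-x)))


# ----------------------------------------------------------------------
# full decomposition
# ----------------------------------------------------------------------

@dataclass
class BindingOptions:
    temperature: float = C.TEMPERATURE
    eps_solvent: float = C.EPSILON_SOLVENT
    eps_solute: float = C.EPSILON_SOLUTE
    gamma: float = C.SASA_GAMMA
    beta: float = C.SASA_BETA
    probe: float = C.SASA_PROBE_RADIUS
    sasa_points: int = C.SASA_N_POINTS
    gb_offset: float = 0.0
    compute_entropy: bool = False
    n_blocks: int = 5

    def metadata(self) -> dict:
        return {
            "polar_solvation": "generalized Born (HCT radii, Still equation)",
            "nonpolar_solvation": "gamma*SASA + beta (Shrake-Rupley)",
            "entropy": (
                "quasi-harmonic" if self.compute_entropy else "not computed"
            ),
            "temperature_K": self.temperature,
            "eps_solvent": self.eps_solvent,
            "gamma_kcal_mol_A2": self.gamma,
            "beta_kcal_mol": self.beta,
        }


@dataclass
class EnergyDecomposition:
    """All terms in kcal/mol; ``errors`` holds standard errors per term."""

    e_int: float
    e_ele: float
    e_vdw: float
    e_mm: float
    g_polar: float
    g_nonpolar: float
    g_solv: float
    enthalpy: float
    minus_t_ds: float
    g_bind: float
    errors: dict = field(default_factory=dict)
    n_frames: int = 0
    n_replicas: int = 1
    metadata: dict = field(default_factory=dict)

    def check_identities(self, tol: float = 1e-10) -> None:
        assert abs(self.e_mm - (self.e_int + self.e_ele + self.e_vdw)) < tol
        assert abs(self.g_solv - (self.g_polar + self.g_nonpolar)) < tol
        assert abs(self.enthalpy - (self.e_mm + self.g_solv)) < tol
        assert abs(self.g_bind - (self.enthalpy + self.minus_t_ds)) < tol

    def as_dict(self) -> dict:
        return {
            "dE_int": self.e_int,
            "dE_ele": self.e_ele,
            "dE_vdW": self.e_vdw,
            "dE_MM": self.e_mm,
            "dG_p_solv": self.g_polar,
            "dG_np_solv": self.g_nonpolar,
            "dG_solv": self.g_solv,
            "dH": self.enthalpy,
            "minus_TdS": self.minus_t_ds,
            "dG_b": self.g_bind,
            "errors": dict(self.errors),
            "n_frames": self.n_frames,
            "n_replicas": self.n_replicas,
            "metadata": dict(self.metadata),
        }


def _block_se(series: np.ndarray, n_blocks: int) -> float:
    from .monolayer import block_mean_se

    return block_mean_se(np.asarray(series, float), n_blocks)[1]


def binding_free_energy(trajs: Trajectory | list[Trajectory],
                        topology: Topology,
                        receptor_selection: np.ndarray,
                        ligand_selection: np.ndarray,
                        options: BindingOptions | None = None
                        ) -> EnergyDecomposition:
    """Single-trajectory end-point decomposition, replica-averaged.

    Receptor and ligand conformations are taken from the complex frames,
    so ΔE_int ≡ 0; the remaining terms are per-frame differences
    term(complex) − term(receptor) − term(ligand), averaged over frames
    (block-averaged standard errors) and then across replicas.
    """
    opts = options or BindingOptions()
    if isinstance(trajs, Trajectory):
        trajs = [trajs]
    rec = np.asarray(receptor_selection, int)
    lig = np.asarray(ligand_selection, int)
    if np.intersect1d(rec, lig).size:
        raise ValueError("receptor and ligand selections overlap")
    if len(rec) == 0:
        raise ValueError("receptor selection is empty")

    if len(lig) == 0:
        zero = EnergyDecomposition(
            e_int=0.0, e_ele=0.0, e_vdw=0.0, e_mm=0.0, g_polar=0.0,
            g_nonpolar=0.0, g_solv=0.0, enthalpy=0.0, minus_t_ds=0.0,
            g_bind=0.0, n_frames=sum(t.n_frames for t in trajs),
            n_replicas=len(trajs), metadata=opts.metadata(),
        )
        zero.check_identities()
        return zero

    comb = np.concatenate([rec, lig])
    rep_means: list[dict] = []
    rep_se: list[dict] = []
    total_frames = 0
    for traj in trajs:
        ele, vdw, pol, nonpol = [], [], [], []
        for f in range(traj.n_frames):
            frame = traj.coords[f]
            e, v = mm_pair_energy(frame, topology, rec, lig)
            ele.append(e)
            vdw.append(v)
            gb_c = gb_polar_solvation(
                frame, topology, comb, opts.eps_solvent, opts.eps_solute,
                opts.gb_offset,
            )
            gb_r = gb_polar_solvation(
                frame, topology, rec, opts.eps_solvent, opts.eps_solute,
                opts.gb_offset,
            )
            gb_l = gb_polar_solvation(
                frame, topology, lig, opts.eps_solvent, opts.eps_solute,
                opts.gb_offset,
            )
            pol.append(gb_c - gb_r - gb_l)
            np_c = sasa_nonpolar(
                frame, topology, comb, opts.gamma, opts.beta, opts.probe,
                opts.sasa_points,
            )
            np_r = sasa_nonpolar(
                frame, topology, rec, opts.gamma, opts.beta, opts.probe,
                opts.sasa_points,
            )
            np_l = sasa_nonpolar(
                frame, topology, lig, opts.gamma, opts.beta, opts.probe,
                opts.sasa_points,
            )
            nonpol.append(np_c - np_r - np_l)
        total_frames += traj.n_frames
        rep_means.append(
            {
                "ele": float(np.mean(ele)),
                "vdw": float(np.mean(vdw)),
                "pol": float(np.mean(pol)),
                "nonpol": float(np.mean(nonpol)),
            }
        )
        rep_se.append(
            {
                "ele": _block_se(ele, opts.n_blocks),
                "vdw": _block_se(vdw, opts.n_blocks),
                "pol": _block_se(pol, opts.n_blocks),
                "nonpol": _block_se(nonpol, opts.n_blocks),
            }
        )

    def agg(key: str) -> tuple[float, float]:
        vals = np.array([m[key] for m in rep_means])
        if len(vals) > 1:
            return float(vals.mean()), float(vals.std(ddof=1) / np.sqrt(len(vals)))
        return float(vals[0]), float(rep_se[0][key])

    e_ele, se_ele = agg("ele")
    e_vdw, se_vdw = agg("vdw")
    g_pol, se_pol = agg("pol")
    g_np, se_np = agg("nonpol")

    minus_t_ds = 0.0
    if opts.compute_entropy:
        vals = []
        for traj in trajs:
            s_c = quasiharmonic_entropy(traj, topology, comb, opts.temperature)
            s_r = quasiharmonic_entropy(traj, topology, rec, opts.temperature)
            s_l = quasiharmonic_entropy(traj, topology, lig, opts.temperature)
            vals.append(s_c - s_r - s_l)
        minus_t_ds = float(np.mean(vals))

    e_int = 0.0  # single-trajectory protocol: bonded terms cancel exactly
    e_mm = e_int + e_ele + e_vdw
    g_solv = g_pol + g_np
    enthalpy = e_mm + g_solv
    g_bind = enthalpy + minus_t_ds
    decomp = EnergyDecomposition(
        e_int=e_int, e_ele=e_ele, e_vdw=e_vdw, e_mm=e_mm,
        g_polar=g_pol, g_nonpolar=g_np, g_solv=g_solv,
        enthalpy=enthalpy, minus_t_ds=minus_t_ds, g_bind=g_bind,
        errors={
            "dE_ele": se_ele, "dE_vdW": se_vdw,
            "dG_p_solv": se_pol, "dG_np_solv": se_np,
        },
        n_frames=total_frames, n_replicas=len(trajs),
        metadata=opts.metadata(),
    )
    decomp.check_identities()
    return decomp


def polarity_split(decomp: EnergyDecomposition) -> tuple[float, float]:
    """Split ΔH into polar and nonpolar parts.

    ΔH_pol = ΔE_ele + ΔG_p_solv;
    ΔH_nonpol = ΔE_vdW + ΔG_np_solv + ΔE_int;  their sum is ΔH exactly.
    """
    h_pol = decomp.e_ele + decomp.g_polar
    h_nonpol = decomp.e_vdw + decomp.g_nonpolar + decomp.e_int
    return h_pol, h_nonpol
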