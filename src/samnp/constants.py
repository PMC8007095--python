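"""Physical constants and model-construction defaults.

All lengths are in angstrom (Å), energies in kcal/mol unless noted, times in
ns.  Harmonic spring constants are stored in kJ mol⁻¹ nm⁻² to match the
convention of the force-field restraint they represent.
"""

from __future__ import annotations

# --- geometric construction defaults -----------------------------------------
N_CORE_ATOMS = 144            # icosahedral gold cluster size (~1.6-1.8 nm core)
AU_NN_SPACING = 2.88          # Å, nearest-neighbour Au-Au spacing on the lattice
AU_AU_BOND_CUTOFF = 2.90      # Å, gold atoms within this distance are bonded
AU_S_BOND_CUTOFF = 3.3        # Å, each thiolate sulfur bonds one gold within this
AU_S_BOND_LENGTH = 2.4        # Å, nominal Au-S bond length used at placement
SPRING_K_KJ_MOL_NM2 = 50000.0  # harmonic constant for Au-Au and Au-S restraints
N_LIGANDS = 50                # thiolate ligands grafted on the core
N_ANALYTES = 30               # analyte copies per complex system
SOLVENT_PADDING = 20.0        # Å, minimum solute-to-box-face distance
WATER_NUMBER_DENSITY = 0.0334  # molecules / Å³ (bulk water at ambient conditions)
CLASH_DISTANCE = 1.5          # Å, minimum heavy-atom distance between molecules
MAX_PLACEMENT_RETRIES = 1000

# --- analysis defaults --------------------------------------------------------
CONTACT_CUTOFF = 5.0          # Å (0.5 nm rule, analyte vs monolayer heavy atoms)
MIN_CONTACT_DURATION = 10.0   # ns, persistence threshold for "contacting"
SALT_BRIDGE_CUTOFF = 4.0      # Å, N(+)...O(-) distance
HBOND_DA_CUTOFF = 3.5         # Å, donor-acceptor distance
HBOND_ANGLE_MIN = 120.0       # degrees, donor-H-acceptor angle
BUNDLE_ANGLE_CUTOFF = 35.0    # degrees, director-angle edge criterion
BUNDLE_DISTANCE_CUTOFF = 5.0  # Å, minimum inter-chain heavy-atom distance
BUNDLE_MIN_SIZE = 3           # chains; smaller connected components = free chains

# --- energetics ---------------------------------------------------------------
TEMPERATURE = 300.0           # K
COULOMB_CONSTANT = 332.0637   # kcal Å mol⁻¹ e⁻²
EPSILON_SOLVENT = 78.5        # water relative permittivity
EPSILON_SOLUTE = 1.0
SASA_GAMMA = 0.00542          # kcal / mol / Å²  (surface-tension coefficient)
SASA_BETA = 0.92              # kcal / mol       (offset)
SASA_PROBE_RADIUS = 1.4       # Å
SASA_N_POINTS = 960
KB_KCAL = 0.0019872041        # kcal / mol / K

# Intrinsic (Born) radii by element, Å.  mbondi-like values; Au from its
# metallic radius.  Used by the generalized-Born and SASA routines.
INTRINSIC_RADII = {
    "H": 1.2,
    "C": 1.7,
    "N": 1.55,
    "O": 1.5,
    "S": 1.8,
    "NA": 1.868,
    "CL": 2.47,
    "AU": 1.66,
}

# HCT descreening scale factors by element (dimensionless).
HCT_SCALE = {
    "H": 0.85,
    "C": 0.72,
    "N": 0.79,
    "O": 0.85,
    "S": 0.96,
}
HCT_SCALE_DEFAULT = 0.8

ATOMIC_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "NA": 22.990,
    "CL": 35.45,
    "AU": 196.967,
}

# --- water geometry (rigid 3-site) --------------------------------------------
WATER_OH_LENGTH = 0.9572      # Å
WATER_HOH_ANGLE = 104.52      # degrees


def default_parameter_table() -> dict:
    """Frozen table of the pipeline's construction/analysis defaults.

    Serves as the single source of truth the run configuration is checked
    against.
    """
    return {
        "core_atoms": N_CORE_ATOMS,
        "n_ligands": N_LIGANDS,
        "au_au_cutoff_A": AU_AU_BOND_CUTOFF,
        "au_s_cutoff_A": AU_S_BOND_CUTOFF,
        "spring_k_kj_mol_nm2": SPRING_K_KJ_MOL_NM2,
        "n_analytes": N_ANALYTES,
        "padding_A": SOLVENT_PADDING,
        "contact_cutoff_A": CONTACT_CUTOFF,
        "min_contact_duration_ns": MIN_CONTACT_DURATION,
        "temperature_K": TEMPERATURE,
    }
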