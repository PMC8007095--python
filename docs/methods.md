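# Methods

`samnp` reconstructs, as testable desk-scale code, the computational
workflow used to study how self-assembled-monolayer (SAM) protected gold
nanoparticles recognize small amphiphilic analytes: rule-based model
construction, monolayer morphology statistics, analyte-contact and bridge
bookkeeping, interfacial hydration mapping, and end-point binding-energy
decomposition.  Real studies of this system rest on hundreds of
nanoseconds of explicit-solvent molecular dynamics; this package replaces
the MD engine with a synthetic-trajectory generator that plants known
ground truth, so every analysis stage can be verified exactly.

## Model construction

**Gold core.**  The core is carved from the Mackay icosahedral lattice
with a nearest-neighbour spacing of 2.88 Å.  The lattice is grown shell
by shell (shell *s* carries 10 s² + 2 sites); the requested atom count is
taken as the sites closest to the lattice centroid, ties broken by
lexicographic coordinate order, and the result is re-centered.  The
default 144-atom core (≈1.6–1.8 nm) is therefore the 147-atom three-shell
Mackay cluster minus the three lexicographically-first outer vertices —
144 is not itself a closed-shell count, so some carve rule is required;
this one preserves the icosahedral habit and is deterministic.  All gold
pairs within 2.90 Å are bonded; Au–Au and Au–S bonds are harmonic
restraints with a single spring constant, 50 000 kJ mol⁻¹ nm⁻²
(a geometry-preserving device, not a chemical force field).  Gold–sulfur
staple motifs are deliberately not modeled.

**Anchor placement.**  "Uniformly distributed" sulfur head groups are
realized by Thomson-style repulsion minimization: *n* points on the unit
sphere minimizing Σ 1/d by L-BFGS with several seeded restarts.  Each
relaxed direction is matched to a distinct surface gold atom (an atom
with fewer than 12 lattice neighbours) by optimal one-to-one assignment
on angular separation; the sulfur sits at the gold's radial distance plus
2.4 Å along its relaxed direction, and the Au–S distance must not exceed
3.3 Å.  Optimal assignment, rather than greedy matching, avoids an
order bias that can push the last anchors past the 3.3 Å rule at 50
ligands.  Note one genuine non-monotonicity of this construction: the
minimal pairwise angular separation of Thomson minimizers is *not*
strictly decreasing in *n* (the n = 12 icosahedron has a larger minimal
separation than the n = 11 optimum); the tests allow this.

**Grafting.**  Ligand templates store an all-trans reference geometry
built from ideal bond lengths and angles (chain axis +z, sulfur at the
origin).  Each ligand is rotated so its axis follows the outward anchor
direction; the azimuth about that axis is fixed by the nearest
neighbouring anchor direction, which makes the whole build equivariant
under rigid rotation of the inputs.  Heavy-atom clashes below 1.5 Å
between different chains trigger a deterministic 15°-step torsional
back-off; a clash that survives a full turn aborts the build.

**Solvation.**  Analytes are dropped at random positions/orientations in
a shell outside the monolayer with clash rejection (1000 bounded
retries); the orthorhombic box leaves at least the configured padding
(default 20 Å) between every solute atom and each face; water is a rigid
3-site geometric species (0.9572 Å / 104.52°, TIP3P-like charges) on a
jittered cubic lattice at 0.0334 molecules Å⁻³, excluded within 2.6 Å of
solute heavy atoms; monovalent Na⁺/Cl⁻ replace random water sites until
the total charge is exactly zero.  Only geometry and charge matter to
the downstream analyses, so no water energetics are implied.

**Templates.**  The bundled S1–S3 / A1–A4 / AN1–AN2 templates are
simplified synthetic topologies: ligands are linear heavy-atom chains
with a sulfonate (−1) or hydroxyl head; aromatic analytes carry an
explicit planar six-ring whose plane contains the molecular axis, an
ammonium (+1), carboxylate (−1) or zwitterionic head, and hydrogens only
on hydrogen-bond donors.  Partial charges are formal charges localized
on the charged group — they are not fitted (RESP-quality) charges and
are not meant to reproduce any specific compound's energetics.  All
templates are plain JSON and user-editable.

## Synthetic trajectories

The generator emulates trajectory *statistics*; it is never a physics
engine, which is what keeps its ground truth exact.

* **Monolayer morphology.**  Each ligand is assigned to one of *k*
  bundle axes (Thomson directions; antipodal for k = 2) by anchor
  alignment; per frame its director is drawn from a von Mises–Fisher
  distribution about the bundle axis with concentration κ (k = 0 uses
  each chain's own radial direction, giving an isotropic shell).  Chains
  are rebuilt rigidly along the sampled director with Gaussian thermal
  jitter (default 0.1 Å).  κ is the order/disorder dial: κ ≈ 200 gives
  tightly bundled shells, small κ a disordered one.
* **Analyte kinetics.**  Each analyte alternates bound/unbound with
  exponential dwell times; the bound mean is the `mean_residence`
  parameter (default 20 ns) and the unbound mean is set so the
  stationary bound probability equals `analyte_bound_fraction`.  When
  bound, the analyte is packed parallel to a randomly chosen host chain
  at ≈3 Å minimum distance (strictly inside `contact_distance_bound`,
  default 4 Å), searched laterally with a guaranteed chain-tip fallback
  and kept clear of the gold core; when unbound it is placed inside the
  box with a *minimum-image* distance to the monolayer strictly above
  `contact_distance_unbound` (default 8 Å), so periodic and direct
  contact analyses agree exactly with the planted state.  Dwell-time
  recovery uses the right-censored exponential MLE (total bound time /
  completed bouts; a bout starting at t = 0 is complete by construction).
* **Water.**  Water fills a spherical shell around the particle
  uniformly at the configured density and is thinned inside the planted
  bundle cones (default half-angle 40°) by the factor
  1 − `water_penetration`; penetration 1 means uniform hydration,
  0 means bone-dry bundles.
* **Determinism.**  One spec seed feeds five named child streams
  (directors, analytes, water, jitter, axes); identical spec + seed gives
  bitwise-identical ground truth and coordinates.
* **Frame spacing** defaults to 0.1 ns so the 10 ns contact-persistence
  rule spans exactly 100 frames.

What the generator does **not** emulate: force-field energetics of the
motion, analyte–analyte excluded volume, water dynamics, or any real
binding kinetics beyond the two-state exponential picture.  Passing
round-trip tests therefore validates the *analysis* code, not any claim
about real monolayer physics.

## Analyses

**Directors and bundles.**  A director is the unit vector from a
ligand's sulfur to its terminal heavy atom.  Bundles are connected
components of a graph with an edge when the director angle is ≤ 35° *and*
the minimum inter-chain heavy-atom distance is ≤ 5 Å; components with at
least 3 chains are bundles, smaller ones are free chains.  The cutoffs
are parameters; the defaults reproduce the bundled-vs-spherical
dichotomy on synthetic morphologies.  (The number of *bundles* is not
monotone in the angle cutoff — merging several sub-threshold free-chain
components can create a new bundle — but the number of connected
components is, and that is the property tested.)

**Shell shape.**  Gyration tensor of the monolayer heavy atoms about
their centroid: eigenvalues λ₁ ≥ λ₂ ≥ λ₃, R_g = √(λ₁+λ₂+λ₃),
asphericity b = λ₁ − (λ₂+λ₃)/2, acylindricity c = λ₂ − λ₃, and relative
shape anisotropy κ² = (b² + ¾c²)/(λ₁+λ₂+λ₃)².  Ensemble statistics use
every stored frame with 5-block standard errors.

**Contacts.**  An analyte is in contact at a frame when the minimum
heavy-atom distance (both sides heavy; the rule's analyte side is a
documented convention) to the monolayer is strictly below 0.5 nm,
minimum-image when a box is present.  A molecule is "contacting" when it
has at least one maximal run of consecutive contact frames strictly
longer than 10 ns — no gap tolerance, and exactly 10 ns does not
qualify.

**Bridges.**  Salt bridges are ammonium-N/sulfonate-O pairs within
4.0 Å.  Hydrogen bonds are geometric: donor–acceptor ≤ 3.5 Å and
donor–H–acceptor angle ≥ 120°.  A water bridge is a water simultaneously
hydrogen-bonded to at least one sulfonate oxygen (water as donor) and
one ammonium group (N–H donating to the water oxygen).  The pooled
"salt + water" statistic is summed per frame and averaged over frames
(and replicas); both per-frame series and the pooled mean are reported
because averaging over analytes instead of frames is also defensible.

**Radial overlap.**  Normalized histograms of distance-from-core-center
for two flagged groups; overlap = Σ min(p_A, p_B)·Δr ∈ [0, 1].

**Parallel orientation.**  For each bound analyte, the angle between its
aromatic best-fit plane (SVD) and the nearest ligand's heavy-atom
principal axis; 0° means the ring plane contains the chain axis.

**Hydration maps.**  On a probe sphere at distance *d* from the gold
surface (radius = mean radial position of surface gold atoms + *d*),
each cell of an equal-area 72 × 36 (φ, cos θ) grid selects, among water
oxygens and thiol carbons whose angular coordinates fall in the cell
*and* whose radius lies within ±5 Å of the probe radius, the atom
minimizing |r − probe radius|; the indicator is 1 for water, 0 for
carbon, averaged over frames.  Cells that never receive a candidate are
*undefined* (never zero — zero would falsely read "carbon always
closest").  The per-cell search and the radial candidate window are
documented conventions: the per-cell variant makes the 2-D projection
meaningful, and the window keeps the map local (atoms far from the probe
shell can neither populate nor alter a cell).  Heterogeneity is
summarized as the fraction of defined cells below 0.5 plus their
standard deviation.

## Binding energetics

Single-trajectory end-point decomposition: receptor and ligand
conformations are taken from the complex frames, so the internal
(bonded) change ΔE_int is identically zero and

    ΔE_MM   = ΔE_int + ΔE_ele + ΔE_vdW
    ΔG_solv = ΔG_p_solv + ΔG_np_solv
    ΔH      = ΔE_MM + ΔG_solv
    ΔG_b    = ΔH + (−TΔS)

hold exactly by construction (asserted to 1e-10 on every run).
ΔE_ele is bare Coulomb with k_e = 332.0637 kcal Å mol⁻¹ e⁻², ΔE_vdW is
12-6 Lennard-Jones with Lorentz–Berthelot combination, no cutoff.

**Polar solvation** is a generalized-Born model: Hawkins–Cramer–Truhlar
pairwise descreening for the effective radii (element-wise scale
factors, zero radius offset so the single-atom limit is exactly the Born
ion formula) and the Still pairwise energy
f_GB = √(r² + R_iR_j exp(−r²/4R_iR_j)), ε_solute = 1, ε_solvent = 78.5.
GB stands in for a numerical Poisson–Boltzmann solver by design: it
preserves every decomposition identity and limit the tests exercise,
and the choice is recorded in the output metadata.  **Nonpolar
solvation** is γ·SASA + β with γ = 0.00542 kcal mol⁻¹ Å⁻²,
β = 0.92 kcal mol⁻¹, Shrake–Rupley areas on a deterministic 960-point
golden-spiral quadrature with a 1.4 Å probe.  The fixed quadrature makes
SASA rotation-invariant only to ~1 Å² (≈0.005 kcal/mol after γ); all
other terms are analytically invariant.

**Entropy** is a quasi-harmonic estimate: frames are mass-weighted
Kabsch-superposed on the first frame, the mass-weighted covariance is
diagonalized, each eigenvalue λ defines ω = √(k_BT/λ), and the quantum
harmonic-oscillator entropies are summed (zero-variance rigid modes
excluded).  It needs at least 10 frames per degree of freedom and is off
by default in the pipeline (−TΔS = 0, ΔG_b = ΔH) because desk-scale runs
rarely satisfy that; the estimator is validated against the analytic
oscillator entropy and is pluggable.

ΔH splits into ΔH_pol = ΔE_ele + ΔG_p_solv and
ΔH_nonpol = ΔE_vdW + ΔG_np_solv + ΔE_int, summing to ΔH exactly.
Replicas are averaged with across-replica standard errors; single
replicas use 5-block averaging.

## Numerical conventions and degenerate inputs

Coordinates are Å everywhere; times ns; energies kcal/mol; spring
constants kJ mol⁻¹ nm⁻² as printed in force-field files.  PDB files are
written with occupancy 1.00 / B-factor 0.00; multi-frame XYZ carries the
frame time in the comment line; DCD stores one frame spacing in its
header, so only uniformly spaced trajectories round-trip times through
DCD.  Structure parsers are strict: truncated or malformed records raise
with the line number rather than returning partial data.  Empty
trajectories refuse to serialize.  Map cells without candidates are NaN
and excluded from statistics.  Bundle labels are assigned by each
component's lowest ligand index, making partitions reproducible and
relabeling-invariant.  One master seed spawns per-stage child seeds
(numpy `SeedSequence`), so any stage can be reproduced in isolation.

## Problem sizes

The default test and pipeline configurations use the full 144-atom /
50-ligand / 30-analyte construction but short synthetic trajectories
(tens of frames at 0.1 ns) and reduced water densities; dwell-time
statistics are exercised on planted interval sets at the full 400 ns /
30-analyte scale, where coordinates are not needed.  These sizes are the
package's chosen study conditions for verification; every analysis
accepts arbitrarily longer inputs.

## Known limitations

* The synthetic ligand/analyte chemistry is schematic; absolute energy
  values are not comparable to fitted force fields, only the
  decomposition structure, limits and signs are meaningful.
* GB replaces PB; quantitative polar-solvation values differ from a grid
  PB solver even though all identities and limits agree.
* The bundle-detection cutoffs are conventions; other published bundle
  definitions may count differently on the same shell.
* Analyte–analyte excluded volume is not enforced by the generator.
* DCD time round-trips assume uniform frame spacing.
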