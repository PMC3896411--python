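# Methods

This note records the models behind each estimator, the defaults and
why they were chosen, the numerical choices that affect results, and
what the synthetic-data generators do and do not emulate.

## Scope and assumptions

`barotraj` analyzes pre-computed conformational ensembles; it does not
run dynamics. Three assumptions run through the package:

1. **The ensemble is representative.** Every fluctuation-based
   quantity (compressibility, quasi-harmonic entropy, formation rates)
   treats the supplied frames as equilibrium samples of one state.
2. **Solvation does not change the solute structure.** The free-energy
   cycle evaluates conformational energy in vacuo on solution
   snapshots and adds continuum solvation separately; this is the
   standard decomposition assumption of implicit-solvent end-point
   methods.
3. **Pressure enters through the inputs.** The package compares two
   labeled ensembles ("low" and "high" pressure); nothing in the
   estimators depends on pressure except the water permittivity model.

## Surface, volume, compressibility

SASA and the excluded volume V_ex are both defined by the track of a
spherical probe (default radius 1.4 Å, the conventional water probe)
rolled over the van der Waals surface: V_ex is the volume of the union
of probe-inflated atomic spheres and SASA the exposed area of that
union. Hydrogens carry no spheres; heavy atoms take class radii from a
hybridization/H-count table (sp³ C, sp³ N, S–H: 2.0 Å; sp² C without
H and sp² N with one H: 1.7 Å; sp² C with H and S without H: 1.85 Å;
sp² N with several H: 1.8 Å; O: 1.4 Å). Two classes extend the protein
table so ATP and proline are representable: sp² N without H at 1.7 Å
(ring nitrogens, amide N of proline) and P at 1.9 Å. Radius-class
assignment is template-driven per residue and *errors* on unknown heavy
atoms rather than defaulting, because a silently defaulted radius
biases both area and volume.

SASA integration uses a deterministic generalized-spiral lattice
(default 960 points per atom); V_ex uses grid occupancy with a
centroid-in-sphere test (default 0.25 Å spacing, refusing grids coarser
than 0.5 Å). Both defaults give <1% error against closed-form sphere
fixtures at interactive cost; both quantities are rigid-motion
invariant to well under 0.5%.

κ_T = (⟨V²⟩ − ⟨V⟩²)/(k_B T ⟨V⟩) accepts any positive volume series
(population variance, ≥2 samples; a constant series returns exactly 0).
The pipeline default feeds it the per-frame *excluded volume* series,
i.e. a protein compressibility — values land in the 0.1 GPa⁻¹ decade
typical of globular proteins, far below bulk water's ~0.5 GPa⁻¹. Box
volumes can be substituted (`kappa_source: box`) when the system
compressibility is wanted instead.

## Free-energy decomposition

ΔG = ΔE_conf + ΔΔμ − TΔS between the two pressure labels, with SDs of
differences propagated in quadrature (the alternative — block SDs of
the difference — requires paired frames, which independent simulations
do not provide).

**ΔE_conf** is the difference of window means of the per-frame solute
energy table. The built-in nonbonded evaluator (vacuum Coulomb with
332.0637·q₁q₂/r plus 12-6 Lennard-Jones under Lorentz–Berthelot
combination) exists so synthetic fixtures are self-contained; it is not
a force field and real workflows should supply engine energies.

**Δμ_polar** comes from a finite-difference two-dielectric Poisson
solve: atomic charges spread trilinearly onto a cubic grid (default
0.4 Å, solute + 8 Å margin), face dielectrics by a midpoint-in-sphere
test, Dirichlet boundaries from screened Coulomb sums, red-black SOR
with over-relaxation factor 2/(1 + sin(π/n)) iterated to a relative
residual below 10⁻⁶ (hard failure with the iteration count otherwise).
The reaction-field energy is the difference between the ε-map solve and
a uniform-ε_in solve *on the identical grid*, which cancels the grid
self-energy exactly; the remaining discretization error against the
Born closed form is <5% at 0.4 Å and <2% at 0.2 Å over radii 1.5–4 Å.
The interior dielectric defaults to 2 (electronic polarization of a
protein interior, the common continuum choice); the exterior comes from
the water model below.

**Water permittivity.** A Kirkwood dipole-correlation form
(ε−1)(2ε+1)/9ε = A·n/T is solved for ε, with the correlation strength A
calibrated once so that ambient water (298.15 K, 0.1 MPa, 0.997 g/cm³)
gives ε = 78.4, and the number density n taken from a tabulated
ρ₀(T) at 0.1 MPa combined with Tait isothermal compression
(C = 0.315, B = 299.6 MPa, log₁₀ form). Valid range 270–380 K,
0–200 MPa; ε increases with pressure and decreases with temperature, as
it must.

**Δμ_nonpolar = γ(T)·A** with γ(277 K) = 0.1091 kcal/mol/Å² and a
linear slope of −1.5×10⁻⁴ kcal/mol/Å²/K around that anchor (the
air–water interfacial tension slope near ambient). The van der Waals
attraction term is fixed at zero — its contribution is orders of
magnitude below the other cycle terms.

**Entropy.** S_trans is Sackur–Tetrode (default standard-state volume
1 L/mol, configurable); S_rot the classical rigid rotor (σ = 1 for an
asymmetric protein) with principal moments from the segment-mean
structure; S_int quasi-harmonic: frames are best-fitted to their mean
(two fit–recompute passes), the covariance of mass-weighted coordinates
√m·x is diagonalized, ω_i = √(k_B T/λ_i), and the quantum
harmonic-oscillator entropy (kinetic term included) is summed. The six
smallest eigenvalues are discarded as external modes, as is anything
below 10⁻⁸ amu·Å² (numerical null space). These closed forms are the
standard statistical-mechanics expressions for the three symbol sets
(h, M, V; I_x, I_y, I_z; ω_i). Block averaging splits the frame range
into n contiguous equal blocks (default 5, trailing remainder dropped;
fewer than 2 blocks is an error) and reports mean ± SD of S over
blocks.

Rank deficiency: with fewer frames than 3N the covariance has exact
zero modes; they fall below the eigenvalue floor and contribute
nothing, but a warning recommends ≥10 frames per atom.

## Interactions

Salt bridge: charged N⁺ within ≤3.2 Å (inclusive — the comparison is
"less than or equal", so a pair at exactly 3.2 Å counts) of charged O⁻.
Charged sets come from residue templates (Asp/Glu carboxylate O, Lys
N^ζ, Arg N^ε/N^η, protonated-His N — only residues flagged protonated
in config or aliased as such, since protonation states cannot be
inferred from coordinates), chain termini (free amine N unless
acetylated; carboxylate O/OXT when an OXT is present), and ATP
phosphate oxygens. The α/β/γ phosphate letters are assigned from P–O
bond connectivity (1.9 Å cutoff): the phosphorus esterified to the
ribose carbon chain is α and the chain walks to the terminal γ;
non-bridging oxygens carry the formal charge, bridging esters carry two
letters and no charge.

Classification: ATP-involved bridges bypass the secondary-structure and
subdomain categories and are counted once, in the ATP column — this is
what makes both printed-total identities (ss categories + ATP =
subdomain categories + ATP = total) hold exactly. Protein–protein
bridges classify by the two residues' labels and element ids: same H/E
element → intra-helix/strand; different H/E elements →
inter-helix/strand; one structured, one coil → helix/strand–loop; both
coil → loop–loop.

The fallback secondary-structure assigner is deliberately simple and
replaceable (an external per-residue annotation always wins): helix
when φ∈[−100°,−30°] and ψ∈[−80°,−5°] over runs of ≥4, strand when
φ∈[−180°,−40°] and ψ∈[90°,180°]∪[−180°,−170°] over runs of ≥3,
terminal residues judged on their single defined angle, everything else
coil. It reproduces canonical helix/strand geometries; it is not a
DSSP replacement (no hydrogen-bond pattern analysis).

Hydrogen bonds use common geometric defaults — donor–acceptor ≤3.0 Å
and D–H···A ≥160°, both configurable — chosen because H-bond counts are
used only qualitatively.

Subdomain ranges default to the actin convention SD1 = 1–32 ∪ 70–141 ∪
338–375, SD2 = 33–69, SD3 = 142–180 ∪ 270–337, SD4 = 181–269,
consistent with hinge residues at 141/142 and 336/337; the map must be
total and single-valued over protein residues and is fully overridable.
These boundaries are a convention of this package, not a measured fact.

## Active site

The attack angle θ is measured at P^γ between the *β–γ bridging*
oxygen and the water oxygen: the bridging oxygen defines the in-line
attack axis opposite the leaving group, which is why it, and not a
terminal β-oxygen, anchors the angle (configurable). Eligibility is
strictly θ > 109.3° (the tetrahedral complement); among eligible waters
the minimum-d_Nu one is assigned, ties broken toward the lowest water
residue id. No spatial pre-filter is applied to the water list. The
(θ, d_Nu) surface is a 2° × 0.1 Å histogram converted to
F = −ln(count/max) in k_BT — a ratio, hence invariant under uniform
count rescaling, with the occupied minimum exactly 0 and empty bins
marked NaN.

Mg²⁺ coordination counts oxygens within 2.6 Å (a typical Mg–O bond is
~2.1 Å; 2.6 closes the first shell without reaching the second);
W-type and Q-type patterns are recognized exactly, everything else is
"other".

## Geometry

Superposition is Kabsch (SVD with proper-rotation correction);
selections of <3 atoms or collinear selections are rejected. The
average structure iterates fit-all-frames → recompute mean until the
RMS mean shift is <10⁻⁶ Å (max 100 iterations, hard error otherwise).
RMSF pools squared deviations over frames and the selection atoms of
each residue after per-frame best fit; backbone heavy atoms are
N/Cα/C/O. The propeller torsion runs through the four subdomain
centroids in the order (2, 1, 3, 4) by default — the order and the
centroid selection (backbone atoms) are conventions reported in the
output metadata, because torsions through centroids depend on both.
Rotamer enumeration uses the gauche−/gauche+/trans canonical set
{−60°, 60°, 180°} per χ; farthest-probe selection breaks ties by
lexicographic χ order so results are deterministic. Dihedral
histograms use 5° bins over (−180°, 180°], with wrap-around handled so
no probability mass is lost at the boundary.

## Synthetic data: what it does and does not emulate

The generators produce every input class with ground truth computed
from closed forms or construction rules, never by the code under test:

* **Harmonic ensembles** sample Gaussian displacements along an
  orthonormal internal-mode basis built orthogonal to the six
  rigid-body modes, so the quasi-harmonic estimator recovers the
  prescribed spectrum exactly in expectation; the closed-form entropy
  is the oscillator sum over the prescribed variances. Optional random
  rigid motion per frame exercises superposition removal.
* **Volume series** invert the fluctuation formula — variance =
  κ·k_B·T·⟨V⟩ — and refuse parameters that would make negative volumes
  more likely than 10⁻⁶.
* **Interaction fixtures** place minimal residues from internal
  templates and pin charged atoms at exact separations (out of the
  template plane, solving one- or two-distance constraints); the truth
  block is recomputed from the final geometry with the generator's own
  charged-atom tables and plain distance arithmetic.
* **Active-site fixtures** place an ATP-like triphosphate fragment,
  Mg²⁺ shells and waters at requested (θ, d) to 10⁻⁶, with shell
  waters confined to the low-θ side so they never compete for the
  nucleophile assignment.
* **Born ions** provide the Poisson oracle.

What passing these tests shows: the estimators implement their defining
formulas correctly, with known discretization error. What it does not
show: behavior on real, anharmonic, multi-basin protein ensembles with
explicit solvent — conformational entropy of such systems is known to
be overestimated by quasi-harmonic treatments, real charge
distributions are not point charges at template positions, and real
water structure is not a dielectric continuum. The fixtures are
geometry generators, not physics simulators.

## Problem sizes

Default test and reproduction runs use desk-scale problems chosen to
keep statistical error well inside the asserted tolerances: 10⁵-sample
volume series, 30-atom/5×10⁴-frame harmonic ensembles, Born ions of
radius 1.5–4 Å on 0.4 Å grids, and interaction fixtures of a handful of
residues over ~10 frames. All stages scale to full-protein inputs
(~10³–10⁴ atoms); the Poisson solver and V_ex grid are the
memory-limiting stages at fine spacings.

## Known limitations

* ΔE_conf requires engine-supplied energy tables for real systems; the
  internal evaluator covers fixtures only.
* The Poisson solver is linear, two-dielectric, salt-free: no
  Poisson–Boltzmann ionic screening, no nonlinear response.
* The secondary-structure fallback is φ/ψ-window-based, not
  H-bond-pattern-based.
* Quasi-harmonic S_int assumes one harmonic basin; block averaging
  quantifies sampling noise, not anharmonicity.
* PDB I/O rejects insertion codes and does not read mmCIF or binary
  trajectory formats; the tabular frame format is the intended
  interchange for large ensembles.
* His protonation, acetylated termini and external secondary-structure
  labels must be declared in config; nothing is inferred.
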