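# barotraj

Pressure-perturbation analysis of protein molecular-dynamics ensembles.

Deep-sea organisms live at pressures of tens of MPa, and some of their
proteins — most famously the α-actins of abyssal grenadiers — tolerate
pressures that measurably impair the orthologs of surface species, even
though the sequences differ by only two or three residues. Deciding
*why* requires comparing conformational ensembles of the variants at
low and high pressure: does pressure squeeze the protein (volume,
surface, compressibility)? does it destabilize it (free energy)? does it
rewire its electrostatic contacts (salt bridges) or the catalytic water
geometry at the ATP site? `barotraj` packages the estimators needed to
answer each of those questions from trajectory data, together with
synthetic-data generators that provide analytic ground truth for every
stage, so the whole pipeline is testable without any MD engine.

It is aimed at structural bioinformaticians and simulators who have
conformational ensembles (multi-model PDB or a tabular frame format,
plus per-frame volume/energy tables) and want publication-table-shaped
summaries of pressure effects.

## What it computes

**Volume, surface, compressibility.** The excluded volume V_ex is the
volume of the union of probe-inflated atomic spheres (probe radius
1.4 Å) and SASA is the exposed area of that union, both with a
hybridization/H-count van der Waals radius table (sp³ C/N and S–H 2.0 Å,
sp² C without H 1.7 Å, sp² C with H 1.85 Å, sp² N with one H 1.7 Å, sp²
N with several H 1.8 Å, O 1.4 Å). The isothermal compressibility comes
from equilibrium volume fluctuations,

    κ_T = (⟨V²⟩ − ⟨V⟩²) / (k_B T ⟨V⟩),

reported in GPa⁻¹.

**Free-energy decomposition.** The stability shift between a
low-pressure state N and a high-pressure state H follows a
thermodynamic cycle in which solvation leaves the solute structure
unchanged:

    ΔG = ΔE_conf + ΔΔμ − TΔS

with ΔE_conf the change in mean solute conformational energy (consumed
from per-frame energy tables), Δμ = Δμ_polar + γ·A the solvation free
energy (finite-difference two-dielectric Poisson solve plus a
surface-tension term, γ(277 K) = 0.1091 kcal/mol/Å²; the van der Waals
attraction term is neglected), and S = S_trans + S_rot + S_int the
solute entropy: Sackur–Tetrode translational, classical rigid-rotor
rotational, and a quasi-harmonic internal term in which the
mass-weighted coordinate covariance is diagonalized, each eigenvalue
λ_i defines an effective frequency ω_i = √(k_B T/λ_i), and the quantum
harmonic-oscillator entropy is summed over modes. Entropies are
averaged over contiguous trajectory blocks (default five) for error
bars. The exterior permittivity comes from a Kirkwood dipole-correlation
estimate driven by the water density at the simulated (T, p).

**Interactions.** A salt bridge is a charged-nitrogen/charged-oxygen
pair within 3.2 Å (boundary inclusive; one residue pair may form
several). Bridges are classified by secondary-structure element
(inter-helix/strand, helix/strand–loop, loop–loop, intra-helix/strand)
and by subdomain (inter/intra), with ATP-involved bridges tagged by the
phosphate oxygen they touch (α/β/γ, assigned from phosphorus
connectivity) and counted in their own category. Aggregation yields
per-category mean counts ± SD and per-pair formation rates (fraction of
frames a contact exists). Geometric hydrogen bonds (D–A ≤ 3.0 Å,
D–H···A ≥ 160°) are detected separately for solute–solute and
solute–water pairs.

**Active-site geometry.** Mg²⁺ coordination shells are classified
(W-type: 4 waters + 2 ATP γ-oxygens; Q-type: 3 waters + 2 γ-oxygens +
a side-chain oxygen). The candidate nucleophilic water of ATP
hydrolysis is assigned per frame as the water with minimum d_Nu =
|P^γ–O^w| among those whose attack angle θ = ∠(O^β, P^γ, O^w) exceeds
109.3° (strict), and the (θ, d_Nu) distribution is exported as a
free-energy surface F = −ln(P/P_max) in k_BT.

**Geometry.** Kabsch superposition, pairwise RMSD matrices of average
structures, per-residue RMSF about the iteratively fitted mean, the
subdomain "propeller" torsion through the four subdomain centroids,
side-chain dihedral histograms, canonical rotamer enumeration
({−60°, 60°, 180°} per χ; lysine → 81 states) with farthest-probe
selection, and minimum inter-residue side-chain carbon distances.

## Worked example

```python
import numpy as np
from barotraj import surface_volume as sv, thermo
from barotraj.synthetic_data import gen_volume_series

# compressibility from volume fluctuations: a Gaussian series built to
# encode 0.14 GPa^-1 at 277 K is recovered by the estimator
series = gen_volume_series(mean=7.4e4, target_kappa=0.14,
                           temperature=277.0, n=100_000, seed=42)
print(f"kappa_T = {sv.isothermal_compressibility(series):.3f} GPa^-1")

# free-energy cycle assembly from component means +- SD (kcal/mol)
rows = {
    "Ac1Q": ((16, 85), (575, 43), (13, 15)),
    "Arm": ((-147, 67), (510, 22), (29, 20)),
    "Yaq": ((-153, 92), (535, 25), (30, 11)),
}
for row in thermo.free_energy_table(rows, reference_label="Ac1Q"):
    print(f"{row.label:5s} dG = {row.delta_g[0]:6.0f} +- {row.delta_g[1]:3.0f} "
          f"kcal/mol   ddG vs Ac1Q = {row.delta_delta_g:5.0f}")
```

prints

```
kappa_T = 0.141 GPa^-1
Ac1Q  dG =    578 +-  96 kcal/mol   ddG vs Ac1Q =     0
Arm   dG =    334 +-  73 kcal/mol   ddG vs Ac1Q =  -244
Yaq   dG =    352 +-  96 kcal/mol   ddG vs Ac1Q =  -226
```

The compressibility sits on the scale measured for globular proteins of
this size (0.09–0.15 GPa⁻¹), and the cycle rows show the deep-sea
variants (Arm, Yaq) destabilized far less by pressurization than the
shallow-water reference — the conformational-energy term, not entropy
or solvation, carries the difference.

A command-line interface mirrors the library
(`barotraj fixtures` writes a self-contained synthetic input set;
`barotraj report --config ...` emits the full TSV report bundle —
surface/volume/compressibility, salt-bridge category and ATP-contact
tables, formation rates, RMSF, propeller angle, attack-geometry FES).

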