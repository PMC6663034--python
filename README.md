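# memsorb

Coarse-grained Monte Carlo simulation of protein adsorption on charged
membranes, plus the trajectory statistics used to characterise
membrane-recruitment dynamics.

## The scientific problem

BAR-domain proteins are curved, banana-shaped dimers that bind and deform
membranes. Some of them (e.g. the ACAP1 BAR-PH dimer) are structurally
symmetric in solution yet are recruited to the membrane *asymmetrically*,
with only one end making contact. `memsorb` implements the computational
machinery to study this:

1. **Adsorption sampling.** A rigid united-residue model (one bead per
   residue at the Cα, formal charges +1 for Lys/Arg, −1 for Asp/Glu) is
   sampled above a flat, negatively charged membrane with parallel
   tempering Monte Carlo (PTMC). The bead–surface energy combines a 9-3
   Lennard-Jones wall with linearised Gouy–Chapman screened electrostatics,

   ```
   u_ele(z) = q e σ_s / (ε0 εr κ) · exp(−κ z),      κ⁻¹ = Debye length(IS, T)
   u_vdw(z) = ε_w [ (2/15)(σ_w/z)⁹ − (σ_w/z)³ ]
   ```

   The orientation observable is cos θ, the angle between the outward
   surface normal and the molecule's electric (or hydrophobic) dipole.

2. **Orientation analysis.** Minimum-energy poses are classified into the
   adsorption archetypes *one-end-on*, *two-end-on*, *lying-on-side*,
   *arch-on* and *desorbed*; per-residue contact fractions identify the key
   membrane-binding residues; sampling densities over (cos θ_e, cos θ_h)
   become pseudo free-energy surfaces F = −k_B T ln ρ.

3. **Trajectory statistics.** For all-atom trajectories (multi-MODEL PDB,
   optionally DCD/XTC): salt-bridge and H-bond occupancy tables (acidic
   O···basic N < 4 Å; polar heavy-atom pairs < 3.5 Å within 30° of
   linearity), per-residue contact numbers, pairwise Coulomb/LJ interaction
   energies, Kabsch superposition, RMSD/RMSF profiles, B-factors
   (B = 8π²⟨Δr²⟩/3), PCA with mode-limited correlation matrices, and TICA
   for slow collective modes (segment-aware; lagged pairs never cross
   trajectory boundaries).

A seeded synthetic-data module generates every input class with known
ground truth: charged arcs emulating BAR dimers with tunable end-charge
asymmetry, and planted trajectories with known fluctuations, collective
modes, two-state dynamics and contact occupancies.

## Worked example

```python
import numpy as np
import memsorb as m

# a BAR-like arc: +6e patch on one tip, scattered acidic beads (net -4e)
cg = m.make_arc_protein(m.ASYMMETRIC_ARC)
print(m.net_charge(cg))                  # -4
d = m.dipoles(cg)
print(np.round(d.electric_dipole, 2))    # [-34.6  3.99  0.] e*nm -> points to the charged tip

sp = m.SurfaceParams(scd=-0.127, ionic_strength=0.18)   # C/m^2, mol/L
print(round(sp.debye_length_nm, 3))      # 0.731

cfg = m.PTMCConfig(temperatures=(310.0, 700.0, 1600.0), cycles_total=30_000,
                   cycles_equil=20_000, record_stride=20, box_edge=15.0,
                   init_height=8.0, seed=0)
result = m.run_ptmc(cg, sp, cfg)

from memsorb.orientation import minimum_energy_pose, classify_orientation
pose, energy = minimum_energy_pose(result)
print(round(energy.u_tot, 1))            # -39.2 kJ/mol
print(classify_orientation(pose, cg).label)   # 'one-end-on'
```

The charge-asymmetric arc adsorbs with its positively charged tip on the
negative membrane in essentially every seed, while the mirror-symmetric
control shows no end preference — the same asymmetric-recruitment logic
used for real BAR-PH dimers. The same run works from the shell:

```bash
memsorb synth fixtures --out fixtures --seed 42
memsorb ptmc run fixtures/arc_asymmetric.json --cycles 30000 --seed 0 --out result.npz
memsorb orient analyze result.npz fixtures/arc_asymmetric.json --out report.json
```

To analyse real structures, place PDB files (e.g. entries 5H3D, 2EFK,
1X03) under `data/pdb/` and use `memsorb cg build` /
`memsorb.read_structure`; the net-charge and energy-ordering checks in
`tests/test_acceptance.py` pick them up from there.

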