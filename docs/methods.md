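# Methods

## The adsorption model

A protein is reduced to one interaction site per residue at its Cα
("united-residue" model) and kept rigid: for adsorption orientation the
protein–surface interaction dominates and internal flexibility is
neglected. Each bead carries

* a formal charge at pH 7 (+1 Lys/Arg, −1 Asp/Glu, His and termini
  neutral) — the only assignment consistent with the integer net charges
  quoted for the reference BAR structures;
* a hydrophobicity value (Kyte–Doolittle, shifted to zero mean over the 20
  standard residues, so that the hydrophobic dipole of an "average"
  composition vanishes);
* Lennard-Jones wall parameters, by default a single generic
  σ = 0.5 nm, ε = 0.5 kJ/mol for every residue type.

The membrane is an infinite flat plane at z = 0 with signed surface charge
density σ_s (C·m⁻², negative for membranes) in a 1:1 electrolyte of ionic
strength IS (mol/L). A bead at height z feels

* screened electrostatics from the linearised Gouy–Chapman plane
  potential, `u_ele = q e σ_s/(ε0 εr κ) exp(−κz)` per mole, with
  κ⁻¹ = √(ε0 εr k_B T / 2 N_A e² IS) the Debye length (≈ 0.73 nm at
  0.18 M, 310 K);
* a 9-3 integrated LJ wall `u_vdw = ε_w[(2/15)(σ_w/z)⁹ − (σ_w/z)³]` with
  Lorentz–Berthelot combination of bead and wall parameters (minimum
  ≈ −0.53 kJ/mol per bead at z ≈ 0.43 nm for the defaults).

The parameterisation is fully exposed: published per-residue parameter
sets drop in through the parameter table, and the wall/electrolyte
constants through the surface config. Absolute
adsorption energies depend on that choice — the default parameter set
reproduces the *qualitative* physics (screening with ionic strength,
attraction scaling with surface charge, orientation selection by charge
anisotropy), not any particular published energy in kJ/mol. The screening
temperature and permittivity are physical constants of the surface model;
replica tempering (below) scales only the Metropolis factor.

Both energy terms depend on bead heights only, so the energy is exactly
invariant under lateral translation and rotation about the surface
normal; this gauge invariance is tested.

## Parallel tempering Monte Carlo

Rigid-body poses (COM position + quaternion orientation) are sampled by a
ladder of canonical Metropolis replicas, default temperatures
(310, 500, 800, 1500, 2500) K with 310 K the physical analysis rung. One
cycle = one translation attempt (each COM component uniform within ±step)
plus one rotation attempt (uniform random axis, angle uniform in
[0, step]) per replica. Default protocol: 15×10⁶ cycles with the first
5×10⁶ for equilibration, swap sweeps every 500 cycles over adjacent rungs
with alternating even/odd pairing (satisfies detailed balance), swap
probability min(1, exp[(β_i−β_j)(U_i−U_j)]).

Numerical/sampling choices that were genuinely open:

* **Step adaptation.** Translation and rotation steps adapt independently
  (×1.1 / ×0.9 toward a 0.5 acceptance target, clamped to
  [10⁻⁴, box/2] nm and [10⁻⁴, π] rad) every 1000 cycles during
  equilibration, then freeze, so production samples come from a fixed
  kernel. The per-move-type split matters: moves that cannot change the
  energy (e.g. rotating a spherically symmetric molecule) would otherwise
  drag the joint acceptance estimate.
* **Boundaries.** Lateral coordinates wrap in a 30 nm periodic box; the
  COM height reflects at the box top so the molecule cannot drift out of
  sampling range; any bead at z ≤ 0 is an overlap signal (infinite
  energy, never accepted) rather than an exception.
* **RNG.** One PCG64 stream per replica plus one for swap decisions, all
  spawned from the master seed; streams are a pure function of (seed,
  replica index), so changing the ladder length does not perturb other
  replicas. Runs are bit-reproducible for a given config.
* **Minimum-energy pose.** The reported minimized configuration is the
  lowest-U_tot production sample at the physical rung (ties break to the
  earliest cycle); `polish_pose` optionally refines it by Nelder–Mead over
  height and orientation, and both values can be reported.
* The Metropolis factor uses molar energies with R = 8.314×10⁻³
  kJ/(mol·K), i.e. β = 1/(RT).

## Orientation analysis

"Ends" of an elongated molecule are the first/last 20% of beads ordered
along the principal axis of the bead cloud (the axis is refused, with a
message, if the top two covariance eigenvalues are within a factor 4 —
near-spherical molecules need explicit ends). "Mid" is the central third.
A bead is in contact below 0.7 nm (≈ bead–wall VDW contact). The class
cascade, first match wins: no contact → *desorbed*; mid contact and ≥ half
of all beads in contact → *lying-on-side*; both ends → *two-end-on*;
exactly one end with mid clear → *one-end-on*; remaining mid-involving
patterns → *arch-on*. The half-length rule keeps a fully flat pose (which
necessarily has both tips down) from being read as two-end-on.

Key membrane-binding residues are reported two ways: per-residue contact
fraction over production frames (threshold 0.5 by default) and the
contacts of the single minimized pose — the two notions coincide for
strongly adsorbed systems.

Pseudo free-energy surfaces over any 2D projection are
F = −RT ln(normalised density), min-shifted; empty bins are masked, not
infinite.

## Contact statistics on all-atom trajectories

Definitions: a salt bridge is an acidic oxygen (Asp OD1/OD2, Glu OE1/OE2,
optional OXT) and a basic nitrogen (Lys NZ, Arg NE/NH1/NH2; His optional
and off by default) strictly under 4 Å. A hydrogen bond is a pair of
polar O/N/S heavy atoms under 3.5 Å whose D–H···A arrangement deviates
from linearity by < 30° (the H–D–A convention is selectable; without
hydrogens in the topology a distance-only fallback must be requested
explicitly). Occupancy is the percentage of analysed frames in which a
residue pair has ≥ 1 qualifying event — multiple atom pairs in one frame
count once, symmetric pairs merge, and the 10% reporting threshold is a
presentation filter only (pass 0 to keep everything). Hydrogens are
associated to their donor heavy atom by distance (< 1.25 Å within the
residue), which is robust for standard topologies without needing a bond
table.

Neighbour searches use a KD-tree; the test suite holds the implementation
to *exact set equality* with an all-pairs brute-force oracle on random
frames. Pairwise interaction energies (Coulomb with configurable
dielectric + 12-6 LJ with Lorentz–Berthelot combination, 10 Å cutoff)
require a user-supplied per-atom parameter table; no force field ships
with the package, and absolute values are only as meaningful as that
table.

## Fluctuation and collective-mode statistics

Superposition is closed-form Kabsch (SVD with a determinant correction so
the rotation is always proper). RMSF is computed about the window-mean
structure after iterative alignment (3 passes, which converges for any
realistic trajectory); B = 8π²/3 · RMSF². Note the statistical identity
RMSF = σ√3 for isotropic per-axis noise σ holds only up to the 6/(3N)
variance absorbed by rigid-body alignment — a ~1/N relative bias, which is
why the planted-noise checks use ≥100 residues.

PCA is the eigendecomposition of the 3N×3N covariance of aligned selected
coordinates (via SVD of the centred data), with a deterministic sign
convention (largest-magnitude component positive). Residue–residue
correlation matrices are reconstructed from the leading n modes
(C_ij from the trace of the 3×3 blocks); with all modes this equals the
direct correlation of the raw fluctuations, which is tested.

TICA solves the symmetrized generalized eigenproblem C_τ v = λ C_0 v with
shrinkage regularisation C_0 += 10⁻⁵ tr(C_0)/d · I; components are
ordered by autocorrelation eigenvalue, which for the reversible estimate
is real and ≤ ~1. Input may be several segments (independent
trajectories, or the two protomers of a dimer analysed jointly); lagged
pairs are never formed across a segment boundary. Data are centred on the
global mean, so a persistent offset *between* segments legitimately
appears as a slow coordinate — concatenate only segments meant to share a
state space. The default lag corresponds to 1 ns when the frame stride is
known; there is no universal best lag and it is exposed as a parameter.

## Synthetic study systems and what they do (not) show

The arc generator places beads on a planar circular arc (default 50
beads, radius 6 nm, 1.5 rad — BAR-like dimensions: ~9 nm arc length,
~1.6 nm sagitta). The default study molecules were fixed once, before any
downstream checks, to emulate BAR electrostatics: a +6e patch on one tip
(vs +3e on each tip for the symmetric control), a weakly negative opposite
tip for the asymmetric molecule, and mirror-symmetrically scattered acidic
body beads giving a small negative net charge. The physics this encodes:
lying flat is penalised by the acidic body, so the charged tip(s) select
end-on poses — one-end-on for the asymmetric molecule, two-end-on
(with no end preference across seeds) for the symmetric control.

The planted-trajectory generator produces Cα-only frames = mean chain +
isotropic Gaussian noise + optional orthonormal collective modes
(constructed orthogonal to the 6 rigid-body motions so alignment cannot
absorb them) + optional slow two-state Markov offset + an optional
terminal residue pair toggling between 3.8 Å and 8 Å at a known Bernoulli
rate. Generators are pure functions of their spec including the seed, and
every ground truth a test consumes is emitted by the generator.

These fixtures carry *statistical* structure only — no force-field
realism, no solvent, no correlated anisotropic fluctuations. Passing
tests therefore demonstrate estimator correctness (that RMSF/PCA/TICA/
occupancy recover planted truth, and that the sampler is canonically
correct), not that any particular real protein behaves as predicted.

## Problem sizes of the shipped checks

The library default PTMC protocol is the full 15×10⁶-cycle, five-rung
ladder. The shipped tests and the acceptance script run scaled-down
versions chosen as the smallest sizes at which each statistical criterion
has a comfortable noise margin: 5×10⁵ cycles for the single-bead
Boltzmann check (KS noise ≈ 0.005 against a 0.02 bound), 3×10⁵ for the
replica-exchange comparison, 3×10⁴ cycles × 3 rungs × 10–12 seeds for the
arc recruitment study, 10⁴ frames for occupancy recovery and 4–10×10³
frames for the fluctuation identities.

## Known limitations

* Electrostatics are linearised (Debye–Hückel/Gouy–Chapman); high surface
  charge densities or multivalent ions would need nonlinear
  Poisson–Boltzmann, which is out of scope.
* Single rigid molecule vs surface only: no protein–protein terms, no
  lattice assembly, no membrane curvature.
* Absolute adsorption energies require an externally supplied per-residue
  parameter set; only orderings and orientations are meaningful with the
  generic defaults.
* The H-bond detector trusts topology hydrogens; for heavy-atom-only
  trajectories the distance-only fallback overcounts bent geometries.
* mmCIF is not parsed (PDB only, plus DCD/XTC through the optional
  mdtraj adapter).
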