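# Methods

## The model

`csrefine` refines a protein structure X against experimental backbone
and CB chemical shifts by Markov-chain Monte Carlo under a hybrid energy

    E_hybrid(X, s) = E_FF(X) + E_CS(X, s),

where E_FF is a (pluggable) force-field term and E_CS measures the
disagreement between shifts predicted from X and the measured shifts.
Following the inferential-structure-determination view, E_CS is the
negative log of the likelihood of the data times the priors of the
nuisance parameters.

Per atom type j ∈ {CA, CB, C, HA, H, N}, predicted isotropic shieldings
σ_ij are related to shifts by a linear calibration with zero-centered
normal noise,

    δ_ij = a_j σ_ij + b_j + ε,   ε ~ N(0, s_j²).

Slope and offset carry flat (non-informative) priors and are integrated
out analytically; because the likelihood is exactly Gaussian in (a_j,
b_j), the "Laplace" integral is exact.  The per-type energy in units of
k_B T is

    E_j = (N_j − 2) ln s_j + RSS_j/(2 s_j²) + ½ ln(N_j S_xx,j)
          + (N_j/2 − 1) ln 2π + ln s_j,

with RSS_j the least-squares residual sum of squares of the calibration
line, S_xx,j the centered sum of squares of σ, and the final `ln s_j`
the Jeffreys prior π(s) ∝ 1/s.  The error scales s_j are *sampled* by
MCMC rather than fixed: they set the weight of the data relative to the
force field probabilistically.  The closed form is validated against a
2-D adaptive-quadrature oracle (`numerical_marginal_oracle`), which
integrates the same likelihood in decorrelated (slope,
offset-at-centroid) coordinates; the two agree to ~1e-14 relative.

There is no tunable restraint weight anywhere: marginalization plus
sampled s_j replace it.

### Known property: marginal-likelihood overfitting

Because E_j decreases without bound as RSS_j → 0 at small s_j, a
sufficiently flexible structure could in principle "explain" the noise
of one atom type exactly and drive s_j to zero.  In real applications
this is blocked by the roughness of physical predictors and the
stiffness of molecular-mechanics force fields.  Two guards are built
in: sampled scales are restricted to [0.05, 100] ppm (below shift
measurement precision a scale is meaningless), and the stand-in force
field (below) is stiff enough that residual noise-chasing distorts the
backbone by well under the fluctuation scale of interest.  Some
post-annealing shrinkage of s_j below the generating noise remains —
the same qualitative behaviour as annealed prediction errors being
smaller than starting errors in real refinements — and is visible in
the trajectory traces.

## Degrees of freedom and geometry

The sampler moves backbone dihedrals (φ, ψ), the three backbone bond
angles per residue, side-chain χ angles and the scales s_j; ω is a
represented degree of freedom held near 180° by a planarity restraint
and never moved directly.  Bond lengths are fixed at ideal values
(N–CA 1.458 Å, CA–C 1.525 Å, C–N 1.329 Å).  Cartesian coordinates are
built by sequential NeRF construction; O, amide H, HA and CB follow
from standard local geometry (CB chirality gives ζ = dihedral(CA, N, C,
CB) ≈ +34°, the L-configuration).  Side chains beyond CB exist only as
χ angles: they are predictor features, not atoms.  The build/extract
round trip is exact to < 1e-6 degrees.

## Stand-in force field

Real force fields are out of scope; E_FF is pluggable and the default
stand-in has four cheap terms (energies in k_B·300 K units):

* soft-sphere repulsion, k (r_min − r)² for backbone N/CA/C pairs of
  residues ≥ 2 apart within r_min = 2.6 Å, k = 10 kT/Å²;
* a broad cosine torsion bias favouring the α/β basins
  (2 kT · (1 − cos(φ + 90°)) and 2 kT · (1 − cos 2(ψ + 47°)));
* harmonic bond-angle restraints about the ideal backbone angles
  (0.1 kT/deg²) and an ω-planarity restraint (0.1 kT/deg²);
* an elastic network: harmonic CA–CA distance restraints (all pairs
  with sequence separation ≥ 2, 0.3 kT/Å²) anchored on the *input*
  structure.

The elastic network stands in for the tertiary cohesion of a real force
field around a folded minimum.  Without it, the lever arms of a
polypeptide let per-dihedral adjustments of a few degrees move distal
residues by Ångströms, and the chain slowly drifts while chasing shift
noise; with it, the backbone fluctuates by a few tenths of an Å, the
scale observed when annealing well-minimized structures in real
refinements.  All pairs are restrained (not just contacts) because in
short or elongated chains hinge motions are invisible to a
contact-cutoff network.  The network is a single-minimum surrogate: it
mildly penalizes *any* departure from the input fold, including genuine
corrections toward the true structure, so refinement recovers the local
(dihedral-level) component of structural error rather than global fold
rearrangements — mirroring the small CA-RMSD changes but large
shift-error reductions seen when annealing against real data.

## Monte Carlo protocol

Moves are drawn with the relative weights 20 (uniform side-chain χ) :
30 (local side-chain χ, Gaussian 15°) : 40 (local backbone) : 10
(backbone bond angle, Gaussian 1.5°, rejected outside [90°, 135°]) : 5
(scale move, symmetric in ln s, half-width 0.3); the weights are
normalized internally.  Half of the backbone moves are single-angle
Gaussian steps (3°) and half are crankshaft rotations of C_i/N_{i+1}
about the CA_i–CA_{i+1} axis (15°): the crankshaft is the local
concerted move that changes (ψ_i, φ_{i+1}) while leaving every CA and
the distal chain fixed, standing in for concerted-rotation move sets.
Without a concerted move, cohesion restraints suppress nearly all
backbone acceptance; with it, local dihedral errors equilibrate freely.

Energies are kept in reduced units of k_B T_ref (T_ref = 300 K); the
acceptance probability at simulation temperature T is
min(1, exp(−ΔE·T_ref/T)), so annealing sharpens the full hybrid
posterior.  Simulated annealing lowers T geometrically from 300 K to
3 K, T(i) = 300·(3/300)^(i/n) (linear interpolation available), and
returns the lowest-E_hybrid state visited.  Constant-temperature runs
collect thinned snapshots for ensemble shielding averaging and
cluster-representative extraction (average-linkage agglomerative
clustering of the pairwise CA-RMSD matrix, cut at 1 Å; the member of
the largest cluster minimizing summed CA-RMSD to its cluster is
returned).  Default desk-scale lengths are 2×10⁵ steps (annealing) and
5×10⁴–5×10⁵ (constant temperature); production-scale counts are
config-reachable.  A run is a pure function of (inputs, seed).

Implementation notes: all energies are cached and updated
incrementally (O(1) regression-sum updates per changed shielding;
downstream-block rotations for dihedral moves; a Verlet-style
repulsion neighbour list with 4 Å margin rebuilt every 5000 steps,
when coordinates are also rebuilt from internal coordinates to cancel
the slow numerical drift of composed rotations).  A consistency check
(`SamplerState.check_consistency`) re-derives everything from scratch.

## Synthetic data

The synthetic module closes the loop without any external data.  The
stand-in predictor assigns each atom type a smooth periodic random
field over (φ, ψ) (36×36 grid, bilinear interpolation, exact at nodes),
plus a small smooth function of χ₁ (5% of the field amplitude) and
small fields over the neighbours' (φ, ψ) (15%).  Field RMS amplitudes
are type-typical: CA 3, CB 2, C 2, HA 0.4, H 0.6, N 6 ppm — the spread
of real secondary shifts — with a correlation length of 40°, which
reproduces the ~0.1 ppm/degree backbone sensitivity reported for
QM-derived CA shifts.  True calibrations use slope −1 (shielding
decreases as shift grows) with offsets placing each type in its
realistic ppm range, and noise scales (CA 0.8, CB 1.5, C 1.5, HA 0.19,
H 0.39, N 2.8 ppm) in the regime of a well-refined predictor.

Reference structures draw dihedrals within ±10° of canonical basins
(helix, sheet, or alternating segments) with random sequences.
Perturbed starting structures apply *local* errors by default:
anti-correlated (ψ_i, φ_{i+1}) counter-rotations, the error mode in
which individual dihedrals can be tens of degrees off while the fold
barely moves — the regime of crystal-versus-solution differences,
where a single ~20° φ error can dominate a residue's shift error.
Independent per-angle errors (`mode="independent"`) are also available;
they produce much larger global displacement per degree of error.  The
bisection helper `perturb_to_rmsd` fixes the residue subset and noise
pattern per seed and scales only the amplitude.

What passing the synthetic tests does *not* show: the stand-in
predictor omits ring currents, hydrogen-bond terms and the ruggedness
of interpolated quantum-chemical surfaces, the force field has no
electrostatics or solvation, and real shift tables contain referencing
errors and assignment gaps.  The tests establish that the machinery —
energy, sampler, statistics — behaves correctly under the model's own
assumptions, not that refinement of real proteins will match.

## Evaluation statistics

* Per-type RMSD, Pearson r and regression slope, with outliers removed
  first by Rosner's generalized ESD test (α = 0.05, up to ⌈10% N⌉
  outliers, per type per protein).  r and slope are computed on
  secondary shifts (sequence-corrected random-coil values subtracted
  from both predicted and experimental shifts) to remove the
  residue-type contribution; the subtraction cancels in the RMSD.
* Per-residue ε: root-mean-square of s-normalized shift deviations over
  the atom types available for the residue (unit-less; a deviation of
  exactly s_j in every type gives ε = 1).  Exported to the PDB B-factor
  column for structure colouring.
* Amino-acid-type offsets: the mean over proteins of per-protein mean
  deviations per (residue type, atom type); applied to predictions as
  an opt-in correction.
* Ensemble averaging: arithmetic mean of per-atom shieldings over the
  snapshot ensemble, then per-protein linear calibration against
  experiment.

## Problem sizes

The shipped study runs a 30-residue synthetic protein, 2×10⁵-step
annealing (4 independent seeds, best of by energy), 5×10⁴-step
constant-temperature runs (snapshot stride 500) and the statistical
checks at the sizes stated in their docstrings.  These sizes were
chosen so the whole study reruns from scratch in minutes on one core
while keeping every Monte-Carlo margin comfortable.

## Limitations

* The elastic network biases refinement toward the input fold; global
  rearrangements (domain motions) are out of reach by construction.
* Scale sampling can shrink some s_j to the lower bound on annealed
  structures (see above); interpret annealed s_j as lower bounds on
  prediction error, as one would annealed RMSD values.
* Proline gets no special backbone treatment beyond having no amide H;
  insertion codes, multi-chain and multi-model files are rejected.
* The crankshaft proposal is symmetric in its rotation angle; the small
  Jacobian between the rotation parameter and the internal-coordinate
  measure is neglected (the ensembles produced under a hybrid energy
  are not thermodynamic ensembles in any case).
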