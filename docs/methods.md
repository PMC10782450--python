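# Methods

## The quantity and the pipeline

The homolytic bond dissociation energy of an R–H bond is
`BDE = E(R•) + E(H•) − E(RH)` at 0 K, without vibrational or thermal
corrections. The pipeline computes it per sp³ C–H site: enumerate the
sites on the closed-shell parent, optimize the parent once, delete each
hydrogen in turn to form a doublet radical, optimize each radical
independently, and take `E(H•)` from the calculator's isolated-atom
reference (a single atom has no internal degrees of freedom, so it is
never "optimized"). Only a single geometry per species is considered —
a deliberate simplification relative to a conformer-ensemble free
energy, made for computational economy and because conformational
effects on relative site reactivity are secondary to the primary /
secondary / α-heteroatom distinction.

**sp³ definition.** Purely topological: a carbon with exactly four
neighbours, all through single bonds. A geometric (angle-based)
criterion would misclassify hot MD snapshots; the topological one is
invariant under any distortion that preserves connectivity.

**Hydrogen equivalence.** Morgan-style iterative neighbourhood
refinement: the initial atom label is (element, degree, bond-order
multiset); each round appends the sorted multiset of neighbour labels;
iteration stops when the partition stabilises. Full label tuples are
compared, never hashes, so collisions cannot merge inequivalent atoms.
This is graph-automorphism equivalence, not conformer equivalence —
conservative in the right direction, since BDEs are computed after
relaxation and graph-equivalent sites relax to equivalent minima. The
test suite checks the partition against explicit VF2 automorphism-orbit
enumeration.

## Units

Internal units are fixed globally: Å, kcal/mol, kcal/mol/Å, ps, amu, K.
Conversions (1 eV = 23.0605 kcal/mol; 1 kcal/mol = 418.4 amu·Å²/ps²)
live in `bdekit.units` and are applied only at calculator-adapter
boundaries. Atom indexing is 0-based everywhere; SDF's 1-based indices
are converted on read.

## The toy force field

The built-in calculator is an analytic stand-in for an ab initio or
machine-learned potential, built so that BDEs have closed-form oracles:

- **Bonds:** Morse, `De[(1 − e^{−a(r−r0)})² − 1]`, zero at dissociation
  and minimum −De, so breaking an isolated bond at frozen geometry
  costs exactly De.
- **Angles:** harmonic in θ, tetrahedral rest angles at carbon.
- **Non-bonded:** 12-6 Lennard-Jones on pairs three or more bonds apart
  (and across disconnected fragments); no cutoff or switching — the
  molecules are desk-sized.
- **Atom references:** per-element isolated-atom energies, zero in the
  pinned `toy-v1` set, i.e. total energies are measured from separated
  atoms (negative atomization energies).
- **Radical stabilisation:** the Morse depth of each C–H bond is
  lowered by `ch_radical_stabilization` (3.0 kcal/mol in `toy-v1`) per
  heavy neighbour of its carbon. Without this term every C–H well is
  identical and, because acyclic molecules relax to zero bond/angle
  strain, within-molecule BDE spreads collapse to the ~0.1 kcal/mol of
  1-4 LJ differences — chemically implausible and useless for rank
  studies. With it, methane/primary/secondary/α-O hydrogens span
  ~100/97/94/94 kcal/mol, matching the few-kcal/mol spreads real
  molecules show, which is the scale the rank-noise experiments probe.
- **Open shells:** a radical is evaluated on its own bond graph with
  the identical functional form — the broken bond simply contributes no
  term. There are no explicit spin terms; spin multiplicity is
  bookkeeping.

Torsions are omitted deliberately: they would add parameters without
adding coverage of the BDE machinery. Consequences to keep in mind:
conformer energetics are governed solely by 1-4+ LJ (barriers are soft),
and symmetry-equivalent sites in different conformational environments
can relax to minima differing by ~0.1 kcal/mol. Passing tests on this
generator demonstrate correctness of the *machinery*, not accuracy of
any real potential; the toy surface has none of the anharmonic coupling,
charge redistribution or spin-state structure of a real PES (in real
systems the lowest surface changes character mid-dissociation — a rigid
scan on any single-reference model, including this one, interpolates
smoothly through that region instead of showing the kink).

## Optimization

FIRE (velocity-projection with adaptive timestep) is the default, with
an explicit descent safeguard: a step that raises the energy by more
than `1e-8·(1+|E|)` is rejected, velocities reset and the timestep
halved, so the accepted-step energy log is non-increasing to that
tolerance. Convergence is on the largest per-atom force norm, default
`fmax = 0.05 kcal/mol/Å` (~0.002 eV/Å) — tight enough that
minima-matching RMSDs reflect the surfaces rather than sloppy
convergence. Per-atom displacement per step is capped (0.2 Å default).
FIRE in unit-mass fictitious dynamics is stability-limited by the
stiffest Morse modes (dt_max = 0.08) and converges slowly below
~0.01 kcal/mol/Å on soft LJ-dominated modes; for tight thresholds
`algorithm="bfgs"` (an L-BFGS wrapper with the same force-norm
convergence contract) is the right choice and is what the tight-
tolerance protocols in the tests use. Both paths are deterministic,
never mutate their input, and report non-convergence as an error object
carrying the best-so-far structure and residual force.

## Molecular dynamics

Langevin dynamics uses BAOAB splitting (half-kick, half-drift, exact
Ornstein–Uhlenbeck velocity refresh, half-drift, half-kick), chosen for
its configurational accuracy at moderate timesteps. Friction is in
1/ps; with friction 0 the OU step is the identity and the integrator is
exactly velocity-Verlet NVE (temperature ignored, zero initial
velocities). Masses are most-abundant-isotope values from an embedded
table. Instantaneous kinetic temperature is defined over all 3N degrees
of freedom — the thermostat acts on every component and conserves
neither momentum nor angular momentum, so no degrees are removed; an
NVE-style (3N−6) bookkeeping would overestimate the temperature of a
thermostatted trajectory by 6/(3N−6). Snapshot selection from a
trajectory is `last` (default, deterministic) or seeded `random`.

Energy conservation is measured as *secular* drift — the difference
between time-averaged total energy at the start and end of a run —
because velocity-Verlet exhibits bounded symplectic oscillation of the
total energy that is not drift.

## Cross-relaxation and RMSD

The protocol: `M = opt(S, A)`, `D = opt(S, B)`, `D′ = opt(M, B)`,
`M′ = opt(D, A)`; reported pairs (D,M), (D′,M), (D,M′), (D′,D). RMSD is
Kabsch superposition restricted to proper rotations (det +1; allowing
reflections would mask chirality differences between minima), all atoms
weighted equally, hydrogens included — the strictest plain-Cartesian
choice. The rotation is applied explicitly rather than using the
singular-value shortcut for the residual, which loses ~1e-7 Å to
cancellation.

The engineered validation surface is a pair of quartic double wells
(single mobile atom; basins at closed-form positions; the second
surface's basins offset by a known amount) plus three stiffly tethered
anchor atoms shared by both surfaces. The anchors pin translation and
rotation so superposition RMSDs between relaxed geometries are
meaningful — for a lone atom the Kabsch RMSD is identically zero. All
four protocol RMSDs are checked against Kabsch applied to the
closed-form basin geometries.

## Rank evaluation

Within-molecule BDE ranks use average ranks on ties. Kendall's τ is the
tie-corrected τ-b by default: with deduplication off, symmetry-
equivalent sites produce exactly tied BDEs and the uncorrected τ-a
(available via a flag) would be attenuated by construction. Molecules
with fewer than two sites, or whose reference or predicted vector is
entirely tied (τ undefined), are skipped with a logged note; the mean τ
is unweighted over the remainder. τ's invariance under strictly
monotone transforms of either input is property-tested — it is what
makes rank comparison across methods that predict related but different
quantities (energies vs enthalpies) legitimate.

The default 20-molecule rank battery cycles propane, butane and ethanol
with seeded 0.03 Å coordinate noise. Fully symmetric fixtures (methane,
ethane, neopentane, methanol) have a single equivalence class, hence no
rank information, and would only be skipped.

## Minimum energy paths

Endpoints for methoxy-mediated abstraction are built geometrically: the
methoxy oxygen is placed on the extension of the C→H axis at the
approach distance, methyl pointing away; the product moves the
transferred hydrogen to the O–H distance along the same axis and swaps
the C–H bond for an O–H bond. Atom ordering is identical in both
composites (substrate first, transferred H at its original index,
abstractor last); both are doublets; any non-bonded pair closer than
0.7 Å raises a steric-clash error.

NEB uses the improved (upwind) tangent — the standard remedy for kinked
paths — with spring forces along the tangent and true forces
perpendicular to it; the climbing image feels the inverted parallel
true force and no springs. Defaults: 11 images, k = 10 kcal/mol/Å²,
fmax = 2.3 kcal/mol/Å (0.1 eV/Å converted). Linear Cartesian
interpolation initialises the band. The interior images are relaxed by
FIRE driven by the projected forces; since that force field is
non-conservative, the integrator carries a divergence guard (velocity
reset and timestep reduction when the residual force grows well past
its best value). Exhausting the iteration budget returns
`converged=False` with the band as-is rather than raising —
non-convergence is a result, not an exception.

Validation surfaces: a 2D double well with a curved valley
(`E = h(x²−1)² + c(y−α(1−x²))²  + k_z z²`, first-order saddle at exactly
`h`, deliberately off the straight-line interpolation) and a collinear
A–H···B exchange system with two always-on Morse bonds sharing the
hydrogen plus a harmonic A–B restraint. The restraint is essential: a
bare sum of two Morse terms has no finite saddle (each term is
independently minimisable), while the restrained surface has a genuine
index-1 saddle that a dense grid scan over the two bond lengths locates
by minimax flood fill. NEB barriers are checked against both oracles.

## Numerical choices and degenerate inputs

- Bond perception: `d ≤ scale·(r_cov,i + r_cov,j)`, scale 1.2, embedded
  Cordero-style radii; pairs closer than 0.4 Å are a collapsed-geometry
  error.
- Angle forces guard `sin θ` away from zero (1e-12 floor); collinear
  angles are not expected for the fixtures and would be a parameter
  pathology, not a code path.
- Extended XYZ accepts `energy` and `Energy` keys and writes `energy`;
  lattices are ignored (gas phase only); writes are ASCII with fixed
  decimals.
- All stochastic components (fixture noise, thermostat, snapshot
  selection) take explicit integer seeds and are bit-reproducible.

## Problem sizes

The shipped protocols run on desk-scale inputs: molecules of 5–17
atoms, a 20-molecule rank battery (~156 sites, 50 noise seeds per
amplitude), 10,000-step NVE and 50,000-step Langevin trajectories,
11–13 NEB images, and 100-rotation / 200-vector oracle comparisons.
These sizes were chosen so the full validation cycle completes in about
a minute while every statistical check retains a comfortable margin
(e.g. the rank-noise means are separated by tens of standard errors).

## Known limitations

- The toy FF's conformational landscape is LJ-only; it does not emulate
  torsional barriers, anharmonic mode coupling, or any electronic
  effect beyond the single stabilisation parameter.
- FIRE below ~0.01 kcal/mol/Å on soft modes is slow; use `bfgs`.
- Kabsch RMSD requires identical atom ordering; no graph-matching
  alignment is attempted.
- NEB locates one saddle along the initialised band; multiple competing
  channels need multiple initialisations.
- The CLI's `--calc` accepts only the built-in toy calculator; external
  back ends attach through the library `AdapterSpec` API, which
  converts units at the boundary and fails at construction (not first
  use) when the back end is unavailable.
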