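# Methods

This note records the models behind each analysis, the parameters that
matter, what the synthetic generator does and does not emulate, and the
design choices made where the design was genuinely open. Nothing here
states a number the tests or `scripts/acceptance.py` do not themselves
compute.

## Data model and units

All analyses operate on a minimal in-memory model: `Topology` (atom
names, author residue numbering plus a 0-based residue index, masses),
`Frame` (positions, orthorhombic box) and `Trajectory`. Units are fixed
package-wide — nm, ps, amu — matching GROMACS conventions; PDB Å are
converted on read. Only orthorhombic boxes are supported: the target
systems use rectangular boxes, and general triclinic minimum-image
handling would add complexity without coverage. Masses are inferred from
atom names via a small element table, overridable per atom name, with an
optional default-mass policy for pseudo-atoms. Water is recognised by
residue name (`SOL`, `HOH`, `WAT`, `TIP3`; extensible) because writers
disagree on the dialect.

PDB, XTC and DCD go through MDAnalysis. GRO — including concatenated
multi-frame GRO, the plain-text fixture dialect every synthetic system is
written in — is implemented directly, because trajectory libraries do not
read multi-frame GRO.

## Collective-diffusion permeability

**Model.** The pore region is a cylinder between the mass-weighted COMs
of two Cα rings, recomputed per frame (under Cα position restraints the
region is static; per-frame recomputation is the superset behaviour).
Membership requires axial coordinate in [0, L] *and* radial distance ≤ r;
the default r = 2 nm is chosen to enclose all pore waters, so radial
excursions within a step are deliberately not clipped — only the axial
part of each straight-line inter-frame segment inside [0, L] counts.
Each water is tracked by a single point (oxygen or COM).

**Fit.** ⟨n(τ)²⟩ is averaged over `n_subtraj` (default 100) disjoint
consecutive blocks of `subtraj_len` (default 50 ps), each re-zeroed at
its start, and fitted through the origin over τ ∈ (0, subtraj_len); the
relation has zero intercept by construction, so a free intercept would
only absorb noise. Blocks are disjoint tiles, not sliding windows. The
standard error is a fixed-seed bootstrap over blocks (200 resamples).
Because the mean-squared and squared-mean block statistics are easily
conflated in print, both estimators are exposed
(`estimator="mean_squared"` is the default and the one the diffusion
relation refers to; `"squared_mean"` is biased low since the ensemble
mean of n cancels).

**Permeability.** P_f = v_w · Dₙ · 10¹² / viscosity_scale, the 10¹²
converting ps⁻¹ to s⁻¹. Defaults: v_w = 2.99 × 10⁻²³ cm³ (18.015 g/mol
at 0.997 g/cm³) and viscosity_scale = 2.87 for rigid 3-site water; both
are configurable and recorded in every output. A negative fitted Dₙ is an
error, not a result.

## Synthetic systems and their ground truth

The generator exists so that every analysis has an input with a known
answer; it emulates statistical structure, not physics.

**Pore** (`kind="pore"`). Non-interacting Brownian waters (per-axis step
variance 2·D·dt) around a cylindrical channel through a slab delimited by
two static pseudo-Cα rings. Inside the channel the radial wall reflects;
outside the slab the box is fully periodic, so the two reservoirs are
connected both through the channel and through the periodic z boundary
(the crossing counter distinguishes the two routes). Defaults — box
4 × 4 × 6 nm, channel radius 1 nm, half-length 1 nm (L = 2 nm),
D = 2.3 × 10⁻³ nm²/ps (a TIP3P-like self-diffusion), 112 waters, 10⁴
frames at 0.5 ps — put on average ≈10 waters in the channel, a realistic
occupancy for a wide water-filled pore, and make one run's analysis
protocol exactly 100 × 50 ps. For independent particles the exact
collective diffusion coefficient is Dₙ = N̄·D/L² with N̄ the *measured*
time-average occupancy (the instantaneous occupancy decorrelates over
hundreds of ps, so N̄ scatters a few percent around the geometric
expectation between seeds; using the measured value keeps the oracle
exact per realisation). The expected per-direction crossing rate is the
same quantity, N̄·D/L², in events per unit time.

**Closed pore.** `barrier=True` models the closed conformation as a
*dewetted* channel: the entire slab, channel included, reflects water, so
the distribution splits into two disjoint reservoirs, crossings are
exactly zero and n(t) ≡ 0. A zero-width reflecting mid-plane was
considered and rejected: with the channel still wet, a mid-plane blocks
*transport* but not equilibrium sloshing, and over 50-ps fitting windows
(short against the ~L²/D compartment equilibration time) the measured Dₙ
drops only ~25 % below the open pore — nowhere near the orders-of-
magnitude contrast that distinguishes a sealed carrier, whose closed
structure is dry, from a leaky one. Dewetting is the faithful emulation
of that observation.

**Salt bridge** (`kind="saltbridge"`). Two rigid three-atom
pseudo-residues whose COM separation follows a two-state telegraph
process between a bound mean (0.45 nm) and an unbound mean (0.95 nm)
plus Gaussian noise (0.05 nm), realised as explicit coordinates. The
transition probabilities over one frame use the exact two-state CTMC
propagator (relaxation factor 1 − e^−(k_on+k_off)dt split in proportion
to the stationary weights), so the stationary bound fraction is
k_on/(k_on+k_off) for *any* frame spacing — naive per-rate
discretisation distorts it when k·dt is not small. Noise ≥ half the
state gap is rejected (states must be separable). Note on statistics:
the occupancy estimator's variance exceeds the binomial value by
roughly 2τ_c/dt (τ_c = 1/(k_on+k_off)), so recovery tests use rate
grids with τ_c ≲ dt.

**Binding** (`kind="binding"`). A static site atom plus a bead chain
tethered at a controlled distance, jittered per frame; ground-truth
contact counts are an exhaustive pairwise recount of the generated
coordinates at the 0.35 nm cutoff.

What the generator does **not** emulate: water–water interactions and
incompressibility (waters are ideal particles — collective
anticorrelations of real water are absent), lipids, electrostatics,
protein flexibility (rings are static), 3-site water geometry. Passing
tests therefore demonstrate the correctness of the *analysis machinery*
and its estimators, not force-field realism.

## Conformational metrics

Superposition is weighted Kabsch (SciPy's rotation solver; proper
rotations enforced), mass-weighted by default following the GROMACS
family, with unit weights a flag away. RMSF uses the iterated
time-average structure as reference (superpose → re-average until the
mean shifts < 10⁻⁶ nm), which is the standard definition; frame-0
reference is retained behind a flag. The RMSD reference frame defaults to
the first trajectory frame and is configurable, since published analyses
rarely state the choice.

"Common" PCA concatenates all frames of all trajectories, superposes them
onto the pooled mean, diagonalises one covariance and projects each
trajectory separately — the only construction in which span areas of two
ensembles are comparable, because the axes are shared. The span area is
the convex hull of the (PC1, PC2) projections: parameter-free and
testable, unlike a density contour whose level is one more tunable.
Degenerate hulls (collinear projections) are area 0 with a warning.

## Salt-bridge and binding analyses

Pair distances are between whole-residue mass-weighted COMs (residues
made whole across the periodic boundary first); the captions this
follows speak of residues, not side chains. The formed/broken threshold
defaults to 0.60 nm: bound-state COM plateaus of carrier salt bridges
sit near 0.4–0.5 nm and broken states beyond 0.8 nm, so 0.60 bisects the
gap; classification is plain per-frame — hysteresis would introduce
unstated parameters into a quantity reported as a distance. The EG-motif
symmetry score is the time-averaged coefficient of variation (population
SD over mean) of the triplet's three pairwise distances: zero iff
equilateral every frame. The motif's residue identities are always
config-supplied, never defaulted.

Contacts are inter-group atom pairs within the cutoff (pair-based
counting matches the magnitude of published contact plots; a
unique-atom variant is a flag). Phosphate–arginine statistics average
each replica's analysis window (default the last half — e.g. the last
10 ns of 20-ns replicas, the first half being equilibration), then
across replicas with sample SD (ddof = 1); the "bound" flag at 0.6 nm is
always reported alongside the raw distances so no conclusion silently
depends on the cutoff.

## Water density, volume maps, crossings

The z-density profile counts waters inside a cylinder about the protein
axis (default radius 2 nm, consistent with the permeability region,
since "inside the protein" is otherwise underdefined) and divides by the
bin volume; halving the bin width preserves the region integral exactly.
The occupancy grid is the per-voxel fraction of frames containing a
selected atom — a normalised map, so an isovalue like 0.2 reads directly
as a presence fraction; continuity is 6-neighbour connectivity with the
channel declared continuous iff one component touches both z faces.

Crossings use two-plane hysteresis: a molecule must pass from beyond one
plane to beyond the other while staying within the lateral gate for
every frame between the planes. Entering and retreating, or drifting out
of the gate, aborts; a direct below→above jump through the periodic
boundary is not a traversal. Consecutive-frame displacements are
minimum-image unwrapped, and a step of nearly half the box aborts the
analysis as undersampled. Plane placement is config-supplied, defaulting
to the pore-region ring levels for synthetic systems.

## Pipeline determinism

One top-level seed governs every stochastic element; per-stage sub-seeds
are derived via `SeedSequence` with a CRC of the stage name (stable
across processes, unlike Python's randomised string hash). CSV floats are
written with a fixed format, so a (config, seed, inputs) triple
reproduces every artefact byte for byte; wall-clock metadata lives only
in `report.json`. A failed stage is recorded and later independent
stages still run.

## Problem sizes and numerical notes

The reference analyses use 10⁴-frame, ~130-atom systems — large enough
that the Dₙ block fit has ~10 % relative bootstrap error while a full
open/closed comparison runs in seconds on one core; recovery assertions
are phrased in standard errors, not absolute values, so they scale with
the realisation. Boundary-clipping convergence under stride refinement
is checked on scripted smooth paths: for Brownian paths the clipped
boundary contributions of a non-differentiable trajectory do not
converge at finite refinement (per-event errors of order one sub-step
accumulate as √N_events), so a stride-refinement identity is not a
meaningful invariant there — only the smooth-path form is.

## Known limitations

No triclinic boxes, bonded topologies, velocities or secondary-structure
assignment. The selection grammar is deliberately small (name / resid /
resname / water with boolean combinators). Contact counting is O(N·M)
per frame, adequate for ligand-vs-protein group sizes; a cell-list path
would be needed for all-vs-all on large systems. The synthetic pore's
reflecting-wall scheme handles one reflection per step, so the no-
penetration guarantee is "within one step's displacement", appropriate
for step sizes well below all geometric features.
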