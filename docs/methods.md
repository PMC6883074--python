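# Methods

## Scope and units

The package measures hydration and gating observables on
molecular-dynamics trajectories of a dimeric membrane transporter whose
substrate path is interrupted by a hydrophobic di-leucine constriction
(residues 554/555 of both chains).  It consumes topologies (PDB/GRO) and
trajectories (XTC/DCD/TRR) produced elsewhere; it does not run or set up
simulations.  Internally every length is nm and every time ps; PDB
coordinates (Å) are converted on read.  Boxes are orthorhombic only —
triclinic inputs are rejected with a clear error rather than silently
mishandled.  Frames are held eagerly in one `(n_frames, n_atoms, 3)`
array: at the problem sizes this package targets (10³–10⁴ frames of
solvent-scale systems) this fits trivially in memory and lets every
analysis be vectorised; the iteration API is unchanged if a lazy backend
is ever needed.

Residue numbering follows the topology's author numbering (554 means
transporter residue 554); selections are resolved by the MDAnalysis
selection language on an in-memory topology mirror, so the standard
expressions (`"chain A and resid 554 and name CA"`) work identically on
real and synthetic systems.

## Valve-anchored compartment boxes and crossing events

The analysis volume follows the published construction: a 4 × 4 × 6 nm
density box and, nested inside it, a 2 × 2 × 4 nm flux volume split at
the valve plane into an upper and a central 2 × 2 × 2 nm sub-box.  The
anchor is the centroid of the valve Cα atoms (residues 554 + 555, both
chains) — the only residue-wise construction the geometry admits — and
the valve plane is the axial coordinate of that centroid.  Boxes are
re-anchored at every analysed frame by default so the boundary tracks
the protein as it drifts; a fixed-anchor mode exists for static
reference frames.  Membership is evaluated on the minimum-image
displacement from the anchor with half-open intervals (a point exactly
on the valve plane is *upper*), which makes the partition exhaustive,
exclusive and deterministic.

A water contributes one crossing event per analysed frame pair
(default stride 10 ps) when its label swaps directly between *central*
and *upper*; paths that leave through the box sides contribute nothing.
Both the raw event tally and the unique-molecule tally per interval are
recorded, since with multiple waters crossing in one interval the two
conventions differ.  Replicate summaries report mean ± SEM with the
n − 1 denominator and refuse a single replicate rather than reporting a
zero SEM.

## Synthetic ground truth

Every analysis is validated against generators whose answer is known by
construction, not against another implementation.

**Barrier solvent box.**  Single-site waters (one particle per molecule,
the same convention the flux analysis uses) perform Brownian motion with
per-coordinate step σ per frame.  Defaults describe liquid-water
self-diffusion at the 10 ps analysis stride (D ≈ 2.3·10⁻³ nm²/ps gives
√(2DΔt) ≈ 0.2 nm), 300 waters in a 6 × 6 × 10 nm box, and a 0.15 nm
barrier half-thickness on the order of a leucine side-chain seal.  The
box is periodic in x/y but *reflective* in z: with z-periodicity a
particle could change barrier side by wrapping through the boundary,
which would break the exactness of the event log; reflection makes the
barrier plane the only route between compartments.  A proposal that
would carry a particle across the plane is an *attempt*; it succeeds
with the configured probability (reflecting off the far slab face if it
would land inside the slab) and otherwise reflects off the near face.
Every sign change of (z − z₀) between consecutive frames is logged, so
the ground-truth event list is exact, and `count_crossings` at
frame-spacing stride must reproduce it exactly after restriction to the
flux-box footprint.  An 8-atom static scaffold named like the valve
(CA/CB of residues 554/555, chains A/B) marks the anchor so the real
selections run unchanged.

**Rate-matched systems.**  For a zero-thickness barrier the expected
crossings per frame are ρ_z σ √(2/π) · p (ρ_z the linear density along
z, p the acceptance probability), times the lateral footprint fraction,
times a per-axis retention factor 1 − σ√(2/π)/L for the requirement that
the crosser still be inside the footprint one frame later.  The closed
form is first-order in σ/L; measured counts agree with it to within a
few percent, well inside the Poisson fluctuation of the target counts.
This parameterisation produces, e.g., a system with one counted crossing
per 5 ns to emulate a wild-type-like seal with rare single-water
transitions.

**Tethered particles** are drawn i.i.d. per frame from isotropic
Gaussians about fixed anchors, so the true RMSF is √3 σ exactly.
**Distance pairs** sample a Gaussian mixture over separation (truncated
at > 0) along a random direction each frame.  **Shifted pairs** are
rigid translations with the shift vector logged.  All generators are
bit-reproducible from their seed, and fixtures are written through the
standard formats (PDB + XTC + a JSON truth sidecar) so the I/O path is
part of what gets tested.

What the generators deliberately do *not* emulate: electrostatics,
lipids, protein flexibility, water–water correlation, or absolute MD
water counts.  Passing tests therefore demonstrate that the analysis
stack measures what it claims on data with the assumed statistical
structure — not that any particular biological number is reproduced at
desk scale; the published multi-hundred-ns quantities require the
original cluster-scale simulations, which the pipeline accepts unchanged.

## Density and displacement maps

Density is the per-voxel time-averaged water count divided by the voxel
volume; mass consistency (Σ ρ·v = time-averaged in-box count) holds
exactly because voxel indexing and box membership use the same half-open
intervals.  The default voxel edge is 0.1 nm — fine enough to resolve
the ~0.3 nm water diameter while keeping the default grid at
40 × 40 × 60.  The displacement map assigns |r(t+Δt) − r(t)| (minimum
image) to the voxel of the *starting* position with Δt equal to the
10 ps analysis stride; lag and assignment are configurable since other
conventions are defensible.  Replicate grids are averaged voxel-wise;
slices take the nearest voxel plane without interpolation.  Grids export
to OpenDX via GridDataFormats.

## Geometry statistics

Distance series sample minimum-image distances at 1 ns by default, one
series per chain for unqualified pair specs (the two transporter
halves), or a single cross-chain series for qualified specs.  Boxplot
statistics follow the convention of the source figures: the centre line
is the arithmetic *mean* (not the median), the box spans Q1–Q3 with
inclusive linear interpolation (numpy's `linear` method — "second and
third quantiles" is ambiguous, so the convention is pinned and
oracle-tested), and whiskers reach the extremes.  Distance probability
histograms pool replicates, normalise to unit mass, and keep
per-replicate histograms for auditing (the published per-construct point
counts cannot be decomposed exactly from the stated run lengths, so the
composition is emitted rather than assumed).

Salt bridges use the conventional 0.4 nm cutoff between side-chain
charged heavy atoms (Arg NE/NH1/NH2, Lys NZ, His ND1/NE2, Glu OE1/OE2,
Asp OD1/OD2); the criterion is symmetric in residue order and the
cutoff is configurable.  A distance spec that names a side-chain atom
missing from a (possibly mutated) topology fails loudly naming the
residue — silent fallback to Cα would corrupt mutant comparisons.

The valve axial shift is the difference of valve-centroid coordinates
along the membrane normal.  When a fit selection is supplied
(conventionally the transmembrane-domain Cα atoms, which stay put while
the valve moves) the second structure is first superposed onto the
first by least-squares (Kabsch); without one the structures are taken as
already sharing a reference frame — necessary for rigidly related test
pairs, where aligning on the moving atoms would cancel the very shift
being measured.  The valve "gap" between the halves is the distance
between per-chain backbone centroids of residues 554–555; both the
residue window and the atom set are configurable since the published
definition is not atom-resolved.

## RMSF and SASA

RMSF removes rigid-body motion by superposing every frame onto the mean
structure (two passes: onto frame 0, then onto the resulting mean) with
a batched Kabsch implementation, then evaluates √⟨|r_i − ⟨r_i⟩|²⟩ on the
target Cα atoms and averages replicate profiles.  The fit can be
skipped (`fit_selection=None`) when frames already share a reference —
the correct choice for the tethered generator, which has no rigid-body
motion to remove; with very few fit atoms the superposition itself
absorbs part of the fluctuation (6 rigid-body degrees of freedom out of
3N), a bias of order 3/N that the no-fit mode avoids in parameter-
recovery tests while a separate property test verifies exact invariance
of the fitted RMSF under added rigid-body motion.

SASA uses the Shrake–Rupley sphere-point method: 960 golden-spiral
points per atom, probe radius 0.14 nm, Bondi van der Waals radii, with
neighbour search via a k-d tree.  A point is buried if strictly inside
any neighbour's solvent sphere; exact surface ties (degenerate
coincident atoms) are awarded to the lower-index atom so duplicates are
not double-counted.  The implementation is checked against the closed
form for an isolated sphere (within 2%) and against an independent
Monte-Carlo surface-point oracle on random multi-sphere toys (within
3%).  The cavity series sums per-atom SASA over a user-supplied list of
cavity-lining residues filtered by polarity class, computed against the
whole topology so occlusion by the rest of the protein counts.  The
polarity table assigns ALA/VAL/LEU/ILE/PHE/MET/TRP/PRO hydrophobic,
GLY and CYS polar (no aliphatic surface / weakly polar thiol),
SER/THR/ASN/GLN/TYR polar, ARG/LYS/HIS positive, ASP/GLU negative; it is
explicit and overridable because the source color-codes rather than
tabulates.  The cavity residue list is a configuration input — the upper
cavity is hand-defined in the source material, and any default list
would be an editorial reconstruction, so none is hard-coded beyond the
valve residues used in examples.  Raw 10 ps series are smoothed with a
1 ns centred running average whose edge windows shrink symmetrically
(even-width windows take one extra trailing sample).

## Pipeline

A YAML run configuration maps construct labels to a topology plus
replicate trajectories, selects analyses and parameters, and fixes the
equilibration cut (default 25 ns, matching the convention of treating
the first 25 ns of production as equilibration).  Validation collects
all errors at once.  Per-replicate artifacts (CSV/DX) are always
written; averaging happens only at the summary layer; SEM fields appear
only with n ≥ 2 replicates.  A failing construct is recorded in the
report and does not abort the others, and reruns of the same
configuration are byte-identical.  The report carries package version,
configuration hash and seed.

## Numerical choices and limitations

* XTC round-trips preserve positions to the format's 10⁻³ nm precision;
  frame count and spacing are preserved exactly.
* Half-open interval conventions make voxel assignment, compartment
  labels and the generator's side convention mutually consistent; the
  flux oracle equivalence is exact, not approximate.
* The crossing-rate closed form is first-order in σ/footprint edge;
  residual bias (measured at a few percent) is far below the Poisson
  noise of the counts it parameterises.
* Acceptance-style checks run at reduced problem sizes (10²–10⁴ frames,
  10²–10³ particles) chosen so each check completes in seconds while
  its statistical test (3σ Poisson bands, 5% recovery tolerances) is
  still sharp.
* The static-structure check against the published inward-facing
  cryo-EM coordinates (RCSB 6ETI) downloads the structure at test time;
  the coordinates are not redistributed with the package, so that single
  test requires network access.
* No permeability coefficients, ion counting, free-energy conversion of
  densities, hydrogen-bond angle criteria, cavity-volume estimation or
  automatic pocket detection: these are outside the package's scope.
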