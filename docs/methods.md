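# Methods

## Scope and conventions

All coordinates are in Å and times in ns, with a right-handed frame whose +z
axis is the membrane normal; the upper leaflet has positive z.  The
interchange formats are deliberately plain text — multi-frame XYZ for
coordinates (1e-3 Å printed precision) and a versioned JSON topology carrying
molecule roles (`ligand`, `phospholipid`, `sterol`, `ganglioside`), leaflet
labels, ring cycles, and H-bond donor/acceptor atom lists.  Inputs are
assumed whole-molecule; no periodic-boundary unwrapping is performed.  A
multi-model PDB importer covers coordinates only; roles and annotations must
come from the JSON topology, and `assign_leaflets` can label leaflets from
frame-0 geometry (molecule mean z vs the bilayer midplane) for imported data.

## Membrane-surface metrics

The membrane "surface" for a species is its **average protrusion**: per
frame, the per-molecule maximum heavy-atom z, averaged over the
upper-leaflet molecules of the species.  This turns a species into a single
height line per frame against which a ligand's mass-weighted COM z can be
compared.  Hydrogens are excluded from protrusion (they carry no structural
information about headgroup reach) but included, mass-weighted, in the COM.

The **contact score** gives each ligand +1 in each frame in which any of its
heavy atoms lies within a cutoff of any heavy atom of a membrane-role
molecule.  Defaults: cutoff 4.0 Å, closed interval (ties count), membrane
roles = phospholipid + sterol + ganglioside.  Both choices are configurable:
"interaction with the surface" has no unique definition, so the package
exposes the distance cutoff, the role set (e.g. excluding ganglioside
atoms), and an alternative COM-below-protrusion mode, and records the
parameters used in every output.  The per-frame implementation uses a k-d
tree over membrane atoms; tests verify exact agreement with an all-pairs
brute-force recomputation on random small systems.

**Insertion onset** is the time of the first frame f where COM ≤ protrusion
holds for `persistence_frames` consecutive frames *and* in at least
`occupancy_min` of all frames from f to the end.  Defaults (10 frames,
occupancy 0.9) encode "inserts and stays inserted" while tolerating brief
excursions; a single-frame dip is never called an onset.  Both parameters
are tunable; the defaults are this package's own convention.

## Interaction geometry

Ring centroids are arithmetic means of ring-atom coordinates; ring normals
are best-fit-plane normals (smallest singular direction of the centered
ring coordinates), compared sign-free with angles folded to [0°, 90°].
A ligand pair is **π-stacked** in a frame iff some ring of one and some
ring of the other have centroid distance ≤ d_max (5.0 Å) and inter-normal
angle ≤ angle_max (30°).  An indole is annotated as two rings (5- and
6-membered) and both are tested.

Contact classes use standard geometric literature criteria, all
configurable, with one classification per heavy partner atom in strict
priority order:

| class | criterion | defaults |
|---|---|---|
| hbond | donor–acceptor heavy distance; D–H–A angle when an explicit H sits ≤ 1.3 Å from the donor, else distance-only | ≤ 3.5 Å, ≥ 120° |
| ch_pi | apolar C (not a donor/acceptor) to ring centroid; elevation from ring plane | ≤ 4.0 Å, ≥ 60° |
| vdw | any heavy-atom pair distance, if nothing above matched | ≤ 4.0 Å |

**Dissociation events** come from a dwell-hysteresis state machine: a pair
is formed at the first run of `dwell_frames` (5) consecutive stacked frames
and dissociated at the first subsequent run of `dwell_frames` frames with
minimum ring-centroid distance ≥ `release_d` (8.0 Å).  The two dwell
requirements prevent flickering series from producing spurious events; an
alternating stacked/unstacked series yields no event at all.

## Tensiometry

The **CMC estimator** fits γ(c) = β₀ + β₁c + β₂(c − b)₊ — continuous at the
knot by construction — minimizing SSR over the break b by a grid over
midpoints of interior data intervals (keeping ≥ 3 points strictly on each
side) followed by bounded scalar minimization in the best bracketing
interval.  The fit is exact (SSR = 0, break recovered to 1e-6) on noiseless
two-segment data, scale-equivariant in concentration, and flags a
`degenerate` solution when |β₂| falls below 0.01 (units of the fitting
axis), i.e. when the data are one straight line and the knot abscissa is
meaningless.  The default abscissa is linear concentration; a log10 mode is
available since isotherm data are often plotted that way.  Uncertainty, when
requested, comes from seeded case-resampling bootstrap (percentile 95% CI).

**Adsorption kinetics** fits π(t) = π₀ + Δπ∞(1 − e^(−kt)) by bounded
nonlinear least squares (Δπ∞, k ≥ 0) with analytic starting values (π₀ from
the first sample, Δπ∞ from the apparent rise, k from the 63%-rise time).
Non-convergence raises an explicit fit failure carrying the initial guess —
never silent defaults.  For a flat trace the model is unidentifiable in k;
the fit then returns Δπ∞ ≈ 0, which is the physically meaningful part.

**ANOVA/Tukey**: F from textbook between/within sums of squares; if all
observations are identical, F = 0 and p = 1 by convention.  Tukey–Kramer
q = |Δmean| / sqrt((MSW/2)(1/nᵢ + 1/nⱼ)) with p-values from
`scipy.stats.studentized_range`; tests pin agreement with statsmodels'
`pairwise_tukeyhsd` to 1e-3.  `include_tukey=False` skips the pairwise table
(the studentized-range integral dominates runtime in simulation loops).

**Monolayer arithmetic**: at equal trough area A and equal surface
pressure, species counts are N = A/a for molecular area a, so the count
ratio of two film formers is a_b/a_a; with ~40 Å² for a sterol and
~1000 Å² for a large ganglioside this gives the 25-fold count asymmetry
used in the analysis scripts.

## Imaging

Aggregates are dark on a light background: pixels at or below the threshold
(Otsu on the ROI histogram by default, or a fixed value) are foreground,
8-connected components under `min_component_px` (25) are discarded as
speckle, and an optional ROI polygon excludes probe/reflection artifacts.
A uniform image under Otsu sets a `degenerate` flag and returns an empty
mask instead of an arbitrary split.  Areas are reported in px² and, via the
squared mm-per-pixel calibration, mm²; both the threshold and filter
parameters are logged in every output.  Measured areas are exactly invariant
under 90° rotations and mirrorings, and match analytic disk areas within 2%
down to radii of a few tens of pixels (discretization dominates below that).

## The synthetic generators

The generators define the validation conditions; they are geometric
stand-ins, not physics.

**Membrane trajectories** are static jittered lattice slabs: phospholipid
head planes at z = ±20 Å (choline N at ±21 Å), sterol hydroxyls slightly
below the plane, and ganglioside headgroups rising above it by a
kind-dependent height (GM1-like +12 Å, GM3-like +8 Å, GT1b-like +16 Å —
values chosen only to create distinguishable geometries).  Molecules sit on
a shuffled lattice with per-frame Gaussian jitter (σ = 0.3 Å).  Ligands are
13-heavy-atom planar indole-like templates (fused 6-/5-rings, hydroxyl,
ethylamine; ring, donor and acceptor annotations emitted in the topology).
Before the onset frame a ligand performs a reflected Gaussian random walk
(σ = 1 Å/frame) above a floor comfortably clear of the tallest headgroup;
from the onset on, each frame is independently a contact frame with
probability `contact_fraction` (drawn i.i.d. and seeded, so the expected
score is binomial and analytically known).  A contact frame places the
ligand just below a phospholipid choline so that both contact definitions
hold simultaneously (min distance ≲ 2 Å ≤ cutoff, COM below the protrusion
line).  Planted dimers hold two parallel rings at 3.5 Å centroid distance
high above the membrane until the dissociation frame, then separate to
12 Å.  All randomness comes from one `numpy.random.default_rng(seed)`
stream per generator; identical spec + seed reproduces outputs bit for bit,
and every generator returns its ground truth (onset frames, exact contact
frame lists, dimer frames) in a sidecar record.

Default study conditions: 250 frames at 0.1 ns/frame (25 ns), 32 POPC + 32
cholesterol per leaflet (1:1), 3 ligands, 80 × 80 × 140 Å box.  The frame
stride behind published score totals is generally not reported alongside
such analyses; 0.1 ns/frame is this package's documented default, not an
assertion about any particular study.

**Tensiometry curves** evaluate the continuous two-segment model at the
spec concentrations plus Gaussian noise (validated surfactant-like:
slope_below < slope_above ≤ 0, ≥ 3 points per segment).  **Kinetics
traces** sample the exponential model; **image series** rasterize dark
disks with linearly shrinking radii (clamped at 0) plus Gaussian intensity
noise, with analytic πr² truth recorded.

What the generators deliberately do *not* emulate: lipid conformational
dynamics, water/ions, periodic images, membrane undulations, partial or
angled insertion geometries, uneven illumination or optical distortion in
images.  Passing tests therefore demonstrate the *estimators'* correctness
on data satisfying the stated geometric model, not force-field-level
realism; on real trajectories the contact cutoff and persistence parameters
in particular should be chosen with the data's noise level in mind.

## Pipeline

A YAML config names a scenario, a global seed, per-system trajectory specs
(or XYZ/JSON paths), and the monolayer/imaging branches.  Per-system seeds
are derived deterministically from the global seed, every stage logs its
parameters, failures are per-stage (successful stages are retained), and
the report's provenance block carries the config hash, seed and package
version, making full runs byte-reproducible for fixed config + seed.  The
shipped `examples/five_system_scenario.yaml` is a fully synthetic
five-system comparison whose planted contact fractions produce the
qualitative affinity ordering GM3 > GM1 > POPC/cholesterol > POPC > GT1b —
it verifies the pipeline end to end by construction and makes no claim
about measured totals.

## Problem sizes

Test and script workloads are sized for a single CPU: 100-seed CMC sweeps,
one 250-frame onset trajectory, 100 random ≤ 20-frame systems for oracle
equivalence, 50-seed contact-fraction recovery on 150-frame systems, 2000
null ANOVA simulations, and 200-frame five-system pipeline runs.  These
sizes are the package's validation conditions; every tolerance stated above
is checked at them in the test suite.

## Known limitations

- The contact-score and insertion definitions are geometric conventions;
  published figures based on visual criteria need not match any particular
  parameterization.
- The H-bond classifier runs distance-only when no explicit hydrogens are
  present (heavy-atom-only topologies), which over-counts bent
  arrangements.
- The CMC model is strictly two-segment; gradual curvature around the break
  biases the knot, and the `degenerate` flag only detects the fully
  collinear case.
- Non-planar rings get best-fit-plane normals; strongly puckered rings make
  the stacking angle criterion less meaningful.
- The bootstrap CI resamples cases and can be short on points near the
  required 3-per-side minimum; such draws are discarded and retried.
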