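# seroraft

Membrane-contact and Langmuir-monolayer analytics for aromatic, amphiphilic
ligands — built around the motivating case of serotonin at ganglioside- and
cholesterol-containing model membranes.

Serotonin is released at concentrations above its water-solubility limit, so
much of it exists as π-stacked aggregates rather than monomers.  Whether a
membrane can capture it then depends on geometry-level events: does the
ligand reach and stay at the bilayer surface, which lipids hold it there, and
can membrane components pry a stacked dimer apart?  On the physicochemical
side the same question appears as monolayer adsorption kinetics, a critical
micellar concentration (CMC), and the dissolution of visible aggregates.
This package provides tested estimators for all of those quantities, plus
seeded synthetic generators with *planted ground truth* so that every
estimator can be validated end to end.

## What it computes

**Trajectory metrics** (multi-frame XYZ + topology JSON; Å / ns; membrane
normal = +z):

- *Average protrusion* of a lipid species: mean over upper-leaflet molecules
  of the per-molecule maximum heavy-atom z — the "membrane surface" line.
- *Ligand COM z*: mass-weighted center, Σmᵢzᵢ/Σmᵢ.
- *Contact score*: per frame, +1 for each ligand with a heavy atom within a
  cutoff (default 4.0 Å, closed interval) of any membrane heavy atom; summed
  over ligands and frames into a trajectory total.
- *Insertion onset*: first time COM ≤ protrusion holds for a persistence
  window (default 10 frames) and in ≥ 90% of the remaining frames.
- *π-stacking*: ring-centroid distance ≤ 5 Å and inter-normal angle ≤ 30°
  (best-fit-plane normals, sign-free); dissociation events via a dwell-based
  two-state machine (release at ≥ 8 Å for 5 consecutive frames).
- *Contact classes*: H-bond (donor–acceptor ≤ 3.5 Å, D–H–A ≥ 120° when an H
  is present), CH-π (apolar C ≤ 4.0 Å from a ring centroid, elevation ≥ 60°),
  van der Waals (≤ 4.0 Å), mutually exclusive in that priority order.

**Monolayer / solution analytics** (CSV tables):

- *CMC*: continuous two-segment least-squares fit of γ(c); the break-point
  abscissa is the CMC, found by SSR grid search plus bounded refinement.
- *Adsorption kinetics*: π(t) = π₀ + Δπ∞(1 − e^(−kt)) by nonlinear least
  squares, with Δπ at any requested endpoint (e.g. 60 min).
- *Group statistics*: one-way ANOVA + Tukey HSD (studentized-range p-values).
- *Monolayer arithmetic*: mole-count ratio of two film formers at equal
  trough area = inverse ratio of their molecular areas.

**Imaging** (grayscale PNG/TIFF): Otsu or fixed-threshold segmentation of
dark aggregates, speckle filtering, ROI polygons, areas in px² and mm².

## Worked example

```python
from seroraft import (TrajectorySpec, TensiometrySpec, gen_membrane_trajectory,
                      gen_tensiometry_curve, compute_contact_score,
                      average_protrusion_series, ligand_com_series,
                      detect_insertion_onset, estimate_cmc)

traj_spec = TrajectorySpec(n_frames=250, dt=0.1, n_ligands=1,
                           onset_frame_per_ligand=(20,),
                           contact_fraction_per_ligand=(1.0,), seed=42)
bundle = gen_membrane_trajectory(traj_spec)
score = compute_contact_score(bundle.trajectory, bundle.topology, cutoff=4.0)
prot = average_protrusion_series(bundle.trajectory, bundle.topology, "POPC")
com = ligand_com_series(bundle.trajectory, bundle.topology,
                        bundle.truth["ligand_molecule_ids"][0])
onset = detect_insertion_onset(com, prot)
print(f"contact-score total: {score.total} / {bundle.trajectory.n_frames}")
print(f"insertion onset: {onset.onset_time} ns (planted 2.0 ns)")

curve = gen_tensiometry_curve(TensiometrySpec(break_point=42.0,
                                              noise_sigma=0.3, seed=1)).curve
est = estimate_cmc(curve)
print(f"estimated CMC: {est.cmc:.2f} mM (planted 42.0 mM)")
```

prints

```
contact-score total: 230 / 250
insertion onset: 2.0 ns (planted 2.0 ns)
estimated CMC: 42.28 mM (planted 42.0 mM)
```

The trajectory plants an insertion at frame 20 (2 ns) with full contact
occupancy afterwards: the score totals the 230 post-onset frames, the onset
detector finds the planted frame exactly, and the CMC estimator recovers the
planted break of a noisy tension curve to a fraction of a mM.

## Analysis scripts

`analysis/01…07` are thin narrative drivers over the library: they generate
the five-system membrane comparison (POPC, POPC/cholesterol, and GM1-/GM3-/
GT1b-like ganglioside systems), score membrane contact and verify the
planted affinity ordering GM3 > GM1 > POPC/cholesterol > POPC > GT1b,
profile insertion onsets (2 / 3 / 14 ns regimes), detect planted dimer
dissociations, estimate the CMC, fit monolayer kinetics with ANOVA/Tukey,
and quantify shrinking aggregates.  Each writes small tables under
`results/`; bulky trajectories and snapshots go to `scratch/`.

The same stages run from a single YAML config through the CLI:

```bash
seroraft run --config examples/five_system_scenario.yaml --format markdown
```

with per-stage subcommands (`simulate-traj`, `score`, `insertion`,
`stacking`, `contacts`, `cmc`, `kinetics`, `stats`, `area`) for individual
steps.

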