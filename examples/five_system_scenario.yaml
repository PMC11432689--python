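# Fully SYNTHETIC five-system membrane comparison.
#
# Emulates the structure of a ganglioside/cholesterol membrane-affinity
# study: three ligands per system, per-frame membrane-contact scoring, and
# planted contact fractions chosen to produce the qualitative affinity
# ordering GM3 > GM1 > POPC/cholesterol > POPC > GT1b in the score totals.
# The totals are planted by construction (they verify the pipeline end to
# end); they are not measurements.
scenario: five-system synthetic membrane comparison
seed: 11
metrics:
  cutoff: 4.0
  persistence_frames: 10
  occupancy_min: 0.9
  protrusion_species: POPC
systems:
  - name: GM3
    trajectory:
      n_frames: 200
      n_popc: 24
      n_chol: 24
      n_ganglioside: 4
      ganglioside_kind: GM3-like
      n_ligands: 3
      onset_frame_per_ligand: [10, 10, 10]
      contact_fraction_per_ligand: [0.9, 0.9, 0.9]
  - name: GM1
    trajectory:
      n_frames: 200
      n_popc: 24
      n_chol: 24
      n_ganglioside: 4
      ganglioside_kind: GM1-like
      n_ligands: 3
      onset_frame_per_ligand: [10, 10, 10]
      contact_fraction_per_ligand: [0.7, 0.7, 0.7]
  - name: POPC/cholesterol
    trajectory:
      n_frames: 200
      n_popc: 24
      n_chol: 24
      n_ligands: 3
      onset_frame_per_ligand: [10, 10, 10]
      contact_fraction_per_ligand: [0.5, 0.5, 0.5]
  - name: POPC
    trajectory:
      n_frames: 200
      n_popc: 48
      n_chol: 0
      n_ligands: 3
      onset_frame_per_ligand: [10, 10, 10]
      contact_fraction_per_ligand: [0.3, 0.3, 0.3]
  - name: GT1b
    trajectory:
      n_frames: 200
      n_popc: 24
      n_chol: 24
      n_ganglioside: 4
      ganglioside_kind: GT1b-like
      n_ligands: 3
      onset_frame_per_ligand: [140, 140, 140]
      contact_fraction_per_ligand: [0.1, 0.1, 0.1]
tensiometry:
  spec:
    break_point: 42.0
    noise_sigma: 0.3
kinetics:
  spec:
    pi0: 20.0
    delta_pi_inf: 10.0
    rate_k: 0.05
    noise_sigma: 0.2
  report_at: 60.0
imaging:
  spec:
    disks: [[70.0, 70.0, 40.0], [180.0, 180.0, 30.0]]
    shrink_rate: 0.6
    n_frames: 7
    noise_sigma: 5.0
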