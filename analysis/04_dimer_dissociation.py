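"""Detect planted π-stacked dimers and their dissociation events.

Aromatic amphiphiles self-assemble face-to-face (π-stacking); contact with
a strong membrane attractor can pry such a dimer apart.  Each synthetic
trajectory here plants a two-ligand dimer (parallel rings, 3.5 Å centroid
separation) that dissociates at a known frame; the detector (stacking:
centroid ≤ 5 Å and inter-normal angle ≤ 30°; dissociation: ring-centroid
distance ≥ 8 Å for 5 consecutive frames) recovers formation and
dissociation to the frame.

Writes results/dimer_events.csv.
"""

from pathlib import Path

import pandas as pd

from seroraft.interaction_geometry import (detect_dissociation_event,
                                           detect_stacking_pairs)
from seroraft.synthetic_data import (DimerSpec, TrajectorySpec,
                                     gen_membrane_trajectory)

ROOT = Path(__file__).resolve().parents[1]

CASES = [
    ("early_dissociation", 0, 20, 101),    # dissociates at 2 ns
    ("mid_dissociation", 5, 60, 202),
    ("late_dissociation", 10, 180, 303),
]


def main() -> None:
    rows = []
    for name, formed, dissociated, seed in CASES:
        spec = TrajectorySpec(
            n_frames=250, dt=0.1, n_ligands=2,
            dimer_spec=DimerSpec((0, 1), dissociate_at_frame=dissociated,
                                 stacked_from_frame=formed),
            seed=seed,
        )
        b = gen_membrane_trajectory(spec)
        (_, series), = detect_stacking_pairs(b.trajectory, b.topology).items()
        ev = detect_dissociation_event(series)
        rows.append({
            "case": name,
            "planted_formed_ns": formed * spec.dt,
            "planted_dissociated_ns": dissociated * spec.dt,
            "detected_formed_ns": ev.formed_at,
            "detected_dissociated_ns": ev.dissociated_at,
            "stacked_frames": int(series.stacked.sum()),
        })
    df = pd.DataFrame(rows)
    (ROOT / "results").mkdir(exist_ok=True)
    df.to_csv(ROOT / "results" / "dimer_events.csv", index=False)
    print(df.to_string(index=False))
    exact = ((df["planted_formed_ns"] == df["detected_formed_ns"])
             & (df["planted_dissociated_ns"] == df["detected_dissociated_ns"]))
    print("\nall events recovered to the frame:", bool(exact.all()))


if __name__ == "__main__":
    main()
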