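"""Insertion profiles: ligand COM vs the POPC protrusion line, with onsets.

Three 25 ns synthetic systems plant insertion onsets at 2, 3 and 14 ns —
the early-/mid-/late-onset regimes a ganglioside comparison produces (a
GM1-like attractor pulls the ligand in almost immediately, a GM3-like one
slightly later, and a GT1b-like system only lets the ligand reach the
membrane surface late).  The onset detector (persistence 10 frames,
occupancy ≥ 0.9 to the trajectory end) recovers each planted onset to the
frame.

Writes results/insertion_onsets.csv and per-system profile tables
results/insertion_profile_<name>.csv (time, COM z, protrusion z).
"""

from pathlib import Path

import pandas as pd

from seroraft.membrane_metrics import (average_protrusion_series,
                                       detect_insertion_onset,
                                       ligand_com_series)
from seroraft.synthetic_data import TrajectorySpec, gen_membrane_trajectory

ROOT = Path(__file__).resolve().parents[1]

SYSTEMS = {
    "GM1_like": (20, 12345),    # onset frame 20 → 2 ns
    "GM3_like": (30, 23456),    # 3 ns
    "GT1b_like": (140, 34567),  # 14 ns
}


def main() -> None:
    rows = []
    (ROOT / "results").mkdir(exist_ok=True)
    for name, (onset_frame, seed) in SYSTEMS.items():
        spec = TrajectorySpec(n_frames=250, dt=0.1, n_ligands=1,
                              onset_frame_per_ligand=(onset_frame,),
                              contact_fraction_per_ligand=(1.0,), seed=seed)
        b = gen_membrane_trajectory(spec)
        prot = average_protrusion_series(b.trajectory, b.topology, "POPC")
        com = ligand_com_series(b.trajectory, b.topology,
                                b.truth["ligand_molecule_ids"][0])
        rep = detect_insertion_onset(com, prot)
        rows.append({
            "system": name,
            "planted_onset_ns": onset_frame * spec.dt,
            "detected_onset_ns": rep.onset_time,
            "occupancy_after_onset": rep.occupancy_after_onset,
        })
        pd.DataFrame({
            "time_ns": com.times,
            "ligand_com_z_A": com.values,
            "popc_protrusion_z_A": prot.values,
        }).to_csv(ROOT / "results" / f"insertion_profile_{name}.csv",
                  index=False)
    df = pd.DataFrame(rows)
    df.to_csv(ROOT / "results" / "insertion_onsets.csv", index=False)
    print(df.to_string(index=False))
    exact = (df["planted_onset_ns"] == df["detected_onset_ns"]).all()
    print("\nall onsets recovered to the frame:", bool(exact))


if __name__ == "__main__":
    main()
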