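"""Per-frame membrane-surface metrics.

The membrane "surface" line for a lipid species is its *average protrusion*:
the per-molecule maximum heavy-atom z (Å), averaged over the upper-leaflet
molecules of that species, per frame.  A ligand's vertical position is its
mass-weighted center (COM) z.  The *contact score* assigns +1 per frame to
every ligand whose heavy atoms come within a cutoff (default 4.0 Å, closed
interval) of any heavy atom of a membrane-role molecule; per-frame scores
sum over ligands and the trajectory total sums over frames.  *Insertion
onset* is the first time the ligand COM drops to or below the protrusion
line and stays there (a persistence window plus an occupancy-to-the-end
requirement guard against transient dips).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .errors import ValidationError
from .trajectory_io import Topology, Trajectory

MEMBRANE_ROLES = ("phospholipid", "sterol", "ganglioside")


@dataclass
class ProtrusionSeries:
    species_label: str
    values: np.ndarray      # Å, per frame
    times: np.ndarray       # ns


@dataclass
class ComZSeries:
    ligand_id: int
    values: np.ndarray      # Å, per frame
    times: np.ndarray


@dataclass
class ContactScoreSeries:
    per_frame: np.ndarray   # int, 0..n_ligands
    per_ligand: dict[int, np.ndarray]  # ligand molecule id → 0/1 per frame
    cutoff: float
    times: np.ndarray

    @property
    def total(self) -> int:
        return int(self.per_frame.sum())


@dataclass
class InsertionReport:
    ligand_id: int
    onset_time: float | None       # ns
    persistence_frames: int
    occupancy_after_onset: float | None


def average_protrusion_series(traj: Trajectory, topology: Topology,
                              species_label: str) -> ProtrusionSeries:
    """Mean over upper-leaflet molecules of the per-molecule max heavy-atom z."""
    mols = [m for m in topology.molecules
            if m.species_label == species_label and m.leaflet == "upper"]
    if not mols:
        raise ValidationError(
            f"no upper-leaflet molecules with species label {species_label!r}"
        )
    heavy = topology.heavy_mask
    per_mol = []
    for m in mols:
        idx = topology.atoms_of(m.id)
        idx = idx[heavy[idx]]
        if idx.size == 0:
            raise ValidationError(f"molecule {m.id} has no heavy atoms")
        per_mol.append(traj.coords[:, idx, 2].max(axis=1))
    values = np.mean(per_mol, axis=0)
    return ProtrusionSeries(species_label, values, traj.times)


def ligand_com_series(traj: Trajectory, topology: Topology,
                      ligand_id: int) -> ComZSeries:
    """Mass-weighted mean z of one ligand per frame."""
    mol = topology.molecule_by_id.get(ligand_id)
    if mol is None:
        raise ValidationError(f"unknown ligand molecule id {ligand_id}")
    idx = topology.atoms_of(ligand_id)
    w = topology.masses[idx]
    if np.any(w <= 0):
        raise ValidationError(f"ligand {ligand_id} has non-positive atomic masses")
    values = traj.coords[:, idx, 2] @ w / w.sum()
    return ComZSeries(ligand_id, values, traj.times)


def compute_contact_score(traj: Trajectory, topology: Topology,
                          cutoff: float = 4.0,
                          membrane_roles: tuple[str, ...] = MEMBRANE_ROLES,
                          mode: str = "distance",
                          protrusion_species: str = "POPC") -> ContactScoreSeries:
    """Per-frame +1 tally of ligands in contact with the membrane surface.

    ``mode="distance"`` (default): a ligand scores in a frame iff the minimum
    heavy-atom distance to any heavy atom of a membrane-role molecule is
    ≤ cutoff (ties at the cutoff count).  ``membrane_roles`` controls whether
    ganglioside atoms count as membrane surface.

    ``mode="com_below_protrusion"``: alternative definition — a ligand scores
    iff its COM z is at or below the average protrusion of
    ``protrusion_species`` that frame.
    """
    if cutoff <= 0:
        raise ValidationError(f"cutoff must be positive, got {cutoff}")
    if mode not in ("distance", "com_below_protrusion"):
        raise ValidationError(f"unknown contact mode {mode!r}")
    ligands = topology.molecules_with_role("ligand")
    if not ligands:
        raise ValidationError("no ligand molecules in topology")
    heavy = topology.heavy_mask

    per_ligand: dict[int, np.ndarray] = {}
    if mode == "com_below_protrusion":
        prot = average_protrusion_series(traj, topology, protrusion_species)
        for lig in ligands:
            com = ligand_com_series(traj, topology, lig.id)
            per_ligand[lig.id] = (com.values <= prot.values).astype(int)
    else:
        mem_idx = np.concatenate([
            topology.atoms_of(m.id) for m in topology.molecules
            if m.role in membrane_roles
        ]) if any(m.role in membrane_roles for m in topology.molecules) else \
            np.empty(0, dtype=int)
        mem_idx = mem_idx[heavy[mem_idx]] if mem_idx.size else mem_idx
        if mem_idx.size == 0:
            raise ValidationError("no membrane heavy atoms in the selected roles")
        lig_idx = {lig.id: topology.atoms_of(lig.id) for lig in ligands}
        lig_idx = {k: v[heavy[v]] for k, v in lig_idx.items()}
        for lig in ligands:
            per_ligand[lig.id] = np.zeros(traj.n_frames, dtype=int)
        for f in range(traj.n_frames):
            tree = cKDTree(traj.coords[f, mem_idx])
            for lig in ligands:
                d, _ = tree.query(traj.coords[f, lig_idx[lig.id]], k=1)
                if d.min() <= cutoff:
                    per_ligand[lig.id][f] = 1
    per_frame = np.sum(list(per_ligand.values()), axis=0).astype(int)
    return ContactScoreSeries(per_frame, per_ligand, cutoff, traj.times)


def detect_insertion_onset(com: ComZSeries, protrusion: ProtrusionSeries,
                           persistence_frames: int = 10,
                           occupancy_min: float = 0.9) -> InsertionReport:
    """First sustained crossing of the ligand COM below the protrusion line.

    Onset = time of the first frame f where COM ≤ protrusion for
    ``persistence_frames`` consecutive frames AND COM ≤ protrusion in at
    least ``occupancy_min`` of the frames from f to the end; ``None`` if no
    such frame exists.
    """
    if persistence_frames < 1:
        raise ValidationError("persistence_frames must be ≥ 1")
    if not (0.0 <= occupancy_min <= 1.0):
        raise ValidationError("occupancy_min must be in [0, 1]")
    if com.values.shape != protrusion.values.shape:
        raise ValidationError(
            f"series lengths differ: COM {com.values.shape[0]} vs "
            f"protrusion {protrusion.values.shape[0]}"
        )
    below = com.values <= protrusion.values
    n = below.size
    for f in range(n - persistence_frames + 1):
        if below[f:f + persistence_frames].all() \
                and below[f:].mean() >= occupancy_min:
            return InsertionReport(com.ligand_id, float(com.times[f]),
                                   persistence_frames, float(below[f:].mean()))
    return InsertionReport(com.ligand_id, None, persistence_frames, None)


def assign_leaflets(traj: Trajectory, topology: Topology,
                    frame: int = 0) -> Topology:
    """Return a topology with leaflets assigned from geometry.

    A membrane-role molecule is "upper" if its mean heavy-atom z on the given
    frame exceeds the bilayer midplane (mean z of all membrane-role atoms);
    ligands keep leaflet "n/a".  Intended for imported data lacking labels.
    """
    from .trajectory_io import Molecule

    mem_idx = [i for i, a in enumerate(topology.atoms)
               if topology.molecule_by_id[a.molecule_id].role in MEMBRANE_ROLES]
    if not mem_idx:
        raise ValidationError("no membrane-role molecules to assign leaflets for")
    midplane = traj.coords[frame, mem_idx, 2].mean()
    new_mols = []
    for m in topology.molecules:
        if m.role in MEMBRANE_ROLES:
            idx = topology.atoms_of(m.id)
            leaflet = "upper" if traj.coords[frame, idx, 2].mean() > midplane \
                else "lower"
            new_mols.append(Molecule(m.id, m.species_label, m.role, leaflet))
        else:
            new_mols.append(m)
    return Topology(list(topology.atoms), new_mols, dict(topology.rings),
                    list(topology.hbond_donors), list(topology.hbond_acceptors))
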