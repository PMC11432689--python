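"""Geometric detection and classification of molecular contacts.

π-stacking between two ligands: some ring of one and some ring of the other
have centroid distance ≤ d_max (default 5.0 Å) and inter-normal angle
≤ angle_max (default 30°, angles folded to [0°, 90°] since ring normals are
sign-free).  Ring normals come from the best-fit plane (smallest singular
direction of the centered ring coordinates).

Ligand–partner contacts are classified with standard geometric criteria, in
priority order (classes mutually exclusive per partner atom):

=========  ==================================================================
hbond      donor–acceptor heavy-atom distance ≤ 3.5 Å; when an explicit H is
           present a donor–H–acceptor angle ≥ 120° is also required, else
           distance-only mode applies
ch_pi      apolar partner carbon ≤ 4.0 Å from a ligand ring centroid with
           elevation ≥ 60° from the ring plane
vdw        any heavy-atom pair ≤ 4.0 Å not classified above
=========  ==================================================================

Dimer dissociation is a two-state machine with dwell hysteresis: a pair is
*formed* at the first time it is stacked for ``dwell_frames`` consecutive
frames, and *dissociated* at the first subsequent time its minimum
ring-centroid distance stays ≥ ``release_d`` (default 8.0 Å) for
``dwell_frames`` consecutive frames; flickering series produce no event.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .errors import ValidationError
from .trajectory_io import Topology, Trajectory


@dataclass
class RingGeometry:
    ring_id: tuple[int, int]      # (molecule id, ring index)
    centroid: np.ndarray          # Å
    normal: np.ndarray            # unit vector, sign-free


@dataclass
class StackingSeries:
    pair: tuple[int, int]         # ligand molecule ids, ordered
    stacked: np.ndarray           # bool per frame
    min_centroid_distance: np.ndarray  # Å per frame, over ring combinations
    d_max: float
    angle_max: float
    times: np.ndarray


@dataclass
class ContactClassification:
    frame: int
    partner_atom_id: int
    ligand_atom_id: int | None    # closest ligand atom (hbond/vdw)
    ring_id: tuple[int, int] | None  # involved ring (ch_pi)
    cls: str                      # hbond | ch_pi | vdw
    distance: float               # Å
    angle: float | None           # °, elevation for ch_pi, D-H-A for hbond


@dataclass
class DissociationEvent:
    pair: tuple[int, int]
    formed_at: float | None       # ns
    dissociated_at: float | None  # ns
    dwell_frames: int
    release_d: float


def ring_geometry(coords: np.ndarray,
                  ring_id: tuple[int, int] = (-1, -1)) -> RingGeometry:
    """Centroid and best-fit-plane unit normal of one ring's coordinates."""
    coords = np.asarray(coords, dtype=float)
    centroid = coords.mean(axis=0)
    centered = coords - centroid
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    normal = vt[-1]
    normal = normal / np.linalg.norm(normal)
    return RingGeometry(ring_id, centroid, normal)


def _ligand_rings(topology: Topology, ligand_id: int) -> list[list[int]]:
    cycles = topology.rings.get(ligand_id, [])
    if not cycles:
        raise ValidationError(f"ligand {ligand_id} has no ring annotations")
    return cycles


def interplanar_angle(n1: np.ndarray, n2: np.ndarray) -> float:
    """Angle between two sign-free plane normals, folded to [0°, 90°]."""
    cosang = abs(float(np.dot(n1, n2)))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def detect_stacking_pairs(traj: Trajectory, topology: Topology,
                          d_max: float = 5.0, angle_max: float = 30.0
                          ) -> dict[tuple[int, int], StackingSeries]:
    """Frame-wise π-stacking flags for every ligand pair."""
    if d_max <= 0 or angle_max < 0:
        raise ValidationError("d_max must be > 0 and angle_max ≥ 0")
    ligands = topology.molecules_with_role("ligand")
    if len(ligands) < 2:
        raise ValidationError("need ≥ 2 ligands with ring annotations")
    ring_atom_idx = {
        lig.id: [np.array([topology.atom_index[a] for a in cyc])
                 for cyc in _ligand_rings(topology, lig.id)]
        for lig in ligands
    }
    out: dict[tuple[int, int], StackingSeries] = {}
    for la, lb in combinations(sorted(l.id for l in ligands), 2):
        stacked = np.zeros(traj.n_frames, dtype=bool)
        mind = np.full(traj.n_frames, np.inf)
        for f in range(traj.n_frames):
            geoms_a = [ring_geometry(traj.coords[f, idx], (la, i))
                       for i, idx in enumerate(ring_atom_idx[la])]
            geoms_b = [ring_geometry(traj.coords[f, idx], (lb, i))
                       for i, idx in enumerate(ring_atom_idx[lb])]
            for ga in geoms_a:
                for gb in geoms_b:
                    d = float(np.linalg.norm(ga.centroid - gb.centroid))
                    mind[f] = min(mind[f], d)
                    if d <= d_max and interplanar_angle(
                            ga.normal, gb.normal) <= angle_max:
                        stacked[f] = True
        out[(la, lb)] = StackingSeries((la, lb), stacked, mind, d_max,
                                       angle_max, traj.times)
    return out


def classify_contacts(traj: Trajectory, topology: Topology, frame: int,
                      partner_selection: list[int],
                      ligand_id: int | None = None,
                      hbond_d: float = 3.5, hbond_angle: float = 120.0,
                      chpi_d: float = 4.0, chpi_elevation: float = 60.0,
                      vdw_d: float = 4.0) -> list[ContactClassification]:
    """Classify ligand–partner contacts in one frame.

    ``partner_selection`` lists partner molecule ids (e.g. one cholesterol).
    Every heavy partner atom receives at most one classification, the best
    it qualifies for in the priority order hbond > ch_pi > vdw.  Hydrogens
    are used only for the donor–H–acceptor angle when present; apolar carbon
    means a C not listed as a donor or acceptor.
    """
    if not (0 <= frame < traj.n_frames):
        raise ValidationError(
            f"frame {frame} out of range (trajectory has {traj.n_frames})"
        )
    ligands = topology.molecules_with_role("ligand")
    if ligand_id is None:
        if len(ligands) != 1:
            raise ValidationError(
                "ligand_id required when the topology has several ligands"
            )
        ligand_id = ligands[0].id
    lig_idx = topology.atoms_of(ligand_id)
    heavy = topology.heavy_mask
    lig_heavy = lig_idx[heavy[lig_idx]]
    donors = set(topology.hbond_donors)
    acceptors = set(topology.hbond_acceptors)
    lig_set = set(int(topology.atoms[i].id) for i in lig_idx)
    X = traj.coords[frame]

    rings = [ring_geometry(
        X[[topology.atom_index[a] for a in cyc]], (ligand_id, i))
        for i, cyc in enumerate(topology.rings.get(ligand_id, []))]

    # explicit hydrogens bonded to a donor: nearest H within 1.3 Å
    h_idx = np.where(~heavy)[0]

    results: list[ContactClassification] = []
    for mol_id in partner_selection:
        p_idx = topology.atoms_of(mol_id)
        p_heavy = p_idx[heavy[p_idx]]
        for j in p_heavy:
            aid_j = int(topology.atoms[j].id)
            d_all = np.linalg.norm(X[lig_heavy] - X[j], axis=1)
            best = None

            # -- hydrogen bond (either side donates) --
            hb = None
            for i in lig_heavy:
                aid_i = int(topology.atoms[i].id)
                pair_da = ((aid_i in donors and aid_j in acceptors)
                           or (aid_j in donors and aid_i in acceptors))
                if not pair_da:
                    continue
                d = float(np.linalg.norm(X[i] - X[j]))
                if d > hbond_d:
                    continue
                donor_idx = i if aid_i in donors else j
                acc_idx = j if donor_idx == i else i
                ang = None
                if h_idx.size:
                    dh = np.linalg.norm(X[h_idx] - X[donor_idx], axis=1)
                    near = h_idx[dh <= 1.3]
                    if near.size:
                        angles = []
                        for h in near:
                            v1 = X[donor_idx] - X[h]
                            v2 = X[acc_idx] - X[h]
                            c = np.dot(v1, v2) / (
                                np.linalg.norm(v1) * np.linalg.norm(v2))
                            angles.append(np.degrees(
                                np.arccos(np.clip(c, -1.0, 1.0))))
                        ang = max(angles)
                        if ang < hbond_angle:
                            continue
                if hb is None or d < hb.distance:
                    hb = ContactClassification(frame, aid_j, aid_i, None,
                                               "hbond", d, ang)
            if hb is not None:
                best = hb

            # -- CH-π: apolar partner carbon over a ligand ring face --
            if best is None and topology.atoms[j].element == "C" \
                    and aid_j not in donors and aid_j not in acceptors:
                for g in rings:
                    v = X[j] - g.centroid
                    d = float(np.linalg.norm(v))
                    if d == 0.0 or d > chpi_d:
                        continue
                    elev = float(np.degrees(
                        np.arcsin(min(1.0, abs(np.dot(v, g.normal)) / d))))
                    if elev >= chpi_elevation:
                        if best is None or d < best.distance:
                            best = ContactClassification(
                                frame, aid_j, None, g.ring_id, "ch_pi", d, elev)

            # -- van der Waals fallback --
            if best is None and d_all.size and d_all.min() <= vdw_d:
                k = int(np.argmin(d_all))
                best = ContactClassification(
                    frame, aid_j, int(topology.atoms[lig_heavy[k]].id), None,
                    "vdw", float(d_all.min()), None)

            if best is not None:
                results.append(best)
    return results


def detect_dissociation_event(series: StackingSeries, dwell_frames: int = 5,
                              release_d: float = 8.0) -> DissociationEvent:
    """Formation/dissociation times from a stacking series with hysteresis."""
    if dwell_frames < 1:
        raise ValidationError("dwell_frames must be ≥ 1")
    stacked = np.asarray(series.stacked, dtype=bool)
    n = stacked.size
    if n == 0:
        raise ValidationError("empty stacking series")
    formed_f = None
    for f in range(n - dwell_frames + 1):
        if stacked[f:f + dwell_frames].all():
            formed_f = f
            break
    if formed_f is None:
        return DissociationEvent(series.pair, None, None, dwell_frames, release_d)
    released = np.asarray(series.min_centroid_distance) >= release_d
    diss_f = None
    for g in range(formed_f + 1, n - dwell_frames + 1):
        if released[g:g + dwell_frames].all():
            diss_f = g
            break
    return DissociationEvent(
        series.pair,
        float(series.times[formed_f]),
        None if diss_f is None else float(series.times[diss_f]),
        dwell_frames, release_d,
    )
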