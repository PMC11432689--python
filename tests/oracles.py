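"""Independent brute-force oracles.

Every function here recomputes a metric by exhaustive loops over atoms,
frames and rule combinations, sharing no code path with the package
implementations (plane normals come from an eigendecomposition of the
coordinate covariance rather than an SVD of the centered coordinates, etc.).
"""

from __future__ import annotations

import math

import numpy as np


def brute_min_distance(xa: np.ndarray, xb: np.ndarray) -> float:
    best = math.inf
    for p in xa:
        for q in xb:
            d = math.dist(p, q)
            best = min(best, d)
    return best


def brute_contact_score(traj, top, cutoff=4.0,
                        roles=("phospholipid", "sterol", "ganglioside")):
    """Per-frame score by all-pairs heavy-atom distances."""
    lig_idx = {}
    mem_idx = []
    for i, atom in enumerate(top.atoms):
        mol = top.molecule_by_id[atom.molecule_id]
        if atom.element == "H":
            continue
        if mol.role == "ligand":
            lig_idx.setdefault(mol.id, []).append(i)
        elif mol.role in roles:
            mem_idx.append(i)
    scores = []
    for f in range(traj.n_frames):
        s = 0
        for idx in lig_idx.values():
            if brute_min_distance(traj.coords[f, idx],
                                  traj.coords[f, mem_idx]) <= cutoff:
                s += 1
        scores.append(s)
    return np.array(scores)


def brute_protrusion(traj, top, species):
    """Mean of per-molecule max heavy-atom z via exhaustive per-atom scan."""
    values = []
    for f in range(traj.n_frames):
        per_mol = []
        for mol in top.molecules:
            if mol.species_label != species or mol.leaflet != "upper":
                continue
            zmax = -math.inf
            for i, atom in enumerate(top.atoms):
                if atom.molecule_id == mol.id and atom.element != "H":
                    zmax = max(zmax, traj.coords[f, i, 2])
            per_mol.append(zmax)
        values.append(sum(per_mol) / len(per_mol))
    return np.array(values)


def brute_com_z(traj, top, ligand_id):
    """Direct Σmᵢzᵢ/Σmᵢ evaluation."""
    values = []
    for f in range(traj.n_frames):
        num = den = 0.0
        for i, atom in enumerate(top.atoms):
            if atom.molecule_id == ligand_id:
                num += atom.mass * traj.coords[f, i, 2]
                den += atom.mass
        values.append(num / den)
    return np.array(values)


def _plane_normal(coords):
    """Unit normal via eigendecomposition of the coordinate covariance."""
    c = np.asarray(coords)
    centered = c - c.mean(axis=0)
    cov = centered.T @ centered
    w, v = np.linalg.eigh(cov)
    n = v[:, 0]
    return n / np.linalg.norm(n)


def brute_stacking(traj, top, la, lb, d_max=5.0, angle_max=30.0):
    """Frame-wise stacked flags by direct geometric evaluation."""
    flags = []
    for f in range(traj.n_frames):
        hit = False
        for cyc_a in top.rings[la]:
            pa = traj.coords[f, [top.atom_index[a] for a in cyc_a]]
            ca, na = pa.mean(axis=0), _plane_normal(pa)
            for cyc_b in top.rings[lb]:
                pb = traj.coords[f, [top.atom_index[a] for a in cyc_b]]
                cb, nb = pb.mean(axis=0), _plane_normal(pb)
                d = math.dist(ca, cb)
                ang = math.degrees(math.acos(
                    min(1.0, abs(float(np.dot(na, nb))))))
                if d <= d_max and ang <= angle_max:
                    hit = True
        flags.append(hit)
    return np.array(flags)


def brute_classify(traj, top, frame, ligand_id, partner_ids,
                   hbond_d=3.5, hbond_angle=120.0, chpi_d=4.0,
                   chpi_elev=60.0, vdw_d=4.0):
    """Best class per heavy partner atom by exhaustive rule evaluation."""
    X = traj.coords[frame]
    donors = set(top.hbond_donors)
    acceptors = set(top.hbond_acceptors)
    lig_heavy = [i for i, a in enumerate(top.atoms)
                 if a.molecule_id == ligand_id and a.element != "H"]
    h_atoms = [i for i, a in enumerate(top.atoms) if a.element == "H"]
    ring_data = []
    for cyc in top.rings.get(ligand_id, []):
        pts = X[[top.atom_index[a] for a in cyc]]
        ring_data.append((pts.mean(axis=0), _plane_normal(pts)))

    out = {}
    for pid in partner_ids:
        p_heavy = [i for i, a in enumerate(top.atoms)
                   if a.molecule_id == pid and a.element != "H"]
        for j in p_heavy:
            aj = top.atoms[j].id
            cls = None
            for i in lig_heavy:
                ai = top.atoms[i].id
                if not ((ai in donors and aj in acceptors)
                        or (aj in donors and ai in acceptors)):
                    continue
                d = math.dist(X[i], X[j])
                if d > hbond_d:
                    continue
                donor_idx = i if ai in donors else j
                acc_idx = j if donor_idx == i else i
                near_h = [h for h in h_atoms
                          if math.dist(X[h], X[donor_idx]) <= 1.3]
                if near_h:
                    ok = False
                    for h in near_h:
                        v1 = X[donor_idx] - X[h]
                        v2 = X[acc_idx] - X[h]
                        cosv = np.dot(v1, v2) / (np.linalg.norm(v1)
                                                 * np.linalg.norm(v2))
                        ang = math.degrees(math.acos(max(-1.0, min(1.0, cosv))))
                        if ang >= hbond_angle:
                            ok = True
                    if not ok:
                        continue
                cls = "hbond"
            if cls is None and top.atoms[j].element == "C" \
                    and aj not in donors and aj not in acceptors:
                for centroid, normal in ring_data:
                    v = X[j] - centroid
                    d = float(np.linalg.norm(v))
                    if d == 0.0 or d > chpi_d:
                        continue
                    elev = math.degrees(math.asin(
                        min(1.0, abs(float(np.dot(v, normal))) / d)))
                    if elev >= chpi_elev:
                        cls = "ch_pi"
            if cls is None:
                for i in lig_heavy:
                    if math.dist(X[i], X[j]) <= vdw_d:
                        cls = "vdw"
                        break
            if cls is not None:
                out[aj] = cls
    return out


def replay_dissociation(stacked, mind, times, dwell, release_d):
    """Explicit two-state machine over the series."""
    state = "free"
    formed_at = dissociated_at = None
    run = 0
    for f in range(len(stacked)):
        if state == "free":
            run = run + 1 if stacked[f] else 0
            if run >= dwell:
                formed_at = times[f - dwell + 1]
                state = "formed"
                run = 0
        elif state == "formed":
            run = run + 1 if mind[f] >= release_d else 0
            if run >= dwell:
                dissociated_at = times[f - dwell + 1]
                break
    return formed_at, dissociated_at
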