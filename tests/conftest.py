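"""Shared builders for small hand-made and random test systems."""

from __future__ import annotations

import numpy as np
import pytest

from seroraft.trajectory_io import ATOMIC_MASS, Atom, Molecule, Topology, Trajectory


def build_system(mol_defs, coords, dt=0.1, rings=None, donors=(), acceptors=(),
                 box=(50.0, 50.0, 50.0)):
    """Construct (Topology, Trajectory) from compact molecule definitions.

    ``mol_defs`` is a list of (species_label, role, leaflet, elements);
    ``coords`` has shape (n_frames, total_atoms, 3) matching the
    concatenated element lists.  ``rings`` maps molecule index → list of
    local-atom-index cycles.
    """
    atoms, molecules = [], []
    ring_map: dict[int, list[list[int]]] = {}
    offsets = []
    next_atom = 0
    for mid, (species, role, leaflet, elements) in enumerate(mol_defs):
        molecules.append(Molecule(mid, species, role, leaflet))
        offsets.append(next_atom)
        for el in elements:
            atoms.append(Atom(next_atom, el, ATOMIC_MASS[el], mid))
            next_atom += 1
    if rings:
        for mid, cycles in rings.items():
            ring_map[mid] = [[offsets[mid] + a for a in cyc] for cyc in cycles]
    topology = Topology(atoms, molecules, ring_map, list(donors), list(acceptors))
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    traj = Trajectory(coords, dt=dt, box=np.asarray(box))
    assert traj.n_atoms == len(atoms)
    return topology, traj


def hexagon(center, normal_axis="z", radius=1.4):
    """Six ring atoms in a plane perpendicular to the given axis."""
    ang = np.deg2rad(np.arange(0, 360, 60))
    flat = np.stack([radius * np.cos(ang), radius * np.sin(ang),
                     np.zeros(6)], axis=1)
    if normal_axis == "x":
        flat = flat[:, [2, 0, 1]]
    elif normal_axis == "y":
        flat = flat[:, [0, 2, 1]]
    return flat + np.asarray(center, dtype=float)


def random_small_system(rng: np.random.Generator):
    """A random ≤20-frame, ≤200-atom system for oracle-equivalence checks.

    Guarantees ≥1 ligand with a ring and ≥1 upper-leaflet POPC molecule so
    that every metric is defined.
    """
    n_frames = int(rng.integers(2, 21))
    mol_defs = []
    rings = {}
    donors, acceptors = [], []

    n_lig = int(rng.integers(1, 4))
    offset = 0
    for _ in range(n_lig):
        n_at = int(rng.integers(6, 11))
        elements = ["C"] * 6 + [str(rng.choice(["C", "N", "O", "H"]))
                                for _ in range(n_at - 6)]
        mol_defs.append(("serotonin", "ligand", "n/a", elements))
        rings[len(mol_defs) - 1] = [list(range(6))]
        for k, el in enumerate(elements):
            if el in ("N", "O") and rng.random() < 0.6:
                (donors if rng.random() < 0.5 else acceptors).append(offset + k)
        offset += n_at

    n_mem = int(rng.integers(2, 9))
    for j in range(n_mem):
        role = str(rng.choice(["phospholipid", "sterol", "ganglioside"]))
        species = {"phospholipid": "POPC", "sterol": "CHOL",
                   "ganglioside": "GM1"}[role]
        leaflet = "upper" if j == 0 else str(rng.choice(["upper", "lower"]))
        if j == 0:
            role, species = "phospholipid", "POPC"
        n_at = int(rng.integers(3, 9))
        elements = [str(rng.choice(["C", "C", "O", "N", "P", "H"]))
                    for _ in range(n_at)]
        if all(e == "H" for e in elements):
            elements[0] = "C"
        mol_defs.append((species, role, leaflet, elements))
        for k, el in enumerate(elements):
            if el in ("N", "O") and rng.random() < 0.6:
                (donors if rng.random() < 0.5 else acceptors).append(offset + k)
        offset += n_at

    total_atoms = sum(len(d[3]) for d in mol_defs)
    assert total_atoms <= 200
    coords = rng.uniform(0.0, 30.0, size=(n_frames, total_atoms, 3))
    return build_system(mol_defs, coords, rings=rings, donors=donors,
                        acceptors=acceptors)


@pytest.fixture
def rng():
    return np.random.default_rng(20240923)
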