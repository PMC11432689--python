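"""Trajectory and topology containers plus text-format I/O.

Conventions used throughout the package: coordinates in Å, times in ns,
right-handed axes with the membrane normal along +z; the upper leaflet has
positive z.  The canonical interchange formats are multi-frame XYZ for
coordinates and a versioned JSON document for the topology (molecule roles,
leaflets, ring annotations, hydrogen-bond donors/acceptors).  A multi-model
PDB importer is provided as a convenience; inputs are assumed whole-molecule
(no periodic-boundary unwrapping is performed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path

import numpy as np

from .errors import ParseError, SchemaError, ValidationError

SCHEMA_VERSION = 1

ROLES = frozenset({"ligand", "phospholipid", "sterol", "ganglioside"})
LEAFLETS = frozenset({"upper", "lower", "n/a"})

#: Standard atomic masses (amu) for the elements the generator emits.
ATOMIC_MASS = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "P": 30.974,
    "S": 32.06,
}


@dataclass(frozen=True)
class Atom:
    id: int
    element: str
    mass: float
    molecule_id: int


@dataclass(frozen=True)
class Molecule:
    id: int
    species_label: str
    role: str
    leaflet: str = "n/a"


@dataclass
class Topology:
    """System composition: atoms, molecules with roles, interaction annotations.

    ``rings`` maps a ligand molecule id to a list of atom-id cycles (length
    ≥ 5); ``hbond_donors``/``hbond_acceptors`` are flat atom-id lists.
    """

    atoms: list[Atom]
    molecules: list[Molecule]
    rings: dict[int, list[list[int]]] = field(default_factory=dict)
    hbond_donors: list[int] = field(default_factory=list)
    hbond_acceptors: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        atom_ids = [a.id for a in self.atoms]
        if len(set(atom_ids)) != len(atom_ids):
            dup = sorted({i for i in atom_ids if atom_ids.count(i) > 1})[0]
            raise SchemaError(f"atoms: duplicate atom id {dup}")
        mol_ids = [m.id for m in self.molecules]
        if len(set(mol_ids)) != len(mol_ids):
            raise SchemaError("molecules: duplicate molecule id")
        mol_set = set(mol_ids)
        for i, m in enumerate(self.molecules):
            if m.role not in ROLES:
                raise SchemaError(
                    f"molecules[{i}].role: {m.role!r} not in {sorted(ROLES)}"
                )
            if m.leaflet not in LEAFLETS:
                raise SchemaError(
                    f"molecules[{i}].leaflet: {m.leaflet!r} not in {sorted(LEAFLETS)}"
                )
        atom_set = set(atom_ids)
        for i, a in enumerate(self.atoms):
            if a.molecule_id not in mol_set:
                raise SchemaError(
                    f"atoms[{i}].molecule_id: unknown molecule {a.molecule_id}"
                )
        for mol_id, cycles in self.rings.items():
            if mol_id not in mol_set:
                raise SchemaError(f"rings.{mol_id}: unknown molecule id")
            for j, cyc in enumerate(cycles):
                if len(cyc) < 5:
                    raise SchemaError(
                        f"rings.{mol_id}[{j}]: ring has {len(cyc)} atoms, need ≥5"
                    )
                for aid in cyc:
                    if aid not in atom_set:
                        raise SchemaError(
                            f"rings.{mol_id}[{j}]: unknown atom id {aid}"
                        )
        for name, ids in (
            ("hbond_donors", self.hbond_donors),
            ("hbond_acceptors", self.hbond_acceptors),
        ):
            for aid in ids:
                if aid not in atom_set:
                    raise SchemaError(f"{name}: unknown atom id {aid}")

    # -- derived index helpers -------------------------------------------

    @cached_property
    def atom_index(self) -> dict[int, int]:
        """Atom id → positional index into coordinate arrays."""
        return {a.id: i for i, a in enumerate(self.atoms)}

    @cached_property
    def elements(self) -> np.ndarray:
        return np.array([a.element for a in self.atoms])

    @cached_property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms], dtype=float)

    @cached_property
    def heavy_mask(self) -> np.ndarray:
        return self.elements != "H"

    @cached_property
    def molecule_by_id(self) -> dict[int, Molecule]:
        return {m.id: m for m in self.molecules}

    @cached_property
    def _mol_atoms(self) -> dict[int, list[int]]:
        out: dict[int, list[int]] = {m.id: [] for m in self.molecules}
        for i, a in enumerate(self.atoms):
            out[a.molecule_id].append(i)
        return out

    def atoms_of(self, molecule_id: int) -> np.ndarray:
        """Positional atom indices of one molecule."""
        try:
            return np.asarray(self._mol_atoms[molecule_id], dtype=int)
        except KeyError:
            raise ValidationError(f"unknown molecule id {molecule_id}") from None

    def molecules_with_role(self, role: str) -> list[Molecule]:
        return [m for m in self.molecules if m.role == role]

    # -- JSON serialization ----------------------------------------------

    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "atoms": [
                {"id": a.id, "element": a.element, "mass": a.mass,
                 "molecule_id": a.molecule_id}
                for a in self.atoms
            ],
            "molecules": [
                {"id": m.id, "species_label": m.species_label,
                 "role": m.role, "leaflet": m.leaflet}
                for m in self.molecules
            ],
            "rings": {str(k): v for k, v in self.rings.items()},
            "hbond_donors": list(self.hbond_donors),
            "hbond_acceptors": list(self.hbond_acceptors),
        }


@dataclass
class Trajectory:
    """Frames of Å coordinates on a fixed atom order.

    ``coords`` has shape (n_frames, n_atoms, 3); ``dt`` is the time per
    frame in ns; ``box`` holds three box lengths in Å.
    """

    coords: np.ndarray
    dt: float
    box: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 0.0]))

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[-1] != 3:
            raise ValidationError(
                f"coords must have shape (n_frames, n_atoms, 3), got {self.coords.shape}"
            )
        if self.dt <= 0:
            raise ValidationError(f"dt must be positive, got {self.dt}")
        if self.coords.size and not np.all(np.isfinite(self.coords)):
            raise ValidationError("coordinates contain non-finite values")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def times(self) -> np.ndarray:
        """Frame times in ns (frame i at i·dt)."""
        return np.arange(self.n_frames) * self.dt


# ---------------------------------------------------------------------------
# topology JSON


def read_topology(path: str | Path) -> Topology:
    """Read and validate a topology JSON document.

    Raises :class:`SchemaError` with a JSON-path-style message on any
    violation (unknown role, ring referencing a missing atom, duplicate id).
    """
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise SchemaError(f"{path}: not valid JSON ({exc})") from exc
    if not isinstance(doc, dict):
        raise SchemaError("$: topology document must be a JSON object")
    version = doc.get("schema_version")
    if version != SCHEMA_VERSION:
        raise SchemaError(f"schema_version: expected {SCHEMA_VERSION}, got {version!r}")
    try:
        atoms = [
            Atom(int(a["id"]), str(a["element"]), float(a["mass"]),
                 int(a["molecule_id"]))
            for a in doc["atoms"]
        ]
        molecules = [
            Molecule(int(m["id"]), str(m["species_label"]), str(m["role"]),
                     str(m.get("leaflet", "n/a")))
            for m in doc["molecules"]
        ]
    except (KeyError, TypeError, ValueError) as exc:
        raise SchemaError(f"atoms/molecules: malformed entry ({exc})") from exc
    rings = {
        int(k): [[int(a) for a in cyc] for cyc in v]
        for k, v in doc.get("rings", {}).items()
    }
    donors = [int(i) for i in doc.get("hbond_donors", [])]
    acceptors = [int(i) for i in doc.get("hbond_acceptors", [])]
    return Topology(atoms, molecules, rings, donors, acceptors)


def write_topology(topology: Topology, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(topology.to_dict(), fh, indent=1)
        fh.write("\n")


# ---------------------------------------------------------------------------
# multi-frame XYZ


def read_xyz_trajectory(path: str | Path, dt: float,
                        box: tuple[float, float, float] | None = None) -> Trajectory:
    """Read a multi-frame XYZ file (atom-count line, comment line, atom lines).

    Frames are returned in file order.  Raises :class:`ParseError` naming the
    offending frame/line for inconsistent atom counts or non-numeric fields.
    """
    frames: list[np.ndarray] = []
    n_atoms_expected: int | None = None
    with open(path) as fh:
        lines = fh.read().splitlines()
    pos = 0
    frame_no = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        frame_no += 1
        try:
            n = int(lines[pos].strip())
        except ValueError:
            raise ParseError(
                f"{path}: frame {frame_no}, line {pos + 1}: expected atom count, "
                f"got {lines[pos]!r}"
            ) from None
        if n_atoms_expected is None:
            n_atoms_expected = n
        elif n != n_atoms_expected:
            raise ParseError(
                f"{path}: frame {frame_no}: atom count {n} differs from "
                f"frame 1 ({n_atoms_expected})"
            )
        body = lines[pos + 2: pos + 2 + n]
        if len(body) < n:
            raise ParseError(
                f"{path}: frame {frame_no}: truncated — expected {n} atom lines, "
                f"found {len(body)}"
            )
        coords = np.empty((n, 3))
        for i, line in enumerate(body):
            parts = line.split()
            if len(parts) < 4:
                raise ParseError(
                    f"{path}: frame {frame_no}, line {pos + 3 + i}: "
                    f"expected 'element x y z', got {line!r}"
                )
            try:
                coords[i] = [float(parts[1]), float(parts[2]), float(parts[3])]
            except ValueError:
                raise ParseError(
                    f"{path}: frame {frame_no}, line {pos + 3 + i}: "
                    f"non-numeric coordinate in {line!r}"
                ) from None
        frames.append(coords)
        pos += 2 + n
    if frames:
        coords3 = np.stack(frames)
    else:
        coords3 = np.empty((0, 0, 3))
    return Trajectory(coords3, dt=dt, box=np.asarray(box if box is not None
                                                    else (0.0, 0.0, 0.0)))


def write_xyz_trajectory(traj: Trajectory, topology: Topology,
                         path: str | Path) -> None:
    """Write standard multi-frame XYZ; the comment line carries ``t=<ns>``.

    Coordinates are printed at 1e-3 Å precision (the format's round-trip
    guarantee).  An empty trajectory produces an empty file.
    """
    if traj.n_frames and traj.n_atoms != len(topology.atoms):
        raise ValidationError(
            f"trajectory has {traj.n_atoms} atoms but topology has "
            f"{len(topology.atoms)}"
        )
    elements = [a.element for a in topology.atoms]
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"{traj.n_atoms}\n")
            fh.write(f"t={f * traj.dt:.6f}\n")
            for el, (x, y, z) in zip(elements, traj.coords[f]):
                fh.write(f"{el} {x:.3f} {y:.3f} {z:.3f}\n")


def read_pdb_trajectory(path: str | Path, dt: float) -> Trajectory:
    """Convenience importer: coordinates from a multi-model PDB file.

    Only coordinates are taken; molecule roles, leaflets and annotations must
    be supplied as a topology JSON (the PDB format does not carry them).
    Assumes whole (un-wrapped) molecules.
    """
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure(model=None)
    coords = np.asarray(stack.coord, dtype=float)
    if coords.ndim == 2:  # single model
        coords = coords[None]
    box = np.array([0.0, 0.0, 0.0])
    return Trajectory(coords, dt=dt, box=box)
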