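"""Seeded synthetic data with planted ground truth.

Four generators emulate the study's raw data sources:

* a lipid-slab trajectory generator (POPC/cholesterol bilayer, optional
  ganglioside with a kind-dependent headgroup height, amphiphilic ligands
  with planted membrane-contact schedules, insertion onsets and π-stacked
  dimers with a planted dissociation frame);
* a two-segment surface-tension vs concentration curve with a planted
  break-point (the CMC);
* a Langmuir-monolayer adsorption trace π(t) = π₀ + Δπ∞(1 − e^(−kt));
* grayscale drop snapshots with dark shrinking disks of known analytic area.

The membrane model is a static jittered lattice slab, not physics: every
downstream metric depends only on geometry, so a geometric stand-in with
known planted truth is sufficient to exercise and validate the estimators.
Each generator draws from a single ``numpy.random.default_rng(seed)`` stream
and is bit-reproducible for identical spec + seed; each returns its ground
truth in a sidecar record.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ValidationError
from .trajectory_io import ATOMIC_MASS, Atom, Molecule, Topology, Trajectory

#: Ganglioside headgroup heights above the phosphate plane (Å), by kind.
#: Chosen only to create clearly distinguishable geometries.
GANGLIOSIDE_HEADGROUP_HEIGHT = {
    "GM1-like": 12.0,
    "GM3-like": 8.0,
    "GT1b-like": 16.0,
}

_HEAD_PLANE_Z = 20.0  # phosphate plane of the upper leaflet, Å


# ---------------------------------------------------------------------------
# molecule templates (local coordinates, Å)


def _rot_z(deg: float) -> np.ndarray:
    t = np.deg2rad(deg)
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _build_ligand_template():
    """Planar indole-like ligand: fused 6- and 5-rings, hydroxyl, ethylamine.

    Returns (elements, coords (13,3), ring_cycles local-idx, donors, acceptors).
    The 6-ring centroid sits at the local origin with its normal along +z.
    """
    ang = np.deg2rad(np.arange(0, 360, 60))
    hexa = np.stack([1.4 * np.cos(ang), 1.4 * np.sin(ang), np.zeros(6)], axis=1)
    a, b = hexa[0], hexa[1]  # shared edge of the fused rings
    mid = (a + b) / 2.0
    u = mid / np.linalg.norm(mid)
    r5 = 1.4 / (2.0 * np.sin(np.pi / 5.0))
    apothem = r5 * np.cos(np.pi / 5.0)
    c5 = mid + apothem * u
    verts = [c5 + _rot_z(k * 72.0) @ (a - c5) for k in range(5)]
    if np.linalg.norm(verts[1] - b) > 1e-6:  # wrong winding: flip
        verts = [c5 + _rot_z(-k * 72.0) @ (a - c5) for k in range(5)]
    assert np.linalg.norm(verts[1] - b) < 1e-6
    penta_new = verts[2:]  # three atoms not shared with the 6-ring

    # hydroxyl O para to the ring fusion; ethylamine chain off the 5-ring
    oxy = hexa[3] * (1.0 + 1.36 / 1.4)
    tip = penta_new[1]
    w = (tip - c5) / np.linalg.norm(tip - c5)
    c_a = tip + 1.5 * w
    c_b = c_a + 1.5 * w + np.array([0.0, 0.0, 0.4])
    n_am = c_b + 1.45 * w + np.array([0.0, 0.0, 0.8])

    coords = np.vstack([hexa, penta_new, oxy, c_a, c_b, n_am])
    elements = ["C"] * 6 + ["N", "C", "C"] + ["O", "C", "C", "N"]
    rings = [[0, 1, 2, 3, 4, 5], [0, 1, 6, 7, 8]]
    donors = [6, 9, 12]      # ring NH, hydroxyl O, amine N
    acceptors = [9]          # hydroxyl O
    return elements, coords, rings, donors, acceptors


_LIG_ELEMENTS, _LIG_COORDS, _LIG_RINGS, _LIG_DONORS, _LIG_ACCEPTORS = \
    _build_ligand_template()


def _popc_template():
    # choline N on top, phosphate at the head plane, glycerol O, tail carbons
    z = [1.0, 0.0, -0.5, -3.0, -6.0, -9.0, -12.0, -15.0]
    xy = [(0, 0), (0, 0), (0.8, 0), (0, 0), (0.5, 0.5), (0, 0), (0.3, -0.4), (0, 0)]
    coords = np.array([[x, y, zz] for (x, y), zz in zip(xy, z)])
    return ["N", "P", "O", "C", "C", "C", "C", "C"], coords


def _chol_template():
    # hydroxyl head slightly below the phosphate plane, apolar body beneath
    z = [-1.5, -3.0, -4.5, -6.0, -7.5, -9.0]
    xy = [(0, 0), (0, 0), (0.5, 0), (0, 0.5), (0, 0), (0.3, 0.3)]
    coords = np.array([[x, y, zz] for (x, y), zz in zip(xy, z)])
    return ["O", "C", "C", "C", "C", "C"], coords


def _ganglioside_template(headgroup_height: float):
    # ceramide anchor down the leaflet plus a sugar chain rising above it
    anchor_z = [0.0, -3.0, -6.0, -9.0]
    anchor = [("C", (0.0, 0.0, z)) for z in anchor_z]
    n_head = 6
    head_z = np.linspace(1.5, headgroup_height, n_head)
    head = [("O" if i % 2 else "C", (0.4 * (-1) ** i, 0.3 * (-1) ** (i // 2), z))
            for i, z in enumerate(head_z)]
    atoms = anchor + head
    elements = [e for e, _ in atoms]
    coords = np.array([p for _, p in atoms])
    return elements, coords


# ---------------------------------------------------------------------------
# specs


@dataclass(frozen=True)
class DimerSpec:
    """A planted π-stacked ligand pair.

    The two members hold parallel rings at 3.5 Å centroid separation from
    ``stacked_from_frame`` until ``dissociate_at_frame``, then separate to
    > 8 Å.
    """

    ligand_ids: tuple[int, int]
    dissociate_at_frame: int
    stacked_from_frame: int = 0


@dataclass(frozen=True)
class TrajectorySpec:
    n_frames: int = 250
    dt: float = 0.1                      # ns per frame
    box: tuple[float, float, float] = (80.0, 80.0, 140.0)
    n_popc: int = 32                     # per leaflet
    n_chol: int = 32
    n_ganglioside: int = 0
    ganglioside_kind: str = "none"       # none | GM1-like | GM3-like | GT1b-like
    n_ligands: int = 3
    onset_frame_per_ligand: tuple[int | None, ...] | None = None
    contact_fraction_per_ligand: tuple[float, ...] | None = None
    dimer_spec: DimerSpec | None = None
    jitter_sigma: float = 0.3            # Å, membrane thermal jitter
    walk_sigma: float = 1.0              # Å per frame, ligand random walk
    seed: int = 0

    def onsets(self) -> list[int | None]:
        if self.onset_frame_per_ligand is None:
            return [None] * self.n_ligands
        return list(self.onset_frame_per_ligand)

    def contact_fractions(self) -> list[float]:
        if self.contact_fraction_per_ligand is None:
            return [1.0] * self.n_ligands
        return list(self.contact_fraction_per_ligand)

    def validate(self) -> None:
        if self.n_frames < 1:
            raise ValidationError("n_frames must be ≥ 1")
        if self.dt <= 0:
            raise ValidationError("dt must be positive")
        if self.n_ligands < 0 or self.n_popc < 0 or self.n_chol < 0 \
                or self.n_ganglioside < 0:
            raise ValidationError("molecule counts must be non-negative")
        if self.n_ganglioside > 0 and self.ganglioside_kind \
                not in GANGLIOSIDE_HEADGROUP_HEIGHT:
            raise ValidationError(
                f"ganglioside_kind {self.ganglioside_kind!r} must be one of "
                f"{sorted(GANGLIOSIDE_HEADGROUP_HEIGHT)} when n_ganglioside > 0"
            )
        onsets = self.onsets()
        fracs = self.contact_fractions()
        if len(onsets) != self.n_ligands or len(fracs) != self.n_ligands:
            raise ValidationError(
                "onset_frame_per_ligand / contact_fraction_per_ligand must have "
                "one entry per ligand"
            )
        for o in onsets:
            if o is not None and not (0 <= o < self.n_frames):
                raise ValidationError(
                    f"onset frame {o} outside trajectory of {self.n_frames} frames"
                )
        for p in fracs:
            if not (0.0 <= p <= 1.0):
                raise ValidationError(f"contact fraction {p} outside [0, 1]")
        d = self.dimer_spec
        if d is not None:
            i, j = d.ligand_ids
            if not (0 <= i < self.n_ligands and 0 <= j < self.n_ligands) or i == j:
                raise ValidationError("dimer ligand ids must be two distinct ligands")
            if not (0 <= d.stacked_from_frame < d.dissociate_at_frame):
                raise ValidationError(
                    "dimer requires 0 ≤ stacked_from_frame < dissociate_at_frame"
                )
        # lattice feasibility: molecules must fit without overlap
        per_leaflet = self.n_popc + self.n_chol + self.n_ganglioside
        if per_leaflet > 0:
            grid = int(np.ceil(np.sqrt(per_leaflet)))
            if min(self.box[0], self.box[1]) / grid < 6.0:
                raise ValidationError(
                    "box too small for the requested molecule counts "
                    "(lattice spacing < 6 Å — overlapping placements)"
                )


@dataclass(frozen=True)
class TensiometrySpec:
    break_point: float                   # mM
    slope_below: float = -0.5            # mN/m per mM (or per log10 mM)
    slope_above: float = 0.0
    intercept: float = 72.0              # mN/m at c → 0
    concentrations: tuple[float, ...] = tuple(np.linspace(5.0, 100.0, 30))
    noise_sigma: float = 0.0             # mN/m
    axis_mode: str = "linear"            # linear | log
    seed: int = 0

    def validate(self) -> None:
        c = np.asarray(self.concentrations, dtype=float)
        if c.size < 6:
            raise ValidationError("need ≥ 6 concentrations")
        if np.any(c <= 0) or np.any(np.diff(c) <= 0):
            raise ValidationError("concentrations must be positive and strictly increasing")
        if self.axis_mode not in ("linear", "log"):
            raise ValidationError("axis_mode must be 'linear' or 'log'")
        if not (self.slope_below < self.slope_above <= 0.0):
            raise ValidationError(
                "surfactant-like curve requires slope_below < slope_above ≤ 0"
            )
        n_below = int(np.sum(c < self.break_point))
        n_above = int(np.sum(c > self.break_point))
        if n_below < 3 or n_above < 3:
            raise ValidationError(
                f"need ≥ 3 concentrations on each side of the break "
                f"(got {n_below} below, {n_above} above)"
            )
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be ≥ 0")


@dataclass(frozen=True)
class KineticsSpec:
    pi0: float = 20.0                    # mN/m, initial monolayer pressure
    delta_pi_inf: float = 10.0           # mN/m, plateau pressure increase
    rate_k: float = 0.05                 # min⁻¹
    duration: float = 60.0               # min
    sampling: float = 0.5                # min
    noise_sigma: float = 0.0             # mN/m
    seed: int = 0

    def validate(self) -> None:
        if self.duration <= 0 or self.sampling <= 0:
            raise ValidationError("duration and sampling must be positive")
        if self.delta_pi_inf < 0 or self.rate_k < 0:
            raise ValidationError("delta_pi_inf and rate_k must be ≥ 0")
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be ≥ 0")


@dataclass(frozen=True)
class AggregateImageSpec:
    width: int = 256
    height: int = 256
    mm_per_pixel: float = 0.02
    disks: tuple[tuple[float, float, float], ...] = ((128.0, 128.0, 50.0),)
    shrink_rate: float = 0.0             # px per frame
    n_frames: int = 1
    background_gray: int = 220
    foreground_gray: int = 40
    noise_sigma: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.width < 1 or self.height < 1 or self.n_frames < 1:
            raise ValidationError("width, height and n_frames must be ≥ 1")
        if self.mm_per_pixel <= 0:
            raise ValidationError("mm_per_pixel must be positive")
        for cx, cy, r in self.disks:
            if r < 0:
                raise ValidationError("disk radius must be ≥ 0")
            if not (r <= cx <= self.width - 1 - r and r <= cy <= self.height - 1 - r):
                raise ValidationError(
                    f"disk at ({cx}, {cy}) radius {r} outside image bounds at t0"
                )
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be ≥ 0")


# ---------------------------------------------------------------------------
# result bundles


@dataclass
class TrajectoryBundle:
    topology: Topology
    trajectory: Trajectory
    truth: dict

    def write(self, out_dir: str | Path, stem: str = "system") -> dict[str, Path]:
        from .trajectory_io import write_topology, write_xyz_trajectory

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "trajectory": out / f"{stem}.xyz",
            "topology": out / f"{stem}.topology.json",
            "truth": out / f"{stem}.truth.json",
        }
        write_xyz_trajectory(self.trajectory, self.topology, paths["trajectory"])
        write_topology(self.topology, paths["topology"])
        paths["truth"].write_text(json.dumps(self.truth, indent=1, sort_keys=True))
        return paths


@dataclass
class CurveBundle:
    curve: object       # TensiometryCurve or KineticsCurve
    truth: dict


@dataclass
class ImageBundle:
    images: list
    times: list[float]
    truth: dict


# ---------------------------------------------------------------------------
# membrane trajectory generator


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix)."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def gen_membrane_trajectory(spec: TrajectorySpec) -> TrajectoryBundle:
    """Generate a slab-membrane trajectory with planted ligand behavior.

    Membrane: phospholipid head planes near z = ±20 Å, sterol hydroxyls
    slightly below, ganglioside headgroups rising above the plane by the
    kind-dependent height; lateral positions on a jittered lattice, with
    per-frame Gaussian jitter of ``jitter_sigma``.

    Ligands perform a reflected Gaussian random walk above the membrane
    before their onset frame; from the onset on, each frame is independently
    a contact frame with probability ``contact_fraction`` (seeded), in which
    the ligand is tethered within contact range of an upper-leaflet
    phospholipid head atom with its mass center below the phospholipid
    protrusion line.  Planted dimers hold parallel rings at 3.5 Å centroid
    distance until their dissociation frame, then separate to > 8 Å.

    The ground-truth sidecar records, per ligand, the onset frame and the
    exact list of planted contact frames, plus dimer frames and plane
    geometry.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    box = np.asarray(spec.box, dtype=float)

    gang_h = GANGLIOSIDE_HEADGROUP_HEIGHT.get(spec.ganglioside_kind, 0.0)
    templates = {
        "POPC": _popc_template(),
        "CHOL": _chol_template(),
    }
    gang_label = spec.ganglioside_kind.replace("-like", "") \
        if spec.ganglioside_kind != "none" else None
    if spec.n_ganglioside > 0:
        templates[gang_label] = _ganglioside_template(gang_h)

    atoms: list[Atom] = []
    molecules: list[Molecule] = []
    base_coords: list[np.ndarray] = []
    rings: dict[int, list[list[int]]] = {}
    donors: list[int] = []
    acceptors: list[int] = []
    next_atom = 0
    next_mol = 0
    popc_head_atom_idx: list[int] = []   # choline N of upper-leaflet POPC

    per_leaflet = spec.n_popc + spec.n_chol + spec.n_ganglioside
    species_seq = (["POPC"] * spec.n_popc + ["CHOL"] * spec.n_chol
                   + ([gang_label] * spec.n_ganglioside if gang_label else []))
    role_of = {"POPC": "phospholipid", "CHOL": "sterol"}
    if gang_label:
        role_of[gang_label] = "ganglioside"

    for leaflet, sign in (("upper", 1.0), ("lower", -1.0)):
        if per_leaflet == 0:
            break
        order = rng.permutation(per_leaflet)
        grid = int(np.ceil(np.sqrt(per_leaflet)))
        sx, sy = box[0] / grid, box[1] / grid
        for site, which in enumerate(order):
            label = species_seq[which]
            el, local = templates[label]
            gx, gy = site % grid, site // grid
            origin = np.array([
                (gx + 0.5) * sx + rng.normal(0.0, 0.5),
                (gy + 0.5) * sy + rng.normal(0.0, 0.5),
                sign * _HEAD_PLANE_Z,
            ])
            pos = local.copy()
            pos[:, 2] *= sign
            pos = pos + origin
            mol_id = next_mol
            molecules.append(Molecule(mol_id, label, role_of[label], leaflet))
            for k, e in enumerate(el):
                atoms.append(Atom(next_atom, e, ATOMIC_MASS[e], mol_id))
                base_coords.append(pos[k])
                if label == "POPC" and leaflet == "upper" and e == "N":
                    popc_head_atom_idx.append(next_atom)
                next_atom += 1
            next_mol += 1

    membrane_top = max((c[2] for c in base_coords), default=0.0)
    floor = membrane_top + 12.0 + 4.0 * spec.jitter_sigma
    if floor + 10.0 > box[2]:
        raise ValidationError(
            f"box z-length {box[2]} too short for ligand region above the "
            f"membrane (needs ≥ {floor + 10.0:.0f} Å)"
        )

    ligand_mols: list[int] = []
    ligand_atom_slices: list[slice] = []
    for _ in range(spec.n_ligands):
        mol_id = next_mol
        molecules.append(Molecule(mol_id, "serotonin", "ligand", "n/a"))
        start = next_atom
        for e in _LIG_ELEMENTS:
            atoms.append(Atom(next_atom, e, ATOMIC_MASS[e], mol_id))
            base_coords.append(np.zeros(3))
            next_atom += 1
        rings[mol_id] = [[start + i for i in cyc] for cyc in _LIG_RINGS]
        donors.extend(start + i for i in _LIG_DONORS)
        acceptors.extend(start + i for i in _LIG_ACCEPTORS)
        ligand_mols.append(mol_id)
        ligand_atom_slices.append(slice(start, start + len(_LIG_ELEMENTS)))
        next_mol += 1

    topology = Topology(atoms, molecules, rings, donors, acceptors)
    n_atoms = len(atoms)
    n_mem = n_atoms - spec.n_ligands * len(_LIG_ELEMENTS)
    base = np.asarray(base_coords)

    onsets = spec.onsets()
    fracs = spec.contact_fractions()
    dimer = spec.dimer_spec
    dimer_members = set(dimer.ligand_ids) if dimer else set()

    # planted contact schedules, drawn i.i.d. per frame after the effective
    # onset (a dimer member only starts its schedule once dissociated)
    contact_frames: list[list[int]] = []
    in_contact = np.zeros((spec.n_ligands, spec.n_frames), dtype=bool)
    for li in range(spec.n_ligands):
        onset = onsets[li]
        frames: list[int] = []
        if onset is not None:
            start_f = onset
            if li in dimer_members:
                start_f = max(onset, dimer.dissociate_at_frame)
            draws = rng.random(spec.n_frames - start_f) < fracs[li]
            frames = [start_f + k for k, hit in enumerate(draws) if hit]
            in_contact[li, frames] = True
        contact_frames.append(frames)

    if spec.n_ligands and onsets and any(
            o is not None for o in onsets) and not popc_head_atom_idx:
        raise ValidationError(
            "contact schedules require upper-leaflet phospholipids (n_popc > 0)"
        )

    # ligand walkers: per-ligand persistent position above the floor
    walker = np.empty((spec.n_ligands, 3))
    for li in range(spec.n_ligands):
        walker[li] = [rng.uniform(0.0, box[0]), rng.uniform(0.0, box[1]),
                      rng.uniform(floor, min(box[2], floor + 20.0))]
    dimer_site = np.array([box[0] / 2.0, box[1] / 2.0, floor + 15.0])

    coords = np.empty((spec.n_frames, n_atoms, 3))
    for f in range(spec.n_frames):
        frame = np.empty((n_atoms, 3))
        frame[:n_mem] = base[:n_mem] + rng.normal(
            0.0, spec.jitter_sigma, size=(n_mem, 3))
        for li in range(spec.n_ligands):
            sl = ligand_atom_slices[li]
            # advance the walker every frame so the stream stays aligned
            step = rng.normal(0.0, spec.walk_sigma, size=3)
            rot = _random_rotation(rng)
            spin = rng.uniform(0.0, 360.0)
            w = walker[li] + step
            w[0] %= box[0]
            w[1] %= box[1]
            if w[2] < floor:
                w[2] = 2.0 * floor - w[2]
            if w[2] > box[2] - 6.0:
                w[2] = 2.0 * (box[2] - 6.0) - w[2]
            walker[li] = w

            stacked = (dimer is not None and li in dimer_members
                       and dimer.stacked_from_frame <= f < dimer.dissociate_at_frame)
            separated = (dimer is not None and li in dimer_members
                         and f >= dimer.dissociate_at_frame
                         and not in_contact[li, f])
            if stacked or separated:
                # flat template (ring normals along z), planted geometry
                first = li == min(dimer_members)
                offset = np.zeros(3)
                if stacked and not first:
                    offset = np.array([0.0, 0.0, 3.5])
                elif separated:
                    offset = (np.array([0.0, 0.0, 0.0]) if first
                              else np.array([12.0, 0.0, 3.5]))
                frame[sl] = _LIG_COORDS @ _rot_z(0.0).T + dimer_site + offset
            elif in_contact[li, f]:
                head = popc_head_atom_idx[
                    rng.integers(0, len(popc_head_atom_idx))]
                anchor = frame[head] + np.array([0.0, 0.0, -1.0])
                frame[sl] = _LIG_COORDS @ _rot_z(spin).T + anchor
            else:
                frame[sl] = _LIG_COORDS @ rot.T + walker[li]
        coords[f] = frame

    trajectory = Trajectory(coords, dt=spec.dt, box=box)
    truth = {
        "head_plane_z": _HEAD_PLANE_Z,
        "ganglioside_headgroup_height": gang_h if spec.n_ganglioside else 0.0,
        "ligand_molecule_ids": ligand_mols,
        "onset_frame": [onsets[li] for li in range(spec.n_ligands)],
        "contact_fraction": fracs,
        "contact_frames": contact_frames,
        "dimer": None if dimer is None else {
            "ligand_ids": list(dimer.ligand_ids),
            "stacked_from_frame": dimer.stacked_from_frame,
            "dissociate_at_frame": dimer.dissociate_at_frame,
        },
        "seed": spec.seed,
    }
    return TrajectoryBundle(topology, trajectory, truth)


# ---------------------------------------------------------------------------
# tensiometry / kinetics / images


def tensiometry_model(c: np.ndarray, break_point: float, slope_below: float,
                      slope_above: float, intercept: float,
                      axis_mode: str = "linear") -> np.ndarray:
    """Continuous two-segment surface-tension model γ(c)."""
    x = np.log10(c) if axis_mode == "log" else np.asarray(c, dtype=float)
    b = np.log10(break_point) if axis_mode == "log" else break_point
    return intercept + slope_below * np.minimum(x, b) \
        + slope_above * np.maximum(x - b, 0.0)


def gen_tensiometry_curve(spec: TensiometrySpec) -> CurveBundle:
    """Surface tension vs concentration from the two-segment model + noise."""
    from .tensiometry import TensiometryCurve

    spec.validate()
    rng = np.random.default_rng(spec.seed)
    c = np.asarray(spec.concentrations, dtype=float)
    gamma = tensiometry_model(c, spec.break_point, spec.slope_below,
                              spec.slope_above, spec.intercept, spec.axis_mode)
    gamma = gamma + rng.normal(0.0, spec.noise_sigma, size=c.size)
    curve = TensiometryCurve(c, gamma, axis_mode=spec.axis_mode)
    truth = {
        "break_point": spec.break_point,
        "slope_below": spec.slope_below,
        "slope_above": spec.slope_above,
        "intercept": spec.intercept,
        "seed": spec.seed,
    }
    return CurveBundle(curve, truth)


def gen_kinetics_curve(spec: KineticsSpec) -> CurveBundle:
    """Adsorption trace π(t) = π₀ + Δπ∞(1 − e^(−kt)) + noise."""
    from .tensiometry import KineticsCurve

    spec.validate()
    rng = np.random.default_rng(spec.seed)
    t = np.arange(0.0, spec.duration + spec.sampling / 2.0, spec.sampling)
    pi = spec.pi0 + spec.delta_pi_inf * (1.0 - np.exp(-spec.rate_k * t))
    pi = pi + rng.normal(0.0, spec.noise_sigma, size=t.size)
    curve = KineticsCurve(t, pi)
    truth = {
        "pi0": spec.pi0,
        "delta_pi_inf": spec.delta_pi_inf,
        "rate_k": spec.rate_k,
        "seed": spec.seed,
    }
    return CurveBundle(curve, truth)


def gen_aggregate_image_series(spec: AggregateImageSpec) -> ImageBundle:
    """Grayscale snapshots with dark shrinking disks of known analytic area."""
    from .imaging import GrayImage

    spec.validate()
    rng = np.random.default_rng(spec.seed)
    yy, xx = np.mgrid[0:spec.height, 0:spec.width]
    images: list[GrayImage] = []
    radii_truth: list[list[float]] = []
    areas_truth: list[float] = []
    for f in range(spec.n_frames):
        img = np.full((spec.height, spec.width), float(spec.background_gray))
        radii = []
        total_area = 0.0
        for cx, cy, r0 in spec.disks:
            r = max(r0 - spec.shrink_rate * f, 0.0)
            radii.append(r)
            total_area += np.pi * r * r
            if r > 0:
                mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r
                img[mask] = float(spec.foreground_gray)
        if spec.noise_sigma > 0:
            img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)
        img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
        images.append(GrayImage(img, mm_per_pixel=spec.mm_per_pixel))
        radii_truth.append(radii)
        areas_truth.append(total_area)
    times = list(range(spec.n_frames))
    truth = {
        "radii_px": radii_truth,
        "area_px2": areas_truth,
        "mm_per_pixel": spec.mm_per_pixel,
        "seed": spec.seed,
    }
    return ImageBundle(images, [float(t) for t in times], truth)


def spec_from_dict(kind: str, data: dict):
    """Build a generator spec from a plain dict (YAML/JSON config)."""
    classes = {
        "trajectory": TrajectorySpec,
        "tensiometry": TensiometrySpec,
        "kinetics": KineticsSpec,
        "images": AggregateImageSpec,
    }
    cls = classes[kind]
    data = dict(data)
    if kind == "trajectory":
        if "dimer_spec" in data and data["dimer_spec"] is not None:
            d = dict(data["dimer_spec"])
            d["ligand_ids"] = tuple(d["ligand_ids"])
            data["dimer_spec"] = DimerSpec(**d)
        for key in ("onset_frame_per_ligand", "contact_fraction_per_ligand", "box"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
    if kind == "tensiometry" and "concentrations" in data:
        data["concentrations"] = tuple(data["concentrations"])
    if kind == "images" and "disks" in data:
        data["disks"] = tuple(tuple(d) for d in data["disks"])
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValidationError(f"unknown {kind} spec fields: {sorted(unknown)}")
    return cls(**data)
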