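"""Protrusion, COM, contact-score and insertion-onset correctness."""

import numpy as np
import pytest

from seroraft.errors import ValidationError
from seroraft.membrane_metrics import (ComZSeries, ProtrusionSeries,
                                       average_protrusion_series,
                                       compute_contact_score,
                                       detect_insertion_onset,
                                       ligand_com_series)
from seroraft.synthetic_data import TrajectorySpec, gen_membrane_trajectory

from conftest import build_system, random_small_system
from oracles import brute_com_z, brute_contact_score, brute_protrusion


def _flat(n_mols, zs_per_mol, species="POPC", role="phospholipid"):
    """One-frame system of n membrane molecules at given atom z heights."""
    mol_defs = [(species, role, "upper", ["C"] * len(z)) for z in zs_per_mol]
    coords = np.array([[0.0, 0.0, z] for zlist in zs_per_mol for z in zlist])
    return build_system(mol_defs, coords[None])


@pytest.mark.parametrize("zs,expected", [
    ([[20.0, 20.0, 20.0]], 20.0),
    ([[18.0, 10.0], [22.0, 5.0]], 20.0),
])
def test_protrusion_simple_cases(zs, expected):
    top, traj = _flat(len(zs), zs)
    series = average_protrusion_series(traj, top, "POPC")
    assert series.values[0] == pytest.approx(expected)


def test_protrusion_excludes_hydrogens():
    top, traj = build_system(
        [("POPC", "phospholipid", "upper", ["C", "H"])],
        np.array([[[0, 0, 18.0], [0, 0, 25.0]]]),
    )
    assert average_protrusion_series(traj, top, "POPC").values[0] == 18.0


def test_protrusion_absent_species_is_an_error():
    top, traj = _flat(1, [[20.0]])
    with pytest.raises(ValidationError, match="GM1"):
        average_protrusion_series(traj, top, "GM1")


@pytest.mark.parametrize("elements,zs,expected", [
    (["C", "C"], [0.0, 10.0], 5.0),          # equal masses
    (["H", "C"], [0.0, 4.0], None),          # masses 1.008 : 12.011
])
def test_com_weighted_mean(elements, zs, expected):
    top, traj = build_system(
        [("serotonin", "ligand", "n/a", elements)],
        np.array([[[0, 0, z] for z in zs]]),
    )
    got = ligand_com_series(traj, top, 0).values[0]
    if expected is None:
        m = top.masses
        expected = (m * np.array(zs)).sum() / m.sum()
    assert got == pytest.approx(expected)


def test_com_mass_ratio_one_to_three():
    """Masses 1:3 at z 0 and 4 put the COM at 3.0."""
    from seroraft.trajectory_io import Atom, Molecule, Topology, Trajectory

    top = Topology([Atom(0, "C", 1.0, 0), Atom(1, "C", 3.0, 0)],
                   [Molecule(0, "X", "ligand", "n/a")])
    traj = Trajectory(np.array([[[0, 0, 0.0], [0, 0, 4.0]]]), dt=0.1)
    assert ligand_com_series(traj, top, 0).values[0] == pytest.approx(3.0)


def test_com_non_positive_mass_rejected():
    from seroraft.trajectory_io import Atom, Molecule, Topology, Trajectory

    top = Topology([Atom(0, "C", 0.0, 0)], [Molecule(0, "X", "ligand", "n/a")])
    traj = Trajectory(np.zeros((1, 1, 3)), dt=0.1)
    with pytest.raises(ValidationError):
        ligand_com_series(traj, top, 0)


def test_contact_score_trivial_far_and_coincident():
    top, traj = build_system(
        [("serotonin", "ligand", "n/a", ["C"]),
         ("POPC", "phospholipid", "upper", ["P"])],
        np.array([
            [[0, 0, 40.0], [0, 0, 20.0]],   # 20 Å apart: no contact
            [[0, 0, 20.0], [0, 0, 20.0]],   # coincident: contact
        ]),
    )
    s = compute_contact_score(traj, top, cutoff=4.0)
    assert list(s.per_frame) == [0, 1]
    assert s.total == 1


def test_contact_score_tie_at_cutoff_counts():
    top, traj = build_system(
        [("serotonin", "ligand", "n/a", ["C"]),
         ("POPC", "phospholipid", "upper", ["P"])],
        np.array([[[0, 0, 24.0], [0, 0, 20.0]]]),
    )
    assert compute_contact_score(traj, top, cutoff=4.0).total == 1


def test_contact_score_invalid_inputs():
    top, traj = build_system(
        [("serotonin", "ligand", "n/a", ["C"]),
         ("POPC", "phospholipid", "upper", ["P"])],
        np.zeros((1, 2, 3)),
    )
    with pytest.raises(ValidationError):
        compute_contact_score(traj, top, cutoff=0.0)
    top2, traj2 = build_system([("POPC", "phospholipid", "upper", ["P"])],
                               np.zeros((1, 1, 3)))
    with pytest.raises(ValidationError):
        compute_contact_score(traj2, top2)


def test_planted_partial_contact_total():
    """1 of 3 ligands in contact frames 50-99 of 100 gives a total of 50."""
    spec = TrajectorySpec(n_frames=100, n_popc=16, n_chol=16, n_ligands=3,
                          onset_frame_per_ligand=(50, None, None),
                          contact_fraction_per_ligand=(1.0, 0.0, 0.0), seed=1)
    b = gen_membrane_trajectory(spec)
    s = compute_contact_score(b.trajectory, b.topology)
    assert s.total == 50
    lig = b.truth["ligand_molecule_ids"][0]
    assert np.flatnonzero(s.per_ligand[lig]).tolist() == list(range(50, 100))


def test_score_bounds_and_cutoff_monotonicity(rng):
    """0 ≤ total ≤ n_frames·n_ligands and larger cutoffs never lower scores."""
    for _ in range(10):
        top, traj = random_small_system(rng)
        n_lig = len(top.molecules_with_role("ligand"))
        prev = None
        for cutoff in (2.0, 4.0, 8.0, 16.0):
            s = compute_contact_score(traj, top, cutoff=cutoff)
            assert 0 <= s.total <= traj.n_frames * n_lig
            assert s.per_frame.max(initial=0) <= n_lig
            if prev is not None:
                assert np.all(s.per_frame >= prev)
            prev = s.per_frame


def test_metrics_match_brute_force_on_random_systems(rng):
    for _ in range(20):
        top, traj = random_small_system(rng)
        s = compute_contact_score(traj, top, cutoff=4.0)
        assert np.array_equal(s.per_frame, brute_contact_score(traj, top, 4.0))
        prot = average_protrusion_series(traj, top, "POPC")
        assert np.allclose(prot.values, brute_protrusion(traj, top, "POPC"),
                           rtol=0, atol=1e-12)
        lig = top.molecules_with_role("ligand")[0].id
        com = ligand_com_series(traj, top, lig)
        assert np.allclose(com.values, brute_com_z(traj, top, lig),
                           rtol=0, atol=1e-9)


def _series(com_z, prot_z, dt=0.1):
    times = np.arange(len(com_z)) * dt
    return (ComZSeries(0, np.asarray(com_z, float), times),
            ProtrusionSeries("POPC", np.asarray(prot_z, float), times))


def test_onset_none_when_always_above():
    com, prot = _series([25.0] * 100, [21.0] * 100)
    assert detect_insertion_onset(com, prot).onset_time is None


def test_onset_at_first_persistent_frame():
    com = [25.0] * 40 + [20.0] * 60
    prot = [21.0] * 100
    rep = detect_insertion_onset(*_series(com, prot))
    assert rep.onset_time == pytest.approx(4.0)
    assert rep.occupancy_after_onset == 1.0


def test_transient_dip_not_called_as_onset():
    """A single-frame dip at frame 10 is skipped; the persistent insertion
    from frame 40 is the onset (exhaustive-scan semantics)."""
    com = np.full(100, 25.0)
    com[10] = 20.0
    com[40:] = 20.0
    rep = detect_insertion_onset(*_series(com, [21.0] * 100))
    assert rep.onset_time == pytest.approx(4.0)


def test_onset_respects_occupancy_threshold():
    # inserted frames 20-39 then detaches: occupancy from 20 is only 0.25
    com = np.full(100, 25.0)
    com[20:40] = 20.0
    rep = detect_insertion_onset(*_series(com, [21.0] * 100))
    assert rep.onset_time is None


def test_onset_mismatched_series_rejected():
    com, _ = _series([20.0] * 10, [21.0] * 10)
    _, prot = _series([20.0] * 12, [21.0] * 12)
    with pytest.raises(ValidationError):
        detect_insertion_onset(com, prot)


def test_planted_onset_recovered_to_the_frame():
    """Noiseless planted insertion: detected onset equals the planted frame."""
    for onset, seed in ((20, 3), (140, 7), (5, 11)):
        spec = TrajectorySpec(n_frames=250, n_popc=24, n_chol=24, n_ligands=1,
                              onset_frame_per_ligand=(onset,),
                              contact_fraction_per_ligand=(1.0,), seed=seed)
        b = gen_membrane_trajectory(spec)
        prot = average_protrusion_series(b.trajectory, b.topology, "POPC")
        com = ligand_com_series(b.trajectory, b.topology,
                                b.truth["ligand_molecule_ids"][0])
        rep = detect_insertion_onset(com, prot)
        assert rep.onset_time == pytest.approx(onset * 0.1, abs=1e-9)


def test_com_below_protrusion_score_mode():
    spec = TrajectorySpec(n_frames=80, n_popc=16, n_chol=16, n_ligands=1,
                          onset_frame_per_ligand=(30,),
                          contact_fraction_per_ligand=(1.0,), seed=5)
    b = gen_membrane_trajectory(spec)
    s = compute_contact_score(b.trajectory, b.topology,
                              mode="com_below_protrusion")
    assert s.total == 50
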