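"""π-stacking, contact classification and dissociation-event detection."""

import numpy as np
import pytest

from seroraft.errors import ValidationError
from seroraft.interaction_geometry import (StackingSeries, classify_contacts,
                                           detect_dissociation_event,
                                           detect_stacking_pairs,
                                           ring_geometry)
from seroraft.synthetic_data import (DimerSpec, TrajectorySpec,
                                     gen_membrane_trajectory)

from conftest import build_system, hexagon, random_small_system
from oracles import brute_classify, brute_stacking, replay_dissociation


def _two_ring_system(coords_a, coords_b):
    return build_system(
        [("serotonin", "ligand", "n/a", ["C"] * 6),
         ("serotonin", "ligand", "n/a", ["C"] * 6)],
        np.concatenate([coords_a, coords_b])[None],
        rings={0: [list(range(6))], 1: [list(range(6))]},
    )


@pytest.mark.parametrize("axis_b,offset,expect", [
    ("z", (0, 0, 3.5), True),     # parallel at 3.5 Å → stacked
    ("x", (0, 0, 3.5), False),    # perpendicular at 3.5 Å → not
    ("z", (0, 0, 6.0), False),    # parallel at 6.0 Å with d_max 5 → not
    ("z", (3.0, 0, 2.0), True),   # offset-parallel, centroids 3.6 Å
])
def test_stacking_geometric_criteria(axis_b, offset, expect):
    top, traj = _two_ring_system(hexagon((0, 0, 0)),
                                 hexagon(offset, normal_axis=axis_b))
    series = detect_stacking_pairs(traj, top, d_max=5.0, angle_max=30.0)
    assert bool(series[(0, 1)].stacked[0]) is expect


def test_ring_normal_is_sign_free_unit_vector():
    g = ring_geometry(hexagon((2.0, 1.0, 5.0)))
    assert np.linalg.norm(g.normal) == pytest.approx(1.0)
    assert abs(g.normal[2]) == pytest.approx(1.0)
    assert g.centroid == pytest.approx([2.0, 1.0, 5.0])


def test_ligand_without_rings_is_an_error():
    top, traj = build_system(
        [("serotonin", "ligand", "n/a", ["C"] * 6),
         ("serotonin", "ligand", "n/a", ["C"] * 6)],
        np.zeros((1, 12, 3)),
        rings={0: [list(range(6))]},
    )
    with pytest.raises(ValidationError, match="ring"):
        detect_stacking_pairs(traj, top)


def test_stacking_symmetry_monotonicity_and_oracle(rng):
    """Frame-wise flags are pair-symmetric, never unmarked by looser
    thresholds, and equal the direct geometric evaluation."""
    checked = 0
    for _ in range(25):
        top, traj = random_small_system(rng)
        ligs = sorted(m.id for m in top.molecules_with_role("ligand"))
        if len(ligs) < 2:
            continue
        series = detect_stacking_pairs(traj, top, d_max=8.0, angle_max=40.0)
        loose = detect_stacking_pairs(traj, top, d_max=12.0, angle_max=60.0)
        for (la, lb), s in series.items():
            assert np.array_equal(
                s.stacked, brute_stacking(traj, top, la, lb, 8.0, 40.0))
            assert np.all(loose[(la, lb)].stacked >= s.stacked)
            checked += 1
    assert checked >= 5


def test_rotational_invariance_of_stacking_and_classification(rng):
    top, traj = random_small_system(rng)
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    rotated = traj.__class__(traj.coords @ q.T, dt=traj.dt, box=traj.box)
    ligs = sorted(m.id for m in top.molecules_with_role("ligand"))
    partners = [m.id for m in top.molecules if m.role != "ligand"]
    a = classify_contacts(traj, top, 0, partners, ligand_id=ligs[0])
    b = classify_contacts(rotated, top, 0, partners, ligand_id=ligs[0])
    assert [(c.partner_atom_id, c.cls) for c in a] \
        == [(c.partner_atom_id, c.cls) for c in b]
    for ca, cb in zip(a, b):
        assert ca.distance == pytest.approx(cb.distance, abs=1e-9)
        if ca.angle is not None:
            assert ca.angle == pytest.approx(cb.angle, abs=1e-6)


def _lig_partner(partner_elements, partner_coords, donors=(), acceptors=()):
    lig_coords = hexagon((0, 0, 0))
    return build_system(
        [("serotonin", "ligand", "n/a", ["C"] * 6),
         ("CHOL", "sterol", "upper", partner_elements)],
        np.concatenate([lig_coords, np.atleast_2d(partner_coords)])[None],
        rings={0: [list(range(6))]},
        donors=donors, acceptors=acceptors,
    )


def test_hbond_by_distance():
    # ligand ring C0 promoted to donor-bearing: mark atom 0 donor, partner O acceptor
    top, traj = _lig_partner(["O"], [(1.4 + 2.8, 0.0, 0.0)],
                             donors=[0], acceptors=[6])
    found = classify_contacts(traj, top, 0, [1])
    assert [c.cls for c in found] == ["hbond"]
    assert found[0].distance == pytest.approx(2.8)


def test_no_hbond_beyond_cutoff_falls_to_nothing():
    top, traj = _lig_partner(["O"], [(1.4 + 4.5, 0.0, 0.0)],
                             donors=[0], acceptors=[6])
    assert classify_contacts(traj, top, 0, [1]) == []


def test_hbond_angle_criterion_with_explicit_hydrogen():
    """With an explicit H on the donor, a bent D-H-A arrangement (< 120°)
    demotes the pair; a near-linear one keeps it."""
    # donor O at origin-side ring atom 0 (x=1.4); acceptor O 2.8 Å away on +x
    linear_h = (2.4, 0.0, 0.0)        # between donor and acceptor: ~180°
    bent_h = (1.4, 1.0, 0.0)          # perpendicular: ~45°
    for h_pos, expect in ((linear_h, ["hbond"]), (bent_h, ["vdw"])):
        top, traj = build_system(
            [("serotonin", "ligand", "n/a", ["C"] * 6 + ["H"]),
             ("CHOL", "sterol", "upper", ["O"])],
            np.concatenate([hexagon((0, 0, 0)), [h_pos], [(4.2, 0.0, 0.0)]])[None],
            rings={0: [list(range(6))]},
            donors=[0], acceptors=[7],
        )
        assert [c.cls for c in classify_contacts(traj, top, 0, [1])] == expect


def test_chpi_carbon_above_ring_centroid():
    top, traj = _lig_partner(["C"], [(0.0, 0.0, 3.5)])
    found = classify_contacts(traj, top, 0, [1])
    assert [c.cls for c in found] == ["ch_pi"]
    assert found[0].angle == pytest.approx(90.0)


def test_vdw_fallback_for_in_plane_carbon():
    # carbon 3 Å from a ring atom but in the ring plane: fails the elevation
    top, traj = _lig_partner(["C"], [(4.4, 0.0, 0.0)])
    assert [c.cls for c in classify_contacts(traj, top, 0, [1])] == ["vdw"]


def test_classification_priority_is_exclusive_per_atom():
    # an acceptor O directly above the centroid: hbond beats proximity classes
    top, traj = _lig_partner(["O"], [(0.0, 0.0, 3.2)],
                             donors=[0, 1, 2, 3, 4, 5], acceptors=[6])
    found = classify_contacts(traj, top, 0, [1])
    assert [c.cls for c in found] == ["hbond"]


def test_classification_matches_exhaustive_oracle(rng):
    for _ in range(25):
        top, traj = random_small_system(rng)
        lig = top.molecules_with_role("ligand")[0].id
        partners = [m.id for m in top.molecules if m.role != "ligand"]
        frame = int(rng.integers(0, traj.n_frames))
        got = {c.partner_atom_id: c.cls
               for c in classify_contacts(traj, top, frame, partners,
                                          ligand_id=lig)}
        assert got == brute_classify(traj, top, frame, lig, partners)


def test_classify_frame_out_of_range():
    top, traj = _lig_partner(["C"], [(0.0, 0.0, 3.5)])
    with pytest.raises(ValidationError, match="frame"):
        classify_contacts(traj, top, 5, [1])


def _series(stacked, mind, dt=0.1):
    stacked = np.asarray(stacked, bool)
    return StackingSeries((0, 1), stacked, np.asarray(mind, float), 5.0, 30.0,
                          np.arange(stacked.size) * dt)


def test_dissociation_called_at_first_sustained_release():
    stacked = [True] * 20 + [False] * 30
    mind = [3.5] * 20 + [9.0] * 30
    ev = detect_dissociation_event(_series(stacked, mind), dwell_frames=5)
    assert ev.formed_at == 0.0
    assert ev.dissociated_at == pytest.approx(2.0)


def test_never_stacked_gives_no_event():
    ev = detect_dissociation_event(_series([False] * 30, [20.0] * 30))
    assert ev.formed_at is None and ev.dissociated_at is None


def test_flickering_series_yields_no_event():
    stacked = [bool(i % 2) for i in range(40)]
    mind = [3.5 if s else 9.0 for s in stacked]
    ev = detect_dissociation_event(_series(stacked, mind), dwell_frames=5)
    assert ev.formed_at is None and ev.dissociated_at is None


def test_brief_release_does_not_dissociate():
    stacked = [True] * 20 + [False] * 3 + [True] * 20
    mind = [3.5] * 20 + [9.0] * 3 + [3.5] * 20
    ev = detect_dissociation_event(_series(stacked, mind), dwell_frames=5)
    assert ev.formed_at == 0.0 and ev.dissociated_at is None


def test_dissociation_matches_state_machine_replay(rng):
    for _ in range(50):
        n = int(rng.integers(10, 60))
        stacked = rng.random(n) < 0.5
        mind = np.where(stacked, 3.5, rng.uniform(4.0, 12.0, n))
        s = _series(stacked, mind)
        ev = detect_dissociation_event(s, dwell_frames=4, release_d=8.0)
        formed, diss = replay_dissociation(stacked, mind, s.times, 4, 8.0)
        assert ev.formed_at == formed and ev.dissociated_at == diss


def test_dwell_validation():
    with pytest.raises(ValidationError):
        detect_dissociation_event(_series([True] * 10, [3.5] * 10),
                                  dwell_frames=0)


def test_planted_dimer_recovered_to_the_frame():
    spec = TrajectorySpec(n_frames=80, n_popc=16, n_chol=16, n_ligands=2,
                          dimer_spec=DimerSpec((0, 1), dissociate_at_frame=45,
                                               stacked_from_frame=10), seed=13)
    b = gen_membrane_trajectory(spec)
    series = detect_stacking_pairs(b.trajectory, b.topology)
    (_, s), = series.items()
    ev = detect_dissociation_event(s, dwell_frames=5, release_d=8.0)
    assert ev.formed_at == pytest.approx(10 * 0.1)
    assert ev.dissociated_at == pytest.approx(45 * 0.1)
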