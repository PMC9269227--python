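"""Geometric contact detection: H-bonds, pi-pi stacks, salt bridges."""

import numpy as np
import pytest

from conftest import hexagon, make_pdb, pdb_line
from ivscreen.interactions import (ContactCutoffs, InteractionReport,
                                   LigandPose, audit_pose, classify_ring_pair,
                                   detect_hbonds, detect_pistacks,
                                   detect_salt_bridges, normalize_label,
                                   score_known_site, ContactAtom, HBondContact)
from ivscreen.panel import clean_structure


def serine_receptor(og_pos, res_id=195, chain="A"):
    """A lone serine with its OG hydroxyl at ``og_pos``."""
    x, y, z = og_pos
    lines = [
        pdb_line(1, "N", "SER", chain, res_id, x + 3.0, y + 2.0, z, element="N"),
        pdb_line(2, "CA", "SER", chain, res_id, x + 2.4, y + 1.0, z),
        pdb_line(3, "C", "SER", chain, res_id, x + 3.2, y, z),
        pdb_line(4, "O", "SER", chain, res_id, x + 4.4, y, z, element="O"),
        pdb_line(5, "CB", "SER", chain, res_id, x + 1.0, y + 0.6, z),
        pdb_line(6, "OG", "SER", chain, res_id, x, y, z, element="O"),
    ]
    return clean_structure(make_pdb(lines), pdb_id="ser")


def hydroxyl_pose(o_pos, h_pos=None):
    """A one-heavy-atom ligand: a hydroxyl oxygen, optionally with its H."""
    donor_h = {0: np.asarray([h_pos])} if h_pos is not None else {}
    return LigandPose(elements=["O"], coords=np.asarray([o_pos], dtype=float),
                      donors=frozenset({0}), acceptors=frozenset({0}),
                      donor_hydrogens=donor_h)


def test_hbond_detected_inside_windows():
    rec = serine_receptor((0.0, 0.0, 0.0))
    # O-H...O at 2.9 Å with a ~165 deg donor angle
    h = np.array([0.0, 0.25, 1.95])
    pose = hydroxyl_pose((0.0, 0.0, 2.9), h_pos=h)
    contacts = detect_hbonds(pose, rec)
    assert contacts
    best = contacts[0]
    assert best.distance == pytest.approx(2.9, abs=1e-6)
    assert best.angle > 150


def test_hbond_beyond_distance_cutoff_not_detected():
    rec = serine_receptor((0.0, 0.0, 0.0))
    pose = hydroxyl_pose((0.0, 0.0, 4.2))
    assert detect_hbonds(pose, rec) == []


def test_hbond_bad_angle_rejected_when_hydrogen_known():
    rec = serine_receptor((0.0, 0.0, 0.0))
    # hydrogen pointing away from the acceptor: angle ~0
    pose = hydroxyl_pose((0.0, 0.0, 2.9), h_pos=(0.0, 0.0, 3.9))
    assert all(c.donor.owner != "ligand" for c in detect_hbonds(pose, rec))


def test_serine_fixture_yields_single_labelled_hbond():
    """A ligand hydroxyl placed at a catalytic serine gives one contact."""
    rec = serine_receptor((0.0, 0.0, 0.0), res_id=195)
    pose = hydroxyl_pose((0.0, 0.0, 2.9), h_pos=(0.0, 0.0, 0.95))
    contacts = detect_hbonds(pose, rec)
    ser = [c for c in contacts if "Ser195" in c.residue_label]
    assert len(ser) == 1
    assert ser[0].residue_label == "A:Ser195"


def phe_receptor(center, normal="z", res_id=264, res_name="PHE"):
    names = ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]
    coords = hexagon(center, normal=normal)
    lines = [pdb_line(i + 1, n, res_name, "A", res_id, *xyz)
             for i, (n, xyz) in enumerate(zip(names, coords))]
    return clean_structure(make_pdb(lines), pdb_id="phe")


def benzene_pose(center, normal="z"):
    coords = hexagon(center, normal=normal)
    return LigandPose(elements=["C"] * 6, coords=coords,
                      rings=(tuple(range(6)),))


def test_parallel_stack_detected():
    rec = phe_receptor((0, 0, 3.8))
    (c,) = detect_pistacks(benzene_pose((0, 0, 0)), rec)
    assert c.geometry == "parallel"
    assert c.centroid_distance == pytest.approx(3.8, abs=1e-6)
    assert c.interplanar_angle == pytest.approx(0.0, abs=1e-6)
    assert c.residue_label == "A:Phe264"


def test_stack_beyond_cutoff_not_detected():
    rec = phe_receptor((0, 0, 7.0))
    assert detect_pistacks(benzene_pose((0, 0, 0)), rec) == []


def test_perpendicular_rings_are_t_shaped():
    rec = phe_receptor((0, 0, 5.0), normal="x")
    (c,) = detect_pistacks(benzene_pose((0, 0, 0)), rec)
    assert c.geometry == "t_shaped"
    assert c.interplanar_angle == pytest.approx(90.0, abs=1e-6)


def test_intermediate_tilt_not_reported():
    # 45 deg tilt: neither parallel (<=30) nor t-shaped (>=60)
    ang = np.radians(45)
    rot = np.array([[1, 0, 0],
                    [0, np.cos(ang), -np.sin(ang)],
                    [0, np.sin(ang), np.cos(ang)]])
    tilted = hexagon((0, 0, 0)) @ rot.T + np.array([0, 0, 4.0])
    dist, angle, geom = classify_ring_pair(hexagon((0, 0, 0)), tilted)
    assert angle == pytest.approx(45.0, abs=1e-6)
    assert geom is None


def test_ring_classification_symmetric_under_role_swap():
    a = hexagon((0, 0, 0))
    b = hexagon((1.0, 0.5, 3.9), normal="x")
    assert classify_ring_pair(a, b) == classify_ring_pair(b, a)


def test_contacts_invariant_under_rigid_rototranslation():
    rec = phe_receptor((0, 0, 3.8))
    pose = benzene_pose((0, 0, 0))
    (before,) = detect_pistacks(pose, rec)

    theta = np.radians(30)
    rot = np.array([[np.cos(theta), -np.sin(theta), 0],
                    [np.sin(theta), np.cos(theta), 0],
                    [0, 0, 1]])
    shift = np.array([5.0, -3.0, 2.0])
    rec.atoms.coord = rec.atoms.coord @ rot.T + shift
    moved = LigandPose(elements=pose.elements, coords=pose.coords @ rot.T + shift,
                       rings=pose.rings)
    (after,) = detect_pistacks(moved, rec)
    # receptor coordinates are stored in single precision
    assert after.centroid_distance == pytest.approx(before.centroid_distance,
                                                    abs=1e-5)
    assert after.geometry == before.geometry


def test_salt_bridge_between_carboxylate_and_arginine():
    lines = [
        pdb_line(1, "CD", "ARG", "A", 288, 3.0, 2.0, 0.0),
        pdb_line(2, "NE", "ARG", "A", 288, 1.0, 1.0, 0.0, element="N"),
        pdb_line(3, "NH1", "ARG", "A", 288, 1.0, -1.0, 0.0, element="N"),
        pdb_line(4, "NH2", "ARG", "A", 288, 2.4, 0.0, 0.0, element="N"),
    ]
    rec = clean_structure(make_pdb(lines), pdb_id="arg")
    pose = LigandPose(elements=["O"], coords=np.array([[0.0, 0.0, 2.0]]),
                      acceptors=frozenset({0}), charges={0: -1})
    (sb,) = detect_salt_bridges(pose, rec)
    assert sb.residue_label == "A:Arg288"
    assert sb.distance <= 4.0


def test_reported_contacts_satisfy_their_own_cutoffs():
    """Self-audit: every reported geometric value is inside its window."""
    rec = serine_receptor((0.0, 0.0, 0.0))
    pose = hydroxyl_pose((0.3, 0.4, 2.7), h_pos=(0.1, 0.2, 0.95))
    cut = ContactCutoffs()
    report = audit_pose(pose, rec)
    for h in report.hbonds:
        assert h.distance <= cut.hbond_distance
        if h.angle is not None:
            assert h.angle >= cut.hbond_angle_min


def test_known_site_scoring_normalizes_chain_conventions():
    report = InteractionReport("c", "p", 1, hbonds=[
        HBondContact(ContactAtom("ligand", "O1", "O1"),
                     ContactAtom("receptor", "B:Ser60", "OG"), 2.9),
        HBondContact(ContactAtom("ligand", "O2", "O2"),
                     ContactAtom("receptor", "B:Leu120", "O"), 3.1),
    ])
    hits = score_known_site(report, ["Ser60", "Leu120", "Gly121"])
    assert hits == ["B:Leu120", "B:Ser60"]
    assert report.known_site_residues_hit == hits
    assert score_known_site(InteractionReport("c", "p", 1), ["Ser60"]) == []
    assert normalize_label("B:Ser60") == normalize_label("ser60")
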