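"""Conformational metrics and the PR/NR/DISORDERED classifier."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from loopstate.errors import MissingAtomError, NotApplicableError
from loopstate.geometry import fit_helix_axis, rotate_about_axis, wrap_angle
from loopstate.hbonds import HBondCriteria
from loopstate.metrics import (
    STATE_DISORDERED,
    STATE_NR,
    STATE_PR,
    StateThresholds,
    axis_rotation_angle,
    ca_pair_distance,
    classify_icl2,
    count_i_i4_hbonds,
    helix5_displacement,
    icl2_angle,
    icl2_helicity,
    loop_end_to_end,
    marker_tm2_distance,
    state_fractions,
    tm5_vertical_shift,
)
from loopstate.structures import (
    AtomMeta,
    Frame,
    LandmarkMap,
    ResidueSpan,
    Topology,
    resolve_anchor,
    select_range,
)
from loopstate.synth import (
    TwoStateSimSpec,
    build_chain,
    build_ideal_helix,
    simulate_two_state,
)


def _marker_indices(frame):
    tip = frame.topology.find("A", 114, "OH")[0]
    base = frame.topology.find("A", 112, "CG")[0]
    return tip, base


# --------------------------------------------------------------------------
# ICL2 angle
# --------------------------------------------------------------------------

def test_icl2_angle_zero_against_itself(toy_frame, toy_map):
    a_raw, a_rel = icl2_angle(toy_frame, toy_frame, toy_map)
    assert a_raw == pytest.approx(80.0, abs=1e-9)  # generator azimuth
    assert a_rel == pytest.approx(0.0, abs=1e-9)


def test_icl2_angle_atan2_convention(toy_frame, toy_map):
    """v = (0, 1, 0) reads 0 deg; v = (0, 0, 2) reads 90 deg on the unit circle."""
    tip, base = _marker_indices(toy_frame)
    for v, expected in (([0.0, 1.0, 0.0], 0.0), ([0.0, 0.0, 2.0], 90.0)):
        coords = toy_frame.coords.copy()
        coords[tip] = coords[base] + np.array(v)
        frame = toy_frame.with_coords(coords)
        a_raw, _ = icl2_angle(frame, toy_frame, toy_map)
        assert a_raw == pytest.approx(expected, abs=1e-9)


def test_icl2_angle_explicit_rotation_oracle(toy_frame, toy_map):
    """Markers rotated -40 deg about the x-axis read a_rel = -40 exactly."""
    R = Rotation.from_euler("x", -40, degrees=True).as_matrix()
    tip, base = _marker_indices(toy_frame)
    coords = toy_frame.coords.copy()
    for i in (tip, base):
        coords[i] = R @ coords[i]
    frame = toy_frame.with_coords(coords)
    _, a_rel = icl2_angle(frame, toy_frame, toy_map)
    assert a_rel == pytest.approx(-40.0, abs=1e-6)


# --------------------------------------------------------------------------
# tip-TM2 distance
# --------------------------------------------------------------------------

def test_marker_tm2_distance_values(toy_frame, toy_map):
    assert marker_tm2_distance(toy_frame, toy_map) == pytest.approx(10.2, abs=1e-9)
    tip, _ = _marker_indices(toy_frame)
    coords = toy_frame.coords.copy()
    coords[tip] = resolve_anchor(toy_frame, toy_map, "tm2_ref") + np.array([3.0, 4.0, 0.0])
    assert marker_tm2_distance(toy_frame.with_coords(coords), toy_map) == pytest.approx(5.0)
    coords[tip] = resolve_anchor(toy_frame, toy_map, "tm2_ref")
    assert marker_tm2_distance(toy_frame.with_coords(coords), toy_map) == 0.0


# --------------------------------------------------------------------------
# Helicity rule
# --------------------------------------------------------------------------

def _loop_map():
    return LandmarkMap(ranges={"icl2": [ResidueSpan("A", 110, 118)]})


def test_helicity_ideal_helix_against_itself(helix9):
    helical, n_hb, rmsd = icl2_helicity(helix9, helix9, _loop_map())
    assert helical and n_hb == 5 and rmsd < 1e-9


def test_helicity_extended_chain_fails_both_branches(helix9):
    extended = build_chain(9, phi=180.0, psi=180.0, start_res=110)
    helical, n_hb, rmsd = icl2_helicity(extended, helix9, _loop_map())
    assert n_hb == 0
    assert rmsd > 2.0
    assert not helical


def test_helicity_broken_hbonds_rescued_by_rmsd_branch(helix9):
    """Carbonyls pushed outward break every H-bond; the RMSD branch still fires."""
    coords = helix9.coords.copy()
    axis = np.array([1.0, 0.0, 0.0])
    for i, meta in enumerate(helix9.topology.atom_meta):
        if meta.atom_name == "O":
            radial = coords[i] - (coords[i] @ axis) * axis
            coords[i] = coords[i] + 2.0 * radial / np.linalg.norm(radial)
    twisted = helix9.with_coords(coords)
    helical, n_hb, rmsd = icl2_helicity(twisted, helix9, _loop_map())
    assert n_hb < 3
    assert rmsd < 2.0  # 9 of 36 backbone atoms moved 2 A -> rmsd = 1.0
    assert rmsd == pytest.approx(1.0, abs=0.05)
    assert helical


def test_helicity_incomplete_backbone_errors(helix9):
    metas = [m for m in helix9.topology.atom_meta if not (m.residue_number == 114 and m.atom_name == "O")]
    keep = [i for i, m in enumerate(helix9.topology.atom_meta)
            if not (m.residue_number == 114 and m.atom_name == "O")]
    frame = Frame(Topology(metas), helix9.coords[keep])
    with pytest.raises(MissingAtomError):
        count_i_i4_hbonds(frame, _loop_map())


# --------------------------------------------------------------------------
# Classifier
# --------------------------------------------------------------------------

@pytest.mark.parametrize(
    "a,d,helical,expected",
    [
        (80.0, 10.0, True, STATE_PR),   # 10 - 80/20 = 6 < 10 < 13
        (130.0, 10.0, True, STATE_NR),  # angle outside (45, 120)
        (80.0, 14.0, True, STATE_NR),   # distance above 13
        (80.0, 10.0, False, STATE_DISORDERED),
        (40.0, 16.3, True, STATE_NR),   # the synthetic NR geometry
    ],
)
def test_classifier_threshold_cases(a, d, helical, expected):
    assert classify_icl2(a, d, helical) == expected


def test_classifier_matches_brute_force_grid():
    """Exact agreement with a literal evaluation of the threshold inequalities
    on a 10,000-point grid over (a, d, helical)."""
    th = StateThresholds()
    a_grid = np.linspace(-180.0, 180.0, 100)
    d_grid = np.linspace(0.0, 20.0, 50)
    for helical in (True, False):
        for a in a_grid:
            for d in d_grid:
                got = classify_icl2(float(a), float(d), helical, th)
                if not helical:
                    want = STATE_DISORDERED
                elif (45.0 < a < 120.0) and (10.0 - a / 20.0 < d < 13.0):
                    want = STATE_PR
                else:
                    want = STATE_NR
                assert got == want, (a, d, helical)


def test_state_fractions():
    states = [STATE_PR, STATE_PR, STATE_NR, STATE_DISORDERED]
    assert state_fractions(states, {STATE_PR}) == 0.5
    assert state_fractions([STATE_PR] * 4, {STATE_PR}) == 1.0
    assert state_fractions([STATE_PR, STATE_NR, STATE_DISORDERED], {STATE_PR, STATE_NR}) == pytest.approx(2 / 3)
    total = sum(
        state_fractions(states, {s}) for s in (STATE_PR, STATE_NR, STATE_DISORDERED)
    )
    assert total == pytest.approx(1.0)


# --------------------------------------------------------------------------
# TM5 vertical shift
# --------------------------------------------------------------------------

def _mini_tm5_frame(ca130, ca141, ca190):
    metas = [
        AtomMeta(1, "CA", "ALA", 130, "A", "C"),
        AtomMeta(2, "CA", "ALA", 141, "A", "C"),
        AtomMeta(3, "CA", "ALA", 190, "A", "C"),
    ]
    lmap = LandmarkMap(
        anchors={
            "tm4_lower": ("A", 130, "CA"),
            "tm4_upper": ("A", 141, "CA"),
            "tm5_probe": ("A", 190, "CA"),
        }
    )
    from loopstate.structures import Anchor

    lmap.anchors = {k: Anchor(*v) for k, v in lmap.anchors.items()}
    return Frame(Topology(metas), np.array([ca130, ca141, ca190], dtype=float)), lmap


def test_tm5_shift_hand_projection():
    frame, lmap = _mini_tm5_frame([0, 0, 0], [0, 0, 10], [3, 0, 4])
    assert tm5_vertical_shift(frame, lmap, reference_s=0.0) == pytest.approx(4.0)
    assert tm5_vertical_shift(frame, lmap, reference_s=4.0) == pytest.approx(0.0)


def test_tm5_shift_toy_self_reference(toy_frame, toy_map):
    s = tm5_vertical_shift(toy_frame, toy_map, reference_s=0.0)
    assert tm5_vertical_shift(toy_frame, toy_map, reference_s=s) == pytest.approx(0.0)


def test_tm5_shift_displaced_probe(toy_frame, toy_map):
    lower = resolve_anchor(toy_frame, toy_map, "tm4_lower")
    upper = resolve_anchor(toy_frame, toy_map, "tm4_upper")
    u = (upper - lower) / np.linalg.norm(upper - lower)
    i190 = toy_frame.topology.find("A", 190, "CA")[0]
    coords = toy_frame.coords.copy()
    coords[i190] += 3.0 * u
    s0 = tm5_vertical_shift(toy_frame, toy_map)
    s1 = tm5_vertical_shift(toy_frame.with_coords(coords), toy_map)
    assert s1 - s0 == pytest.approx(3.0, abs=1e-9)


# --------------------------------------------------------------------------
# CA pair distance, G-protein metrics
# --------------------------------------------------------------------------

def test_ca_pair_distance():
    metas = [AtomMeta(1, "CA", "ALA", 105, "A", "C"), AtomMeta(2, "CA", "ALA", 222, "A", "C")]
    frame = Frame(Topology(metas), np.array([[0.0, 0.0, 0.0], [1.0, 2.0, 2.0]]))
    assert ca_pair_distance(frame, 105, 222) == pytest.approx(3.0)
    assert ca_pair_distance(frame, 105, 105) == 0.0
    with pytest.raises(MissingAtomError):
        ca_pair_distance(frame, 105, 999)


def test_helix5_displacement_translation_and_invariance(toy_frame, toy_map, rng):
    assert helix5_displacement(toy_frame, toy_frame, toy_map) == pytest.approx(0.0, abs=1e-9)
    # G protein rigidly translated by (3, 0, 0) with the receptor fixed
    coords = toy_frame.coords.copy()
    for i, m in enumerate(toy_frame.topology.atom_meta):
        if m.chain_id == "B":
            coords[i] += np.array([3.0, 0.0, 0.0])
    assert helix5_displacement(toy_frame.with_coords(coords), toy_frame, toy_map) == pytest.approx(3.0, abs=1e-9)
    # whole-system rigid motion is removed by the receptor alignment
    R = Rotation.random(random_state=rng).as_matrix()
    t = rng.normal(0, 5, 3)
    moved = toy_frame.with_coords(toy_frame.coords @ R.T + t)
    assert helix5_displacement(moved, toy_frame, toy_map) == pytest.approx(0.0, abs=1e-6)


def test_loop_end_to_end(toy_frame, toy_map):
    assert loop_end_to_end(toy_frame, toy_map) == pytest.approx(7.0)  # built spacing


# --------------------------------------------------------------------------
# Axis-fitted rotation angle
# --------------------------------------------------------------------------

def _rotate_loop(frame, lmap, angle):
    axis = fit_helix_axis(select_range(frame, lmap, "icl2", ("CA",)))
    idx = [
        i for i, m in enumerate(frame.topology.atom_meta)
        if m.chain_id == "A" and 110 <= m.residue_number <= 118
    ]
    coords = frame.coords.copy()
    coords[idx] = rotate_about_axis(coords[idx], axis, angle)
    return frame.with_coords(coords)


def test_axis_rotation_angle_identity_and_rotation(toy_frame, toy_map):
    assert axis_rotation_angle(toy_frame, toy_frame, toy_map) == pytest.approx(0.0, abs=1e-9)
    rotated = _rotate_loop(toy_frame, toy_map, -40.0)
    assert axis_rotation_angle(rotated, toy_frame, toy_map) == pytest.approx(-40.0, abs=1.0)


def test_axis_rotation_angle_agrees_with_plane_projection(toy_frame, toy_map):
    """The two rotation metrics agree within 5 deg when the loop axis is near x."""
    for angle in (-40.0, -20.0, 25.0):
        rotated = _rotate_loop(toy_frame, toy_map, angle)
        axis_angle = axis_rotation_angle(rotated, toy_frame, toy_map)
        _, a_rel = icl2_angle(rotated, toy_frame, toy_map)
        assert abs(axis_angle - a_rel) <= 5.0


def test_axis_rotation_angle_requires_helical(toy_frame, toy_map):
    ext = build_chain(9, phi=180.0, psi=180.0, start_res=110)
    idx = [
        i for i, m in enumerate(toy_frame.topology.atom_meta)
        if m.chain_id == "A" and 110 <= m.residue_number <= 118
    ]
    coords = toy_frame.coords.copy()
    k = 0
    for i in idx:
        m = toy_frame.topology.atom_meta[i]
        hits = ext.topology.find("A", m.residue_number, m.atom_name)
        coords[i] = ext.coords[hits[0]] if hits else coords[i] + 30.0
    with pytest.raises(NotApplicableError):
        axis_rotation_angle(toy_frame.with_coords(coords), toy_frame, toy_map)


# --------------------------------------------------------------------------
# Joint rigid invariance
# --------------------------------------------------------------------------

def test_metrics_invariant_under_joint_rigid_transform(toy_frame, toy_map, rng):
    """Moving frame and reference together changes no metric (tolerance 1e-6).

    The plane-projection angle is measured in the reference's z,y lab plane,
    so its invariance group is the subgroup preserving that plane
    (translations and rotations about x); it is checked under those.  All
    other metrics, including the axis-fitted rotation angle, are invariant
    under arbitrary joint rigid motions.
    """
    sim = simulate_two_state(
        toy_frame, toy_map, TwoStateSimSpec(n_frames=5, noise_sigma=0.1, seed=3,
                                            p_stay_pr=0.5, p_stay_nr=0.5)
    )
    frame = sim.trajectory.frame(3)
    R = Rotation.random(random_state=rng).as_matrix()
    t = rng.normal(0, 5, 3)
    frame_m = frame.with_coords(frame.coords @ R.T + t)
    ref_m = toy_frame.with_coords(toy_frame.coords @ R.T + t)

    # plane-projection angle: invariant under its measurement-plane subgroup
    Rx = Rotation.from_euler("x", 73.0, degrees=True).as_matrix()
    tx = np.array([4.0, -2.0, 7.0])
    a0 = icl2_angle(frame, toy_frame, toy_map)
    a1 = icl2_angle(
        frame.with_coords(frame.coords @ Rx.T + tx),
        toy_frame.with_coords(toy_frame.coords @ Rx.T + tx),
        toy_map,
    )
    assert wrap_angle(a1[0] - a0[0] - 73.0) == pytest.approx(0.0, abs=1e-6)  # raw co-rotates
    assert a1[1] == pytest.approx(a0[1], abs=1e-6)  # zeroed angle invariant

    assert axis_rotation_angle(frame_m, ref_m, toy_map) == pytest.approx(
        axis_rotation_angle(frame, toy_frame, toy_map), abs=1e-6
    )
    assert marker_tm2_distance(frame_m, toy_map) == pytest.approx(
        marker_tm2_distance(frame, toy_map), abs=1e-6
    )
    h0 = icl2_helicity(frame, toy_frame, toy_map)
    h1 = icl2_helicity(frame_m, ref_m, toy_map)
    assert h0[0] == h1[0] and h0[1] == h1[1]
    assert h1[2] == pytest.approx(h0[2], abs=1e-6)
    assert helix5_displacement(frame_m, ref_m, toy_map) == pytest.approx(
        helix5_displacement(frame, toy_frame, toy_map), abs=1e-6
    )
    assert loop_end_to_end(frame_m, toy_map) == pytest.approx(
        loop_end_to_end(frame, toy_map), abs=1e-6
    )
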