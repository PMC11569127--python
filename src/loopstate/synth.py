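"""Synthetic receptor structures and two-state loop trajectories.

Every metric, classifier and statistic in this package can be exercised
without any external download through a *toy receptor*: four parallel
transmembrane (TM) helix stubs spanning a membrane slab along z (the
alignment set), a short alpha-helical intracellular loop (ICL2 analogue)
lying along x on the intracellular side, sidechain marker pseudo-atoms on
loop residues 112 and 114 (L112:CG and Y114:OH analogues), a TM2 reference
atom placed so that the tip-to-TM2 distance discriminates the rotated
state, a TM5 stub with the vertical-shift anchors, and optionally a
G-protein chain (helix-5 and beta6-alpha5 loop CAs) and a bridging water.

:func:`simulate_two_state` drives the loop through a two-state Markov
chain between the crystal-like PR orientation and a rotated NR orientation
(-40 degrees about the fitted helix axis by default), with optional
transient unfolding to an extended conformation and i.i.d. Gaussian
coordinate noise, emitting per-frame ground-truth labels and angles.

The helix builder is parametric: CA atoms sit exactly on a cylinder with
the requested rise, twist and radius, and the N, C, O backbone atoms use
cylindrical offsets fitted once to an ideal alpha-helix built from
canonical (phi, psi) = (-57, -47) internal coordinates, so interior
backbone dihedrals are alpha-helical and all i, i+4 O...N distances are
well inside hydrogen-bonding range (about 2.86 A at the defaults).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import InfeasibleGeometryError, MissingAtomError, ParameterError
from .geometry import fit_helix_axis, rotate_about_axis
from .structures import (
    Anchor,
    AtomMeta,
    Frame,
    LandmarkMap,
    ResidueSpan,
    Topology,
    Trajectory,
    select_range,
)

# Cylindrical offsets of backbone atoms relative to the CA helix:
# (axial offset dz [A], own radius [A], phase offset [deg]); derived from an
# ideal (phi, psi) = (-57, -47) alpha-helix.  CA radius is the builder's
# ``radius`` parameter.
_HELIX_OFFSETS: Mapping[str, tuple[float, float | None, float]] = {
    "N": (-0.918690, 1.551676, -26.753415),
    "CA": (0.0, None, 0.0),
    "C": (1.068956, 1.667124, 26.736067),
    "O": (2.256630, 1.921705, 20.332244),
}

_BACKBONE = ("N", "CA", "C", "O")

# Engh-Huber style internal coordinates for the torsion-driven chain builder
_BOND = {"N-CA": 1.458, "CA-C": 1.525, "C-N": 1.329, "C-O": 1.231}
_ANGLE = {"N-CA-C": 111.2, "CA-C-N": 116.2, "C-N-CA": 121.7, "CA-C-O": 120.8}


def _assemble(metas: Sequence[AtomMeta], coords: Sequence[np.ndarray]) -> Frame:
    return Frame(Topology(metas), np.asarray(coords, dtype=float))


def _helix_positions(
    residues: Sequence[int],
    axis_point: np.ndarray,
    axis_dir: np.ndarray,
    e1: np.ndarray,
    rise: float,
    twist: float,
    radius: float,
    center_residue: float | None = None,
    atom_names: Sequence[str] = _BACKBONE,
) -> dict[tuple[int, str], np.ndarray]:
    """Backbone positions of a parametric helix along an arbitrary axis."""
    axis_dir = np.asarray(axis_dir, dtype=float)
    axis_dir = axis_dir / np.linalg.norm(axis_dir)
    e1 = np.asarray(e1, dtype=float)
    e1 = e1 - (e1 @ axis_dir) * axis_dir
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis_dir, e1)
    if center_residue is None:
        center_residue = (residues[0] + residues[-1]) / 2.0
    out = {}
    for res in residues:
        k = res - center_residue
        for name in atom_names:
            dz, r, dphase = _HELIX_OFFSETS[name]
            rr = radius if r is None else r
            ph = np.deg2rad(k * twist + dphase)
            out[(res, name)] = (
                np.asarray(axis_point, dtype=float)
                + (k * rise + dz) * axis_dir
                + rr * (np.cos(ph) * e1 + np.sin(ph) * e2)
            )
    return out


def build_ideal_helix(
    n_res: int,
    rise: float = 1.5,
    twist: float = 100.0,
    radius: float = 2.3,
    chain: str = "A",
    start_res: int = 1,
    res_name: str = "ALA",
    axis_point: Sequence[float] = (0.0, 0.0, 0.0),
    axis_dir: Sequence[float] = (1.0, 0.0, 0.0),
) -> Frame:
    """An ideal alpha-helical backbone (N, CA, C, O per residue) along an axis.

    Successive CA atoms are separated by exactly ``rise`` along the axis
    and ``twist`` degrees in phase; the default geometry hydrogen-bonds
    every i, i+4 O...N pair at about 2.86 A.
    """
    if n_res < 2:
        raise ParameterError("an ideal helix needs at least 2 residues")
    residues = list(range(start_res, start_res + n_res))
    pos = _helix_positions(
        residues, np.asarray(axis_point, float), np.asarray(axis_dir, float),
        np.array([0.0, 1.0, 0.0]) if abs(np.asarray(axis_dir, float)[1]) < 0.9
        else np.array([1.0, 0.0, 0.0]),
        rise, twist, radius, center_residue=residues[0],
    )
    metas, coords = [], []
    serial = 1
    for res in residues:
        for name in _BACKBONE:
            metas.append(AtomMeta(serial, name, res_name, res, chain, name[0]))
            coords.append(pos[(res, name)])
            serial += 1
    return _assemble(metas, coords)


def _nerf(a, b, c, bond: float, angle: float, torsion: float) -> np.ndarray:
    """Place atom d from a-b-c with given bond length, bond angle, torsion (deg)."""
    angle = np.deg2rad(angle)
    torsion = np.deg2rad(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = bond * np.array(
        [-np.cos(angle), np.sin(angle) * np.cos(torsion), np.sin(angle) * np.sin(torsion)]
    )
    return c + d[0] * bc + d[1] * m + d[2] * n


def build_chain(
    n_res: int,
    phi: float = -57.0,
    psi: float = -47.0,
    omega: float = 180.0,
    chain: str = "A",
    start_res: int = 1,
    res_name: str = "ALA",
    origin: Sequence[float] = (0.0, 0.0, 0.0),
) -> Frame:
    """Backbone chain built from exact (phi, psi, omega) torsions.

    Unlike :func:`build_ideal_helix` this builder guarantees the backbone
    dihedrals exactly; use it for dihedral-recovery fixtures and for
    extended (phi = psi = 180) conformations.
    """
    if n_res < 1:
        raise ParameterError("need at least one residue")
    origin = np.asarray(origin, dtype=float)
    pos: dict[tuple[int, str], np.ndarray] = {}
    n0 = origin
    ca0 = origin + np.array([_BOND["N-CA"], 0.0, 0.0])
    th = np.deg2rad(_ANGLE["N-CA-C"])
    c0 = ca0 + _BOND["CA-C"] * np.array([-np.cos(th), np.sin(th), 0.0])
    pos[(0, "N")], pos[(0, "CA")], pos[(0, "C")] = n0, ca0, c0
    for i in range(1, n_res):
        pos[(i, "N")] = _nerf(
            pos[(i - 1, "N")], pos[(i - 1, "CA")], pos[(i - 1, "C")],
            _BOND["C-N"], _ANGLE["CA-C-N"], psi,
        )
        pos[(i, "CA")] = _nerf(
            pos[(i - 1, "CA")], pos[(i - 1, "C")], pos[(i, "N")],
            _BOND["N-CA"], _ANGLE["C-N-CA"], omega,
        )
        pos[(i, "C")] = _nerf(
            pos[(i - 1, "C")], pos[(i, "N")], pos[(i, "CA")],
            _BOND["CA-C"], _ANGLE["N-CA-C"], phi,
        )
    for i in range(n_res):
        # carbonyl O in the peptide plane, anti to the next N
        pos[(i, "O")] = _nerf(
            pos[(i, "N")], pos[(i, "CA")], pos[(i, "C")],
            _BOND["C-O"], _ANGLE["CA-C-O"], psi + 180.0,
        )
    metas, coords = [], []
    serial = 1
    for i in range(n_res):
        res = start_res + i
        for name in _BACKBONE:
            metas.append(AtomMeta(serial, name, res_name, res, chain, name[0]))
            coords.append(pos[(i, name)])
            serial += 1
    return _assemble(metas, coords)


# --------------------------------------------------------------------------
# Toy receptor
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ToyReceptorSpec:
    """Geometry of the synthetic receptor.

    Defaults put the base-frame ICL2 angle at +80 degrees (inside the PR
    box), the tip-to-TM2 distance at exactly ``marker_tm2_distance``, and
    are arranged so a -40 degree loop rotation carries the tip far enough
    that the rotated state fails both PR threshold tests.
    """

    icl2_range: tuple[int, int] = (110, 118)
    icl2_build_range: tuple[int, int] = (106, 122)  # flanks for terminal dihedrals
    tm_stub_length: int = 20
    marker_tip_azimuth: float = 80.0  # deg in the z,y plane; equals the base ICL2 angle
    marker_base_azimuth: float = -100.0
    marker_tip_radius: float = 9.0  # A from the loop axis (tyrosine OH reach)
    marker_base_radius: float = 5.0
    marker_tm2_distance: float = 10.2  # A, engineered tip-to-TM2 distance
    anchor_rotation: float = -40.0  # deg; TM2 ref is placed anti to this rotation
    rise: float = 1.5
    twist: float = 100.0
    radius: float = 2.3
    chain: str = "A"
    g_chain: str = "B"
    include_gprotein: bool = True
    include_water: bool = False

    def __post_init__(self):
        lo, hi = self.icl2_range
        if hi - lo + 1 < 5:
            raise ParameterError("ICL2 range must span at least 5 residues")
        blo, bhi = self.icl2_build_range
        if not (blo < lo and bhi > hi):
            raise ParameterError("icl2_build_range must enclose icl2_range with flanks")


#: (label, base (x, y), residue span, axis direction sign along z)
_TM_LAYOUT = (
    ("tm1", (0.0, 0.0), (5, 24), -1.0),
    ("tm2", (14.0, 0.0), (30, 49), +1.0),
    ("tm3", (0.0, 12.0), (85, 104), -1.0),
    ("tm4", (12.0, 12.0), (124, 143), +1.0),
    ("tm5", (22.0, 8.0), (181, 200), -1.0),
)

_ICL2_AXIS_POINT = np.array([6.0, 12.0, -16.0])
_ICL2_AXIS_DIR = np.array([1.0, 0.0, 0.0])


def build_toy_receptor(spec: ToyReceptorSpec = ToyReceptorSpec()) -> tuple[Frame, LandmarkMap]:
    """Build the toy receptor frame and its landmark map.

    The returned map resolves every anchor role used by the metric layer:
    ``icl2_marker_tip``, ``icl2_marker_base``, ``tm2_ref``, ``tm5_probe``,
    ``tm4_lower``/``tm4_upper``, and (with the G protein) ``g_loop_start``/
    ``g_loop_end``; ranges ``icl2``, ``align_set``, ``galpha_h5``.
    """
    metas: list[AtomMeta] = []
    coords: list[np.ndarray] = []
    serial = 1

    def add(name, res_name, res, chain, pos, element=None):
        nonlocal serial
        metas.append(
            AtomMeta(serial, name, res_name, res, chain, element or name[0])
        )
        coords.append(np.asarray(pos, dtype=float))
        serial += 1

    # TM stubs along +-z, CA cylinder centered on the membrane midplane z=0
    for label, (x0, y0), (lo, hi), zsign in _TM_LAYOUT:
        residues = list(range(lo, hi + 1))
        pos = _helix_positions(
            residues,
            np.array([x0, y0, 0.0]),
            np.array([0.0, 0.0, zsign]),
            np.array([1.0, 0.0, 0.0]),
            spec.rise, spec.twist, spec.radius,
        )
        for res in residues:
            res_name = "THR" if res == 39 else "ALA"
            for name in _BACKBONE:
                add(name, res_name, res, spec.chain, pos[(res, name)])

    # ICL2 helix along +x on the intracellular side, with flanking residues
    blo, bhi = spec.icl2_build_range
    icl2_residues = list(range(blo, bhi + 1))
    tip_res = 114
    base_res = 112
    pos = _helix_positions(
        icl2_residues, _ICL2_AXIS_POINT, _ICL2_AXIS_DIR, np.array([0.0, 1.0, 0.0]),
        spec.rise, spec.twist, spec.radius, center_residue=float(tip_res),
    )
    for res in icl2_residues:
        res_name = {base_res: "LEU", tip_res: "TYR"}.get(res, "ALA")
        for name in _BACKBONE:
            add(name, res_name, res, spec.chain, pos[(res, name)])
        if res == base_res:
            add("CG", "LEU", res, spec.chain, _marker_position(spec, res, "base"), "C")
        if res == tip_res:
            add("OH", "TYR", res, spec.chain, _marker_position(spec, res, "tip"), "O")

    # TM2 reference atom: on the ray from the rotated tip through the resting
    # tip, so the tip-TM2 distance grows when the loop rotates to NR.
    tip_pr = _marker_position(spec, tip_res, "tip")
    from .geometry import HelixAxis

    exact_axis = HelixAxis(_ICL2_AXIS_POINT, _ICL2_AXIS_DIR)
    tip_nr = rotate_about_axis(tip_pr, exact_axis, spec.anchor_rotation)
    u = tip_pr - tip_nr
    u /= np.linalg.norm(u)
    cb39 = tip_pr + spec.marker_tm2_distance * u
    add("CB", "THR", 39, spec.chain, cb39, "C")

    if spec.include_gprotein:
        h5_residues = list(range(519, 531))
        h5 = _helix_positions(
            h5_residues, np.array([6.0, 6.0, -26.0]), np.array([0.0, 0.0, 1.0]),
            np.array([1.0, 0.0, 0.0]), spec.rise, spec.twist, spec.radius,
            atom_names=("CA",),
        )
        for res in h5_residues:
            add("CA", "ALA", res, spec.g_chain, h5[(res, "CA")])
        for k, res in enumerate(range(504, 509)):
            add("CA", "GLY", res, spec.g_chain, np.array([-2.0 + 1.75 * k, 6.0, -30.0]))

    frame = _assemble(metas, coords)

    lo, hi = spec.icl2_range
    lmap = LandmarkMap(
        anchors={
            "icl2_marker_tip": Anchor(spec.chain, tip_res, "OH"),
            "icl2_marker_base": Anchor(spec.chain, base_res, "CG"),
            "tm2_ref": Anchor(spec.chain, 39, "CB"),
            "tm5_probe": Anchor(spec.chain, 190, "CA"),
            "tm4_lower": Anchor(spec.chain, 130, "CA"),
            "tm4_upper": Anchor(spec.chain, 141, "CA"),
            **(
                {
                    "g_loop_start": Anchor(spec.g_chain, 504, "CA"),
                    "g_loop_end": Anchor(spec.g_chain, 508, "CA"),
                }
                if spec.include_gprotein
                else {}
            ),
        },
        ranges={
            "icl2": [ResidueSpan(spec.chain, lo, hi)],
            "icl2_build": [ResidueSpan(spec.chain, blo, bhi)],
            "align_set": [
                ResidueSpan(spec.chain, span[0], span[1])
                for _label, _xy, span, _zsign in _TM_LAYOUT[:4]
            ],
            **(
                {"galpha_h5": [ResidueSpan(spec.g_chain, 519, 530)]}
                if spec.include_gprotein
                else {}
            ),
        },
        bw_table={"3.55": blo + 2, "4.39": bhi - 2},
    )
    if spec.include_water:
        frame = place_bridge_water(
            frame,
            (spec.chain, tip_res, "OH"),
            (spec.chain, tip_res, "O"),
        )
    return frame, lmap


def _marker_position(spec: ToyReceptorSpec, res: int, which: str) -> np.ndarray:
    """Resting-state position of a marker pseudo-atom on the loop."""
    if which == "tip":
        radius, azimuth = spec.marker_tip_radius, spec.marker_tip_azimuth
    else:
        radius, azimuth = spec.marker_base_radius, spec.marker_base_azimuth
    x = _ICL2_AXIS_POINT[0] + (res - 114) * spec.rise
    ph = np.deg2rad(azimuth)
    return np.array(
        [
            x,
            _ICL2_AXIS_POINT[1] + radius * np.cos(ph),
            _ICL2_AXIS_POINT[2] + radius * np.sin(ph),
        ]
    )


# --------------------------------------------------------------------------
# Bridging water
# --------------------------------------------------------------------------

def place_bridge_water(
    frame: Frame,
    partner_a: tuple[str | None, int, str],
    partner_b: tuple[str | None, int, str],
    leg_length: float = 2.8,
    chain: str = "W",
) -> Frame:
    """Insert a water (O, H1, H2) bridging two solute atoms.

    The oxygen is placed on the perpendicular bisector of the two partner
    atoms at exactly ``leg_length`` from each, with each hydrogen pointing
    at one partner (near-linear O-H...X geometry).  Raises
    :class:`InfeasibleGeometryError` when the partners are too far apart
    for the requested leg length.
    """
    positions = []
    for chain_id, res, name in (partner_a, partner_b):
        hits = frame.topology.find(chain_id, res, name)
        if len(hits) != 1:
            raise MissingAtomError(f"bridge partner {chain_id}:{res}:{name} not unique")
        positions.append(frame.coords[hits[0]])
    a, b = positions
    sep = np.linalg.norm(b - a)
    if sep >= 2.0 * leg_length - 1e-9:
        raise InfeasibleGeometryError(
            f"partners {sep:.2f} A apart cannot both be {leg_length:.2f} A from one water"
        )
    mid = (a + b) / 2.0
    ab = (b - a) / sep
    ref = np.array([0.0, 0.0, 1.0]) if abs(ab[2]) < 0.9 else np.array([0.0, 1.0, 0.0])
    n = np.cross(ab, ref)
    n /= np.linalg.norm(n)
    h = np.sqrt(leg_length**2 - (sep / 2.0) ** 2)
    o_pos = mid + h * n
    h1 = o_pos + 0.96 * (a - o_pos) / np.linalg.norm(a - o_pos)
    h2 = o_pos + 0.96 * (b - o_pos) / np.linalg.norm(b - o_pos)

    existing = [
        m.residue_number for m in frame.topology.atom_meta if m.chain_id == chain
    ]
    res_id = (max(existing) + 1) if existing else 1
    serial0 = len(frame.topology)
    metas = list(frame.topology.atom_meta) + [
        AtomMeta(serial0 + 1, "O", "HOH", res_id, chain, "O"),
        AtomMeta(serial0 + 2, "H1", "HOH", res_id, chain, "H"),
        AtomMeta(serial0 + 3, "H2", "HOH", res_id, chain, "H"),
    ]
    coords = np.vstack([frame.coords, o_pos, h1, h2])
    return Frame(Topology(metas), coords, frame.time)


# --------------------------------------------------------------------------
# Two-state simulator
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TwoStateSimSpec:
    """Markov-chain dynamics of the synthetic loop.

    ``p_stay_pr``/``p_stay_nr`` are per-frame probabilities of remaining in
    the current state; ``unfold_probability`` transiently replaces the loop
    with an extended (phi = psi = 180) conformation for single frames.  The
    seed deterministically controls the state sequence and the coordinate
    noise through two independent sub-streams.
    """

    n_frames: int
    p_stay_pr: float = 0.95
    p_stay_nr: float = 0.95
    nr_rotation: float = -40.0  # deg about the fitted loop axis
    noise_sigma: float = 0.3  # A, i.i.d. Gaussian on every coordinate
    unfold_probability: float = 0.0
    seed: int = 0
    stride_ns: float = 0.2
    start_state: str = "PR"
    label: str = ""

    def __post_init__(self):
        for name in ("p_stay_pr", "p_stay_nr", "unfold_probability"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ParameterError(f"{name} must be a probability, got {p}")
        if self.n_frames < 1:
            raise ParameterError("n_frames must be >= 1")
        if self.start_state not in ("PR", "NR"):
            raise ParameterError("start_state must be PR or NR")
        if self.noise_sigma < 0:
            raise ParameterError("noise_sigma must be >= 0")


@dataclass
class LabeledTrajectory:
    """A synthetic trajectory with per-frame ground truth."""

    trajectory: Trajectory
    true_states: list[str]
    true_angles: np.ndarray  # deg relative to the base frame; NaN when unfolded

    def __post_init__(self):
        n = self.trajectory.n_frames
        if len(self.true_states) != n or len(self.true_angles) != n:
            raise ParameterError("ground-truth lengths must match the trajectory")


def _extended_loop_coords(
    base: Frame, lmap: LandmarkMap, icl2_idx: np.ndarray
) -> np.ndarray:
    """Extended-conformation coordinates for the loop atom block."""
    meta = [base.topology.atom_meta[i] for i in icl2_idx]
    residues = sorted({m.residue_number for m in meta})
    ext = build_chain(len(residues), phi=180.0, psi=180.0, start_res=residues[0])
    anchor = base.coords[icl2_idx[0]]
    first_n = ext.coords[ext.topology.find("A", residues[0], "N")[0]]
    shift = anchor - first_n
    out = np.empty((len(icl2_idx), 3))
    for k, m in enumerate(meta):
        hits = ext.topology.find("A", m.residue_number, m.atom_name)
        if hits:
            out[k] = ext.coords[hits[0]] + shift
        else:  # marker pseudo-atom: ride along near its residue's CA
            ca = ext.coords[ext.topology.find("A", m.residue_number, "CA")[0]]
            out[k] = ca + shift + np.array([0.0, 1.5, 0.0])
    return out


def simulate_two_state(
    base: Frame,
    lmap: LandmarkMap,
    spec: TwoStateSimSpec,
    icl2_range: str = "icl2",
) -> LabeledTrajectory:
    """Simulate a two-state (PR/NR) trajectory of the loop on a base frame.

    NR frames carry the loop atoms (markers included) rotated by
    ``nr_rotation`` about the axis fitted to the base frame's loop CAs;
    unfolding events replace the loop with an extended conformation for
    single frames; Gaussian noise is added to all coordinates last.  The
    same spec always yields bit-identical output.
    """
    spans = lmap.ranges[icl2_range]
    icl2_idx = np.array(
        [
            i
            for i, m in enumerate(base.topology.atom_meta)
            if any(
                m.chain_id == s.chain and s.start <= m.residue_number <= s.stop
                for s in spans
            )
        ],
        dtype=int,
    )
    if icl2_idx.size == 0:
        raise MissingAtomError(f"no atoms in range {icl2_range!r}")
    axis = fit_helix_axis(select_range(base, lmap, icl2_range, ("CA",)))
    pr_block = base.coords[icl2_idx]
    nr_block = rotate_about_axis(pr_block, axis, spec.nr_rotation)
    dis_block = _extended_loop_coords(base, lmap, icl2_idx)

    seq_rng, noise_rng = [
        np.random.default_rng(s) for s in np.random.SeedSequence(spec.seed).spawn(2)
    ]
    n = spec.n_frames
    states: list[str] = []
    cur = spec.start_state
    stay = {"PR": spec.p_stay_pr, "NR": spec.p_stay_nr}
    flip = {"PR": "NR", "NR": "PR"}
    draws = seq_rng.random(n)
    unfold_draws = seq_rng.random(n)
    for t in range(n):
        if t > 0 and draws[t] >= stay[cur]:
            cur = flip[cur]
        states.append(cur)
    unfolded = unfold_draws < spec.unfold_probability

    coords = np.broadcast_to(base.coords, (n, base.n_atoms, 3)).copy()
    labels: list[str] = []
    angles = np.empty(n)
    for t in range(n):
        if unfolded[t]:
            coords[t, icl2_idx] = dis_block
            labels.append("DISORDERED")
            angles[t] = np.nan
        elif states[t] == "NR":
            coords[t, icl2_idx] = nr_block
            labels.append("NR")
            angles[t] = spec.nr_rotation
        else:
            labels.append("PR")
            angles[t] = 0.0
    if spec.noise_sigma > 0:
        coords += noise_rng.normal(0.0, spec.noise_sigma, coords.shape)
    times = np.arange(n) * spec.stride_ns
    traj = Trajectory(base.topology, coords, times, spec.stride_ns, spec.label)
    return LabeledTrajectory(traj, labels, angles)
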