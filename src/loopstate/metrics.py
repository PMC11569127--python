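"""Per-frame conformational metrics and the three-state ICL2 classifier.

The central observable is the orientation of the short helical second
intracellular loop (ICL2), which switches between a "positively rotated"
(PR) state seen in the agonist-bound crystal and a "negatively rotated"
(NR) state about 40 degrees away about the helix axis.  Two per-frame
numbers describe it:

* the ICL2 angle ``a``: after superposing the frame onto a reference on
  the TM1-TM4 CA set, the vector from the marker base atom (L112:CG in
  FFAR1) to the marker tip atom (Y114:OH) is projected into the z,y plane
  and read as an angle on the unit circle, ``a = atan2(v_z, v_y)``;
* the tip-to-TM2 distance ``d`` (Y114:OH to T39:CB in FFAR1), which
  detects whether the tip has swung into or away from the helical bundle.

A frame is *helical* when at least ``hbond_min`` backbone i,i+4 hydrogen
bonds are present in the loop or the loop's backbone RMSD to the helical
reference is below ``rmsd_max``.  The classifier then assigns:

* DISORDERED if not helical;
* PR if helical and ``a_low < a < a_high`` and
  ``d_intercept - a * d_slope < d < d_high`` (thresholds applied to the
  raw angle, under which the crystal conformation itself scores PR);
* NR otherwise (helical but outside the crystal-state box).

Metrics for the receptor-G protein system (TM5 vertical shift, Galpha
helix-5 displacement, beta6-alpha5 loop end-to-end distance, CA pair
distances) live here too.  Anchors and ranges are looked up by role name
in a :class:`~loopstate.structures.LandmarkMap`; the role names used are
``icl2_marker_tip``, ``icl2_marker_base``, ``tm2_ref``, ``tm5_probe``,
``tm4_lower``, ``tm4_upper``, ``g_loop_start``, ``g_loop_end`` and the
ranges ``icl2``, ``align_set``, ``galpha_h5``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import (
    DegenerateGeometryError,
    EmptySeriesError,
    MissingAtomError,
    NotApplicableError,
    ParameterError,
)
from .geometry import (
    HelixAxis,
    apply_transform,
    axial_position,
    fit_helix_axis,
    rmsd as plain_rmsd,
    superpose,
    wrap_angle,
)
from .hbonds import HBondCriteria, attached_hydrogens
from .structures import Frame, LandmarkMap, Trajectory, resolve_anchor, select_range

STATE_PR = "PR"
STATE_NR = "NR"
STATE_DISORDERED = "DISORDERED"


@dataclass(frozen=True)
class StateThresholds:
    """Thresholds of the PR/NR/DISORDERED classifier.

    The PR box is ``a_low < a < a_high`` on the raw ICL2 angle (degrees)
    and ``d_intercept - a * d_slope < d < d_high`` on the tip-TM2 distance
    (Angstrom).  Helicity needs ``hbond_min`` backbone i,i+4 hydrogen
    bonds or a backbone RMSD below ``rmsd_max``.
    """

    a_low: float = 45.0
    a_high: float = 120.0
    d_slope: float = 1.0 / 20.0
    d_intercept: float = 10.0
    d_high: float = 13.0
    hbond_min: int = 3
    rmsd_max: float = 2.0

    def __post_init__(self):
        if not self.a_low < self.a_high:
            raise ParameterError("need a_low < a_high")
        if not self.d_high > self.d_intercept - self.a_high * self.d_slope:
            raise ParameterError("d_high must exceed the lower-d bound at a_high")
        if min(self.d_slope, self.d_intercept, self.d_high, self.rmsd_max) <= 0:
            raise ParameterError("distance thresholds must be positive")
        if self.hbond_min < 0:
            raise ParameterError("hbond_min must be >= 0")


@dataclass(frozen=True)
class ICL2Metrics:
    """Per-frame ICL2 description with the assigned state label."""

    a_raw: float  # degrees in (-180, 180]
    a_rel: float  # degrees, a_raw minus reference a_raw, wrapped
    d: float  # Angstrom
    helical: bool
    n_hbonds: int
    backbone_rmsd: float
    state: str

    def __post_init__(self):
        if (self.state == STATE_DISORDERED) != (not self.helical):
            raise ParameterError("state must be DISORDERED exactly when not helical")


@dataclass
class MetricSeries:
    label: str
    times: np.ndarray  # ns
    values: np.ndarray
    units: str = ""

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.times) != len(self.values):
            raise ParameterError("times and values must have equal length")
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise ParameterError("times must be strictly increasing")


# --------------------------------------------------------------------------
# Alignment helper
# --------------------------------------------------------------------------

def align_to_reference(
    frame: Frame, reference: Frame, lmap: LandmarkMap, align_range: str = "align_set"
):
    """Transform superposing a frame's alignment-set CAs onto the reference's."""
    mobile = select_range(frame, lmap, align_range, ("CA",))
    ref = select_range(reference, lmap, align_range, ("CA",))
    if mobile.shape != ref.shape:
        raise DegenerateGeometryError(
            f"alignment set size differs: {mobile.shape[0]} vs {ref.shape[0]} CAs"
        )
    transform, _ = superpose(mobile, ref)
    return transform


# --------------------------------------------------------------------------
# ICL2 angle and distance
# --------------------------------------------------------------------------

def icl2_angle(
    frame: Frame,
    reference: Frame,
    lmap: LandmarkMap,
    tip: str = "icl2_marker_tip",
    base: str = "icl2_marker_base",
    align_range: str = "align_set",
) -> tuple[float, float]:
    """Raw and reference-zeroed ICL2 rotation angle (degrees).

    The frame is superposed onto the reference on the alignment-set CA
    atoms (which places the ICL2 helix axis approximately along x); the
    marker vector ``v = tip - base`` is then read in the z,y plane as
    ``a_raw = atan2(v_z, v_y)``.  ``a_rel`` is ``a_raw`` minus the
    reference frame's raw angle, wrapped into (-180, 180].
    """
    transform = align_to_reference(frame, reference, lmap, align_range)
    v = apply_transform(transform, resolve_anchor(frame, lmap, tip)) - apply_transform(
        transform, resolve_anchor(frame, lmap, base)
    )
    a_raw = wrap_angle(np.degrees(np.arctan2(v[2], v[1])))
    v_ref = resolve_anchor(reference, lmap, tip) - resolve_anchor(reference, lmap, base)
    a_ref = np.degrees(np.arctan2(v_ref[2], v_ref[1]))
    return float(a_raw), float(wrap_angle(a_raw - a_ref))


def marker_tm2_distance(
    frame: Frame,
    lmap: LandmarkMap,
    tip: str = "icl2_marker_tip",
    tm2: str = "tm2_ref",
) -> float:
    """Euclidean tip-to-TM2 distance (Y114:OH to T39:CB in FFAR1), Angstrom."""
    return float(
        np.linalg.norm(resolve_anchor(frame, lmap, tip) - resolve_anchor(frame, lmap, tm2))
    )


# --------------------------------------------------------------------------
# Helicity
# --------------------------------------------------------------------------

def _icl2_span(lmap: LandmarkMap, icl2_range: str):
    spans = lmap.ranges.get(icl2_range)
    if not spans or len(spans) != 1:
        raise ParameterError(f"range {icl2_range!r} must name one contiguous span")
    return spans[0]


def count_i_i4_hbonds(
    frame: Frame,
    lmap: LandmarkMap,
    criteria: HBondCriteria = HBondCriteria(),
    icl2_range: str = "icl2",
) -> int:
    """Number of backbone O(i)...N(i+4) hydrogen bonds inside the loop range.

    Counts only i, i+4 pairs with both residues inside the range.  When
    amide hydrogens are present the D-H...A angle criterion applies; on
    heavy-atom-only structures the distance criterion alone is used.
    """
    from .hbonds import _dha_ok  # angle test at the donor

    span = _icl2_span(lmap, icl2_range)
    top = frame.topology
    count = 0
    for i in range(span.start, span.stop - 3):
        o_hits = top.find(span.chain, i, "O")
        n_hits = top.find(span.chain, i + 4, "N")
        if len(o_hits) != 1 or len(n_hits) != 1:
            raise MissingAtomError(
                f"incomplete backbone: O of {i} or N of {i + 4} (chain {span.chain})"
            )
        o_idx, n_idx = o_hits[0], n_hits[0]
        dist = np.linalg.norm(frame.coords[o_idx] - frame.coords[n_idx])
        if dist <= criteria.max_da_distance and _dha_ok(frame, n_idx, o_idx, criteria):
            count += 1
    return count


def icl2_backbone_rmsd(
    frame: Frame,
    reference: Frame,
    lmap: LandmarkMap,
    icl2_range: str = "icl2",
) -> float:
    """RMSD of the loop backbone (N, CA, C, O) after superposing that selection."""
    sel = select_range(frame, lmap, icl2_range, ("N", "CA", "C", "O"))
    ref = select_range(reference, lmap, icl2_range, ("N", "CA", "C", "O"))
    if sel.shape != ref.shape:
        raise MissingAtomError("ICL2 backbone atom counts differ between frames")
    transform, fitted_rmsd = superpose(sel, ref)
    return fitted_rmsd


def icl2_helicity(
    frame: Frame,
    reference: Frame,
    lmap: LandmarkMap,
    thresholds: StateThresholds = StateThresholds(),
    criteria: HBondCriteria = HBondCriteria(),
    icl2_range: str = "icl2",
) -> tuple[bool, int, float]:
    """(helical, n_hbonds, backbone_rmsd) for one frame.

    Helical when the loop keeps at least ``hbond_min`` backbone i,i+4
    hydrogen bonds or its backbone RMSD to the helical reference is below
    ``rmsd_max``; the reference must have a folded (helical) loop.
    """
    n_hb = count_i_i4_hbonds(frame, lmap, criteria, icl2_range)
    bb_rmsd = icl2_backbone_rmsd(frame, reference, lmap, icl2_range)
    helical = (n_hb >= thresholds.hbond_min) or (bb_rmsd < thresholds.rmsd_max)
    return helical, n_hb, bb_rmsd


# --------------------------------------------------------------------------
# Classifier
# --------------------------------------------------------------------------

def classify_icl2(
    a_raw: float, d: float, helical: bool, thresholds: StateThresholds = StateThresholds()
) -> str:
    """Assign PR, NR or DISORDERED from the raw angle, distance and helicity."""
    if not helical:
        return STATE_DISORDERED
    th = thresholds
    in_a = th.a_low < a_raw < th.a_high
    in_d = (th.d_intercept - a_raw * th.d_slope) < d < th.d_high
    return STATE_PR if (in_a and in_d) else STATE_NR


def state_fractions(states: Sequence[str], which: set[str] | Sequence[str]) -> float:
    """Fraction of frames whose state is in ``which``."""
    states = list(states)
    if not states:
        raise EmptySeriesError("state_fractions: empty state series")
    which = set(which)
    return sum(s in which for s in states) / len(states)


def icl2_frame_metrics(
    frame: Frame,
    reference: Frame,
    lmap: LandmarkMap,
    thresholds: StateThresholds = StateThresholds(),
    criteria: HBondCriteria = HBondCriteria(),
) -> ICL2Metrics:
    """All ICL2 per-frame numbers plus the assigned state."""
    a_raw, a_rel = icl2_angle(frame, reference, lmap)
    d = marker_tm2_distance(frame, lmap)
    helical, n_hb, bb_rmsd = icl2_helicity(frame, reference, lmap, thresholds, criteria)
    state = classify_icl2(a_raw, d, helical, thresholds)
    return ICL2Metrics(a_raw, a_rel, d, helical, n_hb, bb_rmsd, state)


# --------------------------------------------------------------------------
# TM5 / G protein metrics
# --------------------------------------------------------------------------

def tm5_vertical_shift(
    frame: Frame,
    lmap: LandmarkMap,
    reference_s: float = 0.0,
    membrane_normal: np.ndarray | None = None,
) -> float:
    """Vertical shift of TM5 relative to TM4, Angstrom.

    Projects the TM5 probe CA (residue 190 in FFAR1) onto the line through
    the TM4 lower and upper CAs (residues 130 and 141), signed so that the
    segment direction points toward the extracellular side (+z under the
    OPM membrane convention), minus ``reference_s``.  With ``reference_s``
    taken from the agonist-free crystal, positive values mean an upward
    (extracellular) shift of TM5.
    """
    lower = resolve_anchor(frame, lmap, "tm4_lower")
    upper = resolve_anchor(frame, lmap, "tm4_upper")
    probe = resolve_anchor(frame, lmap, "tm5_probe")
    normal = np.array([0.0, 0.0, 1.0]) if membrane_normal is None else np.asarray(membrane_normal, dtype=float)
    sigma = 1.0 if (upper - lower) @ normal > 0 else -1.0
    return float(sigma * axial_position(probe, lower, upper) - reference_s)


def ca_pair_distance(
    frame: Frame, res_i: int, res_j: int, chain: str | None = "A"
) -> float:
    """Distance between the CA atoms of two residues, Angstrom."""
    out = []
    for res in (res_i, res_j):
        hits = frame.topology.find(chain, res, "CA")
        if len(hits) != 1:
            raise MissingAtomError(
                f"CA of residue {res} (chain {chain}) "
                f"{'missing' if not hits else 'ambiguous'}"
            )
        out.append(frame.coords[hits[0]])
    return float(np.linalg.norm(out[0] - out[1]))


def helix5_displacement(
    frame: Frame,
    reference: Frame,
    lmap: LandmarkMap,
    helix5_range: str = "galpha_h5",
    align_range: str = "align_set",
) -> float:
    """RMSD of the Galpha helix-5 CAs after receptor-only alignment, Angstrom.

    The frame is superposed onto the reference using the receptor TM1-TM4
    CA set; the helix-5 CAs are then compared without further fitting, so
    the number reflects displacement of the G protein relative to the
    receptor.
    """
    transform = align_to_reference(frame, reference, lmap, align_range)
    mobile = apply_transform(transform, select_range(frame, lmap, helix5_range, ("CA",)))
    ref = select_range(reference, lmap, helix5_range, ("CA",))
    if mobile.shape != ref.shape:
        raise MissingAtomError("helix-5 CA counts differ between frame and reference")
    return plain_rmsd(mobile, ref)


def loop_end_to_end(frame: Frame, lmap: LandmarkMap) -> float:
    """End-to-end CA distance of the Galpha beta6-alpha5 loop, Angstrom."""
    return float(
        np.linalg.norm(
            resolve_anchor(frame, lmap, "g_loop_start")
            - resolve_anchor(frame, lmap, "g_loop_end")
        )
    )


# --------------------------------------------------------------------------
# Axis-fitted rotation angle (validation metric)
# --------------------------------------------------------------------------

def axis_rotation_angle(
    frame: Frame,
    reference: Frame,
    lmap: LandmarkMap,
    thresholds: StateThresholds = StateThresholds(),
    criteria: HBondCriteria = HBondCriteria(),
    tip: str = "icl2_marker_tip",
    base: str = "icl2_marker_base",
    icl2_range: str = "icl2",
    align_range: str = "align_set",
) -> float:
    """Rotation of the ICL2 markers about the fitted helix axis, degrees.

    Fits the helix axis to the reference loop CAs, aligns the frame on the
    alignment set, and returns the circular mean of the two markers'
    azimuth changes about that axis.  Positive follows the right-hand rule
    about the axis direction (low to high residue numbers).  Raises
    :class:`NotApplicableError` unless the loop is helical in both frames.
    """
    for label, f in (("reference", reference), ("frame", frame)):
        helical, _, _ = icl2_helicity(f, reference, lmap, thresholds, criteria, icl2_range)
        if not helical:
            raise NotApplicableError(f"ICL2 is not helical in the {label}")
    axis = fit_helix_axis(select_range(reference, lmap, icl2_range, ("CA",)))
    transform = align_to_reference(frame, reference, lmap, align_range)

    deltas = []
    for name in (tip, base):
        p_ref = resolve_anchor(reference, lmap, name) - axis.point
        p_frm = apply_transform(transform, resolve_anchor(frame, lmap, name)) - axis.point
        r_ref = p_ref - (p_ref @ axis.direction) * axis.direction
        r_frm = p_frm - (p_frm @ axis.direction) * axis.direction
        if min(np.linalg.norm(r_ref), np.linalg.norm(r_frm)) < 1e-8:
            continue  # marker on the axis carries no azimuth
        delta = np.arctan2(np.cross(r_ref, r_frm) @ axis.direction, r_ref @ r_frm)
        deltas.append(delta)
    if not deltas:
        raise DegenerateGeometryError("both markers lie on the helix axis")
    mean = np.angle(np.mean(np.exp(1j * np.array(deltas))))
    return float(np.degrees(mean))


# --------------------------------------------------------------------------
# Per-frame metric table
# --------------------------------------------------------------------------

METRIC_COLUMNS = [
    "condition", "replicate", "time_ns", "a_raw", "a_rel", "d", "n_hbonds",
    "backbone_rmsd", "helical", "state", "tm5_shift", "d_105_222",
    "d_104_208", "helix5_rmsd", "loop_e2e",
]


def metrics_table(
    traj: Trajectory,
    reference: Frame,
    lmap: LandmarkMap,
    thresholds: StateThresholds = StateThresholds(),
    criteria: HBondCriteria = HBondCriteria(),
    condition: str = "",
    replicate: str = "",
    tm5_reference_s: float = 0.0,
    ca_pairs: Sequence[tuple[int, int]] = ((105, 222), (104, 208)),
) -> pd.DataFrame:
    """Per-frame metric table for one trajectory (one row per frame).

    Metrics whose anchors are absent from the landmark map or the topology
    are left empty (NaN) rather than failing the whole run.
    """
    def available(fn, *args, **kwargs):
        try:
            fn(traj.frame(0), *args, **kwargs)
            return True
        except (MissingAtomError, ParameterError, KeyError):
            return False

    have_icl2 = available(
        lambda f: icl2_frame_metrics(f, reference, lmap, thresholds, criteria)
    )
    have_tm5 = available(lambda f: tm5_vertical_shift(f, lmap, tm5_reference_s))
    have_h5 = available(lambda f: helix5_displacement(f, reference, lmap))
    have_loop = available(lambda f: loop_end_to_end(f, lmap))
    have_pairs = [
        available(lambda f, p=pair: ca_pair_distance(f, p[0], p[1])) for pair in ca_pairs
    ]

    rows = []
    for i, frame in enumerate(traj):
        row: dict = {
            "condition": condition,
            "replicate": replicate or traj.source_label,
            "time_ns": float(traj.times[i]),
        }
        if have_icl2:
            m = icl2_frame_metrics(frame, reference, lmap, thresholds, criteria)
            row.update(
                a_raw=m.a_raw, a_rel=m.a_rel, d=m.d, n_hbonds=m.n_hbonds,
                backbone_rmsd=m.backbone_rmsd, helical=m.helical, state=m.state,
            )
        row["tm5_shift"] = (
            tm5_vertical_shift(frame, lmap, tm5_reference_s) if have_tm5 else np.nan
        )
        for (pair, ok), col in zip(
            zip(ca_pairs, have_pairs), ("d_105_222", "d_104_208")
        ):
            row[col] = ca_pair_distance(frame, pair[0], pair[1]) if ok else np.nan
        row["helix5_rmsd"] = (
            helix5_displacement(frame, reference, lmap) if have_h5 else np.nan
        )
        row["loop_e2e"] = loop_end_to_end(frame, lmap) if have_loop else np.nan
        rows.append(row)
    table = pd.DataFrame(rows)
    for col in METRIC_COLUMNS:
        if col not in table.columns:
            table[col] = np.nan
    return table[METRIC_COLUMNS]
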