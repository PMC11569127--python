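"""Geometric hydrogen-bond detection, water bridges and frequency tables.

Detection uses the standard geometric criteria: donor--acceptor heavy-atom
distance at most ``max_da_distance`` (default 3.5 A) and, when donor
hydrogens are present, a D-H...A angle of at least ``min_dha_angle``
(default 110 deg, 180 being linear).  On structures without hydrogens the
distance criterion alone applies, which makes heavy-atom detection a
superset of hydrogen-aware detection at equal cutoff.

A water-mediated hydrogen bond (water bridge) joins two solute atoms that
are each hydrogen-bonded to the same single water molecule in one frame;
chains through two or more waters are not counted.

Inputs are assumed re-imaged/whole: no periodic-boundary imaging is done.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, NamedTuple, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .errors import (
    EmptySeriesError,
    MissingHydrogenError,
    ParameterError,
)
from .structures import Frame, Trajectory, WATER_RESNAMES

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class HBondCriteria:
    max_da_distance: float = 3.5  # A, donor to acceptor heavy atom
    min_dha_angle: float = 110.0  # deg at the hydrogen; 180 is linear
    require_hydrogens: bool = False

    def __post_init__(self):
        if self.max_da_distance <= 0:
            raise ParameterError("max_da_distance must be positive")
        if not (0 < self.min_dha_angle <= 180):
            raise ParameterError("min_dha_angle must be in (0, 180]")


class AtomId(NamedTuple):
    """Human-readable atom identity used in interaction events."""

    chain: str
    residue_number: int
    residue_name: str
    atom_name: str

    def __str__(self) -> str:
        return f"{self.chain}:{self.residue_name}{self.residue_number}:{self.atom_name}"


class ResidueId(NamedTuple):
    chain: str
    residue_number: int


@dataclass(frozen=True)
class InteractionEvent:
    frame_index: int
    donor: AtomId
    acceptor: AtomId
    bridge_water: ResidueId | None = None

    def __post_init__(self):
        if self.donor == self.acceptor:
            raise ParameterError("donor and acceptor must differ")


# --------------------------------------------------------------------------
# Donor / acceptor typing
# --------------------------------------------------------------------------

_SIDECHAIN_DONORS = {
    ("SER", "OG"), ("THR", "OG1"), ("TYR", "OH"), ("TRP", "NE1"),
    ("LYS", "NZ"), ("ARG", "NE"), ("ARG", "NH1"), ("ARG", "NH2"),
    ("HIS", "ND1"), ("HIS", "NE2"), ("ASN", "ND2"), ("GLN", "NE2"),
    ("CYS", "SG"),
}
_SIDECHAIN_ACCEPTORS = {
    ("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2"),
    ("ASN", "OD1"), ("GLN", "OE1"), ("SER", "OG"), ("THR", "OG1"),
    ("TYR", "OH"), ("HIS", "ND1"), ("HIS", "NE2"), ("MET", "SD"),
    ("CYS", "SG"),
}


def classify_polar_atoms(frame: Frame) -> tuple[list[int], list[int]]:
    """Default donor and acceptor atom indices for a frame.

    Typing is by residue template where the residue is recognised
    (backbone N donor, backbone O/OXT acceptor, hydroxyls both, carboxylate
    O acceptor, water O both) and falls back to element for unknown
    residues (N donor, O donor-and-acceptor).
    """
    donors: list[int] = []
    acceptors: list[int] = []
    for i, a in enumerate(frame.topology.atom_meta):
        if a.element == "H":
            continue
        res, name = a.residue_name, a.atom_name
        if res in WATER_RESNAMES:
            if a.element == "O":
                donors.append(i)
                acceptors.append(i)
            continue
        if name == "N" and a.element == "N":
            donors.append(i)
            continue
        if name in ("O", "OXT") and a.element == "O":
            acceptors.append(i)
            continue
        if (res, name) in _SIDECHAIN_DONORS:
            donors.append(i)
        if (res, name) in _SIDECHAIN_ACCEPTORS:
            acceptors.append(i)
        if (res, name) not in _SIDECHAIN_DONORS and (res, name) not in _SIDECHAIN_ACCEPTORS:
            # unknown residue (ligand, pseudo-atom): fall back to element
            if a.element == "N":
                donors.append(i)
            elif a.element == "O":
                donors.append(i)
                acceptors.append(i)
    return donors, acceptors


def attached_hydrogens(frame: Frame, heavy_index: int, max_bond: float = 1.25) -> list[int]:
    """Hydrogens of the same residue within covalent range of a heavy atom."""
    meta = frame.topology.atom_meta[heavy_index]
    out = []
    for j in frame.topology.residue_atoms(meta.chain_id, meta.residue_number):
        other = frame.topology.atom_meta[j]
        if other.element != "H" or j == heavy_index:
            continue
        if np.linalg.norm(frame.coords[j] - frame.coords[heavy_index]) <= max_bond:
            out.append(j)
    return out


def add_amide_hydrogens(frame: Frame, chain: str | None = None) -> Frame:
    """Place backbone amide hydrogens on residues that lack them.

    The H sits 1.01 A from N, in the C(i-1)-N-CA plane, opposite the
    bisector of the two N bonds -- the standard trigonal amide geometry.
    Residues without a preceding C (chain starts) are skipped, as are
    residues that already carry an H on N.  Used to prepare crystal
    structures for hydrogen-aware hydrogen-bond detection.
    """
    from .structures import AtomMeta, Topology

    top = frame.topology
    new_meta = list(top.atom_meta)
    new_coords = [frame.coords]
    serial = len(new_meta)
    for (ch, res), atom_idx in top._by_residue.items():
        if chain is not None and ch != chain:
            continue
        n_hits = top.find(ch, res, "N")
        ca_hits = top.find(ch, res, "CA")
        c_prev = top.find(ch, res - 1, "C")
        if len(n_hits) != 1 or len(ca_hits) != 1 or len(c_prev) != 1:
            continue
        if any(top.atom_meta[i].element == "H" and top.atom_meta[i].atom_name == "H"
               for i in atom_idx):
            continue
        n_pos = frame.coords[n_hits[0]]
        u1 = frame.coords[c_prev[0]] - n_pos
        u2 = frame.coords[ca_hits[0]] - n_pos
        u1 /= np.linalg.norm(u1)
        u2 /= np.linalg.norm(u2)
        bisector = u1 + u2
        norm = np.linalg.norm(bisector)
        if norm < 1e-8:
            continue
        serial += 1
        meta = top.atom_meta[n_hits[0]]
        new_meta.append(AtomMeta(serial, "H", meta.residue_name, res, ch, "H"))
        new_coords.append((n_pos - 1.01 * bisector / norm)[None, :])
    return Frame(Topology(new_meta), np.vstack(new_coords), frame.time)


def _atom_id(frame: Frame, i: int) -> AtomId:
    a = frame.topology.atom_meta[i]
    return AtomId(a.chain_id, a.residue_number, a.residue_name, a.atom_name)


def _dha_ok(frame: Frame, donor: int, acceptor: int, crit: HBondCriteria) -> bool:
    """Angle criterion at the hydrogen, if the donor carries any hydrogens."""
    hs = attached_hydrogens(frame, donor)
    if not hs:
        if crit.require_hydrogens:
            raise MissingHydrogenError(
                f"donor {_atom_id(frame, donor)} has no hydrogens"
            )
        return True  # heavy-atom-only mode: distance criterion alone
    d = frame.coords[donor]
    a = frame.coords[acceptor]
    best = -1.0
    for h in hs:
        hd = d - frame.coords[h]
        ha = a - frame.coords[h]
        denom = np.linalg.norm(hd) * np.linalg.norm(ha)
        if denom < 1e-10:
            continue
        ang = np.degrees(np.arccos(np.clip(hd @ ha / denom, -1.0, 1.0)))
        best = max(best, ang)
    return best >= crit.min_dha_angle


def detect_hbonds(
    frame: Frame,
    crit: HBondCriteria = HBondCriteria(),
    donors: Sequence[int] | None = None,
    acceptors: Sequence[int] | None = None,
    frame_index: int = 0,
) -> list[InteractionEvent]:
    """Hydrogen bonds among candidate donor/acceptor atoms of one frame.

    Pairs within the same residue are excluded.  ``donors``/``acceptors``
    default to :func:`classify_polar_atoms`.
    """
    if donors is None or acceptors is None:
        d_def, a_def = classify_polar_atoms(frame)
        donors = d_def if donors is None else donors
        acceptors = a_def if acceptors is None else acceptors
    donors = list(donors)
    acceptors = list(acceptors)
    if not donors or not acceptors:
        return []
    if crit.require_hydrogens and not any(
        a.element == "H" for a in frame.topology.atom_meta
    ):
        raise MissingHydrogenError("structure contains no hydrogens")
    dist = cdist(frame.coords[donors], frame.coords[acceptors])
    events = []
    meta = frame.topology.atom_meta
    for di, dj in zip(*np.nonzero(dist <= crit.max_da_distance)):
        d_idx, a_idx = donors[di], acceptors[dj]
        if d_idx == a_idx:
            continue
        dm, am = meta[d_idx], meta[a_idx]
        if dm.chain_id == am.chain_id and dm.residue_number == am.residue_number:
            continue
        if _dha_ok(frame, d_idx, a_idx, crit):
            events.append(
                InteractionEvent(frame_index, _atom_id(frame, d_idx), _atom_id(frame, a_idx))
            )
    return events


def _water_oxygens(frame: Frame) -> list[int]:
    return [
        i
        for i, a in enumerate(frame.topology.atom_meta)
        if a.residue_name in WATER_RESNAMES and a.element == "O"
    ]


def _leg_bonded(frame: Frame, solute: int, water_o: int, crit: HBondCriteria) -> bool:
    """Solute--water hydrogen bond in either donor/acceptor role."""
    if np.linalg.norm(frame.coords[solute] - frame.coords[water_o]) > crit.max_da_distance:
        return False
    elem = frame.topology.atom_meta[solute].element
    # water as donor toward the solute atom (O and S accept; N rarely, allowed)
    if elem in ("O", "N", "S") and _dha_ok(frame, water_o, solute, crit):
        return True
    # solute as donor toward the water oxygen
    if _dha_ok(frame, solute, water_o, crit):
        return True
    return False


def detect_water_bridges(
    frame: Frame,
    crit: HBondCriteria = HBondCriteria(),
    solute_atoms: Sequence[int] | None = None,
    frame_index: int = 0,
) -> list[InteractionEvent]:
    """Single-water bridges between solute atoms of one frame.

    An event (X, Y, w) is emitted for every unordered solute pair (X, Y)
    where X--w and w--Y each satisfy the hydrogen-bond criteria in either
    role.  A frame without waters yields an empty list.
    """
    if solute_atoms is None:
        d, a = classify_polar_atoms(frame)
        waters = set(_water_oxygens(frame))
        solute_atoms = sorted((set(d) | set(a)) - waters)
    solute_atoms = list(solute_atoms)
    events = []
    meta = frame.topology.atom_meta
    for w in _water_oxygens(frame):
        partners = [s for s in solute_atoms if _leg_bonded(frame, s, w, crit)]
        wm = meta[w]
        for i in range(len(partners)):
            for j in range(i + 1, len(partners)):
                x, y = partners[i], partners[j]
                xm, ym = meta[x], meta[y]
                if xm.chain_id == ym.chain_id and xm.residue_number == ym.residue_number:
                    continue
                events.append(
                    InteractionEvent(
                        frame_index,
                        _atom_id(frame, x),
                        _atom_id(frame, y),
                        ResidueId(wm.chain_id, wm.residue_number),
                    )
                )
    return events


# --------------------------------------------------------------------------
# Frequencies across replicates
# --------------------------------------------------------------------------

PairSpec = tuple[tuple[str | None, int, str], tuple[str | None, int, str]]


def pair_interacts(
    frame: Frame,
    pair: PairSpec,
    crit: HBondCriteria = HBondCriteria(),
    include_water_bridges: bool = True,
    frame_index: int = 0,
) -> bool:
    """Whether the two specified atoms interact in this frame.

    Qualifies on a direct hydrogen bond in either role, or (optionally) a
    single-water bridge between them.
    """
    idx = []
    for chain, res, name in pair:
        hits = frame.topology.find(chain, res, name)
        if len(hits) != 1:
            return False
        idx.append(hits[0])
    a, b = idx
    da = np.linalg.norm(frame.coords[a] - frame.coords[b])
    if da <= crit.max_da_distance and (
        _dha_ok(frame, a, b, crit) or _dha_ok(frame, b, a, crit)
    ):
        return True
    if include_water_bridges:
        for w in _water_oxygens(frame):
            if _leg_bonded(frame, a, w, crit) and _leg_bonded(frame, b, w, crit):
                return True
    return False


@dataclass
class FrequencyRow:
    pair_label: str
    replicate_frequencies: list[float]
    replicate_n_frames: list[int]
    mean: float
    ci68_half_width: float | None

    def __post_init__(self):
        for f in self.replicate_frequencies:
            if not (0.0 <= f <= 1.0):
                raise ParameterError(f"frequency {f} outside [0, 1]")


@dataclass
class FrequencyTable:
    rows: list[FrequencyRow] = field(default_factory=list)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "pair": r.pair_label,
                    "n_replicates": len(r.replicate_frequencies),
                    "mean": r.mean,
                    "ci68": r.ci68_half_width,
                    "replicate_frequencies": ";".join(
                        f"{v:.6f}" for v in r.replicate_frequencies
                    ),
                }
                for r in self.rows
            ]
        )


def interaction_frequency(
    trajs: Sequence[Trajectory],
    pair: PairSpec,
    crit: HBondCriteria = HBondCriteria(),
    frame_filter: Callable[[Frame, int], bool] | None = None,
    include_water_bridges: bool = True,
    pair_label: str | None = None,
) -> FrequencyRow:
    """Per-replicate interaction frequency for one atom pair, with mean/CI.

    For each replicate, frequency = qualifying frames (direct or
    water-mediated) / frames passing ``frame_filter``.  Replicates with no
    frame passing the filter are excluded with a warning; if all are
    excluded an :class:`EmptySeriesError` is raised.  The 68% CI is one
    standard error of the mean across replicates.
    """
    from .stats import replicate_summary

    if not trajs:
        raise EmptySeriesError("no replicates given")
    freqs: list[float] = []
    counts: list[int] = []
    for traj in trajs:
        used = 0
        hits = 0
        for i, frame in enumerate(traj):
            if frame_filter is not None and not frame_filter(frame, i):
                continue
            used += 1
            if pair_interacts(frame, pair, crit, include_water_bridges, i):
                hits += 1
        if used == 0:
            logger.warning(
                "replicate %s: no frames pass the filter; excluded",
                traj.source_label or "<unnamed>",
            )
            continue
        freqs.append(hits / used)
        counts.append(used)
    if not freqs:
        raise EmptySeriesError("all replicates were excluded by the frame filter")
    summary = replicate_summary(freqs)
    label = pair_label or " -- ".join(
        f"{c or '*'}:{r}:{n}" for (c, r, n) in pair
    )
    return FrequencyRow(label, freqs, counts, summary.mean, summary.ci68_half_width)
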