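"""Structures, trajectories and named landmarks.

The in-memory model follows the usual MD-analysis split between a shared
*topology* (atom identities, one copy per trajectory) and per-frame
coordinate arrays, so that a ten-thousand-frame trajectory is a single
``(n_frames, n_atoms, 3)`` array rather than millions of atom objects.
Coordinates are Angstrom throughout; times are nanoseconds.

PDB is the interchange format (multi-model PDB for trajectories); parsing
and writing go through :mod:`biotite`.  A :class:`LandmarkMap` names the
residue/atom anchors and residue ranges that the conformational metrics
need (e.g. the ICL2 marker atoms, the TM1-TM4 alignment set), decoupling
metric code from any one receptor's numbering.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import yaml

from .errors import (
    AmbiguousAtomError,
    EmptySelectionError,
    EmptyStructureError,
    MissingAtomError,
    SchemaError,
    StructureParseError,
    TopologyMismatchError,
)

#: canonical ordering of backbone atoms inside one residue
BACKBONE_ORDER = ("N", "CA", "C", "O")

#: residue names recognised as water
WATER_RESNAMES = frozenset({"HOH", "WAT", "TIP3", "SOL", "TIP"})


class AtomMeta(NamedTuple):
    """Identity of one atom, shared across frames of a trajectory."""

    serial: int
    atom_name: str
    residue_name: str
    residue_number: int
    chain_id: str
    element: str


@dataclass(frozen=True)
class AtomRecord:
    """One atom of one frame: identity plus Cartesian position in Angstrom."""

    serial: int
    atom_name: str
    residue_name: str
    residue_number: int
    chain_id: str
    element: str
    position: np.ndarray

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise SchemaError(f"atom {self.atom_name}: position must be a finite 3-vector")
        if not self.atom_name:
            raise SchemaError("atom_name must be non-empty")
        if self.residue_number < 1:
            raise SchemaError(f"residue_number must be >= 1, got {self.residue_number}")
        object.__setattr__(self, "position", pos)


class Topology:
    """Ordered atom identities with fast (chain, residue, atom-name) lookup."""

    def __init__(self, atoms: Sequence[AtomMeta]):
        self.atom_meta: tuple[AtomMeta, ...] = tuple(atoms)
        self._by_key: dict[tuple[str, int, str], list[int]] = {}
        self._by_residue: dict[tuple[str, int], list[int]] = {}
        for i, a in enumerate(self.atom_meta):
            self._by_key.setdefault((a.chain_id, a.residue_number, a.atom_name), []).append(i)
            self._by_residue.setdefault((a.chain_id, a.residue_number), []).append(i)

    def __len__(self) -> int:
        return len(self.atom_meta)

    def find(self, chain_id: str | None, residue_number: int, atom_name: str) -> list[int]:
        """Indices of atoms matching the key; ``chain_id=None`` matches any chain."""
        if chain_id is not None:
            return list(self._by_key.get((chain_id, residue_number, atom_name), []))
        hits: list[int] = []
        for (ch, res, name), idx in self._by_key.items():
            if res == residue_number and name == atom_name:
                hits.extend(idx)
        return sorted(hits)

    def residue_atoms(self, chain_id: str, residue_number: int) -> list[int]:
        return list(self._by_residue.get((chain_id, residue_number), []))

    def chains(self) -> list[str]:
        return sorted({a.chain_id for a in self.atom_meta})


@dataclass
class Frame:
    """One time point of a system: a topology plus coordinates in Angstrom."""

    topology: Topology
    coords: np.ndarray
    time: float = 0.0

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.topology), 3):
            raise SchemaError(
                f"coords shape {self.coords.shape} does not match "
                f"{len(self.topology)} topology atoms"
            )
        if not np.all(np.isfinite(self.coords)):
            raise SchemaError("frame coordinates must be finite")
        if self.time < 0:
            raise SchemaError("frame time must be >= 0")

    @property
    def n_atoms(self) -> int:
        return len(self.topology)

    @property
    def atoms(self) -> list[AtomRecord]:
        """Materialize per-atom records (convenience; not for hot loops)."""
        return [
            AtomRecord(*meta, position=self.coords[i])
            for i, meta in enumerate(self.topology.atom_meta)
        ]

    def with_coords(self, coords: np.ndarray, time: float | None = None) -> "Frame":
        return Frame(self.topology, coords, self.time if time is None else time)


@dataclass
class Trajectory:
    """Ordered frames sharing one topology, at uniform stride (ns/frame)."""

    topology: Topology
    coords: np.ndarray  # (n_frames, n_atoms, 3)
    times: np.ndarray  # (n_frames,) ns
    stride: float = 0.2
    source_label: str = ""

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[1] != len(self.topology):
            raise SchemaError("trajectory coords must be (n_frames, n_atoms, 3)")
        if self.coords.shape[0] < 1:
            raise SchemaError("trajectory must contain at least one frame")
        if len(self.times) != self.coords.shape[0]:
            raise SchemaError("times length must equal frame count")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise SchemaError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def frame(self, i: int) -> Frame:
        return Frame(self.topology, self.coords[i], float(self.times[i]))

    def __iter__(self):
        for i in range(self.n_frames):
            yield self.frame(i)


# --------------------------------------------------------------------------
# Landmark map
# --------------------------------------------------------------------------

class Anchor(NamedTuple):
    chain: str | None
    residue: int
    atom: str


class ResidueSpan(NamedTuple):
    chain: str
    start: int
    stop: int  # inclusive


@dataclass
class LandmarkMap:
    """Named anchors, residue ranges and a Ballesteros-Weinstein table.

    Metric code refers to anchors and ranges by *role* names (for instance
    ``icl2_marker_tip`` for Y114:OH, ``align_set`` for the TM1-TM4 CA set);
    a map for a particular receptor binds those roles to its own numbering.
    """

    anchors: dict[str, Anchor] = field(default_factory=dict)
    ranges: dict[str, list[ResidueSpan]] = field(default_factory=dict)
    bw_table: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        for name, spans in self.ranges.items():
            if not spans:
                raise SchemaError(f"range {name!r} is empty")
            for sp in spans:
                if sp.stop < sp.start:
                    raise SchemaError(f"range {name!r}: stop < start in {sp}")
        vals = list(self.bw_table.values())
        if len(set(vals)) != len(vals):
            raise SchemaError("bw_table must be injective (one residue per BW code)")

    def bw_residue(self, code: str) -> int:
        if code not in self.bw_table:
            raise SchemaError(f"BW code {code!r} not in bw_table")
        return self.bw_table[code]


def load_landmark_map(path: str | Path) -> LandmarkMap:
    """Read a landmark map from a flat YAML/JSON config file.

    Expected keys: ``anchors`` (name -> {chain, residue, atom}),
    ``ranges`` (name -> {chain, start, stop} or a list of such),
    ``bw_table`` (BW code -> residue number).
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, Mapping):
        raise SchemaError(f"{path}: landmark map must be a mapping")
    anchors = {}
    for name, spec in (raw.get("anchors") or {}).items():
        try:
            anchors[name] = Anchor(spec.get("chain"), int(spec["residue"]), str(spec["atom"]))
        except (KeyError, TypeError, AttributeError) as exc:
            raise SchemaError(f"anchor {name!r}: need {{chain, residue, atom}}") from exc
    ranges = {}
    for name, spec in (raw.get("ranges") or {}).items():
        spans = spec if isinstance(spec, list) else [spec]
        try:
            ranges[name] = [
                ResidueSpan(str(s.get("chain", "A")), int(s["start"]), int(s["stop"]))
                for s in spans
            ]
        except (KeyError, TypeError, AttributeError) as exc:
            raise SchemaError(f"range {name!r}: need {{chain, start, stop}}") from exc
    bw = {str(k): int(v) for k, v in (raw.get("bw_table") or {}).items()}
    return LandmarkMap(anchors=anchors, ranges=ranges, bw_table=bw)


def save_landmark_map(lmap: LandmarkMap, path: str | Path) -> None:
    raw = {
        "anchors": {
            n: {"chain": a.chain, "residue": a.residue, "atom": a.atom}
            for n, a in lmap.anchors.items()
        },
        "ranges": {
            n: [{"chain": s.chain, "start": s.start, "stop": s.stop} for s in spans]
            for n, spans in lmap.ranges.items()
        },
        "bw_table": dict(lmap.bw_table),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=True)


# --------------------------------------------------------------------------
# Selections
# --------------------------------------------------------------------------

def resolve_anchor(frame: Frame, lmap: LandmarkMap, name: str) -> np.ndarray:
    """Position of the unique atom an anchor refers to."""
    if name not in lmap.anchors:
        raise MissingAtomError(f"anchor {name!r} not defined in landmark map")
    anchor = lmap.anchors[name]
    hits = frame.topology.find(anchor.chain, anchor.residue, anchor.atom)
    if not hits:
        raise MissingAtomError(
            f"anchor {name!r}: no atom {anchor.atom} in residue "
            f"{anchor.residue} (chain {anchor.chain})"
        )
    if len(hits) > 1:
        raise AmbiguousAtomError(
            f"anchor {name!r}: {len(hits)} atoms match {anchor.atom} "
            f"in residue {anchor.residue} (chain {anchor.chain})"
        )
    return frame.coords[hits[0]].copy()


def range_indices(
    topology: Topology,
    lmap: LandmarkMap,
    range_name: str,
    atom_names: Iterable[str],
) -> np.ndarray:
    """Atom indices of a named residue range, in (residue, canonical) order.

    Within one residue, backbone atoms come in N, CA, C, O order followed by
    any other requested names alphabetically; selections are therefore
    deterministic and order-stable across frames of one trajectory.
    """
    if range_name not in lmap.ranges:
        raise SchemaError(f"range {range_name!r} not defined in landmark map")
    wanted = set(atom_names)
    ordered_names = [n for n in BACKBONE_ORDER if n in wanted]
    ordered_names += sorted(wanted - set(BACKBONE_ORDER))
    idx: list[int] = []
    for span in lmap.ranges[range_name]:
        for res in range(span.start, span.stop + 1):
            for name in ordered_names:
                idx.extend(topology.find(span.chain, res, name))
    if not idx:
        raise EmptySelectionError(
            f"range {range_name!r} with atoms {sorted(wanted)} selected no atoms"
        )
    return np.asarray(idx, dtype=int)


def select_range(
    frame: Frame,
    lmap: LandmarkMap,
    range_name: str,
    atom_names: Iterable[str] = ("CA",),
) -> np.ndarray:
    """Positions of atoms in a named residue range (see :func:`range_indices`)."""
    return frame.coords[range_indices(frame.topology, lmap, range_name, atom_names)]


# --------------------------------------------------------------------------
# PDB I/O (via biotite)
# --------------------------------------------------------------------------

def _guess_element(atom_name: str) -> str:
    stripped = atom_name.strip().lstrip("0123456789")
    return stripped[:1].upper() if stripped else "X"


def _array_to_topology(array) -> Topology:
    metas = []
    elements = getattr(array, "element", None)
    for i in range(array.array_length()):
        elem = str(elements[i]).strip() if elements is not None else ""
        metas.append(
            AtomMeta(
                serial=i + 1,
                atom_name=str(array.atom_name[i]),
                residue_name=str(array.res_name[i]),
                residue_number=int(array.res_id[i]),
                chain_id=str(array.chain_id[i]),
                element=elem or _guess_element(str(array.atom_name[i])),
            )
        )
    return Topology(metas)


def _topology_to_array(topology: Topology, coords: np.ndarray):
    import biotite.structure as struc

    n = len(topology)
    array = struc.AtomArray(n)
    array.coord = np.asarray(coords, dtype=np.float32)
    array.chain_id = np.array([a.chain_id for a in topology.atom_meta], dtype="U4")
    array.res_id = np.array([a.residue_number for a in topology.atom_meta], dtype=int)
    array.res_name = np.array([a.residue_name for a in topology.atom_meta], dtype="U5")
    array.atom_name = np.array([a.atom_name for a in topology.atom_meta], dtype="U6")
    array.element = np.array([a.element for a in topology.atom_meta], dtype="U2")
    array.hetero = np.array(
        [a.residue_name in WATER_RESNAMES for a in topology.atom_meta], dtype=bool
    )
    return array


def _read_pdb_models(path: str | Path):
    """All models of a PDB file as a biotite AtomArrayStack."""
    from biotite.structure.io.pdb import PDBFile

    try:
        pdb = PDBFile.read(str(path))
        stack = pdb.get_structure(model=None, altloc="first")
    except Exception as exc:  # biotite raises assorted parse errors
        raise StructureParseError(f"{path}: {exc}") from exc
    if stack.array_length() == 0:
        raise EmptyStructureError(f"{path}: no atoms found")
    return stack


def read_structure(path: str | Path) -> Frame:
    """Read one PDB structure; model 1 if the file is multi-model."""
    stack = _read_pdb_models(path)
    first = stack[0]
    return Frame(_array_to_topology(first), np.asarray(first.coord, dtype=float))


def read_trajectory(
    topology_path: str | Path,
    coords_path: str | Path,
    stride: float = 0.2,
    source_label: str = "",
) -> Trajectory:
    """Read a multi-model PDB trajectory against a topology structure.

    Frame times are ``i * stride`` (ns) since multi-model PDB carries none.
    """
    top_frame = read_structure(topology_path)
    stack = _read_pdb_models(coords_path)
    if stack.array_length() != top_frame.n_atoms:
        raise TopologyMismatchError(
            f"topology has {top_frame.n_atoms} atoms but trajectory frames "
            f"have {stack.array_length()}"
        )
    coords = np.asarray(stack.coord, dtype=float)
    times = np.arange(coords.shape[0]) * float(stride)
    return Trajectory(top_frame.topology, coords, times, stride, source_label)


def write_structure(frame: Frame, path: str | Path) -> None:
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile()
    pdb.set_structure(_topology_to_array(frame.topology, frame.coords))
    pdb.write(str(path))


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as a multi-model PDB (one MODEL block per frame)."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    template = _topology_to_array(traj.topology, traj.coords[0])
    stack = struc.stack([template] * traj.n_frames)
    stack.coord = np.asarray(traj.coords, dtype=np.float32)
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


def frames_to_trajectory(
    frames: Sequence[Frame], stride: float = 0.2, source_label: str = ""
) -> Trajectory:
    """Assemble Frames sharing a topology into a Trajectory."""
    if not frames:
        raise SchemaError("need at least one frame")
    top = frames[0].topology
    for f in frames:
        if f.topology is not top and f.topology.atom_meta != top.atom_meta:
            raise TopologyMismatchError("frames do not share an atom ordering")
    coords = np.stack([f.coords for f in frames])
    times = np.array([f.time for f in frames], dtype=float)
    if np.any(np.diff(times) <= 0):
        times = np.arange(len(frames)) * stride
    return Trajectory(top, coords, times, stride, source_label)
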