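"""Config-driven end-to-end analysis over conditions and replicates.

A run is described by a flat YAML config (see :class:`RunConfig`): a list
of conditions, each with a topology, one or more replicate trajectories
and an optional reference structure, plus a landmark map and optional
threshold/criteria overrides.  :func:`run_analysis` produces, per
condition x replicate, the per-frame metric table; per condition, the
replicate-level summaries (mean with 68% CI over per-replicate
time-averages); frequency tables for configured hydrogen-bond pairs; and
a machine-readable manifest.  Identical config and inputs yield
byte-identical tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import EmptySeriesError, SchemaError
from .hbonds import HBondCriteria, interaction_frequency
from .metrics import (
    STATE_DISORDERED,
    STATE_NR,
    STATE_PR,
    StateThresholds,
    icl2_backbone_rmsd,
    metrics_table,
    tm5_vertical_shift,
)
from .stats import mwu_two_sided, replicate_summary
from .structures import (
    Frame,
    LandmarkMap,
    load_landmark_map,
    read_structure,
    read_trajectory,
)

logger = logging.getLogger(__name__)

#: metric columns summarized by per-replicate time-average
_MEAN_METRICS = ("a_rel", "d", "tm5_shift", "d_105_222", "d_104_208",
                 "helix5_rmsd", "loop_e2e")


@dataclass
class ConditionConfig:
    name: str
    topology: str
    trajectories: list[str]
    reference: str | None = None

    def __post_init__(self):
        if not self.trajectories:
            raise SchemaError(f"condition {self.name!r}: needs >= 1 trajectory")


@dataclass
class RunConfig:
    conditions: list[ConditionConfig]
    landmarks: str
    output_dir: str = "loopstate_out"
    stride: float = 0.2
    thresholds: StateThresholds = field(default_factory=StateThresholds)
    criteria: HBondCriteria = field(default_factory=HBondCriteria)
    pairs: list[dict] = field(default_factory=list)
    hbond_filter_helical: bool = True
    tm5_reference_s: float = 0.0
    log_level: str = "INFO"

    def __post_init__(self):
        if not self.conditions:
            raise SchemaError("config needs >= 1 condition")

    def validate_paths(self) -> None:
        """Fail fast, before any computation, if an input file is missing."""
        missing = []
        for c in self.conditions:
            for p in [c.topology, c.reference, *c.trajectories]:
                if p and not Path(p).exists():
                    missing.append(p)
        if not Path(self.landmarks).exists():
            missing.append(self.landmarks)
        if missing:
            raise SchemaError("missing input files: " + ", ".join(missing))


def load_run_config(path: str | Path) -> RunConfig:
    """Parse and schema-check a YAML run config."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, Mapping):
        raise SchemaError(f"{path}: run config must be a mapping")
    try:
        conditions = [
            ConditionConfig(
                name=str(c["name"]),
                topology=str(c["topology"]),
                trajectories=[str(t) for t in c["trajectories"]],
                reference=c.get("reference"),
            )
            for c in raw["conditions"]
        ]
    except (KeyError, TypeError) as exc:
        raise SchemaError(f"{path}: bad conditions block: {exc}") from exc
    if "landmarks" not in raw:
        raise SchemaError(f"{path}: missing 'landmarks'")
    th_over = raw.get("thresholds") or {}
    crit_over = raw.get("hbond_criteria") or {}
    known_th = {f.name for f in dc_fields(StateThresholds)}
    known_cr = {f.name for f in dc_fields(HBondCriteria)}
    if not set(th_over) <= known_th:
        raise SchemaError(f"unknown threshold keys: {sorted(set(th_over) - known_th)}")
    if not set(crit_over) <= known_cr:
        raise SchemaError(f"unknown criteria keys: {sorted(set(crit_over) - known_cr)}")
    return RunConfig(
        conditions=conditions,
        landmarks=str(raw["landmarks"]),
        output_dir=str(raw.get("output_dir", "loopstate_out")),
        stride=float(raw.get("stride", 0.2)),
        thresholds=StateThresholds(**th_over),
        criteria=HBondCriteria(**crit_over),
        pairs=list(raw.get("pairs") or []),
        hbond_filter_helical=bool(raw.get("hbond_filter_helical", True)),
        tm5_reference_s=float(raw.get("tm5_reference_s", 0.0)),
        log_level=str(raw.get("log_level", "INFO")),
    )


def _config_hash(config: RunConfig) -> str:
    """Hash of the analysis-relevant config (output location excluded)."""

    def enc(obj):
        if hasattr(obj, "__dataclass_fields__"):
            return {f: enc(getattr(obj, f)) for f in obj.__dataclass_fields__}
        if isinstance(obj, (list, tuple)):
            return [enc(x) for x in obj]
        return obj

    payload = enc(config)
    payload.pop("output_dir", None)
    payload.pop("log_level", None)
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()


def _replicate_averages(table: pd.DataFrame) -> dict[str, float]:
    """Time-averages and state fractions of one replicate's frame table."""
    out: dict[str, float] = {}
    for col in _MEAN_METRICS:
        vals = table[col].dropna()
        if len(vals):
            out[col] = float(vals.mean())
    states = table["state"].dropna()
    if len(states):
        out["fraction_pr"] = float((states == STATE_PR).mean())
        out["fraction_nr"] = float((states == STATE_NR).mean())
        out["fraction_disordered"] = float((states == STATE_DISORDERED).mean())
        out["fraction_helical"] = float(table["helical"].dropna().astype(bool).mean())
        folded = table.loc[table["helical"].fillna(False).astype(bool), "a_rel"].dropna()
        if len(folded):
            out["a_rel_folded"] = float(folded.mean())
    return out


def run_analysis(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Execute a full run; returns the tables and writes them as CSV.

    Outputs under ``config.output_dir``:

    * ``frames_<condition>_<replicate>.csv`` -- per-frame metrics;
    * ``summary.csv`` -- per condition x metric: n, mean, 68% CI;
    * ``frequencies.csv`` -- hydrogen-bond pair frequencies (if pairs given);
    * ``manifest.json`` -- config hash, package versions, inputs.
    """
    config.validate_paths()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    lmap = load_landmark_map(config.landmarks)

    summary_rows = []
    freq_rows = []
    frame_tables: dict[str, pd.DataFrame] = {}
    for cond in config.conditions:
        reference = read_structure(cond.reference or cond.topology)
        per_metric: dict[str, list[float]] = {}
        trajs = []
        for r_idx, traj_path in enumerate(cond.trajectories):
            rep = f"rep{r_idx + 1}"
            traj = read_trajectory(
                cond.topology, traj_path, stride=config.stride,
                source_label=f"{cond.name}/{rep}",
            )
            trajs.append(traj)
            table = metrics_table(
                traj, reference, lmap, config.thresholds, config.criteria,
                condition=cond.name, replicate=rep,
                tm5_reference_s=config.tm5_reference_s,
            )
            name = f"frames_{cond.name}_{rep}"
            frame_tables[name] = table
            table.to_csv(out_dir / f"{name}.csv", index=False, float_format="%.6f")
            for metric, value in _replicate_averages(table).items():
                per_metric.setdefault(metric, []).append(value)
        for metric, values in sorted(per_metric.items()):
            s = replicate_summary(values, condition=cond.name)
            summary_rows.append(
                {
                    "condition": cond.name,
                    "metric": metric,
                    "n": s.n,
                    "mean": s.mean,
                    "ci68": s.ci68_half_width,
                    "replicate_values": ";".join(f"{v:.6f}" for v in s.replicate_values),
                }
            )
        for pair_cfg in config.pairs:
            freq_rows.append(
                _pair_frequency_row(pair_cfg, cond, trajs, lmap, config, reference)
            )

    summary = pd.DataFrame(
        summary_rows,
        columns=["condition", "metric", "n", "mean", "ci68", "replicate_values"],
    )
    summary.to_csv(out_dir / "summary.csv", index=False, float_format="%.6f")
    results = {"summary": summary, **frame_tables}
    if freq_rows:
        freqs = pd.DataFrame(freq_rows)
        freqs.to_csv(out_dir / "frequencies.csv", index=False, float_format="%.6f")
        results["frequencies"] = freqs

    manifest = {
        "config_sha256": _config_hash(config),
        "loopstate_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "conditions": {
            c.name: {"topology": c.topology, "n_replicates": len(c.trajectories)}
            for c in config.conditions
        },
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return results


def _pair_anchor(lmap: LandmarkMap, name_or_spec):
    if isinstance(name_or_spec, str):
        if name_or_spec not in lmap.anchors:
            raise SchemaError(f"pair refers to unknown anchor {name_or_spec!r}")
        a = lmap.anchors[name_or_spec]
        return (a.chain, a.residue, a.atom)
    return (name_or_spec.get("chain"), int(name_or_spec["residue"]), str(name_or_spec["atom"]))


def _pair_frequency_row(
    pair_cfg: Mapping,
    cond: ConditionConfig,
    trajs,
    lmap: LandmarkMap,
    config: RunConfig,
    reference: Frame,
) -> dict:
    atoms = pair_cfg.get("atoms")
    if not atoms or len(atoms) != 2:
        raise SchemaError("each pair needs 'atoms: [a, b]'")
    pair = (_pair_anchor(lmap, atoms[0]), _pair_anchor(lmap, atoms[1]))
    frame_filter = None
    if config.hbond_filter_helical:
        # folded-frames-only filter, RMSD branch of the helicity rule
        def frame_filter(frame, _i):
            return (
                icl2_backbone_rmsd(frame, reference, lmap)
                < config.thresholds.rmsd_max
            )

    row = interaction_frequency(
        trajs, pair, config.criteria, frame_filter,
        pair_label=pair_cfg.get("label"),
    )
    return {
        "pair": row.pair_label,
        "condition": cond.name,
        "n_replicates": len(row.replicate_frequencies),
        "mean": row.mean,
        "ci68": row.ci68_half_width,
        "replicate_frequencies": ";".join(f"{v:.6f}" for v in row.replicate_frequencies),
        "n_frames_used": ";".join(str(n) for n in row.replicate_n_frames),
    }


def compare_conditions(
    summary: pd.DataFrame,
    pairs: Sequence[tuple[str, str]],
    metrics: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Two-sided Mann-Whitney U comparisons between conditions.

    ``summary`` is the table produced by :func:`run_analysis`; the test is
    applied to the per-replicate time-averaged values, so each independent
    simulation contributes one observation.
    """
    required = {"condition", "metric", "replicate_values"}
    if not required <= set(summary.columns):
        raise SchemaError(f"summary table needs columns {sorted(required)}")
    known = set(summary["condition"])
    rows = []
    for cond_a, cond_b in pairs:
        for c in (cond_a, cond_b):
            if c not in known:
                raise SchemaError(f"unknown condition {c!r}")
        for metric in metrics or sorted(set(summary["metric"])):
            vals = []
            for c in (cond_a, cond_b):
                sel = summary[(summary["condition"] == c) & (summary["metric"] == metric)]
                if len(sel) != 1:
                    break
                vals.append([float(v) for v in sel.iloc[0]["replicate_values"].split(";")])
            if len(vals) != 2:
                continue
            try:
                u, p = mwu_two_sided(vals[0], vals[1])
            except EmptySeriesError:
                continue
            rows.append(
                {
                    "metric": metric,
                    "condition_a": cond_a,
                    "condition_b": cond_b,
                    "n_a": len(vals[0]),
                    "n_b": len(vals[1]),
                    "U": u,
                    "p": p,
                }
            )
    return pd.DataFrame(
        rows, columns=["metric", "condition_a", "condition_b", "n_a", "n_b", "U", "p"]
    )


def crystal_shift_report(
    structure_a: str | Path, structure_b: str | Path, lmap: LandmarkMap
) -> float:
    """Signed difference in TM5 vertical shift between two structures (a - b).

    Both shifts are computed with ``reference_s = 0``, so the number is the
    relative vertical displacement of TM5 along the TM4 axis, positive when
    structure a sits further toward the extracellular side.
    """
    shift_a = tm5_vertical_shift(read_structure(structure_a), lmap, 0.0)
    shift_b = tm5_vertical_shift(read_structure(structure_b), lmap, 0.0)
    return float(shift_a - shift_b)
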