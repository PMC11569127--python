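"""Replicate-level statistics and dihedral principal component analysis.

The sampling unit throughout is the independent simulation (replicate):
condition summaries are means of per-replicate time-averages with a 68%
confidence interval of one standard error of the mean (the 1-sigma
convention), and condition comparisons use the two-sided Mann-Whitney U
test on those per-replicate values, computed exactly by complete
enumeration for small samples.

Dihedral PCA encodes each backbone (phi, psi) pair as (sin, cos) features,
the standard dPCA trick that removes the -180/180 wrap discontinuity, and
diagonalizes the covariance of the resulting matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .errors import (
    EmptySeriesError,
    InsufficientDataError,
    MissingAtomError,
    SchemaError,
)
from .structures import Frame, LandmarkMap, Trajectory


# --------------------------------------------------------------------------
# Replicate summaries
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ConditionSummary:
    condition: str
    replicate_values: tuple[float, ...]
    mean: float
    ci68_half_width: float | None  # None when n < 2
    n: int


def replicate_summary(
    values: Sequence[float], condition: str = "", method: str = "sem"
) -> ConditionSummary:
    """Mean and 68% CI of per-replicate values.

    ``method="sem"`` (default) takes the half-width as one standard error,
    sample SD / sqrt(n); ``method="bootstrap"`` uses the percentile
    bootstrap half-width ((q84 - q16) / 2 over 10000 resamples).  With a
    single replicate the CI is undefined (None).
    """
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0:
        raise EmptySeriesError("replicate_summary: no values")
    mean = float(vals.mean())
    if vals.size < 2:
        ci = None
    elif method == "sem":
        ci = float(vals.std(ddof=1) / np.sqrt(vals.size))
    elif method == "bootstrap":
        rng = np.random.default_rng(0)
        boots = rng.choice(vals, size=(10000, vals.size), replace=True).mean(axis=1)
        lo, hi = np.percentile(boots, [15.865, 84.135])
        ci = float((hi - lo) / 2.0)
    else:
        raise SchemaError(f"unknown CI method {method!r}")
    return ConditionSummary(condition, tuple(vals.tolist()), mean, ci, int(vals.size))


# --------------------------------------------------------------------------
# Mann-Whitney U
# --------------------------------------------------------------------------

def _u_from_ranks(ranks: np.ndarray, n1: int) -> float:
    return float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)


def mwu_two_sided(
    x: Sequence[float], y: Sequence[float], exact_max_n: int = 14
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test with midranks for ties.

    Returns ``(U, p)`` where U is the statistic for ``x``.  For
    ``len(x) + len(y) <= exact_max_n`` the p-value is exact, by complete
    enumeration of all label assignments of the pooled sample (ties are
    handled naturally through midranks); larger samples use the normal
    approximation with tie correction and continuity correction.
    """
    xa = np.asarray(list(x), dtype=float)
    ya = np.asarray(list(y), dtype=float)
    if xa.size == 0 or ya.size == 0:
        raise EmptySeriesError("mwu_two_sided: both samples must be non-empty")
    n1, n2 = xa.size, ya.size
    pooled = np.concatenate([xa, ya])
    ranks = rankdata(pooled)  # midranks
    u_obs = _u_from_ranks(ranks, n1)
    mu = n1 * n2 / 2.0
    dev_obs = abs(u_obs - mu)

    n = n1 + n2
    if n <= exact_max_n:
        count = 0
        total = comb(n, n1)
        idx = np.arange(n)
        for chosen in combinations(idx, n1):
            u = float(ranks[list(chosen)].sum() - n1 * (n1 + 1) / 2.0)
            if abs(u - mu) >= dev_obs - 1e-12:
                count += 1
        p = count / total
    else:
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = float(np.sum(tie_counts**3 - tie_counts))
        sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
        if sigma2 <= 0:
            return u_obs, 1.0  # all values identical
        z = (dev_obs - 0.5) / np.sqrt(sigma2)
        p = float(min(1.0, 2.0 * norm.sf(max(z, 0.0))))
    return u_obs, float(min(1.0, p))


# --------------------------------------------------------------------------
# Dihedrals
# --------------------------------------------------------------------------

def torsion_angle(p0, p1, p2, p3) -> float:
    """Signed torsion angle p0-p1-p2-p3 in degrees, IUPAC convention."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - (b0 @ b1) * b1  # back bond projected off the axis
    w = b2 - (b2 @ b1) * b1  # front bond projected off the axis
    return float(np.degrees(np.arctan2(np.cross(b1, v) @ w, v @ w)))


@dataclass
class DihedralMatrix:
    """Frames x sin/cos-encoded (phi, psi) dihedral features."""

    data: np.ndarray  # (n_frames, 4 * n_residues), entries in [-1, 1]
    feature_names: list[str]
    provenance: pd.DataFrame  # columns: condition, replicate, frame, time_ns

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[1] != len(self.feature_names):
            raise SchemaError("dihedral matrix shape does not match feature names")
        if self.data.size and (np.abs(self.data) > 1 + 1e-9).any():
            raise SchemaError("sin/cos features must lie in [-1, 1]")
        if len(self.provenance) != self.data.shape[0]:
            raise SchemaError("provenance rows must equal frame rows")


def _phi_psi_indices(
    topology, chain: str, residue: int
) -> tuple[list[int], list[int]]:
    """Atom indices for phi (C-, N, CA, C) and psi (N, CA, C, N+) of a residue."""
    def one(res: int, name: str) -> int:
        hits = topology.find(chain, res, name)
        if len(hits) != 1:
            raise MissingAtomError(
                f"backbone atom {name} of residue {res} (chain {chain}) "
                f"{'missing' if not hits else 'ambiguous'}"
            )
        return hits[0]

    phi = [one(residue - 1, "C"), one(residue, "N"), one(residue, "CA"), one(residue, "C")]
    psi = [one(residue, "N"), one(residue, "CA"), one(residue, "C"), one(residue + 1, "N")]
    return phi, psi


def frame_phi_psi(frame: Frame, chain: str, residues: Sequence[int]) -> np.ndarray:
    """(n_residues, 2) array of (phi, psi) in degrees for one frame."""
    out = np.empty((len(residues), 2))
    for k, res in enumerate(residues):
        phi_idx, psi_idx = _phi_psi_indices(frame.topology, chain, res)
        out[k, 0] = torsion_angle(*frame.coords[phi_idx])
        out[k, 1] = torsion_angle(*frame.coords[psi_idx])
    return out


def dihedral_features(
    trajs: Sequence[Trajectory],
    lmap: LandmarkMap,
    residue_range: tuple[int, int] | tuple[str, str] | str,
    chain: str | None = None,
    helical_filter: bool = True,
    reference: Frame | None = None,
    rmsd_max: float = 2.0,
    icl2_range: str = "icl2",
) -> DihedralMatrix:
    """Sin/cos-encoded backbone dihedrals of a residue range across trajectories.

    ``residue_range`` may be a (lo, hi) residue pair, a pair of
    Ballesteros-Weinstein codes resolved through the landmark map's
    ``bw_table``, or the name of a range in the map.  With
    ``helical_filter`` on, only frames whose ICL2 backbone RMSD to the
    reference is below ``rmsd_max`` are kept (the RMSD branch of the
    helicity rule alone, matching how the dihedral analysis selects folded
    frames); the reference defaults to the first frame of the first
    trajectory.
    """
    from .metrics import icl2_backbone_rmsd

    if isinstance(residue_range, str):
        spans = lmap.ranges.get(residue_range)
        if not spans or len(spans) != 1:
            raise SchemaError(f"range {residue_range!r} must name one contiguous span")
        chain = chain or spans[0].chain
        lo, hi = spans[0].start, spans[0].stop
    else:
        a, b = residue_range
        if isinstance(a, str) or isinstance(b, str):
            lo, hi = lmap.bw_residue(str(a)), lmap.bw_residue(str(b))
        else:
            lo, hi = int(a), int(b)
    if chain is None:
        chain = "A"
    if not trajs:
        raise EmptySeriesError("dihedral_features: no trajectories")
    if reference is None:
        reference = trajs[0].frame(0)

    residues = list(range(lo, hi + 1))
    names = []
    for res in residues:
        names += [f"phi_sin_{res}", f"phi_cos_{res}", f"psi_sin_{res}", f"psi_cos_{res}"]

    rows = []
    prov = []
    for traj in trajs:
        for i, frame in enumerate(traj):
            if helical_filter:
                r = icl2_backbone_rmsd(frame, reference, lmap, icl2_range=icl2_range)
                if not r < rmsd_max:
                    continue
            ang = np.deg2rad(frame_phi_psi(frame, chain, residues))
            feats = np.stack(
                [np.sin(ang[:, 0]), np.cos(ang[:, 0]), np.sin(ang[:, 1]), np.cos(ang[:, 1])],
                axis=1,
            ).reshape(-1)
            rows.append(feats)
            prov.append(
                {
                    "condition": "",
                    "replicate": traj.source_label,
                    "frame": i,
                    "time_ns": float(traj.times[i]),
                }
            )
    data = np.array(rows) if rows else np.empty((0, len(names)))
    return DihedralMatrix(data, names, pd.DataFrame(prov, columns=["condition", "replicate", "frame", "time_ns"]))


# --------------------------------------------------------------------------
# PCA
# --------------------------------------------------------------------------

@dataclass
class PCAModel:
    feature_names: list[str]
    mean_vector: np.ndarray
    components: np.ndarray  # (k, n_features), orthonormal rows
    explained_variance: np.ndarray  # descending, >= 0

    def __post_init__(self):
        C = np.asarray(self.components, dtype=float)
        if not np.allclose(C @ C.T, np.eye(C.shape[0]), atol=1e-8):
            raise SchemaError("components must be mutually orthonormal")
        ev = np.asarray(self.explained_variance, dtype=float)
        if (ev < -1e-10).any() or (np.diff(ev) > 1e-10).any():
            raise SchemaError("explained_variance must be non-negative and descending")


def pca_fit(m: DihedralMatrix) -> PCAModel:
    """Mean-centered covariance eigendecomposition of a dihedral matrix.

    Components are sorted by explained variance (descending) with a
    deterministic sign convention: the loading of largest magnitude in each
    component is made positive.
    """
    X = m.data
    if X.shape[0] < 2:
        raise InsufficientDataError("PCA needs at least 2 frames")
    mean = X.mean(axis=0)
    Xc = X - mean
    cov = Xc.T @ Xc / (X.shape[0] - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    comps = evecs[:, order].T
    for k in range(comps.shape[0]):
        j = int(np.argmax(np.abs(comps[k])))
        if comps[k, j] < 0:
            comps[k] = -comps[k]
    return PCAModel(list(m.feature_names), mean, comps, evals)


def pca_project(model: PCAModel, m: DihedralMatrix, k: int | None = None) -> np.ndarray:
    """Scores of frames on the first k components."""
    if list(m.feature_names) != list(model.feature_names):
        raise SchemaError("feature names do not match the fitted model")
    k = model.components.shape[0] if k is None else int(k)
    if not (1 <= k <= model.components.shape[0]):
        raise SchemaError(f"k must be in [1, {model.components.shape[0]}]")
    return (m.data - model.mean_vector) @ model.components[:k].T
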