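"""Replicate statistics, exact Mann-Whitney U, dihedrals and dihedral PCA."""

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import mannwhitneyu, special_ortho_group

from loopstate.errors import EmptySeriesError, InsufficientDataError, SchemaError
from loopstate.stats import (
    DihedralMatrix,
    dihedral_features,
    frame_phi_psi,
    mwu_two_sided,
    pca_fit,
    pca_project,
    replicate_summary,
    torsion_angle,
)
from loopstate.structures import LandmarkMap, ResidueSpan, frames_to_trajectory
from loopstate.synth import build_chain

# --------------------------------------------------------------------------
# Replicate summary
# --------------------------------------------------------------------------

def test_replicate_summary_hand_arithmetic():
    s = replicate_summary([1.0, 2.0, 3.0])
    assert s.mean == pytest.approx(2.0)
    assert s.ci68_half_width == pytest.approx(1.0 / np.sqrt(3))  # SD = 1
    assert s.n == 3


def test_replicate_summary_single_and_constant():
    single = replicate_summary([5.0])
    assert single.mean == 5.0 and single.ci68_half_width is None
    const = replicate_summary([2.5, 2.5, 2.5])
    assert const.mean == 2.5 and const.ci68_half_width == 0.0


def test_replicate_summary_order_invariant_and_empty():
    a = replicate_summary([3.0, 1.0, 2.0])
    b = replicate_summary([1.0, 2.0, 3.0])
    assert a.mean == b.mean and a.ci68_half_width == b.ci68_half_width
    with pytest.raises(EmptySeriesError):
        replicate_summary([])


def test_replicate_summary_bootstrap_close_to_sem(rng):
    vals = rng.normal(0, 1, 10)
    sem = replicate_summary(vals).ci68_half_width
    boot = replicate_summary(vals, method="bootstrap").ci68_half_width
    assert boot == pytest.approx(sem, rel=0.35)


# --------------------------------------------------------------------------
# Mann-Whitney U
# --------------------------------------------------------------------------

def _brute_force_p(x, y):
    """Independent oracle: pair-count U over all label assignments."""
    def u_stat(xs, ys):
        return sum(
            1.0 if xi > yj else (0.5 if xi == yj else 0.0) for xi in xs for yj in ys
        )

    pooled = list(x) + list(y)
    n1 = len(x)
    mu = n1 * len(y) / 2.0
    obs = abs(u_stat(x, y) - mu)
    hits = 0
    total = comb(len(pooled), n1)
    for chosen in combinations(range(len(pooled)), n1):
        xs = [pooled[i] for i in chosen]
        ys = [pooled[i] for i in range(len(pooled)) if i not in chosen]
        if abs(u_stat(xs, ys) - mu) >= obs - 1e-12:
            hits += 1
    return hits / total


def test_mwu_fully_separated_samples():
    u, p = mwu_two_sided([1, 2, 3], [4, 5, 6])
    assert u == 0.0
    assert p == pytest.approx(0.1)  # 2 of C(6,3) = 20 assignments as extreme


def test_mwu_symmetry_and_identical_samples():
    _, p_xy = mwu_two_sided([1.0, 5.0, 2.0], [3.0, 4.0, 0.5])
    _, p_yx = mwu_two_sided([3.0, 4.0, 0.5], [1.0, 5.0, 2.0])
    assert p_xy == pytest.approx(p_yx)
    _, p_same = mwu_two_sided([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])
    assert p_same == 1.0


@settings(max_examples=60, deadline=None)
@given(
    seed=st.integers(0, 100_000),
    n1=st.integers(2, 5),
    n2=st.integers(2, 5),
    ties=st.booleans(),
)
def test_mwu_matches_enumeration_oracle(seed, n1, n2, ties):
    """Exact p equals a complete pair-count enumeration for all n1+n2 <= 10."""
    rng = np.random.default_rng(seed)
    if ties:
        x = rng.integers(0, 4, n1).astype(float)
        y = rng.integers(0, 4, n2).astype(float)
    else:
        x = rng.normal(0, 1, n1)
        y = rng.normal(0, 1, n2)
    _, p = mwu_two_sided(list(x), list(y))
    assert p == pytest.approx(_brute_force_p(list(x), list(y)), abs=1e-12)


def test_mwu_matches_scipy_exact_without_ties(rng):
    x = rng.normal(0, 1, 6)
    y = rng.normal(0.5, 1, 7)
    u, p = mwu_two_sided(list(x), list(y))
    ref = mannwhitneyu(x, y, alternative="two-sided", method="exact")
    assert u == pytest.approx(ref.statistic)
    assert p == pytest.approx(ref.pvalue, abs=1e-12)


def test_mwu_normal_approximation_large_samples(rng):
    x = list(rng.normal(0, 1, 30))
    y = list(rng.normal(0.8, 1, 30))
    _, p = mwu_two_sided(x, y)
    ref = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    assert p == pytest.approx(ref.pvalue, rel=0.05)
    with pytest.raises(EmptySeriesError):
        mwu_two_sided([], [1.0])


# --------------------------------------------------------------------------
# Torsions and dihedral features
# --------------------------------------------------------------------------

def test_torsion_hand_built_60_degrees():
    """Four points constructed so the torsion is 60 deg by explicit geometry."""
    p0 = np.array([1.0, 0.0, -1.0])
    p1 = np.array([0.0, 0.0, 0.0])
    p2 = np.array([0.0, 0.0, 1.0])
    theta = np.deg2rad(60.0)
    p3 = np.array([np.cos(theta), np.sin(theta), 2.0])
    assert torsion_angle(p0, p1, p2, p3) == pytest.approx(60.0, abs=1e-6)
    assert torsion_angle(p0, p1, p2, np.array([1.0, 0.0, 2.0])) == pytest.approx(0.0, abs=1e-9)


def test_chain_builder_dihedral_recovery():
    """Torsion-driven construction round-trips through the dihedral reader."""
    for phi, psi in ((-57.0, -47.0), (-120.0, 130.0)):
        chain = build_chain(8, phi=phi, psi=psi, start_res=1)
        angles = frame_phi_psi(chain, "A", list(range(2, 7)))
        np.testing.assert_allclose(angles[:, 0], phi, atol=0.1)
        np.testing.assert_allclose(angles[:, 1], psi, atol=0.1)


def test_ideal_helix_dihedrals_alpha_region(helix9):
    """The parametric helix sits in the alpha-helical (phi, psi) basin."""
    angles = frame_phi_psi(helix9, "A", list(range(112, 117)))
    np.testing.assert_allclose(angles[:, 0], -57.0, atol=2.0)
    np.testing.assert_allclose(angles[:, 1], -47.0, atol=2.0)


def _loop_map():
    return LandmarkMap(ranges={"icl2": [ResidueSpan("A", 3, 6)]})


def test_dihedral_features_wrap_continuity():
    """phi near +180 and -180 give nearly identical sin/cos features."""
    lmap = _loop_map()
    rows = []
    for phi in (179.5, -179.5):
        chain = build_chain(8, phi=phi, psi=120.0)
        traj = frames_to_trajectory([chain])
        m = dihedral_features([traj], lmap, (3, 6), helical_filter=False)
        rows.append(m.data[0])
    assert np.abs(rows[0] - rows[1]).max() < 0.02


def test_dihedral_features_helical_filter_uses_rmsd_branch(helix9):
    lmap = LandmarkMap(ranges={"icl2": [ResidueSpan("A", 110, 118)]})
    extended = build_chain(9, phi=180.0, psi=180.0, start_res=110)
    traj = frames_to_trajectory(
        [helix9, extended.with_coords(extended.coords, time=0.2)]
    )
    m = dihedral_features(
        [traj], lmap, (111, 117), helical_filter=True, reference=helix9
    )
    assert m.data.shape[0] == 1  # extended frame filtered out
    m_all = dihedral_features([traj], lmap, (111, 117), helical_filter=False)
    assert m_all.data.shape[0] == 2
    assert m.data.shape[1] == 4 * 7
    assert np.all(np.abs(m.data) <= 1.0)


def test_dihedral_features_bw_code_resolution(helix9):
    lmap = LandmarkMap(
        ranges={"icl2": [ResidueSpan("A", 110, 118)]},
        bw_table={"3.55": 111, "4.39": 117},
    )
    traj = frames_to_trajectory([helix9])
    m = dihedral_features([traj], lmap, ("3.55", "4.39"), helical_filter=False)
    assert m.feature_names[0] == "phi_sin_111"
    assert m.data.shape == (1, 4 * 7)


# --------------------------------------------------------------------------
# PCA
# --------------------------------------------------------------------------

def _matrix(data):
    data = np.asarray(data, dtype=float)
    names = [f"f{i}" for i in range(data.shape[1])]
    prov = pd.DataFrame(
        {"condition": "", "replicate": "", "frame": range(len(data)), "time_ns": 0.0}
    )
    return DihedralMatrix(data, names, prov)


def test_pca_variance_in_one_feature(rng):
    data = np.zeros((50, 2))
    data[:, 0] = 0.9 * rng.standard_normal(50)
    data = np.clip(data, -1, 1)
    model = pca_fit(_matrix(data))
    np.testing.assert_allclose(np.abs(model.components[0]), [1.0, 0.0], atol=1e-12)
    assert model.components[0][0] > 0  # deterministic sign
    assert model.explained_variance[1] == pytest.approx(0.0, abs=1e-12)
    assert model.explained_variance[0] == pytest.approx(np.var(data[:, 0], ddof=1))


def test_pca_total_variance_conservation(rng):
    data = np.clip(rng.normal(0, 0.4, (60, 5)), -1, 1)
    model = pca_fit(_matrix(data))
    total = np.trace(np.cov(data.T, ddof=1))
    assert model.explained_variance.sum() == pytest.approx(total, abs=1e-6)


def test_pca_eigenvalues_match_power_iteration_oracle(rng):
    """Deflated power iteration on the covariance reproduces the spectrum."""
    data = np.clip(rng.normal(0, 0.3, (100, 4)), -1, 1)
    model = pca_fit(_matrix(data))
    cov = np.cov(data.T, ddof=1)
    oracle = []
    work = cov.copy()
    for _ in range(4):
        v = np.ones(4) / 2.0
        for _ in range(20000):
            w = work @ v
            norm = np.linalg.norm(w)
            if norm < 1e-30:
                break
            v = w / norm
        lam = float(v @ work @ v)
        oracle.append(lam)
        work = work - lam * np.outer(v, v)
    np.testing.assert_allclose(model.explained_variance, oracle, atol=1e-8)


def test_pca_rotation_invariant_spectrum(rng):
    data = np.clip(rng.normal(0, 0.3, (80, 4)), -1, 1)
    Q = special_ortho_group.rvs(4, random_state=rng)
    m1, m2 = _matrix(data), _matrix(data @ Q.T)
    np.testing.assert_allclose(
        pca_fit(m1).explained_variance, pca_fit(m2).explained_variance, atol=1e-8
    )


def test_pca_projection_completeness_and_mean(rng):
    data = np.clip(rng.normal(0, 0.3, (40, 3)), -1, 1)
    m = _matrix(data)
    model = pca_fit(m)
    scores = pca_project(model, m)
    reconstructed = scores @ model.components + model.mean_vector
    np.testing.assert_allclose(reconstructed, data, atol=1e-8)
    mean_scores = pca_project(model, _matrix(model.mean_vector[None, :]))
    np.testing.assert_allclose(mean_scores, 0.0, atol=1e-10)
    k1 = pca_project(model, m, k=1)
    assert np.var(k1[:, 0], ddof=1) == pytest.approx(model.explained_variance[0])


def test_pca_errors(rng):
    with pytest.raises(InsufficientDataError):
        pca_fit(_matrix(np.zeros((1, 3))))
    data = np.clip(rng.normal(0, 0.3, (10, 3)), -1, 1)
    model = pca_fit(_matrix(data))
    other = _matrix(np.zeros((2, 4)))
    with pytest.raises(SchemaError):
        pca_project(model, other)
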