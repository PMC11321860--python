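import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import pdist, squareform
from scipy.stats import f_oneway
from skbio.stats.distance import DistanceMatrix

from jellydiet.community import (
    _permanova_f,
    bray_curtis,
    dispersion,
    fourth_root,
    nmds,
    pairwise_permanova,
    permanova,
)
from jellydiet.io import ContractError


def euclid_dm(points):
    points = np.asarray(points, dtype=float)
    if points.ndim == 1:
        points = points[:, None]
    return DistanceMatrix(squareform(pdist(points)),
                          ids=[f"s{i}" for i in range(len(points))])


# ---------------------------------------------------------------------------
# transforms and distances
# ---------------------------------------------------------------------------


def test_fourth_root_values():
    df = pd.DataFrame([[0.0, 16.0], [81.0, 1.0]])
    out = fourth_root(df)
    assert out.iloc[0].tolist() == [0.0, 2.0]
    assert out.iloc[1].tolist() == [3.0, 1.0]
    with pytest.raises(ContractError):
        fourth_root(pd.DataFrame([[-1.0]]))


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.floats(0, 1e6, allow_nan=False), st.floats(0, 1e6, allow_nan=False))
def test_fourth_root_monotone(x, y):
    lo, hi = sorted([x, y])
    assert fourth_root(np.array([lo]))[0] <= fourth_root(np.array([hi]))[0]


def test_bray_curtis_hand_example():
    df = pd.DataFrame([[6, 2, 0], [2, 2, 4]], index=["j", "k"])
    dm = bray_curtis(df)
    assert dm["j", "k"] == pytest.approx(0.5)


def test_bray_curtis_identical_and_disjoint():
    df = pd.DataFrame([[3, 1], [3, 1], [0, 5]], index=["a", "b", "c"],
                      columns=["t1", "t2"])
    dm = bray_curtis(df)
    assert dm["a", "b"] == 0.0
    disjoint = pd.DataFrame([[1, 0], [0, 1]], index=["a", "b"])
    assert bray_curtis(disjoint)["a", "b"] == 1.0


def test_bray_curtis_rejects_all_zero_sample():
    df = pd.DataFrame([[1, 1], [0, 0]], index=["ok", "empty"])
    with pytest.raises(ContractError, match="empty"):
        bray_curtis(df)


def test_bray_curtis_zero_taxon_column_irrelevant():
    rng = np.random.default_rng(0)
    df = pd.DataFrame(rng.integers(1, 50, (5, 4)).astype(float))
    with_zero = df.copy()
    with_zero[99] = 0.0
    a, b = bray_curtis(df), bray_curtis(with_zero)
    assert np.allclose(a.data, b.data)
    assert (a.data >= 0).all() and (a.data <= 1).all()


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------


def test_permanova_equals_anova_on_univariate_euclidean():
    """For univariate data with Euclidean distance, the distance-based
    pseudo-F is exactly the classical one-way ANOVA F."""
    rng = np.random.default_rng(5)
    for _ in range(5):
        y = rng.normal(size=15)
        groups = ["A"] * 5 + ["B"] * 4 + ["C"] * 6
        res = permanova(euclid_dm(y), groups, n_permutations=9, seed=0)
        f_classic = f_oneway(y[:5], y[5:9], y[9:]).statistic
        assert res.pseudo_F == pytest.approx(f_classic, abs=1e-10)
        assert 0 <= res.R_squared <= 1


def test_permanova_p_matches_exhaustive_enumeration():
    """Sampled permutation p agrees with full enumeration of all 3+3 label
    assignments within Monte-Carlo error."""
    rng = np.random.default_rng(11)
    y = rng.normal(size=6)
    y[3:] += 1.2
    dm = euclid_dm(y)
    groups = np.array([0, 0, 0, 1, 1, 1])
    d2 = dm.data**2
    f_obs, _ = _permanova_f(d2, groups, 2)
    count = total = 0
    for combo in itertools.combinations(range(6), 3):
        labels = np.ones(6, dtype=int)
        labels[list(combo)] = 0
        f_perm, _ = _permanova_f(d2, labels, 2)
        total += 1
        if f_perm >= f_obs:
            count += 1
    p_exact = count / total
    n_perm = 1999
    res = permanova(dm, ["A"] * 3 + ["B"] * 3, n_permutations=n_perm, seed=2)
    mc_err = 3 * np.sqrt(p_exact * (1 - p_exact) / n_perm) + 2 / n_perm
    assert abs(res.p_value - p_exact) <= mc_err


def test_permanova_deterministic_and_order_invariant():
    rng = np.random.default_rng(3)
    pts = rng.normal(size=(10, 4))
    dm = euclid_dm(pts)
    groups = pd.Series((["A"] * 5 + ["B"] * 5), index=dm.ids)
    r1 = permanova(dm, groups, n_permutations=99, seed=7)
    r2 = permanova(dm, groups, n_permutations=99, seed=7)
    assert r1.p_value == r2.p_value and r1.pseudo_F == r2.pseudo_F
    perm = rng.permutation(10)
    dm2 = DistanceMatrix(dm.data[np.ix_(perm, perm)], ids=[dm.ids[i] for i in perm])
    r3 = permanova(dm2, groups.loc[list(dm2.ids)], n_permutations=99, seed=7)
    assert r3.pseudo_F == pytest.approx(r1.pseudo_F, rel=1e-12)


def test_permanova_contracts():
    dm = euclid_dm(np.arange(4))
    with pytest.raises(ContractError, match="fewer than 2"):
        permanova(dm, ["A", "A", "A", "B"], 9, 0)
    with pytest.raises(ContractError, match="2 groups"):
        permanova(dm, ["A"] * 4, 9, 0)
    with pytest.raises(ContractError, match="n_permutations"):
        permanova(dm, ["A", "A", "B", "B"], 0, 0)


def test_permanova_p_never_zero_and_in_range():
    dm = euclid_dm([0, 0.1, 0.2, 10, 10.1, 10.2])
    res = permanova(dm, ["A"] * 3 + ["B"] * 3, n_permutations=999, seed=0)
    assert 0 < res.p_value <= 1


# ---------------------------------------------------------------------------
# pairwise + Bonferroni
# ---------------------------------------------------------------------------


def test_pairwise_three_groups():
    rng = np.random.default_rng(9)
    pts = np.vstack([rng.normal(0, 1, (4, 3)), rng.normal(3, 1, (4, 3)),
                     rng.normal(6, 1, (4, 3))])
    dm = euclid_dm(pts)
    groups = ["A"] * 4 + ["B"] * 4 + ["C"] * 4
    res = pairwise_permanova(dm, groups, n_permutations=99, seed=0)
    assert res.n_comparisons == 3
    for comp in res.comparisons:
        assert comp["p_adjusted"] == pytest.approx(min(1.0, 3 * comp["p_value"]))
        assert comp["p_adjusted"] >= comp["p_value"]
        assert comp["p_adjusted"] <= 1.0


def test_pairwise_bonferroni_arithmetic():
    # m=3 pairs: raw 0.02 -> adjusted 0.06; raw 0.5 -> capped at 1.0 via min()
    assert min(1.0, 3 * 0.02) == pytest.approx(0.06)
    rng = np.random.default_rng(2)
    dm = euclid_dm(rng.normal(size=(9, 2)))
    res = pairwise_permanova(dm, ["A", "A", "A", "B", "B", "B", "C", "C", "C"],
                             n_permutations=9, seed=0)
    assert all(c["p_adjusted"] <= 1.0 for c in res.comparisons)


# ---------------------------------------------------------------------------
# dispersion
# ---------------------------------------------------------------------------


def test_dispersion_matches_coordinate_space_oracle():
    """For Euclidean distances the PCoA distance-to-centroid equals the
    direct coordinate-space computation."""
    rng = np.random.default_rng(4)
    pts = rng.normal(size=(12, 3))
    groups = ["A"] * 6 + ["B"] * 6
    res = dispersion(euclid_dm(pts), groups, n_permutations=99, seed=1)
    direct = np.zeros(12)
    for g, idx in (("A", range(6)), ("B", range(6, 12))):
        centroid = pts[list(idx)].mean(axis=0)
        for i in idx:
            direct[i] = np.linalg.norm(pts[i] - centroid)
    assert np.allclose(res.distances.to_numpy(), direct, atol=1e-9)
    f_direct = f_oneway(direct[:6], direct[6:]).statistic
    assert res.F == pytest.approx(f_direct, abs=1e-9)


def test_dispersion_duplicated_group_has_zero_spread():
    pts = np.vstack([np.tile([1.0, 2.0], (4, 1)),
                     np.random.default_rng(0).normal(size=(4, 2))])
    res = dispersion(euclid_dm(pts), ["A"] * 4 + ["B"] * 4,
                     n_permutations=99, seed=0)
    assert res.group_mean_distances["A"] == pytest.approx(0.0, abs=1e-12)


def test_dispersion_equal_spreads_give_small_f():
    # two groups that are exact translates: identical dispersion, F ~ 0
    rng = np.random.default_rng(8)
    base = rng.normal(size=(6, 2))
    pts = np.vstack([base, base + 50.0])
    res = dispersion(euclid_dm(pts), ["A"] * 6 + ["B"] * 6,
                     n_permutations=199, seed=0)
    assert res.F == pytest.approx(0.0, abs=1e-18)
    assert res.p_value > 0.5


def test_dispersion_handles_braycurtis_negative_eigenvalues():
    rng = np.random.default_rng(12)
    mat = pd.DataFrame(rng.integers(1, 100, (10, 6)).astype(float))
    dm = bray_curtis(mat)
    res = dispersion(dm, ["A"] * 5 + ["B"] * 5, n_permutations=99, seed=0)
    assert np.isfinite(res.F) and 0 < res.p_value <= 1
    assert all(v >= 0 for v in res.group_mean_distances.values())


# ---------------------------------------------------------------------------
# NMDS
# ---------------------------------------------------------------------------


def test_nmds_perfect_embedding_low_stress():
    rng = np.random.default_rng(6)
    pts = rng.normal(size=(12, 2))
    res = nmds(euclid_dm(pts), k=2, n_restarts=4, seed=0)
    assert res.stress < 0.01
    assert res.converged


def test_nmds_three_points_stress_zero():
    res = nmds(euclid_dm([[0, 0], [1, 0], [5, 3]]), k=2, n_restarts=2, seed=0)
    assert res.stress == pytest.approx(0.0, abs=1e-6)


def test_nmds_stress_trace_non_increasing():
    rng = np.random.default_rng(7)
    mat = pd.DataFrame(rng.integers(0, 60, (9, 5)).astype(float) + 1)
    dm = bray_curtis(mat)
    res = nmds(dm, k=2, n_restarts=5, seed=3)
    trace = np.array(res.stress_trace)
    assert len(trace) >= 1
    assert np.all(np.diff(trace) <= 1e-12)
    assert res.stress >= 0


def test_nmds_deterministic_given_seed():
    rng = np.random.default_rng(10)
    mat = pd.DataFrame(rng.integers(1, 40, (8, 4)).astype(float))
    dm = bray_curtis(mat)
    a = nmds(dm, k=2, n_restarts=3, seed=5)
    b = nmds(dm, k=2, n_restarts=3, seed=5)
    assert a.stress == b.stress
    pd.testing.assert_frame_equal(a.coordinates, b.coordinates)
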