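"""Responder signatures: Ward clustering, selection, stability, association."""

from itertools import product

import numpy as np
import pandas as pd
import pytest

import respsig as rs
from respsig.signatures import (
    CandidateDiagnostics,
    Scaler,
    bootstrap_stability,
    pearson_chi2,
    permutation_chi2,
    select_k,
    standardize_deltas,
)


def _delta_frame(points, groups=None):
    points = np.asarray(points, dtype=float)
    return pd.DataFrame(
        {
            "swimmer_id": [f"S{i}" for i in range(len(points))],
            "group": groups if groups is not None else ["G"] * len(points),
            "delta_upper": points[:, 0],
            "delta_lower": points[:, 1],
        }
    )


def _blobs(n_per=10, sep=10.0, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.normal(0, 0.3, size=(n_per, 2))
    b = rng.normal(sep, 0.3, size=(n_per, 2))
    return np.vstack([a, b])


def brute_force_min_wss_2partition(points):
    """Exhaustive minimum within-cluster-sum-of-squares split into 2 clusters."""
    points = np.asarray(points, dtype=float)
    n = len(points)
    best, best_wss = None, np.inf
    for mask_bits in range(1, 2 ** (n - 1)):  # fix point 0 in cluster 0
        mask = np.array([(mask_bits >> i) & 1 for i in range(n)], dtype=bool)
        wss = 0.0
        for m in (mask, ~mask):
            if m.sum() == 0:
                wss = np.inf
                break
            c = points[m].mean(axis=0)
            wss += ((points[m] - c) ** 2).sum()
        if wss < best_wss:
            best_wss, best = wss, mask
    return best


# ---------------------------------------------------------------- standardize


def test_standardize_deltas_properties(default_delta):
    Z, scaler = standardize_deltas(default_delta)
    assert np.allclose(Z.mean(axis=0), 0, atol=1e-12)
    assert np.allclose(Z.std(axis=0, ddof=1), 1, atol=1e-12)
    X = default_delta[["delta_upper", "delta_lower"]].to_numpy()
    assert np.allclose(scaler.transform(X), Z)


def test_standardize_rejects_constant_column():
    d = _delta_frame([[1, 0], [1, 1], [1, 2]])
    with pytest.raises(ValueError, match="delta_upper"):
        standardize_deltas(d)


# ----------------------------------------------------------------------- ward


def test_ward_separated_blobs():
    pts = _blobs()
    labels = rs.ward_cluster(pts, 2)
    assert len(set(labels[:10])) == 1 and len(set(labels[10:])) == 1
    assert labels[0] != labels[10]


def test_ward_k_equals_n_gives_singletons():
    pts = np.arange(10.0).reshape(5, 2)
    assert sorted(rs.ward_cluster(pts, 5)) == [1, 2, 3, 4, 5]


def test_ward_collinear_points():
    pts = np.array([[0.0, 0], [1, 0], [10, 0], [11, 0]])
    labels = rs.ward_cluster(pts, 2)
    assert labels[0] == labels[1] != labels[2] == labels[3]


def _wss(points, mask):
    total = 0.0
    for m in (mask, ~mask):
        c = points[m].mean(axis=0)
        total += ((points[m] - c) ** 2).sum()
    return total


def test_ward_matches_brute_force_wss_oracle_on_structured_points(rng):
    """With genuine two-group structure Ward's k=2 cut is the exhaustive
    minimum-WSS partition; greedy agglomeration guarantees optimality only
    then, so the exact-match oracle is checked on separated data."""
    for _ in range(10):
        n1, n2 = rng.integers(3, 5, size=2)
        pts = np.vstack(
            [rng.normal(0, 0.6, size=(n1, 2)), rng.normal([6, 0], 0.6, size=(n2, 2))]
        )
        labels = rs.ward_cluster(pts, 2)
        oracle = brute_force_min_wss_2partition(pts)
        same = labels == labels[0]
        assert np.array_equal(same, oracle) or np.array_equal(same, ~oracle)


def test_ward_near_optimal_wss_on_random_points(rng):
    """On unstructured points the greedy merge may miss the global optimum,
    but its within-cluster sum of squares stays close to (and never below)
    the exhaustive minimum."""
    ratios = []
    for _ in range(20):
        pts = rng.normal(size=(8, 2))
        labels = rs.ward_cluster(pts, 2)
        opt = _wss(pts, brute_force_min_wss_2partition(pts))
        got = _wss(pts, labels == labels[0])
        assert got >= opt - 1e-9
        ratios.append(got / opt)
    assert np.median(ratios) < 1.05
    assert max(ratios) < 2.0


def test_ward_k_out_of_range():
    with pytest.raises(ValueError):
        rs.ward_cluster(np.zeros((4, 2)), 1)
    with pytest.raises(ValueError):
        rs.ward_cluster(np.zeros((4, 2)), 5)


# ----------------------------------------------------------------- silhouette


def test_silhouette_hand_case():
    pts = np.array([[0.0, 0], [0, 1], [10, 10], [10, 11]])
    labels = np.array([1, 1, 2, 2])
    # direct a/b computation per point gives 0.9293
    assert rs.silhouette(pts, labels) == pytest.approx(0.929, abs=1e-3)


def test_silhouette_penalizes_split_of_identical_points():
    pts = np.vstack([np.zeros((4, 2)), np.ones((4, 2)) * 5])
    labels = np.array([1, 2, 1, 2, 1, 2, 1, 2])  # splits each location across labels
    assert rs.silhouette(pts, labels) <= 0.0


def test_silhouette_approaches_one_with_separation():
    vals = [rs.silhouette(_blobs(sep=sep, seed=1), np.repeat([1, 2], 10)) for sep in (2, 10, 100)]
    assert vals[0] < vals[1] < vals[2]
    assert vals[2] > 0.99


def test_silhouette_single_cluster_rejected():
    with pytest.raises(ValueError):
        rs.silhouette(np.zeros((4, 2)), np.ones(4))


# ------------------------------------------------------------------- select_k


def test_select_k_two_blobs():
    pts = _blobs(n_per=12, seed=2)
    sol = select_k(pts, (2, 4), min_cluster_size=5)
    assert sol.k == 2
    assert sorted(sol.sizes) == [12, 12]
    assert [c.k for c in sol.candidates] == [2, 3, 4]


def test_select_k_three_blobs():
    rng = np.random.default_rng(3)
    pts = np.vstack([rng.normal(c, 0.2, size=(8, 2)) for c in ((0, 0), (10, 0), (0, 10))])
    sol = select_k(pts, (2, 4), min_cluster_size=5)
    assert sol.k == 3


def test_small_cluster_guard_rule():
    """Direct rule application on constructed diagnostics: guard beats silhouette."""
    cands = [
        CandidateDiagnostics(k=2, silhouette=0.6, sizes=(12, 15)),
        CandidateDiagnostics(k=3, silhouette=0.7, sizes=(15, 9, 3)),
        CandidateDiagnostics(k=4, silhouette=0.8, sizes=(7, 8, 3, 9)),
    ]
    ok = [c for c in cands if c.min_size >= 5]
    best = max(ok, key=lambda c: c.silhouette)
    assert best.k == 2


def test_select_k_guard_in_pipeline():
    """A small third subgroup wins on silhouette at k=3 but trips the
    small-cluster guard; the guarded selection falls back to k=2."""
    rng = np.random.default_rng(8)
    pts = np.vstack(
        [
            rng.normal((0, 0), 0.5, size=(6, 2)),
            rng.normal((10, 0), 0.5, size=(6, 2)),
            rng.normal((5, 8), 0.2, size=(3, 2)),
        ]
    )
    sol_unguarded = select_k(pts, (2, 3), min_cluster_size=1)
    sol = select_k(pts, (2, 3), min_cluster_size=5)
    assert sol_unguarded.k == 3  # silhouette alone isolates the small subgroup
    assert sol.k == 2
    assert min(sol.sizes) >= 5


def test_select_k_fallback_when_all_guarded(caplog):
    pts = _blobs(n_per=3, seed=5)
    with caplog.at_level("WARNING", logger="respsig.signatures"):
        sol = select_k(pts, (2, 3), min_cluster_size=5)
    assert sol.k in (2, 3)
    assert "falling back" in caplog.text


# ------------------------------------------------------------------- profiles


def test_cluster_profiles_hand_table():
    d = _delta_frame([[1, 2], [3, 4], [10, 20], [30, 40]])
    labels = np.array([1, 1, 2, 2])
    prof = rs.cluster_profiles(d, labels)
    row = prof[(prof["cluster"] == 1) & (prof["endpoint"] == "delta_upper")].iloc[0]
    assert row["mean"] == 2.0 and row["n"] == 2
    row = prof[(prof["cluster"] == 2) & (prof["endpoint"] == "delta_lower")].iloc[0]
    assert row["mean"] == 30.0
    const = rs.cluster_profiles(_delta_frame([[1, 1], [1, 1], [2, 2]]), np.array([1, 1, 2]))
    assert const[(const["cluster"] == 1)]["sd"].eq(0).all()


def test_high_responder_cluster_has_larger_mean_change(default_delta):
    Z, scaler = standardize_deltas(default_delta)
    sol = select_k(Z, (2, 4), 5, scaler)
    prof = rs.cluster_profiles(default_delta, sol.labels)
    means = prof[prof["endpoint"] == "delta_upper"].set_index("cluster")["mean"]
    assert means.max() > means.min()


# ------------------------------------------------------------------ ARI / jac


def test_ari_identity_and_relabeling():
    a = [1, 1, 2, 2, 3]
    assert rs.adjusted_rand_index(a, a) == 1.0
    assert rs.adjusted_rand_index(a, [2, 2, 3, 3, 1]) == 1.0


def test_ari_hand_case():
    assert rs.adjusted_rand_index([1, 1, 2, 2], [1, 2, 1, 2]) == pytest.approx(-0.5)


def test_ari_length_mismatch():
    with pytest.raises(ValueError):
        rs.adjusted_rand_index([1, 2], [1, 2, 3])


def test_jaccard_cases():
    assert rs.jaccard({1, 2}, {1, 2}) == 1.0
    assert rs.jaccard({1, 2}, {3, 4}) == 0.0
    assert rs.jaccard({1, 2, 3}, {2, 3, 4}) == 0.5
    with pytest.raises(ValueError):
        rs.jaccard(set(), set())


# ------------------------------------------------------------------- matching


def test_max_overlap_identity_under_name_swap():
    ref = np.array([1, 1, 1, 2, 2, 2])
    new = np.array([2, 2, 2, 1, 1, 1])
    assert rs.max_overlap_match(ref, new) == {2: 1, 1: 2}


def test_max_overlap_contingency_oracle():
    # contingency [[10,2],[1,9]]: identity assignment (10+9) beats the swap (2+1)
    ref = np.repeat([1, 2], [12, 10])
    new = np.concatenate([np.repeat([1, 2], [10, 2]), np.repeat([1, 2], [1, 9])])
    assert rs.max_overlap_match(ref, new) == {1: 1, 2: 2}


def test_max_overlap_missing_new_cluster():
    ref = np.array([1, 1, 2, 2])
    new = np.array([1, 1, 1, 1])  # second cluster empty
    mapping = rs.max_overlap_match(ref, new)
    assert mapping[1] in (1, 2)


# ------------------------------------------------------------------ stability


def _solution_for(delta):
    Z, scaler = standardize_deltas(delta)
    return select_k(Z, (2, 4), 5, scaler)


def test_stability_no_resampling_is_exact(default_delta):
    sol = _solution_for(default_delta)
    rep = bootstrap_stability(default_delta, sol, n_replicates=20, seed=0, resample=False)
    assert rep.ari_mean == 1.0
    assert rep.ari_ci95 == (1.0, 1.0)
    assert all(v == 1.0 for v in rep.jaccard_mean.values())


def test_stability_blobs_near_perfect_and_above_noise():
    blobs = _delta_frame(_blobs(n_per=10, sep=8.0, seed=6))
    noise = _delta_frame(np.random.default_rng(6).normal(size=(20, 2)))
    sol_b = _solution_for(blobs)
    rep_b = bootstrap_stability(blobs, sol_b, n_replicates=100, seed=1)
    Zn, scn = standardize_deltas(noise)
    from respsig.signatures import ward_cluster, silhouette as sil, ClusterSolution

    labels = ward_cluster(Zn, 2)
    sol_n = ClusterSolution(
        k=2,
        labels=labels,
        silhouette=sil(Zn, labels),
        sizes=tuple(int((labels == c).sum()) for c in (1, 2)),
        scaler=scn,
    )
    rep_n = bootstrap_stability(noise, sol_n, n_replicates=100, seed=1)
    assert rep_b.ari_mean > 0.95
    assert min(rep_b.jaccard_mean.values()) > 0.9
    assert rep_n.ari_mean < rep_b.ari_mean - 0.2


def test_stability_deterministic(default_delta):
    sol = _solution_for(default_delta)
    r1 = bootstrap_stability(default_delta, sol, n_replicates=50, seed=3)
    r2 = bootstrap_stability(default_delta, sol, n_replicates=50, seed=3)
    assert np.array_equal(r1.ari_distribution, r2.ari_distribution)
    assert r1.jaccard_mean == r2.jaccard_mean
    assert -1 <= r1.ari_mean <= 1
    for c, (lo, hi) in r1.jaccard_ci95.items():
        assert 0 <= lo <= hi <= 1


# ------------------------------------------------------------------ chi-square


def test_pearson_chi2_printed_table():
    assert pearson_chi2([[0, 3, 9], [9, 6, 0]]) == pytest.approx(18.900, abs=1e-9)


def test_pearson_chi2_hand_cases():
    assert pearson_chi2([[2, 0], [0, 2]]) == pytest.approx(4.0)
    assert pearson_chi2([[3, 3], [3, 3]]) == 0.0


def test_permutation_chi2_strong_association():
    groups = np.repeat(["MSTG", "PTG", "CG"], 9)
    # cluster membership per the strong group-tracking pattern
    labels = np.concatenate([np.full(9, 2), np.repeat([1, 2], [3, 6]), np.full(9, 1)])
    rep = permutation_chi2(groups, labels, n_perm=100_000, seed=0)
    assert rep.chi2 == pytest.approx(18.900, abs=1e-9)
    assert rep.p_perm < 0.001
    assert rep.contingency.to_numpy().sum() == 27


def test_permutation_chi2_uniform_table():
    groups = np.repeat(["A", "B"], 8)
    labels = np.tile([1, 2], 8)
    rep = permutation_chi2(groups, labels, n_perm=2_000, seed=1)
    assert rep.chi2 == pytest.approx(0.0)
    assert rep.p_perm > 0.9


def test_permutation_chi2_null_uniformity():
    rng = np.random.default_rng(2)
    groups = np.repeat(["A", "B", "C"], 9)
    ps = []
    for rep_i in range(20):
        labels = rng.integers(1, 3, size=27)
        if len(np.unique(labels)) < 2:
            continue
        ps.append(permutation_chi2(groups, labels, n_perm=1_000, seed=rep_i).p_perm)
    assert np.mean(np.array(ps) < 0.05) < 0.3
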