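"""Responder-signature discovery in the (ΔUpper, ΔLower) change plane.

Swimmers are clustered on their standardized two-dimensional composite-change
vector with Ward's minimum-variance agglomerative linkage. The number of
clusters is chosen over k = 2..4 by silhouette score with a guard against
very small clusters. Solution stability is quantified by a bootstrap scheme:
each replicate refits the clustering on a resample, every original swimmer is
assigned to the nearest bootstrap centroid in the original standardized
space, bootstrap labels are aligned to the original solution by optimal
maximum-overlap matching, and agreement is summarized by the adjusted Rand
index and cluster-wise Jaccard similarity. Association between training arm
and signature membership uses a permutation chi-square test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import adjusted_rand_score, silhouette_score

from ._utils import child_rng, t_ci

logger = logging.getLogger(__name__)

FEATURES = ("delta_upper", "delta_lower")


@dataclass
class Scaler:
    """Per-dimension mean/SD frozen at the original fit."""

    mean: np.ndarray
    sd: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) / self.sd


@dataclass
class CandidateDiagnostics:
    k: int
    silhouette: float
    sizes: tuple[int, ...]

    @property
    def min_size(self) -> int:
        return min(self.sizes)


@dataclass
class ClusterSolution:
    k: int
    labels: np.ndarray  # 1..k per swimmer
    silhouette: float
    sizes: tuple[int, ...]
    scaler: Scaler
    candidates: list[CandidateDiagnostics] = field(default_factory=list)


@dataclass
class StabilityReport:
    n_replicates: int
    ari_mean: float
    ari_ci95: tuple[float, float]
    ari_sd: float
    ari_distribution: np.ndarray
    jaccard_mean: dict[int, float]
    jaccard_sd: dict[int, float]
    jaccard_ci95: dict[int, tuple[float, float]]
    jaccard_distribution: dict[int, np.ndarray]
    seed: int


@dataclass
class AssociationReport:
    contingency: pd.DataFrame  # clusters x groups
    chi2: float
    p_perm: float
    n_perm: int


def standardize_deltas(delta: pd.DataFrame) -> tuple[np.ndarray, Scaler]:
    """Z-score (delta_upper, delta_lower) by full-sample mean/SD."""
    X = delta[list(FEATURES)].to_numpy(dtype=float)
    if X.shape[0] < 3:
        raise ValueError("standardize_deltas requires n >= 3")
    sd = X.std(axis=0, ddof=1)
    for name, s in zip(FEATURES, sd):
        if not s > 0:
            raise ValueError(f"column {name!r} has zero variance")
    scaler = Scaler(mean=X.mean(axis=0), sd=sd)
    return scaler.transform(X), scaler


def ward_cluster(points: np.ndarray, k: int) -> np.ndarray:
    """Ward-linkage agglomerative clustering cut at k clusters.

    Labels are renumbered 1..k in order of first appearance, so the labeling
    is deterministic in the input row order.
    """
    points = np.asarray(points, dtype=float)
    n = points.shape[0]
    if not 2 <= k <= n:
        raise ValueError(f"k must be in [2, {n}], got {k}")
    raw = fcluster(linkage(points, method="ward"), t=k, criterion="maxclust")
    _, first = np.unique(raw, return_index=True)
    order = raw[np.sort(first)]
    remap = {old: new for new, old in enumerate(order, start=1)}
    return np.array([remap[v] for v in raw])


def silhouette(points: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette score over points (singletons contribute 0)."""
    labels = np.asarray(labels)
    k = len(np.unique(labels))
    n = len(labels)
    if k < 2 or k > n - 1:
        raise ValueError("silhouette requires 2 <= k <= n - 1")
    return float(silhouette_score(np.asarray(points, dtype=float), labels))


def select_k(
    points: np.ndarray,
    k_range: range | tuple[int, int] = (2, 4),
    min_cluster_size: int = 5,
    scaler: Scaler | None = None,
) -> ClusterSolution:
    """Fit every candidate k and pick the best admissible solution.

    Candidates whose smallest cluster is below ``min_cluster_size`` are
    discarded; among survivors the highest silhouette wins. If every
    candidate is discarded the overall silhouette maximum is returned with a
    logged warning.
    """
    if isinstance(k_range, tuple):
        ks = list(range(k_range[0], k_range[1] + 1))
    else:
        ks = list(k_range)
    if not ks:
        raise ValueError("empty k_range")
    points = np.asarray(points, dtype=float)
    fits: dict[int, np.ndarray] = {}
    cands: list[CandidateDiagnostics] = []
    for k in ks:
        labels = ward_cluster(points, k)
        fits[k] = labels
        sizes = tuple(int(np.sum(labels == c)) for c in range(1, k + 1))
        cands.append(CandidateDiagnostics(k=k, silhouette=silhouette(points, labels), sizes=sizes))
    ok = [c for c in cands if c.min_size >= min_cluster_size]
    if not ok:
        logger.warning(
            "all candidate solutions have a cluster smaller than %d; "
            "falling back to the overall silhouette maximum",
            min_cluster_size,
        )
        ok = cands
    best = max(ok, key=lambda c: c.silhouette)
    return ClusterSolution(
        k=best.k,
        labels=fits[best.k],
        silhouette=best.silhouette,
        sizes=best.sizes,
        scaler=scaler if scaler is not None else Scaler(np.zeros(points.shape[1]), np.ones(points.shape[1])),
        candidates=cands,
    )


def cluster_profiles(delta: pd.DataFrame, labels: np.ndarray) -> pd.DataFrame:
    """Per cluster x endpoint: n, mean, SD and t-based 95% CI in raw composite units."""
    rows = []
    for c in np.unique(labels):
        sub = delta.loc[np.asarray(labels) == c]
        for endpoint in FEATURES:
            x = sub[endpoint].to_numpy(dtype=float)
            m, s = float(x.mean()), float(x.std(ddof=1)) if len(x) > 1 else 0.0
            lo, hi = t_ci(m, s, len(x)) if len(x) > 1 else (m, m)
            rows.append(
                {
                    "cluster": int(c),
                    "endpoint": endpoint,
                    "n": len(x),
                    "mean": m,
                    "sd": s,
                    "ci95_lower": lo,
                    "ci95_upper": hi,
                }
            )
    return pd.DataFrame(rows)


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Chance-corrected pair-counting agreement between two partitions."""
    labels_a = np.asarray(labels_a)
    labels_b = np.asarray(labels_b)
    if labels_a.shape != labels_b.shape:
        raise ValueError("labelings must have equal length")
    if labels_a.size < 2:
        raise ValueError("need at least 2 points")
    return float(adjusted_rand_score(labels_a, labels_b))


def jaccard(set_a, set_b) -> float:
    """|A ∩ B| / |A ∪ B|."""
    a, b = set(set_a), set(set_b)
    if not a and not b:
        raise ValueError("both sets empty")
    return len(a & b) / len(a | b)


def max_overlap_match(labels_ref, labels_new) -> dict[int, int]:
    """Map new cluster ids to reference ids maximizing total overlap.

    Optimal one-to-one assignment on the k x k contingency table; unequal
    cluster counts are handled by padding with empty pseudo-clusters.
    """
    labels_ref = np.asarray(labels_ref)
    labels_new = np.asarray(labels_new)
    if labels_ref.shape != labels_new.shape:
        raise ValueError("labelings must cover the same points")
    ref_ids = np.unique(labels_ref)
    new_ids = np.unique(labels_new)
    k = max(len(ref_ids), len(new_ids))
    table = np.zeros((k, k))
    for i, r in enumerate(ref_ids):
        for j, c in enumerate(new_ids):
            table[i, j] = np.sum((labels_ref == r) & (labels_new == c))
    rows, cols = linear_sum_assignment(-table)
    mapping: dict[int, int] = {}
    next_free = [int(r) for r in ref_ids]
    for i, j in zip(rows, cols):
        ref = int(ref_ids[i]) if i < len(ref_ids) else None
        if j < len(new_ids):
            new = int(new_ids[j])
            if ref is not None:
                mapping[new] = ref
                next_free.remove(ref)
    # new clusters beyond the reference count map to fresh ids (unused refs first)
    for new in new_ids:
        if int(new) not in mapping:
            mapping[int(new)] = next_free.pop(0) if next_free else int(new)
    return mapping


def bootstrap_stability(
    delta: pd.DataFrame,
    solution: ClusterSolution,
    n_replicates: int = 2_000,
    seed: int = 0,
    resample: bool = True,
) -> StabilityReport:
    """Bootstrap stability of a fitted cluster solution.

    Per replicate: resample swimmers with replacement, refit Ward with the
    selected k on the resample (in the ORIGINAL standardized space — the
    original scaler is reused), compute bootstrap cluster centroids, assign
    every original swimmer to the nearest centroid (Euclidean, ties to the
    lowest cluster id), align to the original labels by maximum-overlap
    matching, and record the ARI plus per-original-cluster Jaccard with the
    matched cluster. ``resample=False`` is a diagnostic mode in which every
    replicate is the original sample (must return ARI = Jaccard = 1).
    """
    X = solution.scaler.transform(delta[list(FEATURES)].to_numpy(dtype=float))
    n = X.shape[0]
    k = solution.k
    orig = np.asarray(solution.labels)
    orig_sets = {int(c): set(np.flatnonzero(orig == c)) for c in np.unique(orig)}
    rng = child_rng(seed, "stability")

    aris = np.empty(n_replicates)
    jac = {c: np.empty(n_replicates) for c in orig_sets}
    for r in range(n_replicates):
        idx = rng.integers(0, n, size=n) if resample else np.arange(n)
        boot_labels = ward_cluster(X[idx], k)
        centroids = np.vstack([X[idx][boot_labels == c].mean(axis=0) for c in range(1, k + 1)])
        d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        assigned = np.argmin(d2, axis=1) + 1  # argmin ties -> lowest id
        mapping = max_overlap_match(orig, assigned)
        mapped = np.array([mapping[int(c)] for c in assigned])
        aris[r] = adjusted_rand_score(orig, mapped)
        for c, members in orig_sets.items():
            new_members = set(np.flatnonzero(mapped == c))
            if not members and not new_members:
                jac[c][r] = 1.0
            elif not new_members:
                jac[c][r] = 0.0
            else:
                jac[c][r] = jaccard(members, new_members)

    def pct(x):
        lo, hi = np.percentile(x, [2.5, 97.5])
        return (float(lo), float(hi))

    return StabilityReport(
        n_replicates=n_replicates,
        ari_mean=float(aris.mean()),
        ari_ci95=pct(aris),
        ari_sd=float(aris.std(ddof=1)) if n_replicates > 1 else 0.0,
        ari_distribution=aris,
        jaccard_mean={c: float(v.mean()) for c, v in jac.items()},
        jaccard_sd={c: float(v.std(ddof=1)) if n_replicates > 1 else 0.0 for c, v in jac.items()},
        jaccard_ci95={c: pct(v) for c, v in jac.items()},
        jaccard_distribution=jac,
        seed=seed,
    )


def pearson_chi2(table: np.ndarray) -> float:
    """Pearson chi-square statistic on a contingency table (no correction)."""
    O = np.asarray(table, dtype=float)
    rows = O.sum(axis=1, keepdims=True)
    cols = O.sum(axis=0, keepdims=True)
    n = O.sum()
    if np.any(rows == 0) or np.any(cols == 0):
        raise ValueError("contingency table has an empty row or column")
    E = rows @ cols / n
    return float(((O - E) ** 2 / E).sum())


def permutation_chi2(groups, labels, n_perm: int = 100_000, seed: int = 0) -> AssociationReport:
    """Permutation chi-square test of group x cluster association.

    The observed Pearson chi-square is referenced to its permutation null
    obtained by randomly relabeling group assignments; p uses the
    (1 + count) / (n_perm + 1) estimator.
    """
    groups = np.asarray(groups)
    labels = np.asarray(labels)
    if groups.shape != labels.shape or groups.size < 2:
        raise ValueError("groups and labels must be equal-length, n >= 2")
    g_ids, g_idx = np.unique(groups, return_inverse=True)
    c_ids, c_idx = np.unique(labels, return_inverse=True)
    if len(g_ids) < 2 or len(c_ids) < 2:
        raise ValueError("need at least 2 groups and 2 clusters")
    G, C = len(g_ids), len(c_ids)
    n = groups.size

    def table_of(gi):
        return np.bincount(c_idx * G + gi, minlength=C * G).reshape(C, G)

    obs_table = table_of(g_idx)
    chi2_obs = pearson_chi2(obs_table)

    # margins are invariant under relabeling, so E is fixed
    E = obs_table.sum(axis=1, keepdims=True) @ obs_table.sum(axis=0, keepdims=True) / n
    rng = child_rng(seed, "chi2")
    hits = 0
    block = 5_000
    done = 0
    while done < n_perm:
        kk = min(block, n_perm - done)
        perms = rng.permuted(np.tile(g_idx, (kk, 1)), axis=1)
        flat = c_idx[None, :] * G + perms
        offsets = np.arange(kk)[:, None] * (C * G)
        counts = np.bincount((flat + offsets).ravel(), minlength=kk * C * G).reshape(kk, C, G)
        chi2_star = (((counts - E[None]) ** 2) / E[None]).sum(axis=(1, 2))
        hits += int(np.sum(chi2_star >= chi2_obs - 1e-12))
        done += kk
    p = (1 + hits) / (n_perm + 1)

    # order the contingency frame by first appearance for readability
    groups_order = list(dict.fromkeys(groups))
    frame = pd.DataFrame(obs_table, index=[int(c) if np.issubdtype(c_ids.dtype, np.integer) else c for c in c_ids], columns=list(g_ids))
    frame = frame[groups_order]
    frame.index.name = "cluster"
    return AssociationReport(contingency=frame, chi2=chi2_obs, p_perm=p, n_perm=n_perm)
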