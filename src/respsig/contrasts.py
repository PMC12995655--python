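"""Descriptive statistics and pairwise between-group inference on change scores.

Group contrasts on the composite change scores use distribution-light
machinery suited to small arms: label-permutation tests of the mean
difference, stratified bootstrap percentile intervals, Hedges g with the
small-sample correction, and Holm step-down adjustment across the three
pairwise contrasts within each endpoint.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from ._utils import child_rng, t_ci

ENDPOINTS = ("delta_upper", "delta_lower")
ENDPOINT_LABELS = {"delta_upper": "ΔUpper (Post-Pre)", "delta_lower": "ΔLower (Post-Pre)"}


@dataclass
class DescriptiveRow:
    endpoint: str
    group: str
    n: int
    mean: float
    sd: float
    ci95: tuple[float, float]


@dataclass
class ContrastResult:
    endpoint: str
    pair: tuple[str, str]
    mean_diff: float
    boot_ci95: tuple[float, float]
    p_perm: float
    p_holm: float
    hedges_g: float
    n_perm: int
    n_boot: int
    seed: int


def describe(delta: pd.DataFrame, endpoint: str) -> list[DescriptiveRow]:
    """Per-group n, mean, sample SD and t-based 95% CI for one endpoint."""
    rows = []
    for g, sub in delta.groupby("group", sort=False):
        x = sub[endpoint].to_numpy(dtype=float)
        if len(x) < 2:
            raise ValueError(f"group {g!r} has n < 2")
        m, s = float(x.mean()), float(x.std(ddof=1))
        rows.append(DescriptiveRow(endpoint, str(g), len(x), m, s, t_ci(m, s, len(x))))
    return rows


def mean_diff(a, b) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("mean_diff requires nonempty samples")
    return float(a.mean() - b.mean())


def hedges_g(a, b) -> float:
    """Pooled-SD standardized mean difference with small-sample correction.

    g = J * (mean_a - mean_b) / s_pooled, with J = 1 - 3 / (4*df - 1) and
    df = n_a + n_b - 2.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("hedges_g requires n >= 2 per group")
    return hedges_g_from_summary(
        a.mean(), a.std(ddof=1), a.size, b.mean(), b.std(ddof=1), b.size
    )


def hedges_g_from_summary(m_a, s_a, n_a, m_b, s_b, n_b) -> float:
    """Hedges g from group summary statistics (mean, sample SD, n)."""
    df = n_a + n_b - 2
    sp2 = ((n_a - 1) * s_a**2 + (n_b - 1) * s_b**2) / df
    if not sp2 > 0:
        raise ValueError("pooled variance is zero")
    j = 1.0 - 3.0 / (4.0 * df - 1.0)
    return float(j * (m_a - m_b) / np.sqrt(sp2))


def permutation_test(
    a,
    b,
    n_perm: int = 100_000,
    seed: int | np.random.Generator = 0,
    exact_threshold: int = 12,
    plus_one: bool = True,
) -> float:
    """Two-sided permutation p-value for the difference in means.

    Random relabelings of the pooled sample preserve group sizes; the Monte
    Carlo p-value uses the (1 + count) / (n_perm + 1) estimator so p > 0 (set
    ``plus_one=False`` for the uncorrected count / n_perm estimator). When the
    pooled size is at most ``exact_threshold`` all C(n, n_a) splits are
    enumerated and the exact tail proportion is returned.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    pooled = np.concatenate([a, b])
    n, n_a = pooled.size, a.size
    t_obs = abs(a.mean() - b.mean())
    tol = 1e-12 * max(1.0, t_obs)

    if n <= exact_threshold:
        total = pooled.sum()
        hits = splits = 0
        for idx in combinations(range(n), n_a):
            m_a = pooled[list(idx)].mean()
            m_b = (total - pooled[list(idx)].sum()) / (n - n_a)
            splits += 1
            if abs(m_a - m_b) >= t_obs - tol:
                hits += 1
        return hits / splits

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    # vectorized relabeling in manageable blocks
    hits = 0
    block = 20_000
    done = 0
    while done < n_perm:
        k = min(block, n_perm - done)
        mat = np.tile(pooled, (k, 1))
        mat = rng.permuted(mat, axis=1)
        t_star = np.abs(mat[:, :n_a].mean(axis=1) - mat[:, n_a:].mean(axis=1))
        hits += int(np.sum(t_star >= t_obs - tol))
        done += k
    if plus_one:
        return (1 + hits) / (n_perm + 1)
    return hits / n_perm


def bootstrap_ci_mean_diff(
    a, b, n_boot: int = 20_000, seed: int | np.random.Generator = 0
) -> tuple[float, float]:
    """Stratified bootstrap percentile 95% CI for the difference in means.

    Resamples within each group independently with replacement.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("bootstrap requires n >= 2 per group")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ia = rng.integers(0, a.size, size=(n_boot, a.size))
    ib = rng.integers(0, b.size, size=(n_boot, b.size))
    diffs = a[ia].mean(axis=1) - b[ib].mean(axis=1)
    lo, hi = np.percentile(diffs, [2.5, 97.5])
    return (float(lo), float(hi))


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values, returned in input order."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="holm")[1]


def run_contrasts(
    delta: pd.DataFrame,
    n_perm: int = 100_000,
    n_boot: int = 20_000,
    seed: int = 0,
    plus_one: bool = True,
) -> list[ContrastResult]:
    """All pairwise contrasts for both endpoints, Holm-adjusted per endpoint.

    Requires exactly three groups; produces 6 rows (2 endpoints x 3 pairs).
    Each contrast draws from its own deterministic child stream of ``seed``.
    """
    groups = list(dict.fromkeys(delta["group"]))
    if len(groups) != 3:
        raise ValueError(f"expected exactly 3 groups, got {groups}")
    pairs = list(combinations(groups, 2))
    results: list[ContrastResult] = []
    for endpoint in ENDPOINTS:
        samples = {g: delta.loc[delta["group"] == g, endpoint].to_numpy(float) for g in groups}
        partial = []
        for pair in pairs:
            a, b = samples[pair[0]], samples[pair[1]]
            rng_p = child_rng(seed, "perm", endpoint, *pair)
            rng_b = child_rng(seed, "boot", endpoint, *pair)
            partial.append(
                ContrastResult(
                    endpoint=endpoint,
                    pair=pair,
                    mean_diff=mean_diff(a, b),
                    boot_ci95=bootstrap_ci_mean_diff(a, b, n_boot, rng_b),
                    p_perm=permutation_test(a, b, n_perm, rng_p, plus_one=plus_one),
                    p_holm=np.nan,
                    hedges_g=hedges_g(a, b),
                    n_perm=n_perm,
                    n_boot=n_boot,
                    seed=seed,
                )
            )
        adj = holm_adjust([r.p_perm for r in partial])
        for r, p in zip(partial, adj):
            r.p_holm = float(p)
        results.extend(partial)
    return results


def contrasts_frame(results: list[ContrastResult]) -> pd.DataFrame:
    """Tabular view of contrast results (one row per endpoint x pair)."""
    return pd.DataFrame(
        {
            "endpoint": [ENDPOINT_LABELS.get(r.endpoint, r.endpoint) for r in results],
            "contrast": [f"{r.pair[0]} vs. {r.pair[1]}" for r in results],
            "mean_difference": [r.mean_diff for r in results],
            "ci95_lower": [r.boot_ci95[0] for r in results],
            "ci95_upper": [r.boot_ci95[1] for r in results],
            "p_perm": [r.p_perm for r in results],
            "p_holm": [r.p_holm for r in results],
            "hedges_g": [r.hedges_g for r in results],
        }
    )


def descriptives_frame(rows: list[DescriptiveRow]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "endpoint": [ENDPOINT_LABELS.get(r.endpoint, r.endpoint) for r in rows],
            "group": [r.group for r in rows],
            "n": [r.n for r in rows],
            "mean": [r.mean for r in rows],
            "sd": [r.sd for r in rows],
            "ci95_lower": [r.ci95[0] for r in rows],
            "ci95_upper": [r.ci95[1] for r in rows],
        }
    )
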