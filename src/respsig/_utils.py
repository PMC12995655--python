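"""Small shared helpers: t-based intervals, p-value formatting, seeded streams."""

from __future__ import annotations

import numpy as np
from scipy import stats


def t_ci(mean: float, sd: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Two-sided t confidence interval for a mean from summary statistics.

    Uses the t multiplier with n-1 degrees of freedom: mean +/- t * sd/sqrt(n).
    """
    if n < 2:
        raise ValueError("t_ci requires n >= 2")
    half = stats.t.ppf(0.5 + level / 2.0, n - 1) * sd / np.sqrt(n)
    return (mean - half, mean + half)


def format_p(p: float, floor: float = 0.001) -> str:
    """Render a p-value to three decimals, with values below 0.001 as '<0.001'."""
    if p < floor:
        return "<0.001"
    return f"{p:.3f}"


def child_rng(seed: int, *stream: str | int) -> np.random.Generator:
    """Deterministic named child stream derived from a master seed.

    Every stochastic stage draws from its own stream so stages can be re-run
    independently without perturbing each other.
    """
    key = [abs(int(seed))]
    for s in stream:
        if isinstance(s, str):
            key.extend(ord(c) for c in s)
        else:
            key.append(abs(int(s)))
    return np.random.default_rng(np.random.SeedSequence(key))
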