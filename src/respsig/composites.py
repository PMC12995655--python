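"""Baseline-anchored power composites.

Each domain (upper limb, lower limb) is summarized by a single composite
construct: the Pre-intervention indicator block is standardized by its own
means/SDs, a one-component PCA is fitted on the baseline correlation
structure, and the resulting unit-norm loading vector is frozen. Composite
scores at every time point are raw projections through those fixed baseline
loadings and baseline standardization constants, so a composite change of 1
is interpretable in baseline-standardized units. Responsiveness is the
Post - Pre composite change per swimmer (delta_upper, delta_lower).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd


class DegenerateInputError(ValueError):
    pass


class InsufficientDataError(ValueError):
    pass


@dataclass
class CompositeModel:
    """Frozen one-component baseline PCA for one indicator domain.

    ``loadings`` is the leading eigenvector of the baseline correlation
    matrix, unit norm, oriented so its coefficient sum is positive (ties
    broken so the first coefficient is non-negative). ``variance_explained``
    is the leading eigenvalue divided by the trace.
    """

    domain: str
    indicators: tuple[str, ...]
    baseline_mean: np.ndarray
    baseline_sd: np.ndarray
    loadings: np.ndarray
    variance_explained: float

    def __post_init__(self) -> None:
        self.baseline_mean = np.asarray(self.baseline_mean, dtype=float)
        self.baseline_sd = np.asarray(self.baseline_sd, dtype=float)
        self.loadings = np.asarray(self.loadings, dtype=float)
        if not np.isclose(np.linalg.norm(self.loadings), 1.0, atol=1e-9):
            raise ValueError("loadings must be unit norm")
        if np.any(self.baseline_sd <= 0):
            raise ValueError("baseline_sd must be positive")
        if not 0.0 <= self.variance_explained <= 1.0 + 1e-12:
            raise ValueError("variance_explained must be in [0, 1]")

    def to_json(self) -> str:
        return json.dumps(
            {
                "domain": self.domain,
                "indicators": list(self.indicators),
                "baseline_mean": self.baseline_mean.tolist(),
                "baseline_sd": self.baseline_sd.tolist(),
                "loadings": self.loadings.tolist(),
                "variance_explained": self.variance_explained,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "CompositeModel":
        d = json.loads(text)
        return cls(
            domain=d["domain"],
            indicators=tuple(d["indicators"]),
            baseline_mean=np.array(d["baseline_mean"]),
            baseline_sd=np.array(d["baseline_sd"]),
            loadings=np.array(d["loadings"]),
            variance_explained=float(d["variance_explained"]),
        )


def _pre_block(panel: pd.DataFrame, indicators: tuple[str, ...], timepoint: str) -> np.ndarray:
    cols = [f"{ind}_{timepoint}" for ind in indicators]
    missing = [c for c in cols if c not in panel.columns]
    if missing:
        raise KeyError(f"panel is missing columns: {missing}")
    block = panel[cols].to_numpy(dtype=float)
    if np.isnan(block).any():
        raise ValueError("panel contains missing indicator values")
    return block


def fit_baseline_pca(
    panel: pd.DataFrame, domain: str, indicators: tuple[str, ...] | list[str]
) -> CompositeModel:
    """Fit the one-component baseline PCA for a domain.

    Pre columns are standardized by their own mean/SD (SD with n-1
    denominator) and the leading eigenvector of the resulting correlation
    matrix becomes the fixed loading vector.
    """
    indicators = tuple(indicators)
    X = _pre_block(panel, indicators, "pre")
    n, m = X.shape
    if n < 3:
        raise InsufficientDataError(f"baseline PCA requires >= 3 swimmers, got {n}")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    for ind, s in zip(indicators, sd):
        if not s > 0:
            raise DegenerateInputError(f"indicator {ind!r} has zero baseline variance")
    Z = (X - mean) / sd
    corr = np.cov(Z, rowvar=False, ddof=1)
    corr = np.atleast_2d(corr)
    evals, evecs = np.linalg.eigh(corr)
    lead = evecs[:, -1]
    s = lead.sum()
    # a coefficient sum at floating-point scale is a genuine tie (e.g. the
    # (1, -1)/sqrt(2) eigenvector of an anticorrelated pair): orient by the
    # first coefficient instead so the sign is numerically stable
    if abs(s) <= 1e-8:
        if lead[0] < 0:
            lead = -lead
    elif s < 0:
        lead = -lead
    return CompositeModel(
        domain=domain,
        indicators=indicators,
        baseline_mean=mean,
        baseline_sd=sd,
        loadings=lead,
        variance_explained=float(evals[-1] / np.trace(corr)),
    )


def apply_composite(model: CompositeModel, panel: pd.DataFrame, timepoint: str) -> np.ndarray:
    """Project a time point through the frozen baseline model.

    Standardization always uses the baseline (Pre-fit) means/SDs regardless of
    the time point being scored.
    """
    X = _pre_block(panel, model.indicators, timepoint)
    Z = (X - model.baseline_mean) / model.baseline_sd
    return Z @ model.loadings


DELTA_COLUMNS = [
    "swimmer_id",
    "group",
    "upper_pre",
    "upper_mid",
    "upper_post",
    "lower_pre",
    "lower_mid",
    "lower_post",
    "delta_upper",
    "delta_lower",
]


def compute_deltas(
    upper_model: CompositeModel, lower_model: CompositeModel, panel: pd.DataFrame
) -> pd.DataFrame:
    """Composite scores at all time points plus Post - Pre change scores.

    Returns one row per swimmer, preserving panel row order.
    """
    out = pd.DataFrame(
        {
            "swimmer_id": panel["swimmer_id"].to_numpy(),
            "group": panel["group"].to_numpy(),
        }
    )
    for model in (upper_model, lower_model):
        for tp in ("pre", "mid", "post"):
            out[f"{model.domain}_{tp}"] = apply_composite(model, panel, tp)
        out[f"delta_{model.domain}"] = out[f"{model.domain}_post"] - out[f"{model.domain}_pre"]
    return out[DELTA_COLUMNS]
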