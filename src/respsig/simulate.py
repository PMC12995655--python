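"""Seeded synthetic cohort generator for a three-arm dry-land training trial.

The generator emulates the cohort structure this pipeline is designed for:
three training arms (maximal strength, plyometric, active control) of
university sprint swimmers measured at Pre, Mid and Post on six land-based
power indicators — bench press average power and medicine-ball throw for the
upper-limb domain; countermovement jump, squat jump, drop jump and standing
long jump for the lower-limb domain — plus sex, years of training and best
50 m freestyle time.

Generative model (per swimmer):

* one latent domain score at Pre per domain, ~ Normal(0, 1);
* a composite-scale change to Post per domain, ~ Normal(mu_g, sigma_g) for the
  swimmer's group (optionally correlated across domains via ``delta_corr``);
  the latent change injected into the indicators is this value times
  sqrt(1 + sigma_noise^2) / sqrt(m) for an m-indicator domain, which is
  exactly the rescaling the baseline-standardized unit-norm PCA projection
  undoes — so the analysis pipeline recovers the configured composite-change
  distribution;
* the Mid latent is Pre plus ``mid_fraction`` of the change (deterministic
  interpolation);
* each indicator carries a stable swimmer-specific offset, ~ Normal(0,
  sigma_noise), constant across time points (a persistent technique /
  anthropometry signature), so the baseline correlation between two
  same-domain indicators is 1 / (1 + sigma_noise^2);
* indicators are mapped to plausible raw scales by fixed affine constants
  (the analysis standardizes these away).

Default change parameters are the group-wise composite-change means/SDs the
pipeline is validated against; default noise SDs are calibrated so the
baseline PC1 variance fractions are 0.957 (upper) and 0.949 (lower).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

GROUPS = ("MSTG", "PTG", "CG")
DOMAINS = ("upper", "lower")
TIMEPOINTS = ("pre", "mid", "post")

UPPER_INDICATORS = ("bench_press", "mb_throw")
LOWER_INDICATORS = ("cmj", "sj", "dj", "slj")
INDICATORS: dict[str, tuple[str, ...]] = {
    "upper": UPPER_INDICATORS,
    "lower": LOWER_INDICATORS,
}

# Raw-scale affine constants (offset, scale): value = offset + scale * z.
# Purely cosmetic realism — bench press power in W, throws/jumps in m or cm.
RAW_SCALE: dict[str, tuple[float, float]] = {
    "bench_press": (300.0, 60.0),
    "mb_throw": (7.0, 1.2),
    "cmj": (35.0, 5.0),
    "sj": (33.0, 4.5),
    "dj": (32.0, 5.0),
    "slj": (230.0, 20.0),
}

# Group-wise composite-change (Post-Pre) mean/SD per domain.
DEFAULT_DELTA_PARAMS: dict[str, dict[str, tuple[float, float]]] = {
    "MSTG": {"upper": (0.962, 0.129), "lower": (0.822, 0.125)},
    "PTG": {"upper": (0.762, 0.218), "lower": (0.758, 0.150)},
    "CG": {"upper": (0.332, 0.058), "lower": (0.388, 0.059)},
}

# Noise SDs calibrated so same-domain baseline correlations are 0.913 (upper)
# and 0.932 (lower): sigma^2 = (1 - r) / r.
DEFAULT_NOISE_SD: dict[str, float] = {
    "upper": float(np.sqrt((1 - 0.913) / 0.913)),
    "lower": float(np.sqrt((1 - 0.932) / 0.932)),
}

# Per-group covariates: (female fraction, age mean/sd, training-years mean/sd,
# best 50 m freestyle mean/sd in seconds).
DEFAULT_COVARIATE_PARAMS: dict[str, dict] = {
    "MSTG": {"p_female": 3 / 9, "age": (20.0, 1.0), "years": (9.1, 1.7), "best_50m": (27.2, 1.6)},
    "PTG": {"p_female": 4 / 9, "age": (20.4, 1.3), "years": (9.2, 1.5), "best_50m": (28.0, 2.0)},
    "CG": {"p_female": 3 / 9, "age": (20.2, 1.0), "years": (8.9, 1.5), "best_50m": (28.5, 1.9)},
}


@dataclass
class SimulationConfig:
    """Configuration of the synthetic cohort generator.

    Parameters
    ----------
    n_per_group
        Swimmers per arm (>= 2).
    group_names
        Ordered arm labels.
    delta_params
        Per group, per domain: (mean, SD) of the composite-scale Post-Pre
        change, in composite units.
    mid_fraction
        Fraction of the final latent change realized at Mid, in [0, 1].
    indicator_noise_sd
        SD of the stable swimmer-specific indicator offset on the
        standardized latent scale; scalar or per-domain mapping.
    delta_corr
        Correlation between the upper- and lower-domain changes within
        swimmer, in [-1, 1].
    covariate_params
        Per group: female fraction and (mean, SD) for age, training years and
        best 50 m time.
    seed
        Master seed for the generator stream.
    """

    n_per_group: int = 9
    group_names: tuple[str, ...] = GROUPS
    delta_params: Mapping[str, Mapping[str, tuple[float, float]]] = field(
        default_factory=lambda: {g: dict(d) for g, d in DEFAULT_DELTA_PARAMS.items()}
    )
    mid_fraction: float = 0.5
    indicator_noise_sd: float | Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_NOISE_SD)
    )
    delta_corr: float = 0.0
    covariate_params: Mapping[str, Mapping] = field(
        default_factory=lambda: {g: dict(d) for g, d in DEFAULT_COVARIATE_PARAMS.items()}
    )
    seed: int = 0

    def noise_sd(self, domain: str) -> float:
        if isinstance(self.indicator_noise_sd, Mapping):
            return float(self.indicator_noise_sd[domain])
        return float(self.indicator_noise_sd)

    def validate(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if len(self.group_names) < 2 or len(set(self.group_names)) != len(self.group_names):
            raise ValueError("group_names must be distinct labels")
        for g in self.group_names:
            if g not in self.delta_params:
                raise ValueError(f"delta_params missing group {g!r}")
            if g not in self.covariate_params:
                raise ValueError(f"covariate_params missing group {g!r}")
            for d in DOMAINS:
                mu, sd = self.delta_params[g][d]
                if not sd > 0:
                    raise ValueError(f"delta_params[{g!r}][{d!r}] SD must be > 0")
        if not 0.0 <= self.mid_fraction <= 1.0:
            raise ValueError("mid_fraction must be in [0, 1]")
        for d in DOMAINS:
            if self.noise_sd(d) < 0:
                raise ValueError("indicator_noise_sd must be >= 0")
        if not -1.0 <= self.delta_corr <= 1.0:
            raise ValueError("delta_corr must be in [-1, 1]")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["group_names"] = list(self.group_names)
        return d


def panel_columns(group_names=GROUPS) -> list[str]:
    """Ordered column schema of a cohort panel CSV."""
    cols = ["swimmer_id", "group", "sex", "age_years", "years_training", "best_50m"]
    for d in DOMAINS:
        for ind in INDICATORS[d]:
            cols.extend(f"{ind}_{tp}" for tp in TIMEPOINTS)
    return cols


def generate_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Generate a seeded synthetic cohort panel.

    Returns a wide-format DataFrame with one row per swimmer: covariates plus
    ``<indicator>_<timepoint>`` columns for all six indicators at Pre, Mid and
    Post. Identical config (including seed) yields a byte-identical panel.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([abs(int(config.seed)), 0x5E1F]))

    rows: list[dict] = []
    sid = 1
    for g in config.group_names:
        n = config.n_per_group
        cov = config.covariate_params[g]

        # sex: fixed counts (sex-stratified allocation), females listed first
        n_f = int(round(float(cov["p_female"]) * n))
        sexes = ["F"] * n_f + ["M"] * (n - n_f)

        mu_u, sd_u = config.delta_params[g]["upper"]
        mu_l, sd_l = config.delta_params[g]["lower"]
        rho = config.delta_corr
        cov_mat = np.array(
            [[sd_u**2, rho * sd_u * sd_l], [rho * sd_u * sd_l, sd_l**2]]
        )
        changes = rng.multivariate_normal([mu_u, mu_l], cov_mat, size=n)

        age = rng.normal(*cov["age"], size=n)
        years = rng.normal(*cov["years"], size=n)
        best = rng.normal(*cov["best_50m"], size=n)

        for i in range(n):
            row = {
                "swimmer_id": f"S{sid:03d}",
                "group": g,
                "sex": sexes[i],
                "age_years": round(float(age[i]), 3),
                "years_training": round(float(years[i]), 3),
                "best_50m": round(float(best[i]), 3),
            }
            for di, d in enumerate(DOMAINS):
                inds = INDICATORS[d]
                m = len(inds)
                sig = config.noise_sd(d)
                # composite-scale change -> latent-scale change
                scale = np.sqrt(1.0 + sig**2) / np.sqrt(m)
                pre = rng.normal()
                delta = float(changes[i, di]) * scale
                latent = {
                    "pre": pre,
                    "mid": pre + config.mid_fraction * delta,
                    "post": pre + delta,
                }
                offsets = rng.normal(0.0, sig, size=m) if sig > 0 else np.zeros(m)
                for j, ind in enumerate(inds):
                    off, sc = RAW_SCALE[ind]
                    for tp in TIMEPOINTS:
                        row[f"{ind}_{tp}"] = off + sc * (latent[tp] + offsets[j])
            rows.append(row)
            sid += 1

    return pd.DataFrame(rows, columns=panel_columns(config.group_names))
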