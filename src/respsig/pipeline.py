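"""Cohort CSV IO, configuration and seeded orchestration of the full analysis.

``run_all`` executes the whole pipeline on a cohort panel (read from CSV or
simulated): baseline composites -> change-score contrasts -> responder
signatures (clustering, stability, group association) -> prediction models,
and renders table analogues (CSV), figures (PNG) and a JSON report. All
stochastic stages draw from deterministic named child streams of one master
seed, so a run is exactly reproducible and stages can be re-run in isolation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import composites, contrasts, predictors, signatures
from ._utils import format_p
from .simulate import INDICATORS, SimulationConfig, generate_cohort, panel_columns

__all__ = ["RunConfig", "RunReport", "read_panel", "write_panel", "run_all"]


class PanelValidationError(ValueError):
    pass


def _required_columns() -> list[str]:
    return panel_columns()


def validate_panel(panel: pd.DataFrame) -> pd.DataFrame:
    """Validate a cohort panel's schema and contents."""
    required = _required_columns()
    missing = [c for c in required if c not in panel.columns]
    extra = [c for c in panel.columns if c not in required]
    problems = []
    if missing:
        problems.append(f"missing columns: {missing}")
    if extra:
        problems.append(f"unexpected columns: {extra}")
    if problems:
        raise PanelValidationError("; ".join(problems))
    dup = panel["swimmer_id"][panel["swimmer_id"].duplicated()].tolist()
    if dup:
        raise PanelValidationError(f"duplicated swimmer_id values: {dup}")
    numeric = [c for c in required if c not in ("swimmer_id", "group", "sex")]
    for c in numeric:
        col = pd.to_numeric(panel[c], errors="coerce")
        bad = panel.index[col.isna()].tolist()
        if bad:
            raise PanelValidationError(f"non-numeric or missing cells in column {c!r}, rows {bad}")
        panel[c] = col
    return panel


def read_panel(path: str | Path) -> pd.DataFrame:
    """Read and validate a cohort panel CSV."""
    panel = pd.read_csv(path)
    return validate_panel(panel)


def write_panel(panel: pd.DataFrame, path: str | Path) -> None:
    panel.to_csv(path, index=False)


@dataclass
class RunConfig:
    """End-to-end run configuration (defaults are the full-scale procedure counts)."""

    input_path: str | None = None
    simulate: bool = False
    sim_config: SimulationConfig | None = None
    seed: int = 0
    n_perm: int = 100_000
    n_boot_ci: int = 20_000
    n_boot_stability: int = 2_000
    n_boot_coef: int = 2_000
    k_range: tuple[int, int] = (2, 4)
    min_cluster_size: int = 5
    out_dir: str | None = None
    figures: bool = True
    run_predictors: bool = True

    def validate(self) -> None:
        for name in ("n_perm", "n_boot_ci", "n_boot_stability", "n_boot_coef"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not (self.simulate or self.input_path):
            raise ValueError("either input_path or simulate must be set")
        if self.k_range[0] < 2 or self.k_range[1] < self.k_range[0]:
            raise ValueError("invalid k_range")


@dataclass
class RunReport:
    """All pipeline artifacts from one seeded run."""

    panel: pd.DataFrame
    upper_model: composites.CompositeModel
    lower_model: composites.CompositeModel
    delta: pd.DataFrame
    descriptives: list[contrasts.DescriptiveRow]
    contrast_results: list[contrasts.ContrastResult]
    solution: signatures.ClusterSolution
    profiles: pd.DataFrame
    stability: signatures.StabilityReport
    association: signatures.AssociationReport
    ridge_upper: predictors.RegressionReport | None
    ridge_lower: predictors.RegressionReport | None
    classifier: predictors.ClassificationReport | None
    config: RunConfig

    def to_json_dict(self) -> dict:
        def rnd(x):
            return None if x is None else float(x)

        sol = self.solution
        d = {
            "provenance": {
                "seed": self.config.seed,
                "n_perm": self.config.n_perm,
                "n_boot_ci": self.config.n_boot_ci,
                "n_boot_stability": self.config.n_boot_stability,
                "n_boot_coef": self.config.n_boot_coef,
                "k_range": list(self.config.k_range),
                "min_cluster_size": self.config.min_cluster_size,
            },
            "composites": {
                m.domain: json.loads(m.to_json()) for m in (self.upper_model, self.lower_model)
            },
            "descriptives": [
                {
                    "endpoint": r.endpoint,
                    "group": r.group,
                    "n": r.n,
                    "mean": r.mean,
                    "sd": r.sd,
                    "ci95": list(r.ci95),
                }
                for r in self.descriptives
            ],
            "contrasts": [
                {
                    "endpoint": r.endpoint,
                    "pair": list(r.pair),
                    "mean_diff": r.mean_diff,
                    "boot_ci95": list(r.boot_ci95),
                    "p_perm": r.p_perm,
                    "p_holm": r.p_holm,
                    "p_holm_rendered": format_p(r.p_holm),
                    "hedges_g": r.hedges_g,
                }
                for r in self.contrast_results
            ],
            "clustering": {
                "selected_k": sol.k,
                "silhouette": sol.silhouette,
                "sizes": list(sol.sizes),
                "labels": [int(v) for v in sol.labels],
                "candidates": [
                    {"k": c.k, "silhouette": c.silhouette, "sizes": list(c.sizes)}
                    for c in sol.candidates
                ],
                "profiles": self.profiles.to_dict(orient="records"),
            },
            "stability": {
                "n_replicates": self.stability.n_replicates,
                "ari_mean": self.stability.ari_mean,
                "ari_sd": self.stability.ari_sd,
                "ari_ci95": list(self.stability.ari_ci95),
                "jaccard": {
                    str(c): {
                        "mean": self.stability.jaccard_mean[c],
                        "sd": self.stability.jaccard_sd[c],
                        "ci95": list(self.stability.jaccard_ci95[c]),
                    }
                    for c in self.stability.jaccard_mean
                },
            },
            "association": {
                "contingency": self.association.contingency.to_dict(),
                "chi2": self.association.chi2,
                "p_perm": self.association.p_perm,
                "p_rendered": format_p(self.association.p_perm),
                "n_perm": self.association.n_perm,
            },
        }
        if self.ridge_upper is not None:
            d["predictors"] = {
                "ridge": {
                    rep.outcome: {
                        "penalty": rep.penalty,
                        "loo_rmse": rep.loo_rmse,
                        "cv_r2": rep.cv_r2,
                        "intercept": rep.intercept,
                        "coefficients": rep.coefficients.round(6).to_dict(orient="index"),
                    }
                    for rep in (self.ridge_upper, self.ridge_lower)
                },
                "logistic": {
                    "penalty": self.classifier.penalty,
                    "loo_accuracy": self.classifier.loo_accuracy,
                    "loo_logloss": self.classifier.loo_logloss,
                    "intercept": self.classifier.intercept,
                    "coefficients": self.classifier.coefficients.round(6).to_dict(orient="index"),
                    "predicted_prob_by_group": {
                        g: rnd(v) for g, v in self.classifier.predicted_prob_by_group.items()
                    },
                    "logodds_contrasts": self.classifier.logodds_contrasts.round(6).to_dict(
                        orient="records"
                    ),
                },
            }
        return d


def run_all(config: RunConfig) -> RunReport:
    """Execute the full pipeline under one master seed."""
    config.validate()

    if config.simulate:
        sim = config.sim_config or SimulationConfig(seed=config.seed)
        panel = generate_cohort(sim)
    else:
        panel = read_panel(config.input_path)

    try:
        upper = composites.fit_baseline_pca(panel, "upper", INDICATORS["upper"])
        lower = composites.fit_baseline_pca(panel, "lower", INDICATORS["lower"])
        delta = composites.compute_deltas(upper, lower, panel)
    except Exception as e:
        raise RuntimeError(f"composites stage failed: {e}") from e

    try:
        desc = [r for ep in contrasts.ENDPOINTS for r in contrasts.describe(delta, ep)]
        con = contrasts.run_contrasts(delta, config.n_perm, config.n_boot_ci, config.seed)
    except Exception as e:
        raise RuntimeError(f"contrasts stage failed: {e}") from e

    try:
        Z, scaler = signatures.standardize_deltas(delta)
        solution = signatures.select_k(Z, config.k_range, config.min_cluster_size, scaler)
        profiles = signatures.cluster_profiles(delta, solution.labels)
        stability = signatures.bootstrap_stability(
            delta, solution, config.n_boot_stability, config.seed
        )
        association = signatures.permutation_chi2(
            delta["group"].to_numpy(), solution.labels, config.n_perm, config.seed
        )
    except Exception as e:
        raise RuntimeError(f"signatures stage failed: {e}") from e

    ridge_u = ridge_l = classifier = None
    if config.run_predictors:
        try:
            design = predictors.build_design(panel, delta, solution.labels)
            ridge_u = predictors.fit_ridge_loo(
                design, "delta_upper", n_boot=config.n_boot_coef, seed=config.seed
            )
            ridge_l = predictors.fit_ridge_loo(
                design, "delta_lower", n_boot=config.n_boot_coef, seed=config.seed
            )
            classifier = predictors.fit_logistic_l2_loo(
                design, n_boot=config.n_boot_coef, seed=config.seed
            )
        except Exception as e:
            raise RuntimeError(f"predictors stage failed: {e}") from e

    report = RunReport(
        panel=panel,
        upper_model=upper,
        lower_model=lower,
        delta=delta,
        descriptives=desc,
        contrast_results=con,
        solution=solution,
        profiles=profiles,
        stability=stability,
        association=association,
        ridge_upper=ridge_u,
        ridge_lower=ridge_l,
        classifier=classifier,
        config=config,
    )
    if config.out_dir:
        write_outputs(report, Path(config.out_dir))
    return report


def _render_p(p: float) -> str:
    return format_p(p)


def write_outputs(report: RunReport, out: Path) -> None:
    """Write table analogues (CSV), the JSON report and figures."""
    out.mkdir(parents=True, exist_ok=True)

    # loadings table
    rows = []
    for model in (report.upper_model, report.lower_model):
        for ind, w in zip(model.indicators, model.loadings):
            rows.append(
                {
                    "construct": f"{model.domain}-limb power (PC1)",
                    "indicator": f"{ind} (Pre)",
                    "loading_pc1": round(float(w), 3),
                    "variance_explained": round(model.variance_explained, 3),
                }
            )
    pd.DataFrame(rows).to_csv(out / "table_loadings.csv", index=False)

    desc = contrasts.descriptives_frame(report.descriptives).round(3)
    desc.to_csv(out / "table_descriptives.csv", index=False)

    con = contrasts.contrasts_frame(report.contrast_results)
    con["p_holm"] = [_render_p(p) for p in con["p_holm"]]
    con["p_perm"] = [_render_p(p) for p in con["p_perm"]]
    con.round(3).to_csv(out / "table_contrasts.csv", index=False)

    pd.DataFrame(
        [
            {
                "k": c.k,
                "silhouette": round(c.silhouette, 3),
                "min_cluster_size": c.min_size,
                "cluster_sizes": "; ".join(str(s) for s in c.sizes),
            }
            for c in report.solution.candidates
        ]
    ).to_csv(out / "table_selection.csv", index=False)

    report.profiles.round(3).to_csv(out / "table_profiles.csv", index=False)

    pd.DataFrame(
        [
            {
                "cluster": c,
                "cluster_size": int(np.sum(report.solution.labels == c)),
                "mean_jaccard": round(report.stability.jaccard_mean[c], 3),
                "sd_jaccard": round(report.stability.jaccard_sd[c], 3),
                "ci95_lower": round(report.stability.jaccard_ci95[c][0], 3),
                "ci95_upper": round(report.stability.jaccard_ci95[c][1], 3),
            }
            for c in report.stability.jaccard_mean
        ]
    ).to_csv(out / "table_jaccard.csv", index=False)

    report.association.contingency.to_csv(out / "table_contingency.csv")

    write_panel(report.panel, out / "panel.csv")
    report.delta.round(6).to_csv(out / "delta_table.csv", index=False)

    with open(out / "report.json", "w") as fh:
        json.dump(report.to_json_dict(), fh, indent=2)

    if report.config.figures:
        _write_figures(report, out)


def _write_figures(report: RunReport, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    # change-space scatter with cluster labels
    fig, ax = plt.subplots(figsize=(5, 4))
    labels = np.asarray(report.solution.labels)
    for c in np.unique(labels):
        sub = report.delta.loc[labels == c]
        ax.scatter(sub["delta_upper"], sub["delta_lower"], label=f"cluster {c}", alpha=0.8)
    ax.set_xlabel("ΔUpper (Post-Pre, composite units)")
    ax.set_ylabel("ΔLower (Post-Pre, composite units)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out / "fig_change_space.png", dpi=150)
    plt.close(fig)

    # silhouette by k
    fig, ax = plt.subplots(figsize=(4, 3))
    ks = [c.k for c in report.solution.candidates]
    sils = [c.silhouette for c in report.solution.candidates]
    ax.plot(ks, sils, marker="o")
    ax.set_xticks(ks)
    ax.set_xlabel("k")
    ax.set_ylabel("silhouette")
    fig.tight_layout()
    fig.savefig(out / "fig_silhouette.png", dpi=150)
    plt.close(fig)

    # ARI bootstrap distribution
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.hist(report.stability.ari_distribution, bins=30)
    ax.set_xlabel("adjusted Rand index")
    ax.set_ylabel("bootstrap replicates")
    fig.tight_layout()
    fig.savefig(out / "fig_ari_distribution.png", dpi=150)
    plt.close(fig)
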