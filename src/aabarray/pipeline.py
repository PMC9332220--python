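"""End-to-end orchestration: simulate -> call -> featurize -> fit -> evaluate.

A single config (YAML-friendly nested dict) drives every stage with one
seed; reruns with the same config produce byte-identical manifests
(figures excluded). Stage outputs are plain text: TSV tables and JSON.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .arrays import cohort_frame, write_cohort, write_spot_table
from .evaluation import marker_table, outer_cv, panel_evaluate
from .features import build_design
from .seropositivity import call_cohort, immunoreactivity_profile
from .simulate import ConfigError, SimulationConfig, simulate_study


@dataclass
class PipelineConfig:
    """Per-stage settings; defaults reproduce the reference study design."""

    seed: int = 0
    simulation: dict[str, Any] = field(default_factory=dict)
    radius: float | None = None  # background radius; None = half block pitch
    power: float = 2.0  # IDW exponent
    multiplier: float = 5.0  # SDs above background for a call
    trim_lower_pct: float = 5.0
    trim_upper_pct: float = 95.0
    n_lambdas: int = 50
    lambda_min_ratio: float = 0.01
    inner_folds: int = 5
    rule: str = "1se"
    outer_folds: int = 10
    specificity_gate_pct: float = 90.0
    make_figures: bool = True

    def validate(self) -> None:
        if self.multiplier <= 0:
            raise ConfigError("multiplier must be positive")
        if not (0.0 < self.specificity_gate_pct < 100.0):
            raise ConfigError("specificity gate must lie in (0, 100)")
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ConfigError("fold counts must be at least 2")
        if self.rule not in ("min", "1se"):
            raise ConfigError("rule must be 'min' or '1se'")
        self.simulation_config()  # validates the nested block

    def simulation_config(self) -> SimulationConfig:
        sim = SimulationConfig(**{"seed": self.seed, **self.simulation})
        sim.validate()
        return sim

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_all(config: PipelineConfig, outdir: str | Path, write_spots: bool = False) -> Path:
    """Run every stage and write a report directory.

    Artifacts: cohort CSV, ground-truth JSON, call matrix TSV, dropped
    features TSV, marker coefficients and selection JSON, pairwise-AUC
    and confusion TSVs, marker table TSV, panel JSON, immunoreactivity
    profile TSV, run manifest JSON, and (best effort) figures.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "package_version": __version__,
        "stages": {},
    }

    sim = config.simulation_config()
    layout, records, truth, tables = simulate_study(sim)
    write_cohort(records, outdir / "cohort.csv")
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(
            {
                "discriminative": {c: dict(m) for c, m in truth.discriminative.items()},
                "seropositive": {s: sorted(v) for s, v in sorted(truth.seropositive.items())},
            },
            fh,
            indent=1,
            sort_keys=True,
        )
    if write_spots:
        spot_dir = outdir / "spots"
        spot_dir.mkdir(exist_ok=True)
        for t in tables:
            write_spot_table(t, layout, spot_dir / f"{t.sample_id}.tsv")
    manifest["stages"]["simulate"] = {
        "n_samples": len(records),
        "n_spots": len(layout.spots),
        "n_antigens": len(layout.antigens),
    }

    calls = call_cohort(
        tables, layout, radius=config.radius, power=config.power, multiplier=config.multiplier
    )
    long = (
        calls.fold_change.stack()
        .rename("fold_change")
        .to_frame()
        .join(calls.threshold.stack().rename("threshold"))
        .join(calls.calls.stack().rename("call"))
        .reset_index()
        .rename(columns={"level_1": "antigen"})
    )
    long.to_csv(outdir / "calls.tsv", sep="\t", index=False)
    cohort_df = cohort_frame(records)
    profile = immunoreactivity_profile(calls, cohort_df)
    profile.summary.to_csv(outdir / "immunoreactivity_summary.tsv", sep="\t")
    profile.dunn.to_csv(outdir / "immunoreactivity_dunn.tsv", sep="\t", index=False)
    manifest["stages"]["call"] = {
        "n_samples": int(len(calls.calls)),
        "kruskal_p": profile.kruskal_p,
    }

    design = build_design(
        calls, cohort_df, lower_pct=config.trim_lower_pct, upper_pct=config.trim_upper_pct
    )
    pd.Series(design.dropped_antigens, name="reason").rename_axis("antigen").to_csv(
        outdir / "dropped_features.tsv", sep="\t"
    )
    manifest["stages"]["featurize"] = {
        "n_retained_samples": int(len(design.samples)),
        "n_retained_antigens": int(design.X.shape[1]),
        "trim_removed": design.trim_removed,
    }

    result = outer_cv(
        design,
        k=config.outer_folds,
        seed=config.seed,
        n_lambdas=config.n_lambdas,
        lambda_min_ratio=config.lambda_min_ratio,
        cv=config.inner_folds,
        rule=config.rule,
    )
    est = result.estimator
    antigens = list(design.X.columns)
    with open(outdir / "fit.json", "w") as fh:
        json.dump(
            {
                "lambda": est.lambda_,
                "lambda_path": est.lambda_path_.tolist(),
                "cv_deviance": est.cv_deviance_.tolist(),
                "classes": est.classes_.tolist(),
                "selected_markers": result.markers,
                "coefficients": {
                    cls: dict(zip(antigens + ["age_z", "sex"], est.coef_[k].tolist()))
                    for k, cls in enumerate(est.classes_)
                },
            },
            fh,
            indent=1,
            sort_keys=True,
        )
    result.apparent_auc.to_csv(outdir / "pairwise_auc_apparent.tsv", sep="\t")
    result.cv_auc.to_csv(outdir / "pairwise_auc_cv.tsv", sep="\t")
    result.apparent_confusion.to_csv(outdir / "confusion_apparent.tsv", sep="\t")
    result.cv_confusion.to_csv(outdir / "confusion_cv.tsv", sep="\t")
    with open(outdir / "m_values.json", "w") as fh:
        json.dump(
            {"apparent_m": result.apparent_m, "cv_m": result.cv_m, "outer_folds": result.n_folds},
            fh,
            indent=1,
            sort_keys=True,
        )
    manifest["stages"]["fit"] = {
        "n_selected_markers": len(result.markers),
        "selected_markers": result.markers,
        "lambda": est.lambda_,
    }

    markers = result.markers
    if markers:
        tbl = marker_table(design.X, design.y, markers)
        tbl.to_csv(outdir / "marker_table.tsv", sep="\t")
        panel = panel_evaluate(
            design.X,
            design.y,
            markers,
            specificity_gate_pct=config.specificity_gate_pct,
            table=tbl,
        )
        with open(outdir / "panel.json", "w") as fh:
            json.dump(asdict(panel), fh, indent=1, sort_keys=True)
        manifest["stages"]["evaluate"] = {
            "panel_members": panel.members,
            "panel_sensitivity_pct": panel.sensitivity_pct,
            "panel_specificity_pct": panel.specificity_pct,
        }
    else:
        manifest["stages"]["evaluate"] = {"panel_members": [], "note": "no markers selected"}

    if config.make_figures:
        try:
            from .figures import plot_immunoreactivity, plot_marker_heatmap

            plot_immunoreactivity(calls, cohort_df, outdir / "fig_immunoreactivity.png")
            if markers:
                plot_marker_heatmap(design, markers, outdir / "fig_marker_heatmap.png")
        except Exception as exc:  # pragma: no cover - figures are best effort
            manifest["figures_error"] = str(exc)

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return outdir
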