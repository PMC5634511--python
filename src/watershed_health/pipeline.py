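"""End-to-end orchestration: generate -> route -> assemble -> fit -> effects.

One root seed and one config drive the whole run; every output is a plain
CSV/JSON/ASCII-grid file, and the resolved config is written next to the
outputs so a run is reproducible from its own directory.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import covariate_assembly, hydro_routing, marginal_effects, model_fit, synthetic_data
from .errors import ConfigurationError
from .gridio import write_landscape

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunReport", "validate_config", "run_pipeline"]

KNOWN_SUBGROUPS = ("urban", "water", "human_activity")


@dataclass
class RunConfig:
    """Settings for a full pipeline run."""

    seed: int = 0
    landscape: synthetic_data.LandscapeConfig = field(default_factory=synthetic_data.LandscapeConfig)
    survey: synthetic_data.GeneratingParams = field(default_factory=synthetic_data.GeneratingParams)
    window_m: float = 10_000.0  # aggregation window side, meters
    subgroups: tuple[str, ...] = KNOWN_SUBGROUPS
    quartile_variant: bool = True

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["subgroups"] = list(self.subgroups)
        d["survey"]["age_range"] = list(self.survey.age_range)
        d["survey"]["interactions"] = [
            [list(cols), coef] for cols, coef in self.survey.interactions
        ]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "landscape" in d:
            d["landscape"] = synthetic_data.LandscapeConfig(**d["landscape"])
        if "survey" in d:
            sd = dict(d["survey"])
            if "age_range" in sd:
                sd["age_range"] = tuple(sd["age_range"])
            if "interactions" in sd:
                sd["interactions"] = tuple(
                    (tuple(cols), float(coef)) for cols, coef in sd["interactions"]
                )
            d["survey"] = synthetic_data.GeneratingParams(**sd)
        if "subgroups" in d:
            d["subgroups"] = tuple(d["subgroups"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class RunReport:
    out_dir: str
    paths: dict[str, str]
    summary: dict


def validate_config(config: RunConfig) -> list[str]:
    """All violations in one pass; empty list means the config is valid."""
    findings = []
    if not isinstance(config.seed, int) or config.seed < 0:
        findings.append(f"seed must be a nonnegative integer, got {config.seed!r}")
    findings.extend(config.landscape.validate())
    findings.extend(config.survey.validate())
    if config.window_m <= 0:
        findings.append(f"window_m must be positive, got {config.window_m}")
    unknown = set(config.subgroups) - set(KNOWN_SUBGROUPS)
    if unknown:
        findings.append(f"unknown subgroups {sorted(unknown)}; known: {KNOWN_SUBGROUPS}")
    n_cells = config.landscape.n_rows * config.landscape.n_cols
    if config.survey.n_clusters > n_cells:
        findings.append(
            f"n_clusters={config.survey.n_clusters} exceeds the {n_cells}-cell landscape"
        )
    return findings


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            logger.info("stage %s: starting", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            logger.info("stage %s: done", name)
            return out

        return wrapper

    return deco


def _clusters_frame(clusters: list[synthetic_data.ClusterRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cluster_id": [c.cluster_id for c in clusters],
            "true_x": [c.true_coords[0] for c in clusters],
            "true_y": [c.true_coords[1] for c in clusters],
            "reported_x": [c.reported_coords[0] for c in clusters],
            "reported_y": [c.reported_coords[1] for c in clusters],
            "urban": [int(c.urban) for c in clusters],
            "row": [c.row for c in clusters],
            "col": [c.col for c in clusters],
        }
    )


def run_pipeline(config: RunConfig, out_dir) -> RunReport:
    """Execute all stages in order and write every table under ``out_dir``.

    Identical config and seed produce byte-identical outputs. Raises with
    the failing stage's name on any error.
    """
    findings = validate_config(config)
    if findings:
        raise ConfigurationError("; ".join(findings))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    summary: dict = {"seed": config.seed}
    seed = config.seed

    @_stage("generate")
    def do_generate():
        grid = synthetic_data.generate_landscape(config.landscape, seed)
        clusters = synthetic_data.place_clusters(
            grid, config.survey.n_clusters, config.survey.urban_fraction, seed
        )
        extent = (grid.n_cols * grid.cell_size, grid.n_rows * grid.cell_size)
        clusters = synthetic_data.displace_all(clusters, seed, bounds=extent)
        write_landscape(grid, out / "landscape")
        _clusters_frame(clusters).to_csv(out / "clusters.csv", index=False)
        paths["landscape"] = str(out / "landscape")
        paths["clusters"] = str(out / "clusters.csv")
        return grid, clusters

    grid, clusters = do_generate()
    summary["n_clusters"] = len(clusters)
    summary["n_urban_clusters"] = sum(c.urban for c in clusters)

    @_stage("route")
    def do_route():
        network = hydro_routing.derive_flow_network(grid)
        indices = hydro_routing.route_indices(grid, network)
        table = hydro_routing.cluster_index_table(indices, clusters, grid.cell_size, config.window_m)
        table.to_csv(out / "cluster_indices.csv")
        paths["cluster_indices"] = str(out / "cluster_indices.csv")
        return table

    index_table = do_route()

    @_stage("climate")
    def do_climate():
        climatology, survey_month = synthetic_data.generate_cluster_climate(clusters, grid, seed)
        climate = covariate_assembly.standardize_climate(climatology, survey_month)
        env = index_table[["human_index", "tree_index"]].join(climate)
        env.to_csv(out / "cluster_environment.csv")
        paths["cluster_environment"] = str(out / "cluster_environment.csv")
        return env

    environment = do_climate()

    @_stage("survey")
    def do_survey():
        survey = synthetic_data.simulate_survey(clusters, config.survey, environment, seed)
        survey.to_csv(out / "survey.csv", index=False)
        paths["survey"] = str(out / "survey.csv")
        return survey

    survey = do_survey()
    summary["n_children"] = len(survey)

    @_stage("assemble")
    def do_assemble():
        table = covariate_assembly.build_table(survey, environment)
        table.to_csv(out / "analysis_table.csv", index=False)
        paths["analysis_table"] = str(out / "analysis_table.csv")
        return table

    table = do_assemble()
    summary["n_rows_analysis"] = len(table)

    fits: dict[str, model_fit.FitResult] = {}

    @_stage("fit")
    def do_fit():
        fits["full"] = model_fit.fit_three_level_logit(table)
        if "urban" in config.subgroups:
            pair = model_fit.subgroup_fit(table, by="urban")
            fits["rural"], fits["urban"] = pair["0"], pair["1"]
        rural = table.loc[table["urban"] == 0]
        if "water" in config.subgroups:
            pair = model_fit.subgroup_fit(rural, by="improved_water")
            fits["rural_unimproved_water"], fits["rural_improved_water"] = pair["0"], pair["1"]
        if "human_activity" in config.subgroups:
            pair = model_fit.subgroup_fit(rural, by=model_fit.split_high_low(rural, "human_index"))
            fits["rural_low_human_activity"], fits["rural_high_human_activity"] = (
                pair["low"],
                pair["high"],
            )
        if config.quartile_variant:
            fits["quartile_variant"] = model_fit.quartile_variant_fit(table)
        for name, fit in fits.items():
            fit.to_json(out / f"fit_{name}.json")
            fit.odds_ratios().to_csv(out / f"odds_ratios_{name}.csv")
            paths[f"fit_{name}"] = str(out / f"fit_{name}.json")

    do_fit()
    icc_cluster, icc_household = model_fit.icc(fits["full"])
    summary["fits"] = {
        name: {
            "loglik": fit.loglik,
            "sigma_cluster": fit.sigma_cluster,
            "sigma_household": fit.sigma_household,
            "n_children": fit.n_children,
            "converged": fit.converged,
        }
        for name, fit in fits.items()
    }
    summary["icc_cluster"] = icc_cluster
    summary["icc_household_cumulative"] = icc_household
    summary["prevalence"] = float(table["diarrhea"].mean())

    @_stage("effects")
    def do_effects():
        for name in ("full", "rural", "urban"):
            if name not in fits:
                continue
            effects = marginal_effects.policy_table(fits[name])
            marginal_effects.effects_frame(effects).to_csv(out / f"policy_{name}.csv", index=False)
            marginal_effects.effects_to_json(effects, out / f"policy_{name}.json")
            paths[f"policy_{name}"] = str(out / f"policy_{name}.json")

    do_effects()

    config.to_yaml(out / "resolved_config.yaml")
    paths["resolved_config"] = str(out / "resolved_config.yaml")
    with open(out / "report.json", "w") as fh:
        json.dump({"paths": paths, "summary": summary}, fh, indent=2, sort_keys=True)
    paths["report"] = str(out / "report.json")
    return RunReport(out_dir=str(out), paths=paths, summary=summary)
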