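"""End-to-end runs: simulate, community network, gene network.

Each run writes its artifacts plus a provenance file (config, seed,
package version) into an output directory; rerunning with the same config
and seed reproduces the files byte for byte. These functions are the
library face of the command-line interface and of the example scripts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .knockout import (default_scenarios, results_to_frame,
                       run_knockout_experiment, scenario_from_spec)
from .model import fit_mle
from .network import SearchOptions, build_blacklist, hill_climb
from .preprocess import (assemble_model_matrix, drop_zero_variance,
                         minmax_normalize, select_core_taxa)
from .synthetic import (ScenarioConfig, build_template_sem,
                        simulate_community, simulate_expression)
from .table import FeatureTable
from .validation import (CVOptions, CVResult, community_reconstruction_report,
                         loo_cv, null_model_predict)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Validated configuration shared by all pipeline commands."""

    scenario: ScenarioConfig = field(default_factory=ScenarioConfig)
    inputs: dict = field(default_factory=dict)   # name -> path
    min_abundance: float = 0.005
    min_occurrence: float = 0.5
    scope: str = "both"
    allow_within_tier: bool = True
    max_iter: int = 500
    restarts: int = 0
    prediction_method: str = "parents"
    knockout_mode: str = "retrain"
    extra_scenarios: tuple = ()
    output_var: str = "ch4_production"

    def __post_init__(self) -> None:
        for name in ("min_abundance", "min_occurrence"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.scope not in ("both", "per_table"):
            raise ValueError(f"unknown scope {self.scope!r}")
        if self.prediction_method not in ("parents", "joint"):
            raise ValueError(
                f"unknown prediction method {self.prediction_method!r}")
        if self.knockout_mode not in ("retrain", "evidence_only"):
            raise ValueError(f"unknown knockout mode {self.knockout_mode!r}")
        if self.max_iter < 1 or self.restarts < 0:
            raise ValueError("max_iter must be >= 1 and restarts >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        raw = dict(raw)
        if "scenario" in raw and isinstance(raw["scenario"], dict):
            raw["scenario"] = ScenarioConfig(**raw["scenario"])
        if "extra_scenarios" in raw:
            raw["extra_scenarios"] = tuple(raw["extra_scenarios"])
        return cls(**raw)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["extra_scenarios"] = list(self.extra_scenarios)
        return out

    def replace(self, **kwargs) -> "PipelineConfig":
        return dataclasses.replace(self, **kwargs)

    def search_options(self) -> SearchOptions:
        return SearchOptions(max_iter=self.max_iter, restarts=self.restarts,
                             seed=self.scenario.seed)

    def cv_options(self, keep_models: bool = False) -> CVOptions:
        return CVOptions(search=self.search_options(),
                         prediction_method=self.prediction_method,
                         keep_models=keep_models)


def _write_provenance(out_dir: Path, config: PipelineConfig,
                      command: str, extras: dict | None = None) -> None:
    payload = {
        "command": command,
        "artifact_version": __version__,
        "seed": config.scenario.seed,
        "config": config.to_dict(),
        "score": "gaussian_bic_halflog_n_penalty",
        "prediction_method": config.prediction_method,
        "knockout_mode": config.knockout_mode,
    }
    payload.update(extras or {})
    (out_dir / "provenance.json").write_text(
        json.dumps(payload, indent=2, sort_keys=True, default=str) + "\n")
    (out_dir / "run_config.yaml").write_text(
        yaml.safe_dump(config.to_dict(), sort_keys=True))


def _write_cv(cv: CVResult, path: Path) -> None:
    out = cv.predicted.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", float_format="%.17g")


def run_simulate(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Write synthetic dna/rna/environment/expression tables and the SEM."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dna, rna, environment = simulate_community(config.scenario)
    sem = build_template_sem(config.scenario)
    expression = simulate_expression(sem, config.scenario.n_samples,
                                     config.scenario.seed)
    files = {}
    for name, table in (("dna", dna), ("rna", rna),
                        ("environment", environment),
                        ("expression", expression)):
        vpath, mpath = out / f"{name}.tsv", out / f"{name}_metadata.tsv"
        table.write(vpath, mpath)
        files[name] = str(vpath)
        files[f"{name}_metadata"] = str(mpath)
    sem.write(out / "sem_edges.tsv", out / "sem_nodes.tsv")
    files["sem_edges"] = str(out / "sem_edges.tsv")
    files["sem_nodes"] = str(out / "sem_nodes.tsv")
    _write_provenance(out, config, "simulate", {"files": sorted(files)})
    return files


def _load_input(config: PipelineConfig, name: str) -> FeatureTable:
    inputs = config.inputs
    if name not in inputs:
        raise ValueError(f"config lacks input path {name!r}")
    return FeatureTable.read(inputs[name], inputs.get(f"{name}_metadata"))


def run_community_network(config: PipelineConfig, out_dir: str | Path,
                          tables: tuple[FeatureTable, FeatureTable,
                                        FeatureTable] | None = None) -> dict:
    """Learn and validate the taxa + environment network.

    Stages: core-taxon selection (DNA+RNA) → model matrix of core taxon
    activities and environmental variables → min-max normalization → tier
    blacklist → hill climbing → ML parameters → LOO-CV and mean-null
    comparison → network and metrics files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if tables is None:
        tables = (_load_input(config, "dna"), _load_input(config, "rna"),
                  _load_input(config, "environment"))
    dna, rna, environment = tables
    core = select_core_taxa(dna, rna, config.min_abundance,
                            config.min_occurrence, config.scope)
    if not core:
        raise ValueError(
            "core population is empty; relax min_abundance/min_occurrence")
    matrix = assemble_model_matrix([rna.select(core), environment])
    matrix, dropped = drop_zero_variance(matrix)
    normalized, params = minmax_normalize(matrix)
    constraints = build_blacklist(dict(normalized.metadata["tier"]),
                                  config.allow_within_tier)
    dag = hill_climb(normalized, constraints, config.search_options())
    bn = fit_mle(dag, normalized)
    taxa = [v for v in core if v in normalized.variables]
    env_vars = [v for v in normalized.variables if v not in set(taxa)]
    cv = loo_cv(normalized, constraints, taxa + env_vars,
                config.cv_options())
    null = null_model_predict(normalized, taxa + env_vars)
    community_metrics = community_reconstruction_report(
        _subset(cv, taxa), _subset(null, taxa))
    performance_metrics = community_reconstruction_report(
        _subset(cv, env_vars), _subset(null, env_vars))

    bn.write(out / "network_edges.tsv", out / "network_nodes.tsv",
             normalized.metadata)
    bn.write_graphml(out / "network.graphml", normalized.metadata)
    bn.write_dot(out / "network.dot")
    _write_cv(cv, out / "cv_predictions.tsv")
    _write_cv(null, out / "null_predictions.tsv")
    report = pd.concat([
        community_metrics.to_frame().assign(block="community"),
        performance_metrics.to_frame().assign(block="performance"),
    ], ignore_index=True)
    report.to_csv(out / "metrics.tsv", sep="\t", index=False,
                  float_format="%.17g")
    summary = {
        "core_taxa": core,
        "dropped_constant": dropped,
        "community": {
            "bray_curtis_mean": community_metrics.bray_curtis_mean,
            "null_bray_curtis_mean":
                community_metrics.null_bray_curtis_mean,
        },
        "performance": performance_metrics.aggregations,
        "prediction_method": config.prediction_method,
    }
    (out / "metrics.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n")
    _write_provenance(out, config, "community_network")
    return summary


def run_gene_network(config: PipelineConfig, out_dir: str | Path,
                     expression: FeatureTable | None = None) -> pd.DataFrame:
    """Learn the gene network and run the knockout experiment.

    Stages: min-max normalization → tier blacklist (fermenter/Geobacter →
    methanogen → CH₄) → knockout scenarios {complete, delta_IHT,
    delta_DIET} plus any configured extras → per-scenario networks and the
    knockout results table.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if expression is None:
        expression = _load_input(config, "expression")
    output_var = config.output_var
    if output_var not in expression.variables:
        raise ValueError(f"output variable {output_var!r} missing")
    matrix, dropped = drop_zero_variance(expression)
    normalized, _ = minmax_normalize(matrix)
    constraints = build_blacklist(dict(normalized.metadata["tier"]),
                                  config.allow_within_tier)
    scenarios = default_scenarios(normalized.metadata)
    for spec in config.extra_scenarios:
        scenarios.append(scenario_from_spec(dict(spec), normalized.metadata))
    results = run_knockout_experiment(
        normalized, constraints, scenarios, output_var,
        mode=config.knockout_mode, options=config.cv_options())

    from .knockout import silence_genes

    for scenario in scenarios:
        silenced, _ = drop_zero_variance(
            silence_genes(normalized, scenario.silenced))
        dag = hill_climb(silenced, constraints.restrict(silenced.variables),
                         config.search_options())
        bn = fit_mle(dag, silenced)
        bn.write(out / f"network_{scenario.name}_edges.tsv",
                 out / f"network_{scenario.name}_nodes.tsv",
                 normalized.metadata)
        bn.write_dot(out / f"network_{scenario.name}.dot")
    frame = results_to_frame(results)
    frame.to_csv(out / "knockout_results.tsv", sep="\t", index=False,
                 float_format="%.17g")
    (out / "knockout_results.json").write_text(
        frame.to_json(orient="records", indent=2) + "\n")
    logger.info("score=gaussian BIC, prediction=%s, knockout mode=%s",
                config.prediction_method, config.knockout_mode)
    _write_provenance(out, config, "gene_network",
                      {"dropped_constant": dropped})
    return frame


def _subset(cv: CVResult, columns: list[str]) -> CVResult:
    return CVResult(observed=cv.observed[columns],
                    predicted=cv.predicted[columns],
                    provenance=cv.provenance)
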