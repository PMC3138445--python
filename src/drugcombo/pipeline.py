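"""End-to-end pipeline: simulate → fit → score → select → infer interactions.

A :class:`RunConfig` (usually parsed from YAML) fully determines a run: the
panel, the data source (synthetic scenario or an input table), the model
family and hyperparameters, performance parameters, selection parameters
and all seeds.  Every stage writes plain-text artifacts into the output
directory together with a manifest of seeds and versions, so any stage can
be re-run in isolation and two runs of the same config are byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .design import DrugPanel, enumerate_grid, sample_training_design
from .errors import ConfigError
from .interactions import (
    best_subset_regression,
    build_interaction_design,
    classify_interactions,
    select_model_size,
    term_names,
)
from .io import (
    read_response_table,
    write_design,
    write_json,
    write_performance_map,
    write_response_table,
)
from .models import InputScaler, ModelSpec, fit_response_model
from .performance import PerformanceParams, performance_map
from .selection import kmeans_scores, mixture_analysis, rank_combinations
from .simulate import (
    default_two_celltype_scenario,
    merge_tables,
    simulate_measurements,
)


@dataclass
class RunConfig:
    """Everything needed to reproduce one pipeline run."""

    panel: DrugPanel | None = None          # None → the default 4-drug panel
    input_table: str | None = None          # CSV path; None → simulate the scenario
    cell_nc: str = "normal-like"
    cell_cc: str = "cancer-like"
    sigma: float = 0.05
    n_train: int = 148
    family: str = "MLP_1x4"
    restarts: int = 5
    seed: int = 0
    k_clusters: int = 20
    top_k: int = 10
    tau: float = 0.01
    interactions_on: str = "train"          # "train" or "full"
    run_interactions: bool = True
    performance: PerformanceParams = field(default_factory=PerformanceParams)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        if "panel" in doc:
            p = doc["panel"]
            kwargs["panel"] = DrugPanel(
                drugs=tuple(p["drugs"]),
                levels=tuple(tuple(float(v) for v in p["levels"][d]) for d in p["drugs"]),
            )
        if "performance" in doc:
            kwargs["performance"] = PerformanceParams(**doc["performance"])
        for key in (
            "input_table", "cell_nc", "cell_cc", "sigma", "n_train", "family",
            "restarts", "seed", "k_clusters", "top_k", "tau",
            "interactions_on", "run_interactions",
        ):
            if key in doc:
                kwargs[key] = doc[key]
        return cls(**kwargs)


def _validate(config: RunConfig, panel: DrugPanel) -> None:
    if config.run_interactions and panel.n_drugs != 4:
        raise ConfigError(
            f"interaction stage requires a 4-drug panel, config panel has {panel.n_drugs}"
        )
    if not 1 <= config.n_train <= panel.grid_size:
        raise ConfigError(f"n_train {config.n_train} outside 1..{panel.grid_size}")
    if config.k_clusters > panel.grid_size:
        raise ConfigError("k_clusters exceeds grid size")


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Execute every stage and write artifacts; returns the manifest dict."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed, "stages": []}

    # --- data ---------------------------------------------------------------
    if config.input_table is not None:
        if config.panel is None:
            raise ConfigError("an input table requires an explicit panel")
        panel = config.panel
        _validate(config, panel)
        grid = enumerate_grid(panel)
        table = read_response_table(config.input_table, panel)
        manifest["data"] = {"source": str(config.input_table)}
    else:
        cancer, normal = default_two_celltype_scenario()
        panel = config.panel or cancer.panel
        if panel != cancer.panel:
            raise ConfigError("the built-in scenario is defined on the default 4-drug panel")
        _validate(config, panel)
        grid = enumerate_grid(panel)
        table = merge_tables(
            simulate_measurements(cancer, grid, config.sigma, seed=config.seed),
            simulate_measurements(normal, grid, config.sigma, seed=config.seed + 1),
        )
        manifest["data"] = {"source": "synthetic-scenario", "sigma": config.sigma}
    for cell in (config.cell_nc, config.cell_cc):
        if cell not in table.cell_lines:
            raise ConfigError(f"cell line {cell!r} not in table columns {table.cell_lines}")
    write_response_table(table, out / "table.csv")
    manifest["stages"].append("data")

    # --- training design and models -----------------------------------------
    full_grid_table = len(table) == len(grid) and np.array_equal(table.conc, grid.conc)
    if full_grid_table:
        design = sample_training_design(grid, config.n_train, config.seed)
        train_rows = design.grid_indices
        write_design(design, grid, out / "design.csv")
    else:
        train_rows = np.arange(len(table))
    scaler = InputScaler.from_panel(panel)
    models = {}
    for i, cell in enumerate((config.cell_nc, config.cell_cc)):
        spec = ModelSpec(family=config.family, restarts=config.restarts, seed=config.seed + 10 + i)
        m = fit_response_model(
            table.conc[train_rows], table.responses[cell][train_rows], spec, scaler
        )
        models[cell] = m
        (out / f"model_{cell}.json").write_text(m.to_json())
    manifest["stages"].append("fit")
    manifest["train_rows"] = int(len(train_rows))

    # --- performance map, ranking, clustering, mixtures ----------------------
    pmap = performance_map(models[config.cell_nc], models[config.cell_cc], grid, config.performance)
    write_performance_map(pmap, out / "performance_map.csv")

    ranked = rank_combinations(pmap, config.top_k)
    pd.DataFrame(
        [list(c) + [s] for c, s in ranked],
        columns=list(panel.drugs) + ["score"],
    ).to_csv(out / "ranking.csv", index=False, float_format="%.12g")

    clusters = kmeans_scores(pmap.score, config.k_clusters, seed=config.seed)
    pd.DataFrame({"row": np.arange(len(pmap)), "cluster": clusters.assignment}).to_csv(
        out / "clusters.csv", index=False
    )

    report = mixture_analysis(pmap)
    pd.DataFrame(
        [
            {
                "mixture": "+".join(panel.drugs[d] for d in e.drugs),
                "n_drugs": len(e.drugs),
                "best_score": e.best_score,
                "worst_score": e.worst_score,
                "best_predicted_nc": e.best_predicted_nc,
                "best_predicted_cc": e.best_predicted_cc,
                **{panel.drugs[i]: e.best_combination[i] for i in range(panel.n_drugs)},
            }
            for e in report.entries
        ]
    ).to_csv(out / "mixtures.csv", index=False, float_format="%.12g")
    manifest["stages"] += ["performance", "rank", "cluster", "mixtures"]

    # --- interaction inference ----------------------------------------------
    if config.run_interactions:
        names = term_names(panel.drugs)
        fit_table = table if config.interactions_on == "full" else table.subset(train_rows)
        selected = {}
        for cell in (config.cell_cc, config.cell_nc):
            X, y = build_interaction_design(fit_table, cell, scaler)
            result = best_subset_regression(X, y)
            size = select_model_size(result, tau=config.tau)
            selected[cell] = result.selected_terms(size)
            pd.DataFrame(
                [
                    {
                        "size": s,
                        "rss": result.rss[s],
                        "terms": ";".join(names[j] for j in result.subsets[s]),
                        "coefs": ";".join(f"{c:.6g}" for c in result.coefs[s][1:]),
                    }
                    for s in sorted(result.rss)
                ]
            ).to_csv(out / f"interactions_{cell}.csv", index=False)
            manifest[f"selected_size_{cell}"] = size
        cls = classify_interactions(selected[config.cell_cc], selected[config.cell_nc])
        rows = []
        for j in sorted(set(cls.a_only) | set(cls.b_only) | set(cls.common)):
            cat = "common" if j in cls.common else ("cc_only" if j in cls.a_only else "nc_only")
            rows.append(
                {
                    "term": names[j],
                    "sign_cc": cls.signs_a.get(j, 0),
                    "sign_nc": cls.signs_b.get(j, 0),
                    "category": cat,
                }
            )
        pd.DataFrame(rows).to_csv(out / "classification.csv", index=False)
        manifest["stages"].append("interactions")

    write_json(manifest, out / "manifest.json")
    return manifest
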