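"""End-to-end orchestration: ingest -> filter -> fit -> summarize.

`run_species_analysis` reproduces the per-species workflow of the field
study: read (or simulate) a choice-set table, optionally keep one tracked
individual per brood, z-score covariates, fit the nest model and the
hierarchical postfledging model, and write coefficient tables, fit
statistics, use curves, posterior draws and a run manifest under one
output directory.  If the stage-structured juvenile model fails to
converge, the pipeline can automatically refit with late-dependent and
independent stages pooled — the fallback the field analysis itself needed
for one species.

`run_recovery_study` is the simulation harness: repeated
generate -> fit -> summarize cycles reporting bias, RMSE and credible-
interval coverage of the population-level parameters.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .choice_data import (
    Dataset,
    JUVENILE_STAGES,
    filter_one_per_brood,
    read_choice_table,
    standardize_covariates,
)
from .dcm_core import DEFAULT_SPEC
from .inference import (
    MCMCSettings,
    PosteriorDraws,
    PriorSpec,
    fit_nest,
    fit_postfledging,
)
from .summaries import INTERACTION_F_THRESHOLD, coefficient_table, fit_stats, use_curve
from .synthetic_data import SimConfig, flycatcher_preset, generate_dataset, ovenbird_preset

logger = logging.getLogger("fledgechoice")

POOLED_GROUPING = {"early_dependent": 0, "late_dependent": 1, "independent": 1}


@dataclass
class RunConfig:
    """Everything needed to reproduce one per-species analysis run."""

    species: str = "synthetic"
    input_csv: str | None = None          # mutually exclusive with preset
    preset: str | None = None             # "flycatcher" | "ovenbird" | "default"
    stage_grouping: dict[str, int] | None = None
    standardization: str = "zscore"
    one_per_brood: bool = False
    pool_on_nonconvergence: bool = True
    priors: PriorSpec = field(default_factory=PriorSpec)
    settings: MCMCSettings = field(default_factory=MCMCSettings)
    out_dir: str = "fledgechoice_run"
    seed: int = 0
    save_draws: bool = True

    def __post_init__(self) -> None:
        if (self.input_csv is None) == (self.preset is None):
            raise ValueError("exactly one of input_csv or preset must be given")
        if self.input_csv is not None and not Path(self.input_csv).exists():
            raise FileNotFoundError(self.input_csv)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "priors" in raw:
            raw["priors"] = PriorSpec(**raw["priors"])
        if "settings" in raw:
            raw["settings"] = MCMCSettings(**raw["settings"])
        return cls(**raw)

    def echo(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass
class RunManifest:
    """Wall-of-record for one run; sufficient to re-run bit-identically."""

    config: dict
    version: str
    filters: dict
    rhat: dict
    outputs: list[str]
    timings: dict

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {
                "config": self.config,
                "version": self.version,
                "filters": self.filters,
                "rhat": self.rhat,
                "outputs": self.outputs,
                "timings": self.timings,
            },
            indent=1, default=str,
        ))


def _load_input(cfg: RunConfig) -> tuple[Dataset, Dataset | None]:
    """Returns (dataset, nest_dataset_if_separate)."""
    if cfg.input_csv is not None:
        return read_choice_table(cfg.input_csv), None
    if cfg.preset == "flycatcher":
        nest_cfg, juv_cfg = flycatcher_preset(cfg.seed)
    elif cfg.preset == "ovenbird":
        nest_cfg, juv_cfg = ovenbird_preset(cfg.seed)
    elif cfg.preset == "default":
        nest_cfg = SimConfig(stages=("nest",), n_individuals_per_stage=60,
                             sets_per_individual=1,
                             population_sds={"nest": np.zeros(DEFAULT_SPEC.n_params)},
                             species=cfg.species, seed=cfg.seed)
        juv_cfg = SimConfig(species=cfg.species, seed=cfg.seed + 1)
    else:
        raise ValueError(f"unknown preset {cfg.preset!r}")
    nest_ds, _ = generate_dataset(nest_cfg)
    juv_ds, _ = generate_dataset(juv_cfg)
    merged = Dataset(
        sets=nest_ds.sets + juv_ds.sets,
        species=nest_ds.species,
    )
    return merged, None


def _write_model_outputs(
    out: Path,
    tag: str,
    draws: PosteriorDraws,
    dataset: Dataset,
    save_draws: bool,
) -> list[str]:
    files = []
    table = coefficient_table(draws)
    table_path = out / f"{tag}_coefficient_table.csv"
    table.to_csv(table_path, index=False)
    files.append(table_path.name)

    stats = fit_stats(draws, dataset)
    stats_path = out / f"{tag}_fit_stats.json"
    stats_path.write_text(json.dumps(dataclasses.asdict(stats), indent=1))
    files.append(stats_path.name)

    curves = []
    stages = ["nest"] if draws.meta["model"] == "nest" else draws.meta["stage_names"]
    for stage in stages:
        stage_rows = table[table["stage"] == stage].set_index("parameter")
        for cov in DEFAULT_SPEC.main_covariates:
            int_f = stage_rows.loc[f"{cov}:edge_distance", "f"] if \
                f"{cov}:edge_distance" in stage_rows.index else 0.0
            scenarios = ("near", "far") if int_f >= INTERACTION_F_THRESHOLD else ("none",)
            for scen in scenarios:
                c = use_curve(draws, cov, dataset, scenario=scen,
                              stage=None if draws.meta["model"] == "nest" else stage)
                f = c.to_frame()
                f.insert(0, "stage", stage)
                curves.append(f)
    curves_path = out / f"{tag}_use_curves.csv"
    pd.concat(curves, ignore_index=True).to_csv(curves_path, index=False)
    files.append(curves_path.name)

    if save_draws:
        draws_path = out / f"{tag}_draws.csv"
        draws.to_dataframe().to_csv(draws_path, index=False)
        files.append(draws_path.name)
    return files


def run_species_analysis(cfg: RunConfig) -> RunManifest:
    """Execute the full per-species workflow and write all artifacts."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    filters: dict[str, object] = {}
    rhat_summary: dict[str, object] = {}
    outputs: list[str] = []

    t0 = time.perf_counter()
    dataset, _ = _load_input(cfg)
    filters["sets_read"] = len(dataset.sets)
    filters["sets_excluded_incomplete"] = dataset.n_excluded_incomplete

    if cfg.one_per_brood:
        before = len(dataset.individuals())
        dataset = filter_one_per_brood(dataset, seed=cfg.seed)
        filters["individuals_before_brood_filter"] = before
        filters["individuals_after_brood_filter"] = len(dataset.individuals())

    std, record = standardize_covariates(dataset, scheme=cfg.standardization)
    filters["standardization"] = cfg.standardization
    scaling_path = out / "scaling_record.json"
    scaling_path.write_text(json.dumps(
        {"scheme": record.scheme, "means": record.means, "sds": record.sds}, indent=1))
    outputs.append(scaling_path.name)
    timings["prepare_s"] = round(time.perf_counter() - t0, 3)

    # ---- nest model
    nest_ds = std.subset(["nest"])
    if nest_ds.sets:
        t0 = time.perf_counter()
        logger.info("fitting nest model on %d sets", len(nest_ds.sets))
        nest_draws = fit_nest(nest_ds, cfg.priors, cfg.settings)
        timings["fit_nest_s"] = round(time.perf_counter() - t0, 3)
        rhat_summary["nest"] = {
            "max_rhat": max(nest_draws.meta["rhat"].values()),
            "all_converged": nest_draws.meta["all_converged"],
        }
        outputs += _write_model_outputs(out, "nest", nest_draws, nest_ds, cfg.save_draws)

    # ---- postfledging model, with pooled fallback
    juv_ds = std.subset([s for s in JUVENILE_STAGES
                         if any(cs.stage == s for cs in std.sets)])
    if juv_ds.sets:
        grouping = cfg.stage_grouping or {
            s: i for i, s in enumerate(sorted({cs.stage for cs in juv_ds.sets},
                                              key=JUVENILE_STAGES.index))
        }
        t0 = time.perf_counter()
        logger.info("fitting postfledging model on %d sets", len(juv_ds.sets))
        juv_draws = fit_postfledging(juv_ds, grouping, cfg.priors, cfg.settings)
        timings["fit_postfledging_s"] = round(time.perf_counter() - t0, 3)
        rhat_summary["postfledging"] = {
            "max_rhat": max(juv_draws.meta["rhat"].values()),
            "all_converged": juv_draws.meta["all_converged"],
            "stage_names": juv_draws.meta["stage_names"],
        }
        pooled_needed = (
            not juv_draws.meta["all_converged"]
            and cfg.pool_on_nonconvergence
            and len(set(grouping.values())) > 2
        )
        if pooled_needed:
            logger.warning("stage-structured model did not converge; refitting "
                           "with late_dependent + independent pooled")
            pooled = {s: POOLED_GROUPING[s] for s in grouping}
            t0 = time.perf_counter()
            juv_draws = fit_postfledging(juv_ds, pooled, cfg.priors, cfg.settings)
            timings["fit_postfledging_pooled_s"] = round(time.perf_counter() - t0, 3)
            rhat_summary["postfledging_pooled"] = {
                "max_rhat": max(juv_draws.meta["rhat"].values()),
                "all_converged": juv_draws.meta["all_converged"],
                "stage_names": juv_draws.meta["stage_names"],
            }
        outputs += _write_model_outputs(out, "postfledging", juv_draws, juv_ds,
                                        cfg.save_draws)

    manifest = RunManifest(
        config=cfg.echo(),
        version=__version__,
        filters=filters,
        rhat=rhat_summary,
        outputs=outputs,
        timings=timings,
    )
    manifest.to_json(out / "manifest.json")
    return manifest


def run_recovery_study(
    sim: SimConfig,
    n_replicates: int,
    priors: PriorSpec = PriorSpec(),
    settings: MCMCSettings = MCMCSettings(),
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Repeated generate -> fit cycles measuring recovery of mu and sigma.

    Returns a per-(replicate, stage, parameter) table for the population
    means and SDs, plus an aggregate summary with CRI coverage, mean
    absolute bias and RMSE of mu.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rows = []
    base = np.random.SeedSequence(seed)
    rep_seeds = base.generate_state(2 * n_replicates) % (2**31 - 1)
    for r in range(n_replicates):
        cfg_r = dataclasses.replace(sim, seed=int(rep_seeds[2 * r]))
        dataset, truth = generate_dataset(cfg_r)
        std, _ = standardize_covariates(dataset, scheme="zscore")
        settings_r = dataclasses.replace(settings, seed=int(rep_seeds[2 * r + 1]))
        draws = fit_postfledging(std, priors=priors, settings=settings_r)
        stage_names = draws.meta["stage_names"]
        labels = draws.meta["labels"]
        for stage in stage_names:
            mu_true = np.asarray(truth.population_means[stage])
            sd_true = np.asarray(truth.population_sds[stage])
            for k, lab in enumerate(labels):
                for kind, true_val in (("mu", mu_true[k]), ("sigma", sd_true[k])):
                    x = draws.pooled(f"{kind}[{stage}].{lab}")
                    lo, hi = np.percentile(x, [2.5, 97.5])
                    rows.append({
                        "replicate": r,
                        "stage": stage,
                        "parameter": lab,
                        "kind": kind,
                        "truth": float(true_val),
                        "post_mean": float(x.mean()),
                        "cri_low": float(lo),
                        "cri_high": float(hi),
                        "covered": bool(lo <= true_val <= hi),
                        "converged": bool(draws.meta["all_converged"]),
                    })
    report = pd.DataFrame(rows)
    mu_rows = report[report["kind"] == "mu"].copy()
    mu_rows["error"] = mu_rows["post_mean"] - mu_rows["truth"]
    # bias per parameter = error averaged over replicates
    bias = mu_rows.groupby(["stage", "parameter"])["error"].mean()
    summary = {
        "n_replicates": n_replicates,
        "mu_coverage": float(mu_rows["covered"].mean()),
        "mu_mean_abs_bias": float(bias.abs().mean()),
        "mu_mean_abs_error": float(mu_rows["error"].abs().mean()),
        "mu_rmse": float(np.sqrt((mu_rows["error"] ** 2).mean())),
        "sigma_coverage": float(report[report["kind"] == "sigma"]["covered"].mean()),
        "all_converged_fraction": float(report["converged"].mean()),
    }
    return report, summary
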