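"""Study orchestration: sample a population, simulate it, analyze it.

The full study is three stages — ``sample`` (draw synapse configurations),
``simulate`` (replicate runs per configuration, resumable), ``analyze``
(correlations, regressions, distribution, activation probabilities) —
each writing tidy CSV plus a JSON manifest sufficient to regenerate the
outputs bit-identically.  Scale presets:

========  ============  ===============
preset    configurations  runs per config
========  ============  ===============
smoke     2             5
desk      30            50
paper     500           500
========  ============  ===============

``paper`` reproduces the published experiment size (250,000 runs) and is
meant for cluster-scale hardware; ``desk`` reproduces the headline
statistics on one CPU in minutes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import analysis, curves, engine, population
from .geometry import EcsBalanceWarning

__all__ = ["ExperimentConfig", "PRESETS", "run_study", "cmd_sample", "cmd_simulate",
           "cmd_analyze"]

log = logging.getLogger("cleftsim")

PRESETS = {
    "smoke": {"n_configs": 2, "runs_per_config": 5},
    "desk": {"n_configs": 30, "runs_per_config": 50},
    "paper": {"n_configs": 500, "runs_per_config": 500},
}


@dataclass
class ExperimentConfig:
    """Scale, seed and physics of one experiment."""

    n_configs: int = 30
    runs_per_config: int = 50
    root_seed: int = 0
    sim: engine.SimParams = dataclasses.field(default_factory=engine.SimParams)
    scheme_paths: dict[str, str] | None = None  # None -> packaged defaults
    out_dir: str = "results"
    preset: str | None = None

    @classmethod
    def from_preset(cls, preset: str, **kw) -> "ExperimentConfig":
        return cls(**PRESETS[preset], preset=preset, **kw)

    def schemes(self):
        if self.scheme_paths is None:
            return engine.default_schemes()
        from .kinetics import load_scheme

        return {k: load_scheme(v) for k, v in self.scheme_paths.items()}

    def manifest(self) -> dict:
        doc = {
            "n_configs": self.n_configs,
            "runs_per_config": self.runs_per_config,
            "root_seed": self.root_seed,
            "sim": dataclasses.asdict(self.sim),
            "scheme_paths": self.scheme_paths,
            "preset": self.preset,
        }
        doc["config_hash"] = hashlib.sha256(
            json.dumps(doc, sort_keys=True).encode()
        ).hexdigest()[:16]
        import cleftsim

        doc["package_version"] = cleftsim.__version__
        return doc


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def cmd_sample(exp: ExperimentConfig, out_dir: str | Path | None = None,
               id_prefix: str = "syn") -> pd.DataFrame:
    """Sample the population; write population.csv + manifest.json."""
    configs = population.sample_configs(
        exp.n_configs, seed=exp.root_seed, id_prefix=id_prefix
    )
    df = population.configs_to_frame(configs)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        population.write_population(
            configs, out / "population.csv", out / "manifest.json",
            root_seed=exp.root_seed,
        )
        (out / "experiment.json").write_text(json.dumps(exp.manifest(), indent=2))
    return df


def _simulate_one(cfg, exp: ExperimentConfig, schemes) -> tuple:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", EcsBalanceWarning)
        batch = engine.run_batch(
            cfg, exp.runs_per_config, params=exp.sim, schemes=schemes
        )
    summary = curves.summarize_config(cfg.id, batch.results)
    return batch, summary


def cmd_simulate(
    population_df: pd.DataFrame,
    exp: ExperimentConfig,
    out_dir: str | Path | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate every configuration; returns (population table, run table).

    Resumable: each configuration's run-level CSV is written atomically
    (tmp + rename) next to a completion marker, and finished
    configurations are skipped on re-entry, so an interrupted invocation
    never corrupts completed results.
    """
    configs = population.frame_to_configs(population_df)
    schemes = exp.schemes()
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        (out / "runs").mkdir(parents=True, exist_ok=True)

    summaries = []
    run_tables = []
    for i, cfg in enumerate(configs):
        part = out / "runs" / f"{cfg.id}.csv" if out is not None else None
        if part is not None and part.exists():
            run_df = pd.read_csv(part)
            results = None
            log.info("%s: reusing completed runs", cfg.id)
        else:
            batch, _ = _simulate_one(cfg, exp, schemes)
            results = batch.results
            run_df = curves.runs_frame({cfg.id: results})
            if part is not None:
                tmp = part.with_suffix(".csv.tmp")
                run_df.to_csv(tmp, index=False)
                tmp.rename(part)
            log.info(
                "%s (%d/%d): nAMPA=%d mean maxOPEN=%.1f",
                cfg.id, i + 1, len(configs), cfg.nAMPA, run_df["maxOPEN"].mean(),
            )
        run_tables.append(run_df)
        summaries.append(_summary_from_run_df(cfg.id, run_df))

    table = curves.build_population_table(configs, summaries)
    runs = pd.concat(run_tables, ignore_index=True)
    if out is not None:
        table.to_csv(out / "population_table.csv", index=False)
        runs.to_csv(out / "runs.csv", index=False)
    return table, runs


def _summary_from_run_df(config_id: str, run_df: pd.DataFrame) -> curves.ConfigSummary:
    class _R:  # minimal view of a run row
        __slots__ = ("maxOPEN", "peak_time_us", "auc")

        def __init__(self, row):
            self.maxOPEN = row.maxOPEN
            self.peak_time_us = row.peak_time_us
            self.auc = row.auc

    return curves.summarize_config(config_id, [_R(r) for r in run_df.itertuples()])


def cmd_analyze(
    table: pd.DataFrame,
    runs: pd.DataFrame,
    out_dir: str | Path | None = None,
    test_table: pd.DataFrame | None = None,
) -> dict:
    """Correlations, regressions, distribution and activation probabilities.

    With ``test_table`` (an independently simulated population table) the
    power-law fits additionally report held-out RMSE/R^2.
    """
    report: dict = {}

    if len(table) >= 3:
        corr = analysis.correlation_screen(table)
    else:  # smoke scale: too few configurations for a correlation screen
        corr = pd.DataFrame(
            index=analysis.PREDICTORS, columns=analysis.RESPONSES, dtype=float
        )
    report["correlations"] = corr

    dist = analysis.maxopen_distribution(runs["maxOPEN"].to_numpy())
    report["distribution"] = {
        "n_runs": int(len(runs)),
        "mean": float(runs["maxOPEN"].mean()),
        "sd": float(runs["maxOPEN"].std(ddof=1)),
        "cv": float(runs["maxOPEN"].std(ddof=1) / runs["maxOPEN"].mean()),
        "Q1": dist.q1,
        "Q2": dist.q2,
        "Q3": dist.q3,
        "mode": dist.mode,
        "mode_frequency": dist.mode_frequency,
        "prob_le_100": dist.prob_at_most(100),
        "mean_peak_time_us": float(runs["peak_time_us"].mean()),
        "sd_peak_time_us": float(runs["peak_time_us"].std(ddof=1)),
    }

    fits = []
    for predictor in ("As", "nAMPA"):
        for response in ("maxopen_mean", "maxopen_cv"):
            sub = table.dropna(subset=[response])
            if len(sub) < 4:  # smoke scale: not enough points to fit
                continue
            fit = analysis.fit_power_law(
                sub[predictor], sub[response], predictor, response
            )
            if test_table is not None:
                tsub = test_table.dropna(subset=[response])
                analysis.validate_fit(fit, tsub[predictor], tsub[response])
            fits.append(fit)
    report["fits"] = fits

    thr = {"Q1": dist.q1, "Q2": dist.q2, "Q3": dist.q3}
    act = analysis.activation_probability(runs, table, thr)
    report["activation"] = act
    report["activation_curves"] = {
        name: analysis.binned_activation_curve(
            act, f"p_ge_{name}", n_bins=min(20, max(2, len(act) // 2))
        )
        for name in thr
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        corr.to_csv(out / "correlation_screen.csv")
        pd.DataFrame([vars(f) for f in fits]).to_csv(
            out / "power_law_fits.csv", index=False
        )
        act.to_csv(out / "activation_probabilities.csv", index=False)
        (out / "distribution.json").write_text(
            json.dumps(report["distribution"], indent=2)
        )
        dens = pd.DataFrame(
            {"maxOPEN": np.arange(dist.counts.size), "density": dist.density,
             "cdf": dist.cdf}
        )
        dens.to_csv(out / "maxopen_distribution.csv", index=False)
    return report


def run_study(
    n_configs: int,
    runs_per_config: int,
    root_seed: int,
    params: engine.SimParams | None = None,
    out_dir: str | Path | None = None,
    id_prefix: str = "syn",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sample + simulate in one call; returns (population table, run table)."""
    exp = ExperimentConfig(
        n_configs=n_configs,
        runs_per_config=runs_per_config,
        root_seed=root_seed,
        sim=params or engine.SimParams(),
    )
    df = cmd_sample(exp, out_dir, id_prefix=id_prefix)
    return cmd_simulate(df, exp, out_dir)
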