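"""Reduction of open-receptor curves to per-configuration descriptors.

Each run is summarized by three numbers: ``maxOPEN`` (the peak number of
simultaneously open receptors), the peak time (time of the *first*
attainment of the maximum, in us) and the area under the curve.  Per
configuration, replicate runs yield the mean, sample standard deviation
(n-1 denominator) and coefficient of variation cv = sd/mean of maxOPEN
and of the peak time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "summarize_run",
    "summarize_config",
    "ConfigSummary",
    "build_population_table",
    "runs_frame",
]


def summarize_run(series, dt_us: float = 1.0) -> tuple[int, float, float]:
    """(maxOPEN, peak_time_us, auc) of one open-count series.

    Peak time is ``dt * argmax`` with ties broken by the first occurrence;
    auc is ``dt * sum(series)``.
    """
    s = np.asarray(series)
    if s.size == 0:
        raise ValueError("empty series")
    m = int(s.max())
    peak_time = float(dt_us * int(np.argmax(s)))  # argmax returns first maximum
    auc = float(dt_us * s.sum())
    return m, peak_time, auc


@dataclass
class ConfigSummary:
    """Replicate statistics of one synapse configuration."""

    config_id: str
    N_R: int
    maxopen_mean: float
    maxopen_sd: float
    maxopen_cv: float  # NaN when the mean is zero
    peaktime_mean: float
    peaktime_sd: float
    peaktime_cv: float
    auc_mean: float


def _mean_sd_cv(x: np.ndarray) -> tuple[float, float, float]:
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1)) if x.size >= 2 else 0.0
    cv = sd / mean if mean > 0 else math.nan
    return mean, sd, cv


def summarize_config(config_id: str, results: Sequence) -> ConfigSummary:
    """Pool replicate :class:`~cleftsim.engine.RunResult`s of one synapse.

    Order of the runs is irrelevant.  cv is reported as NaN (missing)
    when the mean is zero.
    """
    if len(results) < 1:
        raise ValueError("need at least one run")
    mo = np.array([r.maxOPEN for r in results], dtype=float)
    pt = np.array([r.peak_time_us for r in results], dtype=float)
    auc = np.array([r.auc for r in results], dtype=float)
    mo_m, mo_s, mo_c = _mean_sd_cv(mo)
    pt_m, pt_s, pt_c = _mean_sd_cv(pt)
    return ConfigSummary(
        config_id=config_id,
        N_R=len(results),
        maxopen_mean=mo_m,
        maxopen_sd=mo_s,
        maxopen_cv=mo_c,
        peaktime_mean=pt_m,
        peaktime_sd=pt_s,
        peaktime_cv=pt_c,
        auc_mean=float(np.mean(auc)),
    )


def build_population_table(configs, summaries: Sequence[ConfigSummary]) -> pd.DataFrame:
    """Join configuration parameters with replicate summaries (one row each)."""
    from .population import configs_to_frame

    cfg_df = configs_to_frame(configs).rename(columns={"id": "config_id"})
    sum_df = pd.DataFrame([vars(s) for s in summaries])
    out = cfg_df.merge(sum_df, on="config_id", validate="one_to_one")
    return out


def runs_frame(per_config_results: dict[str, Sequence]) -> pd.DataFrame:
    """Tidy run-level table: one row per (configuration, run)."""
    rows = []
    for config_id, results in per_config_results.items():
        for j, r in enumerate(results):
            rows.append(
                {
                    "config_id": config_id,
                    "run": j,
                    "maxOPEN": r.maxOPEN,
                    "peak_time_us": r.peak_time_us,
                    "auc": r.auc,
                    "removed": r.removed,
                }
            )
    return pd.DataFrame(rows)
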