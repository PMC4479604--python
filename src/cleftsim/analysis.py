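"""Population-level statistics of maxOPEN.

This module carries the statistical layer of the study: a Pearson
correlation screen of configuration parameters against the per-synapse
mean and cv of maxOPEN, three-coefficient power-law regressions
``f(x) = a x^b + c`` with held-out validation, the pooled maxOPEN
density/CDF/quartiles, exceedance ("activation") probabilities relative
to the population quartiles, and spatial maps of receptor opening across
the PSD.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "PREDICTORS",
    "correlation_screen",
    "PowerLawFit",
    "fit_power_law",
    "validate_fit",
    "MaxOpenDistribution",
    "maxopen_distribution",
    "activation_probability",
    "binned_activation_curve",
    "SpatialOpeningMap",
    "spatial_opening_map",
]

#: configuration parameters screened against maxOPEN, in report order.
PREDICTORS = ["glut_density", "La", "ampar_density", "As", "Ls", "nAMPA"]
RESPONSES = ["maxopen_mean", "maxopen_cv"]


def correlation_screen(table: pd.DataFrame) -> pd.DataFrame:
    """Pearson r between configuration parameters and maxOPEN mean / cv.

    ``table`` is a population table (one row per configuration).  A
    zero-variance column yields missing entries and a warning.
    """
    if len(table) < 3:
        raise ValueError("need at least 3 configurations")
    out = pd.DataFrame(index=PREDICTORS, columns=RESPONSES, dtype=float)
    for x in PREDICTORS:
        xv = table[x].to_numpy(dtype=float)
        if np.std(xv) == 0:
            warnings.warn(f"zero-variance predictor {x}: correlations undefined")
            continue
        for y in RESPONSES:
            yv = table[y].to_numpy(dtype=float)
            ok = np.isfinite(xv) & np.isfinite(yv)
            if ok.sum() < 3 or np.std(yv[ok]) == 0:
                warnings.warn(f"zero-variance or missing response {y}")
                continue
            out.loc[x, y] = float(np.corrcoef(xv[ok], yv[ok])[0, 1])
    return out


# ---------------------------------------------------------------------------
# power-law regression f(x) = a x^b + c
# ---------------------------------------------------------------------------


@dataclass
class PowerLawFit:
    """Nonlinear least-squares fit of f(x) = a x^b + c."""

    a: float
    b: float
    c: float
    predictor: str = "x"
    response: str = "y"
    rmse_train: float = math.nan
    r2_train: float = math.nan
    rmse_test: float = math.nan
    r2_test: float = math.nan

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.a * np.power(x, self.b) + self.c


def _rmse_r2(y: np.ndarray, yhat: np.ndarray) -> tuple[float, float]:
    resid = y - yhat
    rmse = float(np.sqrt(np.mean(resid**2)))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 0.0
    return rmse, r2


def fit_power_law(
    x, y, predictor: str = "x", response: str = "y", b_fixed: float | None = None
) -> PowerLawFit:
    """Fit f(x) = a x^b + c by nonlinear least squares.

    Initialization: c0 = min(y) - eps, then (a0, b0) from an ordinary
    least-squares line of log(y - c0) on log(x); on failure a small grid
    of alternative c0 offsets is retried.  Deterministic given the data.
    ``b_fixed`` pins the exponent (b_fixed=1 reduces to linear regression).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 4:
        raise ValueError("need at least 4 points")
    if np.any(x <= 0):
        raise ValueError("predictor values must be positive")

    if np.allclose(y, y[0]):
        # degenerate constant response: a ~ 0 branch, no crash
        return PowerLawFit(0.0, 1.0, float(y[0]), predictor, response, 0.0, 0.0)

    spread = float(y.max() - y.min())
    trace: list[str] = []

    def initial(c_off: float):
        c0 = float(y.min()) - c_off * spread - 1e-9
        pos = y - c0
        lx, ly = np.log(x), np.log(pos)
        b0, la0 = np.polyfit(lx, ly, 1)
        return math.exp(la0), b0, c0

    def model(xv, a, b, c):
        return a * np.power(xv, b) + c

    last_err: Exception | None = None
    for c_off in (0.01, 0.0, 0.1, 0.5, 1.0):
        a0, b0, c0 = initial(c_off)
        try:
            if b_fixed is None:
                popt, _ = curve_fit(
                    model, x, y, p0=(a0, b0, c0), maxfev=20000
                )
                a, b, c = (float(v) for v in popt)
            else:
                popt, _ = curve_fit(
                    lambda xv, a, c: model(xv, a, b_fixed, c),
                    x, y, p0=(a0, c0), maxfev=20000,
                )
                a, c = (float(v) for v in popt)
                b = float(b_fixed)
            rmse, r2 = _rmse_r2(y, model(x, a, b, c))
            return PowerLawFit(a, b, c, predictor, response, rmse, r2)
        except Exception as err:  # retry over the c0 grid
            trace.append(f"c_off={c_off}: {err}")
            last_err = err
    raise RuntimeError(
        "power-law fit did not converge; initializer trace: " + "; ".join(trace)
    ) from last_err


def validate_fit(fit: PowerLawFit, x_test, y_test) -> PowerLawFit:
    """Attach held-out RMSE and R^2 (R^2 may be negative: no fit at all)."""
    x_test = np.asarray(x_test, dtype=float)
    y_test = np.asarray(y_test, dtype=float)
    ok = np.isfinite(x_test) & np.isfinite(y_test)
    fit.rmse_test, fit.r2_test = _rmse_r2(y_test[ok], fit.predict(x_test[ok]))
    return fit


# ---------------------------------------------------------------------------
# pooled maxOPEN distribution
# ---------------------------------------------------------------------------


@dataclass
class MaxOpenDistribution:
    """Integer-binned density, CDF and quartiles of pooled maxOPEN."""

    values: np.ndarray
    counts: np.ndarray  # occurrences per integer 0..max
    density: np.ndarray  # counts / n
    cdf: np.ndarray
    q1: float
    q2: float
    q3: float
    mode: int
    mode_frequency: float

    def prob_at_most(self, k: int) -> float:
        """P(maxOPEN <= k)."""
        if k < 0:
            return 0.0
        k = min(int(k), len(self.cdf) - 1)
        return min(float(self.cdf[k]), 1.0)  # guard cumsum rounding past 1


def maxopen_distribution(pooled) -> MaxOpenDistribution:
    """Distribution of run-level maxOPEN pooled across all configurations.

    Quartiles use linear-interpolation quantiles; the mode is the most
    frequent integer count.
    """
    v = np.asarray(pooled)
    if v.size == 0:
        raise ValueError("empty pooled maxOPEN vector")
    counts = np.bincount(v.astype(np.int64))
    density = counts / v.size
    cdf = np.cumsum(density)
    q1, q2, q3 = (float(q) for q in np.quantile(v, [0.25, 0.5, 0.75]))
    mode = int(np.argmax(counts))
    return MaxOpenDistribution(
        values=v,
        counts=counts,
        density=density,
        cdf=cdf,
        q1=q1,
        q2=q2,
        q3=q3,
        mode=mode,
        mode_frequency=float(density[mode]),
    )


# ---------------------------------------------------------------------------
# activation (exceedance) probabilities
# ---------------------------------------------------------------------------


def activation_probability(
    runs: pd.DataFrame, table: pd.DataFrame, thresholds: dict[str, float]
) -> pd.DataFrame:
    """Per-configuration P(maxOPEN >= threshold) for each quartile threshold.

    ``runs`` is the tidy run-level table (config_id, maxOPEN, ...);
    ``table`` the population table.  Returns the population table with one
    exceedance-probability column per threshold.
    """
    out = table.copy()
    grouped = runs.groupby("config_id")["maxOPEN"]
    for name, thr in thresholds.items():
        p = grouped.apply(lambda v: float(np.mean(v >= thr)))
        out[f"p_ge_{name}"] = out["config_id"].map(p)
    return out


def binned_activation_curve(
    act_table: pd.DataFrame, column: str, by: str = "nAMPA", n_bins: int = 20
) -> pd.DataFrame:
    """Exceedance probability vs a parameter in equal-count bins."""
    t = act_table.sort_values(by).reset_index(drop=True)
    edges = np.linspace(0, len(t), n_bins + 1).astype(int)
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        b = t.iloc[lo:hi]
        if len(b):
            rows.append(
                {by: float(b[by].mean()), column: float(b[column].mean()),
                 "n": len(b)}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# spatial opening map
# ---------------------------------------------------------------------------


@dataclass
class SpatialOpeningMap:
    """Open-receptor fraction on a square grid tiling the PSD.

    ``fractions[k]`` is the per-cell open fraction at time point ``k``
    (open receptors in cell / receptors in cell, averaged over runs);
    cells that never contain a receptor are NaN.
    """

    cell_nm: float
    n_cells: int  # grid is n_cells x n_cells
    times_us: list[float]
    labels: list[str]
    fractions: np.ndarray  # float64[n_times, n_cells, n_cells]
    receptor_counts: np.ndarray = field(default=None)  # mean receptors per cell


def spatial_opening_map(
    cfg,
    n_runs: int = 200,
    cell_nm: float = 55.0,
    times_us: list[float] | None = None,
    root_seed: int | None = None,
    params=None,
) -> SpatialOpeningMap:
    """Map receptor opening probability across the PSD at selected times.

    When ``times_us`` is not given, a pilot batch locates the peak of the
    mean open curve and the map is taken at 0.5x peak (rising phase), the
    peak, 2x peak (falling phase) and 8 ms (late stage).
    """
    from . import engine

    params = params or engine.SimParams()
    if times_us is None:
        pilot = engine.run_batch(cfg, max(10, n_runs // 10), root_seed=root_seed,
                                 params=params)
        t_peak = float(np.argmax(pilot.mean_curve)) * params.dt_us
        t_peak = max(t_peak, 2 * params.dt_us)
        times_us = [0.5 * t_peak, t_peak, 2.0 * t_peak, 8000.0]
        labels = ["rising", "peak", "falling", "late"]
    else:
        labels = [f"t{i}" for i in range(len(times_us))]
    steps = sorted({int(round(t / params.dt_us)) for t in times_us})
    times_us = [s * params.dt_us for s in steps]

    n_cells = int(math.ceil(cfg.Ls / cell_nm))
    open_acc = np.zeros((len(steps), n_cells, n_cells))
    rec_acc = np.zeros((n_cells, n_cells))

    batch = engine.run_batch(
        cfg, n_runs, root_seed=root_seed, params=params, record_steps=steps
    )
    half = cfg.Ls / 2.0
    for r in batch.results:
        xy = r.receptor_xy
        ix = np.clip(((xy[:, 0] + half) / cell_nm).astype(int), 0, n_cells - 1)
        iy = np.clip(((xy[:, 1] + half) / cell_nm).astype(int), 0, n_cells - 1)
        rc = np.zeros((n_cells, n_cells))
        np.add.at(rc, (ix, iy), 1)
        rec_acc += rc
        for k in range(len(steps)):
            flags = r.open_snapshots[k].astype(float)
            oc = np.zeros((n_cells, n_cells))
            np.add.at(oc, (ix, iy), flags)
            with np.errstate(invalid="ignore"):
                open_acc[k] += np.where(rc > 0, oc / np.maximum(rc, 1), 0.0)

    occupied = rec_acc > 0
    fractions = np.where(occupied[None, :, :], open_acc / n_runs, np.nan)
    return SpatialOpeningMap(
        cell_nm=cell_nm,
        n_cells=n_cells,
        times_us=list(times_us),
        labels=labels,
        fractions=fractions,
        receptor_counts=rec_acc / n_runs,
    )
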