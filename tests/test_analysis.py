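"""Statistical layer: correlations, power-law fits, distribution, maps."""

import numpy as np
import pandas as pd
import pytest

from cleftsim import analysis
from cleftsim.analysis import (
    MaxOpenDistribution,
    binned_activation_curve,
    correlation_screen,
    fit_power_law,
    maxopen_distribution,
    spatial_opening_map,
    validate_fit,
)
from cleftsim.population import SynapseConfig


def _table(n=40, seed=0):
    rng = np.random.default_rng(seed)
    nampa = rng.uniform(10, 2000, n)
    df = pd.DataFrame(
        {
            "config_id": [f"c{i}" for i in range(n)],
            "glut_density": rng.uniform(7000, 12000, n),
            "La": rng.uniform(100, 1000, n),
            "ampar_density": rng.uniform(500, 3000, n),
            "As": nampa / 1.75e-3,
            "Ls": np.sqrt(nampa / 1.75e-3),
            "nAMPA": nampa,
            "maxopen_mean": 2.175 * nampa**0.663 - 4.661,
            "maxopen_cv": 0.990 * nampa**-0.457 + 0.017,
        }
    )
    return df


class TestCorrelationScreen:
    def test_perfect_correlation(self):
        t = _table()
        t["maxopen_mean"] = t["nAMPA"]
        r = correlation_screen(t)
        assert r.loc["nAMPA", "maxopen_mean"] == pytest.approx(1.0)

    def test_affine_rescaling_invariance(self):
        t = _table()
        r1 = correlation_screen(t)
        t2 = t.copy()
        t2["nAMPA"] = 3.5 * t2["nAMPA"] - 100.0
        t2["As"] = -0.25 * t2["As"] + 7.0
        r2 = correlation_screen(t2)
        assert r2.loc["nAMPA", "maxopen_mean"] == pytest.approx(
            r1.loc["nAMPA", "maxopen_mean"], rel=1e-12
        )
        assert r2.loc["As", "maxopen_mean"] == pytest.approx(
            -r1.loc["As", "maxopen_mean"], rel=1e-12
        )

    def test_zero_variance_column_warns_and_is_missing(self):
        t = _table()
        t["glut_density"] = 9500.0
        with pytest.warns(UserWarning, match="zero-variance"):
            r = correlation_screen(t)
        assert np.isnan(r.loc["glut_density", "maxopen_mean"])

    def test_requires_three_rows(self):
        with pytest.raises(ValueError):
            correlation_screen(_table(2))


class TestPowerLawFit:
    def test_recovers_reference_coefficients_to_4_sig_figs(self):
        """Noise-free data from a = 2.175, b = 0.663, c = -4.661."""
        x = np.linspace(10, 2000, 60)
        y = 2.175 * x**0.663 - 4.661
        fit = fit_power_law(x, y)
        assert fit.a == pytest.approx(2.175, rel=5e-4)
        assert fit.b == pytest.approx(0.663, rel=5e-4)
        assert fit.c == pytest.approx(-4.661, rel=5e-4)
        assert fit.r2_train == pytest.approx(1.0, abs=1e-9)
        assert fit.rmse_train == pytest.approx(0.0, abs=1e-6)

    def test_negative_exponent_branch(self):
        x = np.linspace(10, 2000, 60)
        y = 0.990 * x**-0.457 + 0.017
        fit = fit_power_law(x, y)
        assert fit.b == pytest.approx(-0.457, rel=1e-3)

    def test_constant_response_degenerates_gracefully(self):
        x = np.linspace(1, 100, 20)
        fit = fit_power_law(x, np.full(20, 3.0))
        assert fit.a == pytest.approx(0.0, abs=1e-9)
        assert fit.c == pytest.approx(3.0)
        assert fit.r2_train == 0.0

    def test_b_fixed_at_one_matches_linear_regression(self):
        """With the exponent pinned to 1 the fit is ordinary least squares."""
        rng = np.random.default_rng(3)
        x = np.linspace(1, 10, 10)
        y = 3.0 * x + 2.0 + rng.normal(0, 0.5, 10)
        fit = fit_power_law(x, y, b_fixed=1.0)
        slope, intercept = np.polyfit(x, y, 1)
        assert fit.a == pytest.approx(slope, rel=1e-6)
        assert fit.c == pytest.approx(intercept, rel=1e-6)

    def test_needs_positive_x_and_four_points(self):
        with pytest.raises(ValueError):
            fit_power_law([1, 2, 3], [1, 2, 3])
        with pytest.raises(ValueError):
            fit_power_law([-1, 2, 3, 4], [1, 2, 3, 4])


class TestValidateFit:
    def test_test_equals_train_gives_identical_metrics(self):
        x = np.linspace(10, 2000, 50)
        y = 2.175 * x**0.663 - 4.661 + np.sin(x / 100)
        fit = fit_power_law(x, y)
        validate_fit(fit, x, y)
        assert fit.rmse_test == pytest.approx(fit.rmse_train, rel=1e-12)
        assert fit.r2_test == pytest.approx(fit.r2_train, rel=1e-12)

    def test_random_response_can_go_negative(self):
        """Held-out R^2 may fall at or below zero: no fit at all."""
        rng = np.random.default_rng(7)
        x = np.linspace(10, 2000, 50)
        fit = fit_power_law(x, 2.175 * x**0.663 - 4.661)
        validate_fit(fit, x, rng.normal(50, 5, 50))
        assert fit.r2_test <= 0.0


class TestMaxOpenDistribution:
    def test_textbook_quantiles(self):
        d = maxopen_distribution(np.array([1, 2, 3, 4]))
        assert d.q2 == pytest.approx(2.5)
        assert d.q1 == pytest.approx(1.75)
        assert d.q3 == pytest.approx(3.25)

    def test_density_and_cdf_consistent(self):
        rng = np.random.default_rng(1)
        d = maxopen_distribution(rng.poisson(30, 5000))
        assert d.density.sum() == pytest.approx(1.0)
        np.testing.assert_allclose(d.cdf, np.cumsum(d.density))
        assert d.cdf[-1] == pytest.approx(1.0)
        assert (np.diff(d.cdf) >= -1e-15).all()
        assert d.q1 <= d.q2 <= d.q3

    def test_mode_is_most_frequent_integer(self):
        d = maxopen_distribution(np.array([5, 5, 5, 7, 9]))
        assert d.mode == 5
        assert d.mode_frequency == pytest.approx(0.6)

    def test_prob_at_most(self):
        d = maxopen_distribution(np.arange(200))
        assert d.prob_at_most(99) == pytest.approx(0.5)
        assert d.prob_at_most(10_000) == 1.0
        assert d.prob_at_most(-1) == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            maxopen_distribution(np.array([]))


class TestActivationProbability:
    def _runs(self):
        rng = np.random.default_rng(0)
        rows = []
        for i, lam in enumerate([5, 20, 80]):
            for j in range(200):
                rows.append({"config_id": f"c{i}", "run": j,
                             "maxOPEN": rng.poisson(lam)})
        return pd.DataFrame(rows)

    def _tbl(self):
        return pd.DataFrame(
            {"config_id": ["c0", "c1", "c2"], "nAMPA": [10, 40, 160]}
        )

    def test_threshold_zero_gives_probability_one(self):
        act = analysis.activation_probability(self._runs(), self._tbl(), {"z": 0})
        assert (act["p_ge_z"] == 1.0).all()

    def test_threshold_above_nampa_gives_zero(self):
        runs = self._runs()
        act = analysis.activation_probability(runs, self._tbl(), {"big": 10_000})
        assert (act["p_ge_big"] == 0.0).all()

    def test_exceedance_nonincreasing_in_threshold(self):
        runs = self._runs()
        act = analysis.activation_probability(
            runs, self._tbl(), {"a": 5, "b": 20, "c": 50}
        )
        assert (act["p_ge_a"] >= act["p_ge_b"]).all()
        assert (act["p_ge_b"] >= act["p_ge_c"]).all()

    def test_binned_curve_shape(self):
        act = analysis.activation_probability(self._runs(), self._tbl(), {"a": 20})
        curve = binned_activation_curve(act, "p_ge_a", n_bins=3)
        assert len(curve) == 3
        assert curve["p_ge_a"].is_monotonic_increasing


@pytest.fixture(scope="module")
def fig7_map():
    """Large-synapse opening map (60 runs; pilot finds the peak)."""
    cfg = SynapseConfig(id="fig7", Ls=385.0, La=578.0, ampar_density=1750.0,
                        glut_density=9500.0, seed=77)
    return spatial_opening_map(cfg, n_runs=60, root_seed=77)


class TestSpatialOpeningMap:
    def test_grid_is_seven_by_seven(self, fig7_map):
        # 385 nm PSD side / 55 nm cells -> 7 x 7 = 49 cells
        assert fig7_map.n_cells == 7
        assert fig7_map.fractions.shape == (4, 7, 7)

    def test_fractions_are_probabilities(self, fig7_map):
        f = fig7_map.fractions
        ok = np.isfinite(f)
        assert ((f[ok] >= 0) & (f[ok] <= 1)).all()

    def test_every_cell_opens_at_peak(self, fig7_map):
        """Even the most peripheral PSD cells open with the high-mobility
        transmitter (about 10% or more near the peak in the large synapse)."""
        peak = fig7_map.fractions[1]
        assert np.isfinite(peak).all()
        assert (peak > 0).all()
        assert np.nanmax(peak) > 0.1

    def test_center_opens_more_than_periphery_at_peak(self, fig7_map):
        peak = fig7_map.fractions[1]
        center = peak[3, 3]
        corners = [peak[0, 0], peak[0, 6], peak[6, 0], peak[6, 6]]
        assert center > np.mean(corners)

    def test_late_map_nearly_silent(self, fig7_map):
        late = fig7_map.fractions[3]
        assert np.nanmean(late) < 0.05
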