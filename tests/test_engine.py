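"""Brownian-dynamics engine: diffusion, reflection, binding, conservation.

The binding machinery is validated against independent mass-action /
Gillespie oracles in a well-mixed sealed box; diffusion against the
Einstein relation and the uniform stationary distribution over the ECS.
"""

import math

import numpy as np
import pytest

from cleftsim.engine import (
    SimParams,
    binding_probability_for_area,
    calibrate_binding_probability,
    default_schemes,
    displacement_sigma,
    run,
    run_batch,
)
from cleftsim.geometry import SynapseGeometry, build_geometry
from cleftsim.kinetics import KineticScheme, Transition, builtin_scheme
from cleftsim.population import SynapseConfig
from oracles import mass_action_binding


class TestDisplacementSigma:
    def test_reference_value(self):
        # sqrt(2 * 330 nm^2/us * 1 us)
        assert displacement_sigma(0.33, 1.0) == pytest.approx(25.6905, abs=1e-3)

    def test_zero_diffusion(self):
        assert displacement_sigma(0.0, 1.0) == 0.0

    def test_scales_with_sqrt_dt(self):
        assert displacement_sigma(0.33, 0.5) == pytest.approx(
            displacement_sigma(0.33, 1.0) / math.sqrt(2), rel=1e-12
        )


class TestBindingProbability:
    def test_zero_kon(self):
        assert calibrate_binding_probability(0.0, 0.33, 1.0, 2000.0) == 0.0

    def test_too_large_probability_advises_smaller_dt(self):
        with pytest.raises(ValueError, match="smaller time step"):
            binding_probability_for_area(1e12, 0.33, 1.0, 1.0)

    def test_matched_flux_independent_of_dt(self):
        """p(dt) x crossing rate(dt) is invariant: halving dt is free.

        The per-step crossing rate scales as E|dz| ~ sqrt(dt), and p is
        calibrated ~ sqrt(dt), so the association flux per unit time is
        unchanged (the calibration contract is < 2%; the identity is exact).
        """
        for dt in (1.0, 0.5, 0.25):
            p = binding_probability_for_area(1e7, 0.33, dt, 500.0)
            crossings_per_us = displacement_sigma(0.33, dt) * math.sqrt(2 / math.pi) / dt
            flux = p * crossings_per_us
            p1 = binding_probability_for_area(1e7, 0.33, 1.0, 500.0)
            flux1 = p1 * displacement_sigma(0.33, 1.0) * math.sqrt(2 / math.pi)
            assert flux == pytest.approx(flux1, rel=1e-12)


def _sticky_schemes(kon=1.0e6):
    """One-step irreversible binder standing in for the receptor scheme."""
    sticky = KineticScheme(
        name="sticky", states=("A", "AG"),
        transitions=(
            Transition("A", "AG", kon, order=2),
            Transition("AG", "A", 1e-9, releases_ligand=True),
        ),
        initial_state="A", open_state="AG", T_ref=35.0, Q10=2.5,
    )
    return {"ampa": sticky, "glut": builtin_scheme("glut")}


_CAL_KON = 1.0e6


@pytest.fixture(scope="module")
def box():
    """Mean bound-receptor curve of the sealed well-mixed calibration box."""
    cfg = SynapseConfig(id="box", Ls=200.0, La=200.0, ampar_density=2500.0,
                        glut_density=0.0, seed=9)
    geom = build_geometry(cfg)
    params = SimParams(T_total_ms=2.0, N_g=2000)
    batch = run_batch(cfg, 20, params=params, schemes=_sticky_schemes(_CAL_KON),
                      geom=geom)
    bound = np.mean([r.open_counts for r in batch.results], axis=0)
    return cfg, geom, params, bound


class TestWellMixedCalibration:
    """Engine association flux vs mass action in a sealed well-mixed box."""

    KON = _CAL_KON

    def test_flux_matches_mass_action_within_5_percent(self, box):
        cfg, geom, params, bound = box
        # compare after a 100 us mixing burn-in (release is a point source),
        # with the oracle initialized from the simulated state at that time
        t0 = 100
        grid = np.array([500, 1000, 1500, 1999])
        oracle = mass_action_binding(
            self.KON, geom.volume_ecs, params.N_g - bound[t0],
            cfg.nAMPA - bound[t0], (grid - t0) * 1e-6,
        )
        for t_us, extra in zip(grid, oracle):
            expected = bound[t0] + extra
            assert bound[t_us] == pytest.approx(expected, rel=0.05)

    def test_halved_dt_gives_same_flux(self, box):
        cfg, geom, params, bound = box
        params_h = SimParams(T_total_ms=2.0, N_g=2000, dt_us=0.5)
        batch = run_batch(cfg, 12, params=params_h, schemes=_sticky_schemes(self.KON),
                          geom=geom)
        bound_h = np.mean([r.open_counts for r in batch.results], axis=0)
        # Monte Carlo tolerance: ~40 bound of 2000 at 2 ms, se ~ 6%
        assert bound_h[3998] == pytest.approx(bound[1999], rel=0.15)


class TestReflect:
    def test_segment_clear_of_walls_is_unchanged(self):
        from cleftsim.engine import reflect

        geom = build_geometry(_cfg_reflect())
        start = np.array([0.0, 0.0, 10.0])  # mid-cleft
        end = reflect(geom, start, [3.0, -2.0, 1.0])
        np.testing.assert_allclose(end, [3.0, -2.0, 11.0])

    def test_perpendicular_incidence_mirrors(self):
        from cleftsim.engine import reflect

        geom = build_geometry(_cfg_reflect())
        # heading straight down from z = 5 with a 12 nm step: wall at z = 0
        # reflects the remaining 7 nm upward
        end = reflect(geom, [10.0, 10.0, 5.0], [0.0, 0.0, -12.0])
        assert end[2] == pytest.approx(7.0, abs=1e-3)
        assert end[0] == 10.0 and end[1] == 10.0
        assert geom.point_in_ecs(end)

    def test_final_position_always_in_ecs(self):
        from cleftsim.engine import reflect

        geom = build_geometry(_cfg_reflect())
        rng = np.random.default_rng(0)
        p = np.array([0.0, 0.0, 10.0])
        for _ in range(200):
            p = reflect(geom, p, rng.normal(0, 25.7, 3))
            assert geom.point_in_ecs(p)


def _cfg_reflect():
    return SynapseConfig(id="r", Ls=200.0, La=300.0, ampar_density=2000.0,
                         glut_density=9500.0, seed=0)


class TestDiffusion:
    def test_msd_matches_einstein_relation(self):
        """Free 3-D diffusion: MSD = 6 D t within 1% at 10^5 particles."""
        from cleftsim.engine import diffuse_tracers

        geom = SynapseGeometry(
            Ls=200.0, La=200.0, Hc=20.0, element_height=200.0,
            peri_gap=500_000.0, ecs_target=0.2, ecs_fraction=0.99,
        )
        n, steps = 100_000, 20
        start = np.zeros((n, 3))
        start[:, 2] = -250_000.0  # far from every wall
        params = SimParams()
        out = diffuse_tracers(geom, start.copy(), steps, params, seed=5,
                              sample_every=steps)
        disp = out[-n:] - start
        msd = float((disp**2).sum(axis=1).mean())
        expected = 6.0 * params.D_g * 1000.0 * steps  # nm^2
        assert msd == pytest.approx(expected, rel=0.01)
        assert abs(disp.mean()) < 1.0  # no drift

    def test_tracer_stationary_distribution_uniform_over_ecs(self):
        """Reflected tracers started uniform stay uniform (chi^2 on octants)."""
        from cleftsim.engine import diffuse_tracers

        cfg = SynapseConfig(id="u", Ls=300.0, La=450.0, ampar_density=2000.0,
                            glut_density=9500.0, seed=1)
        geom = build_geometry(cfg)
        rng = np.random.default_rng(11)
        n = 30_000
        pts = np.empty((0, 3))
        while pts.shape[0] < n:  # rejection-sample uniform ECS points
            cand = rng.uniform(geom.peri_lo, geom.peri_hi, size=(2 * n, 3))
            pts = np.vstack([pts, cand[geom.points_in_ecs(cand)]])
        pts = pts[:n]
        out = diffuse_tracers(geom, pts.copy(), 300, SimParams(), seed=6,
                              sample_every=300)
        assert geom.points_in_ecs(out).all()  # nobody inside a solid element
        # chi^2 against analytic octant ECS volumes
        mid = np.zeros(3)
        obs, exp = [], []
        for sx in (0, 1):
            for sy in (0, 1):
                for sz in (0, 1):
                    blo = np.where([sx, sy, sz], mid, geom.peri_lo)
                    bhi = np.where([sx, sy, sz], geom.peri_hi, mid)
                    sel = np.all(out >= blo, axis=1) & np.all(out < bhi, axis=1)
                    obs.append(sel.sum())
                    exp.append(geom.ecs_volume_in_box(blo, bhi))
        obs = np.array(obs, dtype=float)
        exp = np.array(exp) / sum(exp) * obs.sum()
        chi2 = float(((obs - exp) ** 2 / exp).sum())
        from scipy.stats import chi2 as chi2_dist

        assert chi2 < chi2_dist.ppf(0.999, df=7)


class TestRunInvariants:
    def test_initial_condition_and_bound(self, small_config):
        r = run(small_config, seed=0)
        assert r.open_counts[0] == 0
        assert r.open_counts.max() <= small_config.nAMPA
        assert r.maxOPEN == r.open_counts.max()
        assert r.auc >= r.maxOPEN * r.dt_us
        assert r.discarded_steps == 0

    def test_glutamate_conserved_every_step(self, small_config):
        """free + bound + removed = N_g; the kernel aborts on violation."""
        r = run(small_config, seed=1)
        # the kernel checks the identity internally each step; externally,
        # removed plus the final free count can never exceed the quantum
        assert r.removed + r.free_counts[-1] <= 3000
        assert r.removed > 0  # transporters did take up transmitter

    def test_sealed_synapse_never_loses_glutamate(self, small_config):
        """With [GluT] = 0 the box is sealed: nothing is ever removed."""
        cfg = SynapseConfig(id="sealed", Ls=150.0, La=225.0, ampar_density=2000.0,
                            glut_density=0.0, seed=3)
        params = SimParams(T_total_ms=2.0, N_g=500)
        r = run(cfg, params=params, seed=0)
        assert r.removed == 0
        # free never exceeds the quantum and never drains away
        assert r.free_counts[-1] + r.open_counts[-1] <= 500
        assert r.free_counts[-1] > 0

    def test_receptorless_synapse_never_opens(self, small_config):
        params = SimParams(T_total_ms=1.0, N_g=500)
        r = run(small_config, params=params, seed=2, nampa_override=0)
        assert not r.open_counts.any()

    def test_batch_determinism(self, small_config):
        params = SimParams(T_total_ms=1.0, N_g=1000)
        b1 = run_batch(small_config, 3, params=params)
        b2 = run_batch(small_config, 3, params=params)
        np.testing.assert_array_equal(b1.mean_curve, b2.mean_curve)
        for r1, r2 in zip(b1.results, b2.results):
            np.testing.assert_array_equal(r1.open_counts, r2.open_counts)
            assert r1.seed == r2.seed

    def test_single_run_reproducible_in_isolation(self, small_config):
        params = SimParams(T_total_ms=1.0, N_g=1000)
        batch = run_batch(small_config, 3, params=params)
        lone = run(small_config, params=params, seed=2)  # run index 2
        np.testing.assert_array_equal(lone.open_counts, batch.results[2].open_counts)

    def test_mean_curve_rises_then_decays(self, fig2_config):
        """Mean curve: fast rise, slower decay, long tail toward zero."""
        b = run_batch(fig2_config, 25)
        m = b.mean_curve
        peak = int(np.argmax(m))
        assert 0 < peak < 2000  # peak well inside the window
        # smoothed curve is unimodal: increases into the peak, decreases after
        w = 50
        sm = np.convolve(m, np.ones(w) / w, mode="valid")
        sp = int(np.argmax(sm))
        assert (np.diff(sm[:sp]) >= -1e-9).mean() > 0.9
        assert sm[-1] < 0.1 * sm[sp]  # long tail descending towards 0

    def test_mean_maxopen_monotone_in_receptor_count(self):
        """Doubling nAMPA does not decrease mean maxOPEN (20-run batches)."""
        base = SynapseConfig(id="m1", Ls=150.0, La=225.0, ampar_density=1200.0,
                             glut_density=9500.0, seed=5)
        double = SynapseConfig(id="m2", Ls=150.0, La=225.0, ampar_density=2400.0,
                               glut_density=9500.0, seed=5)
        b1 = run_batch(base, 20)
        b2 = run_batch(double, 20)
        assert b2.max_open_values.mean() >= b1.max_open_values.mean()

    def test_snapshot_recording(self, small_config):
        params = SimParams(T_total_ms=1.0, N_g=1000)
        r = run(small_config, params=params, seed=0, record_steps=[50, 100, 900])
        assert r.open_snapshots.shape == (3, small_config.nAMPA)
        assert r.receptor_xy.shape == (small_config.nAMPA, 2)
        # snapshot at the recorded step agrees with the open-count series
        for k, step in enumerate([50, 100, 900]):
            assert r.open_snapshots[k].sum() == r.open_counts[step]
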