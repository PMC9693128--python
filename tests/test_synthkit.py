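"""Simulator contracts: determinism, mass balance, endpoint modes, dip
structure, the dissolution model and the image renderer."""

import math

import numpy as np
import pytest

from pelletpat import synthkit
from pelletpat.synthkit import (
    CanvasOvercrowdedError,
    analytic_crossing_time,
    deposited_thickness,
    dissolution_closed_form,
    monodisperse_radius,
    render_pellet_image,
    shell_volume,
    simulate_dissolution,
    simulate_run,
    synthesize_covariate_table,
)
from pelletpat.types import CoatingRunConfig, ReleaseModelParams


class TestSimulateRun:
    def test_fixed_seed_is_bit_identical(self, p4_config):
        a = simulate_run(p4_config)
        b = simulate_run(p4_config)
        assert [(f.time, f.d50, f.se, f.n) for f in a[0]] == [
            (f.time, f.d50, f.se, f.n) for f in b[0]
        ]
        assert a[2] == b[2]

    def test_different_seeds_differ(self, p4_config):
        a, _, _ = simulate_run(p4_config)
        b, _, _ = simulate_run(p4_config.replace(seed=99))
        assert any(x.d50 != y.d50 for x, y in zip(a, b))

    def test_mass_conservation_at_endpoint(self, p4_config):
        """Deposited dry mass equals yield x dry fraction x consumed
        suspension to 1e-6 relative."""
        cfg = p4_config
        _, _, rec = simulate_run(cfg)
        r0 = monodisperse_radius(cfg.ssa_m_core, cfg.n_per_mass)
        n_pellets = cfg.n_per_mass * cfg.load_mass * 1000.0
        deposited_mg = (
            n_pellets * shell_volume(r0, rec.final_thickness_um)
            * cfg.coating_density * 1e-9
        )
        expected_mg = (
            cfg.process_yield * cfg.dry_fraction * rec.suspension_g * 1000.0
        )
        assert deposited_mg == pytest.approx(expected_mg, rel=1e-6)

    def test_p4_consumed_suspension_near_442_g(self, p4_config):
        _, _, rec = simulate_run(p4_config)
        assert rec.suspension_g == pytest.approx(442.0, rel=0.01)

    def test_zero_spray_rate_is_no_endpoint_with_zero_thickness(self, p4_config):
        cfg = p4_config.replace(spray_rate=0.0, max_duration=30.0)
        frames, _, rec = simulate_run(cfg)
        assert rec.endpoint_time_min is None
        assert not rec.reached_endpoint
        assert rec.final_thickness_um == 0.0
        assert rec.suspension_g == 0.0
        assert frames  # the run still produces frames up to max_duration

    def test_mass_endpoint_consumes_exactly_the_target(self):
        cfg = CoatingRunConfig(endpoint_mode="mass", suspension_mass=463.0, seed=4)
        _, _, rec = simulate_run(cfg)
        assert rec.suspension_g == 463.0
        assert rec.endpoint_time_min == pytest.approx(
            cfg.dip_duration + 463.0 / cfg.spray_rate
        )

    def test_frames_ordered_with_counts_in_range(self, p4_config):
        frames, _, _ = simulate_run(p4_config)
        times = [f.time for f in frames]
        assert times == sorted(times) and len(set(times)) == len(times)
        lo, hi = p4_config.frame_particle_count_range
        assert all(lo <= f.n <= hi for f in frames)

    def test_dip_minimum_precedes_growth(self):
        """The D50 series dips by about dip_depth in the warm-up phase and
        recovers past the start value during coating."""
        cfg = CoatingRunConfig(seed=7)
        frames, _, _ = simulate_run(cfg)
        d50 = np.array([f.d50 for f in frames])
        t_min = frames[int(np.argmin(d50))].time
        assert abs(t_min - cfg.dip_duration) <= 2.0
        assert d50.min() < d50[0] - cfg.dip_depth / 2
        assert d50[-1] > d50[0]

    def test_true_thickness_stop_matches_analytic_crossing(self, p4_config):
        _, _, rec = simulate_run(p4_config)
        assert rec.endpoint_time_min == pytest.approx(
            analytic_crossing_time(p4_config)
        )

    def test_deposited_thickness_is_monotone_and_sublinear(self, p4_config):
        t = np.linspace(0.0, 40.0, 41)
        h = np.array([deposited_thickness(p4_config, ti) for ti in t])
        assert np.all(np.diff(h) > 0)
        # shell geometry: a growing sphere needs more volume per um
        assert np.all(np.diff(h, 2) < 0)

    def test_lod_relaxes_toward_equilibrium(self):
        cfg = CoatingRunConfig(seed=0, lod_start=1.74, lod_equilibrium=0.70)
        _, lod, rec = simulate_run(cfg)
        assert lod.values[0] < cfg.lod_start
        assert np.all(np.diff(lod.values) < 0)
        assert cfg.lod_equilibrium < rec.lod_finish_pct < cfg.lod_start

    def test_unreachable_thickness_before_max_duration_is_no_endpoint(self):
        cfg = CoatingRunConfig(
            endpoint_mode="true_thickness", target_thickness=50.0, max_duration=20.0
        )
        _, _, rec = simulate_run(cfg)
        assert rec.endpoint_time_min is None

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            CoatingRunConfig(load_mass=-1.0)
        with pytest.raises(ValueError):
            CoatingRunConfig(process_yield=1.5)
        with pytest.raises(ValueError):
            CoatingRunConfig(dry_fraction=1.0)
        with pytest.raises(ValueError):
            CoatingRunConfig(endpoint_mode="mass")  # missing suspension_mass


class TestDissolution:
    def _params(self, **kw) -> ReleaseModelParams:
        base = dict(
            surface=1.057e9,
            thickness=8.0,
            permeability_scale=0.30,
            gradient=2.0e-10,
            dose=100.0,
            coating_density=1.76,
        )
        base.update(kw)
        return ReleaseModelParams(**base)

    def test_doubling_thickness_halves_initial_rate(self):
        t = np.array([0.5])
        r1 = dissolution_closed_form(self._params(), t)[0]
        r2 = dissolution_closed_form(self._params(thickness=16.0), t)[0]
        assert r2 == pytest.approx(r1 / 2.0, rel=1e-12)

    def test_doubling_density_halves_initial_rate(self):
        """Permeability is inversely tied to film density: K = k / rho."""
        t = np.array([0.5])
        r1 = dissolution_closed_form(self._params(), t)[0]
        r2 = dissolution_closed_form(self._params(coating_density=3.52), t)[0]
        assert r2 == pytest.approx(r1 / 2.0, rel=1e-12)

    def test_closed_form_matches_fine_step_integration(self):
        """Independent oracle: explicit Euler at dt = 1e-4 h on the
        reservoir ODE (constant rate while solid drug remains, linear
        depletion of the residual reservoir afterwards)."""
        p = self._params()
        rate = p.surface / p.thickness * p.permeability * p.gradient * 3600.0
        m_c = p.sink_fraction * p.dose
        tau = (p.dose - m_c) / rate
        dt, t_end = 1e-4, 8.0
        steps = int(t_end / dt)
        m = 0.0
        grid = np.arange(1, steps + 1) * dt
        out = np.empty(steps)
        for i in range(steps):
            dmdt = rate if m < m_c else (p.dose - m) / tau
            m += dmdt * dt
            out[i] = m
        want = np.interp([2.0, 4.0, 6.0, 7.5], grid, 100.0 * out / p.dose)
        got = dissolution_closed_form(p, np.array([2.0, 4.0, 6.0, 7.5]))
        np.testing.assert_allclose(got, want, atol=0.02)

    def test_noisy_profile_is_monotone_and_bounded(self, rng):
        prof = simulate_dissolution(self._params(), rng=rng, noise_sd=2.0)
        assert np.all(np.diff(prof.released) >= 0)
        assert np.all((prof.released >= 0) & (prof.released <= 100))

    def test_zero_thickness_rejected(self):
        with pytest.raises(ValueError):
            self._params(thickness=0.0)

    def test_decreasing_times_rejected(self):
        with pytest.raises(ValueError):
            simulate_dissolution(self._params(), times_h=[2.0, 1.0])


class TestRenderer:
    def test_single_circle_ground_truth_area(self):
        img, truth = render_pellet_image([50.0], canvas_px=(848, 848), seed=0)
        assert len(truth) == 1
        assert truth.area_px2.iloc[0] == pytest.approx(math.pi * 25.0**2)
        # pixel mass at half-threshold reproduces the area within AA tolerance
        assert (img > 127).sum() == pytest.approx(math.pi * 25.0**2, rel=0.02)

    def test_hundred_ellipses_yield_hundred_truth_rows(self):
        d = np.linspace(20, 60, 100)
        img, truth = render_pellet_image(
            d, aspect_ratios=np.full(100, 0.8), canvas_px=(848, 848), seed=1
        )
        assert len(truth) == 100
        assert img.shape == (848, 848)

    def test_fixed_seed_gives_identical_image_bytes(self):
        a, _ = render_pellet_image([30.0, 40.0], canvas_px=(200, 200), seed=3)
        b, _ = render_pellet_image([30.0, 40.0], canvas_px=(200, 200), seed=3)
        assert np.array_equal(a, b)

    def test_overcrowded_canvas_reported(self):
        with pytest.raises(CanvasOvercrowdedError):
            render_pellet_image([80.0] * 50, canvas_px=(200, 200), seed=0)


class TestCovariateTable:
    def test_release_tracks_delta_lod(self):
        df = synthesize_covariate_table(n_runs=8, seed=0)
        assert len(df) == 8
        assert np.all((df.released_6h >= 0) & (df.released_6h <= 100))
        # noiseless trend dominates: higher water loss, slower release
        assert np.corrcoef(df.delta_lod, df.released_6h)[0, 1] < -0.9

    def test_too_few_runs_rejected(self):
        with pytest.raises(ValueError):
            synthesize_covariate_table(n_runs=2)
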