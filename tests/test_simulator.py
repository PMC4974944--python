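"""Agent-based survey simulation: movement, detection and encounter rates."""

import math

import numpy as np
import pytest
from scipy import stats

from grem.geometry import SensorSpec, SignalSpec, TWO_PI, is_detected, mean_profile_closed
from grem.simulator import (
    MovementModel,
    SimConfig,
    SimulationTimeout,
    StepLengthModel,
    advance_step,
    detect_on_segment,
    init_population,
    run_survey,
    run_until_captures,
)

R = 0.01


def small_config(**kw):
    """1 km arena (70 animals), short survey; defaults otherwise."""
    base = dict(arena_side=1.0, n_steps=1440, seed=0)
    base.update(kw)
    return SimConfig(**base)


class TestConfigAndPopulation:
    def test_canonical_population_count(self):
        # floor(7.5^2 * 70) animals on the full-size arena
        assert SimConfig().n_animals == 3937

    def test_small_arena_count(self):
        assert small_config().n_animals == 70

    def test_zero_density_empty_population(self):
        cfg = small_config(density=0.0)
        pos, head = init_population(cfg, np.random.default_rng(0))
        assert len(pos) == 0 and len(head) == 0
        assert run_survey(cfg).z == 0

    def test_canonical_duration_150_days(self):
        assert SimConfig().t_total == pytest.approx(150.0)

    def test_step_length_parameters(self):
        cfg = SimConfig()
        assert cfg.mu_d == pytest.approx(40 * 15 / 1440)  # ~0.41667 km
        assert cfg.sigma_d == pytest.approx(cfg.mu_d / 10)
        with pytest.raises(ValueError):
            StepLengthModel(0.0)

    def test_placement_uniform_on_torus(self):
        cfg = small_config()
        pos, head = init_population(cfg, np.random.default_rng(1))
        assert ((pos >= 0) & (pos < cfg.arena_side)).all()
        assert ((head >= 0) & (head < TWO_PI)).all()

    def test_arena_step_guard(self):
        with pytest.raises(ValueError):
            SimConfig(arena_side=0.5)  # one step can span half this torus


class TestAdvanceStep:
    def test_straight_line_headings_constant(self):
        rng = np.random.default_rng(2)
        cfg = small_config()
        pos, head = init_population(cfg, rng)
        sl = StepLengthModel(cfg.mu_d)
        for _ in range(20):
            pos, new_head, moving = advance_step(pos, head, MovementModel(), sl, rng, cfg.arena_side)
            assert np.array_equal(new_head, head)
            assert moving.all()
            head = new_head
        assert ((pos >= 0) & (pos < cfg.arena_side)).all()

    def test_step_lengths_normal(self):
        """With S = A = 0, per-step displacements follow Normal(vT, vT/10)."""
        rng = np.random.default_rng(3)
        cfg = small_config()
        pos, head = init_population(cfg, rng)
        sl = StepLengthModel(cfg.mu_d)
        ds = []
        for _ in range(80):
            new_pos, head, _ = advance_step(pos, head, MovementModel(), sl, rng, cfg.arena_side)
            step = np.mod(new_pos - pos + cfg.arena_side / 2, cfg.arena_side) - cfg.arena_side / 2
            ds.append(np.hypot(step[:, 0], step[:, 1]))
            pos = new_pos
        ds = np.concatenate(ds)
        p = stats.kstest(ds, "norm", args=(cfg.mu_d, cfg.sigma_d)).pvalue
        assert p > 0.01

    def test_stationary_probability(self):
        rng = np.random.default_rng(4)
        cfg = small_config()
        pos, head = init_population(cfg, rng)
        sl = StepLengthModel(cfg.mu_d)
        new_pos, _, moving = advance_step(
            pos, head, MovementModel(stationary_prob=0.75), sl, rng, cfg.arena_side
        )
        frozen = (new_pos == pos).all(axis=1)
        assert frozen[~moving].all()
        # 70 animals: crude binomial check on the stationary fraction
        assert 0.5 < (~moving).mean() < 0.95

    def test_turning_bounded(self):
        rng = np.random.default_rng(5)
        cfg = small_config()
        pos, head = init_population(cfg, rng)
        sl = StepLengthModel(cfg.mu_d)
        A = math.pi / 3
        _, new_head, _ = advance_step(pos, head, MovementModel(0.0, A), sl, rng, cfg.arena_side)
        assert (np.abs(new_head - head) <= A).all()


class TestDetectOnSegment:
    sensor = SensorSpec(TWO_PI, R)
    signal = SignalSpec(TWO_PI)

    def test_pass_through_sensor_one_encounter(self):
        ev, armed = detect_on_segment((-5 * R, 0), (5 * R, 0), 0.0, self.sensor, self.signal, True)
        assert len(ev) == 1
        assert armed  # exits the disc, so re-armed

    def test_outside_radius_no_encounter(self):
        ev, armed = detect_on_segment((-5 * R, 2 * R), (5 * R, 2 * R), 0.0, self.sensor, self.signal, True)
        assert ev == [] and armed is True

    def test_disarmed_pass_not_counted(self):
        ev, armed = detect_on_segment((-0.5 * R, 0), (5 * R, 0), 0.0, self.sensor, self.signal, False)
        assert ev == []
        assert armed  # exit re-arms

    def test_encounter_position_is_detected(self):
        sig = SignalSpec(math.pi / 2)
        ev, _ = detect_on_segment((-5 * R, 0.2 * R), (5 * R, 0.2 * R), 0.0, self.sensor, sig, True)
        assert len(ev) == 1
        s, frac, pos, heading = ev[0]
        assert 0.0 <= frac <= 1.0
        assert is_detected(pos + 1e-9 * np.array([1.0, 0.0]), heading, self.sensor, sig)

    @pytest.mark.parametrize("seed", range(30))
    def test_exact_detection_agrees_with_dense_sampling(self, seed):
        """At most one encounter per pass, and the exact interval logic finds
        a detection iff dense pointwise sampling of the segment does."""
        rng = np.random.default_rng(seed)
        theta = rng.uniform(0.3, TWO_PI)
        alpha = rng.uniform(0.3, TWO_PI)
        sensor, signal = SensorSpec(theta, R), SignalSpec(alpha)
        p0 = rng.uniform(-2 * R, 2 * R, 2)
        gamma = rng.uniform(0, TWO_PI)
        d = rng.uniform(0.5 * R, 6 * R)
        p1 = p0 + d * np.array([math.cos(gamma), math.sin(gamma)])
        ev, _ = detect_on_segment(p0, p1, gamma, sensor, signal, True)
        assert len(ev) <= 1
        s = np.linspace(0, 1, 4001)[:, None]
        pts = p0[None, :] * (1 - s) + p1[None, :] * s
        dense = bool(is_detected(pts, gamma, sensor, signal).any())
        if dense:
            assert len(ev) == 1
        if not ev:
            assert not dense


class TestSurveys:
    def test_reproducible_bit_identical(self):
        a = run_survey(small_config(seed=9)).encounters
        b = run_survey(small_config(seed=9)).encounters
        assert a.equals(b)

    def test_gas_rate_matches_ideal_gas(self):
        """Mean encounter count across replicates matches z = 2 r v t D."""
        zs = [run_survey(small_config(seed=s)).z for s in range(8)]
        expected = 2 * R * 40 * 15 * 70  # 840
        se = np.std(zs, ddof=1) / math.sqrt(len(zs))
        assert abs(np.mean(zs) - expected) < 3 * se + 1

    def test_directional_rate_matches_mean_profile(self):
        """General geometry: encounter rate matches p_bar * v * D."""
        theta, alpha = 8 * math.pi / 9, 6 * math.pi / 11
        sensor, signal = SensorSpec(theta, R), SignalSpec(alpha)
        zs = [
            run_survey(small_config(seed=100 + s, sensor=sensor, signal=signal)).z
            for s in range(8)
        ]
        p_bar = mean_profile_closed(sensor, signal).p_bar
        expected = p_bar * 40 * 15 * 70
        se = np.std(zs, ddof=1) / math.sqrt(len(zs))
        assert abs(np.mean(zs) - expected) < 3 * se + 1

    def test_count_scales_with_density(self):
        means = []
        for dens in (17.5, 35.0, 70.0):
            zs = [
                run_survey(small_config(seed=200 + s, density=dens, n_steps=720)).z
                for s in range(4)
            ]
            means.append(np.mean(zs))
        slope = np.polyfit([17.5, 35.0, 70.0], means, 1)[0]
        expected_slope = 2 * R * 40 * 7.5  # z per unit density over 7.5 days
        assert slope == pytest.approx(expected_slope, rel=0.2)

    def test_stop_start_rate_scales_with_moving_fraction(self):
        zs = [
            run_survey(small_config(seed=300 + s, movement=MovementModel(0.5, 0.0))).z
            for s in range(6)
        ]
        expected = 2 * R * 40 * 0.5 * 15 * 70
        se = np.std(zs, ddof=1) / math.sqrt(len(zs))
        assert abs(np.mean(zs) - expected) < 4 * se + 2


class TestRunUntilCaptures:
    def test_returns_target_and_interpolated_time(self):
        res = run_until_captures(small_config(seed=11), 25)
        assert res.z == 25
        assert len(res.encounters) == 25
        assert res.t_total == pytest.approx(res.encounters["time"].iloc[-1])
        assert res.encounters["time"].is_monotonic_increasing

    def test_waiting_time_matches_gas_rate(self):
        """Mean time to the n-th capture is about n / (2 r v D)."""
        n = 25
        ts = [run_until_captures(small_config(seed=400 + s), n).t_total for s in range(10)]
        rate = 2 * R * 40 * 70  # per day
        se = np.std(ts, ddof=1) / math.sqrt(len(ts))
        assert abs(np.mean(ts) - n / rate) < 3 * se + 0.05

    def test_timeout_guard(self):
        cfg = small_config(sensor=SensorSpec(0.05, R), signal=SignalSpec(0.05))
        with pytest.raises(SimulationTimeout):
            run_until_captures(cfg, 1000, max_steps=50)
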