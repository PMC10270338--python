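"""Synthetic generators and preprocessing: bounds, lengths, periodicity, plants."""

import math

import numpy as np
import pytest

from mpnoise import (
    GeneratorSpec,
    MPConfig,
    Plant,
    acceleration_magnitude,
    compute_matrix_profile,
    gen_calf_like,
    gen_keystroke_like,
    gen_planted,
    gen_traffic_like,
    locate_motif_discord,
    resample_fixed_interval,
)


class TestAccelerationMagnitude:
    def test_pythagorean_triple(self):
        assert acceleration_magnitude((3.0, 4.0, 12.0)) == pytest.approx(13.0)

    def test_zero_vector(self):
        assert acceleration_magnitude((0.0, 0.0, 0.0)) == 0.0

    def test_unit_components(self):
        assert acceleration_magnitude((1.0, 1.0, 1.0)) == pytest.approx(math.sqrt(3))

    def test_rotation_invariance(self, rng):
        v = rng.standard_normal(3)
        q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        assert acceleration_magnitude(q @ v) == pytest.approx(
            acceleration_magnitude(v), rel=1e-10
        )

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            acceleration_magnitude((np.nan, 0.0, 0.0))


class TestResampling:
    def test_constant_trace_mean(self):
        t = np.arange(0, 120, 1 / 12.5)
        ts = resample_fixed_interval(t, np.full(t.size, 2.0), 60.0, agg="mean")
        np.testing.assert_allclose(ts.values, [2.0, 2.0])

    def test_one_minute_at_accelerometer_rate_is_one_bin(self):
        t = np.arange(750) / 12.5
        ts = resample_fixed_interval(t, np.ones(750), 60.0, agg="sum")
        assert ts.n == 1
        assert ts.values[0] == 750.0

    def test_42_days_of_minutes(self):
        t = np.arange(42 * 1440) * 60.0
        ts = resample_fixed_interval(t, np.ones(t.size), 60.0, agg="mean")
        assert ts.n == 60_480

    def test_piecewise_constant_round_trip(self, rng):
        levels = rng.uniform(0, 5, 6)
        t = np.arange(6 * 10) * 1.0
        v = np.repeat(levels, 10)
        ts = resample_fixed_interval(t, v, 10.0, agg="mean")
        np.testing.assert_allclose(ts.values, levels)

    def test_empty_bin_policies(self):
        t = np.array([0.0, 1.0, 25.0])  # bin 1 (seconds 10-20) is empty
        v = np.array([4.0, 6.0, 9.0])
        mean_ts = resample_fixed_interval(t, v, 10.0, agg="mean")
        np.testing.assert_allclose(mean_ts.values, [5.0, 5.0, 9.0])  # carry previous
        sum_ts = resample_fixed_interval(t, v, 10.0, agg="sum")
        np.testing.assert_allclose(sum_ts.values, [10.0, 0.0, 9.0])  # zero fill

    def test_rejects_unsorted_or_zero_interval(self):
        with pytest.raises(ValueError):
            resample_fixed_interval([1.0, 0.5], [1.0, 2.0], 10.0)
        with pytest.raises(ValueError):
            resample_fixed_interval([0.0, 1.0], [1.0, 2.0], 0.0)


class TestKeystrokeGenerator:
    def test_values_bounded_and_positive(self):
        ts = gen_keystroke_like(GeneratorSpec(family="keystroke", n=5000, seed=3))
        assert ts.n == 5000
        assert ts.values.min() > 0
        assert ts.values.max() <= 1000.0

    def test_deterministic_under_seed(self):
        spec = GeneratorSpec(family="keystroke", n=1000, seed=7)
        np.testing.assert_array_equal(
            gen_keystroke_like(spec).values, gen_keystroke_like(spec).values
        )

    def test_planted_pattern_is_the_profile_minimum(self):
        plant = Plant(kind="motif", positions=(100, 700), length=20)
        spec = GeneratorSpec(family="keystroke", n=2000, seed=11, plants=(plant,))
        ts = gen_keystroke_like(spec)
        mp = compute_matrix_profile(ts, MPConfig(window=20))
        motif, _ = locate_motif_discord(mp)
        assert min(abs(motif[0] - p) for p in (100, 700)) <= 20
        assert min(abs(motif[1] - p) for p in (100, 700)) <= 20


class TestCalfGenerator:
    def test_six_weeks_yield_60480_minutes(self):
        ts = gen_calf_like(GeneratorSpec(family="calf", duration_days=42, seed=1))
        assert ts.n == 60_480
        assert np.all(ts.values >= 0)

    def test_circadian_autocorrelation(self):
        ts = gen_calf_like(GeneratorSpec(family="calf", duration_days=4, seed=5))
        x = ts.values - ts.values.mean()
        def acf(lag):
            return float(np.dot(x[:-lag], x[lag:]) / np.dot(x, x))
        assert acf(1440) > acf(720)

    def test_deterministic_under_seed(self):
        spec = GeneratorSpec(family="calf", duration_days=1, seed=2)
        np.testing.assert_array_equal(gen_calf_like(spec).values, gen_calf_like(spec).values)


class TestTrafficGenerator:
    def test_default_length_and_counts(self):
        ts = gen_traffic_like(GeneratorSpec(family="traffic", seed=4))
        assert ts.n == 3600
        assert np.all(ts.values >= 0)

    def test_deterministic_under_seed(self):
        spec = GeneratorSpec(family="traffic", n=480, seed=9)
        np.testing.assert_array_equal(
            gen_traffic_like(spec).values, gen_traffic_like(spec).values
        )

    def test_daily_periodicity_dominates(self):
        ts = gen_traffic_like(GeneratorSpec(family="traffic", n=720, seed=2))
        x = ts.values - ts.values.mean()
        acf24 = np.dot(x[:-24], x[24:]) / np.dot(x, x)
        acf12 = np.dot(x[:-12], x[12:]) / np.dot(x, x)
        assert acf24 > acf12

    def test_anomalous_day_is_the_discord(self):
        spec = GeneratorSpec(family="traffic", n=720, seed=6, anomalous_days=(12,))
        ts = gen_traffic_like(spec)
        mp = compute_matrix_profile(ts, MPConfig(window=24))
        _, discord = locate_motif_discord(mp)
        assert abs(discord - 12 * 24) <= 24

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            gen_traffic_like(GeneratorSpec(family="traffic", n=30))


class TestPlantedGenerator:
    def test_zero_plants_gives_empty_ground_truth(self):
        ts, truth = gen_planted(GeneratorSpec(family="planted", n=256, seed=0))
        assert truth == ()
        assert ts.n == 256

    def test_motif_recovery(self):
        hits = 0
        for seed in range(20):
            plant = Plant(kind="motif", positions=(60, 350), length=16)
            ts, _ = gen_planted(GeneratorSpec(family="planted", n=512, seed=seed, plants=(plant,)))
            mp = compute_matrix_profile(ts, MPConfig(window=16))
            motif, _ = locate_motif_discord(mp)
            if min(abs(motif[0] - p) for p in (60, 350)) <= 16:
                hits += 1
        assert hits >= 19

    def test_discord_recovery(self):
        hits = 0
        for seed in range(20):
            plant = Plant(kind="discord", positions=(200,), length=16)
            ts, _ = gen_planted(GeneratorSpec(family="planted", n=512, seed=seed, plants=(plant,)))
            mp = compute_matrix_profile(ts, MPConfig(window=16))
            _, discord = locate_motif_discord(mp)
            if abs(discord - 200) <= 16:
                hits += 1
        assert hits >= 19

    def test_overlapping_plants_rejected(self):
        plants = (
            Plant(kind="motif", positions=(10, 20), length=16),
        )
        with pytest.raises(ValueError):
            gen_planted(GeneratorSpec(family="planted", n=256, plants=plants))

    def test_out_of_bounds_plant_rejected(self):
        plant = Plant(kind="discord", positions=(250,), length=16)
        with pytest.raises(ValueError):
            gen_planted(GeneratorSpec(family="planted", n=256, plants=(plant,)))
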