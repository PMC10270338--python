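"""Matrix-profile core: distances, profiles, summaries, motif/discord location."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mpnoise import (
    MPConfig,
    MatrixProfile,
    TimeSeries,
    compute_matrix_profile,
    distance_profile,
    locate_motif_discord,
    mp_summary,
    z_normalised_distance,
)

from conftest import brute_force_mp, znorm_distance_oracle


class TestZNormalisedDistance:
    def test_identical_windows_are_at_distance_zero(self, rng):
        a = rng.standard_normal(16)
        assert z_normalised_distance(a, a) == pytest.approx(0.0, abs=1e-12)

    def test_affine_invariance(self, rng):
        a = rng.standard_normal(12)
        assert z_normalised_distance(a, 3.0 * a + 7.0) == pytest.approx(0.0, abs=1e-9)

    def test_matches_elementwise_formula(self, rng):
        for _ in range(20):
            a, b = rng.standard_normal(4), rng.standard_normal(4)
            assert z_normalised_distance(a, b) == pytest.approx(
                znorm_distance_oracle(a, b), abs=1e-10
            )

    def test_zero_variance_conventions(self):
        const = np.full(8, 3.0)
        assert z_normalised_distance(const, const + 4) == 0.0
        varying = np.arange(8.0)
        assert z_normalised_distance(const, varying) == pytest.approx(math.sqrt(8))

    def test_rejects_mismatched_or_short_windows(self):
        with pytest.raises(ValueError):
            z_normalised_distance([1.0, 2.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            z_normalised_distance([1.0], [2.0])


class TestDistanceProfile:
    def test_length_and_self_distance(self, rng):
        series = TimeSeries(rng.standard_normal(100))
        cfg = MPConfig(window=20)
        d = distance_profile(series, 5, cfg, mask_exclusion=False)
        assert d.size == 81
        assert d[5] == pytest.approx(0.0, abs=1e-9)

    def test_exclusion_zone_is_masked(self, rng):
        series = TimeSeries(rng.standard_normal(64))
        cfg = MPConfig(window=8)
        d = distance_profile(series, 10, cfg)
        excl = cfg.resolved_exclusion
        assert np.all(np.isinf(d[10 - excl : 10 + excl + 1]))

    def test_equals_naive_per_window_loop(self, rng):
        x = rng.standard_normal(128)
        series = TimeSeries(x)
        m = 10
        d = distance_profile(series, 40, MPConfig(window=m), mask_exclusion=False)
        naive = [znorm_distance_oracle(x[40 : 40 + m], x[j : j + m]) for j in range(119)]
        np.testing.assert_allclose(d, naive, atol=1e-8)

    def test_query_out_of_range(self, rng):
        series = TimeSeries(rng.standard_normal(50))
        with pytest.raises(ValueError):
            distance_profile(series, 48, MPConfig(window=10))


class TestComputeMatrixProfile:
    def test_profile_length_is_n_minus_m_plus_one(self, rng):
        series = TimeSeries(rng.standard_normal(100))
        mp = compute_matrix_profile(series, MPConfig(window=20))
        assert len(mp) == 81
        assert mp.values.size == mp.indices.size == 81

    def test_matches_brute_force(self, rng):
        for _ in range(5):
            n, m = int(rng.integers(60, 201)), int(rng.integers(4, 13))
            x = rng.standard_normal(n)
            cfg = MPConfig(window=m)
            mp = compute_matrix_profile(TimeSeries(x), cfg)
            bv, _ = brute_force_mp(x, m, cfg.resolved_exclusion)
            assert np.abs(mp.values - bv).max() < 1e-8

    def test_planted_pair_has_lowest_profile_values(self, rng):
        m = 12
        x = rng.standard_normal(240)
        pattern = rng.standard_normal(m)
        x[30 : 30 + m] = pattern
        x[170 : 170 + m] = pattern
        mp = compute_matrix_profile(TimeSeries(x), MPConfig(window=m))
        others = np.delete(mp.values, [30, 170])
        assert mp.values[30] < others.min()
        assert mp.values[170] < others.min()

    def test_values_within_z_normalised_bound(self, rng):
        for m in (4, 8, 16):
            series = TimeSeries(rng.standard_normal(150))
            mp = compute_matrix_profile(series, MPConfig(window=m))
            assert np.all(mp.values >= 0)
            assert np.all(mp.values <= 2 * math.sqrt(m) + 1e-9)

    def test_exclusion_zone_respected_in_indices(self, rng):
        series = TimeSeries(rng.standard_normal(160))
        cfg = MPConfig(window=8)
        mp = compute_matrix_profile(series, cfg)
        gaps = np.abs(mp.indices - np.arange(len(mp)))
        assert gaps.min() > cfg.resolved_exclusion

    def test_strictly_periodic_series_has_near_zero_profile(self):
        period = 32
        base = np.sin(2 * np.pi * np.arange(period) / period) + 0.3 * np.cos(
            6 * np.pi * np.arange(period) / period
        )
        x = np.tile(base, 8)
        mp = compute_matrix_profile(TimeSeries(x), MPConfig(window=16))
        assert np.all(mp.values < 1e-6)

    def test_rejects_short_series_and_nonfinite(self, rng):
        with pytest.raises(ValueError):
            compute_matrix_profile(TimeSeries(rng.standard_normal(30)), MPConfig(window=20))
        with pytest.raises(ValueError):
            TimeSeries(np.array([1.0, np.nan, 2.0]))

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(
        n=st.integers(min_value=64, max_value=200),
        m=st.integers(min_value=4, max_value=16),
        seed=st.integers(min_value=0, max_value=2**20),
    )
    def test_length_and_bound_properties(self, n, m, seed):
        x = np.random.default_rng(seed).standard_normal(n)
        mp = compute_matrix_profile(TimeSeries(x), MPConfig(window=m))
        assert len(mp) == n - m + 1
        assert np.all((mp.values >= 0) & (mp.values <= 2 * math.sqrt(m) + 1e-9))


class TestSummaryAndLocation:
    def test_summary_of_simple_profile(self):
        mp = MatrixProfile([1.0, 2.0, 3.0], [2, 0, 0], window=2, source_length=4)
        s = mp_summary(mp)
        assert (s.mean, s.max, s.min) == (2.0, 3.0, 1.0)

    def test_summary_of_constant_profile(self):
        mp = MatrixProfile([0.7] * 5, [2, 3, 0, 1, 2], window=3, source_length=7)
        s = mp_summary(mp)
        assert s.mean == s.max == s.min == 0.7

    def test_motif_and_discord_from_values(self):
        mp = MatrixProfile([5.0, 1.0, 7.0, 1.0], [2, 3, 0, 1], window=2, source_length=5)
        motif, discord = locate_motif_discord(mp)
        assert motif == (1, 3)
        assert discord == 2

    def test_ties_break_to_lowest_index(self):
        mp = MatrixProfile([2.0, 2.0, 2.0], [2, 0, 0], window=2, source_length=4)
        motif, discord = locate_motif_discord(mp)
        assert motif == (0, 2)
        assert discord == 0

    def test_profile_invariant_on_length(self):
        with pytest.raises(ValueError):
            MatrixProfile([1.0, 2.0], [1, 0], window=3, source_length=6)
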