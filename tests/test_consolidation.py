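import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from circafly.consolidation import (
    CycleLengthChoice,
    DegenerateCycleError,
    UnknownFlyError,
    cycle_set_daily_r,
    daily_r,
    mean_daily_r,
    partition_cycles,
    select_cycle_length,
)
from circafly.dam_io import AgeWindow
from circafly.periodogram import RhythmCall

from conftest import make_series


def brute_force_r(theta, counts):
    """Independent scalar-loop mean-resultant-length oracle."""
    sx = sy = sa = 0.0
    for t, a in zip(theta, counts):
        sx += a * math.cos(t)
        sy += a * math.sin(t)
        sa += a
    if sa == 0:
        return float("nan")
    return math.sqrt((sx / sa) ** 2 + (sy / sa) ** 2)


class TestDailyR:
    def test_single_active_bin_fully_consolidated(self):
        theta = np.linspace(0, 2 * np.pi, 72, endpoint=False)
        counts = np.zeros(72)
        counts[17] = 42
        assert daily_r(theta, counts) == pytest.approx(1.0, abs=1e-12)

    def test_uniform_activity_fully_dispersed(self):
        theta = np.linspace(0, 2 * np.pi, 72, endpoint=False)
        assert daily_r(theta, np.full(72, 7.0)) == pytest.approx(0.0, abs=1e-12)

    def test_two_equal_orthogonal_bins(self):
        r = daily_r(np.array([0.0, np.pi / 2]), np.array([3.0, 3.0]))
        assert r == pytest.approx(math.sqrt(0.5), abs=1e-12)

    def test_zero_activity_cycle_is_missing(self):
        assert math.isnan(daily_r(np.array([0.0, 1.0]), np.array([0.0, 0.0])))

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(31)
        for _ in range(100):
            n = rng.integers(2, 80)
            theta = rng.uniform(0, 2 * np.pi, n)
            counts = rng.poisson(3.0, n).astype(float)
            expected = brute_force_r(theta, counts)
            got = daily_r(theta, counts)
            if math.isnan(expected):
                assert math.isnan(got)
            else:
                assert got == pytest.approx(expected, abs=1e-12)

    @given(
        shift=st.floats(0, 2 * math.pi, allow_nan=False),
        seed=st.integers(0, 10_000),
    )
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_rotation_invariance(self, shift, seed):
        rng = np.random.default_rng(seed)
        theta = rng.uniform(0, 2 * np.pi, 36)
        counts = rng.poisson(4.0, 36) + 1.0
        r0 = daily_r(theta, counts)
        r1 = daily_r(np.mod(theta + shift, 2 * np.pi), counts)
        assert r1 == pytest.approx(r0, abs=1e-12)

    @given(
        scale=st.floats(1e-3, 1e3, allow_nan=False),
        seed=st.integers(0, 10_000),
    )
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_scale_invariance(self, scale, seed):
        rng = np.random.default_rng(seed)
        theta = rng.uniform(0, 2 * np.pi, 36)
        counts = rng.poisson(4.0, 36) + 1.0
        assert daily_r(theta, counts * scale) == pytest.approx(
            daily_r(theta, counts), rel=1e-9
        )

    def test_bounded_in_unit_interval(self):
        rng = np.random.default_rng(8)
        for _ in range(200):
            theta = rng.uniform(0, 2 * np.pi, 24)
            counts = rng.poisson(2.0, 24).astype(float)
            r = daily_r(theta, counts)
            if not math.isnan(r):
                assert 0.0 <= r <= 1.0 + 1e-12


class TestPartitionCycles:
    def test_seven_24h_cycles_of_72_bins(self):
        seg = make_series(np.ones(504))
        cs = partition_cycles(seg, 1440.0, "AW1")
        assert len(cs.cycles) == 7
        assert all(not c.partial for c in cs.cycles)
        assert all(c.counts.size == 72 for c in cs.cycles)

    def test_non_divisor_period_leaves_partial_tail(self):
        seg = make_series(np.ones(504))  # 168 h
        cs = partition_cycles(seg, 24.5 * 60.0)  # 6 x 24.5 = 147 h < 168 h
        complete = [c for c in cs.cycles if not c.partial]
        partial = [c for c in cs.cycles if c.partial]
        assert len(complete) == 6
        assert len(partial) == 1

    def test_first_bin_angle_uses_midpoint_convention(self):
        seg = make_series(np.ones(504))
        cs = partition_cycles(seg, 1440.0)
        for cyc in cs.cycles:
            assert cyc.theta[0] == pytest.approx(2 * np.pi * 10.0 / 1440.0, abs=1e-12)

    def test_consecutive_angles_separated_by_bin_fraction(self):
        seg = make_series(np.ones(300), bin_minutes=20.0)
        T = 1482.0
        cs = partition_cycles(seg, T)
        step = 2 * np.pi * 20.0 / T
        for cyc in cs.cycles:
            assert np.allclose(np.diff(cyc.theta), step, atol=1e-9)
            assert np.all((cyc.theta >= 0) & (cyc.theta < 2 * np.pi))

    def test_degenerate_cycle_length_raises(self):
        with pytest.raises(DegenerateCycleError):
            partition_cycles(make_series(np.ones(100)), 30.0)


class TestSelectCycleLength:
    WINDOW = AgeWindow("AW2", 10, 16)

    @staticmethod
    def _call(fly, period, rhythmic, genotype="g1", window="AW2"):
        return RhythmCall(
            fly, genotype, "run1", window, rhythmic, period, 5.0 if rhythmic else None, 504
        )

    def test_rhythmic_fly_uses_own_period(self):
        calls = [self._call("f1", 24.7, True)]
        choice = select_cycle_length("f1", self.WINDOW, calls, {("g1", "AW2"): 24.7})
        assert choice.T_minutes == pytest.approx(1482.0)
        assert choice.source == "own_period"

    def test_arrhythmic_fly_uses_genotype_mean(self):
        calls = [self._call("f1", None, False), self._call("f2", 24.0, True)]
        choice = select_cycle_length("f1", self.WINDOW, calls, {("g1", "AW2"): 24.0})
        assert choice.T_minutes == pytest.approx(1440.0)
        assert choice.source == "genotype_mean"

    def test_dying_fly_uses_prior_window_period(self):
        calls = [self._call("f1", 24.2, True)]
        prior = [self._call("f1", 25.0, True, window="AW1")]
        choice = select_cycle_length(
            "f1", self.WINDOW, calls, {("g1", "AW2"): 24.2},
            prior_window_calls=prior, death_day=13.0,
        )
        assert choice.T_minutes == pytest.approx(1500.0)
        assert choice.source == "prior_window"

    def test_dying_fly_without_prior_period_falls_back_to_genotype_mean(self):
        calls = [self._call("f1", None, False), self._call("f2", 23.5, True)]
        prior = [self._call("f1", None, False, window="AW1")]
        choice = select_cycle_length(
            "f1", self.WINDOW, calls, {("g1", "AW2"): 23.5},
            prior_window_calls=prior, death_day=12.0,
        )
        assert choice.T_minutes == pytest.approx(23.5 * 60.0)
        assert choice.source == "genotype_mean"

    def test_no_rhythmic_genotype_falls_back_to_24h(self):
        calls = [self._call("f1", None, False)]
        choice = select_cycle_length("f1", self.WINDOW, calls, {("g1", "AW2"): None})
        assert choice.T_minutes == pytest.approx(1440.0)
        assert choice.source == "fallback_24h"

    def test_unknown_fly_raises(self):
        with pytest.raises(UnknownFlyError):
            select_cycle_length("ghost", self.WINDOW, [], {})


class TestMeanDailyR:
    @staticmethod
    def _daily(fly, rs, genotype="g1"):
        return pd.DataFrame(
            {
                "fly_id": fly,
                "genotype": genotype,
                "window": "AW1",
                "cycle_index": range(len(rs)),
                "nominal_day": [3.0 + i for i in range(len(rs))],
                "T_minutes": 1440.0,
                "r": rs,
            }
        )

    def test_mean_and_sem_across_flies(self):
        daily = pd.concat([self._daily("f1", [0.2]), self._daily("f2", [0.4])])
        out = mean_daily_r(daily)
        assert out.loc[0, "mean_r"] == pytest.approx(0.3)
        assert out.loc[0, "sem_r"] == pytest.approx(0.1)
        assert out.loc[0, "n"] == 2

    def test_missing_r_drops_from_n(self):
        daily = pd.concat(
            [self._daily("f1", [0.2]), self._daily("f2", [float("nan")])]
        )
        out = mean_daily_r(daily)
        assert out.loc[0, "n"] == 1
        assert out.loc[0, "mean_r"] == pytest.approx(0.2)

    def test_identical_flies_have_zero_sem(self):
        daily = pd.concat([self._daily(f, [0.5, 0.6]) for f in ("f1", "f2", "f3")])
        out = mean_daily_r(daily)
        assert np.allclose(out["sem_r"], 0.0)

    def test_partial_cycles_excluded_from_fly_table(self):
        seg = make_series(np.random.default_rng(0).poisson(5, 504))
        cs = partition_cycles(seg, 24.5 * 60.0, "AW1")
        daily = cycle_set_daily_r(cs)
        assert math.isnan(daily["r"].iloc[-1])  # trailing partial cycle
        assert daily["r"].iloc[:-1].notna().all()
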