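import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import linregress

from scedan import (
    ValidationError,
    immediacy,
    make_series,
    ols_trend,
    range_lines,
    sd_band,
    split_middle,
    stability_envelope,
)

from conftest import random_series


class TestRangeLines:
    @pytest.mark.parametrize(
        "pre, post, overlapping",
        [([1, 3], [4, 6], False), ([1, 5], [4, 6], True), ([2], [2], True)],
    )
    def test_intersection(self, pre, post, overlapping):
        r = range_lines(make_series(pre, post))
        assert r.overlapping is overlapping
        assert (r.pre_min, r.pre_max) == (min(pre), max(pre))
        assert (r.post_min, r.post_max) == (min(post), max(post))


class TestSdBand:
    def test_hand_computed(self):
        b = sd_band(make_series([1, 2, 3], [5, 3]), k=2)
        assert (b.lower, b.upper) == (0, 4)
        assert b.outside_post == (1,)
        assert b.outside_fraction == 0.5

    def test_degenerate_zero_variance(self):
        b = sd_band(make_series([4, 4, 4], [4]))
        assert b.lower == b.center == b.upper == 4
        assert b.outside_fraction == 0  # point on the limit counts inside

    def test_point_on_limit_is_inside(self):
        b = sd_band(make_series([1, 2, 3], [4.0, 0.0]), k=2)
        assert b.outside_post == ()

    def test_median_center_variant(self):
        b = sd_band(make_series([1, 2, 9], [0]), center="median")
        assert b.center == 2

    def test_too_short(self):
        with pytest.raises(ValidationError) as e:
            sd_band(make_series([1], [2]))
        assert e.value.code == "baseline-too-short"

    @settings(deadline=None, max_examples=100)
    @given(seed=st.integers(0, 2**31 - 1), c=st.floats(-100, 100))
    def test_symmetry_and_shift(self, seed, c):
        """Limits symmetric about the center; shifting scores by c
        shifts center and limits by c."""
        s = random_series(np.random.default_rng(seed), min_len=2)
        b = sd_band(s)
        assert b.upper - b.center == pytest.approx(b.center - b.lower, abs=1e-9)
        b2 = sd_band(make_series(s.pre + c, s.post + c))
        assert b2.center == pytest.approx(b.center + c, abs=1e-8)
        assert b2.lower == pytest.approx(b.lower + c, abs=1e-8)
        assert b2.upper == pytest.approx(b.upper + c, abs=1e-8)


class TestOlsTrend:
    def test_hand_computed(self):
        line = ols_trend([1, 3, 5])
        assert line.slope == pytest.approx(2.0)
        assert line.intercept == pytest.approx(-1.0)

    def test_constant_phase(self):
        assert ols_trend([7, 7, 7, 7]).slope == pytest.approx(0.0)

    def test_two_points_interpolate(self):
        line = ols_trend([2, 8], t_offset=3)
        assert line.predict([4, 5]).tolist() == pytest.approx([2, 8])

    def test_too_short(self):
        with pytest.raises(ValidationError):
            ols_trend([1])

    @settings(deadline=None, max_examples=100)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_matches_closed_form_regression(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.normal(0, 5, size=int(rng.integers(2, 15)))
        line = ols_trend(y)
        ref = linregress(np.arange(1, len(y) + 1), y)
        assert line.slope == pytest.approx(ref.slope, abs=1e-9)
        assert line.intercept == pytest.approx(ref.intercept, abs=1e-9)


class TestSplitMiddle:
    def test_even_length_hand_computed(self):
        line = split_middle([1, 2, 3, 4])
        assert (line.slope, line.intercept) == (1.0, 0.0)

    def test_odd_length_middle_in_both_halves(self):
        line = split_middle([2, 4, 6, 8, 10])
        assert (line.slope, line.intercept) == (2.0, 0.0)

    def test_odd_length_drop_middle_variant(self):
        line = split_middle([2, 4, 6, 8, 10], odd_middle="drop")
        assert line.slope == pytest.approx(2.0)
        assert line.intercept == pytest.approx(0.0)

    def test_constant_phase(self):
        line = split_middle([5, 5, 5, 5])
        assert line.slope == 0 and line.predict(10) == 5

    def test_resistant_to_one_outlier(self):
        """A single wild value moves OLS but not the split-middle line."""
        clean = split_middle([1, 2, 3, 4, 5, 6])
        dirty = split_middle([1, 2, 3, 4, 5, 600])
        assert dirty.slope == pytest.approx(clean.slope)

    def test_too_short(self):
        with pytest.raises(ValidationError) as e:
            split_middle([1])
        assert e.value.code == "phase-too-short"

    @pytest.mark.parametrize("n", [2, 3, 4, 5, 6, 7, 10, 11])
    @pytest.mark.parametrize("odd_middle", ["both", "drop"])
    def test_exact_on_linear_phase(self, n, odd_middle):
        """Both halving conventions recover an exact line, both parities."""
        slope, intercept = -1.75, 12.0
        y = intercept + slope * np.arange(1, n + 1)
        line = split_middle(y, odd_middle=odd_middle)
        assert line.slope == pytest.approx(slope, abs=1e-12)
        assert line.intercept == pytest.approx(intercept, abs=1e-12)


class TestStabilityEnvelope:
    def test_hand_computed(self):
        env = stability_envelope(make_series([1, 2, 3, 4], [5.5, 7]))
        assert env.half_width == pytest.approx(0.625)
        assert env.baseline_within_fraction == 1.0
        assert env.post_within_fraction == 0.5
        assert env.stable is False
        assert env.post_direction == "above"

    def test_points_on_trend_are_stable(self):
        s = make_series([2, 4, 6, 8], [10, 12, 14])
        env = stability_envelope(s)
        assert env.baseline_within_fraction == 1.0
        assert env.post_within_fraction == 1.0
        assert env.stable is True

    def test_post_far_above_flags_direction(self):
        s = make_series([1, 1, 1, 1], [50, 60], aim="increase")
        env = stability_envelope(s)
        assert env.stable is False and env.post_direction == "above"

    @settings(deadline=None, max_examples=60)
    @given(seed=st.integers(0, 2**31 - 1), f1=st.floats(0.05, 0.5), f2=st.floats(0.05, 0.5))
    def test_fraction_monotonicity(self, seed, f1, f2):
        """A wider envelope never contains fewer points."""
        rng = np.random.default_rng(seed)
        s = random_series(rng, min_len=4)
        s = make_series(np.abs(s.pre) + 1, np.abs(s.post) + 1)  # positive scores
        lo, hi = sorted([f1, f2])
        e_lo = stability_envelope(s, fraction=lo)
        e_hi = stability_envelope(s, fraction=hi)
        assert e_hi.baseline_within_fraction >= e_lo.baseline_within_fraction
        assert e_hi.post_within_fraction >= e_lo.post_within_fraction


class TestImmediacy:
    def test_hand_computed(self):
        imm = immediacy(make_series([10, 10, 10, 8, 8], [4] * 5), window=3)
        assert imm.value == pytest.approx(4 - 26 / 3)
        assert imm.label == "improvement"

    def test_flat_no_change(self, flat_series):
        imm = immediacy(flat_series)
        assert imm.value == 0 and imm.label == "no-change"

    def test_degenerate_single_point_window(self):
        imm = immediacy(make_series([3], [9]), window=1)
        assert imm.value == 6 and imm.label == "deterioration"

    def test_window_too_large(self):
        with pytest.raises(ValidationError) as e:
            immediacy(make_series([1, 2], [3, 4, 5]), window=3)
        assert e.value.code == "window-too-large"
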