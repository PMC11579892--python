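"""Error taxonomy, session metrics, polar errors, iEMG, benchmark, chance level."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from synid.direction_decoder import DIRECTIONS, DirectionLabel
from synid.errors import DataError
from synid.evaluation import (
    accuracy_vs_time,
    adjusted_chance_level,
    classify_error,
    iemg,
    kinematic_benchmark,
    movement_end,
    repeatability_errors,
    session_metrics,
    to_polar,
    wrap_angle_deg,
    TrialResult,
)


def D(name):
    return DirectionLabel.from_name(name)


class TestClassifyError:
    @pytest.mark.parametrize(
        "true,est,expected",
        [
            ("N", "N", "correct"),
            ("N", "NW", "type1"),
            ("N", "NE", "type1"),
            ("N", "W", "type2"),
            ("N", "SW", "type3"),
            ("N", "S", "type4"),
            ("E", "SE", "type1"),
            ("SE", "NW", "type4"),
        ],
    )
    def test_circular_taxonomy(self, true, est, expected):
        assert classify_error(D(true), D(est)) == expected

    def test_exhaustive_and_mutually_exclusive(self):
        for a in DIRECTIONS:
            for b in DIRECTIONS:
                cat = classify_error(a, b)
                d = min(abs(a.index - b.index), 8 - abs(a.index - b.index))
                assert cat == ("correct", "type1", "type2", "type3", "type4")[d]


class TestSessionMetrics:
    def test_all_correct(self):
        results = [TrialResult(d, d) for d in DIRECTIONS for _ in range(3)]
        m = session_metrics(results)
        assert m.accuracy_pct == 100.0
        assert m.type1_pct == m.type2_pct == m.type3_pct == m.type4_pct == 0.0

    def test_modified_accuracy_is_accuracy_plus_type1(self):
        # 486 correct + 334 adjacent of 1000 -> 48.6% and 82.0% modified
        results = (
            [TrialResult(D("N"), D("N"))] * 486
            + [TrialResult(D("N"), D("NW"))] * 334
            + [TrialResult(D("N"), D("S"))] * 180
        )
        m = session_metrics(results)
        assert m.accuracy_pct == pytest.approx(48.6)
        assert m.type1_pct == pytest.approx(33.4)
        assert m.modified_accuracy_pct == pytest.approx(82.0)

    @given(st.lists(st.tuples(st.integers(0, 7), st.integers(0, 7)),
                    min_size=1, max_size=60))
    @settings(max_examples=50, deadline=None)
    def test_percentages_sum_to_100(self, pairs):
        results = [TrialResult(DIRECTIONS[a], DIRECTIONS[b]) for a, b in pairs]
        m = session_metrics(results)
        total = (m.accuracy_pct + m.type1_pct + m.type2_pct
                 + m.type3_pct + m.type4_pct)
        assert total == pytest.approx(100.0, abs=1e-9)
        assert m.confusion.sum() == len(results)

    def test_excluded_trials_counted_separately(self):
        results = [TrialResult(D("N"), D("N")),
                   TrialResult(D("S"), excluded=True, exclusion_reason="no onset")]
        m = session_metrics(results)
        assert (m.n_trials, m.n_excluded) == (1, 1)


class TestPolar:
    @pytest.mark.parametrize("p,expected", [
        ((1, 0), (1, 0)), ((0, 1), (1, 90)), ((-1, 0), (1, 180)), ((0, -1), (1, 270)),
    ])
    def test_cardinal_points(self, p, expected):
        rho, theta = to_polar(np.array(p, float))
        assert (rho, theta) == pytest.approx(expected)

    def test_origin_angle_undefined(self):
        rho, theta = to_polar(np.zeros(2))
        assert rho == 0.0 and math.isnan(theta)

    def test_roundtrip_identity(self, rng):
        for _ in range(1000):
            p = rng.normal(size=2)
            rho, theta = to_polar(p)
            back = rho * np.array([np.cos(np.deg2rad(theta)),
                                   np.sin(np.deg2rad(theta))])
            np.testing.assert_allclose(back, p, atol=1e-12)


class TestRepeatability:
    def test_zero_discrepancy(self):
        assert repeatability_errors(np.array([0.2, 0.1]), np.array([0.2, 0.1])) == (0, 0)

    def test_direct_arithmetic(self):
        c = 0.25 * np.array([1.0, 0.0])
        f = 0.27 * np.array([np.cos(np.deg2rad(5)), np.sin(np.deg2rad(5))])
        drho, dtheta = repeatability_errors(f, c)
        assert drho == pytest.approx(0.02, abs=1e-12)
        assert dtheta == pytest.approx(5.0, abs=1e-9)

    def test_angle_wrap(self):
        a = np.array([np.cos(np.deg2rad(359)), np.sin(np.deg2rad(359))])
        b = np.array([np.cos(np.deg2rad(1)), np.sin(np.deg2rad(1))])
        _, dtheta = repeatability_errors(a, b)
        # brute-force wrap oracle
        brute = min(abs(359 - 1), 360 - abs(359 - 1))
        assert dtheta == pytest.approx(brute, abs=1e-9)


class TestIemg:
    def test_zero_envelope(self):
        assert np.all(iemg(np.zeros((6, 100)), np.ones(6)) == 0)

    def test_constant_at_mvc_gives_100(self):
        mvc = np.array([1, 2, 3, 4, 5, 6.0])
        out = iemg(np.tile(mvc[:, None], (1, 50)), mvc)
        np.testing.assert_allclose(out, 100.0, atol=1e-9)

    def test_linear_ramp_gives_50(self):
        ramp = np.linspace(0, 1, 200)[None, :]
        assert iemg(ramp, np.ones(1))[0] == pytest.approx(50.0, abs=0.5)

    def test_missing_mvc_rejected(self):
        with pytest.raises(DataError):
            iemg(np.ones((2, 10)), np.array([1.0, 0.0]))


class TestMovementEnd:
    def test_symmetric_triangle(self):
        t = np.linspace(0, 1, 1001)
        tri = np.where(t <= 0.5, 2 * t, 2 * (1 - t))
        end = movement_end(tri)
        assert t[end.index] == pytest.approx(0.9, abs=1e-3)
        assert end.complete

    def test_gaussian_bump_matches_brute_scan(self):
        t = np.linspace(0, 1, 500)
        x = np.exp(-0.5 * ((t - 0.4) / 0.1) ** 2)
        end = movement_end(x)
        peak = int(np.argmax(x))
        scan = next(i for i in range(peak, x.size) if x[i] <= 0.2 * x[peak])
        assert end.index == scan

    def test_monotone_rising_flags_incomplete(self):
        end = movement_end(np.linspace(0.01, 1, 100))
        assert end.index == 99 and not end.complete

    def test_nonpositive_peak_rejected(self):
        with pytest.raises(DataError):
            movement_end(np.zeros(10))


class TestKinematicBenchmark:
    @pytest.mark.parametrize("theta,expected", [
        (90, "N"), (0, "E"), (45, "NE"), (67.5, "NE"), (180, "W"), (359, "E"),
    ])
    def test_angle_binning(self, theta, expected):
        p = 0.2 * np.array([[np.cos(np.deg2rad(theta)), np.sin(np.deg2rad(theta))]])
        assert DIRECTIONS[kinematic_benchmark(p)[0]].name == expected

    def test_below_min_displacement_inherits_previous(self):
        traj = np.array([[0.0, 0.0], [0.2, 0.0], [0.001, 0.001], [0.0, 0.2]])
        est = kinematic_benchmark(traj, min_disp_m=0.01)
        assert [DIRECTIONS[i].name for i in est] == ["E", "E", "E", "N"]

    def test_matches_angle_bin_oracle(self, rng):
        # brute force: nearest of the eight 45-degree bins by wrapped distance
        pts = rng.normal(size=(10_000, 2))
        est = kinematic_benchmark(pts, min_disp_m=0.0)
        for p, e in zip(pts, est):
            theta = np.degrees(np.arctan2(p[1], p[0])) % 360
            dists = [min(abs(theta - a), 360 - abs(theta - a))
                     for a in (0, 45, 90, 135, 180, 225, 270, 315)]
            assert e == int(np.argmin(dists))


class TestAdjustedChanceLevel:
    def test_reproduces_published_value(self):
        v = adjusted_chance_level(160, 8, 0.95)
        assert v == pytest.approx(18.125, abs=1e-12)
        assert round(v, 1) == 18.1

    def test_matches_exact_enumeration_for_small_n(self):
        # oracle: exact rational binomial CDF enumeration
        for n in range(1, 31):
            p = Fraction(1, 8)
            target = Fraction(975, 1000)
            cdf = Fraction(0)
            k_star = n
            for k in range(n + 1):
                cdf += math.comb(n, k) * p**k * (1 - p) ** (n - k)
                if cdf >= target:
                    k_star = k
                    break
            assert adjusted_chance_level(n, 8) == pytest.approx(
                100.0 * k_star / n, abs=1e-9
            )

    def test_limits_and_monotonicity(self):
        assert adjusted_chance_level(10**6, 8) == pytest.approx(12.5, abs=0.1)
        assert adjusted_chance_level(40, 8) >= adjusted_chance_level(160, 8)
        assert adjusted_chance_level(160, 4) > adjusted_chance_level(160, 8)


class TestAccuracyVsTime:
    def test_constant_correct_traces_are_flat_100(self):
        traces = [np.full(60, d.index) for d in DIRECTIONS]
        curve = accuracy_vs_time(traces, list(DIRECTIONS), control_fs=100.0)
        assert np.all(curve["accuracy_pct"] == 100.0)
        assert curve["time_s"][0] == pytest.approx(0.05)
        assert curve["time_s"][-1] == pytest.approx(0.6)

    def test_final_point_matches_session_metrics(self, small_study):
        m = small_study["metrics"]
        assert m.accuracy_vs_time["accuracy_pct"][-1] == pytest.approx(
            m.modified_accuracy_pct
        )


def test_wrap_angle_range():
    for a in (-720, -180, -1, 0, 1, 179, 180, 359, 720):
        w = wrap_angle_deg(a)
        assert -180 <= w < 180
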