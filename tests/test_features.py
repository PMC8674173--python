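"""Feature engineering: aggregations, the power-law exponent, transition
histograms, consecutive ratios, and the assembled 53-feature vector."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as hst

from reachdecomp.features import (
    DEFAULT_EXCLUDED,
    FeatureConfig,
    aggregate,
    build_feature_vector,
    consecutive_ratio_features,
    feature_names,
    feature_table,
    fit_power_law,
    size_speed_duration_features,
    transition_features,
)
from reachdecomp.segment import MovementElement


def _element(distance, duration=0.2, axis="AP", hand="right", t=0.0, speed=None):
    speed = abs(distance) / duration if speed is None else speed
    return MovementElement(
        axis=axis, start_index=0, end_index=1, duration_s=duration,
        signed_distance_m=distance, distance_m=abs(distance),
        mean_speed_ms=speed, start_time_s=t,
        profile=np.array([1.0]), participant_id="P", visit_id="v1", hand=hand,
    )


class TestAggregate:
    def test_single_value(self):
        a = aggregate([5.0])
        assert (a.mean, a.sd, a.min, a.max, a.median) == (5, 0, 5, 5, 5)
        assert a.range == 0 and a.iqr == 0

    def test_simple_sequence(self):
        a = aggregate([1, 2, 3, 4])
        assert a.mean == 2.5 and a.median == 2.5 and a.range == 3
        # independent order-statistic interpolation
        x = np.sort([1, 2, 3, 4])
        def q(p):
            h = (len(x) - 1) * p
            lo = int(np.floor(h))
            return x[lo] + (h - lo) * (x[min(lo + 1, 3)] - x[lo])
        assert a.p10 == pytest.approx(q(0.10))
        assert a.p90 == pytest.approx(q(0.90))
        assert a.iqr == pytest.approx(q(0.75) - q(0.25))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate([])

    @given(hst.lists(hst.floats(-1e3, 1e3), min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_permutation_invariance(self, values):
        rng = np.random.default_rng(0)
        shuffled = list(values)
        rng.shuffle(shuffled)
        a, b = aggregate(values), aggregate(shuffled)
        for k in ("mean", "sd", "min", "max", "range", "iqr", "median", "p10", "p90"):
            assert getattr(a, k) == pytest.approx(getattr(b, k), rel=1e-9, abs=1e-9)


class TestSizeSpeedDuration:
    def test_identical_elements_zero_spread(self):
        els = [_element(0.1) for _ in range(5)]
        out = size_speed_duration_features(els)
        for k, v in out.items():
            if k.endswith(("_sd", "_range", "_iqr")):
                assert v == 0.0
        assert len(out) == 27

    def test_doubling_distances_shifts_log_mean(self):
        els = [_element(d) for d in (0.1, 0.2, 0.3)]
        doubled = [_element(2 * d) for d in (0.1, 0.2, 0.3)]
        a = size_speed_duration_features(els)
        b = size_speed_duration_features(doubled)
        assert b["log_distance_mean"] - a["log_distance_mean"] == pytest.approx(np.log(2))

    def test_matches_hand_computation(self):
        durations = [0.1, 0.2, 0.3, 0.4, 0.5]
        els = [_element(0.05, duration=t) for t in durations]
        out = size_speed_duration_features(els)
        assert out["duration_mean"] == pytest.approx(np.mean(durations))
        assert out["duration_sd"] == pytest.approx(np.std(durations, ddof=1))


class TestPowerLaw:
    def test_exact_two_thirds(self):
        d = np.array([0.01, 0.05, 0.1, 0.3])
        els = [_element(x, speed=2 * x ** (2 / 3)) for x in d]
        fit = fit_power_law(els)
        assert fit.alpha == pytest.approx(2 / 3, abs=1e-12)
        assert fit.intercept == pytest.approx(np.log(2), abs=1e-12)

    def test_constant_speed_zero_slope(self):
        els = [_element(x, speed=0.5) for x in (0.01, 0.1, 0.2)]
        assert fit_power_law(els).alpha == pytest.approx(0.0, abs=1e-12)

    def test_equal_distances_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_power_law([_element(0.1), _element(0.1)])

    def test_matches_normal_equations_oracle(self, rng):
        d = rng.uniform(0.005, 0.4, 40)
        v = 1.3 * d ** 0.6 * np.exp(rng.normal(0, 0.1, 40))
        els = [_element(x, speed=s) for x, s in zip(d, v)]
        x, y = np.log(d), np.log(v)
        xc = x - x.mean()
        slope = (xc @ (y - y.mean())) / (xc @ xc)
        assert fit_power_law(els).alpha == pytest.approx(slope, abs=1e-10)


class TestTransitions:
    def test_probabilities_sum_to_one(self, rng):
        els = [
            _element(d, t=i * 0.3)
            for i, d in enumerate(rng.uniform(-0.4, 0.4, 30))
        ]
        hist = transition_features(els)
        assert hist.probabilities.sum() == pytest.approx(1.0)
        assert np.all(hist.probabilities >= 0)

    def test_alternating_large_elements_zero_small_mass(self):
        els = [_element(0.4 * (-1) ** i, t=i * 0.5) for i in range(20)]
        hist = transition_features(els)
        assert sum(hist.small_region.values()) == 0.0
        # all mass pairs large-positive with large-negative
        assert hist.n_pairs == 19

    def test_all_tiny_elements_full_small_mass(self):
        els = [_element(0.005 * (-1) ** i, t=i * 0.1) for i in range(15)]
        hist = transition_features(els)
        assert sum(hist.small_region.values()) == pytest.approx(1.0)

    def test_fewer_than_two_elements_warns(self):
        with pytest.warns(UserWarning):
            hist = transition_features([_element(0.1)])
        assert all(v == 0.0 for v in hist.small_region.values())

    def test_pairs_do_not_cross_hands(self):
        els = [
            _element(0.005, hand="left", t=0.0),
            _element(0.005, hand="right", t=0.1),
            _element(0.005, hand="left", t=0.2),
        ]
        hist = transition_features(els)
        assert hist.n_pairs == 1  # only the two left-hand elements pair


class TestConsecutiveRatios:
    def test_equal_distances(self):
        els = [_element(0.1, t=i * 0.2) for i in range(4)]
        out = consecutive_ratio_features(els)
        assert out["log_ratio_sd"] == 0.0 and out["log_ratio_mean"] == 0.0

    def test_single_pair_log2(self):
        els = [_element(0.1, t=0.0), _element(0.2, t=0.2)]
        out = consecutive_ratio_features(els)
        assert out["log_ratio_mean"] == pytest.approx(np.log(2))

    def test_streams_do_not_mix_axes(self):
        els = [
            _element(0.1, axis="AP", t=0.0), _element(0.4, axis="AP", t=0.2),
            _element(0.2, axis="ML", t=0.1), _element(0.1, axis="ML", t=0.3),
        ]
        out = consecutive_ratio_features(els)
        expected = np.mean([np.log(4), np.log(0.5)])
        assert out["log_ratio_mean"] == pytest.approx(expected)


class TestFeatureVector:
    def _elements(self, rng, hand_order=("left", "right")):
        els = []
        for hand in hand_order:
            for axis in ("AP", "ML", "RC"):
                for i in range(12):
                    d = float(rng.uniform(0.002, 0.3)) * (-1) ** i
                    els.append(_element(d, duration=float(rng.uniform(0.05, 0.6)),
                                        axis=axis, hand=hand, t=i * 0.3))
        return els

    def test_default_count_is_53(self):
        assert FeatureConfig().n_features == 53
        assert len(feature_names()) == 53

    def test_build_and_hand_order_invariance(self):
        els = self._elements(np.random.default_rng(5))
        pc1 = np.linspace(-1, 1, len(els))
        pc2 = np.linspace(0, 2, len(els))
        vec = build_feature_vector(els, pc1, pc2)
        assert len(vec) == 53
        assert not vec.isna().any()
        # reversing the hand input order changes nothing
        rev = build_feature_vector(list(reversed(els)),
                                   pc1[::-1].copy(), pc2[::-1].copy())
        pd.testing.assert_series_equal(vec, rev)

    def test_identical_inputs_identical_vectors(self):
        els = self._elements(np.random.default_rng(6))
        pc = np.ones(len(els)), np.zeros(len(els))
        a = build_feature_vector(els, *pc)
        b = build_feature_vector(els, *pc)
        pd.testing.assert_series_equal(a, b)

    def test_missing_morphology_rejected(self):
        els = self._elements(np.random.default_rng(7))
        with pytest.raises(ValueError, match="morphology"):
            build_feature_vector(els, None, None)

    def test_excluded_features_absent(self):
        for name in DEFAULT_EXCLUDED:
            assert name not in feature_names()

    def test_csv_round_trip(self, tmp_path):
        els = self._elements(np.random.default_rng(8))
        vec = build_feature_vector(els, np.ones(len(els)), np.zeros(len(els)))
        table = feature_table({("P", "v1"): vec})
        path = tmp_path / "features.csv"
        table.to_csv(path)
        back = pd.read_csv(path, index_col=[0, 1])
        np.testing.assert_allclose(back.to_numpy(), table.to_numpy(), rtol=1e-12)
        assert list(back.columns) == list(table.columns)
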