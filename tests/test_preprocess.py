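"""Preprocessing chain: truncation, eligibility, block averaging, padding, splits."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from actisurv import (
    CohortSimParams,
    PreprocessConfig,
    block_average,
    is_eligible,
    pad_batch,
    process_cohort,
    simulate_cohort,
    simulate_patient,
    split_dataset,
    truncate_to_horizon,
)
from conftest import make_series


class TestTruncate:
    def test_ten_day_series_truncates_to_48h_sample_count(self):
        series = make_series(np.zeros(10 * 86400, dtype=np.float32))
        out = truncate_to_horizon(series, PreprocessConfig(horizon_h=48))
        assert len(out) == 172_800

    def test_short_series_passes_through(self):
        series = make_series(np.zeros(40 * 3600, dtype=np.float32))
        out = truncate_to_horizon(series, PreprocessConfig(horizon_h=48))
        assert len(out) == 40 * 3600

    def test_retained_span_ends_before_horizon_on_simulation(self):
        params = CohortSimParams(
            sampling_interval_s=600.0, stay_days_range=(3, 3), seed=1
        )
        series, _ = simulate_patient(params, 0, np.random.default_rng(1))
        out = truncate_to_horizon(series, PreprocessConfig(horizon_h=24))
        last_offset_h = (len(out) - 1) * out.interval_s / 3600.0
        assert last_offset_h < 24.0

    def test_empty_series_rejected(self):
        series = make_series(np.zeros(10))
        series.activity = series.activity[:0]
        series.angle = series.angle[:0]
        series.spin = series.spin[:0]
        series.worn = series.worn[:0]
        with pytest.raises(ValueError):
            truncate_to_horizon(series, PreprocessConfig())


class TestEligibility:
    def test_two_hour_gap_is_tracking_interruption(self):
        n = 48 * 60  # 48 h at 1-min sampling
        worn = np.ones(n, dtype=bool)
        worn[600 : 600 + 120] = False  # 2 h off wrist
        series = make_series(np.ones(n), interval_s=60.0, worn=worn)
        ok, reason = is_eligible(
            series, PreprocessConfig(horizon_h=48, max_gap_tolerance_min=30)
        )
        assert not ok
        assert "tracking interruption" in reason

    def test_fully_worn_48h_is_eligible(self):
        series = make_series(np.ones(48 * 60), interval_s=60.0)
        ok, reason = is_eligible(series, PreprocessConfig(horizon_h=48))
        assert ok and reason == "eligible"

    def test_short_recording_fails_data_volume_rule(self):
        series = make_series(np.ones(30 * 60), interval_s=60.0)
        ok, reason = is_eligible(series, PreprocessConfig(horizon_h=48))
        assert not ok
        assert "data volume" in reason

    def test_gap_outside_horizon_does_not_exclude(self):
        n = 72 * 60
        worn = np.ones(n, dtype=bool)
        worn[60 * 60 :] = False  # off-wrist only after the first 48 h... (60 h mark)
        worn[: 48 * 60] = True
        series = make_series(np.ones(n), interval_s=60.0, worn=worn)
        ok, _ = is_eligible(series, PreprocessConfig(horizon_h=48))
        assert ok

    def test_default_gap_parameters_exclude_about_a_quarter(self):
        """With default off-wrist parameters a 60-patient cohort keeps about
        44 eligible recordings on average (the tuned calibration regime)."""
        counts = []
        for rep in range(8):
            cohort = simulate_cohort(
                CohortSimParams(
                    n_patients=60,
                    sampling_interval_s=60.0,
                    stay_days_range=(3, 4),
                    seed=500 + rep,
                )
            )
            cfg = PreprocessConfig(horizon_h=48)
            counts.append(sum(is_eligible(s, cfg)[0] for s, _ in cohort))
        assert 41 <= np.mean(counts) <= 48


class TestBlockAverage:
    def test_window_of_two(self):
        series = make_series([1.0, 2.0, 3.0, 4.0])
        out = block_average(series, PreprocessConfig(block_window=2))
        np.testing.assert_allclose(out.values[:, 0], [1.5, 3.5])
        assert out.valid_length == 2

    def test_48h_at_1hz_window_20_gives_8640_steps(self):
        series = make_series(np.zeros(172_800, dtype=np.float32))
        out = block_average(series, PreprocessConfig(block_window=20))
        assert out.valid_length == 8640

    def test_constant_series_is_preserved(self):
        series = make_series(np.full(101, 2.5))
        out = block_average(series, PreprocessConfig(block_window=7))
        np.testing.assert_allclose(out.values, 2.5, rtol=1e-6)
        assert out.valid_length == math.ceil(101 / 7)

    def test_offwrist_excluded_from_window_means(self):
        worn = np.array([True, False, True, True])
        series = make_series([1.0, 100.0, 3.0, 5.0], worn=worn)
        out = block_average(series, PreprocessConfig(block_window=2))
        np.testing.assert_allclose(out.values[:, 0], [1.0, 4.0])

    def test_fully_offwrist_window_gets_pad_value(self):
        worn = np.array([False, False, True, True])
        series = make_series([1.0, 2.0, 3.0, 5.0], worn=worn)
        out = block_average(series, PreprocessConfig(block_window=2, pad_value=0.0))
        np.testing.assert_allclose(out.values[:, 0], [0.0, 4.0])

    def test_offwrist_as_zero_option(self):
        worn = np.array([True, False, True, True])
        series = make_series([1.0, 100.0, 3.0, 5.0], worn=worn)
        out = block_average(
            series, PreprocessConfig(block_window=2, offwrist_as_zero=True)
        )
        np.testing.assert_allclose(out.values[:, 0], [0.5, 4.0])

    @given(
        n=st.integers(1, 200),
        window=st.integers(1, 25),
        seed=st.integers(0, 1000),
    )
    @settings(max_examples=40, deadline=None)
    def test_matches_naive_oracle_on_worn_complete_data(self, n, window, seed):
        rng = np.random.default_rng(seed)
        values = rng.uniform(0, 5, size=n).astype(np.float32)
        series = make_series(values)
        out = block_average(series, PreprocessConfig(block_window=window))
        expected = [
            float(np.mean(values[k * window : (k + 1) * window]))
            for k in range(math.ceil(n / window))
        ]
        np.testing.assert_allclose(out.values[:, 0], expected, rtol=1e-5)


class TestPadBatch:
    def _tensors(self, lengths):
        cfg = PreprocessConfig(block_window=1)
        return [
            block_average(make_series(np.arange(1, n + 1, dtype=np.float32)), cfg)
            for n in lengths
        ]

    def test_pads_to_batch_maximum(self):
        out = pad_batch(self._tensors([3, 5, 9]), PreprocessConfig())
        assert [len(t) for t in out] == [9, 9, 9]
        assert [t.valid_length for t in out] == [3, 5, 9]
        np.testing.assert_allclose(out[0].values[3:], 0.0)

    def test_single_tensor_unchanged(self):
        (t,) = pad_batch(self._tensors([4]), PreprocessConfig())
        assert len(t) == 4

    def test_zero_padding_conserves_channel_sums(self):
        tensors = self._tensors([3, 7])
        sums = [t.values.sum() for t in tensors]
        padded = pad_batch(tensors, PreprocessConfig(pad_value=0.0))
        np.testing.assert_allclose([t.values.sum() for t in padded], sums, rtol=1e-6)

    def test_front_padding_puts_data_at_the_end(self):
        out = pad_batch(self._tensors([2, 4]), PreprocessConfig(pad_position="front"))
        np.testing.assert_allclose(out[0].values[:2], 0.0)
        np.testing.assert_allclose(out[0].values[2:, 0], [1.0, 2.0])


class TestSplitDataset:
    @staticmethod
    def _labels(n_death, n_stable):
        labels = {f"D{i}": 1 for i in range(n_death)}
        labels.update({f"S{i}": 0 for i in range(n_stable)})
        return labels

    def test_three_way_floor_rule_on_21_23(self):
        split = split_dataset(self._labels(21, 23), (0.7, 0.2, 0.1), seed=0)
        counts = split.counts()
        assert (counts["train"], counts["validation"], counts["test"]) == (30, 8, 6)
        for cls, expected in ((1, (14, 4, 3)), (0, (16, 4, 3))):
            prefix = "D" if cls == 1 else "S"
            per = tuple(
                sum(pid.startswith(prefix) for pid in split.ids(p))
                for p in ("train", "validation", "test")
            )
            assert per == expected

    def test_balanced_two_way_split(self):
        split = split_dataset(self._labels(10, 10), (0.5, 0.5), seed=3)
        assert split.counts() == {"train": 10, "validation": 0, "test": 10}
        for prefix in ("D", "S"):
            assert sum(p.startswith(prefix) for p in split.ids("train")) == 5

    def test_explicit_override_reproduces_balanced_training(self):
        split = split_dataset(
            self._labels(21, 23),
            (0.7, 0.3),
            seed=0,
            override={1: (15, 0, 6), 0: (15, 0, 8)},
        )
        counts = split.counts()
        assert (counts["train"], counts["test"]) == (30, 14)
        assert sum(p.startswith("D") for p in split.ids("train")) == 15

    def test_assignment_randomised_by_seed(self):
        labels = self._labels(12, 12)
        a = split_dataset(labels, (0.7, 0.3), seed=1)
        b = split_dataset(labels, (0.7, 0.3), seed=2)
        assert a.assignment != b.assignment
        assert a.assignment == split_dataset(labels, (0.7, 0.3), seed=1).assignment

    def test_bad_ratios_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            split_dataset(self._labels(3, 3), (0.5, 0.4), seed=0)

    def test_empty_partition_warns(self):
        with pytest.warns(UserWarning, match="empty"):
            split_dataset(self._labels(1, 1), (0.5, 0.3, 0.2), seed=0)

    @given(
        n_death=st.integers(1, 40),
        n_stable=st.integers(1, 40),
        ratio_idx=st.integers(0, 2),
        seed=st.integers(0, 99),
    )
    @settings(max_examples=60, deadline=None)
    def test_floor_rule_property_sweep(self, n_death, n_stable, ratio_idx, seed):
        """Partitions are disjoint, exhaustive, and per-class counts follow
        the floor formula for a range of cohort sizes and ratio choices."""
        ratios = [(0.7, 0.2, 0.1), (0.7, 0.3), (0.5, 0.25, 0.25)][ratio_idx]
        labels = self._labels(n_death, n_stable)
        split = split_dataset(labels, ratios, seed=seed)
        assert set(split.assignment) == set(labels)
        for cls, n_cls in ((1, n_death), (0, n_stable)):
            prefix = "D" if cls == 1 else "S"
            n_train = sum(p.startswith(prefix) for p in split.ids("train"))
            n_val = sum(p.startswith(prefix) for p in split.ids("validation"))
            n_test = sum(p.startswith(prefix) for p in split.ids("test"))
            assert n_train == math.floor(ratios[0] * n_cls)
            expected_val = math.floor(ratios[1] * n_cls) if len(ratios) == 3 else 0
            assert n_val == expected_val
            assert n_test == n_cls - n_train - n_val


class TestFullChain:
    def test_padded_length_formula_for_full_length_cohort(self):
        """With every recording covering the horizon, the padded length is
        ceil(horizon_s / interval_s / block_window)."""
        params = CohortSimParams(
            n_patients=4,
            sampling_interval_s=300.0,
            stay_days_range=(3, 4),
            offwrist_duration_minutes=(5.0, 20.0),
            seed=2,
        )
        cfg = PreprocessConfig(horizon_h=48, block_window=20)
        tensors, excluded = process_cohort(simulate_cohort(params), cfg)
        expected = math.ceil(48 * 3600 / 300 / 20)
        assert not excluded
        assert all(len(t) == expected for t in tensors)
        assert all(t.label in (0, 1) for t in tensors)
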