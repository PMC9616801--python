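"""Windowing, masking, inclusion filters and balanced subsampling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from commdyn.session import (
    CountMatrix,
    EmptySelectionError,
    apply_rate_threshold,
    include_session,
    rate_threshold_mask,
    select_responsive_neurons,
    subsample_balanced,
    window_counts,
)


class TestWindowCounts:
    @pytest.mark.parametrize(
        "window,expected",
        [((0.0, 150.0), 2), ((150.0, 150.0), 1)],
    )
    def test_half_open_counting(self, toy_session, window, expected):
        # neuron 0 in trial 0 spikes at 10, 60, 200 ms
        cm = window_counts(toy_session, window, np.array([0]), neurons=np.array([0]))
        assert cm.counts[0, 0] == expected

    def test_right_edge_belongs_to_next_window(self, toy_session):
        # neuron 1 in trial 0 spikes exactly at 150 ms
        before = window_counts(toy_session, (0.0, 150.0), np.array([0]), np.array([1]))
        after = window_counts(toy_session, (150.0, 150.0), np.array([0]), np.array([1]))
        assert before.counts[0, 0] == 0
        assert after.counts[0, 0] == 1

    def test_windows_tile_stimulus_exactly(self, small_session):
        session, _ = small_session
        total = window_counts(session, (0.0, 500.0))
        parts = [window_counts(session, (o, 100.0)) for o in (0, 100, 200, 300, 400)]
        np.testing.assert_array_equal(
            total.counts, np.sum([p.counts for p in parts], axis=0)
        )

    def test_empty_selection_raises(self, toy_session):
        with pytest.raises(EmptySelectionError):
            window_counts(toy_session, (0.0, 150.0), np.zeros(4, dtype=bool))

    def test_window_outside_recorded_span_raises(self, toy_session):
        with pytest.raises(ValueError):
            window_counts(toy_session, (900.0, 500.0))


class TestRateThreshold:
    def test_low_rate_neuron_masked(self):
        # 0.1 spikes / 150 ms = 0.67 Hz, below the 2.5 Hz guard
        counts = np.zeros((10, 1), dtype=int)
        counts[0, 0] = 1
        cm = CountMatrix(counts, (0.0, 150.0), np.arange(10), np.array([0]))
        assert not apply_rate_threshold(cm, 2.5).mask.any()

    def test_high_rate_unmasked_and_zero_threshold_identity(self):
        counts = np.full((10, 1), 2)  # 13.3 Hz
        cm = CountMatrix(counts, (0.0, 150.0), np.arange(10), np.array([0]))
        assert apply_rate_threshold(cm, 2.5).mask.all()
        assert apply_rate_threshold(cm, 0.0).mask.all()

    def test_masking_monotone_in_threshold(self, small_session):
        session, _ = small_session
        cm = window_counts(session, (0.0, 150.0))
        kept = [rate_threshold_mask(cm, thr).sum() for thr in (0.0, 1.0, 2.5, 5.0, 20.0)]
        assert all(a >= b for a, b in zip(kept, kept[1:]))


class TestResponsiveNeurons:
    def test_silent_and_flat_neurons_excluded(self, toy_session):
        # too few trials per stimulus in the toy session -> guard
        with pytest.raises(ValueError):
            select_responsive_neurons(toy_session)

    def test_driven_neurons_detected(self, small_session):
        session, _ = small_session
        # default simulator gains are ~2x baseline: most target neurons respond
        resp = select_responsive_neurons(session, area="target")
        assert len(resp) >= 0.6 * 15
        target_idx = session.neuron_indices("target")
        assert np.isin(resp, target_idx).all()


class TestSubsampleBalanced:
    def test_downsamples_to_minimum(self):
        labels = np.array(["a"] * 40 + ["b"] * 55)
        idx = subsample_balanced(labels, np.random.default_rng(0))
        assert (labels[idx] == "a").sum() == 40
        assert (labels[idx] == "b").sum() == 40

    def test_equal_groups_unchanged(self):
        labels = np.repeat(["a", "b", "c", "d"], 10)
        idx = subsample_balanced(labels, np.random.default_rng(0))
        assert idx.size == 40

    def test_seed_determinism_and_no_duplicates(self):
        labels = np.array(["x"] * 30 + ["y"] * 20)
        i1 = subsample_balanced(labels, np.random.default_rng(7))
        i2 = subsample_balanced(labels, np.random.default_rng(7))
        i3 = subsample_balanced(labels, np.random.default_rng(8))
        np.testing.assert_array_equal(i1, i2)
        assert not np.array_equal(i1, i3)
        assert np.unique(i1).size == i1.size

    @given(st.integers(1, 30), st.integers(1, 30), st.integers(0, 2**16))
    @settings(max_examples=25, deadline=None)
    def test_group_sizes_property(self, na, nb, seed):
        labels = np.array(["a"] * na + ["b"] * nb)
        idx = subsample_balanced(labels, np.random.default_rng(seed))
        m = min(na, nb)
        assert (labels[idx] == "a").sum() == m
        assert (labels[idx] == "b").sum() == m


class TestIncludeSession:
    def test_too_few_control_trials(self, toy_session):
        ok, reason = include_session(toy_session, check_behavior=False)
        assert not ok and "control trial count" in reason

    def test_good_session_included(self, small_session):
        session, _ = small_session
        ok, reason = include_session(session, n_shuffles=500, seed=0)
        assert ok, reason

    def test_chance_performer_excluded(self):
        from commdyn.simulate import SimConfig, simulate_session

        cfg = SimConfig(n_source=5, n_target=5, n_control=80,
                        n_silencing_per_window=10, hit_rate=0.5, fa_rate=0.5, seed=5)
        session, _ = simulate_session(cfg)
        ok, reason = include_session(session, n_shuffles=500, seed=1)
        assert not ok and "d-prime" in reason
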