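"""Synthetic-session generator: determinism, planted structure, conservation."""

import numpy as np
import pytest

from commdyn.session import window_counts
from commdyn.simulate import (
    SimConfig,
    make_effect_sequence,
    rotating_unit_patterns,
    simulate_behavior,
    simulate_session,
)


def _unit_rows(x):
    return x / np.linalg.norm(x, axis=1, keepdims=True)


class TestEffectSequence:
    @staticmethod
    def _log_gain(cfg, e):
        from commdyn.simulate import _gain_sd_for_magnitude

        sd = _gain_sd_for_magnitude(cfg.effect_magnitude / 100.0)
        return np.log1p(e / 100.0) + 0.5 * sd * sd

    def test_static_mode_all_cosines_one(self):
        cfg = SimConfig(silencing_effect_mode="static", seed=3)
        e = make_effect_sequence(cfg)
        u = _unit_rows(self._log_gain(cfg, e))
        cos = u @ u.T
        np.testing.assert_allclose(cos, 1.0, atol=1e-12)

    def test_orthogonal_rotation_adjacent_cosine_zero(self):
        cfg = SimConfig(silencing_effect_mode="rotating",
                        effect_rotation_cos_per_lag=0.0, n_target=50, seed=4)
        u = _unit_rows(self._log_gain(cfg, make_effect_sequence(cfg)))
        adj = [u[i] @ u[i + 1] for i in range(7)]
        np.testing.assert_allclose(adj, 0.0, atol=1e-10)

    def test_markov_lag2_cosine_near_c_squared(self):
        # composed planar rotations: E[cos at lag 2] = c^2
        c = 0.6
        vals = []
        for seed in range(30):
            p = rotating_unit_patterns(np.random.default_rng(seed), 200, c)
            vals += [p[i] @ p[i + 2] for i in range(6)]
        assert abs(np.mean(vals) - c**2) < 0.02

    def test_magnitude_and_floor(self):
        cfg = SimConfig(silencing_effect_mode="rotating",
                        effect_rotation_cos_per_lag=0.2, effect_magnitude=40.0,
                        n_target=200, seed=0)
        e = make_effect_sequence(cfg)
        assert abs(np.mean(np.abs(e)) - 40.0) < 3.0
        assert e.min() > -100.0

    def test_rotation_needs_two_neurons(self):
        cfg = SimConfig(silencing_effect_mode="rotating",
                        effect_rotation_cos_per_lag=0.0, n_target=1)
        with pytest.raises(ValueError):
            make_effect_sequence(cfg)


class TestSimulateSession:
    def test_bit_identical_reproducibility(self):
        a, _ = simulate_session(SimConfig(seed=9, n_control=20, n_silencing_per_window=5,
                                          n_source=5, n_target=6))
        b, _ = simulate_session(SimConfig(seed=9, n_control=20, n_silencing_per_window=5,
                                          n_source=5, n_target=6))
        np.testing.assert_array_equal(a.spike_time, b.spike_time)
        np.testing.assert_array_equal(a.spike_neuron, b.spike_neuron)
        assert a.trials.equals(b.trials)

    def test_total_source_silencing_empties_window(self):
        cfg = SimConfig(seed=2, source_silencing_factor=0.0, n_control=20,
                        n_silencing_per_window=10, n_source=8, n_target=8)
        s, _ = simulate_session(cfg)
        for w in (1, 5):
            on = s.silencing_onsets[w - 1]
            cm = window_counts(s, (on, 150.0), s.trial_mask(window=w),
                               s.neuron_indices("source"))
            assert cm.counts.sum() == 0

    def test_rate_conservation_unsilenced(self):
        # prestim window: rate = baseline, no gains or latents
        cfg = SimConfig(seed=6, n_control=400, n_silencing_per_window=2,
                        n_source=5, n_target=5)
        s, truth = simulate_session(cfg)
        cm = window_counts(s, (-500.0, 500.0), s.trial_mask(condition="control"))
        est = cm.counts.mean(axis=0) / 0.5  # Hz
        # baseline rates are the first n draws of the generator; recompute
        rng = np.random.default_rng(6)
        base = rng.lognormal(cfg.baseline_rate_log_mean, cfg.baseline_rate_log_sd, 10)
        se = 3 * np.sqrt(base / (0.5 * 400))
        assert np.all(np.abs(est - base) < np.maximum(se, 0.5))

    def test_planted_effect_recovered_by_percent_change(self):
        # -50% on every target neuron; Poisson thinning makes the estimator consistent
        from commdyn.effects import percent_change

        cfg = SimConfig(seed=8, n_control=2500, n_silencing_per_window=2500 // 8,
                        n_source=4, n_target=6, silencing_effect_mode="static",
                        latent_rank=0)
        s, truth = simulate_session(cfg)
        tgt = s.neuron_indices("target")
        w = 3
        on = s.silencing_onsets[w - 1]
        sil = window_counts(s, (on, 150.0), s.trial_mask(window=w), tgt)
        ctl = window_counts(s, (on, 150.0), s.trial_mask(condition="control"), tgt)
        pc = percent_change(sil.counts.mean(0), ctl.counts.mean(0))
        err = pc - truth.effect_vectors_pct[w - 1]
        assert np.mean(np.abs(err)) < 8.0
        assert np.max(np.abs(err)) < 25.0

    def test_no_latent_means_no_noise_correlations(self):
        from commdyn.dynamics import pairwise_noise_correlations

        cfg = SimConfig(seed=13, latent_rank=0, n_control=300,
                        n_silencing_per_window=2, n_source=10, n_target=10)
        s, _ = simulate_session(cfg)
        tm = s.trial_mask(condition="control", stimulus="go")
        bins = np.stack(
            [window_counts(s, (w * 65.0, 65.0), tm).counts for w in range(7)], axis=1
        )
        nc = pairwise_noise_correlations(bins)
        assert abs(np.mean(nc["r"])) < 0.02


class TestSimulateBehavior:
    def test_deterministic_extremes(self):
        cfg = SimConfig(hit_rate=1.0, fa_rate=0.0)
        rng = np.random.default_rng(0)
        stim = np.array(["go"] * 50 + ["nogo"] * 50, dtype=object)
        licks = simulate_behavior(cfg, stim, rng)
        assert np.isfinite(licks[:50]).all()
        assert np.isnan(licks[50:]).all()

    def test_no_lick_before_truncation_bound(self):
        cfg = SimConfig(hit_rate=1.0, rt_shift_ms=150.0)
        rng = np.random.default_rng(1)
        licks = simulate_behavior(cfg, np.array(["go"] * 500, dtype=object), rng)
        assert np.nanmin(licks) >= 150.0

    def test_chance_rates_give_zero_dprime(self):
        from commdyn.behavior import dprime

        cfg = SimConfig(hit_rate=0.5, fa_rate=0.5)
        rng = np.random.default_rng(2)
        stim = np.array(["go", "nogo"] * 5000, dtype=object)
        licks = simulate_behavior(cfg, stim, rng)
        hit = np.isfinite(licks[::2]).mean()
        fa = np.isfinite(licks[1::2]).mean()
        assert abs(dprime(hit, fa, 5000, 5000)) < 0.08
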