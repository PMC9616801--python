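"""Outcome classification, d-prime, shuffle chance, onset correction."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from commdyn.behavior import (
    classify_trials,
    dprime,
    dprime_chance,
    onset_corrected_metrics,
)
from commdyn.session import SessionData


def _behavior_session(lick_times, stimuli, windows=None):
    n = len(lick_times)
    windows = np.zeros(n, dtype=int) if windows is None else np.asarray(windows)
    trials = pd.DataFrame(
        dict(
            stimulus=stimuli,
            condition=np.where(windows == 0, "control", "silencing"),
            silencing_window=windows,
            lick_time=lick_times,
        )
    )
    neurons = pd.DataFrame(dict(area=["source", "target"]))
    return SessionData("b", neurons, trials, np.array([], dtype=int),
                       np.array([], dtype=int), np.array([]))


class TestClassification:
    def test_outcomes(self):
        s = _behavior_session(
            [300.0, 50.0, np.nan, 200.0, np.nan],
            ["go", "go", "go", "nogo", "nogo"],
        )
        out = classify_trials(s)
        assert list(out) == ["hit", "miss", "miss", "false_alarm", "correct_rejection"]


class TestDprime:
    def test_symmetric_rates_zero(self):
        assert dprime(0.4, 0.4) == pytest.approx(0.0)

    @pytest.mark.parametrize(
        "hit,fa,expected",
        [(0.8, 0.2, stats.norm.ppf(0.8) - stats.norm.ppf(0.2)),
         (0.9, 0.1, stats.norm.ppf(0.9) - stats.norm.ppf(0.1))],
    )
    def test_quantile_oracle(self, hit, fa, expected):
        assert dprime(hit, fa) == pytest.approx(expected, abs=1e-9)

    def test_antisymmetry(self):
        assert dprime(0.75, 0.3) == pytest.approx(-dprime(0.3, 0.75))

    def test_boundary_clipping_keeps_finite(self):
        d = dprime(1.0, 0.0, n_go=50, n_nogo=50)
        assert np.isfinite(d)
        assert d == pytest.approx(2 * stats.norm.ppf(1 - 1 / 100))


class TestChanceLevel:
    def test_perfect_performance_beats_chance(self):
        rng = np.random.default_rng(0)
        stim = np.array(["go", "nogo"] * 50, dtype=object)
        licks = np.where(stim == "go", 300.0, np.nan)
        s = _behavior_session(licks, stim)
        chance = dprime_chance(s, n_shuffles=500, seed=1)
        obs = dprime(1.0, 0.0, 50, 50)
        assert obs > chance

    def test_calibration_of_chance_level(self):
        # stimulus-independent licking: ~1% of sessions should beat the 99th pctile
        rng = np.random.default_rng(2)
        above = 0
        n_sessions = 120
        for i in range(n_sessions):
            stim = np.array(["go", "nogo"] * 60, dtype=object)
            lick = np.where(rng.random(120) < 0.5, 300.0, np.nan)
            s = _behavior_session(lick, stim)
            hit = np.isfinite(lick[stim == "go"]).mean()
            fa = np.isfinite(lick[stim == "nogo"]).mean()
            obs = dprime(hit, fa, 60, 60)
            if obs > dprime_chance(s, n_shuffles=300, seed=rng.integers(2**31)):
                above += 1
        assert above / n_sessions < 0.06


class TestOnsetCorrection:
    def _session(self, rt_shift_early=0.0):
        rng = np.random.default_rng(3)
        n_ctrl, n_per_win = 80, 20
        windows = np.concatenate([np.zeros(n_ctrl, dtype=int),
                                  np.repeat(np.arange(1, 9), n_per_win)])
        stim = np.array(["go", "nogo"] * (len(windows) // 2), dtype=object)
        rng.shuffle(stim)
        lick = np.full(len(windows), np.nan)
        go = stim == "go"
        lick[go] = 250.0 + 40 * rng.standard_normal(go.sum())
        early = (windows >= 1) & (windows <= 2) & go
        lick[early] += rt_shift_early
        lick = np.clip(lick, 110.0, 540.0)
        return _behavior_session(lick, stim, windows)

    def test_equal_rts_give_zero_percent_change(self):
        s = _behavior_session(
            np.array([300.0, np.nan] * 60), np.array(["go", "nogo"] * 60, dtype=object),
            np.tile(np.concatenate([np.zeros(8, dtype=int), np.arange(1, 9)]), 15)[:120],
        )
        res = onset_corrected_metrics(s, seed=0)
        rt = res.per_window.rt_pct.dropna()
        assert np.allclose(rt, 0.0, atol=1e-9)

    def test_planted_early_rt_slowdown_detected(self):
        res0 = onset_corrected_metrics(self._session(0.0), seed=1)
        res1 = onset_corrected_metrics(self._session(60.0), seed=1)

        def early_contrast(res):
            el = res.early_late
            sil = el[(el.phase == "early") & (el.condition == "silencing")].rt_pct.iloc[0]
            ctl = el[(el.phase == "early") & (el.condition == "control")].rt_pct.iloc[0]
            return sil - ctl

        assert early_contrast(res1) > early_contrast(res0) + 5.0

    def test_lick_before_onset_excluded(self):
        # window 5 onset is 256 ms; a 200-ms lick cannot enter its statistic
        windows = np.array([5] * 10 + [0] * 20)
        stim = np.array(["go"] * 15 + ["nogo"] * 15, dtype=object)
        lick = np.full(30, np.nan)
        lick[:10] = 200.0
        s = _behavior_session(lick, stim, windows)
        res = onset_corrected_metrics(s, seed=2)
        row = res.per_window[(res.per_window.window == 5)
                             & (res.per_window.condition == "silencing")]
        assert np.isnan(row.rt_pct.iloc[0])
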