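"""Go/no-go behavioural metrics: outcomes, d-prime, shuffle chance levels and
onset-corrected silencing contrasts.

d-prime is the signal-detection discriminability Z(hit rate) - Z(false-alarm
rate), with Z the standard-normal quantile function.  Rates of exactly 0 or
1 are clipped with the 1/(2N) rule so d-prime stays finite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from commdyn.session import CONTROL, GO, NOGO, SessionData

HIT, MISS, FA, CR = "hit", "miss", "false_alarm", "correct_rejection"

DEFAULT_RESPONSE_WINDOW = (100.0, 550.0)


def classify_trials(session: SessionData, response_window: tuple = DEFAULT_RESPONSE_WINDOW) -> np.ndarray:
    """Outcome per trial from lick times.

    A lick inside the response window makes a go trial a hit and a no-go
    trial a false alarm; otherwise miss / correct rejection.
    """
    lo, hi = response_window
    lick = session.trials["lick_time"].to_numpy(dtype=float)
    licked = np.isfinite(lick) & (lick >= lo) & (lick <= hi)
    is_go = (session.trials["stimulus"] == GO).to_numpy()
    out = np.where(is_go, np.where(licked, HIT, MISS), np.where(licked, FA, CR))
    return out


def dprime(hit_rate: float, fa_rate: float, n_go: int | None = None, n_nogo: int | None = None) -> float:
    """Z(hit rate) - Z(false-alarm rate).

    When trial counts are supplied, boundary rates are clipped to
    ``1/(2N)`` / ``1 - 1/(2N)`` (standard signal-detection practice).
    """

    def _clip(p: float, n: int | None) -> float:
        if n is not None and n > 0:
            return float(np.clip(p, 1.0 / (2 * n), 1.0 - 1.0 / (2 * n)))
        return float(np.clip(p, 1e-12, 1.0 - 1e-12))

    return float(stats.norm.ppf(_clip(hit_rate, n_go)) - stats.norm.ppf(_clip(fa_rate, n_nogo)))


def _rates(outcomes: np.ndarray) -> tuple[float, float, int, int]:
    outcomes = np.asarray(outcomes)
    n_go = int(np.sum(outcomes == HIT) + np.sum(outcomes == MISS))
    n_nogo = int(np.sum(outcomes == FA) + np.sum(outcomes == CR))
    hit = np.sum(outcomes == HIT) / n_go if n_go else np.nan
    fa = np.sum(outcomes == FA) / n_nogo if n_nogo else np.nan
    return float(hit), float(fa), n_go, n_nogo


@dataclass
class BehaviorSummary:
    hit_rate: float
    fa_rate: float
    dprime: float
    n_go: int
    n_nogo: int
    rt_values: np.ndarray  # first-lick times (ms) on hit trials


def behavior_summary(session: SessionData, response_window: tuple = DEFAULT_RESPONSE_WINDOW) -> BehaviorSummary:
    keep = session.trial_mask()
    outcomes = classify_trials(session, response_window)[keep]
    hit, fa, n_go, n_nogo = _rates(outcomes)
    lick = session.trials["lick_time"].to_numpy(dtype=float)[keep]
    rts = lick[(outcomes == HIT)]
    return BehaviorSummary(hit, fa, dprime(hit, fa, n_go, n_nogo), n_go, n_nogo, rts)


def dprime_chance(
    session: SessionData,
    n_shuffles: int = 5000,
    seed: int | np.random.Generator = 0,
    response_window: tuple = DEFAULT_RESPONSE_WINDOW,
    percentile: float = 99.0,
) -> float:
    """Chance-level d-prime: the given percentile of the null distribution
    obtained by shuffling go/no-go trial identities.
    """
    rng = np.random.default_rng(seed)
    keep = session.trial_mask()
    lo, hi = response_window
    lick = session.trials["lick_time"].to_numpy(dtype=float)[keep]
    licked = np.isfinite(lick) & (lick >= lo) & (lick <= hi)
    is_go = (session.trials["stimulus"] == GO).to_numpy()[keep]
    n_go, n_nogo = int(is_go.sum()), int((~is_go).sum())
    if n_go < 2 or n_nogo < 2:
        raise ValueError("need at least 2 trials per stimulus to shuffle")
    null = np.empty(n_shuffles)
    for i in range(n_shuffles):
        perm = rng.permutation(is_go)
        hit = licked[perm].mean()
        fa = licked[~perm].mean()
        null[i] = dprime(hit, fa, n_go, n_nogo)
    return float(np.percentile(null, percentile))


@dataclass
class OnsetCorrectedResult:
    """Per-window and early/late percent-change tables for RT and d-prime.

    ``per_window`` has one row per (window, condition) with onset-corrected
    and raw percent changes; ``early_late`` aggregates windows whose onset
    precedes the early/late split.  Cells with no qualifying trials are NaN.
    """

    per_window: pd.DataFrame
    early_late: pd.DataFrame
    mean_rt: float
    mean_dprime: float


def onset_corrected_metrics(
    session: SessionData,
    split_ms: float = 100.0,
    response_window: tuple = DEFAULT_RESPONSE_WINDOW,
    seed: int | np.random.Generator = 0,
) -> OnsetCorrectedResult:
    """Silencing-window-resolved behavioural contrasts.

    For each silencing window, only trials whose first lick started after
    the window's onset enter the statistic (a lick that preceded the
    silencing cannot reflect its effect); no-lick trials are always
    retained.  Each control trial is assigned one of the 8 onsets at random
    (seeded) so control pseudo-windows are filtered identically.  Reaction
    time (first lick on hit trials) and d-prime are expressed as percent
    change from the session mean: ``100 * (x - mean) / mean``.  Raw
    (uncorrected) variants skip the lick-after-onset rule.
    """
    rng = np.random.default_rng(seed)
    keep = session.trial_mask()
    trials = session.trials.loc[keep]
    outcomes = classify_trials(session, response_window)[keep]
    lick = trials["lick_time"].to_numpy(dtype=float)
    cond = trials["condition"].to_numpy()
    silwin = trials["silencing_window"].to_numpy()
    onsets = np.asarray(session.silencing_onsets, dtype=float)

    # control trials get a random pseudo-window each
    pseudo = silwin.copy()
    is_ctrl = cond == CONTROL
    pseudo[is_ctrl] = rng.integers(1, 9, size=int(is_ctrl.sum()))

    mean_rt = float(np.nanmean(lick[outcomes == HIT])) if np.any(outcomes == HIT) else np.nan
    hit, fa, n_go, n_nogo = _rates(outcomes)
    mean_dp = dprime(hit, fa, n_go, n_nogo)

    def _cell(sel: np.ndarray, onset: float, corrected: bool) -> tuple[float, float, int]:
        if corrected:
            sel = sel & (~np.isfinite(lick) | (lick > onset))
        n = int(sel.sum())
        if n == 0:
            return np.nan, np.nan, 0
        out = outcomes[sel]
        rts = lick[sel & (outcomes == HIT)]
        rt_pct = 100.0 * (np.mean(rts) - mean_rt) / mean_rt if rts.size else np.nan
        h, f, ng, nn = _rates(out)
        dp_pct = (
            100.0 * (dprime(h, f, ng, nn) - mean_dp) / mean_dp
            if (ng and nn and mean_dp != 0)
            else np.nan
        )
        return rt_pct, dp_pct, n

    rows = []
    for w in range(1, 9):
        onset = onsets[w - 1]
        for condition in (CONTROL, "silencing"):
            sel = (pseudo == w) & (is_ctrl if condition == CONTROL else ~is_ctrl)
            rt_pct, dp_pct, n = _cell(sel, onset, corrected=True)
            rt_raw, dp_raw, _ = _cell(sel, onset, corrected=False)
            rows.append(
                dict(
                    window=w, onset_ms=onset, condition=condition, n_trials=n,
                    rt_pct=rt_pct, dprime_pct=dp_pct,
                    rt_pct_raw=rt_raw, dprime_pct_raw=dp_raw,
                    phase="early" if onset < split_ms else "late",
                )
            )
    per_window = pd.DataFrame(rows)
    early_late = (
        per_window.groupby(["phase", "condition"], as_index=False)[
            ["rt_pct", "dprime_pct", "rt_pct_raw", "dprime_pct_raw"]
        ].mean()
    )
    return OnsetCorrectedResult(per_window, early_late, mean_rt, mean_dp)
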