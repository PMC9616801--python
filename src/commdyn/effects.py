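"""Per-neuron silencing-effect quantification and selectivity indices.

The effect of silencing the source area on a target neuron is the percent
change ``100 * (Rs - Rc) / Rc`` between its mean spike count in the 150-ms
silencing window (Rs) and in the same window on control trials (Rc).
Significance is assessed against a bootstrap null built purely from control
trials: control trials are resampled with replacement into two pseudo-groups
of the observed condition sizes and the percent change between their means
is recomputed ``n_boot`` times.  An observed effect is significant when it
falls outside the [2.5, 97.5] percentile interval of that null; the
Bonferroni-for-8-windows variant uses [0.3125, 99.6875] (alpha/8,
two-sided).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from commdyn.behavior import CR, FA, HIT, MISS
from commdyn.session import CONTROL, GO, NOGO, SessionData, window_counts, rate_threshold_mask

RAW_PCTL = (2.5, 97.5)
BONF8_PCTL = (100 * 0.05 / 16, 100 * (1 - 0.05 / 16))  # (0.3125, 99.6875)


def percent_change(rs_mean, rc_mean):
    """``100 * (Rs - Rc) / Rc``; NaN (masked) where the control mean is 0."""
    rs = np.asarray(rs_mean, dtype=float)
    rc = np.asarray(rc_mean, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(rc > 0, 100.0 * (rs - rc) / rc, np.nan)
    return out if out.ndim else float(out)


@dataclass
class EffectSignificance:
    percent_change: float
    null_lo: float
    null_hi: float
    null_lo_bonf: float
    null_hi_bonf: float
    significant: bool
    significant_bonf8: bool
    n_control: int
    n_silencing: int


def _null_percentiles(
    control: np.ndarray, n_sil: int, n_boot: int, rng: np.random.Generator
) -> np.ndarray:
    """Null percent-change distribution percentiles, per neuron.

    ``control`` is (n_control, n_neurons); each neuron gets its own
    independent resampling draws.  Returns (4, n_neurons):
    raw lo/hi then Bonferroni lo/hi.
    """
    n_c, n_neur = control.shape
    out = np.empty((4, n_neur))
    chunk = max(1, int(4e6 / (n_boot * max(n_c, n_sil))))
    for j0 in range(0, n_neur, chunk):
        j1 = min(j0 + chunk, n_neur)
        cols = control[:, j0:j1]
        ch = j1 - j0
        idx_c = rng.integers(0, n_c, (n_boot, n_c, ch))
        idx_s = rng.integers(0, n_c, (n_boot, n_sil, ch))
        mc = cols[idx_c, np.arange(ch)].mean(axis=1)
        ms = cols[idx_s, np.arange(ch)].mean(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            null = np.where(mc > 0, 100.0 * (ms - mc) / mc, np.nan)
        out[:, j0:j1] = np.nanpercentile(
            null, [RAW_PCTL[0], RAW_PCTL[1], BONF8_PCTL[0], BONF8_PCTL[1]], axis=0
        )
    return out


def effect_significance_matrix(
    control: np.ndarray,
    silencing: np.ndarray,
    n_boot: int = 1000,
    seed: int | np.random.Generator = 0,
    min_trials: int = 5,
) -> pd.DataFrame:
    """Vectorised effect + bootstrap significance for many neurons at once.

    ``control``/``silencing`` are (trials, neurons) spike-count matrices in
    a common window.  Neurons with an all-zero control mean are masked
    (NaN effect, not significant).
    """
    control = np.asarray(control, dtype=float)
    silencing = np.asarray(silencing, dtype=float)
    if control.shape[0] < min_trials or silencing.shape[0] < min_trials:
        raise ValueError(f"need at least {min_trials} trials per condition")
    rng = np.random.default_rng(seed)
    mc, ms = control.mean(axis=0), silencing.mean(axis=0)
    pc = percent_change(ms, mc)
    lo, hi, blo, bhi = _null_percentiles(control, silencing.shape[0], n_boot, rng)
    ok = np.isfinite(pc) & np.isfinite(lo) & np.isfinite(hi)
    sig = ok & ((pc < lo) | (pc > hi))
    sigb = ok & np.isfinite(blo) & np.isfinite(bhi) & ((pc < blo) | (pc > bhi))
    return pd.DataFrame(
        dict(
            percent_change=pc, null_lo=lo, null_hi=hi,
            null_lo_bonf=blo, null_hi_bonf=bhi,
            significant=sig, significant_bonf8=sigb,
            n_control=control.shape[0], n_silencing=silencing.shape[0],
        )
    )


def effect_significance(
    control_counts: np.ndarray,
    silencing_counts: np.ndarray,
    n_boot: int = 1000,
    seed: int | np.random.Generator = 0,
    min_trials: int = 5,
) -> EffectSignificance:
    """Single-neuron wrapper around :func:`effect_significance_matrix`."""
    df = effect_significance_matrix(
        np.asarray(control_counts, dtype=float)[:, None],
        np.asarray(silencing_counts, dtype=float)[:, None],
        n_boot=n_boot, seed=seed, min_trials=min_trials,
    )
    r = df.iloc[0]
    return EffectSignificance(
        float(r.percent_change), float(r.null_lo), float(r.null_hi),
        float(r.null_lo_bonf), float(r.null_hi_bonf),
        bool(r.significant), bool(r.significant_bonf8),
        int(r.n_control), int(r.n_silencing),
    )


def effect_table(
    session: SessionData,
    target_area: str,
    stimuli: tuple = (GO, NOGO, "pooled"),
    threshold_hz: float = 2.5,
    n_boot: int = 1000,
    seed: int | np.random.Generator = 0,
    neurons: np.ndarray | None = None,
) -> pd.DataFrame:
    """Tidy per (neuron, window, stimulus) silencing-effect table.

    For every silencing window the 150-ms counts of silencing trials are
    compared with the same window on control trials.  Neurons below the
    firing-rate threshold (evaluated on the window's trials pooled across
    conditions) are masked for that window.  ``stimulus == "pooled"`` uses
    go and no-go trials together.
    """
    rng = np.random.default_rng(seed)
    if neurons is None:
        neurons = session.neuron_indices(target_area)
    rows = []
    for w in range(1, 9):
        onset = session.silencing_onsets[w - 1]
        win = (float(onset), session.silencing_duration)
        pooled_cm = window_counts(
            session, win,
            session.trial_mask(condition=CONTROL) | session.trial_mask(window=w),
            neurons,
        )
        keep_rate = rate_threshold_mask(pooled_cm, threshold_hz)
        for stim in stimuli:
            stim_arg = None if stim == "pooled" else stim
            ctrl = window_counts(
                session, win, session.trial_mask(condition=CONTROL, stimulus=stim_arg), neurons
            )
            sil = window_counts(
                session, win, session.trial_mask(window=w, stimulus=stim_arg), neurons
            )
            df = effect_significance_matrix(ctrl.counts, sil.counts, n_boot=n_boot, seed=rng)
            df.loc[~keep_rate, ["percent_change", "null_lo", "null_hi", "null_lo_bonf", "null_hi_bonf"]] = np.nan
            df.loc[~keep_rate, ["significant", "significant_bonf8"]] = False
            df.insert(0, "neuron", neurons)
            df.insert(1, "window", w)
            df.insert(2, "stimulus", stim)
            df.insert(3, "masked", ~keep_rate)
            rows.append(df)
    return pd.concat(rows, ignore_index=True)


def count_significant_windows(table: pd.DataFrame, stimulus: str = "pooled") -> pd.Series:
    """Number of Bonferroni-significant windows (0..8) per neuron.

    Effects are evaluated on go and no-go trials together (``"pooled"``)
    unless another stimulus slice is requested.
    """
    sub = table[table["stimulus"] == stimulus]
    return sub.groupby("neuron")["significant_bonf8"].sum().astype(int)


def _safe_ratio(a: float, b: float) -> float:
    return (a - b) / (a + b) if (a + b) > 0 else np.nan


def selectivity_indices(
    session: SessionData,
    area: str | None = None,
    early_ms: float = 150.0,
) -> pd.DataFrame:
    """Choice and stimulus selectivity per neuron from control trials.

    * choice index: mean of the hit-vs-miss and false-alarm-vs-correct-
      rejection normalised rate differences over the full 500-ms stimulus.
    * stimulus index: |(rH - rC) / (rH + rC)| from the first ``early_ms``
      (pre-movement) of hit and correct-rejection trials; the preferred
      stimulus is the sign of (rH - rC).
    * choice-matched stimulus index: |((RH-RF)/(RH+RF) + (RM-RC)/(RM+RC))/2|.

    Indices with a zero denominator are masked (NaN).
    """
    neurons = session.neuron_indices(area)
    dur = session.stimulus_duration
    full = {}
    early = {}
    for out in (HIT, MISS, FA, CR):
        tmask = session.trial_mask(outcomes=(out,)) & session.trial_mask(condition=CONTROL)
        if tmask.sum() == 0:
            full[out] = np.full(neurons.size, np.nan)
            early[out] = np.full(neurons.size, np.nan)
            continue
        full[out] = window_counts(session, (0.0, dur), tmask, neurons).counts.mean(axis=0)
        early[out] = window_counts(session, (0.0, early_ms), tmask, neurons).counts.mean(axis=0)

    rows = []
    for j, n in enumerate(neurons):
        RH, RM, RF, RC = (full[o][j] for o in (HIT, MISS, FA, CR))
        rH, rC = early[HIT][j], early[CR][j]
        t1, t2 = _safe_ratio(RH, RM), _safe_ratio(RF, RC)
        choice = (t1 + t2) / 2 if np.isfinite(t1) and np.isfinite(t2) else np.nan
        sidx = abs(_safe_ratio(rH, rC)) if np.isfinite(_safe_ratio(rH, rC)) else np.nan
        pref = int(np.sign(rH - rC)) if (rH + rC) > 0 else 0
        m1, m2 = _safe_ratio(RH, RF), _safe_ratio(RM, RC)
        cm = abs((m1 + m2) / 2) if np.isfinite(m1) and np.isfinite(m2) else np.nan
        rows.append(
            dict(
                neuron=n, choice_index=choice, stimulus_index=sidx,
                preferred_stimulus_sign=pref, stimulus_index_choice_matched=cm,
            )
        )
    return pd.DataFrame(rows)
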