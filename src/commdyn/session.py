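"""Session container, spike-count windowing, inclusion filters and trial balancing.

A session is one animal's simultaneous two-area recording: per-neuron spike
times relative to visual stimulus onset, a trial table (go/no-go stimulus,
control vs. silencing condition, silencing-window index 1..8, lick time,
outcome) and neuron metadata (area, cortical depth, receptive-field distance
from the silenced retinotopic location, session mean rate).

Conventions
-----------
* All times are milliseconds relative to visual stimulus onset (onset = 0).
* Analysis windows are half-open ``[onset, onset + duration)``: a spike
  exactly on the right edge belongs to the next window, so disjoint windows
  tiling the stimulus partition its spikes exactly.
* ``trials.silencing_window`` is 1..8 for silencing trials and 0 for control
  trials (condition == "control" iff silencing_window == 0).
* Low-rate entries are handled with an explicit validity mask on count
  matrices rather than NaNs; masked entries are excluded from every
  downstream statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_SILENCING_ONSETS = (0.0, 56.0, 123.0, 189.0, 256.0, 323.0, 390.0, 456.0)

GO, NOGO = "go", "nogo"
CONTROL, SILENCING = "control", "silencing"


@dataclass
class SessionData:
    """One animal's paired-area recording session.

    Parameters
    ----------
    animal_id : str
        Opaque label.
    neurons : pandas.DataFrame
        One row per neuron with at least column ``area`` (two distinct
        values per session, e.g. ``"V1"``/``"LM"`` or ``"source"``/
        ``"target"``); optional ``depth`` (um relative to the initial
        current sink), ``rf_distance`` (visual degrees from the silencing
        retinotopic centre), ``mean_rate`` (Hz) and ``waveform_class``.
    trials : pandas.DataFrame
        One row per trial: ``stimulus`` in {"go", "nogo"}, ``condition`` in
        {"control", "silencing"}, ``silencing_window`` (0 for control,
        1..8 otherwise), ``lick_time`` (ms or NaN), optional ``outcome``
        and ``excluded`` (bool).
    spike_neuron, spike_trial, spike_time : ndarray
        Flat parallel arrays: one entry per spike event, giving the neuron
        row index, the trial row index and the spike time in ms.
    """

    animal_id: str
    neurons: pd.DataFrame
    trials: pd.DataFrame
    spike_neuron: np.ndarray
    spike_trial: np.ndarray
    spike_time: np.ndarray
    stimulus_duration: float = 500.0
    silencing_duration: float = 150.0
    silencing_onsets: tuple = DEFAULT_SILENCING_ONSETS
    recording_span: tuple = (-500.0, 1100.0)

    def __post_init__(self) -> None:
        self.spike_neuron = np.asarray(self.spike_neuron, dtype=np.intp)
        self.spike_trial = np.asarray(self.spike_trial, dtype=np.intp)
        self.spike_time = np.asarray(self.spike_time, dtype=float)
        onsets = np.asarray(self.silencing_onsets, dtype=float)
        if onsets.size != 8 or np.any(np.diff(onsets) <= 0):
            raise ValueError("silencing_onsets must be 8 strictly increasing values")
        if not np.all(np.isfinite(self.spike_time)):
            raise ValueError("spike times must be finite")
        if "excluded" not in self.trials.columns:
            self.trials = self.trials.assign(excluded=False)
        win = self.trials["silencing_window"].to_numpy()
        ctrl = (self.trials["condition"] == CONTROL).to_numpy()
        if not np.array_equal(ctrl, win == 0):
            raise ValueError("condition == 'control' must coincide with silencing_window == 0")
        if not np.isin(win, np.arange(9)).all():
            raise ValueError("silencing_window indices must lie in {0, 1..8}")

    @property
    def n_neurons(self) -> int:
        return len(self.neurons)

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def areas(self) -> tuple:
        return tuple(pd.unique(self.neurons["area"]))

    def neuron_indices(self, area: str | None = None) -> np.ndarray:
        idx = np.arange(self.n_neurons)
        if area is None:
            return idx
        return idx[(self.neurons["area"] == area).to_numpy()]

    def trial_mask(
        self,
        condition: str | None = None,
        stimulus: str | None = None,
        window: int | None = None,
        outcomes: tuple | None = None,
        include_excluded: bool = False,
    ) -> np.ndarray:
        """Boolean mask over trials matching every given filter."""
        m = np.ones(self.n_trials, dtype=bool)
        if not include_excluded:
            m &= ~self.trials["excluded"].to_numpy(dtype=bool)
        if condition is not None:
            m &= (self.trials["condition"] == condition).to_numpy()
        if stimulus is not None:
            m &= (self.trials["stimulus"] == stimulus).to_numpy()
        if window is not None:
            m &= (self.trials["silencing_window"] == window).to_numpy()
        if outcomes is not None:
            m &= self.trials["outcome"].isin(outcomes).to_numpy()
        return m


@dataclass
class CountMatrix:
    """Spike counts of ``trial_index`` x ``neuron_index`` in one time window.

    ``mask`` flags valid entries; masked (False) entries are excluded from
    all statistics downstream.  The window is half-open ``[onset,
    onset + duration)``.
    """

    counts: np.ndarray
    window: tuple
    trial_index: np.ndarray
    neuron_index: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.mask is None:
            self.mask = np.ones(self.counts.shape, dtype=bool)
        if self.counts.shape != self.mask.shape:
            raise ValueError("counts and mask shapes differ")
        if np.any(self.counts < 0):
            raise ValueError("spike counts must be non-negative")

    @property
    def n_trials(self) -> int:
        return self.counts.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.counts.shape[1]

    @property
    def duration(self) -> float:
        return float(self.window[1])

    def neuron_valid(self) -> np.ndarray:
        """Neurons whose entries are valid in every trial of this matrix."""
        return self.mask.all(axis=0)

    def mean_rate_hz(self) -> np.ndarray:
        """Trial-averaged firing rate (Hz) per neuron over valid entries."""
        with np.errstate(invalid="ignore"):
            valid = self.mask.sum(axis=0)
            s = np.where(self.mask, self.counts, 0).sum(axis=0)
            rate = np.where(valid > 0, s / np.maximum(valid, 1), np.nan)
        return rate / self.duration * 1000.0

    def restrict_neurons(self, neuron_sel: np.ndarray) -> "CountMatrix":
        neuron_sel = np.asarray(neuron_sel)
        if neuron_sel.dtype == bool:
            neuron_sel = np.flatnonzero(neuron_sel)
        pos = {n: i for i, n in enumerate(self.neuron_index)}
        cols = np.array([pos[n] for n in neuron_sel], dtype=np.intp)
        return CountMatrix(
            self.counts[:, cols], self.window, self.trial_index.copy(),
            np.asarray(neuron_sel), self.mask[:, cols],
        )


class EmptySelectionError(ValueError):
    """Raised when a trial filter selects no trials."""


def window_counts(
    session: SessionData,
    window: tuple,
    trial_filter=None,
    neurons: np.ndarray | None = None,
) -> CountMatrix:
    """Count spikes per (trial, neuron) in a half-open window.

    Parameters
    ----------
    window : (onset_ms, duration_ms)
    trial_filter : None, boolean mask, index array, or callable
        Callable receives the trial table and returns a boolean mask.
    neurons : optional neuron row indices to keep (default: all).
    """
    onset, dur = float(window[0]), float(window[1])
    if dur <= 0:
        raise ValueError("window duration must be positive")
    lo, hi = session.recording_span
    if onset < lo or onset + dur > hi:
        raise ValueError(
            f"window [{onset}, {onset + dur}) outside recorded span [{lo}, {hi}]"
        )
    if onset < -session.stimulus_duration or onset > session.stimulus_duration:
        raise ValueError("window onset must lie within +/- stimulus_duration of onset")

    if trial_filter is None:
        tmask = ~session.trials["excluded"].to_numpy(dtype=bool)
    elif callable(trial_filter):
        tmask = np.asarray(trial_filter(session.trials), dtype=bool)
    else:
        tf = np.asarray(trial_filter)
        if tf.dtype == bool:
            tmask = tf
        else:
            tmask = np.zeros(session.n_trials, dtype=bool)
            tmask[tf] = True
    trial_ids = np.flatnonzero(tmask)
    if trial_ids.size == 0:
        raise EmptySelectionError("trial filter selected no trials")

    if neurons is None:
        neurons = np.arange(session.n_neurons)
    neurons = np.asarray(neurons, dtype=np.intp)

    trial_pos = np.full(session.n_trials, -1, dtype=np.intp)
    trial_pos[trial_ids] = np.arange(trial_ids.size)
    neuron_pos = np.full(session.n_neurons, -1, dtype=np.intp)
    neuron_pos[neurons] = np.arange(neurons.size)

    in_win = (session.spike_time >= onset) & (session.spike_time < onset + dur)
    tp = trial_pos[session.spike_trial]
    np_ = neuron_pos[session.spike_neuron]
    keep = in_win & (tp >= 0) & (np_ >= 0)
    counts = np.zeros((trial_ids.size, neurons.size), dtype=np.int64)
    np.add.at(counts, (tp[keep], np_[keep]), 1)
    return CountMatrix(counts, (onset, dur), trial_ids, neurons)


def rate_threshold_mask(cm: CountMatrix, threshold_hz: float) -> np.ndarray:
    """Per-neuron keep flag: trial-averaged rate in this window >= threshold."""
    if threshold_hz < 0:
        raise ValueError("threshold must be non-negative")
    if threshold_hz == 0:
        return np.ones(cm.n_neurons, dtype=bool)
    rate = cm.mean_rate_hz()
    return np.where(np.isnan(rate), False, rate >= threshold_hz)


def apply_rate_threshold(
    cm: CountMatrix, threshold_hz: float, reference: CountMatrix | None = None
) -> CountMatrix:
    """Mask all entries of neurons whose window-averaged rate is below threshold.

    The firing-rate criterion guards against dividing by near-zero control
    rates in percent-change statistics.  By default the rate is evaluated on
    ``cm`` itself; pass ``reference`` to evaluate it on a pooled matrix
    (e.g. control + silencing trials of the same window) instead.
    """
    keep = rate_threshold_mask(reference if reference is not None else cm, threshold_hz)
    mask = cm.mask & keep[None, :]
    return replace(cm, mask=mask)


def _paired_wilcoxon_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided paired signed-rank p; 1.0 when every pair ties."""
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    if np.all(d == 0):
        return 1.0
    res = stats.wilcoxon(d, zero_method="wilcox", alternative="two-sided")
    return float(res.pvalue)


def select_responsive_neurons(
    session: SessionData,
    alpha: float = 0.05,
    min_mean_count: float = 1.0,
    area: str | None = None,
) -> np.ndarray:
    """Visually responsive neurons.

    A neuron is kept if, on control trials of at least one stimulus, it
    (a) spikes at least ``min_mean_count`` times on average during the
    500-ms stimulus, and (b) shows a significant paired difference
    (two-sided Wilcoxon signed-rank, p < ``alpha``) between its stimulus
    spike count and its count in the 500-ms window preceding stimulus onset.
    """
    neurons = session.neuron_indices(area)
    dur = session.stimulus_duration
    keep = np.zeros(neurons.size, dtype=bool)
    for stim in (GO, NOGO):
        tmask = session.trial_mask(condition=CONTROL, stimulus=stim)
        if tmask.sum() < 2:
            raise ValueError(f"need at least 2 control {stim} trials")
        stim_cm = window_counts(session, (0.0, dur), tmask, neurons)
        base_cm = window_counts(session, (-dur, dur), tmask, neurons)
        mean_ok = stim_cm.counts.mean(axis=0) >= min_mean_count
        for j in np.flatnonzero(mean_ok & ~keep):
            p = _paired_wilcoxon_p(stim_cm.counts[:, j], base_cm.counts[:, j])
            if p < alpha:
                keep[j] = True
    return neurons[keep]


def subsample_balanced(labels, rng) -> np.ndarray:
    """Downsample each label group, without replacement, to the smallest
    group size; returns sorted indices into ``labels``.  Reproducible for a
    given ``rng`` state; never duplicates an index.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("empty label array")
    groups = pd.unique(labels)
    idx_by_group = {g: np.flatnonzero(labels == g) for g in groups}
    for g, idx in idx_by_group.items():
        if idx.size == 0:
            raise ValueError(f"group {g!r} is empty")
    m = min(idx.size for idx in idx_by_group.values())
    chosen = [rng.choice(idx, size=m, replace=False) for idx in idx_by_group.values()]
    return np.sort(np.concatenate(chosen))


def include_session(
    session: SessionData,
    min_control_trials: int = 10,
    check_behavior: bool = True,
    n_shuffles: int = 5000,
    seed: int | np.random.Generator = 0,
) -> tuple[bool, str]:
    """Session-level inclusion rule.

    Requires at least ``min_control_trials`` control trials and, for
    trained-task analyses, behavioural d-prime above the 99th percentile of
    the trial-shuffled null (see :func:`commdyn.behavior.dprime_chance`).
    Returns ``(included, reason)``; reason is empty when included.
    """
    n_control = int(session.trial_mask(condition=CONTROL).sum())
    if n_control < min_control_trials:
        return False, f"control trial count {n_control} < {min_control_trials}"
    if check_behavior:
        from commdyn import behavior

        summ = behavior.behavior_summary(session)
        chance = behavior.dprime_chance(session, n_shuffles=n_shuffles, seed=seed)
        if not summ.dprime > chance:
            return False, (
                f"behavioural d-prime {summ.dprime:.3f} not above "
                f"shuffle chance level {chance:.3f}"
            )
    return True, ""
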