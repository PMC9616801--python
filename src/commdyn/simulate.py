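"""Synthetic two-area sessions with known ground truth.

The generator emulates the statistical structure the analysis assumes: a
source and a target population firing as doubly-stochastic Poisson processes
whose log-rates carry a shared low-rank latent factor (trial-to-trial noise
correlations and PCs), a slow shared temporal envelope over the stimulus,
go/no-go stimulus gains, and — on silencing trials — a near-complete
multiplicative suppression of the source together with a per-neuron
multiplicative effect vector on the target that either stays fixed across
the eight silencing windows or rotates at a controlled rate.  Go/no-go lick
behaviour is generated from hit / false-alarm probabilities with a shifted
lognormal reaction-time distribution.

Everything is reproducible: one ``numpy`` Generator seeded from
``SimConfig.seed`` drives all randomness in a fixed order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from commdyn.session import (
    CONTROL,
    DEFAULT_SILENCING_ONSETS,
    GO,
    NOGO,
    SILENCING,
    SessionData,
)

MIN_EFFECT_PCT = -99.0  # multiplicative effects below -100% are impossible


@dataclass
class SimConfig:
    """Generator parameters.

    Defaults mirror the experimental design the analysis targets: ~40-50
    neurons per area, ~100 control and ~78 silencing trials per window,
    500-ms stimuli, 150-ms silencing windows at eight onsets, near-complete
    source suppression (residual fraction 0.05), and d-prime ~ 1.7 behaviour
    (hit rate 0.8, false-alarm rate 0.2).
    """

    n_source: int = 40
    n_target: int = 50
    n_control: int = 100
    n_silencing_per_window: int = 78

    # log-normal baseline rates (Hz) and go/no-go stimulus gains
    baseline_rate_log_mean: float = float(np.log(5.0))
    baseline_rate_log_sd: float = 0.5
    stimulus_gain_log_mean: float = float(np.log(2.0))
    stimulus_gain_log_sd: float = 0.35

    # shared slow envelope over the 8 silencing-grid segments of the stimulus
    temporal_envelope: tuple = (1.3, 1.15, 1.05, 1.0, 0.95, 0.92, 0.9, 0.88)

    # low-rank log-rate latent factors
    latent_rank: int = 2
    latent_sd: float = 0.25
    latent_ar1: float = 0.7
    latent_loadings_rotation_per_window: float = 0.0  # radians per window step

    # silencing effects on target neurons
    silencing_effect_mode: str = "static"  # or "rotating"
    effect_magnitude: float = 40.0  # mean |percent change| over target neurons
    effect_rotation_cos_per_lag: float = 1.0
    source_silencing_factor: float = 0.05

    # behaviour
    hit_rate: float = 0.8
    fa_rate: float = 0.2
    rt_log_mu: float = float(np.log(150.0))
    rt_log_sigma: float = 0.35
    rt_shift_ms: float = 150.0

    stimulus_duration: float = 500.0
    silencing_duration: float = 150.0
    silencing_onsets: tuple = DEFAULT_SILENCING_ONSETS
    prestim_duration: float = 500.0
    posttim_duration: float = 200.0

    seed: int = 0

    def validate(self) -> None:
        if not (0 <= self.hit_rate <= 1 and 0 <= self.fa_rate <= 1):
            raise ValueError("hit/fa rates must lie in [0, 1]")
        if not (-1 <= self.effect_rotation_cos_per_lag <= 1):
            raise ValueError("effect_rotation_cos_per_lag must lie in [-1, 1]")
        if self.baseline_rate_log_sd < 0 or self.latent_sd < 0:
            raise ValueError("scale parameters must be non-negative")
        if not (0 <= self.source_silencing_factor):
            raise ValueError("source_silencing_factor must be non-negative")
        if self.silencing_effect_mode not in ("static", "rotating"):
            raise ValueError("silencing_effect_mode must be 'static' or 'rotating'")
        if len(self.temporal_envelope) != 8:
            raise ValueError("temporal_envelope must have 8 entries")
        if np.any(np.asarray(self.temporal_envelope) <= 0):
            raise ValueError("rates must stay positive")


@dataclass
class GroundTruth:
    """Planted quantities exported for recovery tests."""

    effect_vectors_pct: np.ndarray  # (8, n_target) true percent change per window
    adjacent_effect_cosines: np.ndarray  # (7,) cos between consecutive windows
    latent_loadings: np.ndarray  # (8, rank, n_neurons)
    hit_rate: float
    fa_rate: float
    config: dict = field(default_factory=dict)


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def rotating_unit_patterns(
    rng: np.random.Generator, n: int, cos_per_lag: float, n_windows: int = 8
) -> np.ndarray:
    """Markov sequence of unit patterns with exact adjacent cosine.

    ``p_{w+1} = c * p_w + sqrt(1 - c^2) * u`` with ``u`` a random unit
    vector orthogonal to ``p_w``; composing the steps makes the expected
    lag-2 cosine ``c^2`` (planar-rotation composition), up to
    O(1/sqrt(n)) fluctuations.
    """
    if abs(cos_per_lag) < 1 and n < 2:
        raise ValueError("rotation requires at least 2 components")
    p = np.empty((n_windows, n))
    p[0] = _unit(rng.standard_normal(n))
    for w in range(1, n_windows):
        if cos_per_lag >= 1.0:
            p[w] = p[0]
            continue
        u = rng.standard_normal(n)
        u -= (u @ p[w - 1]) * p[w - 1]
        p[w] = cos_per_lag * p[w - 1] + np.sqrt(max(1.0 - cos_per_lag**2, 0.0)) * _unit(u)
    return p


def _gain_sd_for_magnitude(mag_frac: float) -> float:
    """log-gain SD such that E|exp(g) - 1| equals the target |effect|."""
    if mag_frac <= 0:
        return 0.0
    from scipy import optimize, stats

    def mean_abs(s):
        # E|e^(g - s^2/2) - 1| for g ~ N(0, s^2), by Gauss-Hermite quadrature
        x, w = np.polynomial.hermite_e.hermegauss(61)
        return float(np.sum(w * np.abs(np.exp(s * x - 0.5 * s * s) - 1.0)) / np.sqrt(2 * np.pi))

    return float(optimize.brentq(lambda s: mean_abs(s) - mag_frac, 1e-6, 5.0))


def make_effect_sequence(config: SimConfig, rng: np.random.Generator | None = None) -> np.ndarray:
    """Per-window target-neuron effect vectors (percent change), (8, n_target).

    Effects are multiplicative rate gains ``exp(g - sd^2/2)`` with Gaussian
    log-gain patterns g over neurons: the percent change respects the -100%
    floor by construction (a linear Gaussian pattern scaled to tens of
    percent would have to be clipped at the floor, which injects a spurious
    common component across windows), and the mean-one correction keeps the
    population-average gain at 1 so the planted pattern — not a Jensen
    offset shared by all windows — dominates the control-minus-silencing
    population direction.  ``static`` mode repeats one pattern;
    ``rotating`` mode plants a Markov rotation with
    ``cos(g_w, g_{w+1}) = effect_rotation_cos_per_lag`` exactly on the
    log-gain patterns.  The log-gain SD is set so the mean absolute percent
    change equals ``effect_magnitude``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n = config.n_target
    c = 1.0 if config.silencing_effect_mode == "static" else config.effect_rotation_cos_per_lag
    p = rotating_unit_patterns(rng, n, c)
    sd = _gain_sd_for_magnitude(config.effect_magnitude / 100.0)
    g = p * sd * np.sqrt(n)  # unit patterns -> per-neuron log-gain SD = sd
    return 100.0 * (np.exp(g - 0.5 * sd * sd) - 1.0)


def simulate_behavior(
    config: SimConfig, stimulus: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Lick times (ms, NaN = no lick) for the given go/no-go labels.

    Go trials lick with probability ``hit_rate``, no-go with ``fa_rate``;
    lick times are ``rt_shift_ms`` plus a lognormal, truncated to >= 100 ms.
    """
    stimulus = np.asarray(stimulus)
    p = np.where(stimulus == GO, config.hit_rate, config.fa_rate)
    licks = rng.random(stimulus.size) < p
    times = config.rt_shift_ms + rng.lognormal(config.rt_log_mu, config.rt_log_sigma, stimulus.size)
    for _ in range(100):  # truncation by resampling (no atom at the bound)
        bad = licks & (times < 100.0)
        if not bad.any():
            break
        times[bad] = config.rt_shift_ms + rng.lognormal(
            config.rt_log_mu, config.rt_log_sigma, int(bad.sum())
        )
    times = np.maximum(times, 100.0)
    return np.where(licks, times, np.nan)


def _tanh_gain_sd(mag_frac: float, cap: float = 0.95) -> float:
    from scipy import optimize

    x, w = np.polynomial.hermite_e.hermegauss(61)

    def mean_abs(s):
        return cap * float(np.sum(w * np.abs(np.tanh(s * x))) / np.sqrt(2 * np.pi))

    return float(optimize.brentq(lambda s: mean_abs(s) - mag_frac, 1e-3, 50.0))


def tanh_gain_sequence(
    rng: np.random.Generator, n: int, cos_per_lag: float, magnitude_pct: float,
    cap: float = 0.95,
) -> np.ndarray:
    """(8, n) multiplicative silencing gains with a planted pattern rotation.

    Gains are ``1 + cap * tanh(g)`` with Gaussian patterns g rotating by
    ``cos_per_lag`` per window (see :func:`rotating_unit_patterns`): bounded
    in (1-cap, 1+cap) so the -100% floor can never bind, odd in g so there
    is no mean offset shared across windows, and scaled so the mean
    absolute percent change equals ``magnitude_pct``.  Used for count-level
    benchmark datasets where the planted geometry must be exact.
    """
    p = rotating_unit_patterns(rng, n, cos_per_lag)
    sd = _tanh_gain_sd(magnitude_pct / 100.0, cap)
    return 1.0 + cap * np.tanh(p * sd * np.sqrt(n))


def simulate_cd_count_data(
    rng: np.random.Generator,
    n_neurons: int = 40,
    n_control: int = 80,
    n_sil_per_window: int = 48,
    base_mean: float = 5.0,
    go_cos: float = 0.2,
    nogo_cos: float | None = None,
    magnitude_pct: float = 50.0,
):
    """Count-level two-stimulus benchmark dataset for CD-dynamics statistics.

    Returns ``(ctrl, ctrl_go, sil, sil_go)``: control counts (8, n_control,
    n) with go labels, and per-window silencing counts with labels.  With
    ``nogo_cos=None`` go and no-go trials share one silencing-gain process
    (exchangeable null for permutation-test calibration); otherwise the two
    stimuli get independent gain sequences rotating at their own rates
    (e.g. a fast-rotating go vs. static no-go contrast).
    """
    m_go = tanh_gain_sequence(rng, n_neurons, go_cos, magnitude_pct)
    m_ng = m_go if nogo_cos is None else tanh_gain_sequence(rng, n_neurons, nogo_cos, magnitude_pct)
    ctrl = rng.poisson(base_mean, (8, n_control, n_neurons)).astype(float)
    ctrl_go = rng.permutation(np.repeat([True, False], n_control // 2))
    sil, sil_go = [], []
    for w in range(8):
        lab = rng.permutation(np.repeat([True, False], n_sil_per_window // 2))
        lam = np.where(lab[:, None], base_mean * m_go[w], base_mean * m_ng[w])
        sil.append(rng.poisson(lam).astype(float))
        sil_go.append(lab)
    return ctrl, ctrl_go, sil, sil_go


def _latent_loadings(config: SimConfig, rng: np.random.Generator, n_neurons: int) -> np.ndarray:
    """(8, rank, n_neurons) loadings; each factor may rotate in a fixed
    random 2-plane by ``latent_loadings_rotation_per_window`` per step.

    Loadings are unit patterns scaled by ``latent_sd * sqrt(n)`` so that
    ``latent_sd`` is the typical per-neuron log-rate SD contributed by one
    factor (shared variability strong enough to shape PCs and noise
    correlations, as in cortical data)."""
    k = config.latent_rank
    if k == 0:
        return np.zeros((8, 0, n_neurons))
    out = np.empty((8, k, n_neurons))
    theta = config.latent_loadings_rotation_per_window
    scale = config.latent_sd * np.sqrt(n_neurons)
    for f in range(k):
        p = _unit(rng.standard_normal(n_neurons))
        q = rng.standard_normal(n_neurons)
        q = _unit(q - (q @ p) * p)
        for w in range(8):
            a = theta * w
            out[w, f] = scale * (np.cos(a) * p + np.sin(a) * q)
    return out


def simulate_session(config: SimConfig) -> tuple[SessionData, GroundTruth]:
    """Generate one synthetic session plus its ground truth.

    Rates are piecewise constant on the segments delimited by the silencing
    onsets (plus the silencing window edges on silencing trials); spikes are
    an exact Poisson process on each segment.  During a silencing trial's
    150-ms window, source rates are multiplied by ``source_silencing_factor``
    and target rates by ``1 + e_w[n] / 100``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_src, n_tgt = config.n_source, config.n_target
    n_all = n_src + n_tgt

    # --- neurons -----------------------------------------------------------
    base = rng.lognormal(config.baseline_rate_log_mean, config.baseline_rate_log_sd, n_all)
    gains = rng.lognormal(
        config.stimulus_gain_log_mean, config.stimulus_gain_log_sd, (2, n_all)
    )  # row 0 = go, row 1 = nogo
    depth = rng.uniform(-400.0, 600.0, n_all)
    rf = np.abs(rng.normal(0.0, 5.0, n_all))
    rf[n_src:] = np.abs(rng.normal(10.0, 8.0, n_tgt))
    waveform = np.where(rng.random(n_all) < 0.85, "broad", "narrow")
    neurons = pd.DataFrame(
        dict(
            area=np.repeat(["source", "target"], [n_src, n_tgt]),
            depth=depth,
            rf_distance=rf,
            mean_rate=np.nan,
            waveform_class=waveform,
        )
    )

    effects = make_effect_sequence(config, rng)  # (8, n_target) percent
    if np.any(effects <= -100.0):
        raise ValueError("silencing effects below -100% are impossible")
    loadings = _latent_loadings(config, rng, n_all)

    # --- trial table -------------------------------------------------------
    n_sil = 8 * config.n_silencing_per_window
    n_trials = config.n_control + n_sil
    silwin = np.concatenate(
        [np.zeros(config.n_control, dtype=int), np.repeat(np.arange(1, 9), config.n_silencing_per_window)]
    )
    stim = np.empty(n_trials, dtype=object)
    # balanced go/no-go within control and within each window
    for w in range(9):
        idx = np.flatnonzero(silwin == w)
        half = idx.size // 2
        lab = np.array([GO] * half + [NOGO] * (idx.size - half), dtype=object)
        stim[idx] = rng.permutation(lab)
    order = rng.permutation(n_trials)
    silwin, stim = silwin[order], stim[order]

    lick = simulate_behavior(config, stim, rng)

    # --- rates and spikes --------------------------------------------------
    onsets = np.asarray(config.silencing_onsets, dtype=float)
    T, D = config.stimulus_duration, config.silencing_duration
    base_bounds = np.concatenate(([-config.prestim_duration], onsets, [T, T + config.posttim_duration]))
    # segment s covers [bounds[s], bounds[s+1]); stimulus segments 1..8
    stim_seg_of = lambda b: np.clip(np.searchsorted(onsets, (b[:-1] + b[1:]) / 2, side="right") - 1, 0, 7)

    # AR(1) latent per trial per window per factor
    k = config.latent_rank
    z = np.zeros((n_trials, 8, max(k, 1)))
    if k:
        z[:, 0, :k] = rng.standard_normal((n_trials, k))
        rho = config.latent_ar1
        for w in range(1, 8):
            z[:, w, :k] = rho * z[:, w - 1, :k] + np.sqrt(1 - rho * rho) * rng.standard_normal(
                (n_trials, k)
            )

    is_go_row = (stim == GO).astype(int)  # 0 -> gains row 0
    gain_per_trial = gains[1 - is_go_row]  # (n_trials, n_all)
    env = np.asarray(config.temporal_envelope, dtype=float)
    var_n = np.einsum("wfn,wfn->wn", loadings, loadings)  # (8, n_all)

    sp_neuron, sp_trial, sp_time = [], [], []
    for w in range(9):  # 0 = control, 1..8 silencing windows
        tr = np.flatnonzero(silwin == w)
        if tr.size == 0:
            continue
        if w == 0:
            bounds = base_bounds
        else:
            cuts = np.array([onsets[w - 1], onsets[w - 1] + D])
            bounds = np.unique(np.concatenate([base_bounds, cuts]))
        durs = np.diff(bounds)
        mids = (bounds[:-1] + bounds[1:]) / 2
        in_stim = (mids >= 0) & (mids < T)
        seg_win = stim_seg_of(bounds)
        in_sil = np.zeros(durs.size, dtype=bool)
        if w > 0:
            in_sil = (mids >= onsets[w - 1]) & (mids < onsets[w - 1] + D)

        for s in range(durs.size):
            lam = np.broadcast_to(base, (tr.size, n_all)).copy()  # Hz
            if in_stim[s]:
                ww = seg_win[s]
                lam *= gain_per_trial[tr] * env[ww]
                if k:
                    proj = z[tr, ww, :k] @ loadings[ww]  # (n_tr, n_all)
                    lam *= np.exp(proj - 0.5 * var_n[ww])
            if in_sil[s]:
                mult = np.concatenate(
                    [
                        np.full(n_src, config.source_silencing_factor),
                        1.0 + effects[w - 1] / 100.0,
                    ]
                )
                lam = lam * mult
            counts = rng.poisson(lam * durs[s] / 1000.0)
            total = int(counts.sum())
            if total == 0:
                continue
            flat = counts.ravel()
            nz = np.flatnonzero(flat)
            reps = flat[nz]
            t_idx = tr[nz // n_all]
            n_idx = nz % n_all
            sp_trial.append(np.repeat(t_idx, reps))
            sp_neuron.append(np.repeat(n_idx, reps))
            sp_time.append(bounds[s] + rng.random(total) * durs[s])

    sp_neuron = np.concatenate(sp_neuron) if sp_neuron else np.empty(0, dtype=int)
    sp_trial = np.concatenate(sp_trial) if sp_trial else np.empty(0, dtype=int)
    sp_time = np.concatenate(sp_time) if sp_time else np.empty(0)

    trials = pd.DataFrame(
        dict(
            stimulus=stim,
            condition=np.where(silwin == 0, CONTROL, SILENCING),
            silencing_window=silwin,
            lick_time=lick,
            excluded=False,
        )
    )
    span = (-config.prestim_duration, T + config.posttim_duration)
    session = SessionData(
        animal_id=f"sim-{config.seed}",
        neurons=neurons,
        trials=trials,
        spike_neuron=sp_neuron,
        spike_trial=sp_trial,
        spike_time=sp_time,
        stimulus_duration=T,
        silencing_duration=D,
        silencing_onsets=tuple(onsets),
        recording_span=span,
    )
    from commdyn.behavior import classify_trials

    session.trials["outcome"] = classify_trials(session)
    total_time_s = (span[1] - span[0]) / 1000.0 * n_trials
    session.neurons["mean_rate"] = np.bincount(sp_neuron, minlength=n_all) / total_time_s

    # planted rotation lives on the centered log-gain patterns (the mean-one
    # correction subtracts a constant sd^2/2 in log space; add it back)
    sd = _gain_sd_for_magnitude(config.effect_magnitude / 100.0)
    g = np.log1p(effects / 100.0) + 0.5 * sd * sd
    adj = np.array([float(np.dot(_unit(g[i]), _unit(g[i + 1]))) for i in range(7)])
    truth = GroundTruth(
        effect_vectors_pct=effects,
        adjacent_effect_cosines=adj,
        latent_loadings=loadings,
        hit_rate=config.hit_rate,
        fa_rate=config.fa_rate,
        config=asdict(config),
    )
    return session, truth
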