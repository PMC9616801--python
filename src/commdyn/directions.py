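"""Population-level influence geometry.

The communication direction (CD) for one silencing window is the unit normal
to the decision boundary of a regularized linear discriminant separating
target-area population activity on control trials from activity on
source-silencing trials:

    CD  ~  Sigma_gamma^-1 (mu_control - mu_silencing),
    Sigma_gamma = (1 - gamma) * Sigma + gamma * diag(Sigma),

with Sigma the pooled within-class covariance (df-weighted over the two
classes) and gamma the shrinkage parameter.  Coefficients of the unit vector
smaller in magnitude than a threshold delta are zeroed (dropping the
corresponding neurons) and the vector is renormalized.  The sign convention
points from the silenced mean toward the control mean.

Similarity between directions estimated in different windows is measured by
a cross-validated cosine: trials are split in half, direction i estimated
from one half and direction j from the other, the dot product taken, the
roles swapped and averaged, over many random splits.  Estimation noise then
attenuates the similarity toward zero instead of biasing it upward, and the
diagonal (lag 0) measures split-half reliability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from commdyn.session import (
    CONTROL,
    GO,
    NOGO,
    SessionData,
    window_counts,
)

__all__ = [
    "regularized_lda_direction",
    "tune_lda_params",
    "stimulus_decoder",
    "communication_directions",
    "activity_directions",
    "crossval_cosine_matrix",
    "cd_split_estimator",
    "activity_split_estimator",
    "pc_split_estimator",
    "cd_window_data",
    "cd_similarity",
    "top_dynamic_source_subset",
    "simulate_time_invariant",
    "bhattacharyya_magnitude",
    "window_pcs",
    "DirectionSet",
    "SimilarityMatrix",
    "MagnitudeResult",
    "PCResult",
]


# ---------------------------------------------------------------------------
# regularized LDA


def _pooled_cov(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """df-weighted pooled within-class covariance of two (trials, n) blocks."""
    na, nb = a.shape[0], b.shape[0]
    xa = a - a.mean(axis=0)
    xb = b - b.mean(axis=0)
    return (xa.T @ xa + xb.T @ xb) / (na + nb - 2)


def _shrink(cov: np.ndarray, gamma: float) -> np.ndarray:
    out = (1.0 - gamma) * cov
    idx = np.arange(cov.shape[-1])
    out[..., idx, idx] += gamma * cov[..., idx, idx]
    # numerical ridge so neurons with zero variance in a window (no spikes
    # in any trial) do not make the shrunk covariance exactly singular
    d = out[..., idx, idx]
    scale = np.mean(np.abs(d), axis=-1, keepdims=True) + 1e-300
    out[..., idx, idx] = d + 1e-12 * scale
    return out


def _apply_delta(unit_vec: np.ndarray, delta: float) -> np.ndarray:
    if delta <= 0:
        return unit_vec
    v = np.where(np.abs(unit_vec) < delta, 0.0, unit_vec)
    nrm = np.linalg.norm(v)
    if nrm == 0:
        raise ValueError("delta threshold zeroed every coefficient")
    return v / nrm


def regularized_lda_direction(
    class_a: np.ndarray, class_b: np.ndarray, gamma: float, delta: float = 0.0
) -> np.ndarray:
    """Unit LDA direction pointing from the class-b mean toward class a.

    ``class_a``/``class_b`` are (trials, neurons) activity matrices (for
    communication directions, a = control, b = silencing).  ``delta`` zeroes
    unit-vector coefficients below that magnitude and renormalizes.
    Raises ``np.linalg.LinAlgError`` (with advice to shrink) when the
    pooled covariance is singular at gamma = 0.
    """
    a = np.asarray(class_a, dtype=float)
    b = np.asarray(class_b, dtype=float)
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need at least 2 trials per class")
    cov = _shrink(_pooled_cov(a, b), gamma)
    dmu = a.mean(axis=0) - b.mean(axis=0)
    try:
        w = np.linalg.solve(cov, dmu)
    except np.linalg.LinAlgError as e:  # pragma: no cover - message path
        raise np.linalg.LinAlgError(
            f"regularized covariance singular (gamma={gamma}); increase gamma"
        ) from e
    nrm = np.linalg.norm(w)
    if nrm == 0:
        raise ValueError("zero mean difference: direction undefined")
    return _apply_delta(w / nrm, delta)


def _lda_batch(ctrl: np.ndarray, sil: np.ndarray, gamma: float) -> np.ndarray:
    """Stacked LDA directions: ctrl (W, nc, n), sil (W, ns, n) -> (W, n)."""
    nc, ns = ctrl.shape[1], sil.shape[1]
    mc = ctrl.mean(axis=1)
    ms = sil.mean(axis=1)
    xc = ctrl - mc[:, None, :]
    xs = sil - ms[:, None, :]
    cov = (
        np.einsum("wti,wtj->wij", xc, xc) + np.einsum("wti,wtj->wij", xs, xs)
    ) / (nc + ns - 2)
    cov = _shrink(cov, gamma)
    w = np.linalg.solve(cov, (mc - ms)[..., None])[..., 0]
    nrm = np.linalg.norm(w, axis=1, keepdims=True)
    return w / np.where(nrm == 0, 1.0, nrm)


def _misclassification(
    train_a, train_b, test_a, test_b, gamma: float, delta: float
) -> float:
    w = regularized_lda_direction(train_a, train_b, gamma, delta)
    c = 0.5 * w @ (train_a.mean(axis=0) + train_b.mean(axis=0))
    err_a = np.mean(test_a @ w <= c) if len(test_a) else 0.0
    err_b = np.mean(test_b @ w > c) if len(test_b) else 0.0
    na, nb = len(test_a), len(test_b)
    return (err_a * na + err_b * nb) / max(na + nb, 1)


def tune_lda_params(
    class_a: np.ndarray,
    class_b: np.ndarray,
    gammas=(0.0, 0.1, 0.2, 0.4, 0.6, 0.8, 1.0),
    deltas_rel=(0.0, 0.05, 0.1, 0.2, 0.3),
    n_folds: int = 10,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Pick (gamma, delta) minimizing mean 10-fold CV misclassification.

    ``deltas_rel`` are fractions of the largest unit-vector coefficient
    magnitude on each training fold (absolute thresholds are scale-fragile).
    Ties break toward smaller gamma, then smaller delta.
    """
    rng = np.random.default_rng(seed)
    a = np.asarray(class_a, dtype=float)
    b = np.asarray(class_b, dtype=float)
    folds_a = np.array_split(rng.permutation(len(a)), n_folds)
    folds_b = np.array_split(rng.permutation(len(b)), n_folds)
    best = (np.inf, np.inf, np.inf)  # (error, gamma, delta)
    for g in gammas:
        for dr in deltas_rel:
            errs = []
            for fa, fb in zip(folds_a, folds_b):
                ma = np.ones(len(a), dtype=bool)
                ma[fa] = False
                mb = np.ones(len(b), dtype=bool)
                mb[fb] = False
                if ma.sum() < 2 or mb.sum() < 2 or (fa.size + fb.size) == 0:
                    continue
                try:
                    w0 = regularized_lda_direction(a[ma], b[mb], g, 0.0)
                except (np.linalg.LinAlgError, ValueError):
                    errs = [np.inf]
                    break
                delta = dr * np.max(np.abs(w0))
                errs.append(_misclassification(a[ma], b[mb], a[fa], b[fb], g, delta))
            mean_err = float(np.mean(errs)) if errs else np.inf
            key = (round(mean_err, 12), g, dr)
            if key < best:
                best = key
    return best[1], best[2]


# ---------------------------------------------------------------------------
# direction sets


@dataclass
class DirectionSet:
    """Unit vectors per window over a fixed neuron subset.

    ``vectors`` is (n_windows, n_neurons); masked windows are NaN rows.
    """

    kind: str
    vectors: np.ndarray
    neuron_index: np.ndarray
    gamma: float | None = None
    delta: float | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_windows(self) -> int:
        return self.vectors.shape[0]


@dataclass
class SimilarityMatrix:
    values: np.ndarray  # (W, W)
    n_splits: int
    kind: str = ""
    meta: dict = field(default_factory=dict)

    def lag_profile(self) -> np.ndarray:
        from commdyn.dynamics import lag_profile

        return lag_profile(self.values)


def cd_window_data(
    session: SessionData,
    stimulus: str | None,
    neurons: np.ndarray,
    correct_only: bool = False,
) -> tuple[np.ndarray, list]:
    """Per-window count arrays for CD estimation.

    Returns ``(ctrl, sil)``: ``ctrl`` is (8, n_control, n) — the same
    control trials counted in each silencing window's 150-ms range — and
    ``sil`` a list of (n_sil_w, n) silencing-trial counts per window.
    """
    outcomes = ("hit", "correct_rejection") if correct_only else None
    ctrl_mask = session.trial_mask(condition=CONTROL, stimulus=stimulus, outcomes=outcomes)
    ctrl = []
    sil = []
    for w in range(1, 9):
        win = (float(session.silencing_onsets[w - 1]), session.silencing_duration)
        ctrl.append(window_counts(session, win, ctrl_mask, neurons).counts)
        smask = session.trial_mask(window=w, stimulus=stimulus, outcomes=outcomes)
        sil.append(window_counts(session, win, smask, neurons).counts.astype(float))
    return np.stack(ctrl).astype(float), sil


def communication_directions(
    session: SessionData,
    stimulus: str | None,
    gamma: float,
    delta: float = 0.0,
    neurons: np.ndarray | None = None,
) -> DirectionSet:
    """One unit CD per silencing window from 150-ms spike counts."""
    if neurons is None:
        from commdyn.session import select_responsive_neurons

        neurons = select_responsive_neurons(session, area=_target_area(session))
    ctrl, sil = cd_window_data(session, stimulus, neurons)
    vecs = np.stack(
        [
            regularized_lda_direction(ctrl[w], sil[w], gamma, delta)
            for w in range(8)
        ]
    )
    return DirectionSet("communication", vecs, np.asarray(neurons), gamma, delta,
                        meta=dict(stimulus=stimulus))


def _target_area(session: SessionData) -> str:
    areas = session.areas
    return "target" if "target" in areas else areas[-1]


def activity_directions(
    session: SessionData,
    condition: str = CONTROL,
    stimulus: str | None = None,
    window_ms: float = 65.0,
    baseline_subtract: bool = False,
    neurons: np.ndarray | None = None,
) -> DirectionSet:
    """Unit-normalized trial-mean population vectors in consecutive windows.

    65-ms windows (default) tile the stimulus without the temporal overlap
    the 150-ms silencing windows would have.  With ``baseline_subtract`` the
    per-neuron mean count in the 500-ms pre-stimulus window (scaled to the
    window length) is removed first.  Windows with an all-zero mean vector
    are masked (NaN row).
    """
    if neurons is None:
        neurons = session.neuron_indices()
    tmask = session.trial_mask(condition=condition, stimulus=stimulus)
    n_win = int(session.stimulus_duration // window_ms)
    base = 0.0
    if baseline_subtract:
        pre = window_counts(session, (-session.stimulus_duration, session.stimulus_duration), tmask, neurons)
        base = pre.counts.mean(axis=0) * (window_ms / session.stimulus_duration)
    vecs = np.full((n_win, len(neurons)), np.nan)
    for w in range(n_win):
        cm = window_counts(session, (w * window_ms, window_ms), tmask, neurons)
        mu = cm.counts.mean(axis=0) - base
        nrm = np.linalg.norm(mu)
        if nrm > 0:
            vecs[w] = mu / nrm
    return DirectionSet("activity", vecs, np.asarray(neurons),
                        meta=dict(condition=condition, stimulus=stimulus,
                                  window_ms=window_ms, baseline_subtract=baseline_subtract))


# ---------------------------------------------------------------------------
# cross-validated cosine similarity


def _cosine_matrix(d1: np.ndarray, d2: np.ndarray) -> np.ndarray:
    """Pairwise cosines of rows of d1 with rows of d2; NaN entries restrict
    each pair to the common finite support (vectors renormalized there)."""
    if not (np.isnan(d1).any() or np.isnan(d2).any()):
        n1 = d1 / np.linalg.norm(d1, axis=1, keepdims=True)
        n2 = d2 / np.linalg.norm(d2, axis=1, keepdims=True)
        return n1 @ n2.T
    w = d1.shape[0]
    out = np.full((w, d2.shape[0]), np.nan)
    for i in range(w):
        for j in range(d2.shape[0]):
            ok = np.isfinite(d1[i]) & np.isfinite(d2[j])
            if not ok.any():
                continue
            a, b = d1[i, ok], d2[j, ok]
            na, nb = np.linalg.norm(a), np.linalg.norm(b)
            if na > 0 and nb > 0:
                out[i, j] = (a @ b) / (na * nb)
    return out


def crossval_cosine_matrix(
    split_estimator,
    n_splits: int = 100,
    seed: int | np.random.Generator = 0,
    absolute: bool = False,
    kind: str = "",
) -> SimilarityMatrix:
    """Split-half cosine-similarity matrix.

    ``split_estimator(rng)`` must return two (W, n) direction arrays
    estimated from complementary halves of the trials.  Entry (i, j) is the
    average of cos(D1_i, D2_j) and cos(D2_i, D1_j) over ``n_splits`` random
    splits (the swap makes the matrix symmetric).  ``absolute`` takes |cos|
    before averaging (for sign-ambiguous directions such as PCs).
    """
    rng = np.random.default_rng(seed)
    acc = None
    for _ in range(n_splits):
        d1, d2 = split_estimator(rng)
        m = _cosine_matrix(d1, d2)
        if absolute:
            m = np.abs(m)
        m = 0.5 * (m + m.T)  # average cos(D1_i, D2_j) with cos(D2_i, D1_j)
        acc = m if acc is None else acc + m
    return SimilarityMatrix(acc / n_splits, n_splits, kind=kind)


def _half_split(n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    perm = rng.permutation(n)
    h = n // 2
    return perm[:h], perm[h:]


def cd_split_estimator(ctrl: np.ndarray, sil: list, gamma: float, delta: float = 0.0):
    """Split-half CD estimator over (8, n_c, n) control counts and the
    per-window silencing count list; both classes are split in half."""
    n_c = ctrl.shape[1]
    equal_sil = len({s.shape[0] for s in sil}) == 1

    def estimate(rng: np.random.Generator):
        ia, ib = _half_split(n_c, rng)
        splits = [_half_split(s.shape[0], rng) for s in sil]
        if equal_sil and delta == 0.0:
            sa = np.stack([s[sp[0]] for s, sp in zip(sil, splits)])
            sb = np.stack([s[sp[1]] for s, sp in zip(sil, splits)])
            d1 = _lda_batch(ctrl[:, ia], sa, gamma)
            d2 = _lda_batch(ctrl[:, ib], sb, gamma)
        else:
            d1 = np.stack(
                [
                    regularized_lda_direction(ctrl[w][ia], sil[w][splits[w][0]], gamma, delta)
                    for w in range(len(sil))
                ]
            )
            d2 = np.stack(
                [
                    regularized_lda_direction(ctrl[w][ib], sil[w][splits[w][1]], gamma, delta)
                    for w in range(len(sil))
                ]
            )
        return d1, d2

    return estimate


def activity_split_estimator(counts_by_window: list):
    """Split-half trial-mean direction estimator; one (trials, n) count
    matrix per window (trials may differ across windows)."""

    def estimate(rng: np.random.Generator):
        d1, d2 = [], []
        for counts in counts_by_window:
            ia, ib = _half_split(counts.shape[0], rng)
            for idx, out in ((ia, d1), (ib, d2)):
                mu = counts[idx].mean(axis=0)
                nrm = np.linalg.norm(mu)
                out.append(mu / nrm if nrm > 0 else np.full(counts.shape[1], np.nan))
        return np.stack(d1), np.stack(d2)

    return estimate


def cd_similarity(
    session: SessionData,
    stimulus: str | None,
    gamma: float,
    delta: float = 0.0,
    neurons: np.ndarray | None = None,
    n_splits: int = 100,
    seed: int | np.random.Generator = 0,
) -> SimilarityMatrix:
    """Cross-validated 8x8 cosine-similarity matrix of communication
    directions for one stimulus type."""
    if neurons is None:
        from commdyn.session import select_responsive_neurons

        neurons = select_responsive_neurons(session, area=_target_area(session))
    ctrl, sil = cd_window_data(session, stimulus, neurons)
    est = cd_split_estimator(ctrl, sil, gamma, delta)
    sm = crossval_cosine_matrix(est, n_splits=n_splits, seed=seed, kind="communication")
    sm.meta.update(stimulus=stimulus, gamma=gamma, delta=delta)
    return sm


# ---------------------------------------------------------------------------
# stimulus decoding


def stimulus_decoder(
    session: SessionData,
    window: int,
    gamma: float | None = None,
    delta: float = 0.0,
    window_ms: float = 80.0,
    train_frac: float = 0.8,
    n_splits: int = 20,
    seed: int | np.random.Generator = 0,
    neurons: np.ndarray | None = None,
    correct_only: bool = True,
) -> tuple[float, float]:
    """Go/no-go decoding accuracy around one silencing window.

    An LDA classifier is trained on a balanced 80% of the control trials
    using spike counts in the 80-ms window after the silencing onset;
    control accuracy comes from the held-out 20%, silencing accuracy from
    all silencing trials of that window under the same classifier.  Results
    average over ``n_splits`` random 80/20 partitions.  With
    ``gamma=None`` a small shrinkage grid is scanned and the value with the
    best mean held-out control accuracy is used (chosen per animal).
    """
    rng = np.random.default_rng(seed)
    if neurons is None:
        neurons = session.neuron_indices(_target_area(session))
    onset = float(session.silencing_onsets[window - 1])
    win = (onset, window_ms)
    outcomes = ("hit", "correct_rejection") if correct_only else None

    def counts_for(stim, cond_mask):
        m = cond_mask & session.trial_mask(stimulus=stim, outcomes=outcomes)
        return window_counts(session, win, m, neurons).counts.astype(float)

    ctrl_mask = session.trial_mask(condition=CONTROL)
    if ctrl_mask.sum() < 10:
        raise ValueError("fewer than 10 control trials: session excluded")
    sil_mask = session.trial_mask(window=window)
    cg, cn = counts_for(GO, ctrl_mask), counts_for(NOGO, ctrl_mask)
    sg, sn = counts_for(GO, sil_mask), counts_for(NOGO, sil_mask)

    gammas = (gamma,) if gamma is not None else (0.1, 0.3, 0.5, 0.8, 1.0)
    best = None
    for g in gammas:
        accs_c, accs_s = [], []
        grng = np.random.default_rng(rng.integers(2**31))
        for _ in range(n_splits):
            n_tr = int(np.floor(min(len(cg), len(cn)) * train_frac))
            pa, pb = grng.permutation(len(cg)), grng.permutation(len(cn))
            tr_a, te_a = cg[pa[:n_tr]], cg[pa[n_tr:]]
            tr_b, te_b = cn[pb[:n_tr]], cn[pb[n_tr:]]
            w = regularized_lda_direction(tr_a, tr_b, g, delta)
            c = 0.5 * w @ (tr_a.mean(0) + tr_b.mean(0))
            acc_c = np.concatenate([(te_a @ w > c), (te_b @ w <= c)]).mean()
            acc_s = np.concatenate([(sg @ w > c), (sn @ w <= c)]).mean()
            accs_c.append(acc_c)
            accs_s.append(acc_s)
        cand = (float(np.mean(accs_c)), float(np.mean(accs_s)))
        if best is None or cand[0] > best[0]:
            best = cand
    return best


# ---------------------------------------------------------------------------
# source-cell sub-selection


def top_dynamic_source_subset(
    session: SessionData,
    frac: float = 0.2,
    window_ms: float = 65.0,
    neurons: np.ndarray | None = None,
) -> np.ndarray:
    """Source neurons with the most dynamic window-wise activity.

    Each neuron's mean count per 65-ms window (control trials) is z-scored
    across the population within each window; neurons are ranked by the
    standard deviation of their z-scores over windows and the top
    ``ceil(frac * N)`` are returned.  Ties break by neuron index.
    """
    if neurons is None:
        src = "source" if "source" in session.areas else session.areas[0]
        neurons = session.neuron_indices(src)
    neurons = np.asarray(neurons)
    if neurons.size < 5:
        raise ValueError("need at least 5 source neurons")
    tmask = session.trial_mask(condition=CONTROL)
    n_win = int(session.stimulus_duration // window_ms)
    means = np.stack(
        [
            window_counts(session, (w * window_ms, window_ms), tmask, neurons).counts.mean(axis=0)
            for w in range(n_win)
        ]
    )  # (n_win, n_neurons)
    sd_pop = means.std(axis=1, keepdims=True)
    z = (means - means.mean(axis=1, keepdims=True)) / np.where(sd_pop == 0, 1.0, sd_pop)
    score = z.std(axis=0)
    k = int(np.ceil(frac * neurons.size))
    order = np.lexsort((np.arange(neurons.size), -score))
    return np.sort(neurons[order[:k]])


def cd_similarity_random_subsets(
    session: SessionData,
    stimulus: str | None,
    gamma: float,
    frac: float = 0.2,
    n_repeats: int = 100,
    n_splits: int = 20,
    seed: int | np.random.Generator = 0,
    neurons: np.ndarray | None = None,
) -> SimilarityMatrix:
    """CD similarity recomputed on random target subsets of size
    ``ceil(frac * N)``, averaged over ``n_repeats`` draws (companion to
    :func:`top_dynamic_source_subset`, matching its dimensionality)."""
    rng = np.random.default_rng(seed)
    if neurons is None:
        from commdyn.session import select_responsive_neurons

        neurons = select_responsive_neurons(session, area=_target_area(session))
    neurons = np.asarray(neurons)
    k = int(np.ceil(frac * neurons.size))
    acc = np.zeros((8, 8))
    for _ in range(n_repeats):
        sub = np.sort(rng.choice(neurons, size=k, replace=False))
        sm = cd_similarity(
            session, stimulus, gamma, neurons=sub, n_splits=n_splits,
            seed=rng.integers(2**31),
        )
        acc += sm.values
    return SimilarityMatrix(acc / n_repeats, n_splits, kind="communication-subset",
                            meta=dict(frac=frac, n_repeats=n_repeats))


# ---------------------------------------------------------------------------
# time-invariant null simulation


def simulate_time_invariant(
    ctrl_counts: np.ndarray,
    observed_effects_pct: np.ndarray,
    n_sil_trials: int,
    n_repeats: int = 100,
    seed: int | np.random.Generator = 0,
) -> list:
    """Poisson surrogate silencing data with window-invariant effects.

    For each repeat and each target neuron one of its 8 observed per-window
    effects is chosen at random and frozen as the neuron's time-invariant
    effect E.  For every window T, silencing counts are simulated as a
    Poisson sample around the control-trial mean of that window, scaled by
    ``(1 + E/100)`` (floored at 0).  Trial-to-trial Poisson variability and
    the window-resolved control rates are preserved; only the pattern of
    effects across windows is made static.

    Parameters
    ----------
    ctrl_counts : (8, n_control, n) control counts per window.
    observed_effects_pct : (8, n) observed percent effects per window
        (NaN entries fall back to the neuron's nanmean effect, or 0).
    n_sil_trials : simulated silencing trials per window.

    Returns
    -------
    list of (8, n_sil_trials, n) float arrays, one per repeat.
    """
    rng = np.random.default_rng(seed)
    eff = np.asarray(observed_effects_pct, dtype=float)
    n = eff.shape[1]
    fallback = np.nan_to_num(np.nanmean(np.where(np.isfinite(eff), eff, np.nan), axis=0))
    mu_c = ctrl_counts.mean(axis=1)  # (8, n)
    out = []
    for _ in range(n_repeats):
        pick = rng.integers(0, 8, size=n)
        e = eff[pick, np.arange(n)]
        e = np.where(np.isfinite(e), e, fallback)
        scale = np.maximum(1.0 + e / 100.0, 0.0)
        lam = np.broadcast_to(mu_c[:, None, :], (8, n_sil_trials, n))
        sim = rng.poisson(lam) * scale[None, None, :]
        out.append(sim)
    return out


# ---------------------------------------------------------------------------
# Bhattacharyya magnitude


@dataclass
class MagnitudeResult:
    distance: float
    noise_floor: float
    n_boot: int


def bhattacharyya_magnitude(
    control: np.ndarray,
    silencing: np.ndarray,
    gamma: float = 0.0,
    n_boot: int = 100,
    seed: int | np.random.Generator = 0,
) -> MagnitudeResult:
    """Equal-covariance Bhattacharyya distance between conditions.

    Under the shared-covariance multivariate-normal assumption the log-det
    term vanishes and

        D = (1/8) (mu_c - mu_s)^T Sigma_pooled^-1 (mu_c - mu_s).

    The noise floor is the mean distance between two bootstrap resamples of
    the control trials alone (the distance expected with no effect at all).
    """
    rng = np.random.default_rng(seed)
    c = np.asarray(control, dtype=float)
    s = np.asarray(silencing, dtype=float)

    def dist(a, b):
        cov = _shrink(_pooled_cov(a, b), gamma)
        dmu = a.mean(axis=0) - b.mean(axis=0)
        return 0.125 * float(dmu @ np.linalg.solve(cov, dmu))

    d = dist(c, s)
    floor = np.empty(n_boot)
    for i in range(n_boot):
        ia = rng.integers(0, len(c), len(c))
        ib = rng.integers(0, len(c), len(s))
        floor[i] = dist(c[ia], c[ib])
    return MagnitudeResult(d, float(floor.mean()), n_boot)


# ---------------------------------------------------------------------------
# windowed PCA


@dataclass
class PCResult:
    components: np.ndarray  # (W, k, n) orthonormal rows per window
    variances: np.ndarray  # (W, k) variance along each component
    total_top: np.ndarray  # (W,) summed variance across the k components


def _pca(counts: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    x = counts - counts.mean(axis=0)
    cov = (x.T @ x) / max(len(counts) - 1, 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1][:k]
    v = evecs[:, order].T
    for i in range(v.shape[0]):  # deterministic sign: first nonzero positive
        nz = np.flatnonzero(np.abs(v[i]) > 1e-12)
        if nz.size and v[i, nz[0]] < 0:
            v[i] = -v[i]
    return v, np.maximum(evals[order], 0.0)


def window_pcs(counts_by_window: list, n_components: int = 3) -> PCResult:
    """First principal components of trial-to-trial covariance per window.

    ``counts_by_window`` holds one (trials, neurons) matrix per window
    (pre-balanced across conditions by the caller).  Components are
    orthonormal within each window with non-increasing variances.
    """
    comps, var = [], []
    for counts in counts_by_window:
        if counts.shape[0] < 4:
            raise ValueError("need at least 4 trials per window for PCA")
        v, ev = _pca(np.asarray(counts, dtype=float), n_components)
        comps.append(v)
        var.append(ev)
    comps = np.stack(comps)
    var = np.stack(var)
    return PCResult(comps, var, var.sum(axis=1))


def pc_split_estimator(counts_by_window: list, component: int = 0):
    """Split-half PC estimator for cross-validated |cos| similarity."""

    def estimate(rng: np.random.Generator):
        d1, d2 = [], []
        for counts in counts_by_window:
            ia, ib = _half_split(counts.shape[0], rng)
            for idx, out in ((ia, d1), (ib, d2)):
                v, _ = _pca(np.asarray(counts, dtype=float)[idx], component + 1)
                out.append(v[component])
        return np.stack(d1), np.stack(d2)

    return estimate
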