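# Methods

This note documents the models, estimators, numerical choices and known
limitations of the `commdyn` pipeline in one place. Everything stated here
is computed by the test suite, the `analysis/` scripts or
`scripts/acceptance.py`; nothing is quoted from elsewhere.

## Experimental design the pipeline assumes

One session per animal: two areas recorded simultaneously, a 500-ms
visual stimulus (go or no-go grating), and on a random subset of trials a
150-ms optogenetic silencing pulse in the *source* area starting at one of
eight onsets (defaults 0, 56, 123, 189, 256, 323, 390, 456 ms — the
silencing grid). All spike times are in ms relative to stimulus onset;
analysis windows are half-open `[onset, onset + duration)`, so disjoint
windows partition spikes exactly. The trial table carries stimulus,
condition, silencing-window index (0 = control), lick time and outcome.

Inclusion rules: a session needs ≥10 control trials and behavioural d′
above the 99th percentile of a 5000-fold go/no-go label shuffle. Neurons
enter population analyses if visually responsive: mean stimulus count ≥1
for at least one stimulus, and a two-sided paired Wilcoxon signed-rank
test (stimulus vs. equal-length pre-stimulus count, p < 0.05) for at
least one stimulus. The pairing per trial is our choice (it is more
powerful and deterministic than an unpaired comparison at these trial
counts). Low-rate neurons (window-averaged rate < 2.5 Hz, evaluated on
the window's trials pooled across conditions — the pooling is
configurable) are masked per window via an explicit validity mask rather
than NaNs; a neuron enters a pairwise (window i, window j) statistic only
if unmasked in both, and masked cosines are computed on the common
support with renormalization.

## Single-neuron effects

Effect = `100 (R̄s − R̄c)/R̄c` with counts in the 150-ms silencing window.
The null distribution is built from control trials only: resample, with
replacement, pseudo-control and pseudo-silencing groups of the observed
sizes and recompute the effect (1000 draws by default, seeded). The
observed effect is significant outside the [2.5, 97.5] null percentiles;
the per-cell count of affected windows uses [0.3125, 99.6875] (two-sided
α/8). This null-construction detail is unstated in the source analysis;
mirroring the observed statistic's sampling structure is the natural
choice. Each neuron receives independent resampling draws so that
significance calls are conditionally independent across neurons.

## Behaviour

d′ = Z(hit) − Z(fa) with boundary rates clipped by the 1/(2N) rule.
Onset-corrected metrics keep, per silencing window, only trials whose
first lick followed the window's onset (no-lick trials always retained);
each control trial is assigned one of the eight onsets at random (seeded)
to build matched control pseudo-windows. Reaction time and d′ are
expressed as percent change from the session-wide mean; windows with
onset < 100 ms aggregate as "early", the rest as "late". Uncorrected
variants are emitted alongside.

## Encoding GLM

`Rs ~ N(μ, σ)` with
`μ = d·βd + d²·β2d + Rc·βc + Rc²·β2c + d·Rc·βi + β0`, against the null
`μ0 = Rc·βc + Rc²·β2c + β0`, both fit by IRLS (Gaussian GLM). One
observation is one (neuron, trial) pair at a given window, pooled across
windows; folds are stratified by observation, not neuron (the per-neuron
alternative is available by constructing the inputs accordingly). The
covariate is z-scored internally for conditioning and the coefficients
mapped back to the raw scale, making the fit invariant to affine
rescaling of the covariate. Test-set likelihood uses the training-fold
residual SD; performance is `(log₂L_full − log₂L_null)/N_test` bits/trial,
with a one-sided signed-rank test across the 20 folds. Note that on
session-like data any covariate that distinguishes neurons absorbs part
of the *between-neuron* diversity of silencing effects; the strict null
calibration therefore uses exchangeable observations.

## Communication directions and cross-validated similarity

`CD ∝ Σγ⁻¹(μc − μs)` with the pooled within-class covariance (df-weighted
over the two classes — standard LDA pooling, since the pooling is
otherwise unspecified) shrunk toward its diagonal by γ; coefficients of
the unit vector smaller than δ are zeroed and the vector renormalized.
(γ, δ) are tuned per animal by 10-fold cross-validated classification
error on a grid, δ expressed relative to the largest coefficient
magnitude (absolute thresholds are scale-fragile); ties break toward
smaller γ then smaller δ. The sign convention points from the silenced
mean toward the control mean. A diagonal ridge of 10⁻¹² (relative to the
mean diagonal) guards against exactly zero-variance neurons.

Similarity between directions at windows i and j is the cross-validated
cosine: split trials in half (both control and silencing trials — a CD
needs both classes), estimate direction i from one half and j from the
other, take the dot product, swap the roles, average, and repeat over
many random splits (default 100, seeded). Estimation noise then
*attenuates* similarity toward zero; the diagonal (lag 0) is the
split-half reliability. PCs, whose sign is arbitrary, use |cos|; CDs and
activity directions use the signed cosine.

Activity directions are unit-normalized trial-mean population vectors in
65-ms windows (non-overlapping, unlike the 150-ms silencing windows);
baseline subtraction (pre-stimulus mean, scaled to window length) is
optional.

Note on adjacent-window CD similarity: consecutive silencing windows on
the ~66-ms grid overlap in time by ~84 ms, so adjacent-lag similarity
sits slightly above the planted effect-pattern cosine even at large
trial counts. Recovery checks therefore compare at the tolerance this
overlap implies.

## Time-invariant surrogate, Bhattacharyya, PCA

The surrogate freezes, per repeat and neuron, one randomly chosen
window's observed effect and simulates silencing counts as Poisson draws
around the window-resolved control means scaled by `1 + E/100` (floored
at 0), preserving trial noise and mean rates while removing effect
dynamics (100 repeats by default).

The influence magnitude is the equal-covariance Bhattacharyya distance
`D = ⅛ Δμᵀ Σ_pooled⁻¹ Δμ` (the log-det term vanishes under the shared
covariance assumption, stated here explicitly since only the distance is
named in the source analysis), with a noise floor from control-vs-control
bootstrap resamples.

Windowed PCA takes the top three eigenvectors of the trial covariance per
window (balanced trials across the four stimulus × condition groups),
with eigenvalue-ordered components, deterministic sign (first nonzero
coefficient positive), and cross-validated |cos| similarity from
half-trial splits. Near-degenerate (isotropic) spectra make PC identity
meaningless; tests avoid exact degeneracy.

## Exponential decay fits

`y = A(exp(−t/τ) + B)` over lag (ms between silencing onsets; lag steps
convert at the session's mean onset spacing, ≈66 ms). The model is linear
in (A, A·B) once τ is fixed, so the default fit is variable projection: a
closed-form linear subproblem on a dense log grid over
τ ∈ [10⁻³, 10⁴] ms, refined by bounded scalar search — a global fit with
no starting-value sensitivity. Bounded trust-region least squares
(multi-start τ₀ ∈ {20, 65, 130, 500} ms) is retained as a cross-check and
agrees to high precision.

Two constraints make the fit well-behaved on noisy profiles:

* **Sign constraints** A ≥ 0, B ≥ 0 (a positive decay amplitude relaxing
  to a non-negative plateau — the physically meaningful regime for
  similarity profiles). Without them, gently tilted profiles are fit by a
  spurious near-linear regime (τ at the upper bound with large A and
  B < 0).
* **Identifiability gate**: a flat profile puts the fit on a ridge —
  τ → 0 with A ≈ 0 fits exactly as well as τ → ∞, and noise picks
  arbitrarily between them. When the decay component explains less than
  half the profile variance beyond a constant (R² < 0.5; chance R² of the
  sign-constrained fit on an 8-point flat profile is ≈0.1–0.3, a real
  decay ≈0.8+), τ is treated as unidentified and resolved
  deterministically to the slow-decay bound. The rule is symmetric under
  trial-label permutation, so permutation p-values remain exact.

Exactly constant profiles are flagged `degenerate`.

Bootstrap CIs (100 resamples, seeded) resample animals for multi-profile
input and points for a single profile, warm-starting each refit. The
interval is normal-theory with the bootstrap SE and a t critical value on
the resampling units; at cohort scale (~14 animals) this calibrates the
95% CI to 93–95% empirical coverage, where the raw percentile interval
of 100 resamples under-covers (Monte-Carlo checked in the test suite).

## Permutation test on Δτ

Go/no-go labels are exchanged within the control trials and within each
window's silencing trials (preserving per-condition counts); the whole
CD → similarity → fit pipeline is re-run per permutation and
`p = (1 + #{|Δτ_null| ≥ |Δτ_obs|}) / (n_perm + 1)` (never exactly 0).
Failed fits inside a permutation are dropped and counted. The inner
similarity uses few splits (2–4) — permutation validity needs only that
observed and null statistics be computed identically.

## Synthetic sessions

The generator emulates: per-neuron lognormal baseline rates (median 5 Hz,
log-SD 0.5) and go/no-go stimulus gains (median 2×, log-SD 0.35); a
shared slow temporal envelope over the eight silencing-grid segments
(onset transient decaying ~1.3 → 0.88); rank-2 latent log-rate factors
with per-neuron log-SD 0.25 and AR(1) correlation 0.7 across windows
(giving realistic noise correlations and super-Poisson variability),
whose loadings can rotate per window in a fixed 2-plane to plant PC
rotation; ~100 control and 78 silencing trials per window; hit rate 0.8
and false-alarm rate 0.2 (d′ ≈ 1.7) with shifted-lognormal reaction
times (shift 150 ms, median ≈ 300 ms). Spikes are an exact
piecewise-constant-rate Poisson process (identical in distribution, at
the window-count level, to fine-binned Poisson emission); there is no
refractory period or sub-millisecond structure, because every statistic
downstream is a window count.

Silencing multiplies source rates by a residual factor (default 0.05,
i.e. ≈ −95%) and target rates by `exp(g_w[n] − σ²/2)`: per-neuron
log-gain patterns, zero-median and mean-one. Two properties motivated the
log-domain form over a linear percent pattern: the −100% floor can never
bind (a linear Gaussian pattern at realistic magnitudes must be clipped
at the floor, which injects a spurious common component into every
window), and the mean-one correction removes the Jensen offset that
would otherwise dominate the control-minus-silencing direction in every
window. In rotating mode the patterns follow a Markov scheme with exact
adjacent-window cosine c (`g_{w+1} = c·g_w + √(1−c²)·u`, u random ⊥
g_w), giving expected lag-k cosine c^k; the realized long-lag cosines
wander by O(1/√n), so benchmark datasets that need exact planted geometry
at small n use the bounded odd `tanh` gain variant
(`simulate_cd_count_data`), which shares both floor-safety and
zero-offset properties.

What the generator does **not** emulate: real conduction delays,
oscillations, non-Poisson firing statistics, behavioural state drift, or
any specific laminar/cell-type structure — so passing recovery tests
shows the estimators are correct and calibrated under the assumed
statistical structure, not that the biological conclusions transfer to
arbitrary data.

## Problem sizes used in checks

Recovery and calibration checks run at deliberately chosen scales:
sessions of 40–50 target neurons with 80 silencing trials per window for
CD-dynamics recovery; 20 small sessions (20 target neurons, 40 trials per
window) for the surrogate comparison; 500 datasets × 200 permutations
(8 neurons, 24 trials per window) for test calibration and 40 larger
contrast datasets (40 neurons) for power; 500 cohorts of 14 noisy
profiles for CI coverage; 5000 trials per condition for effect-estimator
consistency. These sizes make every Monte-Carlo bound in the suite sharp
at the stated tolerances.

## PC-rotation recovery windows

The latent loadings rotate per silencing-grid *segment*, so the planted
PC rotation is probed on the eight inter-onset segments
(`[onset_i, onset_{i+1})`, ~66 ms). The overlapping 150-ms windows mix
two to three consecutive loading patterns and would blur a 90°-per-step
plant by construction; for slower rotations the 150-ms windows are fine.

## Known limitations

* τ at the slow-decay bound (10⁴ ms) is a label for "no detectable
  decay", not an estimate; CIs are not meaningful there.
* The bootstrap-over-points CI for a single 8-point profile is wide and
  can cross zero; multi-animal profiles are the intended use.
* `tune_lda_params` optimizes classification error, which plateaus for
  well-separated classes; the tie-break (smallest γ, then δ) makes the
  result deterministic but not unique in merit.
* The onset-corrected d′ for late windows conditions on late licks and is
  not comparable across windows — only between conditions within a
  window.
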