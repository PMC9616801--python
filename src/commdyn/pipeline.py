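"""End-to-end orchestration: config -> filters -> effects -> behaviour ->
GLM -> directions -> similarity -> decay statistics -> null comparison ->
PCA -> correlations, with versioned outputs and a seed/parameter manifest.

The pipeline is idempotent given a config: every stochastic stage draws its
seed deterministically from the master seed, and the manifest records the
config hash next to every output.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from commdyn import behavior as beh
from commdyn import directions as dirs
from commdyn import dynamics as dyn
from commdyn import effects as eff
from commdyn import glm as encoding
from commdyn.io import load_session, save_ground_truth, save_session
from commdyn.session import CONTROL, GO, NOGO, SessionData, select_responsive_neurons, window_counts
from commdyn.simulate import SimConfig, simulate_session

DEFAULT_STAGES = (
    "effects", "behavior", "glm", "directions", "decay", "null_sim", "pca", "correlations",
)

DEFAULT_PARAMS = dict(
    threshold_hz=2.5,
    n_boot=1000,
    n_splits=50,
    n_boot_fit=100,
    n_perm=200,
    gamma=None,  # None -> tune per animal
    delta=0.0,
    null_repeats=20,
)


def _config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]


def load_config(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text())


def _get_session(config: dict, out: Path) -> SessionData:
    if "session" in config:
        return load_session(config["session"])
    sim = dict(config.get("simulate", {}))
    sim.setdefault("seed", config.get("seed", 0))
    cfg = SimConfig(**sim)
    session, truth = simulate_session(cfg)
    save_session(session, out / "session.h5")
    save_ground_truth(truth, out / "ground_truth.json")
    return session


def run_pipeline(config: dict) -> dict:
    """Execute the configured stages in dependency order.

    Returns a report dict; writes tables, fits and a manifest under
    ``config['output_dir']``.  A stage failure halts with the stage name,
    preserving outputs of earlier stages.
    """
    out = Path(config.get("output_dir", "results/pipeline"))
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    master = np.random.SeedSequence(seed)
    stage_seeds = {s: int(np.random.default_rng(c).integers(2**31)) for s, c in
                   zip(DEFAULT_STAGES, master.spawn(len(DEFAULT_STAGES)))}
    stages = {s: True for s in DEFAULT_STAGES}
    stages.update(config.get("stages", {}))
    params = dict(DEFAULT_PARAMS)
    params.update(config.get("params", {}))
    report: dict = dict(config_hash=_config_hash(config), seed=seed, stages_run=[], counts={})

    def run_stage(name, fn):
        if not stages.get(name, True):
            return
        try:
            fn()
        except Exception as e:
            manifest()
            raise RuntimeError(f"pipeline stage '{name}' failed: {e}") from e
        report["stages_run"].append(name)

    def manifest():
        (out / "manifest.json").write_text(
            json.dumps(
                dict(config_hash=report["config_hash"], seed=seed,
                     stage_seeds=stage_seeds, params=params,
                     stages_run=report["stages_run"]),
                indent=2, default=str,
            )
        )

    session = _get_session(config, out)
    target = "target" if "target" in session.areas else session.areas[-1]
    source = [a for a in session.areas if a != target][0]

    ok, reason = True, ""
    if not config.get("skip_inclusion", False):
        from commdyn.session import include_session

        ok, reason = include_session(session, n_shuffles=1000, seed=stage_seeds["behavior"])
    report["included"] = ok
    report["inclusion_reason"] = reason
    if not ok and not config.get("force", False):
        manifest()
        return report

    responsive = select_responsive_neurons(session, area=target)
    report["counts"]["responsive_target_neurons"] = int(len(responsive))

    def stage_effects():
        table = eff.effect_table(
            session, target, threshold_hz=params["threshold_hz"],
            n_boot=params["n_boot"], seed=stage_seeds["effects"],
        )
        table.to_csv(out / "effect_table.csv", index=False)
        nsig = eff.count_significant_windows(table)
        nsig.to_csv(out / "significant_windows_per_neuron.csv")
        sel = eff.selectivity_indices(session, area=target)
        sel.to_csv(out / "selectivity.csv", index=False)
        pooled = table[table.stimulus == "pooled"]
        report["median_effect_pct"] = float(np.nanmedian(pooled.percent_change))
        report["frac_neurons_significant"] = float(
            pooled.groupby("neuron")["significant_bonf8"].any().mean()
        )

    def stage_behavior():
        summ = beh.behavior_summary(session)
        onset = beh.onset_corrected_metrics(session, seed=stage_seeds["behavior"])
        onset.per_window.to_csv(out / "behavior_per_window.csv", index=False)
        onset.early_late.to_csv(out / "behavior_early_late.csv", index=False)
        report["dprime"] = summ.dprime
        report["hit_rate"] = summ.hit_rate
        report["fa_rate"] = summ.fa_rate
        (out / "behavior.json").write_text(
            json.dumps(dict(hit_rate=summ.hit_rate, fa_rate=summ.fa_rate,
                            dprime=summ.dprime, n_go=summ.n_go, n_nogo=summ.n_nogo), indent=2)
        )

    def stage_glm():
        rs_all, rc_all, dep_all = [], [], []
        depth = session.neurons["depth"].to_numpy()[responsive]
        for w in range(1, 9):
            win = (float(session.silencing_onsets[w - 1]), session.silencing_duration)
            c = window_counts(session, win, session.trial_mask(condition=CONTROL), responsive).counts
            s = window_counts(session, win, session.trial_mask(window=w), responsive).counts
            n = min(len(c), len(s))
            rs_all.append(s[:n].ravel())
            rc_all.append(c[:n].ravel())
            dep_all.append(np.tile(depth, n))
        rs, rc, dep = map(np.concatenate, (rs_all, rc_all, dep_all))
        res = encoding.excess_loglik(rs, rc, dep, "depth", seed=stage_seeds["glm"])
        pd.DataFrame(dict(fold=np.arange(res.k_folds), bits_per_trial=res.bits_per_trial)).to_csv(
            out / "glm_performance.csv", index=False
        )
        (out / "glm_coefficients.json").write_text(
            json.dumps(dict(full=res.full.coefficients, null=res.null.coefficients,
                            p_value=res.p_value), indent=2)
        )
        report["glm_bits_per_trial"] = float(res.bits_per_trial.mean())
        report["glm_p"] = res.p_value

    gamma_holder: dict = {}

    def stage_directions():
        rng = np.random.default_rng(stage_seeds["directions"])
        g = params["gamma"]
        if g is None:
            ctrl, sil = dirs.cd_window_data(session, None, responsive)
            g, d = dirs.tune_lda_params(
                np.concatenate(list(ctrl)), np.concatenate(sil), seed=rng.integers(2**31)
            )
            params_delta = d
        else:
            params_delta = params["delta"]
        gamma_holder["gamma"] = g
        gamma_holder["delta"] = params_delta
        report["gamma"] = g
        for stim in (GO, NOGO):
            sm = dirs.cd_similarity(
                session, stim, g, neurons=responsive,
                n_splits=params["n_splits"], seed=rng.integers(2**31),
            )
            np.savetxt(out / f"cd_similarity_{stim}.csv", sm.values, delimiter=",")
            np.savetxt(out / f"cd_lag_profile_{stim}.csv", sm.lag_profile(), delimiter=",")
        act = dirs.activity_directions(session, neurons=responsive)
        est = dirs.activity_split_estimator(
            [
                window_counts(session, (w * 65.0, 65.0), session.trial_mask(condition=CONTROL),
                              responsive).counts
                for w in range(7)
            ]
        )
        sm_act = dirs.crossval_cosine_matrix(est, n_splits=params["n_splits"],
                                             seed=rng.integers(2**31), kind="activity")
        np.savetxt(out / "activity_similarity.csv", sm_act.values, delimiter=",")
        np.save(out / "activity_directions.npy", act.vectors)

    def stage_decay():
        rng = np.random.default_rng(stage_seeds["decay"])
        step = float(np.mean(np.diff(session.silencing_onsets)))
        taus = {}
        for stim in (GO, NOGO):
            prof = np.loadtxt(out / f"cd_lag_profile_{stim}.csv", delimiter=",")
            fit = dyn.fit_decay(np.arange(prof.size) * step, prof,
                                n_boot=params["n_boot_fit"], seed=rng.integers(2**31))
            taus[stim] = dict(A=fit.A, tau=fit.tau, B=fit.B, ci=fit.ci,
                              converged=fit.converged)
            report[f"tau_{stim}"] = fit.tau
            report[f"initial_slope_{stim}"] = dyn.initial_slope(prof)
        (out / "decay_fits.json").write_text(json.dumps(taus, indent=2, default=str))
        g = gamma_holder.get("gamma", 0.5)
        ctrl, sil = dirs.cd_window_data(session, None, responsive)
        ctrl_ids = np.flatnonzero(session.trial_mask(condition=CONTROL))
        ctrl_go = (session.trials["stimulus"].to_numpy()[ctrl_ids] == GO)
        sil_go = [
            session.trials["stimulus"].to_numpy()[np.flatnonzero(session.trial_mask(window=w))] == GO
            for w in range(1, 9)
        ]
        perm = dyn.permutation_test_tau(
            ctrl, ctrl_go, sil, sil_go, g, lag_step_ms=step,
            n_perm=params["n_perm"], seed=rng.integers(2**31),
        )
        report["delta_tau"] = perm.observed_delta_tau
        report["perm_p"] = perm.p_value
        (out / "permutation_test.json").write_text(
            json.dumps(dict(delta_tau=perm.observed_delta_tau, p=perm.p_value,
                            n_perm=len(perm.null_delta_tau), dropped=perm.n_dropped), indent=2)
        )

    def stage_null_sim():
        rng = np.random.default_rng(stage_seeds["null_sim"])
        g = gamma_holder.get("gamma", 0.5)
        ctrl, sil = dirs.cd_window_data(session, None, responsive)
        mc = ctrl.mean(axis=1)
        ms = np.stack([s.mean(axis=0) for s in sil])
        obs_eff = eff.percent_change(ms, mc)
        n_sil = min(s.shape[0] for s in sil)
        slopes = []
        for rep in dirs.simulate_time_invariant(
            ctrl, obs_eff, n_sil, n_repeats=params["null_repeats"], seed=rng.integers(2**31)
        ):
            est = dirs.cd_split_estimator(ctrl, list(rep), g)
            sm = dirs.crossval_cosine_matrix(est, n_splits=10, seed=rng.integers(2**31))
            slopes.append(dyn.initial_slope(dyn.lag_profile(sm.values)))
        est = dirs.cd_split_estimator(ctrl, sil, g)
        sm = dirs.crossval_cosine_matrix(est, n_splits=params["n_splits"], seed=rng.integers(2**31))
        obs_slope = dyn.initial_slope(dyn.lag_profile(sm.values))
        report["initial_slope_observed"] = obs_slope
        report["initial_slope_time_invariant_null"] = float(np.mean(slopes))
        (out / "null_sim.json").write_text(
            json.dumps(dict(observed=obs_slope, null_mean=float(np.mean(slopes)),
                            null_values=list(map(float, slopes))), indent=2)
        )

    def stage_pca():
        rng = np.random.default_rng(stage_seeds["pca"])
        from commdyn.session import subsample_balanced

        counts_by_window = []
        for w in range(1, 9):
            win = (float(session.silencing_onsets[w - 1]), session.silencing_duration)
            groups = []
            for stim in (GO, NOGO):
                groups.append(np.flatnonzero(session.trial_mask(condition=CONTROL, stimulus=stim)))
                groups.append(np.flatnonzero(session.trial_mask(stimulus=stim, window=w)))
            sizes = [len(g) for g in groups]
            k = min(sizes)
            sel = np.concatenate([rng.choice(g, size=k, replace=False) for g in groups])
            counts_by_window.append(window_counts(session, win, sel, responsive).counts)
        pcs = dirs.window_pcs(counts_by_window)
        np.save(out / "pc_components.npy", pcs.components)
        np.savetxt(out / "pc_variances.csv", pcs.variances, delimiter=",")
        est = dirs.pc_split_estimator(counts_by_window, component=0)
        sm = dirs.crossval_cosine_matrix(est, n_splits=min(params["n_splits"], 20),
                                         seed=rng.integers(2**31), absolute=True, kind="pc1")
        np.savetxt(out / "pc1_similarity.csv", sm.values, delimiter=",")
        report["pc1_adjacent_abs_cos"] = float(np.mean(np.diagonal(sm.values, 1)))

    def stage_correlations():
        tmask = session.trial_mask(condition=CONTROL, stimulus=GO)
        bins = [window_counts(session, (w * 65.0, 65.0), tmask, responsive).counts for w in range(7)]
        stack = np.stack(bins, axis=1)  # (trials, bins, neurons)
        rows = []
        for j in range(stack.shape[2]):
            lags, r, used = dyn.spike_autocorrelation(stack[:, :, j])
            for lag, rv in zip(lags, r):
                rows.append(dict(neuron=int(responsive[j]), lag=int(lag), r=rv))
        pd.DataFrame(rows).to_csv(out / "autocorrelation.csv", index=False)
        nc = dyn.pairwise_noise_correlations(stack)
        pd.DataFrame(nc).to_csv(out / "noise_correlations.csv", index=False)
        report["mean_noise_correlation"] = float(np.mean(nc["r"])) if len(nc["r"]) else np.nan

    def stage_figures():
        from commdyn import plots

        table_path = out / "effect_table.csv"
        if table_path.exists():
            table = pd.read_csv(table_path)
            plots.plot_effect_distribution(
                table[table.stimulus == "pooled"].percent_change.to_numpy(),
                out / "fig_effects.png", title="target silencing effects")
        profs = {}
        for stim in (GO, NOGO):
            p = out / f"cd_similarity_{stim}.csv"
            if p.exists():
                m = np.loadtxt(p, delimiter=",")
                plots.plot_similarity_matrix(m, out / f"fig_cd_similarity_{stim}.png",
                                             title=f"CD similarity ({stim})")
                profs[stim] = np.loadtxt(out / f"cd_lag_profile_{stim}.csv", delimiter=",")
        if profs:
            plots.plot_lag_profiles(profs, out / "fig_cd_lag_profiles.png")

    run_stage("effects", stage_effects)
    run_stage("behavior", stage_behavior)
    run_stage("glm", stage_glm)
    run_stage("directions", stage_directions)
    if stages.get("decay", True) and not stages.get("directions", True):
        stages["decay"] = False  # decay needs the direction stage's profiles
    run_stage("decay", stage_decay)
    run_stage("null_sim", stage_null_sim)
    run_stage("pca", stage_pca)
    run_stage("correlations", stage_correlations)
    if stages.get("figures", True) and stages.get("directions", True):
        run_stage("figures", stage_figures)

    manifest()
    (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report
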