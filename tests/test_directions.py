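"""Regularized LDA directions, cross-validated similarity, Bhattacharyya,
windowed PCA, time-invariant surrogate."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from commdyn.directions import (
    activity_split_estimator,
    bhattacharyya_magnitude,
    cd_split_estimator,
    crossval_cosine_matrix,
    pc_split_estimator,
    regularized_lda_direction,
    simulate_time_invariant,
    stimulus_decoder,
    top_dynamic_source_subset,
    tune_lda_params,
    window_pcs,
)


def _gauss_classes(rng, mu_a, mu_b, cov, n=100):
    L = np.linalg.cholesky(cov)
    a = mu_a + rng.standard_normal((n, len(mu_a))) @ L.T
    b = mu_b + rng.standard_normal((n, len(mu_b))) @ L.T
    return a, b


class TestRegularizedLDA:
    def test_identity_covariance_gives_mean_difference(self):
        rng = np.random.default_rng(0)
        a, b = _gauss_classes(rng, np.array([1.0, 0.0]), np.zeros(2), np.eye(2), n=30000)
        w = regularized_lda_direction(a, b, gamma=0.2)
        np.testing.assert_allclose(w, [1.0, 0.0], atol=0.03)

    def test_known_diagonal_covariance_solution(self):
        # Sigma = diag(1,4), dmu = (1,2) -> unnormalized (1, 0.5) -> (0.8944, 0.4472)
        rng = np.random.default_rng(1)
        cov = np.diag([1.0, 4.0])
        a, b = _gauss_classes(rng, np.array([1.0, 2.0]), np.zeros(2), cov, n=40000)
        w = regularized_lda_direction(a, b, gamma=0.0)
        np.testing.assert_allclose(w, [0.8944, 0.4472], atol=0.02)

    def test_gamma_one_is_diagonal_oracle(self):
        rng = np.random.default_rng(2)
        a = rng.standard_normal((30, 4)) * [1, 2, 3, 4] + [1, 0, 2, 0]
        b = rng.standard_normal((30, 4)) * [1, 2, 3, 4]
        w = regularized_lda_direction(a, b, gamma=1.0)
        cov = ((a - a.mean(0)).T @ (a - a.mean(0)) + (b - b.mean(0)).T @ (b - b.mean(0))) / 58
        oracle = (a.mean(0) - b.mean(0)) / np.diag(cov)
        oracle /= np.linalg.norm(oracle)
        np.testing.assert_allclose(w, oracle, atol=1e-10)

    def test_delta_zeroes_small_coefficients(self):
        rng = np.random.default_rng(3)
        a = rng.standard_normal((50, 3)) + [3, 0.01, 0]
        b = rng.standard_normal((50, 3))
        w = regularized_lda_direction(a, b, gamma=0.5, delta=0.2)
        assert w[0] != 0 and np.linalg.norm(w) == pytest.approx(1.0)
        assert (np.abs(w) < 0.2).sum() == (w == 0).sum()

    def test_all_zeroed_raises(self):
        rng = np.random.default_rng(4)
        a = rng.standard_normal((20, 3)) + 0.5
        b = rng.standard_normal((20, 3))
        with pytest.raises(ValueError):
            regularized_lda_direction(a, b, gamma=0.5, delta=1.1)

    @given(st.integers(0, 1000))
    @settings(max_examples=20, deadline=None)
    def test_permutation_equivariance(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.standard_normal((25, 5)) + rng.standard_normal(5)
        b = rng.standard_normal((25, 5))
        perm = rng.permutation(5)
        w = regularized_lda_direction(a, b, gamma=0.3)
        wp = regularized_lda_direction(a[:, perm], b[:, perm], gamma=0.3)
        np.testing.assert_allclose(wp, w[perm], atol=1e-10)


class TestTuneLDA:
    def test_separable_classes_tie_break_smallest(self):
        rng = np.random.default_rng(5)
        a = rng.standard_normal((40, 3)) + 50
        b = rng.standard_normal((40, 3))
        g, d = tune_lda_params(a, b, gammas=(0.1, 0.5, 1.0), deltas_rel=(0.0, 0.1), seed=0)
        assert (g, d) == (0.1, 0.0)

    def test_identical_distributions_near_chance(self):
        rng = np.random.default_rng(6)
        a = rng.standard_normal((60, 4))
        b = rng.standard_normal((60, 4))
        g, d = tune_lda_params(a, b, gammas=(0.5,), deltas_rel=(0.0,), seed=1)
        assert (g, d) == (0.5, 0.0)  # only grid point; run completes at ~chance

    def test_shrinkage_selected_when_trials_scarce(self):
        picks = []
        for seed in range(6):
            rng = np.random.default_rng(seed)
            mu = rng.standard_normal(30) * 0.6
            a = rng.standard_normal((25, 30)) + mu
            b = rng.standard_normal((25, 30))
            g, _ = tune_lda_params(a, b, gammas=(0.0, 0.3, 0.7, 1.0),
                                   deltas_rel=(0.0,), seed=seed)
            picks.append(g)
        assert np.mean(np.array(picks) > 0) > 0.5


class TestCrossvalSimilarity:
    def test_noiseless_directions_give_exact_cosines(self):
        v = np.eye(3)[:2]
        d = np.vstack([v, [[np.sqrt(0.5), np.sqrt(0.5), 0.0]]])

        sm = crossval_cosine_matrix(lambda rng: (d, d), n_splits=3)
        np.testing.assert_allclose(sm.values, d @ d.T, atol=1e-12)

    def test_pure_noise_directions_average_zero(self):
        rng_master = np.random.default_rng(7)

        def est(rng):
            d = rng_master.standard_normal((4, 200))
            e = rng_master.standard_normal((4, 200))
            return (d / np.linalg.norm(d, axis=1, keepdims=True),
                    e / np.linalg.norm(e, axis=1, keepdims=True))

        sm = crossval_cosine_matrix(est, n_splits=200, seed=8)
        assert np.abs(sm.values).max() < 0.05

    def test_matrix_symmetric(self):
        rng = np.random.default_rng(9)
        ctrl = rng.poisson(3.0, (4, 40, 6)).astype(float)
        sil = [rng.poisson(2.0, (24, 6)).astype(float) for _ in range(4)]
        sm = crossval_cosine_matrix(cd_split_estimator(ctrl, sil, 0.5), n_splits=5, seed=0)
        np.testing.assert_allclose(sm.values, sm.values.T, atol=1e-12)

    def test_activity_direction_normalization(self):
        counts = [np.array([[3.0, 4.0]] * 10), np.array([[1.0, 0.0]] * 10)]
        est = activity_split_estimator(counts)
        d1, d2 = est(np.random.default_rng(0))
        np.testing.assert_allclose(d1[0], [0.6, 0.8], atol=1e-12)
        np.testing.assert_allclose(np.linalg.norm(d1, axis=1), 1.0, atol=1e-12)


class TestStimulusDecoder:
    def test_chance_when_no_stimulus_signal(self, small_session):
        session, _ = small_session
        # scramble the stimulus labels so go/no-go carry no information
        scrambled = session.trials.copy()
        rng = np.random.default_rng(0)
        scrambled["stimulus"] = rng.permutation(scrambled["stimulus"].to_numpy())
        import dataclasses

        s2 = dataclasses.replace(session, trials=scrambled)
        s2.trials["outcome"] = np.where(
            s2.trials.stimulus == "go",
            np.where(np.isfinite(s2.trials.lick_time), "hit", "miss"),
            np.where(np.isfinite(s2.trials.lick_time), "false_alarm", "correct_rejection"),
        )
        acc_c, acc_s = stimulus_decoder(s2, window=4, gamma=0.5, seed=1, n_splits=10,
                                        correct_only=False)
        assert abs(acc_c - 0.5) < 0.17

    def test_real_stimulus_signal_decoded(self, small_session):
        session, _ = small_session
        acc_c, acc_s = stimulus_decoder(session, window=4, gamma=0.5, seed=2, n_splits=10)
        assert acc_c > 0.6


class TestSourceSubset:
    def test_subset_size_rule(self, small_session):
        session, _ = small_session
        sub = top_dynamic_source_subset(session, frac=0.2)
        assert len(sub) == int(np.ceil(0.2 * 12))

    def test_planted_transient_neuron_ranks_first(self, small_session):
        import dataclasses

        session, _ = small_session
        # add a strong window-specific transient to source neuron 0
        extra_t = np.tile(np.linspace(130, 180, 60), 30)
        extra_trial = np.repeat(np.flatnonzero(session.trial_mask(condition="control"))[:30], 60)
        s2 = dataclasses.replace(
            session,
            spike_neuron=np.concatenate([session.spike_neuron, np.zeros(extra_t.size, dtype=int)]),
            spike_trial=np.concatenate([session.spike_trial, extra_trial]),
            spike_time=np.concatenate([session.spike_time, extra_t]),
        )
        sub = top_dynamic_source_subset(s2, frac=0.1)
        assert 0 in sub


class TestTimeInvariantNull:
    def test_full_suppression_gives_zero_counts(self):
        ctrl = np.full((8, 10, 3), 4.0)
        eff = np.full((8, 3), -100.0)
        reps = simulate_time_invariant(ctrl, eff, n_sil_trials=6, n_repeats=2, seed=0)
        for r in reps:
            assert np.all(r == 0)

    def test_zero_effect_preserves_control_means(self):
        rng = np.random.default_rng(1)
        ctrl = rng.poisson(5.0, (8, 200, 4)).astype(float)
        eff = np.zeros((8, 4))
        reps = simulate_time_invariant(ctrl, eff, n_sil_trials=500, n_repeats=2, seed=2)
        sim_mean = np.mean([r.mean(axis=1) for r in reps], axis=0)
        np.testing.assert_allclose(sim_mean, ctrl.mean(axis=1), atol=0.4)


class TestBhattacharyya:
    def test_equal_means_zero(self):
        rng = np.random.default_rng(2)
        c = rng.standard_normal((200, 4))
        m = bhattacharyya_magnitude(c, c.copy(), gamma=0.0, n_boot=10, seed=0)
        assert m.distance == pytest.approx(0.0, abs=1e-12)

    def test_identity_covariance_closed_form(self):
        # D = ||dmu||^2 / 8 for identity covariance
        rng = np.random.default_rng(3)
        n = 60000
        c = rng.standard_normal((n, 2))
        s = rng.standard_normal((n, 2)) + [1.0, 0.0]
        m = bhattacharyya_magnitude(c, s, gamma=0.0, n_boot=5, seed=1)
        assert m.distance == pytest.approx(0.125, abs=0.01)

    def test_affine_invariance(self):
        rng = np.random.default_rng(4)
        c = rng.standard_normal((300, 4))
        s = rng.standard_normal((300, 4)) + [0.5, -0.2, 0.1, 0.0]
        T = rng.standard_normal((4, 4)) + 2 * np.eye(4)
        d0 = bhattacharyya_magnitude(c, s, gamma=0.0, n_boot=2, seed=0).distance
        d1 = bhattacharyya_magnitude(c @ T, s @ T, gamma=0.0, n_boot=2, seed=0).distance
        # tolerance reflects the tiny diagonal ridge added for singularity safety
        assert d1 == pytest.approx(d0, rel=1e-5)


class TestWindowPCA:
    def test_orthonormal_components_ordered_variances(self):
        rng = np.random.default_rng(5)
        counts = [rng.standard_normal((100, 6)) * [5, 3, 2, 1, 1, 1] for _ in range(3)]
        res = window_pcs(counts)
        for w in range(3):
            np.testing.assert_allclose(res.components[w] @ res.components[w].T,
                                       np.eye(3), atol=1e-10)
            assert np.all(np.diff(res.variances[w]) <= 1e-9)
        np.testing.assert_allclose(res.total_top, res.variances.sum(axis=1))

    def test_stationary_covariance_high_crossval_cos(self):
        rng = np.random.default_rng(6)
        load = np.zeros(8)
        load[:2] = [4.0, 3.0]
        counts = [rng.standard_normal((300, 8)) + np.outer(rng.standard_normal(300) * 3, load / 5)
                  for _ in range(4)]
        sm = crossval_cosine_matrix(pc_split_estimator(counts, 0), n_splits=10,
                                    seed=7, absolute=True)
        assert np.diagonal(sm.values, 1).mean() > 0.9


class TestSklearnCrossCheck:
    def test_unshrunk_direction_matches_sklearn_lda(self):
        """At gamma = 0 the direction coincides (up to scale) with the
        coefficient vector of scikit-learn's least-squares LDA solver —
        an independent implementation of the same discriminant."""
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        rng = np.random.default_rng(11)
        a = rng.standard_normal((200, 6)) @ np.diag([1, 2, 1, 3, 1, 2]) + rng.standard_normal(6)
        b = rng.standard_normal((200, 6)) @ np.diag([1, 2, 1, 3, 1, 2])
        w = regularized_lda_direction(a, b, gamma=0.0)
        X = np.vstack([a, b])
        y = np.array([1] * len(a) + [0] * len(b))
        clf = LinearDiscriminantAnalysis(solver="lsqr").fit(X, y)
        ref = clf.coef_.ravel()
        ref = ref / np.linalg.norm(ref)
        np.testing.assert_allclose(w, ref, atol=5e-2)
        assert abs(float(w @ ref)) > 0.999
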