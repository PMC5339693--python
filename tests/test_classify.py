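"""FLDA against a brute-force Fisher-criterion oracle, the grouped
cross-validation protocol, and score-stacking fusion."""

from __future__ import annotations

import numpy as np
import pytest

from drowsikit.classify import (
    CVResult,
    TrialSet,
    combine_classifiers,
    crossvalidate,
    flda_fit,
    flda_predict,
    flda_score,
    make_trials,
)
from drowsikit.core_io import DrowsikitError, default_band_set
from drowsikit.features import HemoSeries, RPLSeries
from drowsikit.state_id import StateSegmentation


def _series_pair(beta_awake=0.35, beta_drowsy=0.20, hbo_awake=0.02, hbo_drowsy=-0.02,
                 noise=0.0, seed=0, duration=900):
    """1 Hz feature series with an awake window [0,300] and drowsy [600,900]."""
    rng = np.random.default_rng(seed)
    times = np.arange(1.0, duration)
    beta = np.where(times < 450, beta_awake, beta_drowsy) + noise * rng.standard_normal(times.size)
    beta = np.clip(beta, 0.01, 0.97)
    rpl = np.column_stack([(1 - beta) / 4] * 2 + [(1 - beta) / 4] + [beta] + [(1 - beta) / 4])
    rpl /= rpl.sum(axis=1, keepdims=True)
    beta_series = RPLSeries(times=times, rpl=rpl, band_set=default_band_set(),
                            channel_group=(), window_s=2.0, step_s=1.0)
    htimes = np.arange(0.0, duration)
    hbo = np.where(htimes < 450, hbo_awake, hbo_drowsy) + noise * rng.standard_normal(htimes.size)
    hemo = HemoSeries(times=htimes, hbo=hbo, hb=-0.5 * hbo)
    seg = StateSegmentation(
        per_minute_state=tuple(["awake"] * 5 + ["undetermined"] * 5 + ["drowsy"] * 5),
        awake_window=(0.0, 300.0),
        drowsy_window=(600.0, 900.0),
    )
    return seg, beta_series, hemo


class TestMakeTrials:
    def test_sixty_disjoint_trials_per_state(self):
        seg, beta, hemo = _series_pair()
        eeg, nirs = make_trials(seg, beta, hemo)
        assert eeg.trials.shape == (120, 5)
        assert nirs.trials.shape == (120, 5)
        assert (eeg.labels == "awake").sum() == 60
        assert (eeg.labels == "drowsy").sum() == 60

    def test_constant_series_gives_constant_vectors(self):
        seg, beta, hemo = _series_pair(hbo_awake=0.25, hbo_drowsy=0.25)
        _, nirs = make_trials(seg, beta, hemo)
        np.testing.assert_allclose(nirs.trials, 0.25)

    def test_separated_generators_differ_everywhere(self):
        seg, beta, hemo = _series_pair(beta_awake=0.35, beta_drowsy=0.20, noise=0.02)
        eeg, _ = make_trials(seg, beta, hemo)
        mu_a = eeg.trials[eeg.labels == "awake"].mean(axis=0)
        mu_d = eeg.trials[eeg.labels == "drowsy"].mean(axis=0)
        assert np.all(mu_a > mu_d)

    def test_uncovered_window_rejected(self):
        seg, beta, hemo = _series_pair(duration=700)  # drowsy window runs to 900
        with pytest.raises(DrowsikitError):
            make_trials(seg, beta, hemo)


class TestFLDA:
    def test_identity_scatter_recovers_mean_difference(self):
        rng = np.random.default_rng(0)
        n = 2000
        X = rng.standard_normal((2 * n, 5))
        y = np.array(["awake"] * n + ["drowsy"] * n)
        X[:n, 0] += 1.0
        model = flda_fit(X, y)
        w = model.w / np.linalg.norm(model.w)
        assert abs(w[0]) > 0.99

    def test_one_dimensional_separation(self):
        rng = np.random.default_rng(1)
        X = np.concatenate([rng.normal(0, 1, 60), rng.normal(5, 1, 60)])[:, None]
        y = np.array(["awake"] * 60 + ["drowsy"] * 60)
        model = flda_fit(X, y)
        acc = np.mean(flda_predict(model, X) == y)
        assert acc >= 0.95  # Bayes rate for a 5 sigma gap is ~99 %

    def test_matches_grid_search_oracle(self):
        """On anisotropic 2-D classes the closed-form direction maximizes
        the Fisher criterion to within 1 degree of a dense grid search."""
        rng = np.random.default_rng(2)
        cov = np.array([[2.0, 1.2], [1.2, 1.0]])
        L = np.linalg.cholesky(cov)
        Xa = rng.standard_normal((200, 2)) @ L.T
        Xd = rng.standard_normal((200, 2)) @ L.T + np.array([1.5, 0.3])
        X = np.vstack([Xa, Xd])
        y = np.array(["awake"] * 200 + ["drowsy"] * 200)
        model = flda_fit(X, y)

        mu_a, mu_d = Xa.mean(0), Xd.mean(0)
        Sw = (Xa - mu_a).T @ (Xa - mu_a) + (Xd - mu_d).T @ (Xd - mu_d)
        angles = np.deg2rad(np.arange(0.0, 180.0, 0.02))
        best, best_j = None, -np.inf
        for th in angles:
            w = np.array([np.cos(th), np.sin(th)])
            j = (w @ (mu_a - mu_d)) ** 2 / (w @ Sw @ w)
            if j > best_j:
                best, best_j = th, j
        ours = np.arctan2(model.w[1], model.w[0]) % np.pi
        diff = abs(np.rad2deg((ours - best + np.pi / 2) % np.pi - np.pi / 2))
        assert diff < 1.0

    def test_sign_convention_and_boundary(self):
        rng = np.random.default_rng(3)
        X = np.vstack([rng.normal(1, 0.2, (50, 3)), rng.normal(-1, 0.2, (50, 3))])
        y = np.array(["awake"] * 50 + ["drowsy"] * 50)
        model = flda_fit(X, y)
        mu_a = X[:50].mean(0)
        mu_d = X[50:].mean(0)
        assert flda_predict(model, mu_a)[0] == "awake"
        assert flda_predict(model, mu_d)[0] == "drowsy"
        # projected class means are symmetric about the bias
        boundary = (mu_a + mu_d) / 2
        assert abs(flda_score(model, boundary)[0]) < 1e-9
        assert flda_predict(model, boundary)[0] == "awake"  # tie goes to awake

    def test_affine_invariance_of_training_accuracy(self):
        rng = np.random.default_rng(4)
        X = np.vstack([rng.normal(0.3, 1.0, (60, 5)), rng.normal(-0.3, 1.0, (60, 5))])
        y = np.array(["awake"] * 60 + ["drowsy"] * 60)
        A = rng.standard_normal((5, 5)) + 5 * np.eye(5)
        c = rng.standard_normal(5)
        acc1 = np.mean(flda_predict(flda_fit(X, y), X) == y)
        Xt = X @ A.T + c
        acc2 = np.mean(flda_predict(flda_fit(Xt, y), Xt) == y)
        assert acc1 == acc2

    def test_single_class_rejected(self):
        with pytest.raises(DrowsikitError):
            flda_fit(np.zeros((10, 2)), np.array(["awake"] * 10))

    def test_dimension_mismatch_rejected(self):
        model = flda_fit(np.vstack([np.zeros((5, 2)) + 1, np.zeros((5, 2))]),
                         np.array(["awake"] * 5 + ["drowsy"] * 5))
        with pytest.raises(DrowsikitError):
            flda_score(model, np.zeros((1, 3)))


def _random_trials(seed=0, d=5, informative=1.0, n_per=60, modality="eeg"):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((2 * n_per, d))
    X[:n_per] += informative / np.sqrt(d)
    y = np.array(["awake"] * n_per + ["drowsy"] * n_per)
    return TrialSet(trials=X, labels=y, modality=modality)


class TestCrossValidation:
    def test_separable_trials_reach_100(self):
        trials = _random_trials(seed=0, informative=20.0)
        res = crossvalidate(trials, n_repeats=30, seed=1)
        assert res.mean_accuracy == 100.0

    def test_shuffled_labels_converge_to_chance(self):
        """Permuting the labels destroys the class structure; mean accuracy
        over 120 repeats sits at 50 % within 5 points."""
        trials = _random_trials(seed=5, informative=3.0)
        rng = np.random.default_rng(99)
        shuffled = TrialSet(
            trials=trials.trials,
            labels=rng.permutation(trials.labels),
            modality="eeg",
        )
        res = crossvalidate(shuffled, n_repeats=120, seed=2)
        assert abs(res.mean_accuracy - 50.0) <= 5.0

    def test_deterministic_given_seed(self):
        trials = _random_trials(seed=6, informative=1.0)
        r1 = crossvalidate(trials, n_repeats=120, seed=3)
        r2 = crossvalidate(trials, n_repeats=120, seed=3)
        np.testing.assert_array_equal(r1.accuracies, r2.accuracies)
        assert len(r1.accuracies) == 120

    def test_wrong_trial_count_rejected(self):
        trials = _random_trials(n_per=50)
        with pytest.raises(DrowsikitError):
            crossvalidate(trials, n_repeats=2, seed=0)


class TestFusion:
    def test_identical_modalities_equal_single(self):
        """Stacking a modality with itself reproduces the single-modality
        accuracies exactly (stage-1 scores are symmetric about zero)."""
        trials = _random_trials(seed=7, informative=2.0)
        twin = TrialSet(trials=trials.trials.copy(), labels=trials.labels.copy(),
                        modality="nirs")
        single = crossvalidate(trials, n_repeats=60, seed=4)
        fused = combine_classifiers(trials, twin, n_repeats=60, seed=4)
        np.testing.assert_array_equal(single.accuracies, fused.accuracies)

    def test_pure_noise_modality_changes_little(self):
        eeg = _random_trials(seed=8, informative=2.5)
        noise = _random_trials(seed=9, informative=0.0, modality="nirs")
        alone = crossvalidate(eeg, n_repeats=120, seed=5)
        fused = combine_classifiers(eeg, noise, n_repeats=120, seed=5)
        assert abs(fused.mean_accuracy - alone.mean_accuracy) <= 3.0

    def test_complementary_modalities_improve(self):
        """Two weakly informative modalities on complementary coordinates:
        the stacked classifier is at least as good as the better one minus
        sampling noise."""
        rng = np.random.default_rng(10)
        n = 60
        y = np.array(["awake"] * n + ["drowsy"] * n)
        Xa = rng.standard_normal((2 * n, 5))
        Xa[:n, 0] += 1.2
        Xb = rng.standard_normal((2 * n, 5))
        Xb[:n, 1] += 1.2
        eeg = TrialSet(trials=Xa, labels=y, modality="eeg")
        nirs = TrialSet(trials=Xb, labels=y, modality="nirs")
        acc_e = crossvalidate(eeg, n_repeats=120, seed=6).mean_accuracy
        acc_n = crossvalidate(nirs, n_repeats=120, seed=6).mean_accuracy
        acc_f = combine_classifiers(eeg, nirs, n_repeats=120, seed=6).mean_accuracy
        assert acc_f >= max(acc_e, acc_n) - 2.0

    def test_misaligned_modalities_rejected(self):
        eeg = _random_trials(seed=11)
        bad = TrialSet(trials=eeg.trials, labels=eeg.labels[::-1], modality="nirs")
        with pytest.raises(DrowsikitError):
            combine_classifiers(eeg, bad, n_repeats=2, seed=0)
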