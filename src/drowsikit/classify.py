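"""Trial construction, Fisher's linear discriminant, the grouped
cross-validation protocol, and EEG+NIRS classifier stacking.

Each 5-minute analysis window yields 60 disjoint 5-second trials per state.
A trial's feature vector is its five consecutive 1 Hz feature samples
(frontal beta RPL for EEG, channel-averaged HbO for NIRS), so d = 5.

FLDA is implemented from first principles: w ∝ S_w⁻¹(μ₁ − μ₂) with S_w the
pooled within-class scatter (ridge-regularized by 1e-6·trace(S_w)/d for
invertibility), bias b = wᵀ(μ₁ + μ₂)/2, and the sign of w fixed so the
drowsy class projects negative.  A score of exactly zero classifies as
awake.

Cross-validation follows the 10-groups-of-12 protocol: the 120 trials are
shuffled into 10 stratified groups (6 awake + 6 drowsy each), 7 groups
train and 3 test, repeated 120 times with fresh shuffles.  Modality fusion
is classifier stacking: a second FLDA is trained on the 2-D vector of the
per-modality continuous discriminant scores under the identical group
protocol.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import DrowsikitError
from .features import HemoSeries, RPLSeries
from .state_id import StateSegmentation

__all__ = [
    "TrialSet",
    "FLDAModel",
    "CVResult",
    "make_trials",
    "flda_fit",
    "flda_predict",
    "flda_score",
    "crossvalidate",
    "combine_classifiers",
]

AWAKE, DROWSY = "awake", "drowsy"
RIDGE = 1e-6


@dataclass
class TrialSet:
    """Labeled fixed-length trials for one modality."""

    trials: np.ndarray  # n x d
    labels: np.ndarray  # n, in {awake, drowsy}
    modality: str  # eeg | nirs
    trial_s: float = 5.0

    def __post_init__(self) -> None:
        self.trials = np.asarray(self.trials, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.trials.shape[0] != self.labels.shape[0]:
            raise DrowsikitError("trials and labels disagree on n")

    @property
    def n(self) -> int:
        return self.trials.shape[0]


@dataclass(frozen=True)
class FLDAModel:
    """Two-class Fisher discriminant: decision rule sign(wᵀx − b)."""

    w: np.ndarray
    b: float
    class_means_projected: tuple[float, float]  # (awake, drowsy)


@dataclass(frozen=True)
class CVResult:
    """Accuracies (%) from the repeated grouped split."""

    accuracies: np.ndarray
    modality: str

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def sd(self) -> float:
        return float(np.std(self.accuracies, ddof=1))


# ---------------------------------------------------------------------------
# Trials

def _window_samples(times: np.ndarray, values: np.ndarray, window: tuple[float, float],
                    n_needed: int) -> np.ndarray:
    i0 = int(np.searchsorted(times, window[0] - 1e-9, side="left"))
    if i0 + n_needed > values.shape[0]:
        raise DrowsikitError(
            f"window {window} not fully covered by the 1 Hz feature series"
        )
    return values[i0 : i0 + n_needed]


def make_trials(
    seg: StateSegmentation,
    beta_rpl: RPLSeries,
    hemo: HemoSeries,
    trial_s: float = 5.0,
) -> tuple[TrialSet, TrialSet]:
    """Cut both 5-min windows into 5 s trials for each modality.

    Returns ``(eeg_trials, nirs_trials)`` with trials index-aligned across
    modalities (trial k of each covers the same 5 s interval).
    """
    n_per_state = int(round(300.0 / trial_s))
    d = int(round(trial_s))  # 1 Hz features
    feats = {}
    for name, times, values in (
        ("eeg", beta_rpl.times, beta_rpl.beta),
        ("nirs", hemo.times, hemo.hbo),
    ):
        blocks = []
        for window in (seg.awake_window, seg.drowsy_window):
            samples = _window_samples(times, values, window, n_per_state * d)
            blocks.append(samples.reshape(n_per_state, d))
        feats[name] = np.vstack(blocks)
    labels = np.array([AWAKE] * n_per_state + [DROWSY] * n_per_state)
    return (
        TrialSet(trials=feats["eeg"], labels=labels, modality="eeg", trial_s=trial_s),
        TrialSet(trials=feats["nirs"], labels=labels, modality="nirs", trial_s=trial_s),
    )


# ---------------------------------------------------------------------------
# FLDA

def flda_fit(X: np.ndarray, y: np.ndarray) -> FLDAModel:
    """Fit the two-class Fisher discriminant on features X (n × d)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size != 2:
        raise DrowsikitError(f"FLDA needs exactly two classes, got {classes.tolist()}")
    # orient so that AWAKE (or the first class) projects positive
    if AWAKE in classes:
        pos, neg = AWAKE, classes[classes != AWAKE][0]
    else:
        pos, neg = classes[0], classes[1]
    Xp, Xn = X[y == pos], X[y == neg]
    mu_p, mu_n = Xp.mean(axis=0), Xn.mean(axis=0)
    Sw = (Xp - mu_p).T @ (Xp - mu_p) + (Xn - mu_n).T @ (Xn - mu_n)
    d = X.shape[1]
    Sw = Sw + (RIDGE * np.trace(Sw) / d + 1e-300) * np.eye(d)
    w = np.linalg.solve(Sw, mu_p - mu_n)
    b = float(w @ (mu_p + mu_n) / 2.0)
    return FLDAModel(w=w, b=b, class_means_projected=(float(w @ mu_p), float(w @ mu_n)))


def flda_score(model: FLDAModel, X: np.ndarray) -> np.ndarray:
    """Continuous discriminant score wᵀx − b (positive → awake)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.w.shape[0]:
        raise DrowsikitError(
            f"feature dimension {X.shape[1]} != model dimension {model.w.shape[0]}"
        )
    return X @ model.w - model.b


def flda_predict(model: FLDAModel, X: np.ndarray) -> np.ndarray:
    """Hard labels; a score of exactly zero is classified awake."""
    s = flda_score(model, X)
    return np.where(s >= 0.0, AWAKE, DROWSY)


# ---------------------------------------------------------------------------
# Cross-validation protocol

N_GROUPS = 10
TRIALS_PER_GROUP = 12


def _grouped_split(labels: np.ndarray, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """One stratified 10-group shuffle; 7 groups train, 3 test."""
    idx_a = np.flatnonzero(labels == AWAKE)
    idx_d = np.flatnonzero(labels == DROWSY)
    per_class = TRIALS_PER_GROUP // 2
    if idx_a.size != N_GROUPS * per_class or idx_d.size != N_GROUPS * per_class:
        raise DrowsikitError(
            f"need {N_GROUPS * per_class} trials per class for the "
            f"{N_GROUPS}x{TRIALS_PER_GROUP} group protocol"
        )
    rng.shuffle(idx_a)
    rng.shuffle(idx_d)
    groups = [
        np.concatenate([idx_a[g * per_class : (g + 1) * per_class],
                        idx_d[g * per_class : (g + 1) * per_class]])
        for g in range(N_GROUPS)
    ]
    order = rng.permutation(N_GROUPS)
    train = np.concatenate([groups[g] for g in order[:7]])
    test = np.concatenate([groups[g] for g in order[7:]])
    return train, test


def crossvalidate(
    trials: TrialSet, n_repeats: int = 120, seed: int = 0
) -> CVResult:
    """Repeat the grouped 7/3 split ``n_repeats`` times on one modality."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 101]))
    acc = np.empty(n_repeats)
    for r in range(n_repeats):
        train, test = _grouped_split(trials.labels, rng)
        model = flda_fit(trials.trials[train], trials.labels[train])
        pred = flda_predict(model, trials.trials[test])
        acc[r] = 100.0 * np.mean(pred == trials.labels[test])
    return CVResult(accuracies=acc, modality=trials.modality)


def combine_classifiers(
    eeg_trials: TrialSet,
    nirs_trials: TrialSet,
    n_repeats: int = 120,
    seed: int = 0,
) -> CVResult:
    """Stacked EEG+NIRS classification under the identical group protocol.

    Stage 1 fits one FLDA per modality on the training trials; stage 2 fits
    an FLDA on the 2-D vectors of stage-1 continuous scores.  Test trials
    are scored by stage 1 and classified by stage 2.
    """
    if eeg_trials.n != nirs_trials.n or np.any(eeg_trials.labels != nirs_trials.labels):
        raise DrowsikitError("modalities must be index-aligned with identical labels")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 101]))
    labels = eeg_trials.labels
    acc = np.empty(n_repeats)
    for r in range(n_repeats):
        train, test = _grouped_split(labels, rng)
        m_eeg = flda_fit(eeg_trials.trials[train], labels[train])
        m_nirs = flda_fit(nirs_trials.trials[train], labels[train])
        z_train = np.column_stack(
            [flda_score(m_eeg, eeg_trials.trials[train]),
             flda_score(m_nirs, nirs_trials.trials[train])]
        )
        m_stack = flda_fit(z_train, labels[train])
        z_test = np.column_stack(
            [flda_score(m_eeg, eeg_trials.trials[test]),
             flda_score(m_nirs, nirs_trials.trials[test])]
        )
        pred = flda_predict(m_stack, z_test)
        acc[r] = 100.0 * np.mean(pred == labels[test])
    return CVResult(accuracies=acc, modality="eeg+nirs")
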