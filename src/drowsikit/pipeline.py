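"""End-to-end subject and cohort analysis.

``analyze_recording`` runs one recording through the full chain:
preprocessing, 1 Hz frontal beta RPL and channel-averaged HbO, per-minute
state identification, 5-min segment selection, the FLDA cross-validation
(EEG, NIRS, stacked), and DDI detection.  ``run_cohort`` repeats it over a
seeded cohort of simulated subjects and assembles the cross-subject
summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import CVResult, combine_classifiers, crossvalidate, make_trials
from .core_io import MultimodalRecording, default_band_set
from .ddi import DDISeries, DetectionResult, compute_ddi_series, detect_and_evaluate
from .features import (
    HemoSeries,
    RPLSeries,
    band_powers,
    hemo_baseline_average,
    per_minute_parameters,
    sliding_beta_rpl,
)
from .preprocess import preprocess_recording
from .state_id import StateSegmentation, identify_states, select_segments
from .synthetic import GroundTruth, ScenarioConfig, synthesize_recording

__all__ = ["SubjectResult", "analyze_recording", "run_cohort", "cohort_configs"]


@dataclass
class SubjectResult:
    """Everything the downstream summaries need for one subject."""

    minutes: pd.DataFrame
    segmentation: StateSegmentation
    beta_rpl: RPLSeries
    hemo: HemoSeries
    cv_eeg: CVResult
    cv_nirs: CVResult
    cv_combined: CVResult
    ddi: DDISeries
    detection: DetectionResult | None
    band_region_rpl: dict[str, np.ndarray]  # state -> 5 bands x 5 regions
    hemo_state_means: dict[str, float]
    transition_metrics: dict[str, float]


def _band_region_rpl(
    rec: MultimodalRecording, window: tuple[float, float]
) -> np.ndarray:
    """5 bands × 5 regions RPL over one analysis window."""
    bands = default_band_set()
    i0, i1 = int(window[0] * rec.fs_eeg), int(window[1] * rec.fs_eeg)
    out = np.empty((5, 5))
    for j, region in enumerate(("frontal", "central", "temporal", "parietal", "occipital")):
        idx = rec.channel_map.indices_of(rec.channel_map.region_labels(region))
        bp = band_powers(rec.eeg[idx, i0:i1], rec.fs_eeg, bands).mean(axis=0)
        out[:, j] = bp / bp.sum()
    return out


def analyze_recording(
    rec: MultimodalRecording,
    truth: GroundTruth | None = None,
    seed: int = 0,
    apply_ica: bool = False,
    n_repeats: int = 120,
) -> SubjectResult:
    """Run the complete analysis chain on one (preprocessed-from-raw) recording."""
    pre = preprocess_recording(rec, apply_ica=apply_ica, seed=seed)
    cmap = pre.channel_map
    frontal = cmap.indices_of(cmap.frontal_beta_set)
    beta_rpl = sliding_beta_rpl(
        pre.eeg, pre.fs_eeg, group=frontal, group_labels=cmap.frontal_beta_set
    )
    hemo = hemo_baseline_average(pre.hbo, pre.hb, pre.fs_nirs)
    minutes = per_minute_parameters(pre)
    labeled = identify_states(minutes)
    seg = select_segments(labeled["state"])
    eeg_trials, nirs_trials = make_trials(seg, beta_rpl, hemo)
    cv_eeg = crossvalidate(eeg_trials, n_repeats=n_repeats, seed=seed)
    cv_nirs = crossvalidate(nirs_trials, n_repeats=n_repeats, seed=seed)
    cv_combined = combine_classifiers(eeg_trials, nirs_trials, n_repeats=n_repeats, seed=seed)
    ddi = compute_ddi_series(hemo, beta_rpl)
    detection = None
    if truth is not None:
        detection = detect_and_evaluate(ddi, truth.first_eye_closure_s, seg.awake_window)
    band_region = {
        "awake": _band_region_rpl(pre, seg.awake_window),
        "drowsy": _band_region_rpl(pre, seg.drowsy_window),
    }
    hemo_means = {}
    for prefix, window in (("awake", seg.awake_window), ("drowsy", seg.drowsy_window)):
        mask = (hemo.times >= window[0]) & (hemo.times < window[1])
        hemo_means[f"hbo_{prefix}"] = float(hemo.hbo[mask].mean())
        hemo_means[f"hb_{prefix}"] = float(hemo.hb[mask].mean())
    transition_metrics = _transition_metrics(ddi, truth, seg)
    return SubjectResult(
        minutes=labeled,
        segmentation=seg,
        beta_rpl=beta_rpl,
        hemo=hemo,
        cv_eeg=cv_eeg,
        cv_nirs=cv_nirs,
        cv_combined=cv_combined,
        ddi=ddi,
        detection=detection,
        band_region_rpl=band_region,
        hemo_state_means=hemo_means,
        transition_metrics=transition_metrics,
    )


def _transition_metrics(
    ddi: DDISeries, truth: GroundTruth | None, seg: StateSegmentation
) -> dict[str, float]:
    """Per-subject transition parameters: the HbO rise and beta-RPL drop
    during the transition window, and their awake-state maxima."""
    out: dict[str, float] = {}
    a0, a1 = seg.awake_window
    awake_mask = (ddi.times > a0) & (ddi.times < a1)
    if np.any(awake_mask):
        out["hbo_awake_max"] = float(ddi.delta_hbo_v[awake_mask].max())
        out["pct_beta_awake_max"] = float(ddi.pct_delta_beta[awake_mask].max())
    if truth is not None:
        tmask = (ddi.times >= truth.awake_end_s) & (
            ddi.times <= truth.first_eye_closure_s + 1.0
        )
        if np.any(tmask):
            out["hbo_a_d"] = float(ddi.delta_hbo_v[tmask].max())
            out["pct_beta_a_d"] = float(ddi.pct_delta_beta[tmask].max())
    return out


def cohort_configs(
    n_subjects: int = 9, base_seed: int = 1, **overrides
) -> list[ScenarioConfig]:
    """Per-subject scenario configs with seeds derived from ``base_seed``."""
    return [
        ScenarioConfig(seed=int((base_seed * 10007 + i) % 2**31), **overrides)
        for i in range(n_subjects)
    ]


def run_cohort(
    n_subjects: int = 9,
    base_seed: int = 1,
    apply_ica: bool = False,
    n_repeats: int = 120,
    **overrides,
) -> list[tuple[SubjectResult, GroundTruth]]:
    """Simulate and analyze a cohort; returns (result, truth) per subject."""
    out = []
    for cfg in cohort_configs(n_subjects, base_seed, **overrides):
        rec, truth = synthesize_recording(cfg)
        res = analyze_recording(
            rec, truth, seed=cfg.seed, apply_ica=apply_ica, n_repeats=n_repeats
        )
        out.append((res, truth))
    return out
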