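"""Shared fixtures: small synthetic scenarios and the session cohort."""

from __future__ import annotations

import numpy as np
import pytest

import drowsikit as dk
from drowsikit.core_io import ChannelMap


@pytest.fixture(scope="session")
def short_scenario():
    """A 14-minute session with a known onset — fast to generate, exercises
    every downstream stage (>=5 awake and >=5 drowsy minutes)."""
    cfg = dk.ScenarioConfig(duration_min=14, drowsy_onset_min=8, transition_lead_s=25, seed=42)
    rec, truth = dk.synthesize_recording(cfg)
    return cfg, rec, truth


@pytest.fixture(scope="session")
def short_result(short_scenario):
    cfg, rec, truth = short_scenario
    return dk.analyze_recording(rec, truth, seed=cfg.seed)


@pytest.fixture(scope="session")
def cohort():
    """Nine simulated subjects at the default study conditions (30 min,
    onset uniform on minutes 12–25, published effect sizes)."""
    return dk.run_cohort(n_subjects=9, base_seed=1)


@pytest.fixture()
def small_channel_map():
    """A six-channel map for tests that build recordings by hand."""
    return ChannelMap(
        region_of={
            "F1": "frontal",
            "F2": "frontal",
            "C1": "central",
            "P1": "parietal",
            "O1": "occipital",
            "O2": "occipital",
        },
        occipital_alpha_set=("O1", "O2"),
        frontal_beta_set=("F1", "F2"),
    )


def make_small_recording(
    cmap: ChannelMap,
    duration_s: float = 120.0,
    fs: float = 128.0,
    fs_nirs: float = 10.0,
    seed: int = 0,
    annotations=(),
):
    """A minimal valid recording with band-limited EEG noise."""
    from scipy import signal as sig

    rng = np.random.default_rng(seed)
    n = int(duration_s * fs)
    sos = sig.butter(4, [1, 50], btype="bandpass", fs=fs, output="sos")
    eeg = sig.sosfilt(sos, rng.standard_normal((len(cmap.labels), n)), axis=-1) * 20
    eog = rng.standard_normal((2, n)) * 5
    ecg = rng.standard_normal((2, n)) * 5
    nn = int(duration_s * fs_nirs)
    hbo = rng.standard_normal((4, nn)) * 0.005
    hb = rng.standard_normal((4, nn)) * 0.005
    return dk.MultimodalRecording(
        eeg=eeg, eog=eog, ecg=ecg, hbo=hbo, hb=hb,
        fs_eeg=fs, fs_nirs=fs_nirs, channel_map=cmap,
        annotations=list(annotations),
    )
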