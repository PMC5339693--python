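"""Seeded simulator of multimodal drowsy-driving recordings.

The generator emulates a 30-minute simulated-driving session in which the
subject starts awake and becomes drowsy at some minute between 12 and 25:

* **EEG** — each channel is a sum over the five canonical bands of
  band-limited Gaussian noise whose power weights depend on the behavioral
  state.  Awake EEG carries a high frontal beta share; drowsy EEG raises
  delta/theta/alpha and depresses beta/gamma.  Across the transition the
  frontal beta relative power drops by a configurable fraction (default
  0.38).  A 60 Hz mains sinusoid and broadband sensor noise are added so the
  preprocessing filters have real work to do, and a frontally-weighted copy
  of the EOG bleeds into the EEG so artifact rejection can be exercised.
* **NIRS** — channel-averaged HbO sits near +0.019 mM/DPF awake and near
  −0.017 mM/DPF drowsy, with a monotone surge of amplitude 0.10 mM/DPF
  during the transition window that ends at the first eye closure; Hb moves
  with the opposite sign.
* **EOG/ECG** — blink deflections and R-peak spikes at state-dependent
  rates; the EOG flat-lines during eye closures.
* **Annotations** — every eye closure (all ≥ 2 s) is annotated; the first
  one marks the awake→drowsy transition endpoint.

Band-power "wander" (a slow shared log-AR(1) fluctuation) and hemodynamic
wander make within-state features realistically nonstationary; the single
``noise_sd`` knob scales every stochastic nuisance term, so ``noise_sd=0``
yields clean ramps for which downstream detection is exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy import signal

from .core_io import (
    Annotation,
    ChannelMap,
    BandSet,
    MultimodalRecording,
    default_band_set,
    default_channel_map,
    DrowsikitError,
)

__all__ = ["ScenarioConfig", "GroundTruth", "generate_trajectory", "synthesize_recording"]

AWAKE, TRANSITION, DROWSY = "awake", "transition", "drowsy"


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameters of one simulated driving session.

    Band weights are target relative power fractions (they are normalized
    internally); the frontal drowsy beta fraction is pinned to
    ``awake_beta × (1 − beta_drop_frac)`` so the injected frontal beta-RPL
    drop equals ``beta_drop_frac`` by construction.
    """

    duration_min: float = 30.0
    drowsy_onset_min: float | None = None  # integer minute drawn in [12, 25] if unset
    transition_lead_s: float | None = None  # drawn uniform in [10, 50] if unset
    awake_hbo_mean: float = 0.019
    drowsy_hbo_mean: float = -0.017
    awake_hb_mean: float = -0.003
    drowsy_hb_mean: float = 0.005
    hbo_surge: float = 0.10
    beta_drop_frac: float = 0.38
    awake_band_weights: tuple[float, ...] = (0.22, 0.18, 0.20, 0.30, 0.10)
    drowsy_band_weights: tuple[float, ...] = (0.29, 0.23, 0.225, 0.18, 0.075)
    blink_rate_awake: float = 18.0  # blinks/min
    blink_rate_drowsy: float = 8.0
    hr_awake: float = 72.0  # bpm
    hr_drowsy: float = 62.0
    noise_sd: float = 1.0  # global scale on all stochastic nuisance terms
    seed: int = 0
    n_nirs_channels: int = 8
    subject_hbo_offset_sd: float = 0.015  # between-subject shift of both state means

    def __post_init__(self) -> None:
        if self.duration_min <= 0:
            raise DrowsikitError("duration must be positive")
        if self.drowsy_onset_min is not None and not (
            0 < self.drowsy_onset_min < self.duration_min
        ):
            raise DrowsikitError("drowsy onset must lie inside the recording")
        for w in (self.awake_band_weights, self.drowsy_band_weights):
            if len(w) != 5 or any(x < 0 for x in w) or sum(w) <= 0:
                raise DrowsikitError("band weights must be five nonnegative values, not all zero")
        if self.hbo_surge <= 0:
            raise DrowsikitError("hbo_surge must be positive")
        if not (0 < self.beta_drop_frac < 1):
            raise DrowsikitError("beta_drop_frac must be in (0, 1)")
        if self.noise_sd < 0:
            raise DrowsikitError("noise_sd must be nonnegative")


@dataclass(frozen=True)
class GroundTruth:
    """The generator's latent state trajectory and injected effects."""

    awake_end_s: float  # start of the transition window
    first_eye_closure_s: float  # transition end = drowsy onset
    duration_s: float
    eye_closures: tuple[Annotation, ...]
    injected_hbo_surge: float
    injected_beta_drop: float

    def __post_init__(self) -> None:
        closures = [a for a in self.eye_closures if a.duration_s >= 2.0]
        if not closures:
            raise DrowsikitError("ground truth must contain an eye closure of >= 2 s")
        first = min(a.onset_s for a in closures)
        if abs(first - self.first_eye_closure_s) > 1e-9:
            raise DrowsikitError("first_eye_closure_s must match the earliest >=2 s closure")

    @property
    def transition_lead_s(self) -> float:
        return self.first_eye_closure_s - self.awake_end_s

    def state_at(self, t: float) -> str:
        if t < self.awake_end_s:
            return AWAKE
        if t < self.first_eye_closure_s:
            return TRANSITION
        return DROWSY

    def state_of_t(self, times: np.ndarray) -> np.ndarray:
        times = np.asarray(times, dtype=float)
        out = np.full(times.shape, DROWSY, dtype=object)
        out[times < self.first_eye_closure_s] = TRANSITION
        out[times < self.awake_end_s] = AWAKE
        return out


# ---------------------------------------------------------------------------
# Trajectory

def generate_trajectory(cfg: ScenarioConfig) -> GroundTruth:
    """Draw the latent awake→transition→drowsy trajectory and eye closures.

    The drowsy onset is an integer minute (uniform on 12..25 when unset,
    clipped to the recording); the transition lead is uniform on [10, 50] s.
    Eye closures recur throughout the drowsy state with onset-to-onset gaps
    short enough that every drowsy minute contains at least one closure.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 2201]))
    duration_s = cfg.duration_min * 60.0
    if cfg.drowsy_onset_min is None:
        hi = min(25, int(cfg.duration_min) - 1)
        lo = min(12, hi)
        onset_min = int(rng.integers(lo, hi + 1))
    else:
        onset_min = cfg.drowsy_onset_min
        rng.integers(12, 26)  # keep the draw sequence identical either way
    onset_s = float(onset_min * 60.0)
    lead = cfg.transition_lead_s
    drawn_lead = float(rng.uniform(10.0, 50.0))
    if lead is None:
        lead = drawn_lead
    if lead >= onset_s:
        raise DrowsikitError(
            f"transition lead {lead} s is not shorter than the drowsy onset {onset_s} s"
        )
    closures: list[Annotation] = []
    t = onset_s
    while t < duration_s:
        dur = float(rng.uniform(2.5, 5.0))
        dur = min(dur, duration_s - t)
        if dur >= 2.0:
            closures.append(Annotation(onset_s=t, duration_s=dur, kind="eye_closure"))
        t += dur + float(rng.uniform(20.0, 40.0))
    if not closures:
        raise DrowsikitError("recording too short to place the first eye closure")
    return GroundTruth(
        awake_end_s=onset_s - lead,
        first_eye_closure_s=onset_s,
        duration_s=duration_s,
        eye_closures=tuple(closures),
        injected_hbo_surge=cfg.hbo_surge,
        injected_beta_drop=cfg.beta_drop_frac,
    )


# ---------------------------------------------------------------------------
# Signal building blocks

# Transition morphology: a slow drift covering the first quarter of the
# effect amplitude, then a fast collapse over the final 3 s that completes
# 2 s before the eye closure.  The collapse makes the per-second change
# large compared to 1 Hz spectral-estimation noise, as in real transitions
# where the beta drop and HbO surge are abrupt relative to the sampling.
_PRE_CLOSURE_HOLD_S = 3.0
_COLLAPSE_S = 1.0
_SLOW_AMPLITUDE_FRAC = 0.25


def _transition_ramp(times: np.ndarray, truth: GroundTruth) -> np.ndarray:
    """0 before the transition, piecewise slow-drift + collapse inside it,
    1 from 2 s before the closure onward."""
    t = np.asarray(times, dtype=float)
    start = truth.awake_end_s
    closure = truth.first_eye_closure_s
    collapse_end = closure - _PRE_CLOSURE_HOLD_S
    collapse_start = max(collapse_end - _COLLAPSE_S, start)
    slow_len = collapse_start - start
    out = np.zeros_like(t)
    if slow_len > 0:
        u = np.clip((t - start) / slow_len, 0.0, 1.0)
        out += _SLOW_AMPLITUDE_FRAC * u
    col_len = max(collapse_end - collapse_start, 1e-9)
    v = np.clip((t - collapse_start) / col_len, 0.0, 1.0)
    out = np.where(t >= collapse_start, _SLOW_AMPLITUDE_FRAC + (1 - _SLOW_AMPLITUDE_FRAC) * v, out)
    out[t < start] = 0.0
    out[t >= collapse_end] = 1.0
    return out


def _ou_series(rng: np.random.Generator, n: int, fs: float, tau_s: float, sd: float) -> np.ndarray:
    """Stationary Ornstein–Uhlenbeck (AR(1)) path with sd ``sd``, time const ``tau_s``."""
    if sd == 0.0 or n == 0:
        return np.zeros(n)
    rho = math.exp(-1.0 / (fs * tau_s))
    innov = rng.standard_normal(n) * sd * math.sqrt(1.0 - rho * rho)
    x = np.empty(n)
    x[0] = rng.standard_normal() * sd
    for i in range(1, n):
        x[i] = rho * x[i - 1] + innov[i]
    return x


@lru_cache(maxsize=32)
def _band_sos(fs: float, lo: float, hi: float) -> np.ndarray:
    return signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")


@lru_cache(maxsize=8)
def _crosstalk_matrix(fs: float, band_edges: tuple[tuple[float, float], ...]) -> np.ndarray:
    """M[i, j] = fraction of band-j synthesis noise whose power lands in
    measurement band i.  The synthesis filters have finite skirts, so a
    target power composition must be pre-distorted by M⁻¹ for the
    *measured* band mixture to match the configured weights."""
    grid = np.linspace(0.01, fs / 2.0, 8192)
    M = np.zeros((len(band_edges), len(band_edges)))
    for j, (lo, hi) in enumerate(band_edges):
        w, h = signal.sosfreqz(_band_sos(fs, lo, hi), worN=grid, fs=fs)
        S = np.abs(h) ** 2
        total = np.trapezoid(S, w)
        for i, (lo2, hi2) in enumerate(band_edges):
            m = (w >= lo2) & (w < hi2)
            M[i, j] = np.trapezoid(S[m], w[m]) / total
    return M


def _synthesis_weights(target: np.ndarray, M: np.ndarray) -> np.ndarray:
    """Solve M w = target for the synthesis-space power weights."""
    w = np.linalg.solve(M, np.asarray(target, dtype=float))
    return np.clip(w, 0.0, None)


def _band_noise(rng: np.random.Generator, n: int, fs: float, lo: float, hi: float) -> np.ndarray:
    """Unit-variance band-limited Gaussian noise on [lo, hi] Hz."""
    x = signal.sosfilt(_band_sos(fs, lo, hi), rng.standard_normal(n))
    sd = x.std()
    return x / sd if sd > 0 else x


def _raised_cosine(fs: float, width_s: float) -> np.ndarray:
    n = max(int(round(width_s * fs)), 3)
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * np.arange(n) / (n - 1)))


def _triangle(fs: float, width_s: float) -> np.ndarray:
    n = max(int(round(width_s * fs)), 3)
    half = (n - 1) / 2.0
    return 1.0 - np.abs(np.arange(n) - half) / half


def _add_impulses(x: np.ndarray, fs: float, onsets_s: Sequence[float], shape: np.ndarray,
                  amplitude: float) -> None:
    n = x.shape[-1]
    for t in onsets_s:
        i0 = int(round(t * fs))
        i1 = min(i0 + shape.size, n)
        if i0 < n:
            x[..., i0:i1] += amplitude * shape[: i1 - i0]


def _poisson_events(rng: np.random.Generator, rate_per_min: float, t0: float, t1: float) -> list[float]:
    out = []
    if rate_per_min <= 0:
        return out
    t = t0 + rng.exponential(60.0 / rate_per_min)
    while t < t1:
        out.append(t)
        t += rng.exponential(60.0 / rate_per_min)
    return out


def _regular_events(rng: np.random.Generator, rate_per_min: float, t0: float, t1: float,
                    jitter: float = 0.05) -> list[float]:
    """Quasi-periodic events (heartbeats): fixed period with small jitter."""
    period = 60.0 / rate_per_min
    out = []
    t = t0 + period * rng.uniform(0.0, 1.0)
    while t < t1:
        out.append(t)
        t += period * (1.0 + jitter * rng.standard_normal())
    return out


# ---------------------------------------------------------------------------
# Recording synthesis

_EEG_SCALE_UV = 30.0  # overall RMS of the band mixture
_MAINS_AMPL_UV = 8.0
_EEG_SENSOR_NOISE_UV = 2.0
_BLINK_AMPL_UV = 120.0
_BLINK_WIDTH_S = 0.4
_RPEAK_AMPL_UV = 1000.0
_RPEAK_WIDTH_S = 0.03
_EOG_NOISE_UV = 8.0
_ECG_NOISE_UV = 30.0
_BAND_WANDER_SD = 0.20  # shared log-power fluctuation per band
_BAND_WANDER_TAU_S = 45.0
_HBO_WANDER_SD = 0.015  # mM/DPF, shared across NIRS channels
_HBO_WANDER_TAU_S = 60.0
_HBO_CHANNEL_NOISE = 0.010  # mM/DPF white noise per channel (pre low-pass)
_SURGE_DECAY_S = 10.0
_STATE_MEAN_TAU_S = 15.0
_HBO_RAMP_IN_S = 20.0
_BASELINE_S = 10.0


def _frontal_drowsy_weights(cfg: ScenarioConfig) -> np.ndarray:
    """Drowsy weights for frontal channels with the beta fraction pinned to
    ``awake_beta × (1 − beta_drop_frac)``."""
    wa = np.asarray(cfg.awake_band_weights, dtype=float)
    wa = wa / wa.sum()
    wd = np.asarray(cfg.drowsy_band_weights, dtype=float)
    wd = wd / wd.sum()
    beta_target = wa[3] * (1.0 - cfg.beta_drop_frac)
    others = np.delete(wd, 3)
    out = np.empty(5)
    out[3] = beta_target
    out[[0, 1, 2, 4]] = others * (1.0 - beta_target) / others.sum()
    return out


def synthesize_recording(
    cfg: ScenarioConfig,
    channel_map: ChannelMap | None = None,
    band_set: BandSet | None = None,
) -> tuple[MultimodalRecording, GroundTruth]:
    """Generate one recording plus its ground truth; bit-reproducible per cfg."""
    truth = generate_trajectory(cfg)
    cmap = channel_map or default_channel_map()
    bands = band_set or default_band_set()
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 7919]))

    fs, fsn = 512.0, 10.0
    n = int(round(truth.duration_s * fs))
    nn = int(round(truth.duration_s * fsn))
    t_eeg = np.arange(n) / fs
    t_nirs = np.arange(nn) / fsn

    ramp_eeg = _transition_ramp(t_eeg, truth)
    edges = tuple((lo, hi) for _, lo, hi in bands)
    M = _crosstalk_matrix(fs, edges)
    wa_t = np.asarray(cfg.awake_band_weights, float)
    wa_t = wa_t / wa_t.sum()
    wd_t = np.asarray(cfg.drowsy_band_weights, float)
    wd_t = wd_t / wd_t.sum()
    # pre-distort so the *measured* band mixture matches the configured one
    wa = _synthesis_weights(wa_t, M)
    wd = _synthesis_weights(wd_t, M)
    wd_frontal = _synthesis_weights(_frontal_drowsy_weights(cfg), M)

    # shared slow band-power wander, simulated at 1 Hz then interpolated
    t_1hz = np.arange(int(math.ceil(truth.duration_s)) + 1, dtype=float)
    wander = np.empty((5, t_eeg.size))
    for b in range(5):
        w1 = _ou_series(rng, t_1hz.size, 1.0, _BAND_WANDER_TAU_S,
                        _BAND_WANDER_SD * cfg.noise_sd)
        wander[b] = np.interp(t_eeg, t_1hz, w1)
    gain = np.exp(wander)  # multiplicative power fluctuation per band

    frontal_idx = set(cmap.indices_of(cmap.frontal_beta_set).tolist())
    labels = cmap.labels
    eeg = np.zeros((len(labels), n))
    for ch in range(len(labels)):
        is_frontal = ch in frontal_idx
        w_drowsy = wd_frontal if is_frontal else wd
        for b, (_, lo, hi) in enumerate(bands):
            w_t = wa[b] + (w_drowsy[b] - wa[b]) * ramp_eeg
            envelope = np.sqrt(np.clip(w_t * gain[b], 0.0, None))
            eeg[ch] += envelope * _band_noise(rng, n, fs, lo, hi)
        eeg[ch] *= _EEG_SCALE_UV
    # mains interference and sensor noise
    eeg += _MAINS_AMPL_UV * np.sin(2.0 * np.pi * 60.0 * t_eeg)
    if cfg.noise_sd > 0:
        eeg += _EEG_SENSOR_NOISE_UV * cfg.noise_sd * rng.standard_normal(eeg.shape)

    # ---- EOG: blinks + closure flat-lines -------------------------------
    eog = np.zeros((2, n))
    if cfg.noise_sd > 0:
        eog += _EOG_NOISE_UV * cfg.noise_sd * rng.standard_normal((2, n))
    closure_ivals = [(a.onset_s, a.end_s) for a in truth.eye_closures]

    def _in_closure(t: float) -> bool:
        return any(s <= t < e for s, e in closure_ivals)

    blink_shape = _raised_cosine(fs, _BLINK_WIDTH_S)
    blinks_awake = _poisson_events(rng, cfg.blink_rate_awake, 0.0, truth.first_eye_closure_s)
    blinks_drowsy = _poisson_events(
        rng, cfg.blink_rate_drowsy, truth.first_eye_closure_s, truth.duration_s
    )
    blink_onsets = [t for t in blinks_awake + blinks_drowsy if not _in_closure(t)]
    blink_series = np.zeros(n)
    _add_impulses(blink_series, fs, blink_onsets, blink_shape, _BLINK_AMPL_UV)
    eog += blink_series  # both EOG channels see the blink
    for s, e in closure_ivals:  # eyelid closed: EOG flat-lines
        i0, i1 = int(s * fs), min(int(e * fs), n)
        eog[:, i0:i1] *= 0.05

    # frontally-weighted EOG bleed into EEG (what ICA rejection removes)
    bleed = np.array(
        [0.15 if ch in frontal_idx else 0.03 for ch in range(len(labels))]
    )
    eeg += bleed[:, None] * blink_series[None, :]

    # ---- ECG: R-peak train ----------------------------------------------
    ecg = np.zeros((2, n))
    if cfg.noise_sd > 0:
        ecg += _ECG_NOISE_UV * cfg.noise_sd * rng.standard_normal((2, n))
    r_shape = _triangle(fs, _RPEAK_WIDTH_S)
    beats = _regular_events(rng, cfg.hr_awake, 0.0, truth.first_eye_closure_s)
    beats += _regular_events(rng, cfg.hr_drowsy, truth.first_eye_closure_s, truth.duration_s)
    for row, pol in zip(ecg, (1.0, 0.6)):
        series = np.zeros(n)
        _add_impulses(series, fs, beats, r_shape, pol * _RPEAK_AMPL_UV)
        row += series

    # ---- NIRS ------------------------------------------------------------
    subject_offset = float(rng.standard_normal()) * cfg.subject_hbo_offset_sd * cfg.noise_sd
    onset = truth.first_eye_closure_s
    # task-related drift begins after the 10 s baseline window, so the
    # baseline-corrected awake plateau equals the configured state mean
    ramp_in = 1.0 - np.exp(-np.clip(t_nirs - _BASELINE_S, 0.0, None) / _HBO_RAMP_IN_S)
    post = np.clip(t_nirs - onset, 0.0, None)
    settle = np.where(t_nirs >= onset, np.exp(-post / _STATE_MEAN_TAU_S), 1.0)
    awake_m = cfg.awake_hbo_mean + subject_offset
    drowsy_m = cfg.drowsy_hbo_mean + subject_offset
    base_hbo = np.where(
        t_nirs < onset,
        awake_m * ramp_in,
        drowsy_m + (awake_m - drowsy_m) * settle,
    )
    surge = cfg.hbo_surge * _transition_ramp(t_nirs, truth)
    surge = np.where(t_nirs >= onset, cfg.hbo_surge * np.exp(-post / _SURGE_DECAY_S), surge)
    hbo_shared = base_hbo + surge + _ou_series(
        rng, nn, fsn, _HBO_WANDER_TAU_S, _HBO_WANDER_SD * cfg.noise_sd
    )
    awake_mh = cfg.awake_hb_mean - 0.4 * subject_offset
    drowsy_mh = cfg.drowsy_hb_mean - 0.4 * subject_offset
    base_hb = np.where(
        t_nirs < onset,
        awake_mh * ramp_in,
        drowsy_mh + (awake_mh - drowsy_mh) * settle,
    )
    hb_shared = base_hb - 0.3 * surge + _ou_series(
        rng, nn, fsn, _HBO_WANDER_TAU_S, 0.6 * _HBO_WANDER_SD * cfg.noise_sd
    )
    k = cfg.n_nirs_channels
    hbo = hbo_shared[None, :] + _HBO_CHANNEL_NOISE * cfg.noise_sd * rng.standard_normal((k, nn))
    hb = hb_shared[None, :] + 0.6 * _HBO_CHANNEL_NOISE * cfg.noise_sd * rng.standard_normal((k, nn))

    rec = MultimodalRecording(
        eeg=eeg,
        eog=eog,
        ecg=ecg,
        hbo=hbo,
        hb=hb,
        fs_eeg=fs,
        fs_nirs=fsn,
        channel_map=cmap,
        annotations=list(truth.eye_closures),
    )
    return rec, truth
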