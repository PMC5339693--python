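"""Spectral band power, relative power level, hemodynamic averaging, and the
per-minute behavioral parameters.

Band power is the Welch power-spectral-density estimate (1 s Hann segments,
50 % overlap) summed over the band's frequency bins, using the half-open
convention ``lo <= f < hi`` so that the five canonical bands exactly tile
1–50 Hz.  The relative power level (RPL) of a band is its power divided by
the summed power of the five bands, averaged over a channel group first —
a unitless fraction robust to between-subject amplitude differences.

The sliding beta RPL uses a 2 s window advanced by 1 s, giving a 1 Hz
series stamped at window centers (integer seconds).  Channel-averaged,
baseline-corrected HbO/Hb is optionally block-averaged to the same 1 Hz
grid, stamped at each block's left edge so both series share integer
timestamps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .core_io import (
    Annotation,
    BandSet,
    DrowsikitError,
    MultimodalRecording,
    default_band_set,
)

__all__ = [
    "UndefinedRPLError",
    "RPLSeries",
    "HemoSeries",
    "band_power",
    "band_powers",
    "relative_power_level",
    "sliding_rpl",
    "sliding_beta_rpl",
    "hemo_baseline_average",
    "detect_impulses",
    "per_minute_parameters",
]


class UndefinedRPLError(DrowsikitError):
    """All five band powers are zero, so the power ratio is undefined."""


# ---------------------------------------------------------------------------
# Containers

@dataclass
class RPLSeries:
    """Per-window relative power levels for the five bands over one group."""

    times: np.ndarray  # window centers, s
    rpl: np.ndarray  # windows x 5, rows sum to 1
    band_set: BandSet
    channel_group: tuple[str, ...]
    window_s: float
    step_s: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.rpl = np.asarray(self.rpl, dtype=float)
        if self.rpl.ndim != 2 or self.rpl.shape[1] != 5:
            raise DrowsikitError("rpl must be windows x 5")
        if np.any(self.rpl < -1e-12) or np.any(self.rpl > 1 + 1e-12):
            raise DrowsikitError("RPL entries must lie in [0, 1]")
        if not np.allclose(self.rpl.sum(axis=1), 1.0, atol=1e-9):
            raise DrowsikitError("RPL rows must sum to 1")

    def band(self, name: str) -> np.ndarray:
        return self.rpl[:, self.band_set.index(name)]

    @property
    def beta(self) -> np.ndarray:
        return self.band("beta")


@dataclass
class HemoSeries:
    """Channel-averaged, baseline-corrected HbO/Hb (mM/DPF)."""

    times: np.ndarray
    hbo: np.ndarray
    hb: np.ndarray
    baseline_window_s: float = 10.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.hbo = np.asarray(self.hbo, dtype=float)
        self.hb = np.asarray(self.hb, dtype=float)
        if not (self.times.shape == self.hbo.shape == self.hb.shape):
            raise DrowsikitError("times, hbo and hb must have equal length")


# ---------------------------------------------------------------------------
# Spectral estimation

def _welch_psd(x: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Welch PSD with 2 s Hann segments and 50 % overlap along the last axis.

    2 s segments give 0.5 Hz resolution, so the leakage of a component at
    least 1 Hz inside a band stays within that band; on a 2 s sliding
    window this degrades to a single Hann periodogram.
    """
    nper = min(int(round(2 * fs)), x.shape[-1])
    return signal.welch(x, fs=fs, window="hann", nperseg=nper, noverlap=nper // 2, axis=-1)


def _integrate_band(f: np.ndarray, psd: np.ndarray, lo: float, hi: float) -> np.ndarray:
    df = f[1] - f[0] if f.size > 1 else 1.0
    mask = (f >= lo) & (f < hi)
    return psd[..., mask].sum(axis=-1) * df


def band_power(x: np.ndarray, fs: float, band: tuple[float, float]) -> float:
    """Welch band power of a single signal, in signal-units²."""
    x = np.asarray(x, dtype=float)
    lo, hi = band
    if not (0 < lo < hi <= fs / 2.0):
        raise DrowsikitError(f"band ({lo}, {hi}) Hz invalid for fs {fs} Hz")
    if x.shape[-1] < 2 * fs:
        raise DrowsikitError("band power needs at least 2 s of samples")
    f, psd = _welch_psd(x, fs)
    return float(_integrate_band(f, psd, lo, hi))


def band_powers(x: np.ndarray, fs: float, band_set: BandSet) -> np.ndarray:
    """Per-channel band powers: (..., 5) from a (..., samples) array."""
    x = np.asarray(x, dtype=float)
    f, psd = _welch_psd(x, fs)
    return np.stack([_integrate_band(f, psd, lo, hi) for _, lo, hi in band_set], axis=-1)


def relative_power_level(
    x: np.ndarray, fs: float, band_set: BandSet | None = None,
    group: np.ndarray | None = None,
) -> np.ndarray:
    """RPL 5-vector: group-averaged band powers normalized to sum 1.

    ``x`` is channels × samples; ``group`` optionally selects channel rows.
    """
    band_set = band_set or default_band_set()
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if group is not None:
        if len(group) == 0:
            raise DrowsikitError("channel group must be nonempty")
        x = x[np.asarray(group, dtype=int)]
    bp = band_powers(x, fs, band_set).mean(axis=0)
    total = bp.sum()
    if total <= 0:
        raise UndefinedRPLError("all-zero spectrum: RPL undefined")
    return bp / total


def sliding_rpl(
    x: np.ndarray,
    fs: float,
    band_set: BandSet | None = None,
    group: np.ndarray | None = None,
    group_labels: tuple[str, ...] = (),
    window_s: float = 2.0,
    step_s: float = 1.0,
) -> RPLSeries:
    """RPL in a sliding window (default 2 s window, 1 s step → 1 Hz series).

    Times are window centers; at the defaults they fall on integer seconds.
    """
    band_set = band_set or default_band_set()
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if group is not None:
        x = x[np.asarray(group, dtype=int)]
    n = x.shape[-1]
    win = int(round(window_s * fs))
    step = int(round(step_s * fs))
    if n < win:
        raise DrowsikitError(f"signal of {n / fs:.1f} s shorter than the {window_s} s window")
    n_windows = (n - win) // step + 1
    rpl = np.empty((n_windows, 5))
    for k in range(n_windows):
        seg = x[:, k * step : k * step + win]
        bp = band_powers(seg, fs, band_set).mean(axis=0)
        total = bp.sum()
        if total <= 0:
            raise UndefinedRPLError(f"all-zero spectrum in window {k}")
        rpl[k] = bp / total
    times = (np.arange(n_windows) * step + win / 2.0) / fs
    return RPLSeries(
        times=times, rpl=rpl, band_set=band_set,
        channel_group=tuple(group_labels), window_s=window_s, step_s=step_s,
    )


def sliding_beta_rpl(
    eeg: np.ndarray,
    fs: float,
    group: np.ndarray,
    group_labels: tuple[str, ...] = (),
    window_s: float = 2.0,
    step_s: float = 1.0,
    band_set: BandSet | None = None,
) -> RPLSeries:
    """Frontal-group sliding RPL; the beta column is the deliverable."""
    return sliding_rpl(
        eeg, fs, band_set=band_set, group=group, group_labels=group_labels,
        window_s=window_s, step_s=step_s,
    )


# ---------------------------------------------------------------------------
# Hemodynamics

def hemo_baseline_average(
    hbo: np.ndarray,
    hb: np.ndarray,
    fs: float,
    excluded: tuple[int, ...] = (),
    baseline_window_s: float = 10.0,
    downsample_to_1hz: bool = True,
) -> HemoSeries:
    """Baseline-correct each channel, average channels, optionally 1 Hz bin.

    Each channel's mean over the first ``baseline_window_s`` seconds is
    subtracted before averaging over the non-excluded channels.  The 1 Hz
    downsampling is a non-overlapping block mean of ``fs`` samples, stamped
    at the block's left edge (t = 0, 1, 2, … s).
    """
    hbo = np.atleast_2d(np.asarray(hbo, dtype=float))
    hb = np.atleast_2d(np.asarray(hb, dtype=float))
    nb = int(round(baseline_window_s * fs))
    if hbo.shape[1] < nb:
        raise DrowsikitError(
            f"need at least {baseline_window_s} s of data for the baseline"
        )
    keep = [i for i in range(hbo.shape[0]) if i not in set(excluded)]
    if not keep:
        raise DrowsikitError("all NIRS channels excluded")

    def _avg(mat: np.ndarray) -> np.ndarray:
        sub = mat[keep]
        corrected = sub - sub[:, :nb].mean(axis=1, keepdims=True)
        return corrected.mean(axis=0)

    hbo_m, hb_m = _avg(hbo), _avg(hb)
    if downsample_to_1hz:
        block = int(round(fs))
        n_out = hbo_m.size // block
        hbo_m = hbo_m[: n_out * block].reshape(n_out, block).mean(axis=1)
        hb_m = hb_m[: n_out * block].reshape(n_out, block).mean(axis=1)
        times = np.arange(n_out, dtype=float)
    else:
        times = np.arange(hbo_m.size) / fs
    return HemoSeries(times=times, hbo=hbo_m, hb=hb_m, baseline_window_s=baseline_window_s)


# ---------------------------------------------------------------------------
# Per-minute behavioral parameters

def detect_impulses(
    x: np.ndarray,
    fs: float,
    refractory_s: float,
    prominence_sds: float = 3.0,
    smooth_s: float | None = None,
) -> np.ndarray:
    """Onset times (s) of impulse-like peaks in a 1-D signal.

    The trace is smoothed with a moving average of width ``smooth_s``
    (default: half the refractory period) before peak picking — raw
    wideband noise otherwise produces spurious high-prominence local
    maxima.  Peaks must have prominence at least ``prominence_sds`` robust
    standard deviations (1.4826 × MAD of the *raw* trace) and be separated
    by ``refractory_s``.
    """
    x = np.asarray(x, dtype=float)
    if smooth_s is None:
        smooth_s = refractory_s / 2.0
    width = max(int(round(smooth_s * fs)), 1)
    smoothed = np.convolve(x, np.full(width, 1.0 / width), mode="same") if width > 1 else x
    mad = np.median(np.abs(x - np.median(x)))
    threshold = prominence_sds * 1.4826 * mad
    if threshold == 0:
        threshold = 1e-3 * (x.max() - x.min())
    if threshold == 0:
        return np.empty(0)
    peaks, _ = signal.find_peaks(
        smoothed, prominence=threshold,
        distance=max(int(refractory_s * fs), 1),
    )
    return peaks / fs


BLINK_REFRACTORY_S = 0.2
RPEAK_REFRACTORY_S = 0.3


def per_minute_parameters(
    rec: MultimodalRecording, band_set: BandSet | None = None
) -> pd.DataFrame:
    """The five per-minute state-identification parameters.

    Returns one row per complete minute with columns ``blink_rate``
    (EOG peaks/min), ``eye_closure`` (count of ≥ 2 s closures starting in the
    minute), ``heart_rate`` (ECG peaks/min), ``alpha_power`` (occipital
    average, µV²) and ``beta_power`` (frontal average, µV²).
    """
    band_set = band_set or default_band_set()
    cmap = rec.channel_map
    fs = rec.fs_eeg
    n_minutes = int(rec.duration_s // 60)
    if n_minutes < 1:
        raise DrowsikitError("recording shorter than one minute")
    occ = cmap.indices_of(cmap.occipital_alpha_set)
    fro = cmap.indices_of(cmap.frontal_beta_set)
    alpha_band = band_set.bands[band_set.index("alpha")][1:]
    beta_band = band_set.bands[band_set.index("beta")][1:]
    blink_t = detect_impulses(rec.eog[0], fs, BLINK_REFRACTORY_S, smooth_s=0.1)
    rpeak_t = detect_impulses(rec.ecg[0], fs, RPEAK_REFRACTORY_S, smooth_s=0.03)
    closures = rec.eye_closures(min_duration_s=2.0)
    rows = []
    for m in range(n_minutes):
        t0, t1 = 60.0 * m, 60.0 * (m + 1)
        i0, i1 = int(t0 * fs), int(t1 * fs)
        occ_seg = rec.eeg[occ, i0:i1]
        fro_seg = rec.eeg[fro, i0:i1]
        f, psd_occ = _welch_psd(occ_seg, fs)
        _, psd_fro = _welch_psd(fro_seg, fs)
        rows.append(
            {
                "minute": m,
                "blink_rate": int(np.sum((blink_t >= t0) & (blink_t < t1))),
                "eye_closure": sum(1 for a in closures if t0 <= a.onset_s < t1),
                "heart_rate": int(np.sum((rpeak_t >= t0) & (rpeak_t < t1))),
                "alpha_power": float(_integrate_band(f, psd_occ, *alpha_band).mean()),
                "beta_power": float(_integrate_band(f, psd_fro, *beta_band).mean()),
            }
        )
    return pd.DataFrame(rows).set_index("minute")
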