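"""Filtering, detrending, and EOG-correlated ICA component rejection.

The preprocessing chain: a 60 Hz notch on the electrophysiological streams,
a 1–50 Hz band-pass on EEG, a 0.2 Hz low-pass on NIRS, linear detrending of
EOG/ECG, and an automated stand-in for manual ICA component inspection that
zeroes components whose absolute correlation with either EOG channel exceeds
a threshold (default 0.6) before re-mixing.

Filters are zero-phase by default (forward–backward application), so feature
windows stay aligned with behavioral events; the band-pass/low-pass are
4th-order Butterworth and the notch is a quality-factor-30 IIR notch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .core_io import DrowsikitError, MultimodalRecording

__all__ = [
    "FilterSpec",
    "FilterError",
    "DecompositionError",
    "filter_signal",
    "detrend",
    "reject_artifact_components",
    "preprocess_recording",
]


class FilterError(DrowsikitError):
    """Invalid filter specification or input too short for the filter."""


class DecompositionError(DrowsikitError):
    """ICA failed (rank-deficient input or non-convergence)."""


@dataclass(frozen=True)
class FilterSpec:
    """One filtering stage.

    ``edges`` is (lo, hi) for ``bandpass``, a single cutoff for ``lowpass``,
    and the notch frequency for ``notch`` (``order`` then acts as the notch
    quality factor).
    """

    kind: str  # notch | bandpass | lowpass
    edges: tuple[float, ...]
    order: int = 4
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("notch", "bandpass", "lowpass"):
            raise FilterError(f"unknown filter kind {self.kind!r}")
        if self.order < 1:
            raise FilterError("filter order must be >= 1")
        if any(e <= 0 for e in self.edges):
            raise FilterError("filter edges must be positive")


NOTCH_60 = FilterSpec(kind="notch", edges=(60.0,), order=30)


def _ar_extend_row(x: np.ndarray, n_pad: int, order: int = 40) -> np.ndarray:
    """Extend a 1-D signal at both ends by autoregressive extrapolation.

    Reflection padding puts a derivative kink exactly at the signal
    boundary; a high-Q notch then rings at its own pole frequency right
    where the data start.  AR continuation (which extends a sinusoid
    exactly) keeps the junction smooth so filter transients die out inside
    the pad.  Falls back to odd reflection if the AR fit is unstable.
    """
    from scipy.linalg import solve_toeplitz

    n = x.size
    fit = x - x.mean()
    order = min(order, n // 4)

    def _extrapolate(seg: np.ndarray) -> np.ndarray:
        # seg: recent samples ending at the boundary; predict forward
        r = np.correlate(seg, seg, mode="full")[seg.size - 1 : seg.size + order]
        r[0] *= 1.0 + 1e-6  # slight ridge keeps the Toeplitz solve stable
        try:
            a = solve_toeplitz((r[:-1], r[:-1]), r[1:])
        except np.linalg.LinAlgError:
            return None
        buf = seg[-order:].tolist()
        out = np.empty(n_pad)
        for i in range(n_pad):
            nxt = float(np.dot(a, buf[::-1]))
            out[i] = nxt
            buf.pop(0)
            buf.append(nxt)
        return out

    fit_len = min(n, max(4 * order, 1024))
    right = _extrapolate(fit[-fit_len:])
    left_rev = _extrapolate(fit[:fit_len][::-1])
    limit = 10.0 * (np.abs(fit).max() + 1e-30)
    if (
        right is None or left_rev is None
        or np.abs(right).max() > limit or np.abs(left_rev).max() > limit
    ):
        # odd reflection fallback
        left = 2 * x[0] - x[1 : n_pad + 1][::-1]
        rgt = 2 * x[-1] - x[-n_pad - 1 : -1][::-1]
        return np.concatenate([left, x, rgt])
    mean = x.mean()
    return np.concatenate([left_rev[::-1] + mean, x, right + mean])


def _filtfilt_ar_padded(b, a, x: np.ndarray, fs: float) -> np.ndarray:
    """Zero-phase IIR filtering with AR-continuation padding (2 s per side)."""
    x2 = np.atleast_2d(x)
    n_pad = min(int(round(2 * fs)), x2.shape[-1] - 1)
    rows = []
    for row in x2:
        ext = _ar_extend_row(row, n_pad)
        filt = signal.filtfilt(b, a, ext, padlen=0)
        rows.append(filt[n_pad : n_pad + row.size])
    out = np.vstack(rows)
    return out if x.ndim > 1 else out[0]
EEG_BANDPASS = FilterSpec(kind="bandpass", edges=(1.0, 50.0), order=4)
NIRS_LOWPASS = FilterSpec(kind="lowpass", edges=(0.2,), order=4)


def filter_signal(x: np.ndarray, fs: float, spec: FilterSpec) -> np.ndarray:
    """Apply one filter stage along the last axis; shape is preserved."""
    x = np.asarray(x, dtype=float)
    nyq = fs / 2.0
    if any(e >= nyq for e in spec.edges):
        raise FilterError(f"filter edge {max(spec.edges)} Hz >= Nyquist {nyq} Hz")
    n = x.shape[-1]
    if n <= 3 * max(spec.order, 4):
        raise FilterError(f"signal of {n} samples too short for order-{spec.order} filter")
    if spec.kind == "notch":
        b, a = signal.iirnotch(spec.edges[0], Q=float(spec.order), fs=fs)
        if spec.zero_phase:
            return _filtfilt_ar_padded(b, a, x, fs)
        return signal.lfilter(b, a, x, axis=-1)
    btype = "bandpass" if spec.kind == "bandpass" else "lowpass"
    edges = list(spec.edges) if spec.kind == "bandpass" else spec.edges[0]
    sos = signal.butter(spec.order, edges, btype=btype, fs=fs, output="sos")
    if spec.zero_phase:
        return signal.sosfiltfilt(sos, x, axis=-1)
    return signal.sosfilt(sos, x, axis=-1)


def detrend(x: np.ndarray) -> np.ndarray:
    """Remove the least-squares line from each row (or the single vector)."""
    x = np.asarray(x, dtype=float)
    if x.shape[-1] < 2:
        raise FilterError("detrend needs at least 2 samples")
    return signal.detrend(x, axis=-1, type="linear")


def reject_artifact_components(
    eeg: np.ndarray,
    eog: np.ndarray,
    fs: float,
    corr_threshold: float = 0.6,
    seed: int = 0,
    max_iter: int = 500,
) -> tuple[np.ndarray, list[int]]:
    """Zero ICA components correlated with the EOG and re-mix.

    Components of a FastICA decomposition whose absolute Pearson correlation
    with either EOG channel exceeds ``corr_threshold`` are removed before the
    inverse transform.  The decomposition is seeded, hence reproducible.
    Returns ``(cleaned_eeg, rejected_component_indices)``.
    """
    from sklearn.decomposition import FastICA

    eeg = np.asarray(eeg, dtype=float)
    eog = np.atleast_2d(np.asarray(eog, dtype=float))
    if eeg.shape[1] != eog.shape[1]:
        raise DrowsikitError("eeg and eog must share the sample clock")
    if corr_threshold <= 0:
        warnings.warn(
            "corr_threshold <= 0 rejects every component; output is degenerate",
            stacklevel=2,
        )
    ica = FastICA(whiten="unit-variance", random_state=seed, max_iter=max_iter, tol=1e-4)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence warnings handled below
        try:
            sources = ica.fit_transform(eeg.T)  # samples x components
        except (np.linalg.LinAlgError, ValueError) as exc:
            raise DecompositionError(f"ICA decomposition failed: {exc}") from exc
    if not np.all(np.isfinite(sources)):
        raise DecompositionError("ICA produced non-finite sources")
    rejected: list[int] = []
    for k in range(sources.shape[1]):
        src = sources[:, k]
        if src.std() == 0:
            continue
        corr = max(
            abs(np.corrcoef(src, ch)[0, 1]) if ch.std() > 0 else 0.0 for ch in eog
        )
        if corr > corr_threshold or corr_threshold <= 0:
            rejected.append(k)
    kept = sources.copy()
    kept[:, rejected] = 0.0
    cleaned = ica.inverse_transform(kept).T
    return cleaned, rejected


def preprocess_recording(
    rec: MultimodalRecording,
    notch: FilterSpec | None = NOTCH_60,
    eeg_band: FilterSpec | None = EEG_BANDPASS,
    nirs_lowpass: FilterSpec | None = NIRS_LOWPASS,
    apply_ica: bool = False,
    ica_corr_threshold: float = 0.6,
    excluded_nirs_channels: tuple[int, ...] = (),
    seed: int = 0,
) -> MultimodalRecording:
    """Run the full preprocessing chain on a recording, returning a new one.

    ICA rejection is optional (it dominates runtime on long 64-channel
    recordings); NIRS channel exclusion is a user-supplied index list.
    """
    eeg, eog, ecg = rec.eeg, rec.eog, rec.ecg
    if notch is not None:
        eeg = filter_signal(eeg, rec.fs_eeg, notch)
        eog = filter_signal(eog, rec.fs_eeg, notch)
        ecg = filter_signal(ecg, rec.fs_eeg, notch)
    if eeg_band is not None:
        eeg = filter_signal(eeg, rec.fs_eeg, eeg_band)
    eog = detrend(eog)
    ecg = detrend(ecg)
    if apply_ica:
        eeg, _ = reject_artifact_components(
            eeg, eog, rec.fs_eeg, corr_threshold=ica_corr_threshold, seed=seed
        )
    keep = [i for i in range(rec.hbo.shape[0]) if i not in set(excluded_nirs_channels)]
    if not keep:
        raise DrowsikitError("all NIRS channels excluded")
    hbo, hb = rec.hbo[keep], rec.hb[keep]
    if nirs_lowpass is not None:
        hbo = filter_signal(hbo, rec.fs_nirs, nirs_lowpass)
        hb = filter_signal(hb, rec.fs_nirs, nirs_lowpass)
    return MultimodalRecording(
        eeg=eeg,
        eog=eog,
        ecg=ecg,
        hbo=hbo,
        hb=hb,
        fs_eeg=rec.fs_eeg,
        fs_nirs=rec.fs_nirs,
        t0=rec.t0,
        channel_map=rec.channel_map,
        annotations=list(rec.annotations),
        units=dict(rec.units),
    )
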