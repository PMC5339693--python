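"""The drowsiness detection index (DDI) and its evaluation.

The DDI is a binary indicator computed on time-aligned 1 Hz series of the
channel-averaged HbO change and the frontal beta RPL:

* ``ΔHbO_v = HbO_c − HbO_l`` where the running reference ``HbO_l`` tracks
  the current value while HbO is non-increasing and freezes at the
  preceding local minimum during a continuous increase;
* ``%Δbeta = 100 · (beta_h − beta_c) / beta_h`` where ``beta_h`` mirrors
  that rule: it tracks while beta is non-decreasing and freezes at the
  preceding local maximum during a continuous decrease;
* ``DDI = 1`` iff ``ΔHbO_v > 0.05`` (mM/DPF) and ``%Δbeta > 20`` (%).

A zero first difference counts as "not increasing" (the reference keeps
tracking), so flat segments never hold a stale reference.  The index is not
latched: it falls back to 0 as soon as either condition clears, which
allows repeated detections.

Detection is evaluated against the first eye closure of two seconds or
more.  The lead time is closure time minus detection time (positive =
early).  Any DDI firing strictly inside the reference awake window is
flagged as an awake false trigger — the study called this a "false
negative" (misdetection of awake as drowsy), and that alias is kept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core_io import DrowsikitError
from .features import HemoSeries, RPLSeries

__all__ = [
    "DDISeries",
    "DetectionResult",
    "HBO_THRESHOLD",
    "BETA_THRESHOLD_PCT",
    "running_low_reference",
    "running_high_reference",
    "compute_ddi_series",
    "detect_and_evaluate",
]

HBO_THRESHOLD = 0.05  # mM/DPF
BETA_THRESHOLD_PCT = 20.0  # %

TRUE_POSITIVE = "true_positive"
FALSE_NEGATIVE_AWAKE_TRIGGER = "false_negative_awake_trigger"
MISS = "miss"


@dataclass
class DDISeries:
    """Time-indexed DDI state: inputs, running references, and the index."""

    times: np.ndarray
    hbo_c: np.ndarray
    hbo_l: np.ndarray
    delta_hbo_v: np.ndarray
    beta_c: np.ndarray
    beta_h: np.ndarray
    pct_delta_beta: np.ndarray
    hbo_exceeds: np.ndarray  # ΔHbO_v > threshold, per sample
    beta_exceeds: np.ndarray  # %Δbeta > threshold, per sample
    ddi: np.ndarray  # int8 in {0, 1}
    hbo_threshold: float = HBO_THRESHOLD
    beta_threshold_pct: float = BETA_THRESHOLD_PCT

    def detection_times(self) -> np.ndarray:
        """Times of 0→1 rising edges of the index."""
        d = self.ddi.astype(int)
        rising = np.flatnonzero(np.diff(np.concatenate([[0], d])) == 1)
        return self.times[rising]


@dataclass(frozen=True)
class DetectionResult:
    """Outcome of DDI evaluation for one subject."""

    detection_times: tuple[float, ...]  # all rising edges
    first_eye_closure_s: float
    lead_time_s: float | None  # closure − detection; None when missed
    awake_false_trigger: bool  # any DDI=1 strictly inside the awake window
    subject_outcome: str  # true_positive | false_negative_awake_trigger | miss

    @property
    def detected(self) -> bool:
        return self.lead_time_s is not None


def running_low_reference(x: np.ndarray) -> np.ndarray:
    """Preceding-local-minimum reference: tracks x while it is
    non-increasing, freezes during a continuous strict increase."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    if x.size == 0:
        return out
    out[0] = x[0]
    for t in range(1, x.size):
        out[t] = out[t - 1] if x[t] > x[t - 1] else x[t]
    return out


def running_high_reference(x: np.ndarray) -> np.ndarray:
    """Mirror image: tracks while non-decreasing, freezes at the preceding
    local maximum during a continuous strict decrease."""
    return -running_low_reference(-np.asarray(x, dtype=float))


def compute_ddi_series(
    hemo: HemoSeries,
    beta: RPLSeries,
    hbo_threshold: float = HBO_THRESHOLD,
    beta_threshold_pct: float = BETA_THRESHOLD_PCT,
) -> DDISeries:
    """Compute the binary DDI on the common 1 Hz time grid of both series.

    The two series are intersected on exact timestamps; a rate other than
    1 Hz or an empty intersection is a misalignment error.  Samples with a
    non-positive beta reference force DDI = 0 with a warning.
    """
    for name, t in (("hemo", hemo.times), ("beta", beta.times)):
        if t.size >= 2 and not np.allclose(np.diff(t), 1.0, atol=1e-6):
            raise DrowsikitError(f"{name} series is not sampled at 1 Hz")
    common, ih, ib = np.intersect1d(
        np.round(hemo.times, 6), np.round(beta.times, 6), return_indices=True
    )
    if common.size == 0:
        raise DrowsikitError("hemo and beta series share no timestamps: misaligned")
    hbo_c = hemo.hbo[ih]
    beta_c = beta.beta[ib]
    hbo_l = running_low_reference(hbo_c)
    beta_h = running_high_reference(beta_c)
    delta_hbo_v = hbo_c - hbo_l
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = 100.0 * (beta_h - beta_c) / beta_h
    bad = beta_h <= 0
    if np.any(bad):
        warnings.warn(
            f"{int(bad.sum())} samples have non-positive beta reference; DDI forced 0",
            stacklevel=2,
        )
        pct = np.where(bad, 0.0, pct)
    hbo_exceeds = delta_hbo_v > hbo_threshold
    beta_exceeds = pct > beta_threshold_pct
    ddi = (hbo_exceeds & beta_exceeds & ~bad).astype(np.int8)
    return DDISeries(
        times=common,
        hbo_c=hbo_c,
        hbo_l=hbo_l,
        delta_hbo_v=delta_hbo_v,
        beta_c=beta_c,
        beta_h=beta_h,
        pct_delta_beta=pct,
        hbo_exceeds=hbo_exceeds,
        beta_exceeds=beta_exceeds,
        ddi=ddi,
        hbo_threshold=hbo_threshold,
        beta_threshold_pct=beta_threshold_pct,
    )


def detect_and_evaluate(
    series: DDISeries,
    first_eye_closure_s: float,
    awake_window: tuple[float, float],
) -> DetectionResult:
    """Score the DDI against the first ≥ 2 s eye closure.

    The transition detection is the first rising edge after the awake
    reference window and at or before the closure; edges strictly inside
    the awake window are false triggers, not detections.  No qualifying
    edge means a miss.
    """
    if first_eye_closure_s is None:
        raise DrowsikitError("ground truth lacks an eye closure")
    edges = series.detection_times()
    a0, a1 = awake_window
    on = series.times[series.ddi.astype(bool)]
    awake_trigger = bool(np.any((on > a0) & (on < a1)))
    candidates = edges[(edges > a1) & (edges <= first_eye_closure_s)]
    lead = float(first_eye_closure_s - candidates[0]) if candidates.size else None
    if lead is None:
        outcome = MISS
    elif awake_trigger:
        outcome = FALSE_NEGATIVE_AWAKE_TRIGGER
    else:
        outcome = TRUE_POSITIVE
    return DetectionResult(
        detection_times=tuple(float(t) for t in edges),
        first_eye_closure_s=float(first_eye_closure_s),
        lead_time_s=lead,
        awake_false_trigger=awake_trigger,
        subject_outcome=outcome,
    )
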