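"""Per-minute awake/drowsy labeling and 5-minute analysis-segment selection.

A minute is labeled *drowsy* when it contains at least one eye closure of
two seconds or more AND its frontal beta power falls below the awake
reference; *awake* when it has no such closure AND beta is at or above the
reference (less a tolerance that absorbs the normal minute-to-minute power
fluctuation); anything else is *undetermined*.  The remaining three
parameters — blink rate up, heart rate down, occipital alpha up — are
recorded as corroborating flags but are not required for the label, since
beta power and eye closure are by far the most reliable markers.

The awake beta reference is the median frontal beta power of the first five
minutes (subjects start the session awake).  The analysis segments are the
earliest runs of five consecutive awake and five consecutive drowsy minutes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import DrowsikitError

__all__ = [
    "SegmentationUnavailableError",
    "StateSegmentation",
    "awake_reference",
    "identify_states",
    "select_segments",
]

AWAKE, DROWSY, UNDETERMINED = "awake", "drowsy", "undetermined"

REQUIRED_COLUMNS = ("blink_rate", "eye_closure", "heart_rate", "alpha_power", "beta_power")


class SegmentationUnavailableError(DrowsikitError):
    """No qualifying 5-minute run exists; the subject would be excluded."""


@dataclass(frozen=True)
class StateSegmentation:
    """Per-minute labels plus the selected 5-min awake and drowsy windows."""

    per_minute_state: tuple[str, ...]
    awake_window: tuple[float, float]  # (start_s, end_s), 300 s long
    drowsy_window: tuple[float, float]

    def __post_init__(self) -> None:
        for w in (self.awake_window, self.drowsy_window):
            if abs((w[1] - w[0]) - 300.0) > 1e-9:
                raise DrowsikitError("analysis windows must be 300 s long")
        if self.awake_window[1] > self.drowsy_window[0]:
            raise DrowsikitError("awake window must precede the drowsy window")


def awake_reference(params: pd.DataFrame, n_minutes: int = 5) -> dict[str, float]:
    """Median of each parameter over the first ``n_minutes`` minutes."""
    if len(params) < n_minutes:
        raise DrowsikitError(f"need at least {n_minutes} minutes of parameters")
    head = params.iloc[:n_minutes]
    return {c: float(head[c].median()) for c in REQUIRED_COLUMNS if c != "eye_closure"}


def identify_states(
    params: pd.DataFrame,
    baselines: dict[str, float] | None = None,
    beta_tolerance: float = 0.2,
) -> pd.DataFrame:
    """Label each minute awake/drowsy/undetermined.

    ``baselines`` maps parameter name → awake reference value (computed from
    the first five minutes when omitted).  ``beta_tolerance`` is the relative
    slack below the beta reference within which a closure-free minute still
    counts as awake.  Returns a frame with a ``state`` column and boolean
    corroborating flags ``flag_blink_up``, ``flag_hr_down``, ``flag_alpha_up``.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in params.columns]
    if missing:
        raise DrowsikitError(f"per-minute table lacks columns {missing}")
    if len(params) < 5:
        raise DrowsikitError("need at least 5 minutes of parameters")
    if baselines is None:
        baselines = awake_reference(params)
    beta_ref = baselines["beta_power"]
    states = []
    for _, row in params.iterrows():
        has_closure = row["eye_closure"] >= 1
        if has_closure and row["beta_power"] < beta_ref:
            states.append(DROWSY)
        elif not has_closure and row["beta_power"] >= beta_ref * (1.0 - beta_tolerance):
            states.append(AWAKE)
        else:
            states.append(UNDETERMINED)
    out = params.copy()
    out["state"] = states
    out["flag_blink_up"] = params["blink_rate"] > baselines.get("blink_rate", np.inf)
    out["flag_hr_down"] = params["heart_rate"] < baselines.get("heart_rate", -np.inf)
    out["flag_alpha_up"] = params["alpha_power"] > baselines.get("alpha_power", np.inf)
    return out


def _earliest_run(states: list[str], target: str, run_len: int = 5) -> int | None:
    count = 0
    for i, s in enumerate(states):
        count = count + 1 if s == target else 0
        if count == run_len:
            return i - run_len + 1
    return None


def select_segments(states: "pd.Series | list[str]", run_len: int = 5) -> StateSegmentation:
    """Pick the earliest 5-consecutive-minute awake and drowsy runs."""
    states = list(states)
    a = _earliest_run(states, AWAKE, run_len)
    d = _earliest_run(states, DROWSY, run_len)
    if a is None or d is None:
        missing = AWAKE if a is None else DROWSY
        raise SegmentationUnavailableError(
            f"no run of {run_len} consecutive {missing} minutes; subject excluded"
        )
    if a * 60.0 + 300.0 > d * 60.0:
        raise SegmentationUnavailableError(
            "awake run does not precede the drowsy run; subject excluded"
        )
    return StateSegmentation(
        per_minute_state=tuple(states),
        awake_window=(a * 60.0, a * 60.0 + 300.0),
        drowsy_window=(d * 60.0, d * 60.0 + 300.0),
    )
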