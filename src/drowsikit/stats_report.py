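"""Cohort statistics and report assembly.

Two statistical summaries mirror the study's tables: an unpaired ("unconnected")
two-tailed t-test per (band, region) cell on the cohort RPL values, with a
Bonferroni-style significance level of 0.05 / number-of-cells, and the
hemodynamic state summary — per-subject awake/drowsy HbO and Hb means with
grand means ± SD and a two-tailed t-test across subjects.  The hemodynamic
test is paired by default (the same subjects contribute both states); the
unpaired variant is exposed as well.  Report rounding follows the field's
conventions: 3 decimals for mM/DPF, 1 decimal for percentages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import DrowsikitError, REGIONS

__all__ = [
    "BandRegionTestMatrix",
    "HemoStateSummary",
    "band_region_ttests",
    "hemo_state_summary",
    "summarize_state_means",
    "modality_accuracy_summary",
    "transition_parameter_summary",
    "threshold_rule_outcomes",
]

BAND_NAMES = ("delta", "theta", "alpha", "beta", "gamma")


@dataclass(frozen=True)
class BandRegionTestMatrix:
    """p-values of the per-band, per-region awake-vs-drowsy tests."""

    p: pd.DataFrame  # 5 bands x 5 regions
    alpha_sig: float

    def significant(self) -> pd.DataFrame:
        return self.p < self.alpha_sig


@dataclass(frozen=True)
class HemoStateSummary:
    """Per-subject and grand-mean HbO/Hb state means (mM/DPF)."""

    per_subject: pd.DataFrame  # columns hbo_awake, hbo_drowsy, hb_awake, hb_drowsy
    grand_mean: dict[str, float]
    grand_sd: dict[str, float]
    p_hbo: float
    p_hb: float
    p_hbo_unpaired: float
    p_hb_unpaired: float


def band_region_ttests(
    awake: np.ndarray, drowsy: np.ndarray, alpha_total: float = 0.05
) -> BandRegionTestMatrix:
    """Unpaired two-tailed t-test per (band, region) cell.

    ``awake`` and ``drowsy`` are subjects × 5 bands × 5 regions arrays of
    band power (or RPL).  The significance level is ``alpha_total`` divided
    by the number of cells (0.002 for the default 5 × 5 matrix).
    """
    awake = np.asarray(awake, dtype=float)
    drowsy = np.asarray(drowsy, dtype=float)
    if awake.ndim != 3 or drowsy.ndim != 3 or awake.shape[1:] != drowsy.shape[1:]:
        raise DrowsikitError("inputs must be subjects x bands x regions")
    if awake.shape[0] < 2 or drowsy.shape[0] < 2:
        raise DrowsikitError("need at least 2 subjects per state")
    res = stats.ttest_ind(awake, drowsy, axis=0)
    p = np.asarray(res.pvalue)
    if np.any(~np.isfinite(p)):
        raise DrowsikitError("zero variance in both groups for some cell")
    n_cells = p.shape[0] * p.shape[1]
    frame = pd.DataFrame(
        p,
        index=list(BAND_NAMES[: p.shape[0]]),
        columns=list(REGIONS[: p.shape[1]]),
    )
    return BandRegionTestMatrix(p=frame, alpha_sig=alpha_total / n_cells)


def summarize_state_means(
    hbo_awake, hbo_drowsy, hb_awake, hb_drowsy, subjects=None
) -> HemoStateSummary:
    """Grand means ± SD and t-tests from per-subject state means."""
    cols = {
        "hbo_awake": np.asarray(hbo_awake, float),
        "hbo_drowsy": np.asarray(hbo_drowsy, float),
        "hb_awake": np.asarray(hb_awake, float),
        "hb_drowsy": np.asarray(hb_drowsy, float),
    }
    n = len(cols["hbo_awake"])
    if n < 2:
        raise DrowsikitError("need at least 2 subjects")
    per_subject = pd.DataFrame(cols, index=list(subjects) if subjects else range(n))

    def _p(paired: bool, a: np.ndarray, b: np.ndarray) -> float:
        if np.allclose(a, b):
            return 1.0
        res = stats.ttest_rel(a, b) if paired else stats.ttest_ind(a, b)
        return float(res.pvalue)

    return HemoStateSummary(
        per_subject=per_subject,
        grand_mean={k: float(v.mean()) for k, v in cols.items()},
        grand_sd={k: float(v.std(ddof=1)) for k, v in cols.items()},
        p_hbo=_p(True, cols["hbo_awake"], cols["hbo_drowsy"]),
        p_hb=_p(True, cols["hb_awake"], cols["hb_drowsy"]),
        p_hbo_unpaired=_p(False, cols["hbo_awake"], cols["hbo_drowsy"]),
        p_hb_unpaired=_p(False, cols["hb_awake"], cols["hb_drowsy"]),
    )


def hemo_state_summary(hemo_series_list, segments_list, subjects=None) -> HemoStateSummary:
    """Per-subject state means over the 5-min windows, then the summary.

    ``hemo_series_list`` holds one :class:`~drowsikit.features.HemoSeries`
    per subject and ``segments_list`` the matching segmentations.
    """
    if len(hemo_series_list) != len(segments_list):
        raise DrowsikitError("one segmentation per hemodynamic series required")
    means = {k: [] for k in ("hbo_awake", "hbo_drowsy", "hb_awake", "hb_drowsy")}
    for hemo, seg in zip(hemo_series_list, segments_list):
        for prefix, window in (("awake", seg.awake_window), ("drowsy", seg.drowsy_window)):
            mask = (hemo.times >= window[0]) & (hemo.times < window[1])
            if not np.any(mask):
                raise DrowsikitError(f"no hemodynamic samples in the {prefix} window")
            means[f"hbo_{prefix}"].append(float(hemo.hbo[mask].mean()))
            means[f"hb_{prefix}"].append(float(hemo.hb[mask].mean()))
    return summarize_state_means(
        means["hbo_awake"], means["hbo_drowsy"], means["hb_awake"], means["hb_drowsy"],
        subjects=subjects,
    )


# ---------------------------------------------------------------------------
# Report arithmetic on per-subject columns

def modality_accuracy_summary(nirs, eeg, combined) -> dict[str, float]:
    """Cohort means (1 decimal) per modality and the fusion gains."""
    out = {
        "nirs_mean": round(float(np.mean(nirs)), 1),
        "eeg_mean": round(float(np.mean(eeg)), 1),
        "combined_mean": round(float(np.mean(combined)), 1),
        "nirs_sd": round(float(np.std(nirs, ddof=1)), 1),
        "eeg_sd": round(float(np.std(eeg, ddof=1)), 1),
        "combined_sd": round(float(np.std(combined, ddof=1)), 1),
    }
    out["gain_over_eeg"] = round(out["combined_mean"] - out["eeg_mean"], 1)
    out["gain_over_nirs"] = round(out["combined_mean"] - out["nirs_mean"], 1)
    return out


def transition_parameter_summary(
    hbo_a_d, hbo_lead_s, pct_beta_a_d, beta_lead_s
) -> dict[str, float]:
    """Cohort means of the transition parameters, with report rounding."""
    return {
        "hbo_a_d_mean": round(float(np.mean(hbo_a_d)), 2),
        "hbo_lead_mean_s": round(float(np.mean(hbo_lead_s)), 1),
        "pct_beta_a_d_mean": round(float(np.mean(pct_beta_a_d)), 0),
        "beta_lead_mean_s": round(float(np.mean(beta_lead_s)), 1),
    }


def threshold_rule_outcomes(
    transition_values, awake_max_values, threshold: float
) -> dict[str, float]:
    """Apply a single-modality threshold rule to per-subject columns.

    True-positive rate = share of subjects whose transition change exceeds
    the threshold; false-trigger rate = share whose awake-state maximum
    change also exceeds it (the study's "false negative": awake misread as
    drowsy).  Both in %, rounded to integers.
    """
    tv = np.asarray(transition_values, float)
    av = np.asarray(awake_max_values, float)
    return {
        "true_positive_pct": round(100.0 * float(np.mean(tv > threshold)), 0),
        "false_trigger_pct": round(100.0 * float(np.mean(av > threshold)), 0),
    }
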