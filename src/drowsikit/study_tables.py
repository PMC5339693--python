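"""Subject-level summary values reported for the nine-driver cohort.

These are the published per-subject numbers of the driving study that this
package's synthetic cohort emulates: state means of the hemodynamic
response, per-modality classification accuracies, and the transition
parameters feeding the detection thresholds.  They serve as inputs for the
report-arithmetic routines (grand means, paired tests, threshold rules) and
as calibration anchors for the generator defaults.

Subjects are S1–S8 and S10 (S9 and S11 were excluded from the study).
"""

from __future__ import annotations

SUBJECTS = ("S1", "S2", "S3", "S4", "S5", "S6", "S7", "S8", "S10")

# Hemodynamic state means, mM/DPF.
HBO_AWAKE = (0.022, 0.073, 0.005, -0.011, 0.017, 0.036, 0.022, 0.023, -0.013)
HBO_DROWSY = (-0.002, -0.001, -0.017, -0.027, -0.057, -0.003, -0.016, 0.003, -0.031)
HB_AWAKE = (-0.007, -0.024, -0.013, 0.003, -0.009, 0.019, -0.011, 0.009, 0.003)
HB_DROWSY = (0.009, 0.016, -0.017, 0.016, -0.004, 0.007, 0.009, -0.001, 0.011)

# Classification accuracy (%), per modality.
ACC_NIRS = (70.0, 85.7, 68.3, 69.2, 86.2, 77.0, 70.8, 70.9, 64.9)
ACC_EEG = (72.4, 62.2, 90.4, 56.8, 71.0, 63.0, 67.1, 77.9, 73.4)
ACC_COMBINED = (74.5, 99.5, 84.1, 78.6, 86.4, 72.6, 74.5, 70.5, 71.7)

# Awake→drowsy transition parameters.
HBO_A_D = (0.09, 0.06, 0.08, 0.12, 0.13, 0.08, 0.16, 0.10, 0.06)  # mM/DPF rise
HBO_A_MAX = (0.03, 0.04, 0.01, 0.04, 0.05, 0.04, 0.10, 0.10, 0.03)  # awake max rise
HBO_LEAD_S = (5.0, 6.0, 4.0, 6.0, 5.0, 3.0, 5.0, 3.0, 2.0)
PCT_BETA_A_D = (30.0, 24.0, 61.0, 33.0, 57.0, 27.0, 42.0, 33.0, 33.0)  # % drop
PCT_BETA_A_MAX = (6.0, 26.0, 51.0, 35.0, 18.0, 23.0, 22.0, 33.0, 9.0)
BETA_LEAD_S = (6.0, 3.0, 5.0, 4.0, 5.0, 5.0, 6.0, 4.0, 5.0)
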