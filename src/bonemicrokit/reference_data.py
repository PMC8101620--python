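"""Published summary statistics from the distal-tibia CT pilot study.

These printed tables are *inputs* to worked examples and consistency
checks (calibration-line centroid identities, effect-size recomputation,
cohort arithmetic, the power scenario).  Nothing here is a computed
output of this package; all derived numbers are recomputed through the
package's statistics functions at run time.
"""

from __future__ import annotations

import pandas as pd

#: Accuracy study (n = 175 matched ROIs): per-measure micro-CT (reference)
#: and CT means/SDs, Pearson r, and the CT → reference calibration line.
ACCURACY_TABLE = pd.DataFrame(
    [
        # measure, ref_mean, ref_sd, ct_mean, ct_sd, r, intercept, slope
        ("tb_vbmd", 505.9, 78.8, 1098.5, 61.7, 0.901, -757.679, 1.150),
        ("tb_tbmd", 144.6, 49.5, 240.0, 93.1, 0.935, 25.384, 0.497),
        ("tb_na", 0.72, 0.30, 0.62, 0.30, 0.924, 0.145, 0.931),
        ("tb_pw", 530.2, 99.9, 1045.7, 321.6, 0.913, 233.730, 0.284),
        ("tb_th", 124.6, 14.1, 124.4, 16.9, 0.703, 51.477, 0.588),
        ("tb_sp", 488.8, 93.8, 415.7, 108.0, 0.732, 224.545, 0.636),
        ("ei", 0.41, 0.18, 0.76, 0.46, 0.711, 0.190, 0.286),
        ("smi", 0.69, 0.48, 1.64, 1.26, 0.865, 0.154, 0.325),
    ],
    columns=["measure", "ref_mean", "ref_sd", "ct_mean", "ct_sd", "r", "intercept", "slope"],
).set_index("measure")

#: Unadjusted fracture-group comparison (no fracture n = 9 vs ≥1 fracture
#: n = 21): printed means (SD), mean difference, pooled SD, p, effect size.
GROUP_COMPARISON_TABLE = pd.DataFrame(
    [
        ("tb_vbmd", 1135.4, 48.3, 1088.6, 32.0, 46.9, 37.4, 0.004, 1.25),
        ("tb_tbmd", 301.0, 93.6, 201.0, 61.4, 99.9, 72.1, 0.002, 1.39),
        ("tb_na", 0.77, 0.30, 0.48, 0.17, 0.29, 0.21, 0.002, 1.36),
        ("tb_pw", 1170.7, 212.4, 968.2, 143.7, 202.5, 166.3, 0.005, 1.22),
        ("tb_th", 126.2, 14.7, 116.6, 6.5, 9.5, 9.6, 0.019, 0.99),
        ("tb_sp", 331.3, 79.5, 499.9, 187.7, -168.6, 164.2, 0.016, -1.03),
        ("ei", 0.70, 0.17, 0.86, 0.37, -0.16, 0.33, 0.232, -0.49),
        ("smi", 1.54, 0.57, 1.85, 1.05, -0.31, 0.94, 0.414, -0.33),
        ("cb_poro", 0.17, 0.01, 0.20, 0.03, -0.03, 0.03, 0.022, -0.97),
        ("cb_th", 1.64, 0.60, 1.56, 0.59, 0.08, 0.59, 0.738, 0.13),
    ],
    columns=[
        "measure", "mean_nofx", "sd_nofx", "mean_fx", "sd_fx",
        "mean_difference", "pooled_sd", "p_value", "effect_size",
    ],
).set_index("measure")

#: Pilot cohort (n = 30): counts by prevalent-vertebral-fracture number.
FRACTURE_COUNTS = {0: 9, 1: 10, 2: 11}  # key 2 means "2 or more"

#: Pilot-study power scenario: two-sided two-sample t, α = 0.05, n = 9/21.
POWER_SCENARIO = {"n1": 9, "n2": 21, "alpha": 0.05, "sides": 2}
#: Printed exact powers at selected effect sizes under that scenario.
PRINTED_POWER = {1.0: 0.68, 1.10: 0.76}

#: Spherical accuracy-ROI geometry: 7.05 mm diameter at 150 μm voxels.
SPHERE_ROI = {"diameter_mm": 7.05, "spacing_mm": 0.15, "printed_span_voxels": 47}
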