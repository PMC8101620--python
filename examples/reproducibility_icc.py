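"""Repeat-scan reproducibility analysis with the one-way random ICC.

Simulates a repeat-scan experiment — each unit measured on k = 3
replicate scans with known between-unit and within-unit variances — and
recovers the intraclass correlation with its exact F-based confidence
interval.
"""

from bonemicrokit import icc_oneway
from bonemicrokit.phantoms import simulate_replicates

for var_b, var_w in [(0.8, 0.2), (0.5, 0.5), (0.99, 0.01)]:
    values = simulate_replicates(n_units=200, k_replicates=3,
                                 var_between=var_b, var_within=var_w, seed=3)
    res = icc_oneway(values)
    target = var_b / (var_b + var_w)
    print(f"target ICC {target:4.2f}  ->  estimated {res.icc:5.3f} "
          f"(95% CI {res.ci_low:5.3f} .. {res.ci_high:5.3f})")
# The estimate tracks the generating variance ratio and the CI is an
# exact F-distribution interval for the one-way random-effects model —
# the same analysis applied to repeat CT scans of the same limb.
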