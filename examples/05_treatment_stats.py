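"""Drought x land-use statistics on cumulative outcomes.

Classical two-way ANOVA F values are reported as effect sizes; p-values
come from a permutation scheme (restricted label permutation for main
effects, residual permutation for the interaction), fully enumerated when
the arrangement count allows.
"""

import numpy as np

from pulsechase import permutation_anova

rng = np.random.default_rng(0)
# cumulated CO2 (mol m-2) for 12 monoliths: drought halves respiration
control = rng.normal(1.0, 0.08, 6)
drought = rng.normal(0.5, 0.05, 6)
values = np.r_[control, drought]
treatment = ["control"] * 6 + ["drought"] * 6
land_use = (["managed"] * 3 + ["abandoned"] * 3) * 2

res = permutation_anova(values, treatment, land_use, n_perm=5000, seed=0)
names = {"factor_a": "drought", "factor_b": "land use", "interaction": "interaction"}
for term, r in res.items():
    how = "enumerated" if r.enumerated else f"{r.n_perm} sampled"
    print(f"{names[term]:>12}: F = {r.F:7.2f}  p_F = {r.p_classical:.4f}  "
          f"p_exact = {r.p_exact:.4f} ({how})")
# p_exact for main effects is exact (400 arrangements enumerated); its
# resolution is 1/400, so strong effects bottom out at p = 2/400 = 0.005.
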