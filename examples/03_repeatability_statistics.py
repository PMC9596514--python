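"""Repeatability and agreement statistics on a toy measurement table.

Shows the three validation statistics on their own, without phantoms:
ICC(2,1) for triplicate re-analyses, Bland-Altman limits of agreement
for contralateral values, and the exact Wilcoxon signed-rank test.
"""

import numpy as np

import rootvoi as rv

rng = np.random.default_rng(0)

# triplicate re-analysis of 10 sites: tiny re-execution scatter
site_values = rng.normal(0.62, 0.018, (10, 1))
triplicates = site_values + rng.normal(0, 0.002, (10, 3))
icc, form = rv.icc_triplicate(triplicates)
print(f"{form} over triplicates = {icc:.4f}  (1.0 would be perfect repeatability)")

# contralateral agreement in untreated animals (values in % BV/TV)
left = 100 * rng.normal(0.62, 0.018, 8)
right = left + rng.normal(-1.9, 1.0, 8)
ba = rv.bland_altman(right, left)
print(f"Bland-Altman: mean difference {ba.mean_diff:+.2f}%, "
      f"limits [{ba.loa_low:+.2f}%, {ba.loa_high:+.2f}%], "
      f"critical difference {ba.critical_diff:.2f}%")

wil = rv.wilcoxon_signed_rank(right, left)
print(f"Wilcoxon signed rank: W+ = {wil.statistic:.0f}, {wil.method} p = {wil.p_value:.4f}")
# Differences within the limits of agreement and a non-significant p
# indicate left/right comparability; the critical difference is the
# smallest change distinguishable from measurement noise.
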