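"""Simulate and analyze a split-mouth protraction study.

Each of 8 animals gets an untreated left quadrant (bone fraction drawn
around 41.3% +/- 4.9%) and a treated right quadrant (33.2% +/- 5.7%).
Every quadrant goes through the full pipeline; the per-animal paired
BV/TV values are compared with the exact Wilcoxon signed-rank test and
summarized with Bland-Altman limits of agreement.
"""

import warnings

import rootvoi as rv

base = rv.reduced_phantom_spec()  # ~1 mm quadrant on a fast 56-voxel grid
config = rv.RunConfig(crop_offset_voxels=base.crop_offset_voxels)

study = rv.generate_split_mouth_study(n_animals=8, base_spec=base, seed=42)
print(study.truth_table.round(4).to_string(index=False))

with warnings.catch_warnings():
    warnings.simplefilter("ignore")  # shell may touch the reduced grid border
    report, table = rv.run_application_part(study, config)

print("\nmeasured BV/TV per animal:")
print(table.round(4).to_string(index=False))
d = report.to_dict()
print(f"\nWilcoxon W+ = {d['wilcoxon_stat']:.0f}, exact p = {d['wilcoxon_p']:.4f} "
      f"({'significant' if report.significant else 'not significant'} at alpha = {report.alpha})")
print(f"Bland-Altman: mean difference {d['ba_mean_diff']:+.4f}, "
      f"critical difference {d['ba_critical_diff']:.4f}")
# A negative mean difference means the treated side lost peri-root bone;
# p < 0.05 detects the protraction effect within this small cohort.
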