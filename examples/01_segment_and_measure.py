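"""Segment a synthetic jaw quadrant and measure peri-root BV/TV.

Generates a full-resolution phantom (10.4 µm voxels), runs the complete
analysis — median filter, Sobel gradient, seeded watershed, CEJ-plane
alignment, 100 µm shell VOI — and compares the measured bone volume
fraction with the phantom's ground truth.
"""

import rootvoi as rv

spec = rv.PhantomSpec(seed=1)
volume, truth, seeds, cej = rv.generate_quadrant(spec)
print(f"phantom: {spec.shape} voxels at {spec.voxel_size_um} um, "
      f"{len(seeds)} seed markers, true shell BV/TV = {truth.bv_tv:.4f}")

config = rv.RunConfig()  # median x3, crop 30 voxels, 100 um shell
result = rv.run_site(config, volume, seeds, cej)

print(f"measured BV/TV = {result.bv_tv:.4f}  "
      f"(BV {result.bv_mm3:.5f} mm^3 / TV {result.tv_mm3:.5f} mm^3)")
print(f"absolute error vs ground truth = {abs(result.bv_tv - truth.bv_tv):.4f}")
# The error reflects the real procedure's bias at ~10 um voxels (median
# filtering slightly erodes thin roots and trabeculae); it stays within
# +/- 0.02 of truth under the default imaging conditions.
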