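"""Agreement metrics: overlap, contour distances, mapping values, ICC.

Shows why the epicardial Dice is reported on the ring-shaped myocardium
(more error-sensitive than a filled disk), the analytic Hausdorff case, and
ICC recovery from raters with known noise.
"""

import numpy as np

from cardiomapseg import geometry as G
from cardiomapseg import metrics as M

# ring vs disk sensitivity to the same 1 px shift
ys, xs = np.mgrid[0:48, 0:48]
rr = np.hypot(xs - 24, ys - 24)
ring = G.SegmentationMask(np.where((rr >= 8) & (rr <= 12), 2, 0).astype(np.uint8))
disk = G.SegmentationMask(np.where(rr <= 12, 1, 0).astype(np.uint8))
shift = lambda m: G.SegmentationMask(np.roll(m.labels, 1, axis=1))
print(f"1 px shift: ring (epicardial) Dice "
      f"{M.dice(ring, shift(ring), 'epicardial'):.3f}  vs  disk (endocardial) "
      f"Dice {M.dice(disk, shift(disk), 'endocardial'):.3f}")

# analytic distance case: concentric circles 2 px apart at 1.5 mm spacing
t = np.linspace(0, 2 * np.pi, 2000, endpoint=False)
c10 = np.column_stack([10 * np.cos(t), 10 * np.sin(t)])
c12 = np.column_stack([12 * np.cos(t), 12 * np.sin(t)])
print(f"concentric circles r=10,12 px: HD "
      f"{M.hausdorff_mm(c10, c12, (1.5, 1.5)):.2f} mm, MSD "
      f"{M.mean_surface_distance_mm(c10, c12, (1.5, 1.5)):.2f} mm (analytic 3.0)")

# ICC(2,k) with variance components planted for an expected value of 0.9
rng = np.random.default_rng(3)
truth = rng.normal(0, 1, 100)
ratings = truth[:, None] + rng.normal(0, 1 / np.sqrt(3), (100, 3))
icc, lo, hi = M.icc_average_raters(ratings)
print(f"ICC(2,k) of simulated raters: {icc:.3f}  (95% CI {lo:.3f}-{hi:.3f}; "
      f"planted 0.9)")
# Expected: ring Dice < disk Dice for the identical shift; HD and MSD match
# the 3.0 mm analytic gap; the ICC CI covers the planted 0.9.
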