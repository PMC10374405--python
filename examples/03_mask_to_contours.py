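"""Fit smooth epi-/endocardial contours to a 3-class segmentation mask.

The pipeline traces region boundaries, keeps Teh-Chin dominant points,
filters spurious candidate regions by roundness and area, repairs C-shaped
cavities with their convex hull, and resamples with a periodic B-spline.
The same run with stages disabled shows what each stage buys.
"""

import warnings

import numpy as np

warnings.filterwarnings("ignore")

from cardiomapseg import contour_fit as CF
from cardiomapseg import geometry as G
from cardiomapseg.harness import corrupt_mask
from cardiomapseg.metrics import hausdorff_mm

# clean annulus truth
epi = G.ellipse_contour((32, 32), 15, 13.5, 0.4, 180)
endo = G.ellipse_contour((32, 32), 10, 9, 0.4, 180)
mask = G.contours_to_mask(epi, endo, (64, 64))

# corrupt it the way an imperfect segmenter would: a spurious blob and a
# C-shaped cavity
corrupted = corrupt_mask(mask, np.random.default_rng(5),
                         blob_probability=1.0, cshape_probability=1.0)

for name, stages in [
    ("no post-processing", CF.PipelineStages(False, False, False)),
    ("+ interpolation", CF.PipelineStages(True, False, False)),
    ("+ filtering", CF.PipelineStages(True, True, False)),
    ("+ hull correction", CF.PipelineStages(True, True, True)),
]:
    fitted = CF.fit_contours(corrupted, stages=stages)
    hd = max(hausdorff_mm(fitted.epi, epi), hausdorff_mm(fitted.endo, endo))
    print(f"{name:22s} worst-contour HD {hd:6.2f} mm")
# Expected: HD drops as stages are enabled — filtering removes the blob's
# contribution, hull correction closes the C-shaped cavity; the full
# pipeline lands near the rasterization floor (~1-2 mm at 1.5 mm pixels).
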