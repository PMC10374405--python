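"""Generate a cohort of synthetic mapping subjects and write it to disk.

Each case has three short-axis slices (basal, midventricular, apical) with
analytic epi-/endocardial truth contours, weighted stacks, and fitted T1/T2
maps; apical anatomy is drawn smaller, matching how real apical slices show
the smallest myocardial cross-section.
"""

import tempfile
from pathlib import Path

from cardiomapseg import io, phantom, training

cases = phantom.generate_phantom_cohort(5, seed=42)
for sl in cases[0].slices:
    g = sl.geometry
    print(f"{g.slice_position:15s} epi radius {g.epi_radius:5.1f} px, "
          f"wall {g.epi_radius - g.endo_radius:4.1f} px, "
          f"myocardium pixels {(sl.mask.labels == 2).sum()}")

split = training.split_cases([c.case_id for c in cases], (0.6, 0.2, 0.2), seed=0)
out = Path(tempfile.mkdtemp()) / "dataset"
manifest = io.write_dataset(out, cases, split.assignment)
print(f"\nwrote {len(manifest)} map images to {out}")
print(manifest.groupby(["split", "map_kind"]).size())
# Expected: 5 cases x 3 slices x 2 maps = 30 images; each case's images all
# share one split partition (case-level splitting, no leakage).
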