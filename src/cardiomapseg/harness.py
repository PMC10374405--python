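"""Reproducible ablation harnesses at phantom scale.

Two experiment families:

* post-processing ablation — corrupt ground-truth masks the way an imperfect
  segmenter does (spurious disjoint blobs, C-shaped cavities from a too-thin
  myocardium) and measure mean Hausdorff distance against the exact truth
  contours while the pipeline stages are enabled cumulatively:
  none -> +interpolation -> +filtering -> +hull correction;
* architecture comparison — parameter counts and (optionally) short
  trainings of two presets on the same phantom data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .contour_fit import FitConfig, PipelineStages, fit_contours
from .geometry import CAVITY, MYOCARDIUM, ContourPointSet, SegmentationMask
from .metrics import hausdorff_mm
from .network import ModelConfig, build_model

#: cumulative stage settings in the order the stages were introduced
ABLATION_STEPS = (
    ("no post-processing", PipelineStages(interpolate=False, filter=False, hull_correct=False)),
    ("+ interpolation", PipelineStages(interpolate=True, filter=False, hull_correct=False)),
    ("+ size/roundness filtering", PipelineStages(interpolate=True, filter=True, hull_correct=False)),
    ("+ convex-hull correction", PipelineStages(interpolate=True, filter=True, hull_correct=True)),
)


def corrupt_mask(
    mask: SegmentationMask,
    rng: np.random.Generator,
    blob_probability: float = 0.7,
    cshape_probability: float = 0.5,
) -> SegmentationMask:
    """Emulate typical segmentation failures on a clean mask.

    With ``blob_probability`` adds a small spurious blob of each foreground
    class away from the heart; with ``cshape_probability`` opens the cavity
    into a C shape by overwriting a wedge of it with myocardium.
    """
    labels = mask.labels.copy()
    h, w = labels.shape
    ys, xs = np.nonzero(labels == CAVITY)
    if len(ys) == 0:
        return SegmentationMask(labels, mask.pixel_spacing_mm)
    cy, cx = ys.mean(), xs.mean()

    if rng.random() < cshape_probability:
        ang = rng.uniform(0, 2 * np.pi)
        half = rng.uniform(0.35, 0.6)
        theta = np.arctan2(ys - cy, xs - cx)
        diff = np.angle(np.exp(1j * (theta - ang)))
        wedge = np.abs(diff) < half
        labels[ys[wedge], xs[wedge]] = MYOCARDIUM

    for cls in (CAVITY, MYOCARDIUM):
        if rng.random() < blob_probability:
            for _ in range(50):
                by = rng.integers(3, h - 3)
                bx = rng.integers(3, w - 3)
                if labels[by - 3:by + 4, bx - 3:bx + 4].max() == 0:
                    r = int(rng.integers(1, 3))
                    yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
                    disk = yy * yy + xx * xx <= r * r
                    labels[by - r:by + r + 1, bx - r:bx + r + 1][disk] = cls
                    break
    return SegmentationMask(labels, mask.pixel_spacing_mm)


def _hd_against_truth(mask, epi_truth, endo_truth, config, stages) -> float:
    fitted = fit_contours(mask, config, stages)
    spacing = mask.pixel_spacing_mm
    return max(
        hausdorff_mm(fitted.epi, epi_truth, spacing),
        hausdorff_mm(fitted.endo, endo_truth, spacing),
    )


def postprocessing_ablation(
    items: list[tuple[SegmentationMask, ContourPointSet, ContourPointSet]],
    config: FitConfig | None = None,
) -> pd.DataFrame:
    """Mean HD per cumulative post-processing step.

    ``items`` are (predicted-or-corrupted mask, truth epi, truth endo)
    triples. Returns one row per step, in introduction order.
    """
    config = config or FitConfig()
    rows = []
    for name, stages in ABLATION_STEPS:
        hds = [
            _hd_against_truth(mask, epi, endo, config, stages)
            for mask, epi, endo in items
        ]
        rows.append({"step": name, "mean_hd_mm": float(np.mean(hds)),
                     "median_hd_mm": float(np.median(hds)), "n": len(hds)})
    return pd.DataFrame(rows)


def ablation_items_from_cases(
    cases, seed: int = 0, n_items: int | None = None, **corrupt_kwargs
) -> list[tuple[SegmentationMask, ContourPointSet, ContourPointSet]]:
    """Build ablation inputs from phantom cases: corrupted truth masks paired
    with the exact analytic truth contours."""
    rng = np.random.default_rng(seed)
    items = []
    for case in cases:
        for sl in case.slices:
            if sl.geometry.gap_angle > 0:
                continue  # keep truth contours convex for this experiment
            corrupted = corrupt_mask(sl.mask, rng, **corrupt_kwargs)
            items.append((corrupted, sl.epi_contour, sl.endo_contour))
    if n_items is not None:
        items = items[:n_items]
    return items


def architecture_comparison(presets=("original-unet", "resnet50-like"),
                            input_size=(224, 224)) -> pd.DataFrame:
    """Parameter counts of the architecture presets (the size column of an
    architecture ablation table)."""
    rows = []
    for kind in presets:
        model = build_model(ModelConfig(encoder_kind=kind, input_size=input_size))
        rows.append({"preset": kind, "parameters": model.num_params()})
    return pd.DataFrame(rows)
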