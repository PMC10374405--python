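"""Agreement metrics and mapping-value statistics.

Overlap metrics (Dice, IoU) are computed on mask regions; the endocardial
score on the disk-like cavity region, the epicardial score on the ring-like
myocardium region — the ring topology makes the epicardial Dice strictly more
sensitive to the same boundary error, which is why the two are reported
separately. Distance metrics (Hausdorff, mean surface distance) are computed
between contour point sets, scaled to millimetres per axis; contours are
expected to be spline-resampled so the point sets densely sample the curves.

Empty-region comparisons are flagged NaN, never silently coerced to 0 or 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .contour_fit import FitConfig, PipelineStages, fit_contours
from .geometry import ContourPointSet, SegmentationMask, contours_to_mask, mask_class_region

_REGION_OF = {"endocardial": "cavity", "epicardial": "myocardium"}


@dataclass
class MetricsRecord:
    """Per-sample agreement between one prediction and one reference."""

    sample_id: str
    comparison: str
    dice_endo: float
    dice_epi: float
    iou_endo: float
    iou_epi: float
    hd_mm: float
    msd_mm: float
    slice_position: str = ""
    map_kind: str = ""


@dataclass
class MappingValueStats:
    median_ms: float
    iqr_ms: float
    n_pixels: int


def _region_pair(mask_a: SegmentationMask, mask_b: SegmentationMask, region: str):
    if region not in _REGION_OF:
        raise ValueError(f"region must be 'endocardial' or 'epicardial', got {region!r}")
    if mask_a.shape != mask_b.shape:
        raise ValueError("masks must share a shape")
    target = _REGION_OF[region]
    return mask_class_region(mask_a, target), mask_class_region(mask_b, target)


def dice(mask_a: SegmentationMask, mask_b: SegmentationMask, region: str) -> float:
    """Dice overlap 2|A∩B|/(|A|+|B|) on the named region.

    NaN (with a warning) when both regions are empty.
    """
    a, b = _region_pair(mask_a, mask_b, region)
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        warnings.warn(f"dice undefined: both {region} regions are empty")
        return float("nan")
    return 2.0 * int(np.sum(a & b)) / denom


def iou(mask_a: SegmentationMask, mask_b: SegmentationMask, region: str) -> float:
    """Jaccard index |A∩B|/|A∪B| on the named region; NaN if both empty."""
    a, b = _region_pair(mask_a, mask_b, region)
    union = int(np.sum(a | b))
    if union == 0:
        warnings.warn(f"iou undefined: both {region} regions are empty")
        return float("nan")
    return int(np.sum(a & b)) / union


def _scaled_points(contour: ContourPointSet | np.ndarray,
                   pixel_spacing: tuple[float, float] | float) -> np.ndarray:
    pts = contour.points if isinstance(contour, ContourPointSet) else np.asarray(contour, float)
    if np.isscalar(pixel_spacing):
        scale = np.array([pixel_spacing, pixel_spacing], dtype=float)
    else:
        # spacing is (row, col) mm; points are (x=col, y=row)
        scale = np.array([pixel_spacing[1], pixel_spacing[0]], dtype=float)
    return pts * scale[None, :]


def _directed_nearest(a_mm: np.ndarray, b_mm: np.ndarray) -> np.ndarray:
    d, _ = cKDTree(b_mm).query(a_mm)
    return d


def hausdorff_mm(
    contour_a: ContourPointSet | np.ndarray,
    contour_b: ContourPointSet | np.ndarray,
    pixel_spacing: tuple[float, float] | float = (1.5, 1.5),
) -> float:
    """Symmetric (max) Hausdorff distance between two contour point sets, mm."""
    a = _scaled_points(contour_a, pixel_spacing)
    b = _scaled_points(contour_b, pixel_spacing)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("cannot compute Hausdorff distance of an empty point set")
    return float(max(_directed_nearest(a, b).max(), _directed_nearest(b, a).max()))


def mean_surface_distance_mm(
    contour_a: ContourPointSet | np.ndarray,
    contour_b: ContourPointSet | np.ndarray,
    pixel_spacing: tuple[float, float] | float = (1.5, 1.5),
) -> float:
    """Symmetric mean nearest-point distance (average of both directions), mm."""
    a = _scaled_points(contour_a, pixel_spacing)
    b = _scaled_points(contour_b, pixel_spacing)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("cannot compute surface distance of an empty point set")
    return float(0.5 * (_directed_nearest(a, b).mean() + _directed_nearest(b, a).mean()))


def myocardial_value_stats(
    map_image,
    mask: SegmentationMask,
) -> MappingValueStats:
    """Median and IQR of map values over the myocardium (class 2) pixels.

    ``map_image`` may be a :class:`~cardiomapseg.phantom.MapImage` or a bare
    2D array. NaN map pixels (failed fits) are excluded.
    """
    data = getattr(map_image, "data", map_image)
    data = np.asarray(data, dtype=float)
    region = mask_class_region(mask, "myocardium")
    if data.shape != region.shape:
        raise ValueError("map and mask must share a shape")
    values = data[region]
    values = values[np.isfinite(values)]
    if len(values) == 0:
        warnings.warn("no myocardium pixels with valid map values; stats undefined")
        return MappingValueStats(float("nan"), float("nan"), 0)
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return MappingValueStats(float(med), float(q3 - q1), int(len(values)))


def icc_average_raters(ratings: np.ndarray) -> tuple[float, float, float]:
    """Two-way random-effects, average-measures ICC — ICC(2,k) — with 95% CI.

    ``ratings`` is a (samples x raters) matrix with no missing cells.
    Returns (icc, ci_low, ci_high). Constant ratings are degenerate (NaN).
    """
    ratings = np.asarray(ratings, dtype=float)
    if ratings.ndim != 2 or ratings.shape[0] < 5 or ratings.shape[1] < 2:
        raise ValueError("need a (>=5 samples) x (>=2 raters) ratings matrix")
    if not np.all(np.isfinite(ratings)):
        raise ValueError("ratings matrix must have no missing cells")
    if np.ptp(ratings) == 0:
        warnings.warn("constant ratings: ICC is degenerate")
        return float("nan"), float("nan"), float("nan")
    import pingouin as pg  # heavy import, deferred

    n, k = ratings.shape
    frame = pd.DataFrame(
        {
            "targets": np.repeat(np.arange(n), k),
            "raters": np.tile(np.arange(k), n),
            "ratings": ratings.ravel(),
        }
    )
    table = pg.intraclass_corr(
        data=frame, targets="targets", raters="raters", ratings="ratings"
    ).set_index("Type")
    # two-way random, average measures: labelled ICC2k or ICC(A,k) depending
    # on whether Shrout-Fleiss or McGraw-Wong naming is in use
    label = "ICC2k" if "ICC2k" in table.index else "ICC(A,k)"
    row = table.loc[label]
    ci_col = "CI95%" if "CI95%" in table.columns else "CI95"
    ci_low, ci_high = (float(v) for v in row[ci_col])
    return float(row["ICC"]), ci_low, ci_high


def best_achievable_hd(
    epi: ContourPointSet,
    endo: ContourPointSet,
    shape: tuple[int, int],
    pixel_spacing: tuple[float, float] = (1.5, 1.5),
    config: FitConfig | None = None,
) -> dict[str, float]:
    """Rasterize->fit->Hausdorff round trip of ground-truth contours.

    Converting exact contours to a mask loses sub-pixel information; fitting
    contours back and measuring the Hausdorff distance to the originals gives
    the accuracy floor no model evaluated through this pipeline can beat.
    Returns per-structure distances in mm.
    """
    mask = contours_to_mask(epi, endo, shape, pixel_spacing)
    fitted = fit_contours(mask, config)
    return {
        "epi": hausdorff_mm(fitted.epi, epi, pixel_spacing),
        "endo": hausdorff_mm(fitted.endo, endo, pixel_spacing),
    }


def records_to_frame(records: list[MetricsRecord]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in records])


def aggregate_report(
    records: list[MetricsRecord] | pd.DataFrame,
    group_by: list[str] | str = ("slice_position",),
) -> pd.DataFrame:
    """Mean and median of every metric, grouped (e.g. by slice or map kind).

    The output has one row per group — the shape of a per-slice / per-map
    results table; any external statistics package can consume it.
    """
    frame = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    if isinstance(group_by, str):
        group_by = [group_by]
    group_by = list(group_by)
    value_cols = [
        c for c in ("dice_endo", "dice_epi", "iou_endo", "iou_epi", "hd_mm", "msd_mm")
        if c in frame.columns
    ]
    grouped = frame.groupby(group_by, dropna=False)[value_cols]
    out = grouped.agg(["mean", "median", "count"])
    out.columns = ["_".join(c) for c in out.columns]
    return out.reset_index()


def compare_masks(
    pred: SegmentationMask,
    truth: SegmentationMask,
    sample_id: str = "",
    comparison: str = "model-vs-truth",
    slice_position: str = "",
    map_kind: str = "",
    fit_config: FitConfig | None = None,
    truth_contours: tuple[ContourPointSet, ContourPointSet] | None = None,
) -> MetricsRecord:
    """Full agreement record between a predicted and a reference mask.

    Overlap metrics come from the masks directly; distance metrics from
    contours fitted on the predicted mask against the reference contours
    (fitted from the truth mask unless exact truth contours are given).
    """
    spacing = truth.pixel_spacing_mm
    fitted_pred = fit_contours(pred, fit_config)
    if truth_contours is None:
        fitted_truth = fit_contours(truth, fit_config)
        epi_ref, endo_ref = fitted_truth.epi, fitted_truth.endo
    else:
        epi_ref, endo_ref = truth_contours
    hd = max(
        hausdorff_mm(fitted_pred.epi, epi_ref, spacing),
        hausdorff_mm(fitted_pred.endo, endo_ref, spacing),
    )
    msd = 0.5 * (
        mean_surface_distance_mm(fitted_pred.epi, epi_ref, spacing)
        + mean_surface_distance_mm(fitted_pred.endo, endo_ref, spacing)
    )
    return MetricsRecord(
        sample_id=sample_id,
        comparison=comparison,
        dice_endo=dice(pred, truth, "endocardial"),
        dice_epi=dice(pred, truth, "epicardial"),
        iou_endo=iou(pred, truth, "endocardial"),
        iou_epi=iou(pred, truth, "epicardial"),
        hd_mm=hd,
        msd_mm=msd,
        slice_position=slice_position,
        map_kind=map_kind,
    )
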