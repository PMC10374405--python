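"""Conversions between ordered contour point sets and 3-class segmentation masks.

The package-wide raster convention (used for ground-truth generation, training
targets and evaluation alike):

* coordinates are 0-based ``(x=column, y=row)`` in pixel units;
* pixel centers sit at integer coordinates;
* a pixel belongs to a polygon iff its center lies inside it (even-odd rule);
* a center exactly on a polygon edge counts as inside (deterministic ties).

Class labels: 0 = background, 1 = LV cavity (blood pool enclosed by the
endocardial contour), 2 = myocardium (between endo- and epicardial contour).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import shapely

BACKGROUND = 0
CAVITY = 1
MYOCARDIUM = 2

#: region selectors accepted by :func:`mask_class_region`
REGION_TARGETS = ("cavity", "myocardium", "epicardial-union")


class GeometryError(ValueError):
    """Raised for invalid contour/mask combinations."""


def shoelace_area(points: np.ndarray) -> float:
    """Signed area of a closed polygon given ordered vertices (x, y)."""
    pts = np.asarray(points, dtype=float)
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


@dataclass
class ContourPointSet:
    """Ordered set of real-valued (x, y) pixel coordinates describing a contour.

    On construction consecutive duplicate points are dropped and the
    orientation is normalized counter-clockwise (positive shoelace area).
    """

    points: np.ndarray
    closed: bool = True

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float).reshape(-1, 2)
        if len(pts) >= 2:
            keep = np.ones(len(pts), dtype=bool)
            keep[1:] = np.any(np.abs(np.diff(pts, axis=0)) > 1e-12, axis=1)
            pts = pts[keep]
            # drop a trailing point identical to the first
            if len(pts) > 1 and np.allclose(pts[0], pts[-1]):
                pts = pts[:-1]
        if len(pts) < 3:
            raise GeometryError(
                f"a contour needs at least 3 distinct points, got {len(pts)}"
            )
        if self.closed and shoelace_area(pts) < 0:
            pts = pts[::-1].copy()
        self.points = pts

    def __len__(self) -> int:
        return len(self.points)

    @property
    def area(self) -> float:
        """Enclosed (unsigned) area in px^2, shoelace formula."""
        return abs(shoelace_area(self.points))

    def bounding_box_aspect(self) -> float:
        """Axis-aligned bounding-box aspect ratio, long side / short side."""
        spans = self.points.max(axis=0) - self.points.min(axis=0)
        short = max(float(spans.min()), 1e-9)
        return float(spans.max()) / short

    def to_polygon(self) -> shapely.Polygon:
        return shapely.Polygon(self.points)

    @classmethod
    def from_json(cls, payload: str | dict, key: str | None = None) -> "ContourPointSet":
        data = json.loads(payload) if isinstance(payload, str) else payload
        if key is not None:
            data = data[key]
        return cls(np.asarray(data, dtype=float))

    def to_list(self) -> list[list[float]]:
        return [[float(x), float(y)] for x, y in self.points]


@dataclass
class SegmentationMask:
    """Per-pixel 3-class label grid with physical pixel spacing (row, col) in mm."""

    labels: np.ndarray
    pixel_spacing_mm: tuple[float, float] = (1.5, 1.5)

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 2:
            raise GeometryError("mask labels must be a 2D grid")
        if not np.isin(labels, (BACKGROUND, CAVITY, MYOCARDIUM)).all():
            raise GeometryError("mask labels must be in {0, 1, 2}")
        self.labels = labels.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape


def rasterize_polygon(contour: ContourPointSet, shape: tuple[int, int]) -> np.ndarray:
    """Binary grid of pixels whose centers lie inside (or on) the contour."""
    rows, cols = shape
    poly = contour.to_polygon()
    xs, ys = np.meshgrid(np.arange(cols, dtype=float), np.arange(rows, dtype=float))
    # intersects == covers for points: the boundary counts as inside
    inside = shapely.intersects_xy(poly, xs.ravel(), ys.ravel())
    return inside.reshape(rows, cols)


def contours_to_mask(
    epi: ContourPointSet,
    endo: ContourPointSet,
    shape: tuple[int, int],
    pixel_spacing_mm: tuple[float, float] = (1.5, 1.5),
) -> SegmentationMask:
    """Rasterize an epi/endo contour pair into a 3-class mask.

    Pixel class is 1 (cavity) if the center is inside the endocardial polygon,
    else 2 (myocardium) if inside the epicardial polygon, else 0.

    Raises
    ------
    GeometryError
        If the rasterized endocardial region is not strictly inside the
        epicardial region, or the pair leaves no myocardium pixels.
    """
    endo_in = rasterize_polygon(endo, shape)
    epi_in = rasterize_polygon(epi, shape)
    escaped = int(np.sum(endo_in & ~epi_in))
    if escaped:
        raise GeometryError(
            f"endocardial region is not contained in the epicardial region "
            f"({escaped} cavity pixels fall outside the epicardial polygon)"
        )
    labels = np.zeros(shape, dtype=np.uint8)
    labels[epi_in] = MYOCARDIUM
    labels[endo_in] = CAVITY
    if not np.any(labels == MYOCARDIUM):
        raise GeometryError(
            "degenerate contour pair: rasterization produced no myocardium pixels"
        )
    return SegmentationMask(labels, pixel_spacing_mm)


def mask_class_region(mask: SegmentationMask, target: str) -> np.ndarray:
    """Binary region for a named target.

    ``cavity`` selects class 1, ``myocardium`` class 2 and
    ``epicardial-union`` the filled epicardial disk (classes 1 and 2 merged) —
    the region whose outer boundary is the epicardial contour.
    """
    labels = mask.labels
    if target == "cavity":
        return labels == CAVITY
    if target == "myocardium":
        return labels == MYOCARDIUM
    if target == "epicardial-union":
        return labels != BACKGROUND
    raise GeometryError(f"unknown region target {target!r}; expected one of {REGION_TARGETS}")


def ellipse_contour(
    center: tuple[float, float],
    semi_x: float,
    semi_y: float,
    rotation: float = 0.0,
    n_points: int = 180,
) -> ContourPointSet:
    """Dense counter-clockwise point sampling of an analytic (rotated) ellipse."""
    theta = np.linspace(0.0, 2.0 * np.pi, n_points, endpoint=False)
    x = semi_x * np.cos(theta)
    y = semi_y * np.sin(theta)
    c, s = np.cos(rotation), np.sin(rotation)
    pts = np.column_stack([center[0] + c * x - s * y, center[1] + s * x + c * y])
    return ContourPointSet(pts)


def contours_to_json(epi: ContourPointSet, endo: ContourPointSet) -> str:
    """Serialize an epi/endo pair to the on-disk JSON contour format."""
    return json.dumps({"epi": epi.to_list(), "endo": endo.to_list()})


def contours_from_json(payload: str | dict) -> tuple[ContourPointSet, ContourPointSet]:
    data = json.loads(payload) if isinstance(payload, str) else payload
    return (
        ContourPointSet(np.asarray(data["epi"], dtype=float)),
        ContourPointSet(np.asarray(data["endo"], dtype=float)),
    )
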