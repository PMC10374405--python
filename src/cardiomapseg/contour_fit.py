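"""Deterministic mask-to-contour fitting.

A predicted 3-class mask is turned into smooth epi- and endocardial contours
in four stages:

1. trace the closed pixel boundary of every connected component of the target
   region (cavity for the endocardial contour, the filled epicardial disk —
   classes 1+2 — for the epicardial one);
2. reduce each boundary to its dominant points with the Teh-Chin
   region-of-support / k-cosine algorithm;
3. if several candidate contours exist, discard "too elongated" ones
   (axis-aligned bounding-box aspect ratio above 3) and keep the largest
   remaining area;
4. if the contour is C-shaped — its convex hull exceeds its own area by more
   than a configurable fraction — replace it with its convex hull; finally
   resample it with a periodic B-spline so distance metrics are computed on a
   dense smooth curve rather than sparse polygon vertices.

Stages 3 and 4 only act when their trigger condition holds; every stage can
also be disabled outright, which powers the post-processing ablation harness.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import interpolate
from scipy.spatial import ConvexHull
from skimage import measure

from .geometry import (
    ContourPointSet,
    SegmentationMask,
    mask_class_region,
    shoelace_area,
)


class MissingRegionError(ValueError):
    """A structure required for contour fitting is absent from the mask."""

    def __init__(self, structure: str):
        self.structure = structure
        super().__init__(f"mask contains no {structure} region to fit a contour on")


@dataclass(frozen=True)
class FitConfig:
    """Tunables of the mask-to-contour pipeline."""

    elongation_limit: float = 3.0  # max bounding-box long/short ratio
    hull_area_ratio_threshold: float = 0.05  # relative hull-area excess trigger
    spline_degree: int = 3
    spline_samples: int = 200
    collinearity_tolerance: float = 0.05  # k-cosine closeness to -1 treated as straight

    def __post_init__(self) -> None:
        if self.elongation_limit <= 1:
            raise ValueError("elongation_limit must exceed 1")
        if not (0 < self.hull_area_ratio_threshold < 1):
            raise ValueError("hull_area_ratio_threshold must lie in (0, 1)")


@dataclass(frozen=True)
class PipelineStages:
    """Switches for the conditional stages (all on by default)."""

    interpolate: bool = True
    filter: bool = True
    hull_correct: bool = True


@dataclass
class FittedContours:
    epi: ContourPointSet
    endo: ContourPointSet
    warnings: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# boundary tracing
# ---------------------------------------------------------------------------

# Moore neighborhood in clockwise order (image coordinates, y down),
# starting east, as (dx, dy)
_NEIGHBORS = [(1, 0), (1, 1), (0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1), (1, -1)]
# after stepping from c to its neighbor at direction d, the new backtrack is
# the neighbor of c checked just before d; expressed as a direction from the
# new pixel it is:
_BACKTRACK = [6, 6, 0, 0, 2, 2, 4, 4]


def _trace_loop(region: np.ndarray, start: tuple[int, int]) -> np.ndarray:
    """Moore-neighbor boundary trace of one 8-connected component.

    ``region`` is a binary grid, ``start`` the topmost-then-leftmost pixel of
    the component as (x, y). Returns ordered boundary pixel coordinates
    (x, y); the trace stops when the first transition repeats (so the start
    point is not duplicated at the end).
    """
    h, w = region.shape

    def filled(x: int, y: int) -> bool:
        return 0 <= x < w and 0 <= y < h and bool(region[y, x])

    points = [start]
    current = start
    backtrack_dir = 4  # the pixel west of the start is outside the region
    first_transition: tuple[tuple[int, int], int] | None = None
    limit = 4 * h * w + 8
    for _ in range(limit):
        found_dir = None
        for step in range(1, 9):
            d = (backtrack_dir + step) % 8
            nx, ny = current[0] + _NEIGHBORS[d][0], current[1] + _NEIGHBORS[d][1]
            if filled(nx, ny):
                found_dir = d
                break
        if found_dir is None:  # isolated single pixel
            return np.asarray(points, dtype=float)
        transition = (current, found_dir)
        if first_transition is None:
            first_transition = transition
        elif transition == first_transition:
            break
        current = (nx, ny)
        backtrack_dir = _BACKTRACK[found_dir]
        points.append(current)
    if len(points) > 1 and points[-1] == points[0]:
        points.pop()
    return np.asarray(points, dtype=float)


def extract_boundaries(mask: SegmentationMask, target: str) -> list[np.ndarray]:
    """Ordered closed boundary pixel loops, one per connected component of
    the target region (``cavity``, ``myocardium`` or ``epicardial-union``).

    Returns an empty list for an empty region.
    """
    region = mask_class_region(mask, target)
    labeled = measure.label(region, connectivity=2)
    loops = []
    for lab in range(1, labeled.max() + 1):
        comp = labeled == lab
        ys, xs = np.nonzero(comp)
        order = np.lexsort((xs, ys))  # topmost, then leftmost
        start = (int(xs[order[0]]), int(ys[order[0]]))
        loops.append(_trace_loop(comp, start))
    return loops


# ---------------------------------------------------------------------------
# Teh-Chin dominant points
# ---------------------------------------------------------------------------

def _region_of_support(pts: np.ndarray) -> np.ndarray:
    """Per-point region-of-support size k on a closed curve.

    Support grows while the chord p_{i-k} .. p_{i+k} keeps lengthening and
    the signed perpendicular-distance / chord-length ratio keeps shrinking in
    magnitude (zero distance — locally straight — always extends). This stops
    the support at the nearest real curvature structure, so straight runs get
    wide support and smooth arcs narrow support.
    """
    n = len(pts)
    kmax = max(1, n // 2 - 1)
    ks = np.ones(n, dtype=int)
    for i in range(n):
        prev_l = 0.0
        prev_ratio = 0.0
        k = 1
        accepted = 1
        while k <= kmax:
            a = pts[(i - k) % n]
            b = pts[(i + k) % n]
            chord = b - a
            l = float(np.hypot(*chord))
            if l <= prev_l + 1e-12:
                break
            # signed perpendicular distance of p_i from the chord
            d = (chord[0] * (pts[i][1] - a[1]) - chord[1] * (pts[i][0] - a[0])) / l
            ratio = d / l
            if k > 1 and abs(prev_ratio) > 1e-9:
                if prev_ratio > 0 and ratio > prev_ratio + 1e-12:
                    break
                if prev_ratio < 0 and ratio < prev_ratio - 1e-12:
                    break
            prev_l, prev_ratio = l, ratio
            accepted = k
            k += 1
        ks[i] = accepted
    return ks


def _k_cosine(pts: np.ndarray, ks: np.ndarray) -> np.ndarray:
    """Curvature measure: cosine of the angle between the two support arms.

    -1 on a straight run, 0 at a right-angle corner, toward +1 for spikes.
    """
    n = len(pts)
    cos = np.empty(n)
    for i in range(n):
        k = ks[i]
        a = pts[(i + k) % n] - pts[i]
        b = pts[(i - k) % n] - pts[i]
        na, nb = np.hypot(*a), np.hypot(*b)
        if na < 1e-12 or nb < 1e-12:
            cos[i] = -1.0
            continue
        cos[i] = float(np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0))
    return cos


def dominant_points(loop: np.ndarray, config: FitConfig | None = None) -> ContourPointSet:
    """Teh-Chin dominant-point subset of a closed boundary loop.

    The region of support of each point is determined from chord length and
    perpendicular distance, curvature is measured with the k-cosine, and
    non-maxima (and straight-run points) are suppressed. Ordered and closed.

    A degenerate (collinear) loop collapses to a minimal 3-point contour with
    a warning.
    """
    config = config or FitConfig()
    pts = np.asarray(loop, dtype=float)
    n = len(pts)
    if n < 4:
        raise ValueError("dominant-point detection needs a loop of at least 4 points")
    ks = _region_of_support(pts)
    cos = _k_cosine(pts, ks)

    survives = np.ones(n, dtype=bool)
    # suppress straight runs
    survives[cos <= -1.0 + config.collinearity_tolerance] = False
    # non-maxima suppression within half the region of support
    for i in range(n):
        if not survives[i]:
            continue
        half = max(1, ks[i] // 2)
        for off in range(1, half + 1):
            for j in ((i - off) % n, (i + off) % n):
                if cos[j] > cos[i] + 1e-12:
                    survives[i] = False
                    break
            if not survives[i]:
                break
    idx = np.nonzero(survives)[0]
    if len(idx) >= 2:
        # collapse runs of adjacent survivors, keeping the highest curvature
        groups: list[list[int]] = [[int(idx[0])]]
        for i in idx[1:]:
            if i - groups[-1][-1] <= 1:
                groups[-1].append(int(i))
            else:
                groups.append([int(i)])
        if len(groups) > 1 and (groups[0][0] + n - groups[-1][-1]) <= 1:
            groups[0] = groups.pop() + groups[0]
        idx = np.asarray([max(g, key=lambda j: (cos[j], -j)) for g in groups])
        idx.sort()
    if len(idx) < 3:
        warnings.warn("degenerate boundary loop; returning a minimal 3-point contour")
        uniq = np.unique(pts, axis=0)
        if len(uniq) >= 3:
            fallback = uniq[[0, len(uniq) // 2, len(uniq) - 1]]
        else:
            p = uniq[0]
            fallback = np.vstack([p, p + [0.5, 0.0], p + [0.0, 0.5]])
        return ContourPointSet(fallback)
    return ContourPointSet(pts[idx])


# ---------------------------------------------------------------------------
# candidate filtering / hull correction / spline
# ---------------------------------------------------------------------------

def filter_candidate_contours(
    contours: list[ContourPointSet], config: FitConfig | None = None
) -> ContourPointSet:
    """Pick one contour out of several candidates.

    Candidates whose axis-aligned bounding-box aspect ratio (long/short side)
    exceeds ``elongation_limit`` are discarded; of the remaining ones the
    largest enclosed area wins. If the filter discards everything, the
    largest-area candidate overall is returned with a warning.
    """
    config = config or FitConfig()
    if not contours:
        raise MissingRegionError("candidate")
    round_enough = [c for c in contours if c.bounding_box_aspect() <= config.elongation_limit]
    if not round_enough:
        warnings.warn("all candidate contours exceeded the elongation limit; "
                      "falling back to the largest area")
        round_enough = contours
    return max(round_enough, key=lambda c: c.area)


def convex_hull_correct(
    contour: ContourPointSet, config: FitConfig | None = None
) -> ContourPointSet:
    """Replace a C-shaped contour by its convex hull.

    The correction fires only when the hull's area exceeds the contour's own
    (shoelace) area by more than ``hull_area_ratio_threshold`` of the hull
    area — i.e. when the contour is not closed into a convex-ish ring.
    """
    config = config or FitConfig()
    pts = contour.points
    hull = ConvexHull(pts)
    hull_area = float(hull.volume)  # 2D: "volume" is the area
    if hull_area <= 0:
        return contour
    ratio = (hull_area - contour.area) / hull_area
    if ratio > config.hull_area_ratio_threshold:
        return ContourPointSet(pts[hull.vertices])
    return contour


def spline_interpolate(
    contour: ContourPointSet, config: FitConfig | None = None
) -> ContourPointSet:
    """Resample a closed contour with a periodic interpolating B-spline.

    The spline passes through the input points and is sampled uniformly in
    parameter between them (``spline_samples`` output points). With fewer
    points than a cubic needs, the degree is lowered automatically.
    """
    config = config or FitConfig()
    pts = contour.points
    n = len(pts)
    degree = min(config.spline_degree, n - 1)
    if degree < config.spline_degree:
        warnings.warn(f"only {n} contour points; lowering spline degree to {degree}")
    closed = np.vstack([pts, pts[:1]])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # splprep chatters about knot repeats
        tck, _ = interpolate.splprep([closed[:, 0], closed[:, 1]], s=0, per=1, k=degree)
    u = np.linspace(0.0, 1.0, max(config.spline_samples, n), endpoint=False)
    x, y = interpolate.splev(u, tck)
    return ContourPointSet(np.column_stack([x, y]))


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def _fit_structure(
    mask: SegmentationMask,
    target: str,
    structure: str,
    config: FitConfig,
    stages: PipelineStages,
    notes: list[str],
) -> ContourPointSet:
    loops = extract_boundaries(mask, target)
    loops = [lp for lp in loops if len(lp) >= 4]
    if not loops:
        raise MissingRegionError(structure)
    candidates = [dominant_points(lp, config) for lp in loops]
    if len(candidates) == 1:
        contour = candidates[0]
    elif stages.filter:
        contour = filter_candidate_contours(candidates, config)
    else:
        # unfiltered: the prediction genuinely proposes several contours;
        # represent it as the union of their points
        notes.append(f"{structure}: {len(candidates)} unfiltered candidate contours merged")
        if stages.interpolate:
            # tiny speck contours are left polygonal: an interpolating spline
            # through a handful of pixel corners only overshoots them
            candidates = [
                spline_interpolate(c, config) if len(c) >= 8 else c
                for c in candidates
            ]
        merged = np.vstack([c.points for c in candidates])
        return ContourPointSet(merged, closed=False)
    if stages.hull_correct:
        corrected = convex_hull_correct(contour, config)
        if corrected is not contour:
            notes.append(f"{structure}: C-shaped contour replaced by its convex hull")
            contour = corrected
    if stages.interpolate:
        contour = spline_interpolate(contour, config)
    return contour


def fit_contours(
    mask: SegmentationMask,
    config: FitConfig | None = None,
    stages: PipelineStages | None = None,
) -> FittedContours:
    """Fit epi- and endocardial contours to a 3-class segmentation mask.

    The epicardial contour is fitted on the filled epicardial disk (classes
    1+2 merged) so the outer boundary of the ring is isolated; the
    endocardial contour on the cavity region. Filtering and hull correction
    run only when their trigger conditions hold.

    Raises :class:`MissingRegionError` naming the missing structure when the
    mask has no cavity or no epicardial region.
    """
    config = config or FitConfig()
    stages = stages or PipelineStages()
    notes: list[str] = []
    epi = _fit_structure(mask, "epicardial-union", "epicardial", config, stages, notes)
    endo = _fit_structure(mask, "cavity", "endocardial", config, stages, notes)
    return FittedContours(epi=epi, endo=endo, warnings=notes)
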