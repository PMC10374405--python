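"""Synthetic short-axis cardiac mapping phantoms with known ground truth.

A phantom case emulates one subject of a clinical T1/T2 mapping study:
three short-axis slices (basal, midventricular, apical), each an annular
myocardium around an elliptical LV blood pool. For every slice the generator
produces

* analytic ground-truth epi-/endocardial contours,
* the 3-class mask rasterized from those contours (so contours and images are
  consistent by construction),
* a stack of 8 T1-weighted images following the inversion-recovery signal
  model ``S(t) = A - B * exp(-t / T1)`` (signed recovery, no magnitude
  operation),
* a stack of 3 T2-weighted images following mono-exponential decay
  ``S(TE) = S0 * exp(-TE / T2)`` at echo times 0/25/55 ms,
* per-pixel fitted T1 and T2 parametric maps recovered from the (noisy)
  weighted stacks, which is exactly how scanner software builds the maps.

Apical slices are drawn smaller than basal ones (scale 0.5-0.7), reproducing
the feature that makes apical segmentation the hardest; an optional gap angle
thins the myocardium to zero over a sector, producing the C-shaped cavity
regions that the contour post-processing has to repair.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .geometry import (
    CAVITY,
    MYOCARDIUM,
    ContourPointSet,
    SegmentationMask,
    contours_to_mask,
    ellipse_contour,
)

SLICE_POSITIONS = ("basal", "midventricular", "apical")

#: MOLLI-like spread of 8 inversion times (ms); the count is the protocol's,
#: the values are configurable defaults.
DEFAULT_INVERSION_TIMES_MS = (100.0, 180.0, 260.0, 1100.0, 1180.0, 1900.0, 2700.0, 3500.0)
#: T2-prepared echo times (ms) of the mapping protocol.
DEFAULT_ECHO_TIMES_MS = (0.0, 25.0, 55.0)

_TISSUE_INDEX = {"background": 0, "blood": 1, "myocardium": 2}


class PhantomError(ValueError):
    """Raised for invalid phantom configuration or inputs."""


@dataclass(frozen=True)
class TissueParams:
    """Relaxation times (ms) and signal amplitudes per tissue class.

    Index order matches mask classes: (background, blood pool, myocardium).
    Defaults sit at native-mapping magnitudes: myocardial T1 ~ 1000 ms and
    T2 ~ 50 ms, blood with longer T1/T2, low-signal background.
    """

    t1_ms: tuple[float, float, float] = (300.0, 1600.0, 1000.0)
    t2_ms: tuple[float, float, float] = (30.0, 250.0, 50.0)
    proton_amplitude: tuple[float, float, float] = (150.0, 1000.0, 800.0)

    def __post_init__(self) -> None:
        for name in ("t1_ms", "t2_ms"):
            vals = getattr(self, name)
            if any(v <= 0 for v in vals):
                raise PhantomError(f"{name} must be strictly positive, got {vals}")
            srt = sorted(vals)
            for a, b in zip(srt, srt[1:]):
                if (b - a) < 0.1 * a:
                    raise PhantomError(
                        f"{name} tissue values {vals} are not separated by >=10%"
                    )

    def class_map(self, labels: np.ndarray, which: str) -> np.ndarray:
        values = np.asarray(getattr(self, which), dtype=float)
        return values[labels]


@dataclass(frozen=True)
class AcquisitionSpec:
    """Synthetic acquisition protocol: timing, grid and noise."""

    inversion_times_ms: tuple[float, ...] = DEFAULT_INVERSION_TIMES_MS
    echo_times_ms: tuple[float, ...] = DEFAULT_ECHO_TIMES_MS
    pixel_spacing_mm: tuple[float, float] = (1.5, 1.5)
    image_shape: tuple[int, int] = (64, 64)
    noise_sigma: float = 0.02  # additive Gaussian, relative to max amplitude

    def __post_init__(self) -> None:
        ti = np.asarray(self.inversion_times_ms, dtype=float)
        if len(ti) != 8 or not np.all(np.diff(ti) > 0):
            raise PhantomError("inversion_times_ms must be 8 strictly increasing values")
        te = np.asarray(self.echo_times_ms, dtype=float)
        if len(te) != 3 or te[0] != 0 or not np.all(np.diff(te) > 0):
            raise PhantomError("echo_times_ms must be 3 increasing values starting at 0")
        if self.noise_sigma < 0:
            raise PhantomError("noise_sigma must be non-negative")


@dataclass(frozen=True)
class SliceGeometry:
    """Analytic anatomy of one short-axis slice."""

    center: tuple[float, float]
    endo_radius: float
    epi_radius: float
    ellipticity: float = 1.0  # minor/major axis ratio
    rotation: float = 0.0
    gap_angle: float = 0.0  # >0 carves a wedge -> C-shaped cavity
    slice_position: str = "midventricular"

    def __post_init__(self) -> None:
        if not (self.epi_radius > self.endo_radius > 0):
            raise PhantomError("need epi_radius > endo_radius > 0")
        if not (0.0 <= self.gap_angle <= np.pi / 2):
            raise PhantomError("gap_angle must lie in [0, pi/2]")
        if self.slice_position not in SLICE_POSITIONS:
            raise PhantomError(f"unknown slice_position {self.slice_position!r}")

    def epi_contour(self, n_points: int = 180) -> ContourPointSet:
        return ellipse_contour(
            self.center, self.epi_radius, self.epi_radius * self.ellipticity,
            self.rotation, n_points,
        )

    def endo_contour(self, n_points: int = 180) -> ContourPointSet:
        """Endocardial truth contour; a wedge is carved out when gap_angle > 0."""
        if self.gap_angle <= 0:
            return ellipse_contour(
                self.center, self.endo_radius, self.endo_radius * self.ellipticity,
                self.rotation, n_points,
            )
        g = self.gap_angle
        theta = np.linspace(g / 2.0, 2.0 * np.pi - g / 2.0, max(n_points, 90))
        x = self.endo_radius * np.cos(theta)
        y = self.endo_radius * self.ellipticity * np.sin(theta)
        # close through two points near the center: a thin core wedge remains,
        # the region is C-shaped (convex-hull area clearly exceeds region area)
        r0 = 0.1 * self.endo_radius
        x = np.concatenate([x, r0 * np.cos([theta[-1], theta[0]])])
        y = np.concatenate([y, r0 * self.ellipticity * np.sin([theta[-1], theta[0]])])
        c, s = np.cos(self.rotation), np.sin(self.rotation)
        pts = np.column_stack(
            [self.center[0] + c * x - s * y, self.center[1] + s * x + c * y]
        )
        return ContourPointSet(pts)


@dataclass(frozen=True)
class GeometrySamplerConfig:
    """Ranges from which per-case slice anatomy is drawn (units: px, rad)."""

    center_jitter_px: float = 4.0
    basal_epi_radius: tuple[float, float] = (13.0, 17.0)
    wall_thickness: tuple[float, float] = (3.5, 5.5)
    ellipticity: tuple[float, float] = (0.85, 1.0)
    mid_scale: tuple[float, float] = (0.75, 0.9)
    apical_scale: tuple[float, float] = (0.5, 0.7)
    gap_probability: float = 0.05  # chance of a C-shaped (thin-wall) apical cavity
    gap_angle: tuple[float, float] = (0.6, 1.2)
    max_attempts: int = 100


@dataclass
class MapImage:
    """A 2D parametric map (or weighted image) plus acquisition metadata."""

    data: np.ndarray
    pixel_spacing_mm: tuple[float, float]
    slice_position: str
    map_kind: str  # T1map / T2map / T1weighted / T2weighted
    fit_failed: np.ndarray | None = None  # boolean grid where the fit gave no value


@dataclass
class PhantomSlice:
    geometry: SliceGeometry
    epi_contour: ContourPointSet
    endo_contour: ContourPointSet
    mask: SegmentationMask
    true_t1: np.ndarray
    true_t2: np.ndarray
    t1_weighted: np.ndarray  # (8, H, W)
    t2_weighted: np.ndarray  # (3, H, W)
    fitted_t1: MapImage | None = None
    fitted_t2: MapImage | None = None


@dataclass
class PhantomCase:
    case_id: str
    slices: list[PhantomSlice]
    tissue: TissueParams
    acquisition: AcquisitionSpec
    rng_seed: int


# ---------------------------------------------------------------------------
# signal models
# ---------------------------------------------------------------------------

def simulate_t1_stack(
    t1_map: np.ndarray,
    amp_map: np.ndarray,
    b_map: np.ndarray,
    inversion_times: Sequence[float],
) -> np.ndarray:
    """Inversion-recovery stack ``S_k = A - B * exp(-t_k / T1)`` per pixel.

    The signal is kept signed (early inversion times give negative values);
    no magnitude/polarity-restoration step is applied.
    """
    t1 = np.asarray(t1_map, dtype=float)
    a = np.asarray(amp_map, dtype=float)
    b = np.asarray(b_map, dtype=float)
    if not (t1.shape == a.shape == b.shape):
        raise PhantomError("t1_map, amp_map and b_map must share a shape")
    if np.any(t1 <= 0):
        raise PhantomError("T1 must be strictly positive everywhere")
    times = np.asarray(inversion_times, dtype=float)
    if times.ndim != 1 or len(times) != 8:
        raise PhantomError("expected 8 inversion times")
    return a[None] - b[None] * np.exp(-times[:, None, None] / t1[None])


def simulate_t2_stack(
    t2_map: np.ndarray,
    s0_map: np.ndarray,
    echo_times: Sequence[float],
) -> np.ndarray:
    """Mono-exponential decay stack ``S_k = S0 * exp(-TE_k / T2)`` per pixel."""
    t2 = np.asarray(t2_map, dtype=float)
    s0 = np.asarray(s0_map, dtype=float)
    if t2.shape != s0.shape:
        raise PhantomError("t2_map and s0_map must share a shape")
    if np.any(t2 <= 0):
        raise PhantomError("T2 must be strictly positive everywhere")
    times = np.asarray(echo_times, dtype=float)
    if len(times) != 3 or times[0] != 0:
        raise PhantomError("expected 3 echo times with TE1 = 0")
    return s0[None] * np.exp(-times[:, None, None] / t2[None])


# ---------------------------------------------------------------------------
# per-pixel map fitting
# ---------------------------------------------------------------------------

def _gauss_newton_t1(signals: np.ndarray, times: np.ndarray, n_iter: int = 60):
    """Vectorized damped Gauss-Newton fit of (A, B, T1) per pixel.

    ``signals``: (n_times, n_pixels). Returns (A, B, T1, converged).
    """
    n_t, n_px = signals.shape
    a = signals[-1].copy()
    b = a - signals[0]
    b = np.where(np.abs(b) < 1e-12, 1.0, b)
    # initialize T1 from the log-linearized recovery (A0 - S)/B0 = exp(-t/T1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = (a[None, :] - signals) / b[None, :]
        logr = np.where(ratio > 1e-9, np.log(np.maximum(ratio, 1e-300)), np.nan)
    tcol = times[:, None]
    valid = np.isfinite(logr)
    num = np.nansum(np.where(valid, tcol * logr, 0.0), axis=0)
    den = np.sum(np.where(valid, tcol * tcol, 0.0), axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = -den / num
    t1 = np.where(np.isfinite(t1) & (t1 > 1.0) & (t1 < 1e5), t1,
                  float(np.median(times)) / np.log(2.0))
    lam = np.full(n_px, 1e-3)
    prev_cost = np.full(n_px, np.inf)
    for _ in range(n_iter):
        e = np.exp(-times[:, None] / t1[None, :])
        model = a[None] - b[None] * e
        r = model - signals
        cost = np.sum(r * r, axis=0)
        # damp pixels whose cost went up, relax the rest
        worse = cost > prev_cost * (1 + 1e-12)
        lam = np.where(worse, lam * 10.0, np.maximum(lam * 0.3, 1e-12))
        prev_cost = np.minimum(cost, prev_cost)
        # Jacobian columns: d/dA = 1, d/dB = -e, d/dT1 = -B * e * t / T1^2
        j_t1 = -b[None] * e * times[:, None] / (t1 * t1)[None]
        jtj = np.empty((n_px, 3, 3))
        jtj[:, 0, 0] = n_t
        jtj[:, 0, 1] = jtj[:, 1, 0] = -np.sum(e, axis=0)
        jtj[:, 0, 2] = jtj[:, 2, 0] = np.sum(j_t1, axis=0)
        jtj[:, 1, 1] = np.sum(e * e, axis=0)
        jtj[:, 1, 2] = jtj[:, 2, 1] = -np.sum(e * j_t1, axis=0)
        jtj[:, 2, 2] = np.sum(j_t1 * j_t1, axis=0)
        jtr = np.stack(
            [np.sum(r, axis=0), -np.sum(e * r, axis=0), np.sum(j_t1 * r, axis=0)],
            axis=1,
        )
        jtj[:, 0, 0] += lam
        jtj[:, 1, 1] += lam * np.maximum(jtj[:, 1, 1], 1e-6)
        jtj[:, 2, 2] += lam * np.maximum(jtj[:, 2, 2], 1e-6)
        det = np.linalg.det(jtj)
        ok = np.isfinite(det) & (np.abs(det) > 1e-300)
        step = np.zeros((n_px, 3))
        if np.any(ok):
            step[ok] = np.linalg.solve(jtj[ok], -jtr[ok][..., None])[..., 0]
        a += step[:, 0]
        b += step[:, 1]
        dt1 = np.clip(step[:, 2], -0.5 * t1, 0.5 * t1)  # trust region on T1
        t1 = np.clip(t1 + dt1, 1e-2, 1e6)
    e = np.exp(-times[:, None] / t1[None, :])
    resid = np.sum((a[None] - b[None] * e - signals) ** 2, axis=0)
    scale = np.maximum(np.sum(signals * signals, axis=0), 1e-12)
    spread = signals.max(axis=0) - signals.min(axis=0)
    degenerate = spread <= 1e-9 * np.maximum(np.abs(signals).max(axis=0), 1.0)
    converged = (
        np.isfinite(resid)
        & ~degenerate
        & (t1 > 1e-2)
        & (t1 < 1e5)
        & (resid / scale < 0.5)
    )
    return a, b, t1, converged


def fit_t1_map(
    stack: np.ndarray,
    inversion_times: Sequence[float],
    pixel_spacing_mm: tuple[float, float] = (1.5, 1.5),
    slice_position: str = "midventricular",
) -> MapImage:
    """Per-pixel 3-parameter least-squares fit of ``A - B*exp(-t/T1)``.

    Pixels where the fit is unidentifiable (e.g. constant signal) or does not
    converge are set to NaN and flagged in ``fit_failed``.
    """
    stack = np.asarray(stack, dtype=float)
    times = np.asarray(inversion_times, dtype=float)
    if stack.shape[0] != len(times):
        raise PhantomError("stack depth must match the number of inversion times")
    if len(np.unique(times)) < 3:
        raise PhantomError("need at least 3 distinct inversion times to fit 3 parameters")
    h, w = stack.shape[1:]
    signals = stack.reshape(len(times), -1)
    _, _, t1, converged = _gauss_newton_t1(signals, times)
    t1_img = np.where(converged, t1, np.nan).reshape(h, w)
    return MapImage(
        data=t1_img,
        pixel_spacing_mm=pixel_spacing_mm,
        slice_position=slice_position,
        map_kind="T1map",
        fit_failed=(~converged).reshape(h, w),
    )


def fit_t2_map(
    stack: np.ndarray,
    echo_times: Sequence[float],
    pixel_spacing_mm: tuple[float, float] = (1.5, 1.5),
    slice_position: str = "midventricular",
) -> MapImage:
    """Per-pixel 2-parameter fit of ``S0 * exp(-TE/T2)``.

    A log-linear regression gives the closed-form solution (exact for
    noiseless data, near-optimal at the noise levels of interest). Pixels
    with non-positive signal or no measurable decay are flagged.
    """
    stack = np.asarray(stack, dtype=float)
    times = np.asarray(echo_times, dtype=float)
    if stack.shape[0] != len(times):
        raise PhantomError("stack depth must match the number of echo times")
    if len(np.unique(times)) < 2:
        raise PhantomError("need at least 2 distinct echo times")
    h, w = stack.shape[1:]
    signals = stack.reshape(len(times), -1)
    valid = np.all(signals > 0, axis=0)
    logs = np.where(signals > 0, np.log(np.maximum(signals, 1e-300)), 0.0)
    t_mean = times.mean()
    t_var = float(np.sum((times - t_mean) ** 2))
    slope = np.sum((times - t_mean)[:, None] * (logs - logs.mean(axis=0)[None]), axis=0) / t_var
    with np.errstate(divide="ignore", invalid="ignore"):
        t2 = -1.0 / slope
    converged = valid & np.isfinite(t2) & (slope < -1e-12) & (t2 < 1e5)
    t2_img = np.where(converged, t2, np.nan).reshape(h, w)
    return MapImage(
        data=t2_img,
        pixel_spacing_mm=pixel_spacing_mm,
        slice_position=slice_position,
        map_kind="T2map",
        fit_failed=(~converged).reshape(h, w),
    )


# ---------------------------------------------------------------------------
# case generation
# ---------------------------------------------------------------------------

def _sample_slice_geometry(
    rng: np.random.Generator,
    cfg: GeometrySamplerConfig,
    shape: tuple[int, int],
    position: str,
    scale: float,
) -> SliceGeometry:
    cy = shape[0] / 2.0 + rng.uniform(-cfg.center_jitter_px, cfg.center_jitter_px)
    cx = shape[1] / 2.0 + rng.uniform(-cfg.center_jitter_px, cfg.center_jitter_px)
    for _ in range(cfg.max_attempts):
        epi = scale * rng.uniform(*cfg.basal_epi_radius)
        wall = max(scale, 0.7) * rng.uniform(*cfg.wall_thickness)
        endo = epi - wall
        if endo <= 1.5:
            continue
        gap = 0.0
        if position == "apical" and rng.random() < cfg.gap_probability:
            gap = rng.uniform(*cfg.gap_angle)
        return SliceGeometry(
            center=(cx, cy),
            endo_radius=endo,
            epi_radius=epi,
            ellipticity=rng.uniform(*cfg.ellipticity),
            rotation=rng.uniform(0.0, np.pi),
            gap_angle=gap,
            slice_position=position,
        )
    raise PhantomError(
        f"geometry sampler failed to produce a valid {position} slice in "
        f"{cfg.max_attempts} attempts"
    )


def generate_phantom_case(
    case_id: str,
    seed: int,
    tissue: TissueParams | None = None,
    acquisition: AcquisitionSpec | None = None,
    sampler: GeometrySamplerConfig | None = None,
    fit_maps: bool = True,
    contour_points: int = 180,
) -> PhantomCase:
    """Generate one synthetic subject: three slices, contours, stacks, maps.

    Deterministic given ``seed``. Slices are ordered basal -> midventricular
    -> apical with decreasing radii; noise is added to the weighted stacks
    after synthesis and the parametric maps are fitted from the noisy stacks.
    """
    tissue = tissue or TissueParams()
    acq = acquisition or AcquisitionSpec()
    cfg = sampler or GeometrySamplerConfig()
    rng = np.random.default_rng(seed)
    shape = acq.image_shape
    sigma = acq.noise_sigma * max(tissue.proton_amplitude)

    scales = {
        "basal": 1.0,
        "midventricular": rng.uniform(*cfg.mid_scale),
        "apical": rng.uniform(*cfg.apical_scale),
    }
    slices: list[PhantomSlice] = []
    for position in SLICE_POSITIONS:
        geom = _sample_slice_geometry(rng, cfg, shape, position, scales[position])
        epi = geom.epi_contour(contour_points)
        endo = geom.endo_contour(contour_points)
        mask = contours_to_mask(epi, endo, shape, acq.pixel_spacing_mm)
        labels = mask.labels
        true_t1 = tissue.class_map(labels, "t1_ms")
        true_t2 = tissue.class_map(labels, "t2_ms")
        amp = tissue.class_map(labels, "proton_amplitude")
        t1w = simulate_t1_stack(true_t1, amp, 2.0 * amp, acq.inversion_times_ms)
        t2w = simulate_t2_stack(true_t2, amp, acq.echo_times_ms)
        if sigma > 0:
            t1w = t1w + rng.normal(0.0, sigma, t1w.shape)
            t2w = t2w + rng.normal(0.0, sigma, t2w.shape)
        fitted_t1 = fitted_t2 = None
        if fit_maps:
            fitted_t1 = fit_t1_map(t1w, acq.inversion_times_ms, acq.pixel_spacing_mm, position)
            fitted_t2 = fit_t2_map(t2w, acq.echo_times_ms, acq.pixel_spacing_mm, position)
        slices.append(
            PhantomSlice(
                geometry=geom,
                epi_contour=epi,
                endo_contour=endo,
                mask=mask,
                true_t1=true_t1,
                true_t2=true_t2,
                t1_weighted=t1w,
                t2_weighted=t2w,
                fitted_t1=fitted_t1,
                fitted_t2=fitted_t2,
            )
        )
    return PhantomCase(case_id=case_id, slices=slices, tissue=tissue,
                       acquisition=acq, rng_seed=seed)


def generate_phantom_cohort(
    n_cases: int,
    seed: int,
    **kwargs,
) -> list[PhantomCase]:
    """Generate ``n_cases`` independent cases with per-case seeds derived
    from ``seed`` (deterministic, order-independent)."""
    if n_cases <= 0:
        raise PhantomError("n_cases must be positive")
    root = np.random.SeedSequence(seed)
    children = root.spawn(n_cases)
    cases = []
    for i, child in enumerate(children):
        case_seed = int(child.generate_state(1)[0] % (2**31 - 1))
        cases.append(generate_phantom_case(f"case{i:04d}", case_seed, **kwargs))
    return cases
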