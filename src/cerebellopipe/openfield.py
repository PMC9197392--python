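"""Open-field video tracking and locomotor metrics.

Tracking follows the classical contour pipeline: ROI crop, grayscale,
binary threshold (dark animal on a light background), edge-preserving
bilateral filter plus Gaussian blur to reject thin high-spatial-frequency
structure (the headstage cable, floor particles), Canny edge detection,
fill of the largest closed contour, and the centroid (arithmetic mean) of
the enclosed pixels.  Pixel positions become centimeters through a single
scale factor.

Downstream metrics: frame-to-frame speed averaged over sliding 1 s
windows, total distance, the occupancy histogram, thigmotaxis index
(fraction of time beyond 0.75 of the arena radius), percent time in the
center (within 0.5 of the radius), active-wake percentage, and the
aggregation of ordinal dystonia scores per 10-min block.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import canny
from skimage.filters import gaussian
from skimage.measure import label, regionprops
from skimage.restoration import denoise_bilateral

from . import defaults as d
from .types import BehaviorScoreSeries, Trajectory


@dataclass(frozen=True)
class TrackingConfig:
    """Region of interest, threshold, smoothing and scale parameters."""

    roi_center_px: tuple | None = None  # (col, row); frame center if None
    roi_radius_px: float | None = None  # no ROI mask if None
    binary_threshold: int = d.BINARY_THRESHOLD
    bilateral_sigma_spatial: float = d.TRACK_BILATERAL_SIGMA_SPATIAL
    bilateral_sigma_color: float = d.TRACK_BILATERAL_SIGMA_COLOR
    gaussian_sigma: float = d.TRACK_GAUSSIAN_SIGMA
    px_per_cm: float = 1.0
    fps: float = 25.0
    arena_radius_cm: float = d.ARENA_RADIUS_CM

    def __post_init__(self):
        if not 0 <= self.binary_threshold <= 255:
            raise ValueError("binary_threshold must lie in [0, 255]")
        if self.px_per_cm <= 0 or self.fps <= 0:
            raise ValueError("px_per_cm and fps must be positive")


@dataclass(frozen=True)
class OpenFieldMetrics:
    total_distance: float
    median_speed: float
    thigmotaxis_index: float
    pct_time_center: float
    occupancy: np.ndarray


@dataclass(frozen=True)
class ActivityResult:
    aw_pct: float
    bouts: list
    dystonia_block_means: np.ndarray | None = None


def _frame_centroid(frame: np.ndarray, cfg: TrackingConfig):
    """Centroid (col, row) of the largest closed dark contour, or None."""
    img = frame.astype(float) / 255.0
    if cfg.roi_radius_px is not None:
        h, w = img.shape
        c = cfg.roi_center_px or ((w - 1) / 2.0, (h - 1) / 2.0)
        rows, cols = np.mgrid[0:h, 0:w]
        outside = np.hypot(rows - c[1], cols - c[0]) > cfg.roi_radius_px
        img = img.copy()
        img[outside] = 1.0  # treat outside-ROI as background
    binary = (img < cfg.binary_threshold / 255.0).astype(float)
    if not binary.any():
        return None
    smoothed = denoise_bilateral(
        binary, sigma_color=cfg.bilateral_sigma_color,
        sigma_spatial=cfg.bilateral_sigma_spatial)
    smoothed = gaussian(smoothed, sigma=cfg.gaussian_sigma)
    # high threshold set to pass the full-contrast animal outline while
    # rejecting the low-amplitude residue of thin structures (cable)
    edges = canny(smoothed, sigma=1.0, low_threshold=0.1, high_threshold=0.3)
    filled = ndi.binary_fill_holes(edges | (smoothed > 0.5))
    regions = regionprops(label(filled))
    if not regions:
        return None
    blob = max(regions, key=lambda r: r.area)
    row, col = blob.centroid
    return col, row


def track(frames, cfg: TrackingConfig, arena_center_cm=(0.0, 0.0)
          ) -> Trajectory:
    """Track the animal centroid across a frame stack.

    ``frames`` iterates ``(index, 2-D uint8 array)`` as produced by
    :func:`cerebellopipe.io.read_frame_stack`.  Frames without a
    detectable contour inherit the last valid position (the first frames,
    the first valid one); more than 10% imputed frames raises a hard
    warning.
    """
    centers_px = []
    missing = []
    shape = None
    for i, frame in frames:
        if shape is None:
            shape = frame.shape
        c = _frame_centroid(frame, cfg)
        centers_px.append(c)
        if c is None:
            missing.append(i)
    n = len(centers_px)
    if n == 0:
        raise ValueError("empty frame stack")
    first_valid = next((c for c in centers_px if c is not None), None)
    if first_valid is None:
        # total tracking failure: flag every frame and fall back to the
        # frame center so the failure stays visible, not fatal
        h, w = shape
        first_valid = ((w - 1) / 2.0, (h - 1) / 2.0)
    filled = []
    last = first_valid
    for c in centers_px:
        if c is not None:
            last = c
        filled.append(last)
    if missing:
        frac = len(missing) / n
        msg = (f"{len(missing)}/{n} frames ({frac:.0%}) had no contour; "
               "positions imputed from the last valid frame")
        if frac > d.MAX_IMPUTED_FRACTION:
            warnings.warn("TRACKING QUALITY: " + msg, stacklevel=2)
        else:
            warnings.warn(msg, stacklevel=2)
    h, w = shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    px = np.asarray(filled, dtype=float)
    pos_cm = np.column_stack([
        (px[:, 0] - cx) / cfg.px_per_cm + arena_center_cm[0],
        (px[:, 1] - cy) / cfg.px_per_cm + arena_center_cm[1],
    ])
    ts = np.arange(n) / cfg.fps
    return Trajectory(ts, pos_cm, arena_center=tuple(arena_center_cm),
                      arena_radius=cfg.arena_radius_cm,
                      px_per_cm=cfg.px_per_cm)


def speeds(traj: Trajectory, window: float = d.SPEED_WINDOW_S) -> np.ndarray:
    """Frame-to-frame speed averaged over centered sliding 1 s windows.

    Returns one value per frame interval (length ``n_samples - 1``);
    windows are truncated at the session edges.
    """
    if traj.n_samples < 2:
        raise ValueError("need >= 2 samples")
    dt = float(traj.timestamps[1] - traj.timestamps[0])
    disp = np.diff(traj.positions, axis=0)
    inst = np.hypot(disp[:, 0], disp[:, 1]) / dt
    half = max(int(round(window / dt)) // 2, 0)
    if half == 0:
        return inst
    csum = np.concatenate([[0.0], np.cumsum(inst)])
    n = inst.size
    lo = np.clip(np.arange(n) - half, 0, n)
    hi = np.clip(np.arange(n) + half + 1, 0, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def total_distance(traj: Trajectory) -> float:
    """Sum of consecutive displacements (cm)."""
    disp = np.diff(traj.positions, axis=0)
    return float(np.hypot(disp[:, 0], disp[:, 1]).sum())


def occupancy_metrics(traj: Trajectory, n_bins: int = d.OCCUPANCY_BINS,
                      thigmo_frac: float = d.THIGMOTAXIS_FRACTION,
                      center_frac: float = d.CENTER_FRACTION
                      ) -> OpenFieldMetrics:
    """Occupancy histogram plus thigmotaxis and center-time fractions.

    Thigmotaxis index: fraction of samples with radial distance beyond
    ``thigmo_frac`` of the arena radius; percent time in center: samples
    within ``center_frac`` of the radius.  The histogram covers the arena
    bounding square and its mass equals the sample count.
    """
    r = traj.radii()
    radius = traj.arena_radius
    thigmo = float(np.mean(r > thigmo_frac * radius))
    center = float(np.mean(r < center_frac * radius)) * 100.0
    extent = [traj.arena_center[0] - radius, traj.arena_center[0] + radius]
    extent_y = [traj.arena_center[1] - radius, traj.arena_center[1] + radius]
    occ, _, _ = np.histogram2d(
        traj.positions[:, 0], traj.positions[:, 1],
        bins=n_bins, range=[extent, extent_y])
    sp = speeds(traj)
    return OpenFieldMetrics(
        total_distance=total_distance(traj),
        median_speed=float(np.median(sp)),
        thigmotaxis_index=thigmo,
        pct_time_center=center,
        occupancy=occ,
    )


def _bouts_from_mask(active: np.ndarray, dt: float, min_bout: float):
    """Contiguous True runs of at least ``min_bout`` seconds, as
    (start_s, end_s) pairs; shorter runs are dissolved."""
    bouts = []
    n = active.size
    i = 0
    while i < n:
        if active[i]:
            j = i
            while j < n and active[j]:
                j += 1
            if (j - i) * dt >= min_bout:
                bouts.append((i * dt, j * dt))
            i = j
        else:
            i += 1
    return bouts


def active_wake(traj: Trajectory,
                speed_threshold: float = d.ACTIVE_SPEED_CM_S,
                min_bout: float = d.MIN_BOUT_S,
                window: float = d.SPEED_WINDOW_S) -> ActivityResult:
    """Percentage of the session spent in active wake (walking).

    A sample is active when its 1 s window speed reaches the threshold;
    bouts shorter than ``min_bout`` are dissolved before the active time
    is summed.
    """
    dt = float(traj.timestamps[1] - traj.timestamps[0])
    sp = speeds(traj, window=window)
    active = sp >= speed_threshold
    bouts = _bouts_from_mask(active, dt, min_bout)
    active_time = sum(e - s for s, e in bouts)
    total_time = sp.size * dt
    return ActivityResult(aw_pct=100.0 * active_time / total_time,
                          bouts=bouts)


def aggregate_scores(series: BehaviorScoreSeries):
    """Per-block mean across raters plus a session summary.

    Returns ``(block_means, summary_dict)`` where the summary holds the
    session mean (mean of block means) and the exact inter-rater
    agreement fraction.
    """
    scores = series.block_scores
    if scores.shape[1] == 0:
        raise ValueError("no score blocks")
    block_means = scores.mean(axis=0)
    agreement = float(np.mean(np.all(scores == scores[0], axis=0)))
    summary = {
        "session_mean": float(block_means.mean()),
        "inter_rater_agreement": agreement,
        "n_blocks": int(scores.shape[1]),
        "n_raters": int(scores.shape[0]),
    }
    return block_means, summary
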