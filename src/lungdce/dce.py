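"""Model-free DCE analysis: relative enhancement, drift correction, binning.

The analysis follows the model-free scheme used for slowly-sampled rodent
lung DCE: a per-pixel baseline S0 is the mean of the pre-injection frames
(frames 1-50 in 1-based counting), relative enhancement is the signal
change over baseline RE(t) = (S(t) - S0)/S0, a background trace measured
in corner ROIs outside the animal is subtracted per animal (radial streak
artefact and noise levels are not constant over the acquisition), and lung
pixels are binned into 7 classes by their post-injection maximum RE using
the thresholds {1, 2, 3, 4, 8, 12}.  Bin volumes, the aggregate
low-enhancement volume (classes with peak RE below 3) and the ROI-mean
enhancement curve summarize each animal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .recon import ImageSeries

__all__ = [
    "DEFAULT_THRESHOLDS",
    "LungROI",
    "EnhancementResult",
    "compute_baseline",
    "relative_enhancement",
    "corner_rois",
    "background_trace",
    "correct_background",
    "bin_pixels",
    "bin_volumes",
    "low_enhancement_fraction",
    "mean_lung_curve",
    "group_average",
    "lung_volume",
    "analyze_series",
]

DEFAULT_THRESHOLDS = (1.0, 2.0, 3.0, 4.0, 8.0, 12.0)


@dataclass
class LungROI:
    """Binary lung mask per slice (vessels and high-signal areas included)."""

    mask: np.ndarray  # (slice, row, col) bool
    pixel_spacing_mm: float
    slice_thickness_mm: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError(f"mask must be (slice, row, col), got {self.mask.shape}")
        if not self.mask.any():
            raise ValueError("lung mask is empty")

    @property
    def voxel_volume_ml(self) -> float:
        return self.pixel_spacing_mm**2 * self.slice_thickness_mm / 1000.0

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass
class EnhancementResult:
    """Per-animal model-free DCE summary."""

    s0: np.ndarray  # baseline map (slice, row, col)
    re: np.ndarray  # corrected RE (frame, slice, row, col)
    background: np.ndarray  # drift b(t) per frame
    bin_map: np.ndarray  # int8 class 0-6 on lung pixels, -1 elsewhere
    bin_volumes_ml: dict[int, float]
    mean_curve: np.ndarray  # lung-ROI average RE per frame
    frame_mid_time: np.ndarray
    roi: LungROI
    thresholds: tuple = DEFAULT_THRESHOLDS
    n_excluded: int = 0  # lung pixels with S0 <= 0, excluded from RE
    meta: dict = field(default_factory=dict)

    @property
    def lung_volume_ml(self) -> float:
        return lung_volume(self.roi)

    def low_enhancement_volume_ml(self, re_threshold: float = 3.0) -> float:
        """Aggregate volume of classes whose upper RE edge is <= threshold."""
        n_low = int(np.searchsorted(self.thresholds, re_threshold, side="right"))
        return sum(v for c, v in self.bin_volumes_ml.items() if c < n_low)

    def low_enhancement_fraction(self, re_threshold: float = 3.0) -> float:
        return self.low_enhancement_volume_ml(re_threshold) / self.lung_volume_ml


def compute_baseline(
    series: ImageSeries,
    frame_range: tuple[int, int] = (1, 50),
    injection_time_s: float | None = None,
) -> np.ndarray:
    """Per-pixel mean over the pre-injection frames (1-based, inclusive).

    If the injection time is known, every baseline frame must lie before it.
    """
    lo, hi = int(frame_range[0]), int(frame_range[1])
    if not 1 <= lo <= hi:
        raise ValueError(f"invalid frame range {frame_range} (1-based, inclusive)")
    if series.n_frames < hi:
        raise ValueError(
            f"series has {series.n_frames} frames, fewer than baseline range end {hi}"
        )
    if injection_time_s is not None:
        end = series.frame_mid_time[hi - 1] + 0.0
        if end >= injection_time_s:
            raise ValueError(
                f"baseline frame {hi} (mid-time {end:.1f} s) is not before the "
                f"injection at {injection_time_s:.1f} s"
            )
    return series.frames[lo - 1 : hi].mean(axis=0)


def relative_enhancement(series: ImageSeries, s0: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """RE(t) = (S(t) - S0)/S0 per pixel per frame.

    Returns (re, valid): pixels with S0 <= 0 get RE = 0 and valid = False so
    callers can report the excluded count.
    """
    s0 = np.asarray(s0, dtype=np.float64)
    if s0.shape != series.frames.shape[1:]:
        raise ValueError(f"S0 shape {s0.shape} does not match frames")
    valid = s0 > 0
    safe = np.where(valid, s0, 1.0)
    re = (series.frames - s0) / safe
    re[:, ~valid] = 0.0
    return re, valid


def corner_rois(shape: tuple[int, int, int], size: int = 8) -> np.ndarray:
    """Four size x size squares at the image corners, on every slice."""
    mask = np.zeros(shape, dtype=bool)
    mask[:, :size, :size] = True
    mask[:, :size, -size:] = True
    mask[:, -size:, :size] = True
    mask[:, -size:, -size:] = True
    return mask


def background_trace(
    series: ImageSeries,
    corner_mask: np.ndarray | None = None,
    frame_range: tuple[int, int] = (1, 50),
    lung_mask: np.ndarray | None = None,
    corner_size: int = 8,
) -> np.ndarray:
    """Normalized background drift b(t) = (B(t) - B0)/B0.

    B(t) is the mean magnitude over corner ROIs outside the animal; B0 its
    mean over the baseline frames.  The corner ROIs must not intersect the
    lung mask (they sample streak artefact and noise only).
    """
    if corner_mask is None:
        corner_mask = corner_rois(series.frames.shape[1:], corner_size)
    corner_mask = np.asarray(corner_mask, dtype=bool)
    if lung_mask is not None and np.any(corner_mask & np.asarray(lung_mask, bool)):
        raise ValueError("background ROIs overlap the lung mask")
    b_t = series.frames[:, corner_mask].mean(axis=1)
    lo, hi = int(frame_range[0]), int(frame_range[1])
    b0 = b_t[lo - 1 : hi].mean()
    if b0 <= 0:
        raise ValueError("baseline background level is not positive")
    return b_t / b0 - 1.0


def correct_background(re: np.ndarray, b: np.ndarray, mode: str = "subtract") -> np.ndarray:
    """Remove the background drift from RE curves, per animal.

    ``subtract`` implements RE_corr(t) = RE(t) - b(t).  ``divide`` rescales
    by (1 + b(t)) instead, which is exact when the drift is a purely
    multiplicative modulation of the whole image; subtraction then leaves a
    residual of order b(t) * RE(t).  ``none`` disables the correction (for
    data whose corner ROIs carry no meaningful background signal).
    """
    re = np.asarray(re, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if b.shape[0] != re.shape[0]:
        raise ValueError(
            f"background has {b.shape[0]} frames but RE has {re.shape[0]}"
        )
    bb = b.reshape((-1,) + (1,) * (re.ndim - 1))
    if mode == "subtract":
        return re - bb
    if mode == "divide":
        return (1.0 + re) / (1.0 + bb) - 1.0
    if mode == "none":
        return re.copy()
    raise ValueError(f"mode must be 'subtract', 'divide' or 'none', got {mode!r}")


def bin_pixels(
    re_corr: np.ndarray,
    post_injection_frames: np.ndarray,
    roi: LungROI | None = None,
    thresholds=DEFAULT_THRESHOLDS,
) -> np.ndarray:
    """Classify pixels by the maximum RE directly after injection.

    ``post_injection_frames`` is a boolean or index selector over the frame
    axis.  Class c means thresholds[c-1] <= max RE < thresholds[c], i.e.
    with the default thresholds {1, 2, 3, 4, 8, 12}: class 0 below 1,
    class 4 in [4, 8), class 6 at or above 12.  Returns int8 with -1
    outside the ROI.
    """
    sel = np.asarray(post_injection_frames)
    window = re_corr[sel] if sel.dtype == bool else re_corr[sel.astype(np.int64)]
    if window.shape[0] == 0:
        raise ValueError("post-injection window selects no frames")
    peak = window.max(axis=0)
    bins = np.digitize(peak, np.asarray(thresholds, dtype=np.float64)).astype(np.int8)
    if roi is not None:
        bins = np.where(roi.mask, bins, np.int8(-1))
    return bins


def bin_volumes(bin_map: np.ndarray, roi: LungROI) -> dict[int, float]:
    """Volume (ml) per enhancement class over the lung ROI; partitions it."""
    voxel = roi.voxel_volume_ml
    inside = bin_map[roi.mask]
    return {c: float((inside == c).sum()) * voxel for c in range(7)}


def low_enhancement_fraction(
    volumes: dict[int, float], lung_volume_ml: float, re_threshold: float = 3.0,
    thresholds=DEFAULT_THRESHOLDS,
) -> float:
    """Fraction of the lung with peak RE below the threshold (default 3)."""
    n_low = int(np.searchsorted(np.asarray(thresholds), re_threshold, side="right"))
    low = sum(v for c, v in volumes.items() if c < n_low)
    return low / lung_volume_ml


def mean_lung_curve(re_corr: np.ndarray, roi: LungROI) -> np.ndarray:
    """Arithmetic mean RE over lung pixels, per frame."""
    return re_corr[:, roi.mask].mean(axis=1)


def group_average(curves) -> tuple[np.ndarray, np.ndarray]:
    """Group mean and SEM across animals (curves share the frame axis)."""
    curves = [np.asarray(c, dtype=np.float64) for c in curves]
    if not curves:
        raise ValueError("need at least one animal")
    n_frames = {c.shape[0] for c in curves}
    if len(n_frames) != 1:
        raise ValueError(f"frame-count mismatch across animals: {sorted(n_frames)}")
    arr = np.stack(curves)
    mean = arr.mean(axis=0)
    n = arr.shape[0]
    sem = arr.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros_like(mean)
    return mean, sem


def lung_volume(roi: LungROI) -> float:
    """Total lung volume in ml: voxel count x pixel area x slice thickness."""
    return roi.n_voxels * roi.voxel_volume_ml


def analyze_series(
    series: ImageSeries,
    roi: LungROI,
    baseline_frames: tuple[int, int] = (1, 50),
    injection_time_s: float | None = None,
    post_window_s: float = 60.0,
    thresholds=DEFAULT_THRESHOLDS,
    corner_size: int = 8,
    background_mode: str = "subtract",
    bin_on_corrected: bool = True,
    re_mode: str = "delta",
) -> EnhancementResult:
    """Run the full model-free analysis on one reconstructed series.

    The post-injection binning window defaults to the ``post_window_s``
    seconds directly after the injection (clipped to the series end).
    ``re_mode="delta"`` (default) reports RE = (S - S0)/S0; ``"ratio"``
    reports S/S0, under which "less than 3 times the baseline" means
    thresholding the ratio at 3 (the thresholds are applied as given in
    either convention).
    """
    if re_mode not in ("delta", "ratio"):
        raise ValueError(f"re_mode must be 'delta' or 'ratio', got {re_mode!r}")
    s0 = compute_baseline(series, baseline_frames, injection_time_s)
    re_raw, valid = relative_enhancement(series, s0)
    if re_mode == "ratio":
        re_raw = re_raw + 1.0
    b = background_trace(
        series, frame_range=baseline_frames, lung_mask=roi.mask, corner_size=corner_size
    )
    re_corr = correct_background(re_raw, b, mode=background_mode)

    if injection_time_s is None:
        # fall back to "everything after the baseline window"
        post = np.arange(series.n_frames) >= baseline_frames[1]
    else:
        t = series.frame_mid_time
        post = (t >= injection_time_s) & (t <= injection_time_s + post_window_s)
    if not post.any():
        raise ValueError("post-injection window selects no frames")

    source = re_corr if bin_on_corrected else re_raw
    bmap = bin_pixels(source, post, roi=roi, thresholds=thresholds)
    vols = bin_volumes(bmap, roi)
    return EnhancementResult(
        s0=s0,
        re=re_corr,
        background=b,
        bin_map=bmap,
        bin_volumes_ml=vols,
        mean_curve=mean_lung_curve(re_corr, roi),
        frame_mid_time=series.frame_mid_time.copy(),
        roi=roi,
        thresholds=tuple(thresholds),
        n_excluded=int((~valid & roi.mask).sum()),
        meta={
            "baseline_frames": tuple(baseline_frames),
            "background_mode": background_mode,
            "post_window_s": post_window_s,
            "re_mode": re_mode,
        },
    )
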