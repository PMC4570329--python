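"""Plant counting in a single straightened image.

The smoothed vegetation-intensity image is collapsed to a vertical
projection histogram (one bin per image column, summed over the rows of a
region of interest).  Each plant, once straightened, produces one hump in
this histogram, so the stand count of the image is the number of local
maxima of the histogram.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.ndimage import gaussian_filter1d

from .segmentation import (
    SegmentationConfig,
    excess_green_segment,
    gaussian_smooth,
    to_intensity,
)

__all__ = [
    "RegionOfInterest",
    "LocalMaxima",
    "ImageCount",
    "vertical_projection",
    "smooth_histogram",
    "detect_local_maxima",
    "count_single_image",
]


@dataclass(frozen=True)
class RegionOfInterest:
    """Half-open pixel box [x_min, x_max) x [y_min, y_max).

    In the field the ROI is chosen once per camera setup to contain the
    target crop row and exclude adjacent rows visible near the horizon.
    """

    x_min: int
    x_max: int
    y_min: int
    y_max: int

    def __post_init__(self) -> None:
        if not (0 <= self.x_min < self.x_max):
            raise ValueError(f"need 0 <= x_min < x_max, got [{self.x_min}, {self.x_max})")
        if not (0 <= self.y_min < self.y_max):
            raise ValueError(f"need 0 <= y_min < y_max, got [{self.y_min}, {self.y_max})")

    @classmethod
    def full(cls, shape: tuple[int, ...]) -> "RegionOfInterest":
        """ROI covering a whole image of the given (H, W, ...) shape."""
        return cls(0, shape[1], 0, shape[0])

    def clip_check(self, shape: tuple[int, ...]) -> None:
        h, w = shape[0], shape[1]
        if self.x_max > w or self.y_max > h:
            raise ValueError(
                f"ROI [{self.x_min},{self.x_max})x[{self.y_min},{self.y_max}) "
                f"exceeds image bounds {w}x{h}"
            )


@dataclass(frozen=True)
class LocalMaxima:
    """Detected histogram peaks: strictly increasing positions and heights."""

    positions: np.ndarray
    values: np.ndarray

    def __len__(self) -> int:
        return len(self.positions)


@dataclass(frozen=True)
class ImageCount:
    """Per-image counting result with the parameters that produced it."""

    n_plants: int
    maxima: LocalMaxima
    histogram: np.ndarray = field(repr=False)
    params: object = None
    seg_cfg: SegmentationConfig | None = None
    roi: RegionOfInterest | None = None

    def to_record(self, image_id: str = "") -> dict:
        rec = {
            "image_id": image_id,
            "n_plants": self.n_plants,
            "maxima_positions": [int(p) for p in self.maxima.positions],
            "maxima_values": [float(v) for v in self.maxima.values],
        }
        if self.params is not None:
            rec["delta_x"] = float(self.params.delta_x)
            rec["delta_y"] = float(self.params.delta_y)
        if self.roi is not None:
            rec["roi"] = [self.roi.x_min, self.roi.x_max, self.roi.y_min, self.roi.y_max]
        return rec


def vertical_projection(smoothed: np.ndarray, roi: RegionOfInterest) -> np.ndarray:
    """Column sums of the smoothed intensity over the ROI rows.

    Returns a histogram with one bin per image column; columns outside the
    ROI hold zero, so the histogram length always equals the image width.
    """
    smoothed = np.asarray(smoothed, dtype=np.float64)
    roi.clip_check(smoothed.shape)
    hist = np.zeros(smoothed.shape[1], dtype=np.float64)
    hist[roi.x_min : roi.x_max] = smoothed[roi.y_min : roi.y_max, roi.x_min : roi.x_max].sum(
        axis=0
    )
    return hist


def smooth_histogram(hist: np.ndarray, sigma: float, roi: RegionOfInterest | None = None) -> np.ndarray:
    """1-D Gaussian smoothing of the projection histogram.

    Only the ROI span is smoothed (reflective boundary at the ROI edges)
    so no histogram mass bleeds into columns outside the ROI.
    """
    if sigma <= 0:
        return np.asarray(hist, dtype=np.float64).copy()
    out = np.zeros_like(hist, dtype=np.float64)
    lo, hi = (roi.x_min, roi.x_max) if roi is not None else (0, len(hist))
    out[lo:hi] = gaussian_filter1d(np.asarray(hist[lo:hi], dtype=np.float64), sigma, mode="reflect")
    return out


def detect_local_maxima(
    hist: np.ndarray,
    min_prominence: float = 0.0,
    domain: tuple[int, int] | None = None,
) -> LocalMaxima:
    """Interior histogram bins strictly above both neighbours.

    A plateau — a run of equal values strictly above both flanking values —
    collapses to a single maximum at the run's centre (rounding down), so
    flat-topped peaks produced by quantisation still count once.  Bins 0
    and W-1 are never maxima.  ``domain`` restricts the scan to the
    half-open bin range the histogram is actually defined on (the ROI
    columns); its edge bins are then excluded exactly as the image edge
    bins are, so a plant cut by the ROI boundary cannot register as a
    ramp apex at the boundary bin.  ``min_prominence`` optionally drops
    peaks whose topographic prominence falls below it (off by default).
    """
    h_full = np.asarray(hist, dtype=np.float64)
    lo, hi = (0, len(h_full)) if domain is None else domain
    if not 0 <= lo < hi <= len(h_full):
        raise ValueError(f"domain [{lo}, {hi}) outside histogram of {len(h_full)} bins")
    h = h_full[lo:hi]
    n = len(h)
    if n < 3:
        raise ValueError(f"histogram needs at least 3 bins, got {n}")
    positions: list[int] = []
    start = 0
    while start < n:
        end = start
        while end + 1 < n and h[end + 1] == h[start]:
            end += 1
        if start > 0 and end < n - 1 and h[start - 1] < h[start] and h[end + 1] < h[end]:
            positions.append((start + end) // 2)
        start = end + 1
    pos = np.asarray(positions, dtype=np.intp) + lo
    h = h_full
    if min_prominence > 0 and len(pos) > 0:
        prom = signal.peak_prominences(h, pos)[0]
        pos = pos[prom >= min_prominence]
    return LocalMaxima(positions=pos, values=h[pos])


def count_single_image(
    image: np.ndarray,
    params,
    seg_cfg: SegmentationConfig | None = None,
    roi: RegionOfInterest | None = None,
    min_prominence: float = 0.0,
) -> ImageCount:
    """Full single-image pipeline: straighten, segment, smooth, project, count.

    ``params`` is a :class:`rowcount.geometry.PerspectiveParams`; the stand
    count of the image is the number of local maxima of the smoothed
    vertical projection histogram inside the ROI.
    """
    from .geometry import make_corner_correspondence, solve_perspective_matrix, warp_perspective

    image = np.asarray(image)
    if seg_cfg is None:
        seg_cfg = SegmentationConfig()
    if roi is None:
        roi = RegionOfInterest.full(image.shape)
    h, w = image.shape[:2]
    matrix = solve_perspective_matrix(make_corner_correspondence(w, h, params))
    warped = warp_perspective(image, matrix)
    seg = excess_green_segment(warped, seg_cfg)
    intensity = to_intensity(seg, mode=seg_cfg.intensity_mode)
    smoothed = gaussian_smooth(intensity, seg_cfg.sigma)
    hist = vertical_projection(smoothed, roi)
    hist = smooth_histogram(hist, seg_cfg.hist_sigma, roi)
    maxima = detect_local_maxima(
        hist, min_prominence=min_prominence, domain=(roi.x_min, roi.x_max)
    )
    return ImageCount(
        n_plants=len(maxima),
        maxima=maxima,
        histogram=hist,
        params=params,
        seg_cfg=seg_cfg,
        roi=roi,
    )
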