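"""Perspective "plant straightening" transform.

Images are captured obliquely (about 60 degrees to the ground) along a crop
row, so plants lean increasingly as they approach the left and right image
borders.  A projective warp that maps the image rectangle onto a symmetric
trapezoid — top corners pulled inward by ``delta_x``, bottom corners pushed
outward, both rails shifted down by ``delta_y`` — makes the plant stems
near-vertical, which is what lets one column-histogram peak correspond to
one plant.

The pair (``delta_x``, ``delta_y``) is found once per dataset by a grid
search that runs the whole counting pipeline for each candidate and keeps
the candidate maximising the summed height of the strongest histogram
peaks: straightened plants concentrate their mass into fewer, taller
columns.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import map_coordinates
from skimage.transform import ProjectiveTransform

__all__ = [
    "PerspectiveParams",
    "QuadCorrespondence",
    "AutoSearchConfig",
    "make_corner_correspondence",
    "solve_perspective_matrix",
    "warp_perspective",
    "auto_determine_params",
    "save_calibration",
    "load_calibration",
]


@dataclass(frozen=True)
class PerspectiveParams:
    """Straightening parameters: horizontal and vertical corner shifts, px."""

    delta_x: float
    delta_y: float


@dataclass(frozen=True)
class QuadCorrespondence:
    """Four source points and their four destination points, as (x, y)."""

    source: np.ndarray
    destination: np.ndarray

    def __post_init__(self) -> None:
        for name, pts in (("source", self.source), ("destination", self.destination)):
            pts = np.asarray(pts, dtype=np.float64)
            if pts.shape != (4, 2):
                raise ValueError(f"{name} must be 4 (x, y) points, got shape {pts.shape}")
            if _any_three_collinear(pts):
                raise ValueError(f"degenerate {name} quad: three points are collinear")
            object.__setattr__(self, name, pts)


@dataclass(frozen=True)
class AutoSearchConfig:
    """Grid-search configuration for parameter auto-determination.

    ``n_top_maxima`` is how many of the largest histogram local maxima are
    summed into the objective (default 10, roughly the plants per frame at
    10 cm spacing); ``step_x``/``step_y`` are the grid steps in pixels.
    """

    n_top_maxima: int = 10
    step_x: int = 4
    step_y: int = 8

    def __post_init__(self) -> None:
        if self.n_top_maxima < 1:
            raise ValueError(f"n_top_maxima must be >= 1, got {self.n_top_maxima}")
        if self.step_x < 1 or self.step_y < 1:
            raise ValueError(f"grid steps must be >= 1, got ({self.step_x}, {self.step_y})")


def _any_three_collinear(pts: np.ndarray, tol: float = 1e-9) -> bool:
    from itertools import combinations

    for i, j, k in combinations(range(4), 3):
        a, b, c = pts[i], pts[j], pts[k]
        cross = (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
        scale = max(1.0, np.abs(pts).max())
        if abs(cross) <= tol * scale * scale:
            return True
    return False


def make_corner_correspondence(
    width: int, height: int, params: PerspectiveParams
) -> QuadCorrespondence:
    """Corner mapping of the straightening warp for a W x H image.

    Source corners are the image rectangle; destination corners form the
    symmetric trapezoid ``(dx, dy), (W-1-dx, dy), (W-1+dx, H-1+dy),
    (-dx, H-1+dy)``.  ``delta_x`` is bounded by W/4 and ``delta_y`` by H/2,
    the ranges the auto-search explores.
    """
    if width < 2 or height < 2:
        raise ValueError(f"image must be at least 2x2, got {width}x{height}")
    dx, dy = params.delta_x, params.delta_y
    if not 0 <= dx <= width / 4:
        raise ValueError(f"delta_x={dx} violates bound 0 <= delta_x <= W/4 = {width / 4}")
    if not 0 <= dy <= height / 2:
        raise ValueError(f"delta_y={dy} violates bound 0 <= delta_y <= H/2 = {height / 2}")
    w1, h1 = width - 1, height - 1
    source = np.array([(0, 0), (w1, 0), (w1, h1), (0, h1)], dtype=np.float64)
    destination = np.array(
        [(dx, dy), (w1 - dx, dy), (w1 + dx, h1 + dy), (-dx, h1 + dy)], dtype=np.float64
    )
    return QuadCorrespondence(source=source, destination=destination)


def solve_perspective_matrix(corr: QuadCorrespondence) -> np.ndarray:
    """3x3 projective matrix mapping each source corner to its destination.

    Solved by normalised DLT (scikit-image); the result is scaled so the
    bottom-right entry is 1 and maps each corner exactly (to numerical
    tolerance) since four correspondences determine the matrix.
    """
    tform = ProjectiveTransform.from_estimate(corr.source, corr.destination)
    if not tform:
        raise np.linalg.LinAlgError("singular correspondence: cannot solve perspective matrix")
    matrix = tform.params
    if not np.all(np.isfinite(matrix)) or abs(matrix[2, 2]) < 1e-12:
        raise np.linalg.LinAlgError("singular correspondence: cannot solve perspective matrix")
    matrix = matrix / matrix[2, 2]
    if abs(np.linalg.det(matrix)) < 1e-12:
        raise np.linalg.LinAlgError("perspective matrix is not invertible")
    return matrix


def _inverse_grid(matrix: np.ndarray, width: int, height: int) -> tuple[np.ndarray, np.ndarray]:
    """Source sampling coordinates (row, col maps) for each output pixel."""
    try:
        inv = np.linalg.inv(matrix)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("perspective matrix is not invertible") from exc
    xx, yy = np.meshgrid(np.arange(width, dtype=np.float64), np.arange(height, dtype=np.float64))
    denom = inv[2, 0] * xx + inv[2, 1] * yy + inv[2, 2]
    src_x = (inv[0, 0] * xx + inv[0, 1] * yy + inv[0, 2]) / denom
    src_y = (inv[1, 0] * xx + inv[1, 1] * yy + inv[1, 2]) / denom
    return src_y, src_x


def _sample(channel: np.ndarray, grid: tuple[np.ndarray, np.ndarray]) -> np.ndarray:
    return map_coordinates(
        np.asarray(channel, dtype=np.float64), grid, order=1, mode="constant", cval=0.0
    )


def warp_perspective(image: np.ndarray, matrix: np.ndarray) -> np.ndarray:
    """Apply a projective warp: output (x, y) samples the source at P^-1(x, y).

    Content therefore moves *forward* by the matrix (a pure-translation
    matrix with p13 = 5 shifts the image 5 px to the right).  Sampling is
    bilinear via the inverse map; samples falling outside the source frame
    are zero (black), which contributes nothing to the excess-green mask.
    Output size equals input size; dtype is float64.
    """
    image = np.asarray(image)
    height, width = image.shape[:2]
    grid = _inverse_grid(np.asarray(matrix, dtype=np.float64), width, height)
    if image.ndim == 2:
        return _sample(image, grid)
    return np.stack([_sample(image[..., c], grid) for c in range(image.shape[2])], axis=-1)


def _objective(hist_maxima_values: np.ndarray, n_top: int) -> float:
    """Sum of the n_top largest local-maxima heights (all, if fewer exist)."""
    if len(hist_maxima_values) == 0:
        return -np.inf
    top = np.sort(hist_maxima_values)[::-1][:n_top]
    return float(top.sum())


def auto_determine_params(
    image: np.ndarray,
    cfg: AutoSearchConfig | None = None,
    seg_cfg=None,
    roi=None,
) -> PerspectiveParams:
    """Grid-search the straightening parameters on a dataset's first frame.

    Candidates (delta_x in [0, W/4], delta_y in [0, H/2] at the configured
    steps) are each scored by running warp -> segmentation -> smoothing ->
    projection -> local maxima and summing the ``n_top_maxima`` largest
    peak heights; the argmax candidate wins, ties going to the smaller
    (delta_x, delta_y) lexicographically.  Because the excess-green index
    and luma are linear in the colour channels, the per-candidate warp is
    applied to precomputed index maps rather than to the full colour image;
    the score is identical to warping the colour image first.
    """
    from .counting import (
        RegionOfInterest,
        detect_local_maxima,
        smooth_histogram,
        vertical_projection,
    )
    from .segmentation import SegmentationConfig, excess_green, gaussian_smooth

    if cfg is None:
        cfg = AutoSearchConfig()
    if seg_cfg is None:
        seg_cfg = SegmentationConfig()
    image = np.asarray(image)
    height, width = image.shape[:2]
    if roi is None:
        roi = RegionOfInterest.full(image.shape)

    exg = excess_green(image)
    if seg_cfg.intensity_mode == "luma":
        from .segmentation import _LUMA_WEIGHTS

        luma = np.asarray(image, dtype=np.float64) @ _LUMA_WEIGHTS
    else:
        luma = None

    best_score = -np.inf
    best: PerspectiveParams | None = None
    for dx in range(0, int(width // 4) + 1, cfg.step_x):
        for dy in range(0, int(height // 2) + 1, cfg.step_y):
            params = PerspectiveParams(float(dx), float(dy))
            matrix = solve_perspective_matrix(make_corner_correspondence(width, height, params))
            grid = _inverse_grid(matrix, width, height)
            warped_exg = _sample(exg, grid)
            mask = warped_exg > seg_cfg.exg_threshold
            if luma is None:
                intensity = np.where(mask, np.clip(warped_exg, 0.0, None), 0.0)
            else:
                intensity = np.where(mask, _sample(luma, grid), 0.0)
            smoothed = gaussian_smooth(intensity, seg_cfg.sigma)
            hist = smooth_histogram(vertical_projection(smoothed, roi), seg_cfg.hist_sigma, roi)
            maxima = detect_local_maxima(hist)
            score = _objective(maxima.values, cfg.n_top_maxima)
            if score > best_score:
                best_score = score
                best = params
    if best is None or not np.isfinite(best_score):
        raise RuntimeError("no plants detected during auto-calibration")
    return best


def save_calibration(path: str | Path, params: PerspectiveParams, cfg: AutoSearchConfig) -> None:
    """Persist the per-dataset calibration as a small key=value text file."""
    lines = [
        f"delta_x={params.delta_x}",
        f"delta_y={params.delta_y}",
        f"n_top_maxima={cfg.n_top_maxima}",
        f"step_x={cfg.step_x}",
        f"step_y={cfg.step_y}",
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def load_calibration(path: str | Path) -> tuple[PerspectiveParams, AutoSearchConfig]:
    kv: dict[str, float] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition("=")
        kv[key.strip()] = float(value)
    params = PerspectiveParams(kv["delta_x"], kv["delta_y"])
    cfg = AutoSearchConfig(
        n_top_maxima=int(kv.get("n_top_maxima", 10)),
        step_x=int(kv.get("step_x", 4)),
        step_y=int(kv.get("step_y", 8)),
    )
    return params, cfg
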