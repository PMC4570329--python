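"""Inter-frame registration and double-counting avoidance.

Consecutive images of the same (approximately planar) crop-row scene are
related by a homography H with x_t = H x_{t-1}.  For a camera translating
along the row without zoom, H is close to an affine homography whose
``h13`` entry is the horizontal image translation between the frames; the
frame overlap is then (W - |h13|) / W, and histogram peaks that fall in
the already-seen part of the current frame are flagged as duplicates so a
sequence total counts each plant once.

The keypoint detector backend is pluggable behind a uniform contract; the
default is ORB (FAST keypoints with Harris ranking and 256-bit binary
descriptors).  What the sequence logic consumes is only the fitted ``h13``
accuracy, not any particular descriptor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from skimage.feature import ORB
from skimage.measure import ransac as _ransac
from skimage.transform import ProjectiveTransform

from .counting import ImageCount, LocalMaxima, RegionOfInterest, count_single_image
from .geometry import PerspectiveParams
from .segmentation import SegmentationConfig

logger = logging.getLogger(__name__)

__all__ = [
    "RegistrationError",
    "DetectorConfig",
    "RansacConfig",
    "KeypointSet",
    "MatchSet",
    "Homography",
    "DoubleCountDecision",
    "PairRecord",
    "SequenceCount",
    "detect_and_describe",
    "match_descriptors",
    "filter_matches",
    "estimate_homography",
    "affine_validity",
    "estimate_overlap",
    "compute_buffer",
    "mark_double_counted",
    "register_pair",
    "count_sequence",
]


class RegistrationError(RuntimeError):
    """A frame pair could not be related (no features, matches or model)."""


@dataclass(frozen=True)
class DetectorConfig:
    """Keypoint detector settings.

    ``response_threshold`` plays the role of the detector's blob-response
    cutoff (the reference field configuration used a Hessian threshold of
    400 with a SURF detector); keypoints whose response falls below it are
    discarded.
    """

    backend: str = "orb"
    n_keypoints: int = 400
    fast_threshold: float = 0.08
    response_threshold: float = 0.0


@dataclass(frozen=True)
class RansacConfig:
    """Reproducible RANSAC settings for homography fitting."""

    seed: int = 0
    residual_threshold: float = 3.0
    max_trials: int = 2000


@dataclass(frozen=True)
class KeypointSet:
    """Detected keypoints: (x, y) positions, responses and descriptors."""

    positions: np.ndarray
    responses: np.ndarray
    descriptors: np.ndarray
    detector_name: str = "orb"

    def __len__(self) -> int:
        return len(self.positions)


@dataclass(frozen=True)
class MatchSet:
    """Descriptor correspondences between two keypoint sets."""

    indices: np.ndarray  # (m, 2) indices into (a, b)
    distances: np.ndarray
    src_xy: np.ndarray  # positions in the first (earlier) image
    dst_xy: np.ndarray  # positions in the second (later) image

    def __len__(self) -> int:
        return len(self.indices)


@dataclass(frozen=True)
class Homography:
    """Fitted 3x3 homography (h33 = 1) with its RANSAC inlier mask."""

    matrix: np.ndarray
    inliers: np.ndarray

    @property
    def h13(self) -> float:
        return float(self.matrix[0, 2])

    @property
    def n_inliers(self) -> int:
        return int(self.inliers.sum())


@dataclass(frozen=True)
class DoubleCountDecision:
    """Per-maximum duplicate/new flags for one frame."""

    duplicate: np.ndarray
    buffer: float
    h13: float

    @property
    def n_new(self) -> int:
        return int((~self.duplicate).sum())


@dataclass(frozen=True)
class PairRecord:
    """Registration outcome for one consecutive frame pair."""

    n_matches: int
    n_inliers: int
    matrix: np.ndarray | None
    h13: float
    affine_valid: bool
    overlap_pct: float
    fallback: bool
    decision: DoubleCountDecision | None = None


@dataclass
class SequenceCount:
    """Accumulated sequence result: total plus per-image and per-pair detail."""

    total: int
    image_counts: list[ImageCount]
    pair_records: list[PairRecord] = field(default_factory=list)


def _to_gray(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image, dtype=np.float64)
    if img.ndim == 3:
        img = img @ np.array([0.299, 0.587, 0.114])
    return img / 255.0


def detect_and_describe(image: np.ndarray, cfg: DetectorConfig | None = None) -> KeypointSet:
    """Detect keypoints and extract descriptors on one image.

    Returns an empty set (rather than raising) when the image has no
    usable structure; the caller decides how to fall back.
    """
    if cfg is None:
        cfg = DetectorConfig()
    if cfg.backend != "orb":
        raise ValueError(f"unknown detector backend {cfg.backend!r}")
    orb = ORB(n_keypoints=cfg.n_keypoints, fast_threshold=cfg.fast_threshold)
    try:
        orb.detect_and_extract(_to_gray(image))
    except RuntimeError:
        empty = np.empty((0, 2))
        return KeypointSet(empty, np.empty(0), np.empty((0, 256), dtype=bool), cfg.backend)
    positions = orb.keypoints[:, ::-1].astype(np.float64)  # (row, col) -> (x, y)
    responses = np.asarray(orb.responses, dtype=np.float64)
    keep = responses >= cfg.response_threshold
    return KeypointSet(positions[keep], responses[keep], orb.descriptors[keep], cfg.backend)


def match_descriptors(a: KeypointSet, b: KeypointSet, mode: str = "exact") -> MatchSet:
    """Nearest-neighbour matching of binary descriptors by Hamming distance.

    ``"exact"`` does an exhaustive search; ``"tree"`` queries a k-d tree on
    the raw bit vectors (squared Euclidean distance between 0/1 vectors
    equals Hamming distance, so the tree returns the same neighbours up to
    ties).
    """
    if len(a) == 0 or len(b) == 0:
        raise RegistrationError("no descriptors to match")
    da = np.asarray(a.descriptors, dtype=bool)
    db = np.asarray(b.descriptors, dtype=bool)
    if mode == "exact":
        dist_matrix = (da[:, None, :] ^ db[None, :, :]).sum(axis=2)
        nn = dist_matrix.argmin(axis=1)
        dists = dist_matrix[np.arange(len(da)), nn].astype(np.float64)
    elif mode == "tree":
        tree = cKDTree(db.astype(np.float64))
        d2, nn = tree.query(da.astype(np.float64), k=1)
        dists = d2.astype(np.float64) ** 2  # squared Euclidean == Hamming on bits
    else:
        raise ValueError(f"unknown matching mode {mode!r}")
    indices = np.column_stack([np.arange(len(da)), nn])
    return MatchSet(
        indices=indices,
        distances=np.round(dists),
        src_xy=a.positions[indices[:, 0]],
        dst_xy=b.positions[indices[:, 1]],
    )


def filter_matches(matches: MatchSet, k: float = 3.0, eps: float = 1e-9) -> MatchSet:
    """Keep "good" matches: distance strictly below k times the minimum distance.

    The minimum is floored at ``eps`` so that perfect (distance-0) matches
    survive.  With k > 1 the best match is always retained.
    """
    if len(matches) == 0:
        raise RegistrationError("no matches to filter: frames cannot be related")
    threshold = k * max(float(matches.distances.min()), eps)
    keep = matches.distances < threshold
    if not keep.any():
        raise RegistrationError("all matches filtered out: frames cannot be related")
    return MatchSet(
        indices=matches.indices[keep],
        distances=matches.distances[keep],
        src_xy=matches.src_xy[keep],
        dst_xy=matches.dst_xy[keep],
    )


def estimate_homography(matches: MatchSet, cfg: RansacConfig | None = None) -> Homography:
    """RANSAC homography fit x_t = H x_{t-1}; h33 normalised to 1.

    Minimises the reprojection error over consensus inliers with a fixed
    seed so repeated runs give identical matrices.
    """
    if cfg is None:
        cfg = RansacConfig()
    if len(matches) < 4:
        raise RegistrationError(f"need >= 4 matches for a homography, got {len(matches)}")
    model, inliers = _ransac(
        (matches.src_xy, matches.dst_xy),
        ProjectiveTransform,
        min_samples=4,
        residual_threshold=cfg.residual_threshold,
        max_trials=cfg.max_trials,
        rng=cfg.seed,
    )
    if model is None or inliers is None or inliers.sum() < 4:
        raise RegistrationError("homography estimation failed (degenerate correspondences)")
    matrix = model.params
    if not np.all(np.isfinite(matrix)) or abs(matrix[2, 2]) < 1e-12:
        raise RegistrationError("homography estimation produced a singular matrix")
    return Homography(matrix=matrix / matrix[2, 2], inliers=np.asarray(inliers, dtype=bool))


def affine_validity(matrix: np.ndarray, tol_p: float = 1e-3, tol_s: float = 0.1) -> bool:
    """Is the homography consistent with along-row camera translation?

    Requires a near-affine bottom row (|h31|, |h32| <= tol_p,
    |h33 - 1| <= tol_p) and near-unit scaling (|h11 - 1|, |h22 - 1| <=
    tol_s), since the camera neither zooms nor approaches the row.
    """
    m = np.asarray(matrix, dtype=np.float64)
    return bool(
        abs(m[2, 0]) <= tol_p
        and abs(m[2, 1]) <= tol_p
        and abs(m[2, 2] - 1.0) <= tol_p
        and abs(m[0, 0] - 1.0) <= tol_s
        and abs(m[1, 1] - 1.0) <= tol_s
    )


def estimate_overlap(h13: float, width: int) -> float:
    """Consecutive-frame overlap from the x-translation, as a percentage."""
    return 100.0 * max(0.0, width - abs(h13)) / width


def compute_buffer(maxima: LocalMaxima, width: int, default_fraction: float = 1 / 20) -> float:
    """Border buffer b: half the mean gap between neighbouring maxima.

    The buffer absorbs peak-localisation error near the image borders
    (lens distortion makes border plants less straight).  With a single
    maximum there is no gap to average, so b falls back to
    ``default_fraction * width`` (W/20 by default).
    """
    n = len(maxima)
    if n == 0:
        raise ValueError("cannot compute a buffer from an empty maxima set")
    if n == 1:
        return default_fraction * width
    return float(np.diff(np.sort(maxima.positions)).mean() / 2.0)


def mark_double_counted(
    maxima: LocalMaxima, h13: float, buffer: float, width: int
) -> DoubleCountDecision:
    """Flag maxima lying in the region already covered by the previous frame.

    For h13 > 0 (content moved right) a maximum at i is a duplicate iff
    i - b > h13; for h13 <= 0 (content moved left, the forward-travel
    case) iff i + b < W + h13.  Every maximum gets exactly one flag.
    """
    if buffer < 0:
        raise ValueError("buffer must be >= 0")
    pos = np.asarray(maxima.positions, dtype=np.float64)
    if h13 > 0:
        duplicate = pos - buffer > h13
    else:
        duplicate = pos + buffer < width + h13
    return DoubleCountDecision(duplicate=duplicate, buffer=float(buffer), h13=float(h13))


def register_pair(
    prev_image: np.ndarray,
    curr_image: np.ndarray,
    det_cfg: DetectorConfig | None = None,
    ransac_cfg: RansacConfig | None = None,
    match_mode: str = "exact",
    filter_k: float = 3.0,
) -> Homography:
    """Detect, match, filter and fit the homography for one frame pair."""
    kp_prev = detect_and_describe(prev_image, det_cfg)
    kp_curr = detect_and_describe(curr_image, det_cfg)
    matches = filter_matches(match_descriptors(kp_prev, kp_curr, mode=match_mode), k=filter_k)
    return estimate_homography(matches, ransac_cfg)


def count_sequence(
    images: list[np.ndarray],
    params: PerspectiveParams,
    seg_cfg: SegmentationConfig | None = None,
    roi: RegionOfInterest | None = None,
    det_cfg: DetectorConfig | None = None,
    ransac_cfg: RansacConfig | None = None,
    nominal_overlap_pct: float = 60.0,
) -> SequenceCount:
    """Count distinct plants across an ordered overlapping image sequence.

    The first image contributes all of its histogram maxima; every later
    image contributes only the maxima not flagged as duplicates given the
    homography fitted against its predecessor.  A pair that cannot be
    registered (or whose homography is not affine-valid) falls back to the
    configured nominal overlap: h13 = -(W * (1 - nominal/100)); the
    failure is logged and processing continues.
    """
    if len(images) == 0:
        raise ValueError("need at least one image")
    if seg_cfg is None:
        seg_cfg = SegmentationConfig()
    width = np.asarray(images[0]).shape[1]
    image_counts = [count_single_image(im, params, seg_cfg, roi) for im in images]
    total = image_counts[0].n_plants
    pair_records: list[PairRecord] = []
    fallback_h13 = -(width * (1.0 - nominal_overlap_pct / 100.0))

    for t in range(1, len(images)):
        matrix = None
        n_matches = n_inliers = 0
        fallback = False
        try:
            kp_prev = detect_and_describe(images[t - 1], det_cfg)
            kp_curr = detect_and_describe(images[t], det_cfg)
            matches = filter_matches(match_descriptors(kp_prev, kp_curr))
            n_matches = len(matches)
            hom = estimate_homography(matches, ransac_cfg)
            matrix = hom.matrix
            n_inliers = hom.n_inliers
            if affine_validity(matrix):
                h13 = hom.h13
            else:
                logger.warning(
                    "pair %d->%d: homography not affine-valid, using nominal overlap", t - 1, t
                )
                fallback = True
                h13 = fallback_h13
        except RegistrationError as exc:
            logger.warning("pair %d->%d: registration failed (%s), using nominal overlap",
                           t - 1, t, exc)
            fallback = True
            h13 = fallback_h13

        maxima = image_counts[t].maxima
        if len(maxima) > 0:
            buffer = compute_buffer(maxima, width)
            decision = mark_double_counted(maxima, h13, buffer, width)
            total += decision.n_new
        else:
            decision = DoubleCountDecision(
                duplicate=np.zeros(0, dtype=bool), buffer=0.0, h13=float(h13)
            )
        pair_records.append(
            PairRecord(
                n_matches=n_matches,
                n_inliers=n_inliers,
                matrix=matrix,
                h13=float(h13),
                affine_valid=not fallback,
                overlap_pct=estimate_overlap(h13, width),
                fallback=fallback,
                decision=decision,
            )
        )
    return SequenceCount(total=total, image_counts=image_counts, pair_records=pair_records)
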