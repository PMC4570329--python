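"""Synthetic nursery-row scenes with full ground truth.

Renders crop-row images that emulate the conditions of an outdoor seedling
nursery imaged obliquely from a moving vehicle: juvenile trees at roughly
10 cm in-row spacing drawn as clusters of green leaf ellipses around a
stem, a textured soil background (mottling plus pebbles, which also gives
keypoint detectors something to lock onto), optional shadow patches,
weakly green surface residue, non-green background objects, and a
position-dependent plant lean that mimics camera perspective.  A whole
virtual row can be rendered once and cropped into an overlapping frame
sequence with exactly known inter-frame translation.

The scale convention is ~6 px per cm at the row: 10 cm plant spacing is
60 px, and the 40 cm maximum plant height is 240 px.

All randomness flows from the single integer seed in the spec through one
generator instance, so a fixed spec renders byte-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from skimage.draw import ellipse as draw_ellipse

from .geometry import PerspectiveParams

__all__ = ["ShadowPatch", "SceneSpec", "SceneTruth", "render_scene", "render_sequence"]

#: Pixels per centimetre at the crop row (640 px spanning roughly 1 m).
PX_PER_CM = 6.0

#: Maximum plant height the system targets, px ("40 cm").
MAX_PLANT_HEIGHT_PX = 40.0 * PX_PER_CM


@dataclass(frozen=True)
class ShadowPatch:
    """Axis-aligned shadow rectangle; pixel brightness is multiplied by
    ``darkening`` inside it (plants included, as in the field)."""

    x: int
    y: int
    width: int
    height: int
    darkening: float = 0.55


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of a rendered nursery-row scene.

    Defaults describe the nominal study conditions: ten plants per
    640 x 480 frame at 60 px (~10 cm) spacing, 150 px (~25 cm) tall with a
    36 px (~6 cm) canopy, on bare soil with mild sensor noise and no
    shadows, residue or background clutter.
    """

    n_plants: int = 10
    spacing: float = 60.0
    plant_height: float = 150.0
    canopy_width: float = 36.0
    tilt_deg: float = 0.0
    width: int = 640
    height: int = 480
    soil_rgb: tuple[int, int, int] = (135, 92, 70)
    noise_sigma: float = 2.5
    shadows: tuple[ShadowPatch, ...] = ()
    residue_density: float = 0.0
    n_background_objects: int = 0
    undersized_fraction: float = 0.0
    occluded_pairs: int = 0
    margin: float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_plants < 0:
            raise ValueError(f"n_plants must be >= 0, got {self.n_plants}")
        if not 0 <= self.residue_density < 0.1:
            raise ValueError(f"residue_density must be in [0, 0.1), got {self.residue_density}")
        if self.plant_height > MAX_PLANT_HEIGHT_PX:
            raise ValueError(
                f"plant_height {self.plant_height} px exceeds the {MAX_PLANT_HEIGHT_PX:.0f} px "
                f"(40 cm) design maximum"
            )
        if not 0 <= self.undersized_fraction <= 1:
            raise ValueError("undersized_fraction must be in [0, 1]")
        if self.occluded_pairs < 0 or 2 * self.occluded_pairs > self.n_plants:
            raise ValueError("occluded_pairs needs two plants per pair")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


@dataclass
class SceneTruth:
    """Ground truth of a rendered scene or frame sequence.

    For sequences, ``stem_x`` and ``labels`` are in virtual-row
    coordinates, ``frame_offsets`` holds each frame's left edge, and
    ``overlap`` is the true consecutive-frame overlap fraction.
    """

    stem_x: np.ndarray
    labels: np.ndarray = field(repr=False)
    n_plants: int
    tilt_deg: float
    straightening: PerspectiveParams
    frame_offsets: np.ndarray | None = None
    translation: float | None = None
    overlap: float | None = None
    distinct_total: int | None = None

    def plants_in_frame(self, frame_index: int, frame_width: int) -> np.ndarray:
        """Stem x-positions (frame coordinates) whose base lies in a frame."""
        if self.frame_offsets is None:
            raise ValueError("not a sequence truth")
        off = self.frame_offsets[frame_index]
        inside = (self.stem_x >= off) & (self.stem_x < off + frame_width)
        return self.stem_x[inside] - off

    def first_entry_counts(self, frame_width: int) -> np.ndarray:
        """Per-frame number of plants whose stem base is seen for the first time."""
        if self.frame_offsets is None:
            raise ValueError("not a sequence truth")
        counts = np.zeros(len(self.frame_offsets), dtype=int)
        for x in self.stem_x:
            for f, off in enumerate(self.frame_offsets):
                if off <= x < off + frame_width:
                    counts[f] += 1
                    break
        return counts


def _expected_straightening(spec: SceneSpec) -> PerspectiveParams:
    """Straightening parameters that undo the rendered perspective lean.

    The lean field puts a shear of ``tan(tilt) * (x - cx) / cx`` on a plant
    based at x; the trapezoid warp with horizontal shift ``delta_x`` tilts
    a vertical line at x by ``4 * delta_x * (x - cx) / ((W - 1) * H)`` per
    unit height, so the two cancel at ``delta_x = H * tan(tilt) / 2``.
    """
    dx = spec.height * math.tan(math.radians(spec.tilt_deg)) / 2.0
    dx = min(dx, spec.width / 4.0)
    return PerspectiveParams(delta_x=float(dx), delta_y=0.0)


def _soil_background(spec: SceneSpec, width: int, rng: np.random.Generator) -> np.ndarray:
    """Soil with low-frequency mottling and scattered pebbles.

    Brightness variations scale all three channels together, so soil keeps
    its negative excess-green index everywhere.
    """
    h = spec.height
    soil = np.asarray(spec.soil_rgb, dtype=np.float64)
    coarse = rng.uniform(0.9, 1.1, size=(h // 24 + 2, width // 24 + 2))
    yy = np.linspace(0, coarse.shape[0] - 1.001, h)
    xx = np.linspace(0, coarse.shape[1] - 1.001, width)
    from scipy.ndimage import map_coordinates

    grid_y, grid_x = np.meshgrid(yy, xx, indexing="ij")
    mottle = map_coordinates(coarse, [grid_y, grid_x], order=1)
    image = soil[None, None, :] * mottle[..., None]

    n_pebbles = int(width * h / 700)
    pr = rng.uniform(1.0, 3.0, n_pebbles)
    py = rng.uniform(0, h - 1, n_pebbles)
    px = rng.uniform(0, width - 1, n_pebbles)
    pf = rng.uniform(0.65, 1.35, n_pebbles)
    for r, y, x, f in zip(pr, py, px, pf):
        rr, cc = draw_ellipse(y, x, r, r * rng.uniform(0.7, 1.4), shape=(h, width))
        image[rr, cc] = soil * f
    return image


def _add_residue(image: np.ndarray, spec: SceneSpec, width: int, rng: np.random.Generator) -> None:
    """Sprinkle small, weakly green residue speckles over the background.

    Residue is given an excess-green index drawn from [0, 18] — green
    enough to be visibly distinct from soil but safely below the ExG
    threshold of 40, as dry plant residue is in the field.
    """
    h = spec.height
    target_area = spec.residue_density * width * h
    area = 0.0
    while area < target_area:
        r = rng.uniform(1.0, 3.0)
        y = rng.uniform(0, h - 1)
        x = rng.uniform(0, width - 1)
        exg_target = rng.uniform(0.0, 18.0)
        brightness = rng.uniform(0.8, 1.2)
        base = np.asarray(spec.soil_rgb, dtype=np.float64) * brightness
        green = (base[0] + base[2] + exg_target) / 2.0
        color = np.array([base[0], green, base[2]])
        rr, cc = draw_ellipse(y, x, r, r * rng.uniform(0.7, 1.3), shape=(h, width))
        image[rr, cc] = color
        area += math.pi * r * r


def _add_background_objects(
    image: np.ndarray, spec: SceneSpec, width: int, rng: np.random.Generator
) -> None:
    """Non-green clutter (stakes, tools, stones) in the upper image band."""
    h = spec.height
    palette = [(92, 92, 118), (150, 140, 135), (60, 55, 52), (160, 60, 50)]
    for _ in range(spec.n_background_objects):
        ow = int(rng.integers(8, 40))
        oh = int(rng.integers(6, 25))
        x0 = int(rng.integers(0, max(1, width - ow)))
        y0 = int(rng.integers(0, max(1, h // 4)))
        color = palette[int(rng.integers(0, len(palette)))]
        image[y0 : y0 + oh, x0 : x0 + ow] = np.asarray(color, dtype=np.float64)


def _draw_plant(
    image: np.ndarray,
    labels: np.ndarray,
    label: int,
    base_x: float,
    base_y: float,
    height_px: float,
    canopy_width: float,
    shear: float,
    rng: np.random.Generator,
) -> None:
    h, w = labels.shape
    # stem: a narrow green column following the lean
    stem_color = np.array([80.0, 125.0, 60.0])
    for dy in range(int(height_px)):
        y = int(round(base_y - dy))
        x = int(round(base_x + shear * dy))
        if 0 <= y < h:
            x0, x1 = max(0, x - 1), min(w, x + 2)
            if x0 < x1:
                image[y, x0:x1] = stem_color
                labels[y, x0:x1] = label
    # leaves: ellipses clustered along the upper three quarters of the stem
    n_leaves = int(rng.integers(9, 15))
    for _ in range(n_leaves):
        t = rng.uniform(0.25, 1.0)
        cy = base_y - t * height_px + rng.normal(0, height_px / 12)
        cx = base_x + shear * t * height_px + rng.normal(0, canopy_width / 7)
        ry = rng.uniform(canopy_width / 10, canopy_width / 6)
        rx = rng.uniform(canopy_width / 7, canopy_width / 4)
        color = np.array(
            [
                rng.uniform(45, 75),
                rng.uniform(125, 160),
                rng.uniform(40, 70),
            ]
        )
        rr, cc = draw_ellipse(cy, cx, ry, rx, shape=(h, w), rotation=rng.uniform(-0.8, 0.8))
        image[rr, cc] = color
        labels[rr, cc] = label


def _render(spec: SceneSpec, width: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Render a scene of the given width; returns (image, labels, stem_x)."""
    if spec.n_plants > 0:
        span = spec.margin + (spec.n_plants - 1) * spec.spacing + spec.margin
        if span > width:
            raise ValueError(
                f"{spec.n_plants} plants at spacing {spec.spacing} px do not fit in "
                f"a {width} px frame with {spec.margin} px margins"
            )
    rng = np.random.default_rng(spec.seed)
    h = spec.height
    image = _soil_background(spec, width, rng)
    if spec.n_background_objects:
        _add_background_objects(image, spec, width, rng)
    if spec.residue_density > 0:
        _add_residue(image, spec, width, rng)

    labels = np.zeros((h, width), dtype=np.int32)
    cx = (width - 1) / 2.0
    max_shear = math.tan(math.radians(spec.tilt_deg))
    stem_x = np.empty(spec.n_plants, dtype=np.float64)
    for i in range(spec.n_plants):
        stem_x[i] = spec.margin + i * spec.spacing + rng.uniform(-3, 3)
    # foliage occlusion: pull the second plant of each designated pair to
    # half a canopy width from its neighbour (50% canopy overlap)
    for k in range(spec.occluded_pairs):
        stem_x[2 * k + 1] = stem_x[2 * k] + spec.canopy_width / 2.0
    for i in range(spec.n_plants):
        x = stem_x[i]
        base_y = h - 30 + rng.uniform(-5, 5)
        height_px = spec.plant_height * rng.uniform(0.75, 1.0)
        if rng.uniform() < spec.undersized_fraction:
            height_px *= 0.4
        shear = max_shear * (x - cx) / cx if cx > 0 else 0.0
        _draw_plant(
            image, labels, i + 1, x, base_y, height_px, spec.canopy_width, shear, rng
        )

    for patch in spec.shadows:
        y0, y1 = max(0, patch.y), min(h, patch.y + patch.height)
        x0, x1 = max(0, patch.x), min(width, patch.x + patch.width)
        image[y0:y1, x0:x1] *= patch.darkening

    if spec.noise_sigma > 0:
        image = image + rng.normal(0, spec.noise_sigma, image.shape)
    image = np.clip(image, 0, 255).astype(np.uint8)
    return image, labels, stem_x


def render_scene(spec: SceneSpec) -> tuple[np.ndarray, SceneTruth]:
    """Render one frame and its ground truth."""
    image, labels, stem_x = _render(spec, spec.width)
    truth = SceneTruth(
        stem_x=stem_x,
        labels=labels,
        n_plants=spec.n_plants,
        tilt_deg=spec.tilt_deg,
        straightening=_expected_straightening(spec),
    )
    return image, truth


def render_sequence(
    spec: SceneSpec, n_frames: int, translation: int
) -> tuple[list[np.ndarray], SceneTruth]:
    """Render a long virtual row once and crop an overlapping frame sequence.

    Frames are ``spec.width``-wide crops whose left edge advances by
    ``translation`` px per frame, so the true consecutive-frame overlap is
    ``(W - translation) / W`` and the scene content shifts *left* by
    ``translation`` px from one frame to the next.  Plants are spread over
    the whole virtual row; ``distinct_total`` is the row's plant count.
    """
    if n_frames < 1:
        raise ValueError("need at least one frame")
    translation = int(translation)
    if not 0 <= translation < spec.width:
        raise ValueError(f"translation must be in [0, frame width), got {translation}")
    row_width = spec.width + (n_frames - 1) * translation
    image, labels, stem_x = _render(spec, row_width)
    offsets = np.arange(n_frames) * translation
    frames = [np.ascontiguousarray(image[:, o : o + spec.width]) for o in offsets]
    truth = SceneTruth(
        stem_x=stem_x,
        labels=labels,
        n_plants=spec.n_plants,
        tilt_deg=spec.tilt_deg,
        straightening=_expected_straightening(spec),
        frame_offsets=offsets,
        translation=float(translation),
        overlap=(spec.width - translation) / spec.width,
        distinct_total=spec.n_plants,
    )
    return frames, truth


def counting_roi(spec: SceneSpec) -> "RegionOfInterest":
    """The ROI a field operator would draw for this scene's row.

    The de-duplication buffer b is half the plant spacing, and its border
    rule assumes plants are not reliably detected in the last b columns of
    a frame.  Histogram smoothing lets a plant register while its stem is
    up to about 1.5 sigma beyond the ROI edge, so trimming a horizontal
    margin of b - 1.5 sigma from both sides puts the detectability cutoff
    right at W - b: a plant is first counted in the frame where it leaves
    the buffer band, once and only once.
    """
    from .counting import RegionOfInterest
    from .segmentation import SegmentationConfig

    reach = round(1.5 * SegmentationConfig().hist_sigma)
    margin = max(0, int(spec.spacing / 2) - reach)
    return RegionOfInterest(margin, spec.width - margin, 0, spec.height)


def sequence_spec_for_overlap(
    base: SceneSpec, n_frames: int, overlap_fraction: float, fill_spacing: float | None = None
) -> tuple[SceneSpec, int]:
    """Helper: translation for a target overlap, with plants spread to fill.

    Returns a spec whose plant count fills the virtual row at
    ``fill_spacing`` (default: the base spec's spacing) and the integer
    per-frame translation realising the requested overlap fraction.
    """
    translation = int(round(base.width * (1.0 - overlap_fraction)))
    row_width = base.width + (n_frames - 1) * translation
    spacing = base.spacing if fill_spacing is None else fill_spacing
    n = int((row_width - 2 * base.margin) // spacing) + 1
    return replace(base, n_plants=n, spacing=spacing), translation
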