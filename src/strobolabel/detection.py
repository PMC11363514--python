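"""HSB color filtering and marker centroid localization on UV frames.

Each paw carries a fluorescent ink of a distinct color, visible only under
UV illumination.  Detection proceeds per color: threshold the frame in
hue–saturation–brightness space (hue is angular, so bounds may wrap
through 0°), restrict the result to one camera view with a binary mask
(direct wheel-surface view vs. the 45° mirror view), then take the
centroid of the largest sufficiently large connected component.  Four ink
colors × two views encode the eight keypoints.

HSB convention throughout: hue in degrees [0, 360), saturation and
brightness in [0, 1], independent of any library's internal scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

import imageio.v3 as iio
import numpy as np
from skimage import color as skcolor
from skimage import measure, morphology

from .frames import Frame, Modality

VIEW_NAMES = ("bottom", "side")

#: minimum component area in pixels; rejects single-pixel chroma noise
DEFAULT_MIN_AREA = 9
#: second-largest / largest area ratio at or above which a detection is ambiguous
AMBIGUITY_RATIO = 0.5


@dataclass(frozen=True)
class HSBBounds:
    """Per-color lower/upper hue-saturation-brightness bounds.

    ``lower`` and ``upper`` are (hue°, saturation, brightness) triples.
    Saturation and brightness satisfy lower ≤ upper; the hue interval may
    wrap: lower hue > upper hue means the interval passes through 0°
    (e.g. [350°, 10°] covers red hues around zero).
    """

    color_name: str
    lower: tuple[float, float, float]
    upper: tuple[float, float, float]

    def __post_init__(self) -> None:
        for i, name in ((1, "saturation"), (2, "brightness")):
            lo, hi = self.lower[i], self.upper[i]
            if not (0.0 <= lo <= hi <= 1.0):
                raise ValueError(
                    f"{self.color_name}: {name} bounds [{lo}, {hi}] invalid "
                    "(need 0 ≤ lower ≤ upper ≤ 1)"
                )
        for h in (self.lower[0], self.upper[0]):
            if not (0.0 <= h < 360.0):
                raise ValueError(f"{self.color_name}: hue {h} outside [0, 360)")

    @property
    def wraps(self) -> bool:
        return self.lower[0] > self.upper[0]

    def contains(self, h: float, s: float, v: float) -> bool:
        """Scalar membership test (hue wrap-aware); the vectorized filter
        in :func:`filter_color` must agree with this pixel-by-pixel."""
        lo_h, lo_s, lo_v = self.lower
        hi_h, hi_s, hi_v = self.upper
        if not (lo_s <= s <= hi_s and lo_v <= v <= hi_v):
            return False
        if self.wraps:
            return h >= lo_h or h <= hi_h
        return lo_h <= h <= hi_h


class ViewMaskSet:
    """Named disjoint binary masks, one per camera view.

    The wheel position is fixed relative to the camera, so static masks
    separate the direct bottom view from the mirror side view.  Masks must
    be pairwise disjoint and non-empty, and match the frame geometry.
    """

    def __init__(self, masks: Mapping[str, np.ndarray]):
        self.masks: dict[str, np.ndarray] = {}
        shape: tuple[int, ...] | None = None
        for name, mask in masks.items():
            mask = np.asarray(mask).astype(bool)
            if mask.ndim != 2:
                raise ValueError(f"view mask {name!r} must be 2-D, got shape {mask.shape}")
            if shape is None:
                shape = mask.shape
            elif mask.shape != shape:
                raise ValueError("view masks must share one shape")
            if not mask.any():
                raise ValueError(f"view mask {name!r} is empty")
            self.masks[name] = mask
        names = list(self.masks)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                if (self.masks[a] & self.masks[b]).any():
                    raise ValueError(f"view masks {a!r} and {b!r} overlap")

    @classmethod
    def from_files(cls, paths: Mapping[str, str | Path]) -> "ViewMaskSet":
        """Load masks from image files; any nonzero pixel is a member."""
        masks = {}
        for name, p in paths.items():
            img = iio.imread(p)
            if img.ndim == 3:
                img = img.max(axis=-1)
            masks[name] = img > 0
        return cls(masks)

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.masks.values())).shape

    def items(self):
        return self.masks.items()


class DetectionStatus(Enum):
    FOUND = "found"
    MISSING = "missing"
    AMBIGUOUS = "ambiguous"


@dataclass
class MarkerDetection:
    """One color × view localization result.

    ``centroid`` is (x, y) in subpixel image coordinates (x rightward,
    y downward); the unweighted mean of member-pixel coordinates of the
    selected component.  AMBIGUOUS still carries the largest component's
    centroid but flags that a competing blob of at least half its area
    exists.  MISSING has centroid None.
    """

    color_name: str
    view_name: str
    centroid: tuple[float, float] | None
    area: int
    n_components: int
    status: DetectionStatus


def rgb_to_hsb(image: np.ndarray) -> np.ndarray:
    """Convert an H×W×3 uint8 RGB image to HSB with hue in degrees [0,360)
    and saturation/brightness in [0, 1]."""
    hsv = skcolor.rgb2hsv(image)
    hsv[..., 0] = (hsv[..., 0] * 360.0) % 360.0
    return hsv


def filter_color(image: np.ndarray, bounds: HSBBounds) -> np.ndarray:
    """Binary mask of pixels whose HSB value lies within ``bounds``.

    Hue membership honors wrap-around: with lower hue 350° and upper hue
    10°, a pixel at 5° is inside and one at 180° is outside.
    """
    if image.ndim != 3 or image.shape[-1] != 3:
        raise ValueError(f"expected H×W×3 color image, got shape {image.shape}")
    return _hsb_membership(rgb_to_hsb(image), bounds)


def _hsb_membership(hsb: np.ndarray, bounds: HSBBounds) -> np.ndarray:
    h, s, v = hsb[..., 0], hsb[..., 1], hsb[..., 2]
    lo_h, lo_s, lo_v = bounds.lower
    hi_h, hi_s, hi_v = bounds.upper
    sv_ok = (s >= lo_s) & (s <= hi_s) & (v >= lo_v) & (v <= hi_v)
    if bounds.wraps:
        h_ok = (h >= lo_h) | (h <= hi_h)
    else:
        h_ok = (h >= lo_h) & (h <= hi_h)
    return sv_ok & h_ok


def apply_view_mask(mask: np.ndarray, view: np.ndarray) -> np.ndarray:
    """Elementwise conjunction of a color mask with a view mask."""
    mask = np.asarray(mask, dtype=bool)
    view = np.asarray(view, dtype=bool)
    if mask.shape != view.shape:
        raise ValueError(f"mask shape {mask.shape} != view shape {view.shape}")
    return mask & view


def detect_marker(
    mask: np.ndarray,
    min_area: int = DEFAULT_MIN_AREA,
    color_name: str = "",
    view_name: str = "",
) -> MarkerDetection:
    """Locate one marker in a binary mask by connected-component analysis.

    Components (8-connectivity) with area ≥ ``min_area`` are candidates.
    With no candidate the status is MISSING.  Otherwise the largest is
    selected and its unweighted centroid returned; ties on area are broken
    by the smaller (y, then x) centroid for determinism.  If the runner-up
    candidate holds at least half the winner's area the status is
    AMBIGUOUS (the winner's centroid is still reported).
    """
    mask = np.asarray(mask, dtype=bool)
    labels = measure.label(mask, connectivity=2)
    props = measure.regionprops(labels)
    candidates = [p for p in props if p.area >= min_area]
    if not candidates:
        return MarkerDetection(color_name, view_name, None, 0, 0, DetectionStatus.MISSING)
    # sort: area desc, then centroid (y, x) asc for the equal-area tie-break
    candidates.sort(key=lambda p: (-p.area, p.centroid[0], p.centroid[1]))
    best = candidates[0]
    cy, cx = best.centroid
    status = DetectionStatus.FOUND
    if len(candidates) > 1 and candidates[1].area >= AMBIGUITY_RATIO * best.area:
        status = DetectionStatus.AMBIGUOUS
    return MarkerDetection(
        color_name, view_name, (float(cx), float(cy)), int(best.area),
        len(candidates), status,
    )


def detect_all(
    uv: Frame,
    color_specs: Sequence[HSBBounds],
    views: ViewMaskSet,
    min_area: int = DEFAULT_MIN_AREA,
    opening: bool = False,
) -> list[MarkerDetection]:
    """Detect every color in every view of one UV frame.

    Returns exactly len(colors) × len(views) detections in a fixed
    (color, view) order; deterministic given identical inputs.  The
    optional 3×3 morphological opening (off by default) suppresses
    speckle before component analysis.
    """
    if uv.modality is not Modality.UV:
        raise ValueError(f"frame {uv.index} is not a UV frame")
    detections: list[MarkerDetection] = []
    hsb = rgb_to_hsb(uv.pixels)  # one conversion shared by all colors
    for bounds in color_specs:
        cmask = _hsb_membership(hsb, bounds)
        if opening:
            cmask = morphology.binary_opening(cmask, morphology.footprint_rectangle((3, 3)))
        for view_name, vmask in views.items():
            detections.append(
                detect_marker(
                    apply_view_mask(cmask, vmask), min_area,
                    color_name=bounds.color_name, view_name=view_name,
                )
            )
    return detections
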