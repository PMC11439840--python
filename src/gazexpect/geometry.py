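"""Screen and region-of-interest geometry.

The experiments present face stimuli on a fixed monitor viewed from a chin
rest, so all conversions between pixel extents and degrees of visual angle
are static properties of the setup.  Gaze analysis then reduces to asking
which labelled rectangle (facial-feature ROI, prior corner, face box, screen
centre) a pixel coordinate falls into.

Conventions
-----------
* pixel coordinates: origin at the top-left of the screen, x rightward,
  y downward, 0-based;
* rectangles are half-open: a point belongs to ``[x, x + w) x [y, y + h)``,
  so shared edges are unambiguous;
* one ROI label may own several disjoint rectangles (the "ears" feature is
  split across the two sides of the face but counts as a single region).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import yaml

__all__ = [
    "ScreenGeometry",
    "Rect",
    "ROISet",
    "FEATURE_LABELS",
    "CORNER_LABELS",
    "px_to_deg",
    "deg_to_px",
    "classify_point",
    "build_default_roiset",
    "load_roi_config",
]

#: The four facial-feature regions, one per learned identity.
FEATURE_LABELS = ("forehead", "chin", "ears", "nose")

#: Screen corners where the name prior can appear.
CORNER_LABELS = ("top_left", "top_right", "bottom_left", "bottom_right")


@dataclass(frozen=True)
class ScreenGeometry:
    """Physical monitor model used for pixel <-> visual-angle conversion.

    Defaults describe a 41.0 x 31.0 cm display at 1600 x 1200 px viewed
    from 560 mm.
    """

    width_mm: float = 410.0
    height_mm: float = 310.0
    width_px: int = 1600
    height_px: int = 1200
    viewing_distance_mm: float = 560.0

    def __post_init__(self) -> None:
        for name in ("width_mm", "height_mm", "width_px", "height_px",
                     "viewing_distance_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"ScreenGeometry.{name} must be > 0")

    def mm_per_px(self, axis: str) -> float:
        if axis == "x":
            return self.width_mm / self.width_px
        if axis == "y":
            return self.height_mm / self.height_px
        raise ValueError(f"axis must be 'x' or 'y', got {axis!r}")


def px_to_deg(extent_px: float, axis: str, screen: ScreenGeometry) -> float:
    """Convert a pixel extent (centred on the line of sight) to degrees.

    Uses the full arctangent form
    ``angle = 2 * atan(extent_mm / (2 * distance))``.
    """
    if extent_px < 0:
        raise ValueError("extent_px must be >= 0")
    extent_mm = extent_px * screen.mm_per_px(axis)
    return math.degrees(2.0 * math.atan2(extent_mm, 2.0 * screen.viewing_distance_mm))


def deg_to_px(extent_deg: float, axis: str, screen: ScreenGeometry) -> float:
    """Inverse of :func:`px_to_deg`."""
    if extent_deg < 0:
        raise ValueError("extent_deg must be >= 0")
    extent_mm = 2.0 * screen.viewing_distance_mm * math.tan(math.radians(extent_deg) / 2.0)
    return extent_mm / screen.mm_per_px(axis)


@dataclass(frozen=True)
class Rect:
    """Axis-aligned rectangle in pixel coordinates, half-open."""

    x: float
    y: float
    w: float
    h: float

    def __post_init__(self) -> None:
        if self.w <= 0 or self.h <= 0:
            raise ValueError("Rect width/height must be > 0")

    @property
    def area(self) -> float:
        return self.w * self.h

    def contains(self, px: float, py: float) -> bool:
        return self.x <= px < self.x + self.w and self.y <= py < self.y + self.h

    def center(self) -> tuple[float, float]:
        return (self.x + self.w / 2.0, self.y + self.h / 2.0)

    def intersects(self, other: "Rect") -> bool:
        return (self.x < other.x + other.w and other.x < self.x + self.w
                and self.y < other.y + other.h and other.y < self.y + self.h)


@dataclass
class ROISet:
    """Labelled screen regions: feature ROIs plus auxiliary regions.

    ``features`` maps each of the four feature labels to one or more
    rectangles; the four labels must cover identical total areas and be
    pairwise disjoint, and every feature rectangle must lie inside
    ``face_bbox``.
    """

    screen: ScreenGeometry
    features: dict[str, tuple[Rect, ...]]
    corners: dict[str, Rect]
    face_bbox: Rect
    center: Rect
    extras: dict[str, tuple[Rect, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.features) != set(FEATURE_LABELS):
            raise ValueError(
                f"feature labels must be exactly {FEATURE_LABELS}, got {sorted(self.features)}")
        if set(self.corners) != set(CORNER_LABELS):
            raise ValueError(
                f"corner labels must be exactly {CORNER_LABELS}, got {sorted(self.corners)}")
        areas = {lab: sum(r.area for r in rects) for lab, rects in self.features.items()}
        if len({round(a, 6) for a in areas.values()}) != 1:
            raise ValueError(f"feature ROIs must have identical total area, got {areas}")
        flat = [(lab, r) for lab, rects in self.features.items() for r in rects]
        for i, (la, ra) in enumerate(flat):
            for lb, rb in flat[i + 1:]:
                if ra.intersects(rb):
                    raise ValueError(f"feature ROIs overlap: {la} and {lb}")
            if not (self.face_bbox.x <= ra.x
                    and ra.x + ra.w <= self.face_bbox.x + self.face_bbox.w
                    and self.face_bbox.y <= ra.y
                    and ra.y + ra.h <= self.face_bbox.y + self.face_bbox.h):
                raise ValueError(f"feature ROI {la} extends outside the face bounding box")

    def feature_center(self, label: str) -> tuple[float, float]:
        """Centre of the (first rectangle of the) named feature ROI."""
        return self.features[label][0].center()


def classify_point(x_px: float, y_px: float, rois: ROISet) -> str | None:
    """Return the feature-ROI label containing the point, or ``None``.

    Disjointness of the feature ROIs guarantees uniqueness; membership uses
    the half-open convention (left/top edges inclusive).
    """
    if not (math.isfinite(x_px) and math.isfinite(y_px)):
        return None
    for label, rects in rois.features.items():
        for r in rects:
            if r.contains(x_px, y_px):
                return label
    return None


def classify_corner(x_px: float, y_px: float, rois: ROISet) -> str | None:
    """Return the prior-corner label containing the point, or ``None``."""
    for label, r in rois.corners.items():
        if r.contains(x_px, y_px):
            return label
    return None


def build_default_roiset(
    screen: ScreenGeometry | None = None,
    face_w_px: int = 1064,
    face_h_px: int = 736,
) -> ROISet:
    """Construct the default region set for a centred face stimulus.

    The four feature ROIs are placed proportionally over the face box:
    a forehead band at the top, a chin band at the bottom, a nose block in
    the middle and two lateral ear rectangles.  The exact placements are a
    package default (overridable via config); the analysis logic only relies
    on the regions being equal-area, disjoint and inside the face box.
    """
    screen = screen or ScreenGeometry()
    if face_w_px < 320 or face_h_px < 320:
        raise ValueError("face bounding box too small to host disjoint equal-area ROIs")
    fx = (screen.width_px - face_w_px) // 2
    fy = (screen.height_px - face_h_px) // 2
    bbox = Rect(fx, fy, face_w_px, face_h_px)

    # proportional placements; areas made exactly equal in integer pixels
    band_w = int(face_w_px * 0.375)          # forehead / chin width
    band_h = int(face_h_px * 0.204)          # forehead / chin height
    area = band_w * band_h
    nose_w = int(face_w_px * 0.226)
    nose_h = area // nose_w
    ear_h = int(face_h_px * 0.272)
    ear_w = area // (2 * ear_h)
    # absorb integer-division remainders into the last row of pixels
    nose_area = nose_w * nose_h
    ear_area = 2 * ear_w * ear_h
    if nose_area != area:
        nose_h += (area - nose_area) / nose_w
    if ear_area != area:
        ear_h += (area - ear_area) / (2 * ear_w)

    forehead = Rect(fx + (face_w_px - band_w) / 2, fy + face_h_px * 0.014, band_w, band_h)
    chin = Rect(fx + (face_w_px - band_w) / 2, fy + face_h_px - band_h - face_h_px * 0.014,
                band_w, band_h)
    nose = Rect(fx + (face_w_px - nose_w) / 2, fy + face_h_px * 0.40, nose_w, nose_h)
    ear_y = fy + face_h_px * 0.30
    ear_l = Rect(fx + face_w_px * 0.02, ear_y, ear_w, ear_h)
    ear_r = Rect(fx + face_w_px * 0.98 - ear_w, ear_y, ear_w, ear_h)

    # prior corners: outer quadrant rectangles where the name cue appears
    cw, ch = screen.width_px * 0.30, screen.height_px * 0.30
    corners = {
        "top_left": Rect(0, 0, cw, ch),
        "top_right": Rect(screen.width_px - cw, 0, cw, ch),
        "bottom_left": Rect(0, screen.height_px - ch, cw, ch),
        "bottom_right": Rect(screen.width_px - cw, screen.height_px - ch, cw, ch),
    }
    # central landing zone (just below the eyes): sits in the free band
    # between the forehead and nose ROIs so central fixations classify as
    # no feature
    center = Rect(screen.width_px / 2 - 100, fy + face_h_px * 0.23, 200, face_h_px * 0.16)

    return ROISet(
        screen=screen,
        features={
            "forehead": (forehead,),
            "chin": (chin,),
            "ears": (ear_l, ear_r),
            "nose": (nose,),
        },
        corners=corners,
        face_bbox=bbox,
        center=center,
    )


def load_roi_config(path) -> ROISet:
    """Load screen + ROI definitions from a YAML/JSON config file.

    Expected structure::

        screen: {width_mm: ..., height_mm: ..., width_px: ..., height_px: ...,
                 viewing_distance_mm: ...}
        face_bbox: {x: ..., y: ..., w: ..., h: ...}
        center:    {x: ..., y: ..., w: ..., h: ...}
        features:  {forehead: [{x,y,w,h}, ...], ...}
        corners:   {top_left: {x,y,w,h}, ...}
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    try:
        screen = ScreenGeometry(**cfg["screen"])
        features = {
            lab: tuple(Rect(**r) for r in rects)
            for lab, rects in cfg["features"].items()
        }
        corners = {lab: Rect(**r) for lab, r in cfg["corners"].items()}
        return ROISet(
            screen=screen,
            features=features,
            corners=corners,
            face_bbox=Rect(**cfg["face_bbox"]),
            center=Rect(**cfg["center"]),
        )
    except (KeyError, TypeError) as exc:
        raise ValueError(f"invalid ROI config {path}: {exc}") from exc


def save_roi_config(rois: ROISet, path) -> None:
    """Write an ROISet to a YAML config readable by :func:`load_roi_config`."""
    def rect_d(r: Rect) -> dict:
        return {"x": r.x, "y": r.y, "w": r.w, "h": r.h}

    cfg = {
        "screen": {
            "width_mm": rois.screen.width_mm,
            "height_mm": rois.screen.height_mm,
            "width_px": rois.screen.width_px,
            "height_px": rois.screen.height_px,
            "viewing_distance_mm": rois.screen.viewing_distance_mm,
        },
        "face_bbox": rect_d(rois.face_bbox),
        "center": rect_d(rois.center),
        "features": {lab: [rect_d(r) for r in rects]
                     for lab, rects in rois.features.items()},
        "corners": {lab: rect_d(r) for lab, r in rois.corners.items()},
    }
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
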