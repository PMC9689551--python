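"""Single-grain segmentation from multi-grain scans.

Each connected foreground component of the preprocessed binary mask is
traced to a contour, fitted with its minimum-area (rotated) enclosing
rectangle, and extracted as an upright color crop: the image is rotated
locally about the box center so the grain's long axis is vertical, then
cropped with a fixed pixel margin around the box.

Coordinates are pixel coordinates with origin at the top-left corner,
x rightward (columns), y downward (rows). Box angles are reported in
(-90, 0] degrees, the rotating-calipers convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from skimage import measure

from .preprocess import PreprocessConfig, preprocess_scan

__all__ = [
    "Contour",
    "OrientedBox",
    "GrainCrop",
    "canny_foreground",
    "find_grain_contours",
    "min_area_box",
    "extract_grain",
    "segment_image",
]


@dataclass
class Contour:
    """Closed boundary of one connected component, with its pixel area."""

    points: np.ndarray  # (n, 2) float, columns (x, y)
    area_px: int

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2 or len(self.points) < 3:
            raise ValueError("contour needs at least 3 (x, y) points")


@dataclass
class OrientedBox:
    """Minimum-area enclosing rectangle: four (x, y) vertices in order,
    rotation angle in (-90, 0] degrees, and side lengths (long >= short)."""

    vertices: np.ndarray  # (4, 2), consecutive corners
    angle_deg: float
    long_side: float
    short_side: float

    @property
    def center(self) -> np.ndarray:
        return self.vertices.mean(axis=0)

    @property
    def area(self) -> float:
        return self.long_side * self.short_side

    def as_polygon(self):
        from shapely.geometry import Polygon

        return Polygon(self.vertices)

    def iou(self, other: "OrientedBox") -> float:
        a, b = self.as_polygon(), other.as_polygon()
        inter = a.intersection(b).area
        union = a.union(b).area
        return inter / union if union > 0 else 0.0

    def to_dict(self) -> dict:
        return {
            "vertices": [[float(x), float(y)] for x, y in self.vertices],
            "angle_deg": float(self.angle_deg),
            "long_side": float(self.long_side),
            "short_side": float(self.short_side),
        }


@dataclass
class GrainCrop:
    """Upright color crop of one grain (height >= width)."""

    image: np.ndarray
    box: OrientedBox
    margin_px: int


def canny_foreground(gray: np.ndarray, low: int = 50, high: int = 150) -> np.ndarray:
    """Alternative foreground extraction: Canny edges with hysteresis
    thresholds (default 50/150 on the 0-255 scale) closed and filled into
    solid regions. The default pipeline traces contours on the thresholded
    mask instead — the mask already isolates grains — but this path stays
    available for scans where gradient edges are more reliable than a
    global threshold."""
    from skimage import feature

    gray = np.asarray(gray)
    edges = feature.canny(gray.astype(float), sigma=1.5,
                          low_threshold=low, high_threshold=high)
    closed = ndimage.binary_closing(edges, structure=np.ones((3, 3)))
    return ndimage.binary_fill_holes(closed).astype(np.uint8)


def find_grain_contours(mask: np.ndarray, min_area_px: int = 200) -> list[Contour]:
    """One contour per connected foreground component with pixel area of at
    least `min_area_px`; smaller components are discarded as debris.
    Components are returned in row-major order of their first pixel."""
    mask = np.asarray(mask).astype(bool)
    labels, n = ndimage.label(mask)
    contours = []
    for lab in range(1, n + 1):
        comp = labels == lab
        area = int(comp.sum())
        if area < min_area_px:
            continue
        # pad so components touching the border still yield closed contours
        padded = np.pad(comp.astype(float), 1)
        rings = measure.find_contours(padded, 0.5)
        ring = max(rings, key=len)  # outer boundary
        pts = np.column_stack([ring[:, 1] - 1.0, ring[:, 0] - 1.0])  # (x, y)
        contours.append(Contour(pts, area))
    return contours


def min_area_box(contour: Contour | np.ndarray) -> OrientedBox:
    """Rotating-calipers minimum-area rectangle of a point set.

    The optimum rectangle shares an edge direction with the convex hull,
    so it suffices to test one orientation per hull edge. Raises on
    degenerate (collinear) input.
    """
    pts = contour.points if isinstance(contour, Contour) else np.asarray(contour, float)
    if len(pts) < 3:
        raise ValueError("need at least 3 points")
    try:
        hull = ConvexHull(pts)
    except QhullError as e:
        raise ValueError(f"degenerate (collinear) contour: {e}") from None
    hp = pts[hull.vertices]
    edges = np.diff(np.vstack([hp, hp[:1]]), axis=0)
    angles = np.unique(np.mod(np.arctan2(edges[:, 1], edges[:, 0]), np.pi / 2))
    cos, sin = np.cos(angles), np.sin(angles)
    # rotate hull points into each candidate frame: (n_angles, n_pts, 2)
    x = hp[:, 0][None, :] * cos[:, None] + hp[:, 1][None, :] * sin[:, None]
    y = -hp[:, 0][None, :] * sin[:, None] + hp[:, 1][None, :] * cos[:, None]
    w = x.max(axis=1) - x.min(axis=1)
    h = y.max(axis=1) - y.min(axis=1)
    best = int(np.argmin(w * h))
    theta = angles[best]
    x0, x1 = x[best].min(), x[best].max()
    y0, y1 = y[best].min(), y[best].max()
    corners_rot = np.array([[x0, y0], [x1, y0], [x1, y1], [x0, y1]])
    c, s = np.cos(theta), np.sin(theta)
    rot_back = np.array([[c, -s], [s, c]])
    vertices = corners_rot @ rot_back.T
    sides = (w[best], h[best])
    long_side, short_side = max(sides), min(sides)
    # angle of the rectangle's first edge, normalized to (-90, 0]
    angle = np.degrees(theta)
    while angle > 0:
        angle -= 90.0
    if angle <= -90.0:
        angle += 90.0
    return OrientedBox(vertices, float(angle), float(long_side), float(short_side))


def _upright_rotation_deg(box: OrientedBox) -> float:
    """Angle to rotate the image (counterclockwise in pixel coordinates) so
    the box's long side becomes vertical; square boxes rotate by 0."""
    if np.isclose(box.long_side, box.short_side):
        return 0.0
    v = box.vertices
    edges = [v[1] - v[0], v[2] - v[1]]
    lengths = [np.hypot(*e) for e in edges]
    ex, ey = edges[int(np.argmax(lengths))]
    # ndimage.rotate(a) maps direction (ex, ey) to
    # (ex cos a + ey sin a, -ex sin a + ey cos a); solving for a vertical
    # result gives a = -atan2(ex, ey)
    ang = -np.degrees(np.arctan2(ex, ey))
    # normalize to the smallest rotation magnitude
    while ang > 90:
        ang -= 180
    while ang < -90:
        ang += 180
    return float(ang)


def extract_grain(img: np.ndarray, box: OrientedBox, margin: int = 5,
                  background: int = 0) -> GrainCrop:
    """Rotate the scan locally about the box center so the grain's long
    side is vertical, then crop (short + 2*margin) wide by
    (long + 2*margin) tall. The rotation acts on a padded local window, so
    memory stays bounded for large scans; border crops are clamped to the
    part of the window covered by real image pixels."""
    H, W = img.shape[:2]
    cx, cy = box.center
    if not (-box.long_side <= cx <= W + box.long_side
            and -box.long_side <= cy <= H + box.long_side):
        raise ValueError("box lies outside the image")
    crop_w = int(round(box.short_side)) + 2 * margin
    crop_h = int(round(box.long_side)) + 2 * margin
    half = int(np.ceil(np.hypot(crop_w, crop_h) / 2)) + 2
    # local window centered on the box center, background-filled out of bounds
    ys = np.arange(int(round(cy)) - half, int(round(cy)) + half)
    xs = np.arange(int(round(cx)) - half, int(round(cx)) + half)
    valid_y = (ys >= 0) & (ys < H)
    valid_x = (xs >= 0) & (xs < W)
    window = np.full((len(ys), len(xs), 3), background, dtype=img.dtype)
    window[np.ix_(valid_y, valid_x)] = img[np.ix_(ys[valid_y], xs[valid_x])]
    inside = np.zeros(window.shape[:2], dtype=np.float32)
    inside[np.ix_(valid_y, valid_x)] = 1.0

    ang = _upright_rotation_deg(box)
    if abs(ang) > 1e-9:
        rot = ndimage.rotate(window.astype(np.float32), ang, reshape=False,
                             order=1, cval=background)
        inside = ndimage.rotate(inside, ang, reshape=False, order=0, cval=0.0)
    else:
        rot = window.astype(np.float32)
    ch, cw = rot.shape[0] // 2, rot.shape[1] // 2
    r0, r1 = ch - crop_h // 2, ch - crop_h // 2 + crop_h
    c0, c1 = cw - crop_w // 2, cw - crop_w // 2 + crop_w
    crop = rot[r0:r1, c0:c1]
    cov = inside[r0:r1, c0:c1] > 0.5
    # clamp: drop border rows/columns with no real image coverage
    rows = np.flatnonzero(cov.any(axis=1))
    cols = np.flatnonzero(cov.any(axis=0))
    if rows.size == 0 or cols.size == 0:
        raise ValueError("box lies fully outside the image")
    crop = crop[rows[0]: rows[-1] + 1, cols[0]: cols[-1] + 1]
    crop = np.clip(np.rint(crop), 0, 255).astype(np.uint8)
    if crop.shape[0] < crop.shape[1]:  # uprightness can only fail on clamping
        crop = np.transpose(crop, (1, 0, 2))[::-1].copy()
    return GrainCrop(crop, box, margin)


def segment_image(img: np.ndarray, cfg: PreprocessConfig | None = None,
                  min_area_px: int = 200, margin: int = 5,
                  background: int = 0, edge_method: str = "mask") -> list[GrainCrop]:
    """Full segmentation: preprocess to a mask, trace contours, fit
    minimum-area boxes, extract upright crops. Crops are returned in
    row-major order of box centers. `edge_method` selects foreground
    extraction: "mask" (fixed-threshold pipeline, default) or "canny"
    (hysteresis edge detection, see canny_foreground)."""
    if edge_method == "mask":
        mask = preprocess_scan(img, cfg)
    elif edge_method == "canny":
        from .preprocess import median_smooth, to_grayscale

        cfg_ = cfg or PreprocessConfig()
        mask = canny_foreground(median_smooth(to_grayscale(img), cfg_.median_kernel))
    else:
        raise ValueError(f"edge_method must be 'mask' or 'canny', got {edge_method!r}")
    contours = find_grain_contours(mask, min_area_px)
    crops = [extract_grain(img, min_area_box(c), margin, background) for c in contours]
    crops.sort(key=lambda cr: (round(cr.box.center[1]), round(cr.box.center[0])))
    return crops
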