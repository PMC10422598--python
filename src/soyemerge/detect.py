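"""Seedling emergence detection: Otsu thresholding and connected-component counting.

The detector segments green vegetation from soil in a nadir RGB field image by
maximising the between-class variance of a grayscale transform (Otsu), keeps the
original colour under the resulting mask, labels 8-connected foreground regions,
filters them by area, and reports each surviving region as one seedling with its
minimum axis-aligned bounding rectangle.

Coordinate convention used throughout: ``(x, y) = (column, row)``, 0-based.
Bounding rectangles are ``(x_min, y_min, width, height)`` with
``width = x_max - x_min + 1`` (closed on both ends).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "FieldImage",
    "OtsuResult",
    "BinaryMask",
    "Component",
    "Detection",
    "DetectParams",
    "to_gray",
    "otsu_threshold",
    "binarize",
    "mask_to_color",
    "label_components",
    "filter_components",
    "min_bounding_rect",
    "detect_seedlings",
    "annotate",
]

GrayRule = Literal["exg", "green", "luminance"]

# 8-connectivity: a pixel touches its horizontal, vertical and diagonal
# neighbours; 4-connectivity drops the diagonals.
_STRUCT_8 = np.ones((3, 3), dtype=bool)
_STRUCT_4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass
class FieldImage:
    """An 8-bit RGB raster plus acquisition metadata."""

    pixels: np.ndarray  # (H, W, 3) uint8
    source: Optional[str] = None
    flight_height_m: Optional[float] = None
    capture_date: Optional[str] = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(f"expected (H, W, 3) RGB raster, got {self.pixels.shape}")
        if self.pixels.dtype != np.uint8:
            if self.pixels.min() < 0 or self.pixels.max() > 255:
                raise ValueError("pixel values must lie in [0, 255]")
            self.pixels = self.pixels.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass
class OtsuResult:
    """Threshold choice with the full between-class-variance bookkeeping.

    ``sigma2`` is the between-class variance at the chosen threshold ``k``:
    ``sigma2(k) = w0*(mu - mu0)**2 + w1*(mu - mu1)**2`` where class 0 (the
    target, vegetation) is the pixels strictly above ``k`` and class 1 (the
    background) those at or below.
    """

    k: int
    sigma2: float
    w0: float
    w1: float
    mu: float
    mu0: float
    mu1: float
    histogram: np.ndarray  # 256 bin counts
    degenerate: bool = False


@dataclass
class BinaryMask:
    pixels: np.ndarray  # (H, W) bool, True = vegetation/target

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2:
            raise ValueError("mask must be a 2-D boolean raster")


@dataclass
class Component:
    """One maximal connected set of foreground pixels."""

    label: int
    pixel_set: np.ndarray  # (n, 2) array of (x, y)
    area: int
    bbox: tuple[int, int, int, int]  # (x_min, y_min, width, height)


@dataclass
class Detection:
    """One counted seedling: 1-based index, component and its drawn rectangle."""

    index: int
    component: Component
    rect: tuple[int, int, int, int]


@dataclass
class DetectParams:
    gray_rule: GrayRule = "exg"
    min_area: int = 25  # px; ~1 cm^2 footprint at 2 mm/px ground sampling
    max_area: Optional[int] = None
    connectivity: int = 8
    # vegetation floor: if the Otsu target class's mean grey falls below this,
    # the scene is treated as bare soil (thresholding noise is not vegetation)
    min_target_gray: int = 60


def to_gray(image: FieldImage | np.ndarray, rule: GrayRule = "exg") -> np.ndarray:
    """Collapse RGB to one channel.

    ``exg`` is the excess-green index ``2G - R - B`` clipped to [0, 255] —
    the default because the targets are green plants on brown soil. ``green``
    takes the raw G channel and ``luminance`` the ITU-R 601 weighting.
    """
    rgb = image.pixels if isinstance(image, FieldImage) else np.asarray(image)
    r = rgb[..., 0].astype(np.int32)
    g = rgb[..., 1].astype(np.int32)
    b = rgb[..., 2].astype(np.int32)
    if rule == "exg":
        gray = np.clip(2 * g - r - b, 0, 255)
    elif rule == "green":
        gray = g
    elif rule == "luminance":
        gray = np.round(0.299 * r + 0.587 * g + 0.114 * b).astype(np.int32)
    else:
        raise ValueError(f"unknown gray rule: {rule!r}")
    return gray.astype(np.uint8)


def otsu_threshold(gray: np.ndarray) -> OtsuResult:
    """Pick the grey level maximising the between-class variance.

    Every candidate threshold k in 0..255 is evaluated; pixels strictly above
    k form the target class, the rest the background. Ties are broken by the
    smallest maximising k. A constant image has zero variance everywhere and
    is returned with ``degenerate=True`` and k set to the constant value.
    """
    gray = np.asarray(gray)
    if gray.size == 0:
        raise ValueError("empty raster")
    hist = np.bincount(gray.ravel().astype(np.int64), minlength=256)[:256].astype(np.float64)
    n = hist.sum()
    p = hist / n
    levels = np.arange(256, dtype=np.float64)
    mu = float((p * levels).sum())

    # cumulative background (<= k) statistics for every k
    w_le = np.cumsum(p)
    m_le = np.cumsum(p * levels)
    w1 = w_le                     # background probability at each k
    w0 = 1.0 - w_le               # target probability (> k)
    with np.errstate(divide="ignore", invalid="ignore"):
        mu1 = np.where(w1 > 0, m_le / w1, 0.0)
        mu0 = np.where(w0 > 0, (mu - m_le) / w0, 0.0)
    sigma2 = w0 * (mu - mu0) ** 2 + w1 * (mu - mu1) ** 2

    k = int(np.argmax(sigma2))  # argmax returns the first (smallest) maximiser
    best = float(sigma2[k])
    degenerate = bool(np.isclose(best, 0.0))
    if degenerate:
        k = int(gray.ravel()[0])
    return OtsuResult(
        k=k,
        sigma2=best,
        w0=float(w0[k]),
        w1=float(w1[k]),
        mu=mu,
        mu0=float(mu0[k]),
        mu1=float(mu1[k]),
        histogram=hist.astype(np.int64),
        degenerate=degenerate,
    )


def binarize(gray: np.ndarray, otsu: OtsuResult | int) -> BinaryMask:
    """Threshold strictly: a pixel is foreground iff ``gray > k``."""
    k = otsu.k if isinstance(otsu, OtsuResult) else int(otsu)
    return BinaryMask(np.asarray(gray) > k)


def mask_to_color(image: FieldImage, mask: BinaryMask) -> FieldImage:
    """Keep the original RGB under the mask, black elsewhere.

    Downstream component analysis treats any non-black pixel of this masked
    colour image as foreground, which reproduces a colour-image connected
    component pass without inventing a colour adjacency metric.
    """
    if mask.pixels.shape != image.shape:
        raise ValueError(f"shape mismatch: mask {mask.pixels.shape} vs image {image.shape}")
    out = np.where(mask.pixels[..., None], image.pixels, 0).astype(np.uint8)
    return FieldImage(out, source=image.source, flight_height_m=image.flight_height_m,
                      capture_date=image.capture_date)


def label_components(mask: BinaryMask | np.ndarray, connectivity: int = 8) -> list[Component]:
    """Label maximal connected foreground regions (default 8-connectivity).

    Labels follow raster-scan order of each region's first pixel.
    """
    pixels = mask.pixels if isinstance(mask, BinaryMask) else np.asarray(mask, dtype=bool)
    if connectivity == 8:
        structure = _STRUCT_8
    elif connectivity == 4:
        structure = _STRUCT_4
    else:
        raise ValueError("connectivity must be 4 or 8")
    labelled, n = ndimage.label(pixels, structure=structure)
    components: list[Component] = []
    slices = ndimage.find_objects(labelled)
    for lab in range(1, n + 1):
        sl = slices[lab - 1]
        ys, xs = np.nonzero(labelled[sl] == lab)
        ys = ys + sl[0].start
        xs = xs + sl[1].start
        pixel_set = np.column_stack([xs, ys]).astype(np.int64)
        bbox = (int(xs.min()), int(ys.min()),
                int(xs.max() - xs.min() + 1), int(ys.max() - ys.min() + 1))
        components.append(Component(label=lab, pixel_set=pixel_set,
                                    area=int(len(xs)), bbox=bbox))
    return components


def filter_components(components: Sequence[Component], min_area: int = 1,
                      max_area: Optional[int] = None) -> list[Component]:
    """Keep components with ``min_area <= area <= max_area``, order preserved."""
    if min_area < 1:
        raise ValueError("min_area must be >= 1")
    if max_area is not None and min_area > max_area:
        raise ValueError(f"min_area {min_area} > max_area {max_area}")
    hi = np.inf if max_area is None else max_area
    return [c for c in components if min_area <= c.area <= hi]


def min_bounding_rect(component: Component | np.ndarray) -> tuple[int, int, int, int]:
    """Smallest axis-aligned rectangle containing every pixel of a component."""
    pts = component.pixel_set if isinstance(component, Component) else np.asarray(component)
    if len(pts) == 0:
        raise ValueError("empty component")
    x_min, y_min = pts.min(axis=0)
    x_max, y_max = pts.max(axis=0)
    return (int(x_min), int(y_min), int(x_max - x_min + 1), int(y_max - y_min + 1))


def detect_seedlings(image: FieldImage,
                     params: DetectParams | None = None) -> tuple[list[Detection], int]:
    """Run the full detection chain and count seedlings.

    gray -> Otsu -> strict binarise -> colour mask -> 8-connected labelling on
    non-black pixels -> area filter -> minimum bounding rectangles. Each
    surviving component is counted as exactly one seedling.
    """
    params = params or DetectParams()
    gray = to_gray(image, params.gray_rule)
    otsu = otsu_threshold(gray)
    if otsu.degenerate or otsu.mu0 < params.min_target_gray:
        return [], 0  # no vegetation class present; Otsu split is noise-only
    mask = binarize(gray, otsu)
    masked = mask_to_color(image, mask)
    foreground = masked.pixels.any(axis=2)
    components = label_components(foreground, connectivity=params.connectivity)
    components = filter_components(components, params.min_area, params.max_area)
    detections = [Detection(index=i + 1, component=c, rect=min_bounding_rect(c))
                  for i, c in enumerate(components)]
    return detections, len(detections)


# 3x5 bitmap digits for the blue index labels drawn next to each detection.
_DIGITS = {
    "0": ["###", "# #", "# #", "# #", "###"],
    "1": [" # ", "## ", " # ", " # ", "###"],
    "2": ["###", "  #", "###", "#  ", "###"],
    "3": ["###", "  #", "###", "  #", "###"],
    "4": ["# #", "# #", "###", "  #", "  #"],
    "5": ["###", "#  ", "###", "  #", "###"],
    "6": ["###", "#  ", "###", "# #", "###"],
    "7": ["###", "  #", "  #", "  #", "  #"],
    "8": ["###", "# #", "###", "# #", "###"],
    "9": ["###", "# #", "###", "  #", "###"],
}

RED = (255, 0, 0)
BLUE = (0, 0, 255)


def _draw_rect(px: np.ndarray, rect: tuple[int, int, int, int],
               color: tuple[int, int, int]) -> None:
    h, w = px.shape[:2]
    x0, y0, rw, rh = rect
    x1, y1 = x0 + rw - 1, y0 + rh - 1
    xa, xb = max(x0, 0), min(x1, w - 1)
    ya, yb = max(y0, 0), min(y1, h - 1)
    if xa > xb or ya > yb:
        return
    if 0 <= y0 < h:
        px[y0, xa:xb + 1] = color
    if 0 <= y1 < h:
        px[y1, xa:xb + 1] = color
    if 0 <= x0 < w:
        px[ya:yb + 1, x0] = color
    if 0 <= x1 < w:
        px[ya:yb + 1, x1] = color


def _draw_text(px: np.ndarray, text: str, x: int, y: int,
               color: tuple[int, int, int]) -> tuple[int, int, int, int]:
    """Render digits with the 3x5 font; returns the text bounding box drawn."""
    h, w = px.shape[:2]
    cx = x
    for ch in text:
        glyph = _DIGITS[ch]
        for dy, row in enumerate(glyph):
            for dx, cell in enumerate(row):
                if cell == "#" and 0 <= y + dy < h and 0 <= cx + dx < w:
                    px[y + dy, cx + dx] = color
        cx += 4
    return (x, y, cx - x - 1, 5)


def annotate(image: FieldImage, detections: Sequence[Detection],
             return_label_boxes: bool = False):
    """Draw red minimum-rectangle borders and blue seedling indices.

    With ``return_label_boxes=True`` also returns the bounding box of each
    rendered index, one per detection, for render bookkeeping.
    """
    out = image.pixels.copy()
    boxes = []
    for det in detections:
        _draw_rect(out, det.rect, RED)
        x0, y0, _, _ = det.rect
        ty = y0 - 7 if y0 - 7 >= 0 else y0 + 1
        boxes.append(_draw_text(out, str(det.index), max(x0, 0), ty, BLUE))
    annotated = FieldImage(out, source=image.source,
                           flight_height_m=image.flight_height_m,
                           capture_date=image.capture_date)
    if return_label_boxes:
        return annotated, boxes
    return annotated
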