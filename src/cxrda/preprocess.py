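"""Chest-cavity extraction pipeline for radiographs.

Stages: grayscale conversion, contrast-limited adaptive histogram
equalization (CLAHE), 3x3 Gaussian smoothing, border zoom-crop, Otsu
binarization (lung fields = dark = foreground), morphological opening,
connected-component lung candidates, union bounding box ("chest cavity"),
crop, and bilinear resize with channel triplication to the network input
shape (299 x 299 x 3 by default).  Everything is deterministic; the module
draws no random numbers.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import exposure, measure, transform

log = logging.getLogger(__name__)

#: Luminance weights used for RGB -> gray reduction (ITU-R BT.709, as in
#: scikit-image's rgb2gray).
LUMINANCE_WEIGHTS = (0.2125, 0.7154, 0.0721)


class PreprocessError(ValueError):
    pass


@dataclass(frozen=True)
class PreprocessConfig:
    """All knobs of the chest-cavity extraction pipeline.

    ``clahe_clip_limit`` uses scikit-image's normalized convention (fraction
    of pixels per tile that any histogram bin may hold; higher = more
    contrast).  ``zoom_fraction`` is the border fraction removed per side and
    per axis.  ``min_contour_area_frac`` is the smallest connected-component
    area (as a fraction of image area) still considered a lung candidate.
    """

    clahe_clip_limit: float = 0.01
    clahe_tile_grid: tuple[int, int] = (8, 8)
    gaussian_kernel: int = 3
    gaussian_sigma: float = 0.8
    zoom_fraction: float = 0.1
    binarization: str = "otsu"
    morph_kernel: int = 3
    morph_iterations: int = 1
    min_contour_area_frac: float = 0.02
    output_side: int = 299
    output_channels: int = 3
    crop_enabled: bool = True

    def validate(self) -> None:
        for name in ("gaussian_kernel", "morph_kernel"):
            v = getattr(self, name)
            if v < 1 or v % 2 == 0:
                raise PreprocessError(f"{name} must be odd and >= 1, got {v}")
        if not 0.0 <= self.zoom_fraction < 0.5:
            raise PreprocessError(f"zoom_fraction must be in [0, 0.5), got {self.zoom_fraction}")
        if self.output_side < 32:
            raise PreprocessError(f"output_side must be >= 32, got {self.output_side}")
        if self.binarization != "otsu":
            raise PreprocessError(f"unsupported binarization method {self.binarization!r}")
        if self.output_channels < 1:
            raise PreprocessError("output_channels must be >= 1")


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box, 0-based, half-open: [x, x+width) x [y, y+height)."""

    x: int
    y: int
    width: int
    height: int

    def __post_init__(self):
        if self.width <= 0 or self.height <= 0:
            raise PreprocessError(f"degenerate bounding box {self}")

    @property
    def area(self) -> int:
        return self.width * self.height

    def clamped(self, side_y: int, side_x: int) -> "BoundingBox":
        x0, y0 = max(self.x, 0), max(self.y, 0)
        x1 = min(self.x + self.width, side_x)
        y1 = min(self.y + self.height, side_y)
        return BoundingBox(x0, y0, x1 - x0, y1 - y0)

    def contains(self, other: "BoundingBox") -> bool:
        return (self.x <= other.x and self.y <= other.y
                and self.x + self.width >= other.x + other.width
                and self.y + self.height >= other.y + other.height)


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Reduce to one channel; 3-channel input via BT.709 luminance weighting."""
    if image.ndim == 2:
        return image
    if image.ndim == 3 and image.shape[2] == 1:
        return image[:, :, 0]
    if image.ndim == 3 and image.shape[2] == 3:
        w = np.asarray(LUMINANCE_WEIGHTS, dtype=image.dtype)
        return image @ w
    raise PreprocessError(f"unsupported channel count: shape {image.shape}")


def equalize_clahe(image: np.ndarray, cfg: PreprocessConfig = PreprocessConfig()) -> np.ndarray:
    """CLAHE on a [0, 1] grayscale image; constant inputs pass through."""
    if np.ptp(image) == 0:
        return image.copy()
    rows, cols = cfg.clahe_tile_grid
    kernel = (max(1, image.shape[0] // rows), max(1, image.shape[1] // cols))
    return exposure.equalize_adapthist(
        np.clip(image, 0.0, 1.0), kernel_size=kernel, clip_limit=cfg.clahe_clip_limit
    ).astype(np.float32)


def gaussian_kernel_2d(size: int, sigma: float) -> np.ndarray:
    """Normalized square Gaussian kernel."""
    if size % 2 == 0:
        raise PreprocessError(f"Gaussian kernel size must be odd, got {size}")
    r = np.arange(size) - size // 2
    k1 = np.exp(-(r ** 2) / (2.0 * sigma ** 2))
    k = np.outer(k1, k1)
    return k / k.sum()


def gaussian_smooth(image: np.ndarray, cfg: PreprocessConfig = PreprocessConfig()) -> np.ndarray:
    """Convolve with the normalized Gaussian kernel; reflected borders."""
    k = gaussian_kernel_2d(cfg.gaussian_kernel, cfg.gaussian_sigma)
    return ndimage.convolve(image.astype(np.float32), k.astype(np.float32), mode="reflect")


def zoom_crop(image: np.ndarray, cfg: PreprocessConfig = PreprocessConfig()) -> np.ndarray:
    """Remove floor(zoom_fraction * side) pixels from each border, per axis."""
    dy = int(np.floor(cfg.zoom_fraction * image.shape[0]))
    dx = int(np.floor(cfg.zoom_fraction * image.shape[1]))
    out = image[dy : image.shape[0] - dy, dx : image.shape[1] - dx]
    if out.size == 0:
        raise PreprocessError("zoom_crop produced an empty image")
    return out


def binarize(image: np.ndarray, cfg: PreprocessConfig = PreprocessConfig()) -> np.ndarray:
    """Otsu-threshold, then invert: dark (lung-field) pixels become foreground."""
    cfg.validate()
    from skimage.filters import threshold_otsu

    if np.ptp(image) == 0:
        raise PreprocessError("degenerate histogram: constant image cannot be binarized")
    t = threshold_otsu(image, nbins=256)
    return image < t


def morphological_clean(mask: np.ndarray, cfg: PreprocessConfig = PreprocessConfig()) -> np.ndarray:
    """Opening (erosion then dilation) with a square structuring element."""
    if mask.dtype != bool:
        mask = mask.astype(bool)
    if not mask.any():
        return mask.copy()
    structure = np.ones((cfg.morph_kernel, cfg.morph_kernel), dtype=bool)
    out = ndimage.binary_erosion(mask, structure, iterations=cfg.morph_iterations)
    out = ndimage.binary_dilation(out, structure, iterations=cfg.morph_iterations)
    return out


def find_lung_boxes(mask: np.ndarray, cfg: PreprocessConfig = PreprocessConfig()) -> list[BoundingBox]:
    """Tight boxes of the up-to-2 largest components above the area floor."""
    labeled = measure.label(mask, connectivity=2)
    min_area = cfg.min_contour_area_frac * mask.size
    candidates = []
    for region in measure.regionprops(labeled):
        if region.area >= min_area:
            y0, x0, y1, x1 = region.bbox
            candidates.append((region.area, BoundingBox(x0, y0, x1 - x0, y1 - y0)))
    if not candidates:
        raise PreprocessError("no lung candidates: no component above the area floor")
    candidates.sort(key=lambda t: (-t[0], t[1].x, t[1].y))
    return [box for _, box in candidates[:2]]


def chest_cavity_box(boxes: list[BoundingBox]) -> BoundingBox:
    """Minimal box containing every input box (min of mins, max of maxes)."""
    if not boxes:
        raise PreprocessError("chest_cavity_box requires at least one box")
    x0 = min(b.x for b in boxes)
    y0 = min(b.y for b in boxes)
    x1 = max(b.x + b.width for b in boxes)
    y1 = max(b.y + b.height for b in boxes)
    return BoundingBox(x0, y0, x1 - x0, y1 - y0)


def crop_resize_triplicate(image: np.ndarray, box: BoundingBox,
                           cfg: PreprocessConfig = PreprocessConfig()) -> np.ndarray:
    """Crop to box, bilinear-resize to the output side, replicate channels."""
    box = box.clamped(image.shape[0], image.shape[1])
    crop = image[box.y : box.y + box.height, box.x : box.x + box.width]
    if crop.shape == (cfg.output_side, cfg.output_side):
        resized = crop.astype(np.float32)
    else:
        resized = transform.resize(
            crop.astype(np.float64), (cfg.output_side, cfg.output_side),
            order=1, mode="edge", anti_aliasing=False, preserve_range=True,
        ).astype(np.float32)
    return np.repeat(resized[:, :, None], cfg.output_channels, axis=2)


def preprocess_pipeline(image: np.ndarray, cfg: PreprocessConfig = PreprocessConfig()) -> np.ndarray:
    """Full pipeline; when ``crop_enabled`` is false, or when no lung
    candidate is found (with a warning), the zoomed image is used whole."""
    cfg.validate()
    gray = to_grayscale(image)
    eq = equalize_clahe(gray, cfg)
    smooth = gaussian_smooth(eq, cfg)
    zoomed = zoom_crop(smooth, cfg)
    full_box = BoundingBox(0, 0, zoomed.shape[1], zoomed.shape[0])
    box = full_box
    if cfg.crop_enabled:
        try:
            mask = morphological_clean(binarize(zoomed, cfg), cfg)
            box = chest_cavity_box(find_lung_boxes(mask, cfg))
        except PreprocessError as exc:
            msg = f"chest-cavity cropping failed ({exc}); using the zoomed image"
            log.warning(msg)
            warnings.warn(msg, stacklevel=2)
            box = full_box
    return crop_resize_triplicate(zoomed, box, cfg)
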