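"""Image preprocessing, the five-operator augmentation pipeline, and image
encoding to grid + pooled features.

Preprocessing normalizes intensities to 0-255, finds a foreground bounding box
(Otsu threshold with a floor of 5, morphological opening with a 40x40
rectangle), crops to the box and bilinearly resizes to 448x448.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.transform import resize as _sk_resize
from skimage.transform import rotate as _sk_rotate

from .backbones import EncoderContract, get_backbone, validate_grid
from .errors import InvalidInputError

__all__ = [
    "AugSpec", "FeatureGrid", "ForegroundMask",
    "normalize_intensity", "otsu_threshold", "extract_foreground_bbox",
    "preprocess_image", "augment_image", "encode_image",
    "TARGET_SIZE", "OPENING_SIZE", "THRESHOLD_FLOOR",
]

TARGET_SIZE = 448
OPENING_SIZE = 40
THRESHOLD_FLOOR = 5

_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class ForegroundMask:
    mask: np.ndarray                      # binary H x W
    bbox: tuple[int, int, int, int]       # (row_min, col_min, row_max, col_max), half-open


@dataclass
class FeatureGrid:
    """P positions x K channels plus the position-mean pooled K-vector."""

    grid: np.ndarray
    pooled: np.ndarray = field(init=False)

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=np.float64)
        if self.grid.ndim != 2:
            raise InvalidInputError("feature grid must be 2-D (positions x channels)")
        self.pooled = self.grid.mean(axis=0)

    @property
    def d_v(self) -> int:
        return self.grid.shape[1]


@dataclass
class AugSpec:
    """Operator magnitude ranges; defaults are the reference pipeline values."""

    crop_low: tuple[float, float] = (0.0, 0.1)
    crop_high: tuple[float, float] = (0.9, 1.0)
    brightness: tuple[float, float] = (0.5, 1.5)
    ratio: tuple[float, float] = (0.8, 1.5)
    rotation_deg: tuple[float, float] = (3.0, 10.0)
    noise_mean: float = 0.0
    noise_var: float = 0.01
    multiplicity: int = 5
    seed: int = 0


# ---------------------------------------------------------------------------
# Intensity normalization and thresholding
# ---------------------------------------------------------------------------

def normalize_intensity(img: np.ndarray) -> np.ndarray:
    """Bring intensities into the 0-255 range (float64); idempotent.

    Unit-scaled floats (max <= 1) and out-of-range arrays are min-max
    rescaled; arrays already within [0, 255] pass through unchanged.  A
    constant image is clipped into range (there is nothing to rescale).
    """
    arr = np.asarray(img, dtype=np.float64)
    lo, hi = arr.min(), arr.max()
    if hi <= lo:
        return np.clip(arr, 0.0, 255.0)
    if lo >= 0.0 and hi <= 255.0 and hi > 1.0:
        return arr
    return (arr - lo) / (hi - lo) * 255.0


def _luminance(img: np.ndarray) -> np.ndarray:
    """Rec.601 luma, rounded to integer levels so exact-level thresholds
    are not crossed by floating-point dust."""
    arr = np.asarray(img, dtype=np.float64)
    if arr.ndim != 2:
        arr = arr @ _LUMA
    return np.round(arr)


def otsu_threshold(img: np.ndarray, floor: float = THRESHOLD_FLOOR) -> float:
    """Between-class-variance-maximizing level over 256 bins, floored at 5.

    A constant image has no between-class variance to maximize and returns
    the floor.
    """
    gray = _luminance(normalize_intensity(img))
    hist, _ = np.histogram(gray, bins=256, range=(0.0, 255.0))
    total = hist.sum()
    if total == 0:
        return float(floor)
    p = hist / total
    omega = np.cumsum(p)                      # class-0 mass for t = 0..255
    mu = np.cumsum(p * np.arange(256))
    mu_t = mu[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mu_t * omega - mu) ** 2 / (omega * (1.0 - omega))
    sigma_b = np.nan_to_num(sigma_b, nan=0.0, posinf=0.0)
    if sigma_b.max() <= 0.0:
        return float(floor)
    return float(max(int(np.argmax(sigma_b)), floor))


# ---------------------------------------------------------------------------
# Foreground bounding box
# ---------------------------------------------------------------------------

def _opening(mask: np.ndarray, size: int = OPENING_SIZE) -> np.ndarray:
    """Morphological opening with a size x size rectangle.

    Border handling is erosion-style: pixels beyond the frame count as
    foreground during erosion, so components touching the border are treated
    like interior ones.  Implemented as a minimum filter (erosion: the
    rectangle fits entirely in foreground) followed by a maximum filter over
    the reflected window (dilation: union of all fitting rectangles).
    """
    padded = np.pad(mask.astype(np.uint8), size, constant_values=1)
    eroded = ndimage.minimum_filter(padded, size=size, mode="constant", cval=1)
    opened = ndimage.maximum_filter(eroded, size=size, mode="constant", cval=0,
                                    origin=-((size + 1) % 2))
    return opened[size:-size, size:-size].astype(bool)


def extract_foreground_bbox(img: np.ndarray) -> ForegroundMask:
    """Threshold, open with the 40x40 rectangle, and box the survivors.

    An empty post-opening mask falls back to the full frame.
    """
    arr = normalize_intensity(img)
    gray = _luminance(arr)
    t = otsu_threshold(arr)
    mask = _opening(gray > t)
    h, w = gray.shape
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    if rows.size == 0 or cols.size == 0:
        return ForegroundMask(mask=mask, bbox=(0, 0, h, w))
    return ForegroundMask(mask=mask,
                          bbox=(int(rows[0]), int(cols[0]),
                                int(rows[-1]) + 1, int(cols[-1]) + 1))


def _bilinear_resize(img: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    if img.shape[:2] == shape:
        return img.astype(np.float64)
    return _sk_resize(img, shape, order=1, anti_aliasing=False,
                      preserve_range=True, mode="edge")


def preprocess_image(img: np.ndarray, target: int = TARGET_SIZE) -> np.ndarray:
    """normalize -> foreground bbox -> crop -> bilinear resize to 448x448."""
    arr = normalize_intensity(img)
    fg = extract_foreground_bbox(arr)
    r0, c0, r1, c1 = fg.bbox
    if r1 <= r0 or c1 <= c0:
        r0, c0, r1, c1 = 0, 0, arr.shape[0], arr.shape[1]
    cropped = arr[r0:r1, c0:c1]
    return _bilinear_resize(cropped, (target, target))


# ---------------------------------------------------------------------------
# Augmentation: five operators, one output each
# ---------------------------------------------------------------------------

def _center_crop(img: np.ndarray, h: int, w: int) -> np.ndarray:
    hh, ww = img.shape[:2]
    r0 = max((hh - h) // 2, 0)
    c0 = max((ww - w) // 2, 0)
    return img[r0:r0 + h, c0:c0 + w]


def augment_image(img: np.ndarray, spec: AugSpec | None = None
                  ) -> tuple[list[np.ndarray], list[dict]]:
    """Produce one output per operator (edge crop, rotation, aspect rescale,
    Gaussian noise, brightness), returning the images and a log of the draws.

    The original is never modified.  Noise has variance `spec.noise_var` on
    unit-scaled intensities and the result is clipped back into range.
    """
    spec = spec or AugSpec()
    rng = np.random.default_rng(spec.seed)
    arr = normalize_intensity(img)
    h, w = arr.shape[:2]
    outputs: list[np.ndarray] = []
    log: list[dict] = []

    # 1) edge crop
    top = rng.uniform(*spec.crop_low)
    left = rng.uniform(*spec.crop_low)
    bottom = rng.uniform(*spec.crop_high)
    right = rng.uniform(*spec.crop_high)
    r0, r1 = int(top * h), max(int(bottom * h), int(top * h) + 1)
    c0, c1 = int(left * w), max(int(right * w), int(left * w) + 1)
    outputs.append(arr[r0:r1, c0:c1].copy())
    log.append({"op": "crop", "top": top, "left": left,
                "bottom": bottom, "right": right})

    # 2) rotation (canvas expanded, then center-cropped to the original size)
    angle = rng.uniform(*spec.rotation_deg)
    rotated = _sk_rotate(arr, angle, resize=True, order=1, preserve_range=True)
    outputs.append(_center_crop(rotated, h, w).copy())
    log.append({"op": "rotate", "angle_deg": angle})

    # 3) aspect-ratio rescale
    ratio = rng.uniform(*spec.ratio)
    outputs.append(_bilinear_resize(arr, (h, max(int(round(w * ratio)), 1))))
    log.append({"op": "ratio", "factor": ratio})

    # 4) additive Gaussian noise on unit-scaled intensities
    sigma = float(np.sqrt(spec.noise_var))
    noise = rng.normal(spec.noise_mean, sigma, size=arr.shape)
    noisy = np.clip(arr / 255.0 + noise, 0.0, 1.0) * 255.0
    outputs.append(noisy)
    log.append({"op": "noise", "mean": spec.noise_mean, "var": spec.noise_var})

    # 5) brightness
    bright = rng.uniform(*spec.brightness)
    outputs.append(np.clip(arr * bright, 0.0, 255.0))
    log.append({"op": "brightness", "factor": bright})

    if spec.multiplicity != len(outputs):
        raise InvalidInputError(
            f"the pipeline produces {len(outputs)} variants, spec declares "
            f"{spec.multiplicity}")
    return outputs, log


# ---------------------------------------------------------------------------
# Encoding
# ---------------------------------------------------------------------------

def encode_image(img: np.ndarray, contract: EncoderContract) -> FeatureGrid:
    """Backbone grid -> (1x1-conv channel unification if needed) -> FeatureGrid.

    `img` is an H x W x 3 preprocessed image.  The pooled vector is the exact
    position-wise mean of the grid.
    """
    arr = np.asarray(img, dtype=np.float64)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise InvalidInputError("encode_image expects an H x W x 3 image")
    backbone = get_backbone(contract)
    grid = np.asarray(backbone(arr.transpose(2, 0, 1)))
    if grid.ndim != 2 or grid.shape[0] != contract.positions:
        grid = validate_grid(grid, contract)
    if grid.shape[1] != contract.output_channels:
        # 1x1 convolution over positions == per-position linear map
        rng = np.random.default_rng(contract.seed)
        unify = rng.normal(0.0, np.sqrt(1.0 / grid.shape[1]),
                           size=(grid.shape[1], contract.output_channels))
        grid = grid @ unify
    grid = validate_grid(grid, contract)
    return FeatureGrid(grid=grid)
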