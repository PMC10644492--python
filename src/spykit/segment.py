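"""Spike detection and enumeration in scanner scenes.

Spikes are separated from the dark background either by a fixed threshold on
one RGB channel (default: red > 20) or by Otsu's method on the luminance
image with a multiplicative scaling factor (default 0.29) that compensates
for the strong background class pulling the Otsu threshold upward on dark
backgrounds. Detected components are enumerated left-to-right, and each
spike is exported as background-zeroed RGB / HSV / CIELAB crops.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage import color as skcolor
from skimage import measure, transform

from .errors import ValidationError

CHANNEL_INDEX = {"R": 0, "G": 1, "B": 2}
DEFAULT_RED_THRESHOLD = 20
DEFAULT_OTSU_FACTOR = 0.29
DEFAULT_MIN_AREA = 2000
DEFAULT_PAD_PX = 10


@dataclass(frozen=True)
class SegmentationParams:
    """Parameters of the spike segmentation stage."""

    method: str = "channel_thresh"          # or "otsu_scaled"
    channel: str = "R"
    threshold: float = DEFAULT_RED_THRESHOLD
    otsu_factor: float = DEFAULT_OTSU_FACTOR
    rescale_rgb: float = 1.0
    min_area: int = DEFAULT_MIN_AREA

    def validate(self) -> None:
        if self.method not in ("channel_thresh", "otsu_scaled"):
            raise ValidationError(f"unknown method {self.method!r}")
        if self.channel not in CHANNEL_INDEX:
            raise ValidationError(f"unknown channel {self.channel!r}")
        if not (0 <= self.threshold <= 255):
            raise ValidationError("threshold must be in [0, 255]")
        if not (0 < self.otsu_factor <= 1):
            raise ValidationError("otsu_factor must be in (0, 1]")
        if not (0 < self.rescale_rgb <= 1):
            raise ValidationError("rescale_rgb must be in (0, 1]")

    @property
    def effective_min_area(self) -> int:
        """min_area is defined at full resolution; scale by rescale^2."""
        return max(int(round(self.min_area * self.rescale_rgb ** 2)), 1)


@dataclass
class LabeledScene:
    """Enumerated spikes: label raster (0 = background, 1..k = spikes)."""

    labels: np.ndarray
    k: int
    bboxes: list[tuple[int, int, int, int]] = field(default_factory=list)
    centroids: list[tuple[float, float]] = field(default_factory=list)
    areas: list[int] = field(default_factory=list)


@dataclass
class SpikeRecord:
    """One segmented spike with per-color-space crops.

    Crops are padded by ``pad_px`` on all sides and zeroed outside the
    spike mask. Channel scales: RGB in [0, 255]; H in [0, 360), S and V in
    [0, 255]; L* in [0, 100], a*/b* signed (sRGB, D65).
    """

    label: int
    bbox: tuple[int, int, int, int]
    pad_px: int
    mask: np.ndarray
    rgb: np.ndarray
    hsv: np.ndarray
    lab: np.ndarray

    @property
    def area(self) -> int:
        return int(self.mask.sum())


def _check_rgb(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValidationError("expected an (H, W, 3) 8-bit RGB image")
    return image


def to_gray(image: np.ndarray) -> np.ndarray:
    """Luminance gray: round(0.299 R + 0.587 G + 0.114 B), 8-bit."""
    image = _check_rgb(image).astype(float)
    gray = 0.299 * image[..., 0] + 0.587 * image[..., 1] + 0.114 * image[..., 2]
    return np.round(gray).astype(np.uint8)


def channel_threshold_mask(image: np.ndarray, channel: str = "R",
                           threshold: float = DEFAULT_RED_THRESHOLD) -> np.ndarray:
    """Foreground where the chosen channel strictly exceeds ``threshold``."""
    image = _check_rgb(image)
    if not (0 <= threshold <= 255):
        raise ValidationError("threshold must be in [0, 255]")
    if channel not in CHANNEL_INDEX:
        raise ValidationError(f"unknown channel {channel!r}")
    return image[..., CHANNEL_INDEX[channel]] > threshold


def otsu_threshold(gray: np.ndarray) -> int:
    """Otsu's threshold by exhaustive scan of all 256 candidate levels.

    Returns the 8-bit level t maximizing the between-class variance of the
    split ``gray <= t`` / ``gray > t`` (smallest maximizer on ties). A
    constant image has no separable classes: its value is returned with a
    warning.
    """
    gray = np.asarray(gray)
    if gray.size == 0:
        raise ValidationError("empty gray raster")
    hist = np.bincount(gray.ravel().astype(np.int64), minlength=256)[:256]
    total = hist.sum()
    levels = np.arange(256)
    if np.count_nonzero(hist) == 1:
        value = int(np.nonzero(hist)[0][0])
        warnings.warn("constant image: Otsu threshold is degenerate",
                      stacklevel=2)
        return value
    w0 = np.cumsum(hist)                      # pixels with level <= t
    w1 = total - w0
    csum = np.cumsum(hist * levels)
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = csum / w0
        mu1 = (csum[-1] - csum) / w1
        bcv = w0.astype(float) * w1.astype(float) * (mu0 - mu1) ** 2
    bcv[~np.isfinite(bcv)] = -1.0
    return int(np.argmax(bcv))


def scaled_otsu_mask(image: np.ndarray, factor: float = DEFAULT_OTSU_FACTOR) -> np.ndarray:
    """Foreground where luminance exceeds ``factor * t_otsu``.

    ``factor=1`` reproduces the plain Otsu segmentation; the default 0.29
    compensates for the dominant dark-background class.
    """
    if not (0 < factor <= 1):
        raise ValidationError("otsu factor must be in (0, 1]")
    gray = to_gray(image)
    return gray > factor * otsu_threshold(gray)


def rescale_image(image: np.ndarray, factor: float) -> np.ndarray:
    """Bilinear downscaling of an RGB image; ``factor=1`` is the identity."""
    image = _check_rgb(image)
    if not (0 < factor <= 1):
        raise ValidationError("rescale factor must be in (0, 1]")
    if factor == 1.0:
        return image.copy()
    h = int(round(image.shape[0] * factor))
    w = int(round(image.shape[1] * factor))
    if h < 1 or w < 1:
        raise ValidationError("rescaled image would be empty")
    out = transform.resize(image.astype(float), (h, w), order=1,
                           anti_aliasing=False, preserve_range=True)
    return np.clip(np.round(out), 0, 255).astype(np.uint8)


def label_spikes(mask: np.ndarray, min_area: int = DEFAULT_MIN_AREA) -> LabeledScene:
    """Enumerate 8-connected components of area >= ``min_area``.

    Components are renumbered 1..k left-to-right by bounding-box left edge
    (ties: top edge), matching how spikes are laid out on a scanner bed.
    """
    mask = np.asarray(mask).astype(bool)
    raw = measure.label(mask, connectivity=2)
    props = [p for p in measure.regionprops(raw) if p.area >= min_area]
    props.sort(key=lambda p: (p.bbox[1], p.bbox[0]))
    labels = np.zeros_like(raw)
    scene = LabeledScene(labels=labels, k=len(props))
    for new_label, p in enumerate(props, start=1):
        labels[raw == p.label] = new_label
        scene.bboxes.append(tuple(p.bbox))
        scene.centroids.append(tuple(p.centroid))
        scene.areas.append(int(p.area))
    return scene


def segment_image(image: np.ndarray, params: SegmentationParams):
    """Full stage: optional rescale, threshold, component filter.

    Returns ``(mask, LabeledScene, working_image)`` where ``working_image``
    is the (possibly rescaled) image the mask refers to.
    """
    params.validate()
    work = rescale_image(image, params.rescale_rgb)
    if params.method == "channel_thresh":
        mask = channel_threshold_mask(work, params.channel, params.threshold)
    else:
        mask = scaled_otsu_mask(work, params.otsu_factor)
    scene = label_spikes(mask, params.effective_min_area)
    return mask, scene, work


def extract_spike(image: np.ndarray, scene: LabeledScene, label: int,
                  pad_px: int = DEFAULT_PAD_PX) -> SpikeRecord:
    """Crop one spike with background zeroed, in RGB, HSV and CIELAB.

    The crop covers the component's bounding box plus ``pad_px`` on every
    side (zero-padded beyond the image border), which gives downstream
    morphology room to operate.
    """
    image = _check_rgb(image)
    if not (1 <= label <= scene.k):
        raise KeyError(f"unknown spike label {label}")
    r0, c0, r1, c1 = scene.bboxes[label - 1]
    h, w = r1 - r0 + 2 * pad_px, c1 - c0 + 2 * pad_px

    mask = np.zeros((h, w), dtype=bool)
    rgb = np.zeros((h, w, 3), dtype=np.uint8)
    rr0, cc0 = max(r0 - pad_px, 0), max(c0 - pad_px, 0)
    rr1 = min(r1 + pad_px, image.shape[0])
    cc1 = min(c1 + pad_px, image.shape[1])
    dst_r = rr0 - (r0 - pad_px)
    dst_c = cc0 - (c0 - pad_px)
    sub_labels = scene.labels[rr0:rr1, cc0:cc1]
    sub_mask = sub_labels == label
    mask[dst_r:dst_r + sub_mask.shape[0], dst_c:dst_c + sub_mask.shape[1]] = sub_mask
    sub_rgb = image[rr0:rr1, cc0:cc1]
    rgb_block = np.where(sub_mask[..., None], sub_rgb, 0)
    rgb[dst_r:dst_r + sub_mask.shape[0], dst_c:dst_c + sub_mask.shape[1]] = rgb_block

    rgb_f = rgb.astype(float) / 255.0
    hsv = skcolor.rgb2hsv(rgb_f)
    hsv[..., 0] *= 360.0
    hsv[..., 1] *= 255.0
    hsv[..., 2] *= 255.0
    lab = skcolor.rgb2lab(rgb_f)
    return SpikeRecord(label=label, bbox=(r0, c0, r1, c1), pad_px=pad_px,
                       mask=mask, rgb=rgb, hsv=hsv, lab=lab)


def count_rmse(predicted, observed):
    """Count RMSE across images and the SD of the absolute per-image error.

    ``rmse = sqrt(mean((p - o)^2))``; the second value is the population
    standard deviation of ``|p - o|`` (the error bars of the threshold
    sweeps).
    """
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.size == 0 or p.shape != o.shape:
        raise ValidationError("predicted/observed must be equal-length, non-empty")
    err = p - o
    rmse = float(np.sqrt(np.mean(err ** 2)))
    sd = float(np.std(np.abs(err)))
    return rmse, sd
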