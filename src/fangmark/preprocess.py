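"""Contrast enhancement by weighted exposure fusion, resizing, augmentation.

The enhancement follows the camera-response exposure-fusion scheme: a
brightness transform function (BTF) simulates a longer exposure of the
under-exposed regions, an illumination-derived weight map decides per pixel
how much of the original versus the synthetic exposure to keep, and the
fused result is the pixelwise weighted sum over the exposure set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

# Camera-model BTF defaults; exposed through EnhanceConfig.
BTF_A = -0.3293
BTF_B = 1.1258
DEFAULT_MU = 0.5
DEFAULT_RATIO_GRID = (1.5, 2.0, 3.0, 4.0, 6.0, 8.0)


class PreprocessError(ValueError):
    pass


@dataclass(frozen=True)
class EnhanceConfig:
    """Tunables of the exposure-fusion enhancement stage."""

    btf_a: float = BTF_A
    btf_b: float = BTF_B
    mu: float = DEFAULT_MU
    ratio_grid: tuple[float, ...] = DEFAULT_RATIO_GRID
    underexposed_threshold: float = 0.5
    # below this under-exposed pixel fraction the image counts as well
    # exposed: a handful of dark pixels (e.g. deep wound marks) must not
    # dictate a global exposure boost, and this is what makes repeated
    # enhancement saturate
    underexposed_fraction_floor: float = 0.05


@dataclass(frozen=True)
class AugmentConfig:
    """Flip/zoom augmentation settings.

    ``rotate90`` emits one 90-degree rotated variant, ``zoom`` one seeded
    center-zoom variant with factor drawn uniformly from ``zoom_range``
    (factor < 1 crops then rescales to the original size), and ``mirror``
    optionally adds a horizontal mirror.
    """

    rotate90: bool = True
    zoom: bool = True
    mirror: bool = False
    zoom_range: tuple[float, float] = (0.5, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.zoom_range
        if not (0.0 < lo <= hi <= 2.0):
            raise PreprocessError(f"zoom_range must lie in (0, 2]: {self.zoom_range}")

    @property
    def n_variants(self) -> int:
        return int(self.rotate90) + int(self.zoom) + int(self.mirror)


@dataclass
class ExposureSet:
    """The images P_i of an exposure stack, their weight maps and ratios."""

    images: list[np.ndarray]  # each H x W x 3 in [0, 1]
    weights: list[np.ndarray]  # each H x W, summing to 1 pixelwise
    ratios: list[float]

    def __post_init__(self) -> None:
        if len(self.images) < 1:
            raise PreprocessError("exposure set must contain >= 1 image")
        if not (len(self.images) == len(self.weights) == len(self.ratios)):
            raise PreprocessError("images, weights, ratios must align")
        shape = self.images[0].shape
        for im in self.images:
            if im.shape != shape:
                raise PreprocessError("all exposures must share one shape")
        for w in self.weights:
            if w.shape != shape[:2]:
                raise PreprocessError("weight maps must match image H x W")
        total = np.sum(self.weights, axis=0)
        if not np.allclose(total, 1.0, atol=1e-6):
            raise PreprocessError("weight maps must sum to 1 at every pixel")
        if any(k <= 0 for k in self.ratios):
            raise PreprocessError("exposure ratios must be > 0")


def _as_image(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image, dtype=np.float64)
    if img.size == 0:
        raise PreprocessError("empty image")
    return img


def brightness_transform(image: np.ndarray, exposure_ratio: float,
                         a: float = BTF_A, b: float = BTF_B) -> np.ndarray:
    """Apply the camera-model BTF g(P, k) = e^{b(1-k^a)} * P^{k^a}.

    Identity at ratio 1; monotone in the input; clipped to [0, 1].
    """
    if exposure_ratio <= 0:
        raise PreprocessError(f"exposure ratio must be > 0, got {exposure_ratio}")
    img = _as_image(image)
    beta = np.exp(b * (1.0 - exposure_ratio ** a))
    gamma = exposure_ratio ** a
    return np.clip(beta * np.power(img, gamma), 0.0, 1.0)


def estimate_weight_map(image: np.ndarray, mu: float = DEFAULT_MU) -> np.ndarray:
    """Weight map W = T^mu with T the per-pixel max-channel illumination."""
    if not (0.0 < mu <= 1.0):
        raise PreprocessError(f"mu must lie in (0, 1], got {mu}")
    img = _as_image(image)
    illum = img.max(axis=2) if img.ndim == 3 else img
    return np.power(np.clip(illum, 0.0, 1.0), mu)


def find_exposure_ratio(image: np.ndarray,
                        grid: tuple[float, ...] = DEFAULT_RATIO_GRID,
                        config: EnhanceConfig | None = None) -> float:
    """Pick the grid ratio whose transformed under-exposed pixels have the
    highest-entropy brightness histogram; ties and the (near-)degenerate
    well-exposed case resolve to the smallest ratio."""
    cfg = config or EnhanceConfig(ratio_grid=tuple(grid))
    candidates = sorted(cfg.ratio_grid if config else grid)
    if not candidates:
        raise PreprocessError("empty exposure-ratio grid")
    img = _as_image(image)
    weights = estimate_weight_map(img, cfg.mu)
    dark = weights < cfg.underexposed_threshold
    if dark.mean() < cfg.underexposed_fraction_floor:
        return float(candidates[0])
    illum = img.max(axis=2) if img.ndim == 3 else img
    dark_pixels = illum[dark]
    best_ratio, best_entropy = candidates[0], -np.inf
    for k in candidates:
        transformed = brightness_transform(dark_pixels, k,
                                           a=cfg.btf_a, b=cfg.btf_b)
        hist, _ = np.histogram(transformed, bins=128, range=(0.0, 1.0))
        p = hist[hist > 0] / dark_pixels.size
        entropy = float(-(p * np.log2(p)).sum())
        if entropy > best_entropy + 1e-12:
            best_entropy, best_ratio = entropy, k
    return float(best_ratio)


def fuse_exposures(exposure_set: ExposureSet) -> np.ndarray:
    """Per channel c: R_c = sum_i W_i * P_i[c], the enhancement result."""
    out = np.zeros_like(exposure_set.images[0])
    for w, p in zip(exposure_set.weights, exposure_set.images):
        out += w[:, :, None] * p if p.ndim == 3 else w * p
    return np.clip(out, 0.0, 1.0)


def enhance(image: np.ndarray, config: EnhanceConfig | None = None) -> np.ndarray:
    """Two-exposure fusion: original weighted by W, synthetic exposure by 1-W.

    Well-exposed pixels (W near 1) pass through unchanged; under-exposed
    regions are replaced mostly by the brightened exposure, so their mean
    intensity never decreases.
    """
    cfg = config or EnhanceConfig()
    img = _as_image(image)
    if img.ndim == 2:
        img = np.repeat(img[:, :, None], 3, axis=2)
    weight = estimate_weight_map(img, cfg.mu)
    ratio = find_exposure_ratio(img, config=cfg)
    bright = brightness_transform(img, ratio, a=cfg.btf_a, b=cfg.btf_b)
    stack = ExposureSet(images=[img, bright],
                        weights=[weight, 1.0 - weight],
                        ratios=[1.0, ratio])
    return fuse_exposures(stack)


def resize_to_canonical(image: np.ndarray, side: int = 1000) -> np.ndarray:
    """Bilinear resize to side x side x 3; grayscale replicated to 3 channels."""
    if side < 8:
        raise PreprocessError(f"canonical side must be >= 8, got {side}")
    img = _as_image(image)
    if img.ndim == 2:
        img = np.repeat(img[:, :, None], 3, axis=2)
    if img.shape[:2] == (side, side):
        return img.copy()
    downscale = side < max(img.shape[:2])
    out = resize(img, (side, side, 3), order=1, mode="reflect",
                 anti_aliasing=downscale, preserve_range=True)
    return np.clip(out, 0.0, 1.0)


def _center_zoom(image: np.ndarray, factor: float) -> np.ndarray:
    """Zoom in by cropping the central ``factor`` fraction then rescaling."""
    if factor >= 1.0:
        return image.copy()
    h, w = image.shape[:2]
    ch, cw = max(int(round(h * factor)), 1), max(int(round(w * factor)), 1)
    top, left = (h - ch) // 2, (w - cw) // 2
    crop = image[top:top + ch, left:left + cw]
    out = resize(crop, image.shape, order=1, mode="reflect",
                 anti_aliasing=False, preserve_range=True)
    return np.clip(out, 0.0, 1.0)


def augment(image: np.ndarray, config: AugmentConfig | None = None) -> list[np.ndarray]:
    """Emit the original plus one variant per enabled augmentation kind."""
    cfg = config or AugmentConfig()
    img = _as_image(image)
    rng = np.random.default_rng(cfg.seed)
    out = [img.copy()]
    if cfg.rotate90:
        out.append(np.rot90(img).copy())  # exact, no interpolation
    if cfg.zoom:
        factor = float(rng.uniform(*cfg.zoom_range))
        out.append(_center_zoom(img, factor))
    if cfg.mirror:
        out.append(img[:, ::-1].copy())
    return out
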