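"""Seeded generation of two-class bite-mark images and epidemiology tables.

The two classes mirror the anatomical distinction the classifier relies on:
a venomous "cobra" bite leaves two deep fang punctures, while a bite from a
non-venomous species leaves a curved double row of many small tooth marks.
Every generator is deterministic for a fixed seed so downstream modules are
testable without any external dataset.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

COBRA = "cobra"
OTHER = "other"
LABELS = (COBRA, OTHER)


class GenerationError(ValueError):
    """Raised for invalid generator inputs (unknown label, bad counts)."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters controlling synthetic bite-mark rendering.

    All ranges are inclusive ``(low, high)`` tuples in pixel or intensity
    units; sampling is uniform within each range.
    """

    image_size: int = 256
    fang_distance_range: tuple[float, float] = (0.22, 0.34)  # fraction of side
    puncture_radius_range: tuple[float, float] = (0.030, 0.045)  # fraction
    tooth_radius_range: tuple[float, float] = (0.012, 0.02)  # fraction
    n_teeth_range: tuple[int, int] = (6, 10)  # per row
    puncture_depth: float = 0.9
    tooth_depth: float = 0.6
    mark_mass: float = 0.08  # exact fraction of intensity removed by marks
    texture_amplitude: float = 0.04
    brightness_range: tuple[float, float] = (0.3, 1.0)
    noise_sigma_range: tuple[float, float] = (0.0, 0.05)
    base_tone: tuple[float, float, float] = (0.78, 0.62, 0.52)

    def __post_init__(self) -> None:
        if self.image_size < 32:
            raise GenerationError("image_size must be >= 32")
        for name in ("fang_distance_range", "puncture_radius_range",
                     "tooth_radius_range", "n_teeth_range",
                     "brightness_range", "noise_sigma_range"):
            lo, hi = getattr(self, name)
            if hi < lo:
                raise GenerationError(f"{name} is empty: {lo!r} > {hi!r}")


@dataclass
class LabeledImage:
    """An H x W x 3 float image in [0, 1] with its class label and provenance."""

    pixels: np.ndarray
    label: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise GenerationError(
                f"unknown label {self.label!r}; expected one of {LABELS}")
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 3 or px.shape[2] != 3:
            raise GenerationError("pixels must be H x W x 3")
        if px.shape[0] < 32 or px.shape[1] < 32:
            raise GenerationError("image must be at least 32 x 32")
        if not np.all(np.isfinite(px)) or px.min() < 0.0 or px.max() > 1.0:
            raise GenerationError("pixels must be finite and within [0, 1]")
        self.pixels = px


@dataclass(frozen=True)
class StateEpidemiology:
    """Per-state snakebite counts: total bites n, deaths d, dangerous cases p."""

    state: str
    n: int
    d: int
    p: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise GenerationError("n (total bites) must be >= 1")
        if self.d < 0 or self.p < 0:
            raise GenerationError("d and p must be >= 0")
        if self.p + self.d > self.n:
            raise GenerationError("p + d must not exceed n")


def _skin_background(rng: np.random.Generator, cfg: GeneratorConfig) -> np.ndarray:
    side = cfg.image_size
    base = np.empty((side, side, 3))
    for c, tone in enumerate(cfg.base_tone):
        field_ = rng.standard_normal((side, side))
        field_ = gaussian_filter(field_, sigma=side / 24.0)
        peak = np.abs(field_).max()
        if peak > 0:
            field_ *= cfg.texture_amplitude / peak
        base[:, :, c] = tone + field_
    return base


def _mark_profile(side: int, cy: float, cx: float, ry: float, rx: float,
                  angle: float) -> np.ndarray:
    """Soft elliptical gaussian bump, peak 1, used as a mark footprint."""
    yy, xx = np.mgrid[0:side, 0:side].astype(np.float64)
    dy, dx = yy - cy, xx - cx
    ca, sa = np.cos(angle), np.sin(angle)
    u = (ca * dx + sa * dy) / rx
    v = (-sa * dx + ca * dy) / ry
    return np.exp(-0.5 * (u ** 2 + v ** 2) * 4.0)


def _apply_marks(img: np.ndarray, log_depth: np.ndarray,
                 target_mass: float) -> None:
    """Darken by exp(-t * log_depth) with t chosen so the mean intensity
    removed equals ``target_mass`` exactly.

    Normalizing the removed mass per image makes overall brightness
    uninformative about the class, so classifiers must rely on the spatial
    mark pattern rather than a mean-intensity shortcut.
    """
    if log_depth.max() <= 0 or target_mass <= 0:
        return
    lo, hi = 0.0, 1.0
    deficit = lambda t: float(np.mean(1.0 - np.exp(-t * log_depth)))  # noqa: E731
    while deficit(hi) < target_mass and hi < 1e4:
        hi *= 2.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if deficit(mid) < target_mass:
            lo = mid
        else:
            hi = mid
    img *= np.exp(-0.5 * (lo + hi) * log_depth)[:, :, None]


def generate_bite_image(label: str,
                        config: GeneratorConfig | None = None,
                        seed: int = 0) -> LabeledImage:
    """Render one synthetic bite-mark image.

    ``cobra`` images carry exactly two elliptical fang punctures separated by
    a sampled inter-fang distance; ``other`` images carry a curved double row
    of at least six small tooth marks. Mark centers are recorded in ``meta``.
    """
    if label not in LABELS:
        raise GenerationError(
            f"unknown label {label!r}; expected one of {LABELS}")
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(seed)
    side = cfg.image_size
    img = _skin_background(rng, cfg)

    center = side / 2.0 + rng.uniform(-0.02, 0.02, size=2) * side
    axis_angle = rng.uniform(-0.2, 0.2)  # radians, near-horizontal bite axis
    centers: list[tuple[float, float]] = []

    log_depth = np.zeros((side, side))
    if label == COBRA:
        # two deep fang punctures on the bite axis through the center
        gap = rng.uniform(*cfg.fang_distance_range) * side
        radius = rng.uniform(*cfg.puncture_radius_range) * side
        ca, sa = np.cos(axis_angle), np.sin(axis_angle)
        for sign in (-1.0, 1.0):
            cy = center[0] + sign * sa * gap / 2.0
            cx = center[1] + sign * ca * gap / 2.0
            log_depth += cfg.puncture_depth * _mark_profile(
                side, cy, cx, radius * rng.uniform(0.9, 1.1), radius,
                angle=rng.uniform(0, np.pi))
            centers.append((float(cy), float(cx)))
    else:
        # upper/lower jaw imprint: two gently curved rows of small teeth
        n_teeth = int(rng.integers(cfg.n_teeth_range[0],
                                   cfg.n_teeth_range[1] + 1))
        row_offset = rng.uniform(0.10, 0.14) * side
        span = rng.uniform(0.22, 0.28) * side
        bow = rng.uniform(0.02, 0.04) * side  # curvature of each row
        xs = np.linspace(-span, span, n_teeth)
        ca, sa = np.cos(axis_angle), np.sin(axis_angle)
        for row_sign in (-1.0, 1.0):
            for x_off in xs:
                curve = row_sign * bow * (1.0 - (x_off / span) ** 2)
                y_off = row_sign * row_offset - curve
                cy = center[0] + sa * x_off + ca * y_off
                cx = center[1] + ca * x_off - sa * y_off
                tooth = rng.uniform(*cfg.tooth_radius_range) * side
                log_depth += cfg.tooth_depth * _mark_profile(
                    side, cy, cx, tooth, tooth * rng.uniform(0.8, 1.2),
                    angle=rng.uniform(0, np.pi))
                centers.append((float(cy), float(cx)))
    _apply_marks(img, log_depth, cfg.mark_mass)

    brightness = rng.uniform(*cfg.brightness_range)
    noise_sigma = rng.uniform(*cfg.noise_sigma_range)
    img *= brightness
    if noise_sigma > 0:
        img += rng.normal(0.0, noise_sigma, size=img.shape)
    img = np.clip(img, 0.0, 1.0)

    meta = {
        "mark_centers": centers,
        "brightness": float(brightness),
        "noise_sigma": float(noise_sigma),
        "seed": int(seed),
    }
    return LabeledImage(pixels=img, label=label, meta=meta)


def generate_dataset(n_cobra: int, n_other: int,
                     config: GeneratorConfig | None = None,
                     seed: int = 0) -> list[LabeledImage]:
    """Generate ``n_cobra + n_other`` labeled images with per-image seeds
    derived from the master seed."""
    if n_cobra < 0 or n_other < 0:
        raise GenerationError("class counts must be >= 0")
    cfg = config or GeneratorConfig()
    master = np.random.default_rng(seed)
    seeds = master.integers(0, 2 ** 31 - 1, size=n_cobra + n_other)
    images = [generate_bite_image(COBRA, cfg, int(seeds[i]))
              for i in range(n_cobra)]
    images += [generate_bite_image(OTHER, cfg, int(seeds[n_cobra + i]))
               for i in range(n_other)]
    return images


def generate_state_table(n_states: int, seed: int = 0) -> list[StateEpidemiology]:
    """Generate a per-state epidemiology table with p + d <= n guaranteed."""
    if n_states < 0:
        raise GenerationError("n_states must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_states):
        n = int(rng.integers(50, 2000))
        severe = rng.uniform(0.02, 0.35)  # fraction of bites that turn severe
        total_severe = int(round(severe * n))
        d = int(rng.integers(0, total_severe + 1))
        p = total_severe - d
        rows.append(StateEpidemiology(state=f"state_{i:02d}", n=n, d=d, p=p))
    return rows


def write_dataset(images: list[LabeledImage], out_dir: str | Path) -> Path:
    """Write images as PNG plus a ``manifest.csv`` (path,label,seed)."""
    from PIL import Image

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = out / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["path", "label", "seed"])
        for i, im in enumerate(images):
            name = f"{im.label}_{i:05d}.png"
            arr = np.clip(np.rint(im.pixels * 255.0), 0, 255).astype(np.uint8)
            Image.fromarray(arr).save(out / name)
            writer.writerow([name, im.label, im.meta.get("seed", "")])
    return manifest


def read_dataset(directory: str | Path) -> list[LabeledImage]:
    """Load a dataset previously written by :func:`write_dataset`."""
    from PIL import Image

    directory = Path(directory)
    manifest = directory / "manifest.csv"
    images = []
    with open(manifest, newline="") as fh:
        for row in csv.DictReader(fh):
            arr = np.asarray(Image.open(directory / row["path"]).convert("RGB"))
            pixels = arr.astype(np.float64) / 255.0
            seed = int(row["seed"]) if row["seed"] else -1
            images.append(LabeledImage(pixels=pixels, label=row["label"],
                                       meta={"seed": seed,
                                             "path": row["path"]}))
    return images


def write_state_table(rows: list[StateEpidemiology], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["state", "n", "d", "p"])
        for r in rows:
            writer.writerow([r.state, r.n, r.d, r.p])


def read_state_table(path: str | Path) -> list[StateEpidemiology]:
    with open(path, newline="") as fh:
        return [StateEpidemiology(state=row["state"], n=int(row["n"]),
                                  d=int(row["d"]), p=int(row["p"]))
                for row in csv.DictReader(fh)]
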