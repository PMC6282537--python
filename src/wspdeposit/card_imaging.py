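"""Synthetic WSP card images and stain segmentation.

The synthetic side rasterizes circular stains of known physical
diameter onto a grayscale card at a given scan resolution (dpi), using
deterministic pixel-center-in-circle rasterization so every generated
image has an exact pixel-count ground truth.  This reproduces the kind
of artificial-stain fixtures used to validate droplet-analysis software
(equal-size stain pairs that touch tangentially or sit apart, and
field-like cards with a right-skewed diameter spectrum).

The segmentation side binarizes a card scan (automatic between-class
variance threshold, i.e. Otsu, or a fixed level) and extracts connected
components as :class:`~wspdeposit.stain_geometry.StainRecord` objects.
Touching stains deliberately merge into a single component — the
working assumption of DepositScan-style analysis.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

from .stain_geometry import StainRecord, stain_diameter_from_area

__all__ = [
    "UM_PER_INCH",
    "PlacementError",
    "CardImage",
    "SegmentationConfig",
    "blank_card",
    "rasterize_circle",
    "generate_touching_pair",
    "generate_card",
    "sample_log_uniform_diameters",
    "sample_field_diameters",
    "binarize",
    "extract_stains",
    "segment_card",
    "read_card",
    "write_card",
]

UM_PER_INCH = 25400.0


class PlacementError(RuntimeError):
    """Raised when random stain placement exhausts its retry budget."""


@dataclass
class CardImage:
    """A grayscale card scan: uint8 pixel grid plus its resolution."""

    pixels: np.ndarray
    dpi: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.uint8)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D grayscale array")
        if self.dpi <= 0:
            raise ValueError("dpi must be > 0")

    @property
    def pitch_um(self) -> float:
        """Pixel pitch in µm (600 dpi -> 42.3̄ µm)."""
        return UM_PER_INCH / self.dpi

    @property
    def height_px(self) -> int:
        return self.pixels.shape[0]

    @property
    def width_px(self) -> int:
        return self.pixels.shape[1]

    @property
    def area_cm2(self) -> float:
        """Physical card area in cm² (1 cm² = 1e8 µm²)."""
        return self.width_px * self.height_px * self.pitch_um**2 * 1e-8


@dataclass
class SegmentationConfig:
    threshold_mode: str = "automatic"  # "automatic" | "fixed"
    fixed_threshold: int = 128
    connectivity: int = 8  # 4 or 8
    min_pixels: int = 1
    stains_darker: bool = True

    def __post_init__(self) -> None:
        if self.threshold_mode not in ("automatic", "fixed"):
            raise ValueError(f"unknown threshold_mode {self.threshold_mode!r}")
        if not 0 <= self.fixed_threshold <= 255:
            raise ValueError("fixed_threshold must be in [0, 255]")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.min_pixels < 1:
            raise ValueError("min_pixels must be >= 1")


def blank_card(width_px: int, height_px: int, dpi: float, background: int = 255) -> CardImage:
    return CardImage(np.full((height_px, width_px), background, dtype=np.uint8), dpi)


def _circle_mask(shape, center, radius_px):
    cx, cy = center
    x0 = max(int(math.floor(cx - radius_px)), 0)
    x1 = min(int(math.ceil(cx + radius_px)), shape[1] - 1)
    y0 = max(int(math.floor(cy - radius_px)), 0)
    y1 = min(int(math.ceil(cy + radius_px)), shape[0] - 1)
    ys, xs = np.mgrid[y0 : y1 + 1, x0 : x1 + 1]
    inside = (xs - cx) ** 2 + (ys - cy) ** 2 <= radius_px**2
    return (slice(y0, y1 + 1), slice(x0, x1 + 1)), inside


def rasterize_circle(
    image: CardImage,
    center: tuple[float, float],
    diameter_um: float,
    intensity: int = 0,
) -> int:
    """Draw a circular stain; returns the number of pixels set.

    A pixel belongs to the stain when its center (integer coordinates,
    0-based) lies within the circle.  The circle must fit inside the
    image bounds.
    """
    if diameter_um <= 0:
        raise ValueError("diameter must be > 0")
    r_px = 0.5 * diameter_um / image.pitch_um
    cx, cy = center
    if (
        cx - r_px < -0.5
        or cy - r_px < -0.5
        or cx + r_px > image.width_px - 0.5
        or cy + r_px > image.height_px - 0.5
    ):
        raise ValueError(
            f"circle of diameter {diameter_um} µm at {center} exceeds the "
            f"{image.width_px}x{image.height_px} px card bounds"
        )
    window, inside = _circle_mask(image.pixels.shape, (cx, cy), r_px)
    image.pixels[window][inside] = intensity
    return int(inside.sum())


def generate_touching_pair(
    diameter_um: float,
    dpi: float = 600.0,
    touching: bool = True,
    margin_px: int = 4,
    background: int = 255,
    intensity: int = 0,
) -> CardImage:
    """Two equal stains, tangent (center spacing = one diameter) or apart.

    The tangent pair merges into one component under segmentation
    (combined extent 2d x d); the separated pair keeps >= 2 pixel
    pitches of background between the stains.
    """
    pitch = UM_PER_INCH / dpi
    r_px = 0.5 * diameter_um / pitch
    sep_px = 2.0 * r_px if touching else 2.0 * r_px + 4.0
    width = int(math.ceil(2 * r_px + sep_px)) + 2 * margin_px + 2
    height = int(math.ceil(2 * r_px)) + 2 * margin_px + 2
    card = blank_card(width, height, dpi, background)
    cy = (height - 1) / 2.0
    cx1 = margin_px + r_px + 0.5
    rasterize_circle(card, (cx1, cy), diameter_um, intensity)
    rasterize_circle(card, (cx1 + sep_px, cy), diameter_um, intensity)
    return card


def generate_card(
    stain_diameters: Sequence[float],
    dpi: float = 600.0,
    width_px: int = 512,
    height_px: int = 512,
    rng: np.random.Generator | int | None = None,
    margin_px: int = 2,
    min_gap_px: float = 2.0,
    max_tries: int = 2000,
    background: int = 255,
    intensity: int = 0,
) -> tuple[CardImage, pd.DataFrame]:
    """Random non-overlapping placement of circular stains on a card.

    Returns the card image and a ground-truth table (stain_id,
    diameter_um, x_px, y_px, pixel_count).  Placement is reproducible
    from ``rng``; stains are placed largest-first and kept at least
    ``min_gap_px`` apart so segmentation recovers them individually.
    """
    rng = np.random.default_rng(rng)
    card = blank_card(width_px, height_px, dpi, background)
    pitch = card.pitch_um
    order = np.argsort(stain_diameters)[::-1]
    placed: list[tuple[float, float, float]] = []  # (cx, cy, r_px)
    rows = []
    for idx in order:
        d_um = float(stain_diameters[idx])
        r_px = 0.5 * d_um / pitch
        lo_x, hi_x = margin_px + r_px + 0.5, width_px - 1.5 - margin_px - r_px
        lo_y, hi_y = margin_px + r_px + 0.5, height_px - 1.5 - margin_px - r_px
        if lo_x >= hi_x or lo_y >= hi_y:
            raise PlacementError(
                f"stain of {d_um} µm does not fit a {width_px}x{height_px} px card; "
                "use a larger card or fewer/smaller stains"
            )
        for _ in range(max_tries):
            cx = rng.uniform(lo_x, hi_x)
            cy = rng.uniform(lo_y, hi_y)
            if all(
                math.hypot(cx - px, cy - py) >= r_px + pr + min_gap_px
                for px, py, pr in placed
            ):
                break
        else:
            raise PlacementError(
                f"could not place stain of {d_um} µm after {max_tries} tries; "
                "use a larger card or fewer stains"
            )
        n_px = rasterize_circle(card, (cx, cy), d_um, intensity)
        placed.append((cx, cy, r_px))
        rows.append({"stain_id": int(idx), "diameter_um": d_um, "x_px": cx, "y_px": cy, "pixel_count": n_px})
    truth = pd.DataFrame(rows, columns=["stain_id", "diameter_um", "x_px", "y_px", "pixel_count"])
    if len(truth):
        truth = truth.sort_values("stain_id").reset_index(drop=True)
    return card, truth


def sample_log_uniform_diameters(
    n: int,
    low_um: float = 95.5,
    high_um: float = 1438.0,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Log-uniform stain diameters over the artificial-stain range."""
    rng = np.random.default_rng(rng)
    return np.exp(rng.uniform(math.log(low_um), math.log(high_um), size=n))


def sample_field_diameters(
    n: int,
    rng: np.random.Generator | int | None = None,
    median_um: float = 134.0,
    sigma_log: float = 0.678,
    low_um: float = 52.8,
    high_um: float = 1438.0,
) -> np.ndarray:
    """Right-skewed droplet-diameter spectrum typical of orchard spraying.

    Truncated lognormal calibrated so that roughly a third of droplets
    are <= 100 µm and over 70% are < 200 µm, matching the strong skew
    toward fine droplets seen on field cards.
    """
    rng = np.random.default_rng(rng)
    out = np.empty(0)
    while out.size < n:
        draw = rng.lognormal(math.log(median_um), sigma_log, size=2 * n)
        out = np.concatenate([out, draw[(draw >= low_um) & (draw <= high_um)]])
    return out[:n]


def binarize(image: CardImage, config: SegmentationConfig | None = None) -> np.ndarray:
    """Boolean stain mask from a grayscale card.

    Automatic mode maximizes between-class variance on the intensity
    histogram (Otsu); a uniform image falls back to the fixed threshold
    with a warning.  Stains are the darker class by default.
    """
    config = SegmentationConfig() if config is None else config
    px = image.pixels
    if config.threshold_mode == "automatic":
        if px.min() == px.max():
            warnings.warn(
                "uniform image: automatic threshold undefined, falling back to "
                f"fixed threshold {config.fixed_threshold}",
                stacklevel=2,
            )
            thr = config.fixed_threshold
        else:
            thr = threshold_otsu(px)
    else:
        thr = config.fixed_threshold
    return px <= thr if config.stains_darker else px > thr


def extract_stains(
    mask: np.ndarray, dpi: float, config: SegmentationConfig | None = None
) -> list[StainRecord]:
    """Connected components of the mask as stain records.

    Components smaller than ``min_pixels`` are dropped; areas convert
    via the squared pixel pitch.
    """
    config = SegmentationConfig() if config is None else config
    pitch = UM_PER_INCH / dpi
    lab = label(mask, connectivity=2 if config.connectivity == 8 else 1)
    stains = []
    for rp in regionprops(lab):
        if rp.area < config.min_pixels:
            continue
        area_um2 = float(rp.area) * pitch**2
        stains.append(
            StainRecord(
                pixel_count=int(rp.area),
                area_um2=area_um2,
                stain_diameter_um=float(stain_diameter_from_area(area_um2)),
                centroid=(float(rp.centroid[1]), float(rp.centroid[0])),
            )
        )
    return stains


def segment_card(
    image: CardImage, config: SegmentationConfig | None = None
) -> tuple[np.ndarray, list[StainRecord]]:
    config = SegmentationConfig() if config is None else config
    mask = binarize(image, config)
    return mask, extract_stains(mask, image.dpi, config)


def read_card(path, dpi: float) -> CardImage:
    """Read a PNG/BMP/TIFF/GIF scan; color inputs convert by luminance."""
    arr = iio.imread(Path(path))
    if arr.ndim == 3:
        arr = arr[..., :3] @ np.array([0.299, 0.587, 0.114])
    return CardImage(np.clip(np.round(arr), 0, 255).astype(np.uint8), dpi)


def write_card(image: CardImage, path) -> None:
    iio.imwrite(Path(path), image.pixels)
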