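"""Two-path segmentation of marbled tissue crops.

A square RGB crop is reduced to a binary fat/muscle mask by one of two
routes:

* **unfiltered** — grayscale, then a fixed manual threshold at 175: pale
  (white/yellow) fat pixels go above it, dark red lean pixels below.
* **high-pass filtered** — the grayscale crop is high-pass filtered
  (original minus a Gaussian blur, re-centred at mid-gray 128) at radius
  25 or 50 px, the high-pass layer is superimposed on the original with
  an Overlay blend, and the result is thresholded at 150.  The high-pass
  step flattens slowly varying illumination/color so the threshold acts
  on local contrast rather than absolute brightness.

Masks are boolean ``numpy`` arrays with ``True`` = fat.  The pixel-table
export encodes each pixel as ``(column, row, code)`` with 1-based
coordinates, code 1 for fat and 2 for muscle, in row-major order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "FAT_CODE",
    "MUSCLE_CODE",
    "FilterConfig",
    "crop_square",
    "to_grayscale",
    "gaussian_blur",
    "high_pass",
    "overlay_blend",
    "binarize",
    "run_unfiltered",
    "run_highpass",
    "run_method",
    "mask_to_table",
    "table_to_mask",
    "fat_fraction",
]

FAT_CODE = 1
MUSCLE_CODE = 2

#: method name -> high-pass radius in px (None = unfiltered path)
METHOD_RADII: dict[str, float | None] = {"unfiltered": None, "hp25": 25.0, "hp50": 50.0}


@dataclass(frozen=True)
class FilterConfig:
    """Parameters of the two segmentation paths.

    radius_px
        High-pass filter radius in pixels (25 or 50 in the reference
        workflow).  Must satisfy ``0 < radius_px < crop_side / 2``.
    threshold_filtered, threshold_unfiltered
        Gray-level cut points (150 and 175 respectively); a pixel at or
        above the threshold is labelled fat.
    crop_side
        Side of the square crop the pipeline operates on (512 px).
    """

    radius_px: float = 25.0
    threshold_filtered: int = 150
    threshold_unfiltered: int = 175
    crop_side: int = 512

    def __post_init__(self) -> None:
        if not 0 < self.radius_px < self.crop_side / 2:
            raise ValueError(
                f"radius_px must lie in (0, crop_side/2); got {self.radius_px}"
            )
        for name in ("threshold_filtered", "threshold_unfiltered"):
            t = getattr(self, name)
            if not 0 <= t <= 255:
                raise ValueError(f"{name} must be in [0, 255]; got {t}")
        if self.crop_side < 1:
            raise ValueError("crop_side must be positive")


def _round_half_up(x: np.ndarray) -> np.ndarray:
    # np.rint rounds half to even; the pipeline fixes half-up for
    # bit-reproducibility across platforms.
    return np.floor(x + 0.5)


def crop_square(image: np.ndarray, top_left: tuple[int, int], side: int) -> np.ndarray:
    """Copy a ``side`` x ``side`` window out of an RGB image.

    ``top_left`` is (row, col) of the window's upper-left pixel; the
    window must lie fully inside the image.
    """
    r, c = top_left
    h, w = image.shape[:2]
    if side < 1:
        raise ValueError("side must be positive")
    if r < 0 or c < 0 or r + side > h or c + side > w:
        raise ValueError(
            f"crop window (({r},{c}), side={side}) exceeds image of shape {h}x{w}"
        )
    return image[r : r + side, c : c + side].copy()


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Rec. 601 luma, rounded half-up to 8 bits: 0.299 R + 0.587 G + 0.114 B."""
    rgb = np.asarray(image, dtype=np.float64)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError("expected an HxWx3 RGB array")
    luma = 0.299 * rgb[..., 0] + 0.587 * rgb[..., 1] + 0.114 * rgb[..., 2]
    return np.clip(_round_half_up(luma), 0, 255).astype(np.uint8)


def gaussian_blur(image: np.ndarray, radius_px: float) -> np.ndarray:
    """Isotropic Gaussian blur with sigma = radius/3, truncated at 3 sigma.

    Borders are handled by edge replication so crop edges do not acquire
    a dark vignette that would read as low-frequency signal.  Output is
    kept at float precision for the downstream high-pass subtraction.
    """
    if radius_px <= 0:
        raise ValueError("radius_px must be positive")
    return ndimage.gaussian_filter(
        np.asarray(image, dtype=np.float64),
        sigma=radius_px / 3.0,
        mode="nearest",
        truncate=3.0,
    )


def high_pass(image: np.ndarray, radius_px: float) -> np.ndarray:
    """High-pass layer: original − Gaussian blur + 128, clipped to 8 bits.

    Constant and slowly varying content maps to mid-gray 128; detail at
    scales below ``radius_px`` survives as excursions around it.
    """
    img = np.asarray(image, dtype=np.float64)
    if radius_px >= min(img.shape[:2]) / 2:
        raise ValueError("radius_px must be below half the image side")
    hp = img - gaussian_blur(img, radius_px) + 128.0
    return np.clip(_round_half_up(hp), 0, 255).astype(np.uint8)


def overlay_blend(base: np.ndarray, hp: np.ndarray) -> np.ndarray:
    """Photoshop-style Overlay blend of layer ``hp`` onto ``base``.

    With a, b the two images rescaled to [0, 1], the result is ``2ab``
    where the base is dark (a < 0.5) and ``1 − 2(1−a)(1−b)`` where it is
    light.  A uniform mid-gray (128) layer is neutral to within one gray
    level, so a high-pass layer only modulates the base near detail.
    """
    base = np.asarray(base)
    hp = np.asarray(hp)
    if base.shape != hp.shape:
        raise ValueError(f"shape mismatch: base {base.shape} vs layer {hp.shape}")
    a = base.astype(np.float64) / 255.0
    b = hp.astype(np.float64) / 255.0
    out = np.where(a < 0.5, 2.0 * a * b, 1.0 - 2.0 * (1.0 - a) * (1.0 - b))
    return np.clip(_round_half_up(out * 255.0), 0, 255).astype(np.uint8)


def binarize(image: np.ndarray, threshold: int) -> np.ndarray:
    """Label pixels at or above ``threshold`` fat (True), the rest muscle."""
    if not 0 <= threshold <= 255:
        raise ValueError("threshold must be in [0, 255]")
    return np.asarray(image) >= threshold


def _check_crop(image: np.ndarray, cfg: FilterConfig) -> None:
    if image.shape[:2] != (cfg.crop_side, cfg.crop_side):
        raise ValueError(
            f"expected a {cfg.crop_side}x{cfg.crop_side} crop, got {image.shape[:2]}"
        )


def run_unfiltered(image: np.ndarray, cfg: FilterConfig = FilterConfig()) -> np.ndarray:
    """Unfiltered path: grayscale then threshold at ``cfg.threshold_unfiltered``."""
    _check_crop(image, cfg)
    return binarize(to_grayscale(image), cfg.threshold_unfiltered)


def run_highpass(image: np.ndarray, cfg: FilterConfig = FilterConfig()) -> np.ndarray:
    """Filtered path: high-pass at ``cfg.radius_px``, Overlay onto the
    grayscale original, threshold at ``cfg.threshold_filtered``.

    Filtering acts on the grayscale image (binarization follows
    immediately, so only luma matters).
    """
    _check_crop(image, cfg)
    g = to_grayscale(image)
    blended = overlay_blend(g, high_pass(g, cfg.radius_px))
    return binarize(blended, cfg.threshold_filtered)


def run_method(image: np.ndarray, method: str, cfg: FilterConfig = FilterConfig()) -> np.ndarray:
    """Dispatch on method name: ``unfiltered``, ``hp25`` or ``hp50``."""
    if method not in METHOD_RADII:
        raise ValueError(f"unknown method {method!r}; choose from {sorted(METHOD_RADII)}")
    radius = METHOD_RADII[method]
    if radius is None:
        return run_unfiltered(image, cfg)
    return run_highpass(image, FilterConfig(radius, cfg.threshold_filtered,
                                            cfg.threshold_unfiltered, cfg.crop_side))


def mask_to_table(mask: np.ndarray) -> pd.DataFrame:
    """Export a mask as the three-column pixel table.

    One row per pixel in row-major order: horizontal position (column,
    1-based), vertical position (row, 1-based), and code 1 = fat (white),
    2 = muscle (black).
    """
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    rows, cols = np.indices((h, w))
    code = np.where(mask, FAT_CODE, MUSCLE_CODE)
    return pd.DataFrame(
        {
            "col": (cols + 1).ravel(),
            "row": (rows + 1).ravel(),
            "code": code.ravel(),
        }
    )


def table_to_mask(table: pd.DataFrame) -> np.ndarray:
    """Rebuild the boolean mask from a pixel table (inverse of mask_to_table)."""
    cols = table["col"].to_numpy()
    rows = table["row"].to_numpy()
    code = table["code"].to_numpy()
    h, w = int(rows.max()), int(cols.max())
    if len(table) != h * w:
        raise ValueError(f"table has {len(table)} rows; expected {h}x{w}={h * w}")
    mask = np.zeros((h, w), dtype=bool)
    mask[rows - 1, cols - 1] = code == FAT_CODE
    return mask


def fat_fraction(mask: np.ndarray) -> float:
    """Proportion of pixels labelled fat."""
    mask = np.asarray(mask, dtype=bool)
    return float(mask.sum()) / mask.size
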