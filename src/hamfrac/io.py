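"""Raster and table I/O: PNG masks, pixel-table CSV, JSON records."""

from __future__ import annotations

import json
from dataclasses import asdict, is_dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .pipeline import FAT_CODE, mask_to_table, table_to_mask

__all__ = [
    "load_image",
    "save_image",
    "save_mask_png",
    "load_mask_png",
    "write_pixel_table",
    "read_pixel_table",
    "load_mask",
    "write_json",
]


def load_image(path: str | Path) -> np.ndarray:
    """Read a PNG/TIFF/JPEG file as an HxWx3 uint8 RGB array."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))


def save_image(image: np.ndarray, path: str | Path) -> None:
    Image.fromarray(np.asarray(image, dtype=np.uint8)).save(path)


def save_mask_png(mask: np.ndarray, path: str | Path) -> None:
    """Write a boolean mask as an 8-bit PNG: fat = 255 (white), muscle = 0."""
    arr = np.where(np.asarray(mask, dtype=bool), 255, 0).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(path)


def load_mask_png(path: str | Path) -> np.ndarray:
    """Read a mask PNG; any pixel at or above 128 counts as fat."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"))
    return arr >= 128


def write_pixel_table(table: pd.DataFrame, path: str | Path) -> None:
    """Headerless 3-column CSV (col,row,code) with LF line endings."""
    table.to_csv(path, header=False, index=False, lineterminator="\n")


def read_pixel_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, header=None, names=["col", "row", "code"])
    if not df["code"].isin([1, 2]).all():
        raise ValueError(f"{path}: pixel codes must be 1 (fat) or 2 (muscle)")
    return df


def load_mask(path: str | Path) -> np.ndarray:
    """Load a mask from either a PNG or a pixel-table CSV, by extension."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        return table_to_mask(read_pixel_table(path))
    return load_mask_png(path)


def _default(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return asdict(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_json(record: dict, path: str | Path) -> None:
    """Stable JSON: sorted keys, LF endings, dataclasses/numpy handled."""
    text = json.dumps(record, indent=2, sort_keys=True, default=_default)
    Path(path).write_text(text + "\n")
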