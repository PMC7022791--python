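"""Aggregation of per-image dimension estimates into reporting tables.

Mirrors the three reporting surfaces of a designation-comparison study:
per-class/per-method means with standard errors of the mean, scatter
data of each dimension against the image's fat fraction, and
box-and-whisker five-number summaries with an interquartile-range
dispersion comparison across segmentation methods.

The standard error here is the across-sample SD/sqrt(n); the
regression standard error attached to each individual estimate is a
different quantity and is never mixed into these tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from .sandbox import DimensionEstimate

__all__ = [
    "METHODS",
    "DIMENSIONS",
    "ImageResult",
    "FiveNumber",
    "summarize",
    "five_number",
    "boxplot_table",
    "dispersion_comparison",
    "scatter_table",
    "plot_scatter",
    "plot_boxes",
]

METHODS = ("unfiltered", "hp25", "hp50")
DIMENSIONS = ("D0", "D1", "D2")
_Q_FOR = {"D0": 0.0, "D1": 1.0, "D2": 2.0}


@dataclass(frozen=True)
class ImageResult:
    """One (image, method) record: the three dimensions plus fat fraction."""

    image_id: str
    class_label: str
    method: str
    d0: DimensionEstimate
    d1: DimensionEstimate
    d2: DimensionEstimate
    fat_fraction: float

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}; got {self.method!r}")

    def value(self, dim: str) -> float:
        return {"D0": self.d0, "D1": self.d1, "D2": self.d2}[dim].value


class FiveNumber(NamedTuple):
    """Box-and-whisker statistics."""

    minimum: float
    q1: float
    median: float
    q3: float
    maximum: float


def _tidy(results: Iterable[ImageResult]) -> pd.DataFrame:
    rows = [
        {
            "image_id": r.image_id,
            "class_label": r.class_label,
            "method": r.method,
            "fat_fraction": r.fat_fraction,
            "D0": r.d0.value,
            "D1": r.d1.value,
            "D2": r.d2.value,
        }
        for r in results
    ]
    return pd.DataFrame(rows)


def summarize(results: Iterable[ImageResult]) -> pd.DataFrame:
    """Per-class, per-method mean and SE of the mean for D0, D1, D2.

    Returns one row per (class, method) with columns
    ``{D0,D1,D2}_mean``, ``{D0,D1,D2}_se`` and ``n``; SE = SD/sqrt(n)
    with the sample (ddof=1) standard deviation.  Groups of a single
    image are rejected: no standard error exists for them.
    """
    df = _tidy(results)
    if df.empty:
        raise ValueError("no results to summarize")
    out = []
    for (label, method), grp in df.groupby(["class_label", "method"], sort=True):
        if len(grp) < 2:
            raise ValueError(
                f"group ({label!r}, {method!r}) has a single image; "
                "standard errors need n >= 2"
            )
        row: dict[str, object] = {"class_label": label, "method": method, "n": len(grp)}
        for dim in DIMENSIONS:
            vals = grp[dim].to_numpy()
            row[f"{dim}_mean"] = vals.mean()
            row[f"{dim}_se"] = vals.std(ddof=1) / np.sqrt(len(vals))
        out.append(row)
    return pd.DataFrame(out)


def five_number(values: Iterable[float]) -> FiveNumber:
    """Min, quartiles and max with inclusive linear interpolation.

    The quartile convention matches SPSS's weighted-average default
    (numpy's ``linear`` method on the ordered sample).
    """
    vals = np.asarray(list(values), dtype=float)
    if vals.size < 5:
        raise ValueError(f"need at least 5 values for a five-number summary; got {vals.size}")
    q1, med, q3 = np.percentile(vals, [25, 50, 75], method="linear")
    return FiveNumber(float(vals.min()), float(q1), float(med), float(q3), float(vals.max()))


def boxplot_table(results: Iterable[ImageResult]) -> pd.DataFrame:
    """Five-number summaries per (class, method, dimension) — the box-plot data."""
    df = _tidy(results)
    out = []
    for (label, method), grp in df.groupby(["class_label", "method"], sort=True):
        for dim in DIMENSIONS:
            fn = five_number(grp[dim].to_numpy())
            out.append(
                {
                    "class_label": label,
                    "method": method,
                    "dimension": dim,
                    **fn._asdict(),
                }
            )
    return pd.DataFrame(out)


def dispersion_comparison(results: Iterable[ImageResult]) -> pd.DataFrame:
    """Pooled-over-classes IQR per method and dimension.

    One row per (method, dimension) with the interquartile range of the
    pooled estimates and a flag ``hp25_le_unfiltered`` recording
    whether the 25-px filtered path is at least as concentrated as the
    unfiltered one for that dimension.
    """
    df = _tidy(results)
    present = set(df["method"].unique())
    missing = set(METHODS) - present
    if missing:
        raise ValueError(f"dispersion comparison needs all methods; missing {sorted(missing)}")
    iqr: dict[tuple[str, str], float] = {}
    for method in METHODS:
        sub = df[df["method"] == method]
        for dim in DIMENSIONS:
            q1, q3 = np.percentile(sub[dim].to_numpy(), [25, 75], method="linear")
            iqr[(method, dim)] = float(q3 - q1)
    rows = [
        {
            "method": method,
            "dimension": dim,
            "iqr": iqr[(method, dim)],
            "hp25_le_unfiltered": iqr[("hp25", dim)] <= iqr[("unfiltered", dim)],
        }
        for method in METHODS
        for dim in DIMENSIONS
    ]
    return pd.DataFrame(rows)


def scatter_table(results: Iterable[ImageResult]) -> pd.DataFrame:
    """Tidy long-format export: one row per result, dimensions vs fat fraction."""
    df = _tidy(results)
    return df[["class_label", "method", "fat_fraction", "D0", "D1", "D2"]].copy()


def plot_scatter(scatter: pd.DataFrame, dimension: str, path: str) -> None:
    """Render dimension-vs-fat-fraction scatter panels, one per method."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    methods = [m for m in METHODS if m in set(scatter["method"])]
    fig, axes = plt.subplots(1, len(methods), figsize=(4 * len(methods), 3.2),
                             sharey=True, squeeze=False)
    for ax, method in zip(axes[0], methods):
        sub = scatter[scatter["method"] == method]
        for label, grp in sub.groupby("class_label"):
            ax.scatter(grp["fat_fraction"], grp[dimension], s=14, label=label)
        ax.set_title(method)
        ax.set_xlabel("fat fraction")
    axes[0][0].set_ylabel(dimension)
    axes[0][-1].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_boxes(results: Iterable[ImageResult], dimension: str, path: str) -> None:
    """Render per-class box-and-whisker panels of one dimension, one per method."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = _tidy(results)
    methods = [m for m in METHODS if m in set(df["method"])]
    fig, axes = plt.subplots(1, len(methods), figsize=(4 * len(methods), 3.2),
                             sharey=True, squeeze=False)
    for ax, method in zip(axes[0], methods):
        sub = df[df["method"] == method]
        labels = sorted(sub["class_label"].unique())
        data = [sub[sub["class_label"] == lbl][dimension].to_numpy() for lbl in labels]
        ax.boxplot(data, tick_labels=labels, whis=(0, 100))
        ax.set_title(method)
    axes[0][0].set_ylabel(dimension)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
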