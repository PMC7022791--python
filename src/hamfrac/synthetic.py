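"""Synthetic benchmark fractals and marbled tissue-slice images.

Two families of test objects:

* **Benchmark fractals** with analytically known dimensions — the
  Sierpinski carpet (D = log 8 / log 3 for the uniform measure on the
  support, identical at every moment order because the measure is
  self-similar and uniform), the filled square (D = 2) and a straight
  line (D = 1).  These are the oracles for the sandbox estimator.

* **Synthetic ham-slice images**: a dark-red lean matrix carrying pale
  marbling streaks (random-walk polylines, 1–4 px wide) and accumulated
  fat clusters (random ellipses), multiplied by a smooth low-frequency
  illumination field and topped with per-pixel sensor noise.  The
  generator returns the ground-truth fat mask alongside the rendered
  image, so segmentation accuracy can be scored exactly — something no
  photograph permits.  Streak count is calibrated by bisection so the
  realized fat fraction hits a requested target.

All randomness flows from one explicit seed; identical parameters and
seed give bit-identical rasters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from skimage import draw as skdraw
from skimage import morphology as skmorph

__all__ = [
    "SliceParams",
    "SliceSample",
    "BenchmarkFractal",
    "GenerationError",
    "CARPET_DIMENSION",
    "make_sierpinski_carpet",
    "make_filled_square",
    "make_line",
    "shading_field",
    "make_slice",
    "make_class_fixture",
]

CARPET_DIMENSION = math.log(8) / math.log(3)

DEFAULT_LEAN_RGB = (120, 30, 30)
DEFAULT_FAT_RGB = (250, 245, 230)

#: absolute tolerance the calibration aims for; generation fails beyond 0.05
_CALIBRATION_TOL = 0.02
_MAX_DRAWS = 20


class GenerationError(RuntimeError):
    """The requested fat fraction could not be reached."""


@dataclass(frozen=True)
class SliceParams:
    """Parameters of one synthetic marbled slice.

    fat_fraction_target
        Desired proportion of fat pixels; the streak count is bisected
        until the realized fraction is within 0.02 of it.
    n_clusters
        Number of elliptical accumulated-fat clusters.
    streak_density
        Initial guess for marbling streaks per 512x512 px of area (the
        calibration's starting point, not a hard setting).
    illumination_amplitude
        Peak relative deviation of the multiplicative shading field from
        1 (0 = perfectly even lighting; 0.3 = ±30 %).
    illumination_scale_px
        Correlation length of the shading field in pixels; must exceed
        the high-pass radius for the filter to be able to remove it.
    noise_sd
        Standard deviation of additive per-pixel Gaussian noise (gray
        levels, applied per channel).
    """

    side_px: int = 512
    fat_fraction_target: float = 0.20
    n_clusters: int = 8
    streak_density: float = 150.0
    illumination_amplitude: float = 0.0
    illumination_scale_px: float = 128.0
    lean_rgb: tuple[int, int, int] = DEFAULT_LEAN_RGB
    fat_rgb: tuple[int, int, int] = DEFAULT_FAT_RGB
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.side_px < 8:
            raise ValueError("side_px must be at least 8")
        if not 0.0 < self.fat_fraction_target < 1.0:
            raise ValueError("fat_fraction_target must lie in (0, 1)")
        if self.n_clusters < 0 or self.streak_density < 0:
            raise ValueError("n_clusters and streak_density must be non-negative")
        if self.illumination_amplitude < 0 or self.noise_sd < 0:
            raise ValueError("amplitude and noise_sd must be non-negative")
        if self.illumination_scale_px <= 0:
            raise ValueError("illumination_scale_px must be positive")
        for rgb in (self.lean_rgb, self.fat_rgb):
            if len(rgb) != 3 or any(not 0 <= v <= 255 for v in rgb):
                raise ValueError(f"invalid 8-bit color triple {rgb}")


@dataclass(frozen=True)
class SliceSample:
    """One generated slice with its ground truth and provenance."""

    image: np.ndarray  # (side, side, 3) uint8
    mask: np.ndarray  # (side, side) bool, True = fat
    class_label: str
    params: SliceParams


@dataclass(frozen=True)
class BenchmarkFractal:
    """A binary mask with analytically known generalized dimensions."""

    name: str
    mask: np.ndarray
    analytic_d0: float
    analytic_d1: float
    analytic_d2: float

    def __post_init__(self) -> None:
        if not (self.analytic_d0 >= self.analytic_d1 >= self.analytic_d2):
            raise ValueError("analytic dimensions must be non-increasing in q")
        if not np.asarray(self.mask).any():
            raise ValueError("benchmark mask must be nonempty")


def make_sierpinski_carpet(level: int) -> BenchmarkFractal:
    """Standard Sierpinski carpet at the given subdivision level.

    The mask is 3^level on a side with 8^level set pixels; the uniform
    measure on a self-similar set is monofractal, so all D_q equal
    log 8 / log 3 ≈ 1.8928.
    """
    if not 1 <= level <= 6:
        raise ValueError(f"level must be in [1, 6]; got {level}")
    cell = np.ones((3, 3), dtype=bool)
    cell[1, 1] = False
    mask = np.ones((1, 1), dtype=bool)
    for _ in range(level):
        mask = np.kron(mask, cell)
    d = CARPET_DIMENSION
    return BenchmarkFractal(f"sierpinski_carpet_L{level}", mask, d, d, d)


def make_filled_square(side_px: int) -> BenchmarkFractal:
    """All-set mask: a plane-filling set, D0 = D1 = D2 = 2."""
    if side_px < 8:
        raise ValueError("side_px must be at least 8")
    return BenchmarkFractal(
        f"filled_square_{side_px}", np.ones((side_px, side_px), dtype=bool), 2.0, 2.0, 2.0
    )


def make_line(side_px: int) -> BenchmarkFractal:
    """Single horizontal row through the image center, D0 = D1 = D2 = 1."""
    if side_px < 8:
        raise ValueError("side_px must be at least 8")
    mask = np.zeros((side_px, side_px), dtype=bool)
    mask[side_px // 2, :] = True
    return BenchmarkFractal(f"line_{side_px}", mask, 1.0, 1.0, 1.0)


def shading_field(
    side: int, amplitude: float, scale_px: float, rng: np.random.Generator
) -> np.ndarray:
    """Smooth multiplicative illumination surface with mean exactly 1.

    A sum of three plane-wave harmonics with random orientation, phase
    and weight, wavelengths drawn in [2, 4] x ``scale_px``, centred and
    rescaled so the peak deviation from 1 equals ``amplitude``.
    """
    if amplitude == 0.0:
        return np.ones((side, side), dtype=np.float64)
    yy, xx = np.mgrid[0:side, 0:side].astype(np.float64)
    s = np.zeros((side, side), dtype=np.float64)
    for _ in range(3):
        wavelength = scale_px * rng.uniform(2.0, 4.0)
        theta = rng.uniform(0.0, np.pi)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        weight = rng.normal(0.0, 1.0)
        s += weight * np.cos(
            2.0 * np.pi * (xx * np.cos(theta) + yy * np.sin(theta)) / wavelength + phase
        )
    s -= s.mean()
    peak = np.abs(s).max()
    if peak > 0:
        s /= peak
    return 1.0 + amplitude * s


def _draw_fat_mask(side: int, n_clusters: int, n_streaks: int, seed: int) -> np.ndarray:
    """Rasterize clusters then streaks from a fresh seeded stream.

    Because the stream is re-seeded identically on every call, the first
    k streaks are the same regardless of n_streaks: the mask is
    monotone non-decreasing in n_streaks, which makes the fat-fraction
    calibration a well-posed bisection.
    """
    rng = np.random.default_rng(seed)
    mask = np.zeros((side, side), dtype=bool)
    for _ in range(n_clusters):
        r0 = rng.uniform(0, side)
        c0 = rng.uniform(0, side)
        a = rng.uniform(side / 64, side / 20)
        b = rng.uniform(side / 64, side / 20)
        rot = rng.uniform(0, np.pi)
        rr, cc = skdraw.ellipse(r0, c0, a, b, shape=mask.shape, rotation=rot)
        mask[rr, cc] = True
    # group streak pixels by width; one dilation per width at the end
    by_width: dict[int, np.ndarray] = {}
    step = 3.0
    for _ in range(n_streaks):
        width = int(rng.integers(1, 5))
        length = rng.uniform(side / 8, side / 2)
        n_steps = max(2, int(length / step))
        r = rng.uniform(0, side - 1)
        c = rng.uniform(0, side - 1)
        angle = rng.uniform(0, 2 * np.pi)
        canvas = by_width.setdefault(width, np.zeros((side, side), dtype=bool))
        for _ in range(n_steps):
            angle += rng.normal(0.0, 0.25)
            r2 = float(np.clip(r + step * np.sin(angle), 0, side - 1))
            c2 = float(np.clip(c + step * np.cos(angle), 0, side - 1))
            rr, cc = skdraw.line(int(round(r)), int(round(c)), int(round(r2)), int(round(c2)))
            canvas[rr, cc] = True
            r, c = r2, c2
    for width, canvas in by_width.items():
        if width > 1:
            canvas = skmorph.dilation(canvas, footprint=np.ones((width, width)))
        mask |= canvas
    return mask


def _calibrated_mask(params: SliceParams) -> np.ndarray:
    """Bisect the streak count until the fat fraction hits its target."""
    side = params.side_px
    area = side * side
    target = params.fat_fraction_target

    draws = 0

    def frac_for(n: int) -> tuple[float, np.ndarray]:
        nonlocal draws
        draws += 1
        m = _draw_fat_mask(side, params.n_clusters, n, params.seed)
        return m.sum() / area, m

    n0 = max(0, round(params.streak_density * (side / 512.0) ** 2))
    best_mask: np.ndarray | None = None
    best_diff = math.inf

    def consider(f: float, m: np.ndarray) -> None:
        nonlocal best_mask, best_diff
        if abs(f - target) < best_diff:
            best_diff = abs(f - target)
            best_mask = m

    f0, m0 = frac_for(n0)
    consider(f0, m0)
    lo, hi = n0, n0
    f_lo, f_hi = f0, f0
    while f_hi < target and draws < _MAX_DRAWS:
        lo, f_lo = hi, f_hi
        hi = max(1, hi * 2)
        f_hi, m = frac_for(hi)
        consider(f_hi, m)
    while f_lo > target and lo > 0 and draws < _MAX_DRAWS:
        hi, f_hi = lo, f_lo
        lo = lo // 2
        f_lo, m = frac_for(lo)
        consider(f_lo, m)
    while best_diff > _CALIBRATION_TOL and hi - lo > 1 and draws < _MAX_DRAWS:
        mid = (lo + hi) // 2
        f_mid, m = frac_for(mid)
        consider(f_mid, m)
        if f_mid < target:
            lo, f_lo = mid, f_mid
        else:
            hi, f_hi = mid, f_mid
    if best_mask is None or best_diff > 0.05:
        raise GenerationError(
            f"could not reach fat fraction {target:.3f} within {_MAX_DRAWS} draws "
            f"(best miss {best_diff:.3f}); adjust n_clusters/streak_density"
        )
    return best_mask


def make_slice(params: SliceParams) -> tuple[np.ndarray, np.ndarray]:
    """Render one synthetic slice.

    Returns ``(image, mask)``: the uint8 RGB image built as
    shading_field x (lean/fat base colors) + noise, clipped to 8 bits,
    and the ground-truth boolean fat mask.  The realized fat fraction is
    within 0.05 of ``params.fat_fraction_target`` (generation fails
    loudly otherwise).
    """
    mask = _calibrated_mask(params)
    side = params.side_px
    # image-formation randomness comes after calibration, from an offset
    # stream so it does not interact with the mask draw
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 1]))
    field = shading_field(side, params.illumination_amplitude,
                          params.illumination_scale_px, rng)
    base = np.where(
        mask[..., None],
        np.asarray(params.fat_rgb, dtype=np.float64),
        np.asarray(params.lean_rgb, dtype=np.float64),
    )
    img = field[..., None] * base
    if params.noise_sd > 0:
        img = img + rng.normal(0.0, params.noise_sd, size=img.shape)
    img = np.clip(np.floor(img + 0.5), 0, 255).astype(np.uint8)
    return img, mask


def make_class_fixture(
    class_specs: dict[str, SliceParams] | list[SliceParams],
    n_per_class: int,
    seed: int,
) -> list[SliceSample]:
    """Generate a labelled multi-class fixture of synthetic slices.

    Per-slice parameters are jittered around each class spec (±5 %
    relative on the fat-fraction target, ±2 clusters) so within-class
    dispersion exists, as it does across real slices of one
    designation.  ``class_specs`` maps labels to parameter sets; a bare
    list gets labels ``class_0 ...``.
    """
    if not class_specs:
        raise ValueError("class_specs must not be empty")
    if n_per_class < 2:
        raise ValueError("n_per_class must be at least 2")
    if not isinstance(class_specs, dict):
        class_specs = {f"class_{i}": p for i, p in enumerate(class_specs)}
    master = np.random.default_rng(seed)
    samples: list[SliceSample] = []
    for label, spec in class_specs.items():
        for _ in range(n_per_class):
            target = float(
                np.clip(spec.fat_fraction_target * (1.0 + master.uniform(-0.05, 0.05)),
                        0.01, 0.99)
            )
            clusters = int(max(0, spec.n_clusters + master.integers(-2, 3)))
            p = replace(
                spec,
                fat_fraction_target=target,
                n_clusters=clusters,
                seed=int(master.integers(2**31)),
            )
            image, mask = make_slice(p)
            samples.append(SliceSample(image, mask, label, p))
    return samples
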