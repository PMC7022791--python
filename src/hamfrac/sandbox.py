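"""Sandbox estimation of the generalized (Rényi) dimensions D0, D1, D2.

The sandbox method places discs of growing radius r on randomly chosen
pixels *of the measured set* and records the mass M(r) — the number of
set pixels — inside each disc.  For a set of linear size L with a
uniform counting measure, the moments of M(r)/M0 scale as power laws of
r/L, and the generalized dimension of order q is the log-log slope

    D_q = slope of  (1/(q-1)) * ln < (M(r)/M0)^(q-1) >   vs  ln(r/L)

where <.> averages over disc centers and M0 is the total mass.  The
q = 1 case uses the limit (entropy) form, slope of < ln(M(r)/M0) >.
D0 is the capacity/box-counting dimension of the support, D1 the
information dimension (uniformity of the measure), D2 the correlation
dimension (pattern complexity); D_q is non-increasing in q.

Each slope is fit by ordinary least squares over all configured radii;
the regression standard error and R² are reported so users can judge
the scaling range instead of the package pruning it silently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import signal, stats

__all__ = [
    "SandboxConfig",
    "MassMatrix",
    "DimensionEstimate",
    "MaskAnalysis",
    "SupportError",
    "resolve_radii",
    "sample_centers",
    "count_masses",
    "estimate_dimension",
    "analyze_mask",
]


class SupportError(ValueError):
    """The mask's measured phase is too small (or too marginal) to sandbox."""


@dataclass(frozen=True)
class SandboxConfig:
    """Sandbox estimator parameters.

    n_centers
        Disc centers drawn uniformly with replacement from interior set
        pixels (default 1000).
    r_min_px, r_max_px
        Radius range in pixels.  ``r_max_px=None`` resolves to side/4 at
        analysis time, keeping a decade of scales above pixel
        discreteness and below the crop scale.
    n_radii
        Number of geometrically spaced radii (default 12).
    q_values
        Moment orders to estimate; 0, 1 and 2 by default.
    min_support_px
        Minimum number of set pixels required to attempt an estimate.
    phase
        Which phase carries the measure: ``"fat"`` (default) or
        ``"muscle"``.
    """

    n_centers: int = 1000
    r_min_px: float = 5.0
    r_max_px: float | None = None
    n_radii: int = 12
    q_values: tuple[float, ...] = (0.0, 1.0, 2.0)
    seed: int = 0
    min_support_px: int = 100
    phase: str = "fat"

    def __post_init__(self) -> None:
        if self.n_centers < 10:
            raise ValueError("n_centers must be at least 10")
        if self.n_radii < 3:
            raise ValueError("n_radii must be at least 3")
        if self.r_min_px <= 0:
            raise ValueError("r_min_px must be positive")
        if self.r_max_px is not None and self.r_max_px <= self.r_min_px:
            raise ValueError("r_max_px must exceed r_min_px")
        if self.phase not in ("fat", "muscle"):
            raise ValueError("phase must be 'fat' or 'muscle'")


@dataclass
class MassMatrix:
    """Sandbox counts: masses[i, j] = set pixels within radii[j] of center i."""

    masses: np.ndarray  # (n_centers, n_radii) int64
    centers: np.ndarray  # (n_centers, 2) int (row, col)
    radii: np.ndarray  # (n_radii,) float
    total_mass: int

    def __post_init__(self) -> None:
        if (self.masses < 1).any():
            raise ValueError("every mass must be >= 1 (each center is a set pixel)")
        if (np.diff(self.masses, axis=1) < 0).any():
            raise ValueError("masses must be non-decreasing along the radius axis")
        if (self.masses > self.total_mass).any():
            raise ValueError("a disc cannot hold more than the total mass")


@dataclass(frozen=True)
class DimensionEstimate:
    """One generalized dimension with its OLS fit diagnostics."""

    q: float
    value: float
    std_error: float
    r_squared: float
    n_points: int


@dataclass(frozen=True)
class MaskAnalysis:
    """Per-mask sandbox result: one estimate per q, sharing centers/masses."""

    estimates: tuple[DimensionEstimate, ...]
    fat_fraction: float
    config: SandboxConfig

    def dimension(self, q: float) -> DimensionEstimate:
        for est in self.estimates:
            if est.q == q:
                return est
        raise KeyError(f"no estimate for q={q}")


def resolve_radii(side: int, cfg: SandboxConfig) -> np.ndarray:
    """Geometric radius schedule in [r_min, r_max] (r_max defaults to side/4)."""
    r_max = cfg.r_max_px if cfg.r_max_px is not None else side / 4.0
    if not cfg.r_min_px < r_max <= side / 2:
        raise ValueError(f"need r_min < r_max <= side/2; got [{cfg.r_min_px}, {r_max}]")
    return np.geomspace(cfg.r_min_px, r_max, cfg.n_radii)


def _phase_mask(mask: np.ndarray, cfg: SandboxConfig) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    return mask if cfg.phase == "fat" else ~mask


def sample_centers(
    mask: np.ndarray, cfg: SandboxConfig, radii: np.ndarray | None = None
) -> np.ndarray:
    """Draw disc centers uniformly with replacement from interior set pixels.

    Eligible pixels lie on the measured set at distance >= r_max from
    every border, so every disc fits inside the image and no count is
    edge-truncated.
    """
    m = _phase_mask(mask, cfg)
    if int(m.sum()) < cfg.min_support_px:
        raise SupportError(
            f"insufficient support: {int(m.sum())} set pixels "
            f"(need >= {cfg.min_support_px})"
        )
    if radii is None:
        radii = resolve_radii(m.shape[0], cfg)
    margin = math.ceil(float(radii[-1]))
    h, w = m.shape
    interior = np.zeros_like(m)
    if h > 2 * margin and w > 2 * margin:
        interior[margin : h - margin, margin : w - margin] = True
    eligible = np.flatnonzero(m & interior)
    if eligible.size == 0:
        raise SupportError(
            "no set pixels at distance >= r_max from the borders; "
            "reduce r_max_px or supply a larger mask"
        )
    rng = np.random.default_rng(cfg.seed)
    picks = rng.choice(eligible, size=cfg.n_centers, replace=True)
    return np.column_stack(np.unravel_index(picks, m.shape))


def count_masses(mask: np.ndarray, centers: np.ndarray, radii: np.ndarray) -> MassMatrix:
    """Count set pixels inside Euclidean discs of each radius at each center.

    Disc membership is pixel-center distance <= r.  Counts are computed
    with an FFT convolution of the mask against the binary disc kernel
    and rounded back to exact integers (counts are bounded well below
    the float64 mantissa, so the rounding is exact).
    """
    mask = np.asarray(mask, dtype=bool)
    centers = np.asarray(centers)
    radii = np.asarray(radii, dtype=float)
    if (np.diff(radii) <= 0).any():
        raise ValueError("radii must be strictly ascending")
    if not mask[centers[:, 0], centers[:, 1]].all():
        raise ValueError("every center must lie on a set pixel")
    dense = np.asarray(mask, dtype=np.float64)
    masses = np.empty((len(centers), len(radii)), dtype=np.int64)
    for j, r in enumerate(radii):
        R = int(math.floor(r))
        dy, dx = np.mgrid[-R : R + 1, -R : R + 1]
        kernel = (dy * dy + dx * dx <= r * r).astype(np.float64)
        conv = signal.fftconvolve(dense, kernel, mode="same")
        masses[:, j] = np.rint(conv[centers[:, 0], centers[:, 1]]).astype(np.int64)
    # guard against any accumulation drift along the radius axis
    np.maximum.accumulate(masses, axis=1, out=masses)
    return MassMatrix(masses, centers, radii, int(mask.sum()))


def estimate_dimension(mm: MassMatrix, q: float, side: int) -> DimensionEstimate:
    """OLS log-log slope of the q-th sandbox moment against ln(r/side).

    For q != 1 the moment is averaged over centers before the logarithm;
    for q = 1 the entropy (L'Hôpital) form averages the logarithm.
    """
    if len(mm.radii) < 3:
        raise ValueError("need at least 3 radii for a slope estimate")
    x = np.log(mm.radii / side)
    if np.ptp(x) == 0:
        raise ValueError("zero variance in ln(r); cannot regress")
    rel = mm.masses / mm.total_mass
    if q == 1.0:
        y = np.mean(np.log(rel), axis=0)
    else:
        y = np.log(np.mean(rel ** (q - 1.0), axis=0)) / (q - 1.0)
    fit = stats.linregress(x, y)
    return DimensionEstimate(
        q=float(q),
        value=float(fit.slope),
        std_error=float(fit.stderr),
        r_squared=float(fit.rvalue**2),
        n_points=len(mm.radii),
    )


def analyze_mask(mask: np.ndarray, cfg: SandboxConfig = SandboxConfig()) -> MaskAnalysis:
    """Full sandbox analysis of one mask.

    Centers and masses are drawn once and shared across all q values so
    D0/D1/D2 are comparable; the fat fraction of the mask (not of the
    measured phase) is attached for downstream scatter analyses.
    """
    mask = np.asarray(mask, dtype=bool)
    side = mask.shape[0]
    radii = resolve_radii(side, cfg)
    centers = sample_centers(mask, cfg, radii)
    mm = count_masses(_phase_mask(mask, cfg), centers, radii)
    estimates = tuple(estimate_dimension(mm, q, side) for q in cfg.q_values)
    frac = float(np.asarray(mask, dtype=bool).sum()) / mask.size
    return MaskAnalysis(estimates=estimates, fat_fraction=frac, config=cfg)
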