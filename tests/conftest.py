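"""Shared fixtures: the shaded-slice study set, reused across test modules.

Generating and analyzing 20 synthetic slices under strong multiplicative
shading is the most expensive part of the suite, so it is built once per
session and shared by the robustness, monotonicity and dispersion tests.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from hamfrac import SandboxConfig, SliceParams, analyze_mask, make_slice, run_method
from hamfrac.summary import METHODS

settings.register_profile("suite", deadline=None, max_examples=25, derandomize=True)
settings.load_profile("suite")

N_SLICES = 20

#: study conditions of the filter-robustness experiment: 512-px crops,
#: 20 % fat, ±30 % multiplicative shading at 128-px scale, mild noise
SHADED_PARAMS = dict(
    fat_fraction_target=0.20,
    illumination_amplitude=0.3,
    illumination_scale_px=128.0,
    noise_sd=3.0,
)


@pytest.fixture(scope="session")
def shaded_slices() -> list[tuple[np.ndarray, np.ndarray]]:
    """20 seeded (image, ground-truth mask) pairs under strong shading."""
    return [make_slice(SliceParams(seed=s, **SHADED_PARAMS)) for s in range(N_SLICES)]


@pytest.fixture(scope="session")
def method_masks(shaded_slices) -> dict[str, list[np.ndarray]]:
    """Segmentation of every shaded slice by all three methods."""
    return {
        m: [run_method(img, m) for img, _ in shaded_slices] for m in METHODS
    }


@pytest.fixture(scope="session")
def method_analyses(method_masks):
    """Sandbox analyses (default config, per-slice seeds) of every mask."""
    return {
        m: [analyze_mask(mask, SandboxConfig(seed=1000 + i)) for i, mask in enumerate(masks)]
        for m, masks in method_masks.items()
    }
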