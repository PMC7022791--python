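"""Sandbox estimator tests: counting oracle, sampling rules, estimates."""

import numpy as np
import pytest

from hamfrac import (
    SandboxConfig,
    SupportError,
    analyze_mask,
    count_masses,
    estimate_dimension,
    make_filled_square,
    make_sierpinski_carpet,
    sample_centers,
)
from hamfrac.sandbox import MassMatrix, resolve_radii


def naive_masses(mask, centers, radii):
    """Independent oracle: per-pixel distance check for every disc."""
    h, w = mask.shape
    yy, xx = np.mgrid[0:h, 0:w]
    out = np.empty((len(centers), len(radii)), dtype=np.int64)
    for i, (r0, c0) in enumerate(centers):
        d2 = (yy - r0) ** 2 + (xx - c0) ** 2
        for j, r in enumerate(radii):
            out[i, j] = int((mask & (d2 <= r * r)).sum())
    return out


def random_mask_with_centers(rng, side=48, density=0.3, n_centers=5):
    mask = rng.random((side, side)) < density
    mask[side // 2, side // 2] = True  # guarantee support
    set_idx = np.flatnonzero(mask)
    picks = rng.choice(set_idx, size=n_centers, replace=True)
    return mask, np.column_stack(np.unravel_index(picks, mask.shape))


class TestCountMasses:
    RADII = np.array([2.5, 4.0, 7.3, 11.0])

    def test_matches_naive_enumeration(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            mask, centers = random_mask_with_centers(rng)
            mm = count_masses(mask, centers, self.RADII)
            assert np.array_equal(mm.masses, naive_masses(mask, centers, self.RADII))

    def test_discrete_disc_of_radius_5_has_81_pixels(self):
        mask = make_filled_square(64).mask
        mm = count_masses(mask, np.array([[32, 32]]), np.array([5.0]))
        assert mm.masses[0, 0] == 81

    def test_isolated_pixel_mass_is_one(self):
        mask = np.zeros((32, 32), bool)
        mask[10, 10] = True
        mm = count_masses(mask, np.array([[10, 10]]), np.array([3.0, 8.0]))
        assert (mm.masses == 1).all()

    def test_masses_nondecreasing_in_radius(self):
        rng = np.random.default_rng(1)
        mask, centers = random_mask_with_centers(rng)
        mm = count_masses(mask, centers, self.RADII)
        assert (np.diff(mm.masses, axis=1) >= 0).all()

    def test_center_off_support_rejected(self):
        mask = np.zeros((16, 16), bool)
        mask[3, 3] = True
        with pytest.raises(ValueError):
            count_masses(mask, np.array([[0, 0]]), np.array([2.0]))


class TestSampleCenters:
    def test_border_margin_respected(self):
        mask = make_filled_square(512).mask
        cfg = SandboxConfig(seed=4, r_max_px=128.0)
        centers = sample_centers(mask, cfg)
        assert centers.min() >= 128 and centers.max() <= 512 - 1 - 128

    def test_same_seed_same_centers(self):
        mask = make_sierpinski_carpet(5).mask
        cfg = SandboxConfig(seed=11)
        assert np.array_equal(sample_centers(mask, cfg), sample_centers(mask, cfg))

    def test_insufficient_support_raises(self):
        with pytest.raises(SupportError, match="insufficient support"):
            sample_centers(np.zeros((64, 64), bool), SandboxConfig())

    def test_no_interior_pixels_suggests_smaller_radius(self):
        mask = np.zeros((64, 64), bool)
        mask[:2, :] = True  # plenty of support, all on the border
        with pytest.raises(SupportError, match="r_max"):
            sample_centers(mask, SandboxConfig(r_max_px=30.0))


class TestEstimateDimension:
    def test_too_few_radii_rejected(self):
        mm = MassMatrix(
            masses=np.array([[1, 2]]), centers=np.array([[5, 5]]),
            radii=np.array([2.0, 4.0]), total_mass=10,
        )
        with pytest.raises(ValueError):
            estimate_dimension(mm, 0.0, 64)

    def test_estimates_carry_fit_diagnostics(self):
        mask = make_sierpinski_carpet(4).mask
        analysis = analyze_mask(mask, SandboxConfig(seed=2, n_centers=200))
        for est in analysis.estimates:
            assert 0.0 <= est.r_squared <= 1.0
            assert est.std_error >= 0.0
            assert est.n_points == 12


class TestAnalyzeMask:
    def test_spectrum_nonincreasing_on_carpet(self):
        analysis = analyze_mask(make_sierpinski_carpet(5).mask, SandboxConfig(seed=6))
        d0, d1, d2 = (analysis.dimension(q).value for q in (0.0, 1.0, 2.0))
        assert d0 >= d1 >= d2

    def test_scale_invariance_under_pixel_replication(self):
        """Upsampling x2 with doubled radii moves each D_q by < 0.05."""
        mask = make_sierpinski_carpet(4).mask
        up = np.kron(mask, np.ones((2, 2), bool))
        a1 = analyze_mask(mask, SandboxConfig(seed=5, r_min_px=5, r_max_px=20))
        a2 = analyze_mask(up, SandboxConfig(seed=5, r_min_px=10, r_max_px=40))
        for e1, e2 in zip(a1.estimates, a2.estimates):
            assert abs(e1.value - e2.value) < 0.05

    def test_seed_stability_on_carpet(self):
        """1000 centers make the estimate nearly independent of the draw."""
        mask = make_sierpinski_carpet(5).mask
        a1 = analyze_mask(mask, SandboxConfig(seed=11))
        a2 = analyze_mask(mask, SandboxConfig(seed=77))
        for e1, e2 in zip(a1.estimates, a2.estimates):
            assert abs(e1.value - e2.value) < 0.03

    def test_muscle_phase_switch(self):
        """Analyzing the complement phase of a sparse mask sees a near-plane."""
        rng = np.random.default_rng(3)
        mask = rng.random((256, 256)) < 0.05
        analysis = analyze_mask(mask, SandboxConfig(seed=1, phase="muscle"))
        assert analysis.dimension(0.0).value == pytest.approx(2.0, abs=0.1)
        # fat_fraction still reports the fat phase
        assert analysis.fat_fraction == pytest.approx(0.05, abs=0.01)

    def test_error_propagates_from_sampling(self):
        with pytest.raises(SupportError):
            analyze_mask(np.zeros((64, 64), bool), SandboxConfig())

    def test_radii_resolution_bounds(self):
        with pytest.raises(ValueError):
            resolve_radii(512, SandboxConfig(r_min_px=5, r_max_px=400))
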