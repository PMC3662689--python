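"""Hit-probability quadratures against closed forms and Monte-Carlo oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import erf

from motormodel.hit_probability import (InternalModel, TargetShape,
                                        circle_hit_prob, equivalent_radius,
                                        hit_prob, rect_hit_prob,
                                        uniform_disk_hit_prob)


def mc_rect_prob(w, h, sh, sv, rho, n=10_000_000, seed=0):
    """Monte-Carlo oracle: fraction of correlated Gaussian draws in the rect."""
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, 2))
    x = sh * z[:, 0]
    y = sv * (rho * z[:, 0] + math.sqrt(1 - rho**2) * z[:, 1])
    p = np.mean((np.abs(x) <= w / 2) & (np.abs(y) <= h / 2))
    se = math.sqrt(p * (1 - p) / n)
    return p, se


def mc_circle_prob(r, sh, sv, center=(0.0, 0.0), n=10_000_000, seed=0):
    rng = np.random.default_rng(seed)
    x = sh * rng.standard_normal(n) - center[0]
    y = sv * rng.standard_normal(n) - center[1]
    p = np.mean(x * x + y * y <= r * r)
    se = math.sqrt(p * (1 - p) / n)
    return p, se


class TestRectHitProb:
    def test_two_sigma_rectangle_closed_form(self):
        """w=2σh, h=2σv, ρ=0 → erf(1/√2)² ≈ 0.4661."""
        p = rect_hit_prob(TargetShape.rectangle(8.0, 11.52), 4.0, 5.76)
        assert p == pytest.approx(erf(1 / math.sqrt(2)) ** 2, abs=1e-12)

    def test_total_mass_and_vanishing_width_limits(self):
        assert rect_hit_prob(TargetShape.rectangle(1e5, 1e5), 4, 5) == pytest.approx(1.0, abs=1e-12)
        assert rect_hit_prob(TargetShape.rectangle(1e-12, 10), 4, 5) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("rho", [-0.44, 0.33])
    def test_correlated_rectangle_matches_monte_carlo(self, rho):
        w, h, sh, sv = 6.0, 9.0, 4.0, 5.76
        p = rect_hit_prob(TargetShape.rectangle(w, h), sh, sv, rho)
        p_mc, se = mc_rect_prob(w, h, sh, sv, rho)
        assert abs(p - p_mc) < 3 * se

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            TargetShape.rectangle(0.0, 1.0)
        with pytest.raises(ValueError):
            rect_hit_prob(TargetShape.circle(1.0), 1, 1)


class TestCircleHitProb:
    def test_isotropic_closed_form(self):
        """Isotropic Gaussian: P(hit circle r) = 1 − exp(−r²/2σ²) (Rayleigh)."""
        for r, s in [(8.97, 4.05), (2.0, 4.0), (30.0, 4.0)]:
            p = circle_hit_prob(TargetShape.circle(r), s, s)
            assert p == pytest.approx(1 - math.exp(-r**2 / (2 * s**2)), abs=1e-11)

    def test_half_probability_radius(self):
        """r = σ√(2 ln 2) is the isotropic 50% radius."""
        s = 3.7
        p = circle_hit_prob(TargetShape.circle(s * math.sqrt(2 * math.log(2))), s, s)
        assert p == pytest.approx(0.5, abs=1e-11)

    def test_vanishing_radius(self):
        assert circle_hit_prob(TargetShape.circle(1e-9), 4, 5.76) < 1e-10

    def test_anisotropic_matches_monte_carlo(self):
        p = circle_hit_prob(TargetShape.circle(5.0), 4.0, 5.76)
        p_mc, se = mc_circle_prob(5.0, 4.0, 5.76)
        assert abs(p - p_mc) < 3 * se

    def test_offset_circle_matches_monte_carlo(self):
        p = circle_hit_prob(TargetShape.circle(8.97, center=(-6.0, 0.0)), 4.05, 4.05)
        p_mc, se = mc_circle_prob(8.97, 4.05, 4.05, center=(-6.0, 0.0))
        assert abs(p - p_mc) < 3 * se

    def test_large_radius_to_sigma_ratio_regime(self):
        # adaptive fallback regime: huge circle swallows nearly all mass
        p = circle_hit_prob(TargetShape.circle(300.0), 1.0, 1.5)
        assert p == pytest.approx(1.0, abs=1e-9)


class TestUniformDisk:
    def test_concentric_circle_area_ratio(self):
        assert uniform_disk_hit_prob(TargetShape.circle(4.0), 8.0) == pytest.approx(0.25)
        assert uniform_disk_hit_prob(TargetShape.circle(9.0), 8.0) == pytest.approx(1.0)

    def test_rect_disk_area_against_shapely(self):
        import shapely.geometry as geom
        R = 8.1
        disk = geom.Point(0, 0).buffer(R, quad_segs=512)
        for (w, h, cx, cy) in [(6, 9, 0, 0), (20, 3, 4, 2), (30, 30, 0, 0)]:
            rect = TargetShape.rectangle(w, h, center=(cx, cy))
            box = geom.box(cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2)
            expected = box.intersection(disk).area / (math.pi * R**2)
            got = uniform_disk_hit_prob(rect, R)
            assert got == pytest.approx(expected, abs=5e-4)


class TestEquivalentRadius:
    def test_area_matching_identity(self):
        r = equivalent_radius(TargetShape.rectangle(4, 1), InternalModel.area_matching())
        assert r == pytest.approx(math.sqrt(4 / math.pi), rel=1e-12)

    def test_infinite_variance_limit_is_area_matching(self):
        """Gaussian equivalent radius → sqrt(wh/π) as σ̃² → ∞."""
        rect = TargetShape.rectangle(8, 2)
        r_area = math.sqrt(16 / math.pi)
        r_big = equivalent_radius(rect, InternalModel.gaussian(1e6, 1.0))
        assert r_big == pytest.approx(r_area, rel=1e-4)

    def test_gaussian_radius_smaller_than_area_radius(self):
        """Circles concentrate near the mode: r_eq < sqrt(wh/π) for η̃=1."""
        for s2 in (1.0, 10.0, 100.0):
            rect = TargetShape.rectangle(6, 1.5)
            r = equivalent_radius(rect, InternalModel.gaussian(s2, 1.0))
            assert r < math.sqrt(rect.w * rect.h / math.pi)

    def test_grid_search_oracle_isotropic_square(self):
        """Brute-force radius grid agrees with the root-find (Δr = 1e-5)."""
        rect = TargetShape.rectangle(2, 2)
        model = InternalModel.gaussian(1.0, 1.0)
        p_rect = rect_hit_prob(rect, 1.0, 1.0)
        radii = np.arange(0.5, 2.0, 1e-5)
        probs = 1 - np.exp(-radii**2 / 2.0)
        r_oracle = radii[int(np.argmin(np.abs(probs - p_rect)))]
        assert equivalent_radius(rect, model) == pytest.approx(r_oracle, abs=2e-5)

    def test_orientation_symmetry(self):
        """Swapping (w,h) and inverting η̃ leaves the fit geometry unchanged."""
        m = InternalModel.gaussian(23.04, 1.44)
        m_inv = InternalModel.gaussian(23.04, 1 / 1.44)
        r1 = equivalent_radius(TargetShape.rectangle(12, 3), m)
        r2 = equivalent_radius(TargetShape.rectangle(3, 12), m_inv)
        assert r1 == pytest.approx(r2, rel=1e-8)

    def test_probability_saturation_regime(self):
        """Huge rectangle vs tiny σ̃: complement branch still brackets a root."""
        rect = TargetShape.rectangle(57.9, 14.5)
        r = equivalent_radius(rect, InternalModel.gaussian(2.17, 0.25))
        assert min(rect.w, rect.h) / 2 <= r <= math.hypot(rect.w, rect.h) / 2


class TestInvariants:
    # dimensions are drawn in units of σ and kept below the float-saturation
    # regime (P indistinguishable from 1) where strict ordering is meaningless
    @given(st.floats(0.3, 8.0), st.floats(0.3, 8.0), st.floats(0.5, 8.0))
    @settings(max_examples=25, deadline=None)
    def test_monotone_in_dimensions(self, wu, hu, s):
        w, h = wu * s, hu * s
        p = rect_hit_prob(TargetShape.rectangle(w, h), s, s)
        p_wider = rect_hit_prob(TargetShape.rectangle(w * 1.2, h), s, s)
        p_taller = rect_hit_prob(TargetShape.rectangle(w, h * 1.2), s, s)
        assert p_wider > p and p_taller > p

    @given(st.floats(0.2, 5.0), st.floats(0.5, 8.0))
    @settings(max_examples=25, deadline=None)
    def test_circle_monotone_in_radius(self, ru, s):
        r = ru * s
        assert (circle_hit_prob(TargetShape.circle(r * 1.1), s, s * 1.3)
                > circle_hit_prob(TargetShape.circle(r), s, s * 1.3))

    def test_hit_prob_dispatch(self):
        m = InternalModel.gaussian(16.0, 1.0)
        assert hit_prob(TargetShape.circle(4.0), m) == pytest.approx(
            1 - math.exp(-0.5), abs=1e-10)
        with pytest.raises(ValueError):
            hit_prob(TargetShape.circle(4.0), InternalModel.area_matching())
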