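"""Solid angles, eclipse estimates, terminating segments, quadratic fits."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from dnaloop import (
    EclipseScene,
    LoopCriteria,
    f_inf_eclipse,
    f_inf_static,
    fit_quadratic_eclipse,
    solid_angle_sphere,
    terminating_segments_correction,
)
from dnaloop.eclipse_model import GeometryError, sample_region_points

REGION = LoopCriteria(d_min=4.6, epsilon=9.2, domega=2 * math.pi * 0.1)


class TestSolidAngle:
    def test_tangent_half_space(self):
        assert solid_angle_sphere(1.0, 1.0) == pytest.approx(2 * math.pi)

    def test_twice_radius_exact(self):
        expect = 2 * math.pi * (1 - math.sqrt(3) / 2)
        assert solid_angle_sphere(2.0, 1.0) == pytest.approx(expect)
        assert expect == pytest.approx(0.8418, abs=5e-4)

    def test_far_field_limit(self):
        d, r = 100.0, 1.0
        assert solid_angle_sphere(d, r) == pytest.approx(math.pi * r * r / d / d, rel=1e-3)

    def test_inside_raises(self):
        with pytest.raises(GeometryError):
            solid_angle_sphere(0.5, 1.0)

    @given(st.floats(min_value=1.0, max_value=100.0))
    def test_monotone_decreasing_in_distance(self, d):
        assert solid_angle_sphere(d, 1.0) >= solid_angle_sphere(d + 1.0, 1.0)

    def test_brute_force_direction_sampling(self, rng):
        """The closed form matches the fraction of uniform directions whose
        rays hit the sphere, across d/R_eff in [1, 100]."""
        n = 400_000
        z = rng.normal(size=(n, 3))
        dirs = z / np.linalg.norm(z, axis=1, keepdims=True)
        for ratio in (1.0, 1.5, 3.0, 10.0, 100.0):
            cos_half = math.sqrt(max(0.0, 1.0 - 1.0 / ratio**2))
            hits = dirs[:, 2] > cos_half if ratio > 1 else dirs[:, 2] > 0
            est = 4 * math.pi * hits.mean()
            p = hits.mean()
            se = 4 * math.pi * math.sqrt(p * (1 - p) / n)
            assert abs(est - solid_angle_sphere(ratio, 1.0)) < 3 * se


class TestRegionSampling:
    def test_points_inside_region(self, rng):
        pts = sample_region_points(REGION, 5000, rng)
        r = np.linalg.norm(pts, axis=1)
        assert np.all(r >= REGION.d_min - 1e-9)
        assert np.all(r <= REGION.d_min + REGION.epsilon + 1e-9)
        cos_c = 1 - abs(REGION.domega) / (2 * math.pi)
        assert np.all(pts[:, 0] / r >= cos_c - 1e-9)

    def test_negative_domega_faces_back(self, rng):
        region = LoopCriteria(4.6, 9.2, -2 * math.pi * 0.1)
        pts = sample_region_points(region, 1000, rng)
        assert np.all(pts[:, 0] < 0)


class TestStaticEclipse:
    def test_vanishing_object(self, rng):
        # a vanishing protrusion still carries the w/2 tube radius of the
        # approaching terminus, leaving a per-mille residual occlusion
        res = f_inf_static([41.45, 0, 0], 1e-9, REGION, 4.6, 20_000, rng)
        assert res.f_inf == pytest.approx(1.0, abs=2e-3)
        assert res.f_inf < 1.0

    def test_distant_object(self, rng):
        res = f_inf_static([1e6, 0, 0], 23.0, REGION, 4.6, 20_000, rng)
        assert res.f_inf == pytest.approx(1.0, abs=1e-6)

    def test_object_in_region_raises(self, rng):
        with pytest.raises(GeometryError):
            f_inf_static([10.0, 0, 0], 23.0, REGION, 4.6, 20_000, rng)

    def test_monotone_in_radius_and_distance(self, rng):
        f_small = f_inf_static([60, 0, 0], 10.0, REGION, 4.6, 50_000, rng).f_inf
        f_big = f_inf_static([60, 0, 0], 20.0, REGION, 4.6, 50_000, rng).f_inf
        f_far = f_inf_static([120, 0, 0], 10.0, REGION, 4.6, 50_000, rng).f_inf
        assert 0 < f_big < f_small <= 1
        assert f_far > f_small


class TestFullEclipse:
    def test_reduces_to_static_without_chain(self, rng):
        pos = np.array([41.45, 0, 0])
        scene = EclipseScene(region=REGION, object_position=pos,
                             object_radius=23.0, w=4.6)
        full = f_inf_eclipse(scene, 300_000, rng)
        static = f_inf_static(pos, 23.0, REGION, 4.6, 300_000, rng)
        assert full.i_chain == 0.0
        assert abs(full.f_inf - static.f_inf) < 4 * math.hypot(full.se, static.se)

    def test_total_shadowing_cancels_object(self, rng):
        # a huge chain sphere in front of the object: every direction that
        # reaches the object first crosses the chain, so F returns to ~1
        scene = EclipseScene(
            region=REGION,
            object_position=np.array([200.0, 0, 0]),
            object_radius=5.0,
            w=80.0,  # chain occlusion radius w = 80
            chain_joints=np.array([[100.0, 0, 0]]),
        )
        res = f_inf_eclipse(scene, 200_000, rng)
        assert res.i_both == pytest.approx(res.i_object, rel=1e-6)
        assert res.f_inf == pytest.approx(1.0, abs=1e-9)

    def test_intersection_term_grows_slower_than_object_term(self, rng):
        """Doubling R_o at fixed K barely changes the chain-object overlap
        while the object term scales like (R_o + w/2)^2."""
        # frozen straight chain along +z up to the anchor, object hung at +x
        K = 32.3
        joints = np.column_stack([np.zeros(20), np.zeros(20),
                                  np.linspace(1.6, K, 20)])
        out = {}
        for R in (9.2, 18.4):
            scene = EclipseScene(
                region=REGION,
                object_position=np.array([2.3 + R, 0.0, K]),
                object_radius=R,
                w=4.6,
                chain_joints=joints,
            )
            out[R] = f_inf_eclipse(scene, 400_000, rng)
        ratio_obj = out[18.4].i_object / out[9.2].i_object
        expect = ((18.4 + 2.3) / (9.2 + 2.3)) ** 2
        assert ratio_obj == pytest.approx(expect, rel=0.25)
        # intersection term changes far less than the object term does
        change_both = abs(out[18.4].i_both - out[9.2].i_both)
        change_obj = abs(out[18.4].i_object - out[9.2].i_object)
        assert change_both < 0.5 * change_obj


class TestTerminatingSegments:
    scene = EclipseScene(region=REGION, object_position=np.array([41.45, 0, 0]),
                         object_radius=23.0, w=4.6)

    def test_object_removed_gives_unity(self, rng):
        far = EclipseScene(region=REGION, object_position=np.array([1e6, 0, 0]),
                           object_radius=1e-6, w=4.6)
        p, _ = terminating_segments_correction(64.45, far, 4.6, 106.0, 20_000, rng)
        assert p == 1.0

    def test_rigid_limit_matches_rod_blocking(self, rng):
        """A single rigid link of length T reproduces the rod-model blocked
        fraction (the solid-angle average) within MC error."""
        from dnaloop.eclipse_model import f_inf_static

        T = 120.0  # long enough to span the object's shadow from the region
        p_rigid, se = terminating_segments_correction(
            T, self.scene, 4.6, 106.0, 300_000, rng, rigid=True)
        rod = f_inf_static(self.scene.object_position, 23.0, REGION, 4.6,
                           300_000, rng)
        assert abs(p_rigid - rod.f_inf) < 4 * math.hypot(se, rod.se)

    def test_flexible_chains_block_more(self, rng):
        p_flex, se_f = terminating_segments_correction(
            64.45, self.scene, 4.6, 106.0, 150_000, rng)
        p_rigid, se_r = terminating_segments_correction(
            64.45, self.scene, 4.6, 106.0, 150_000, rng, rigid=True)
        assert p_flex < p_rigid - 2 * math.hypot(se_f, se_r)


class TestQuadraticFit:
    def test_exact_recovery(self):
        A, B, w = 1e-4, 0.01, 4.6
        radii = np.array([5.0, 10.0, 15.0, 20.0, 25.0])
        f = 1 - A * (radii + w / 2) ** 2 + B
        fit = fit_quadratic_eclipse(radii, f, np.full(5, 1e-3), w)
        assert fit.A_K == pytest.approx(A, rel=1e-10)
        assert fit.B_K == pytest.approx(B, rel=1e-10)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_needs_three_points(self):
        with pytest.raises(ValueError):
            fit_quadratic_eclipse([1, 2], [0.9, 0.8], [0.1, 0.1], 4.6)

    def test_singular_design(self):
        with pytest.raises(np.linalg.LinAlgError):
            fit_quadratic_eclipse([5, 5, 5], [0.9, 0.8, 0.7], [0.1] * 3, 4.6)

    def test_noisy_recovery_with_weights(self, rng):
        A, B, w = 2e-4, 0.0, 4.6
        radii = np.linspace(5, 25, 9)
        se = np.full(9, 0.004)
        f = 1 - A * (radii + w / 2) ** 2 + B + rng.normal(0, 0.004, 9)
        fit = fit_quadratic_eclipse(radii, f, se, w)
        assert fit.A_K == pytest.approx(A, rel=0.2)
        assert fit.r_squared > 0.95
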