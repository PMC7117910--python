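"""Curvature profiles, extrema, classification, hold lifetimes, matching."""

import numpy as np
import pytest

from spindlemech.config import RunConfig
from spindlemech.curvature import (
    CurvatureProfile,
    compute_curvature_profile,
    locate_extrema,
    classify_negative_curvature,
    hold_lifetime,
    match_needle_positions,
)
from spindlemech.geometry import RigidTransform2D


def sine_fiber(amplitude=0.5, x_max=4 * np.pi, n=2000):
    x = np.linspace(0.0, x_max, n)
    return np.column_stack([x, amplitude * np.sin(x)])


class TestProfile:
    def test_circular_arc_constant_curvature(self, arc_factory, config):
        # radius 2 um, length 6 um; reference oriented along the outward
        # bow of the arc, so kappa is +0.5 across the defined range
        p = arc_factory(2.0, 3.0, n=500)
        outward = p[len(p) // 2] / np.linalg.norm(p[len(p) // 2])
        prof = compute_curvature_profile(p, config=config, normal_ref=outward)
        assert np.allclose(prof.kappa, 0.5, atol=5e-3)
        assert prof.kappa.min() > 0

    def test_straight_fiber_zero_everywhere(self, config):
        p = np.column_stack([np.linspace(0, 10, 300), np.zeros(300)])
        prof = compute_curvature_profile(p, config=config)
        assert np.abs(prof.kappa).max() < 1e-9

    def test_defined_range_respects_window(self, config):
        p = np.column_stack([np.linspace(0, 10, 200), np.zeros(200)])
        prof = compute_curvature_profile(p, config=config)
        assert prof.s.min() >= config.curvature_window_um - 1e-9
        assert prof.s.max() <= prof.length - config.curvature_window_um + 1e-9
        assert np.all(np.diff(prof.u) > 0)

    def test_sine_curve_against_analytic_curvature(self, config):
        # analytic plane-curve oracle kappa = y'' / (1 + y'^2)^(3/2); the
        # reference normal (0, -1) maps the bow-toward-reference sign onto
        # the standard leftward-turn convention of the oracle
        p = sine_fiber()
        prof = compute_curvature_profile(p, config=config, normal_ref=np.array([0, -1.0]))
        x_at_s = np.interp(prof.s, np.concatenate([[0], np.cumsum(
            np.linalg.norm(np.diff(p, axis=0), axis=1))]), p[:, 0])
        y1 = 0.5 * np.cos(x_at_s)
        y2 = -0.5 * np.sin(x_at_s)
        kappa_true = y2 / (1 + y1**2) ** 1.5
        err = np.abs(prof.kappa - kappa_true).max()
        assert err < 0.05 * np.abs(kappa_true).max()
        # sign agrees everywhere the curve bends appreciably
        big = np.abs(kappa_true) > 0.1
        assert np.all(np.sign(prof.kappa[big]) == np.sign(kappa_true[big]))

    def test_rigid_motion_invariance_and_reflection_flip(self, config):
        p = sine_fiber(x_max=2 * np.pi, n=800)
        ref = np.array([0.0, 1.0])
        prof = compute_curvature_profile(p, config=config, normal_ref=ref)
        tf = RigidTransform2D(25.0, (3.0, -1.0))
        prof_rigid = compute_curvature_profile(
            tf.apply(p), config=config, normal_ref=tf.matrix @ ref
        )
        assert np.abs(prof_rigid.kappa - prof.kappa).max() < 1e-9
        mirrored = p * np.array([1.0, -1.0])
        prof_mirror = compute_curvature_profile(mirrored, config=config, normal_ref=ref)
        assert np.abs(prof_mirror.kappa + prof.kappa).max() < 1e-9

    def test_curvature_bounded_by_window_geometry(self, config):
        p = sine_fiber()
        prof = compute_curvature_profile(p, config=config)
        assert np.abs(prof.kappa).max() <= 2.0 / config.curvature_window_um

    def test_short_fiber_rejected(self, config):
        p = np.column_stack([np.linspace(0, 1.5, 50), np.zeros(50)])
        with pytest.raises(ValueError, match="too short"):
            compute_curvature_profile(p, config=config)

    def test_needle_arc_position_located(self, config):
        p = np.column_stack([np.linspace(0, 10, 300), np.zeros(300)])
        prof = compute_curvature_profile(p, needle=np.array([7.0, 0.3]), config=config)
        assert prof.s_needle == pytest.approx(7.0, abs=0.1)
        assert prof.u_needle == pytest.approx(0.7, abs=0.01)


class TestExtrema:
    def _profile(self, s, kappa, length=10.0, s_needle=None):
        return CurvatureProfile(s=np.asarray(s, float), u=np.asarray(s) / length,
                                kappa=np.asarray(kappa, float), window=1.0,
                                length=length, s_needle=s_needle)

    def test_gaussian_bump_located_on_grid(self):
        s = np.linspace(1, 9, 81)
        ex = locate_extrema(self._profile(s, np.exp(-((s - 5) ** 2))))
        assert ex.s_max == pytest.approx(5.0, abs=0.1)

    def test_flat_profile_returns_plus_end_proximal_zeros(self):
        s = np.linspace(1, 9, 81)
        ex = locate_extrema(self._profile(s, np.zeros_like(s)))
        assert ex.kappa_max == ex.kappa_min == 0.0
        assert ex.s_max == ex.s_min == s[0]

    def test_ties_break_toward_plus_end(self):
        s = np.linspace(1, 9, 81)
        kappa = np.sin(np.pi * s)  # many equal-height extrema
        ex = locate_extrema(self._profile(s, kappa))
        first_max = s[np.argmax(kappa)]
        assert ex.s_max == pytest.approx(first_max)

    def test_distances_from_needle_reported(self):
        s = np.linspace(1, 9, 81)
        ex = locate_extrema(self._profile(s, np.exp(-((s - 5) ** 2)), s_needle=6.0))
        assert ex.max_from_needle == pytest.approx(abs(ex.s_max - 6.0))


class TestClassification:
    def _ex(self, kappa_min, s_min, L=10.0):
        from spindlemech.curvature import CurvatureExtrema

        return CurvatureExtrema(s_max=5.0, kappa_max=0.5, s_min=s_min,
                                kappa_min=kappa_min, length=L)

    def test_deep_trough_near_plus_end_is_chromosome_proximal(self, config):
        assert classify_negative_curvature(self._ex(-0.2, 2.0), config=config) \
            == "chromosome_proximal"

    def test_shallow_trough_is_none(self, config):
        assert classify_negative_curvature(self._ex(-0.05, 2.0), config=config) == "none"

    def test_deep_trough_near_pole_is_pole_proximal(self, config):
        assert classify_negative_curvature(self._ex(-0.2, 9.0), config=config) \
            == "pole_proximal"

    def test_mid_fiber_trough_not_classified(self, config):
        assert classify_negative_curvature(self._ex(-0.2, 5.0), config=config) == "none"

    def test_sensitivity_of_window_fraction(self, config):
        # the proximal window is configurable; the same trough at s=3.5 um
        # flips classification between fraction 0.3 and 0.5 on a 10 um fiber
        ex = self._ex(-0.2, 3.5)
        assert classify_negative_curvature(
            ex, config=config.with_(proximal_fraction=0.3)) == "none"
        assert classify_negative_curvature(
            ex, config=config.with_(proximal_fraction=0.5)) == "chromosome_proximal"


class TestHoldLifetime:
    def _series(self, kmin_fn, times, L=10.0):
        profiles = []
        s = np.linspace(1.0, L - 1.0, 90)
        for t in times:
            kappa = np.full_like(s, 0.05)
            kappa[np.abs(s - 2.0) < 0.5] = kmin_fn(t)
            profiles.append(CurvatureProfile(s=s, u=s / L, kappa=kappa, window=1.0,
                                             length=L, time_s=t))
        return profiles

    def test_linear_relaxation_crosses_threshold_at_ten_seconds(self, config):
        times = np.arange(-1.0, 21.0)
        profiles = self._series(lambda t: -0.3 + 0.02 * max(t, 0.0), times)
        res = hold_lifetime(profiles, hold_start=0.0, config=config)
        assert not res.censored
        assert res.lifetime_s == pytest.approx(10.0)

    def test_persistent_trough_is_censored(self, config):
        times = np.arange(-1.0, 10.0)
        res = hold_lifetime(self._series(lambda t: -0.3, times), 0.0, config=config)
        assert res.censored
        assert res.lifetime_s is None

    def test_already_relaxed_at_hold_start_gives_zero(self, config):
        times = np.arange(-2.0, 8.0)
        res = hold_lifetime(
            self._series(lambda t: -0.3 if t < 0 else -0.05, times), 0.0, config=config
        )
        assert res.lifetime_s == pytest.approx(0.0)

    def test_single_frame_flicker_ignored(self, config):
        times = np.arange(-1.0, 12.0)

        def kmin(t):
            if t < 4:
                return -0.3
            return -0.15 if t == 7 else -0.05  # one-frame dip back below

        res = hold_lifetime(self._series(kmin, times), 0.0, config=config)
        assert res.lifetime_s == pytest.approx(4.0)

    def test_no_pre_hold_negative_curvature_rejected(self, config):
        times = np.arange(-1.0, 6.0)
        with pytest.raises(ValueError, match="nothing to track"):
            hold_lifetime(self._series(lambda t: -0.02, times), 0.0, config=config)


class TestNeedleMatching:
    def test_identical_distributions_keep_everything(self):
        u = np.linspace(0.2, 0.8, 10)
        res = match_needle_positions(u, u.copy())
        assert res.keep_a.all() and res.keep_b.all()
        assert res.p_value > 0.05

    def test_ranges_trimmed_to_intersection(self):
        a = np.linspace(0.2, 0.8, 13)
        b = np.linspace(0.4, 0.9, 11)
        res = match_needle_positions(a, b)
        assert res.u_range == (pytest.approx(0.4), pytest.approx(0.8))
        assert np.all(a[res.keep_a] >= 0.4 - 1e-12)
        assert np.all(b[res.keep_b] <= 0.8 + 1e-12)
        assert (~res.keep_a).sum() == (a < 0.4).sum()

    def test_single_outlier_removed(self):
        a = np.array([0.45, 0.55, 0.65, 0.75, 0.95])  # one record above B's range
        b = np.array([0.45, 0.5, 0.6, 0.7, 0.8])
        res = match_needle_positions(a, b)
        assert (~res.keep_a).sum() == 1
        assert (~res.keep_b).sum() == 0

    def test_disjoint_ranges_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            match_needle_positions([0.1, 0.2], [0.7, 0.9])
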