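"""Elastic-rod mechanics, scene generation, rendering, step programs."""

import numpy as np
import pandas as pd
import pytest

from spindlemech.config import RunConfig
from spindlemech.curvature import compute_curvature_profile, locate_extrema
from spindlemech.simulate import (
    RodModel,
    Protocol,
    SceneParams,
    make_rod,
    degrade_reinforcement,
    rod_energy_gradient,
    simulate_rod_equilibrium,
    generate_manipulation_series,
    series_to_trace_table,
    render_frame,
    needle_step_program,
)
from spindlemech.strain import build_strain_map

UP = np.array([0.0, 1.0])


class TestRodEnergy:
    def test_rest_shape_has_zero_energy_and_gradient(self):
        rod = make_rod(length=10, n_nodes=51, model=2, sagitta=0.3)
        E, g = rod_energy_gradient(rod.rest.copy(), rod)
        assert E == pytest.approx(0.0, abs=1e-12)
        assert np.abs(g).max() < 1e-9

    def test_analytic_gradient_matches_finite_differences(self, rng):
        rod = make_rod(length=10, n_nodes=51, model=2, sagitta=0.3)
        x = rod.rest + 0.01 * rng.standard_normal(rod.rest.shape)
        _, g = rod_energy_gradient(x, rod)
        eps = 1e-6
        for i, k in [(0, 0), (10, 1), (25, 0), (50, 1)]:
            xp, xm = x.copy(), x.copy()
            xp[i, k] += eps
            xm[i, k] -= eps
            fd = (rod_energy_gradient(xp, rod)[0] - rod_energy_gradient(xm, rod)[0]) / (2 * eps)
            assert g[i, k] == pytest.approx(fd, rel=1e-5, abs=1e-6)

    def test_model1_requires_uniform_anchorage(self):
        with pytest.raises(ValueError):
            make_rod(model=1, k_enh=100.0)
        with pytest.raises(ValueError):
            make_rod(model=3)


class TestEquilibrium:
    def test_zero_displacement_returns_rest_unchanged(self):
        rod = make_rod(length=10, n_nodes=51, model=2)
        x = simulate_rod_equilibrium(rod, None)
        assert np.array_equal(x, rod.rest)

    def test_pinned_beam_matches_euler_bernoulli_shape(self):
        # three-point bending of a rod with no crosslinks, both ends pinned:
        # closed form y(x) = delta * (3 L^2 x - 4 x^3) / L^3 on [0, L/2]
        L, delta = 10.0, 0.05
        rod = make_rod(length=L, n_nodes=51, model=1, kc_base=0.0)
        x = simulate_rod_equilibrium(
            rod, np.array([0.0, delta]), s_needle=L / 2, pin_plus_end=True
        )
        xs = rod.rest[:, 0]
        mirrored = np.minimum(xs, L - xs)
        beam = delta * (3 * L**2 * mirrored - 4 * mirrored**3) / L**3
        assert np.abs(x[:, 1] - beam).max() < 0.02 * delta

    def test_equilibrium_energy_below_naive_constrained_rest(self):
        rod = make_rod(length=10, n_nodes=51, model=2)
        disp = np.array([0.0, 2.0])
        x = simulate_rod_equilibrium(rod, disp, s_needle=5.0)
        naive = rod.rest.copy()
        node = int(np.argmin(np.abs(rod.s - 5.0)))
        naive[node] += disp
        E_eq, _ = rod_energy_gradient(x, rod)
        E_naive, _ = rod_energy_gradient(naive, rod)
        assert E_eq < E_naive

    def test_inextensibility_maintained(self):
        rod = make_rod(length=10, n_nodes=51, model=2)
        x = simulate_rod_equilibrium(rod, np.array([0.0, 2.5]), s_needle=5.0)
        seg = np.linalg.norm(np.diff(x, axis=0), axis=1)
        assert np.abs(seg / rod.seg_rest - 1).max() < 0.03

    def test_model2_pull_creates_needle_peak_and_proximal_trough(self, config):
        rod = make_rod(length=10, n_nodes=51, model=2)
        x = simulate_rod_equilibrium(rod, np.array([0.0, 2.5]), s_needle=5.0)
        prof = compute_curvature_profile(x, config=config, normal_ref=UP)
        ex = locate_extrema(prof)
        assert ex.kappa_max > 0.2
        assert abs(ex.s_max - 5.0) < 1.0  # positive peak at the needle
        assert ex.kappa_min < -0.1
        assert 1.0 <= ex.s_min <= 3.0  # reverse bend near the plus-end


class TestReinforcementTurnover:
    def test_zero_time_unchanged(self):
        rod = make_rod(model=2)
        assert degrade_reinforcement(rod, 0.0, 20.0).k_enh == rod.k_enh

    def test_one_lifetime_scales_by_e(self):
        rod = make_rod(model=2)
        out = degrade_reinforcement(rod, 20.0, 20.0)
        assert out.k_enh == pytest.approx(rod.k_enh / np.e)
        assert out.kc_base == rod.kc_base

    def test_long_times_approach_uniform_anchorage(self):
        rod = make_rod(model=2)
        assert degrade_reinforcement(rod, 1e6, 20.0).k_enh < 1e-6

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            degrade_reinforcement(make_rod(model=2), -1.0, 20.0)
        with pytest.raises(ValueError):
            degrade_reinforcement(make_rod(model=2), 1.0, 0.0)


class TestSceneGeneration:
    def test_final_needle_displacement_is_exactly_the_pull(self):
        scene = SceneParams(seed=1, noise_sigma_um=0.0, jitter_rot_deg=0.0,
                            jitter_trans_um=0.0)
        proto = Protocol.pull60()
        series, gt = generate_manipulation_series(scene, proto)
        assert gt.needle_displacement_um[-1] == pytest.approx(2.5)
        moved = gt.needle_path[-1] - gt.needle_path[0]
        assert np.linalg.norm(moved) == pytest.approx(2.5)

    def test_same_seed_bit_identical(self):
        scene = SceneParams(seed=77)
        proto = Protocol.pull12()
        t1 = series_to_trace_table(generate_manipulation_series(scene, proto)[0])
        t2 = series_to_trace_table(generate_manipulation_series(scene, proto)[0])
        pd.testing.assert_frame_equal(t1, t2)

    def test_different_seeds_differ(self):
        proto = Protocol.pull12()
        t1 = series_to_trace_table(
            generate_manipulation_series(SceneParams(seed=1), proto)[0])
        t2 = series_to_trace_table(
            generate_manipulation_series(SceneParams(seed=2), proto)[0])
        assert not t1.equals(t2)

    def test_jitter_only_series_has_noise_floor_strain(self, config):
        # no pull: after rigid correction the residual displacement is the
        # tracing-noise floor.  Both frames carry independent noise of
        # amplitude sigma per component, so the pair difference has
        # component sd sigma*sqrt(2) and mean magnitude
        # sigma*sqrt(2)*sqrt(pi/2) ~ 1.77 sigma; the maximum over ~10^3
        # correlated samples sits a further factor ~2 up
        scene = SceneParams(seed=5)
        series, _ = generate_manipulation_series(scene, Protocol.unmanipulated())
        smap = build_strain_map(series.frames[0], series.frames[-1], config=config)
        sig = scene.noise_sigma_um
        assert 0.5 * sig < smap.D.mean() < 2.5 * sig
        assert smap.D.max() < 5 * sig

    def test_frame_interval_longer_than_pull_rejected(self):
        with pytest.raises(ValueError):
            Protocol("pull12", 1.8, 12.0, frame_interval_s=20.0)

    def test_trace_table_round_trips_through_io(self, tmp_path, config):
        from spindlemech.io import TraceTable, write_trace_table, read_trace_table

        scene = SceneParams(seed=3)
        series, _ = generate_manipulation_series(scene, Protocol.pull12())
        df = series_to_trace_table(series)
        table = TraceTable(df)
        write_trace_table(table, tmp_path / "t.csv")
        back = read_trace_table(tmp_path / "t.csv", config)
        assert np.allclose(
            back.df[["x_um", "y_um"]].to_numpy(),
            table.df[["x_um", "y_um"]].to_numpy(),
        )
        frames = back.to_frames(series.cell_id)
        assert len(frames) == len(series.frames)
        assert "pair0" in frames[0].kt_pairs


class TestRendering:
    def _tiny_frame(self):
        from spindlemech.scene import FiberTrace, SpindleFrame

        fiber = FiberTrace("f", np.column_stack(
            [np.linspace(1, 9, 50), np.full(50, 2.0)]), role="kfiber")
        return SpindleFrame(pole1=np.array([0.5, 2.0]), pole2=np.array([9.5, 2.0]),
                            fibers={"f": fiber})

    def test_straight_fiber_renders_ridge_on_its_axis(self):
        img = render_frame(self._tiny_frame(), pixel_size=0.105, psf_sigma=0.2,
                           fov_um=(12.0, 4.0), origin_um=(-1.0, 0.0))
        row_of_peak = np.unravel_index(np.argmax(img), img.shape)[0]
        assert abs(row_of_peak - (2.0 - 0.0) / 0.105) <= 1

    def test_total_intensity_invariant_to_subpixel_shift(self):
        frame = self._tiny_frame()
        img0 = render_frame(frame, fov_um=(12, 4), origin_um=(-1, 0))
        for tr in frame.fibers.values():
            tr.points = tr.points + np.array([0.0371, 0.051])
        frame.pole1 = frame.pole1 + np.array([0.0371, 0.051])
        frame.pole2 = frame.pole2 + np.array([0.0371, 0.051])
        img1 = render_frame(frame, fov_um=(12, 4), origin_um=(-1, 0))
        assert img1.sum() == pytest.approx(img0.sum(), rel=0.01)

    def test_empty_frame_is_zero_image(self):
        from spindlemech.scene import SpindleFrame

        img = render_frame(SpindleFrame(pole1=None, pole2=None),
                           fov_um=(5, 5), origin_um=(0, 0))
        assert img.sum() == 0.0

    def test_too_small_field_of_view_rejected(self):
        with pytest.raises(ValueError, match="field of view"):
            render_frame(self._tiny_frame(), fov_um=(3.0, 1.0), origin_um=(0, 0))


class TestStepProgram:
    def test_sixty_second_program_has_forty_steps(self):
        prog = needle_step_program(90.0, 2.5, 60.0)
        assert len(prog) == 40  # 2.5 / 0.0625
        assert np.allclose(prog["dwell_s"], 1.5)
        assert np.allclose(prog["dx_um"], 0.0, atol=1e-12)
        assert prog["dy_um"].sum() == pytest.approx(2.5)

    def test_single_minimum_step(self):
        prog = needle_step_program(0.0, 0.0625, 1.0)
        assert len(prog) == 1

    def test_sub_step_distance_warns(self):
        with pytest.warns(UserWarning):
            prog = needle_step_program(0.0, 0.03, 1.0)
        assert len(prog) == 1
        assert prog["dx_um"].iloc[0] == pytest.approx(0.03)

    def test_total_displacement_within_one_step(self):
        prog = needle_step_program(30.0, 1.83, 10.0)
        total = np.hypot(prog["dx_um"].sum(), prog["dy_um"].sum())
        assert abs(total - 1.83) <= 0.0625
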