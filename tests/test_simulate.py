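"""Two-pool kinetics and movie rendering."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad
from skimage.measure import label

import pulsechase as pc
from pulsechase.simulate import CONVERT_488, RESTORE_405


def two_cycle_plan():
    return pc.make_cycle_plan(2, [8.0, 60.0], 3.0)


class TestCyclePlan:
    def test_two_cycle_arithmetic(self):
        plan = two_cycle_plan()
        (c1, c2) = plan.cycles
        assert (c1.nef_time, c1.neb_time) == (0.0, 8.0)
        assert (c2.nef_time, c2.neb_time) == (11.0, None)
        assert plan.end_time == 71.0

    def test_single_cycle_is_open_ended(self):
        plan = pc.make_cycle_plan(1, [10.0], 3.0)
        assert len(plan.cycles) == 1
        assert plan.cycles[0].neb_time is None

    @pytest.mark.parametrize("n, inter, mit", [
        (0, [], 3.0),
        (2, [8.0, 10.0], 0.0),
        (2, [8.0, -1.0], 3.0),
        (2, [8.0], 3.0),
    ])
    def test_invalid_plans_rejected(self, n, inter, mit):
        with pytest.raises(ValueError):
            pc.make_cycle_plan(n, inter, mit)

    def test_cycle_indices_count_back_from_last(self):
        plan = pc.make_cycle_plan(3, [8.0, 10.0, 20.0], 3.0)
        assert [c.index for c in plan.cycles] == [12, 13, 14]


class TestKinetics:
    def test_conserved_without_sources_or_sinks(self):
        params = pc.KineticParams(schedule=pc.RateSchedule.constant(0.0), L0=1.0)
        traj = pc.simulate_kinetics(params, two_cycle_plan())
        assert np.allclose(traj.L, 1.0)
        assert np.allclose(traj.D, 0.0)

    def test_closed_form_exponential(self):
        params = pc.KineticParams(schedule=pc.RateSchedule.constant(0.1), L0=1.0)
        traj = pc.simulate_kinetics(params, two_cycle_plan())
        assert traj.L_at(10.0) == pytest.approx(math.exp(-1.0), rel=1e-9)

    def test_complete_conversion_conserves_total(self):
        params = pc.KineticParams(schedule=pc.RateSchedule.constant(0.0),
                                  L0=0.8, D0=0.2, eps_off=1.0)
        ev = [pc.PhotoswitchEvent(2.0, CONVERT_488)]
        traj = pc.simulate_kinetics(params, two_cycle_plan(), ev)
        rec = traj.event_records[0]
        assert rec.L_after == pytest.approx(0.0, abs=1e-15)
        assert rec.D_after == pytest.approx(1.0, abs=1e-15)
        assert rec.L_after + rec.D_after == pytest.approx(rec.L_before + rec.D_before)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(eps_off=st.floats(0.1, 1.0), eps_on=st.floats(0.1, 1.0),
           s=st.floats(0.0, 5.0), k=st.floats(0.0, 0.3),
           t_conv=st.floats(1.0, 30.0))
    def test_events_conserve_total_pool(self, eps_off, eps_on, s, k, t_conv):
        params = pc.KineticParams(synthesis_rate=s,
                                  schedule=pc.RateSchedule.constant(k),
                                  eps_off=eps_off, eps_on=eps_on, L0=1.0, D0=0.1)
        ev = [pc.PhotoswitchEvent(t_conv, CONVERT_488),
              pc.PhotoswitchEvent(t_conv + 10.0, RESTORE_405)]
        traj = pc.simulate_kinetics(params, two_cycle_plan(), ev)
        for rec in traj.event_records:
            assert rec.L_after + rec.D_after == pytest.approx(
                rec.L_before + rec.D_before, rel=0, abs=1e-12)

    def test_rk4_matches_integrating_factor_solution(self):
        # logistic k(t) forces the RK4 path; compare with quadrature oracle
        sched = pc.RateSchedule(k_base=0.02, k_max=0.3, t_half=30.0, steepness=4.0)
        s, L0, D0 = 1.5, 10.0, 4.0
        params = pc.KineticParams(synthesis_rate=s, schedule=sched, L0=L0, D0=D0)
        traj = pc.simulate_kinetics(params, two_cycle_plan())
        for t_eval in (5.0, 20.0, 40.0, 70.0):
            K = quad(sched, 0.0, t_eval, limit=200)[0]
            D_exact = D0 * math.exp(-K)
            L_exact = math.exp(-K) * (
                L0 + s * quad(lambda u: math.exp(quad(sched, 0.0, u, limit=200)[0]),
                              0.0, t_eval, limit=200)[0])
            assert traj.D_at(t_eval) == pytest.approx(D_exact, rel=1e-6)
            assert traj.L_at(t_eval) == pytest.approx(L_exact, rel=1e-6)

    @pytest.mark.parametrize("s", [0.0, 0.5, 5.0])
    def test_chase_is_synthesis_independent(self, s):
        sched = pc.RateSchedule(k_base=0.01, k_max=0.2, t_half=20.0, steepness=3.0)
        params = pc.KineticParams(synthesis_rate=s, schedule=sched,
                                  eps_off=1.0, eps_on=1.0, L0=50.0)
        ev = [pc.PhotoswitchEvent(4.5, CONVERT_488),
              pc.PhotoswitchEvent(15.5, RESTORE_405)]
        traj = pc.simulate_kinetics(params, two_cycle_plan(), ev)
        conv, rest = traj.event_records
        surviving = rest.D_before / conv.D_after
        K = quad(sched, 4.5, 15.5, limit=200)[0]
        assert surviving == pytest.approx(math.exp(-K), rel=1e-6)

    def test_unordered_events_rejected(self):
        params = pc.KineticParams(schedule=pc.RateSchedule.constant(0.0), L0=1.0)
        ev = [pc.PhotoswitchEvent(5.0, CONVERT_488),
              pc.PhotoswitchEvent(2.0, RESTORE_405)]
        with pytest.raises(ValueError, match="ordered"):
            pc.simulate_kinetics(params, two_cycle_plan(), ev)

    def test_event_outside_grid_rejected(self):
        params = pc.KineticParams(schedule=pc.RateSchedule.constant(0.0), L0=1.0)
        ev = [pc.PhotoswitchEvent(1000.0, CONVERT_488)]
        with pytest.raises(ValueError, match="outside"):
            pc.simulate_kinetics(params, two_cycle_plan(), ev)


class TestRateSchedule:
    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            pc.RateSchedule(k_base=-0.1, k_max=0.2, t_half=0.0, steepness=1.0)
        with pytest.raises(ValueError):
            pc.RateSchedule(k_base=0.3, k_max=0.2, t_half=0.0, steepness=1.0)
        with pytest.raises(ValueError):
            pc.RateSchedule(k_base=0.1, k_max=0.2, t_half=0.0, steepness=0.0)

    def test_logistic_midpoint(self):
        sched = pc.RateSchedule(k_base=0.0, k_max=0.2, t_half=10.0, steepness=2.0)
        assert sched(10.0) == pytest.approx(0.1)


class TestRendering:
    def small_layout(self, **kw):
        defaults = dict(height=96, width=96, frame_interval_s=30.0,
                        nuclear_radius_um=2.4, n_initial=2)
        defaults.update(kw)
        return pc.MovieLayout(**defaults)

    def render_noiseless(self, L0=50.0, layout=None, n_cycles=2):
        plan = pc.make_cycle_plan(n_cycles, [8.0, 10.0][:n_cycles], 3.0)
        params = pc.KineticParams(schedule=pc.RateSchedule.constant(0.0), L0=L0)
        traj = pc.simulate_kinetics(params, plan)
        layout = layout or self.small_layout()
        noise = pc.NoiseParams(seed=0, photons_per_unit=0.0, read_sigma=0.0)
        return pc.render_movie(traj, plan, layout, noise), plan

    def test_noiseless_plateau_reporter_mean_is_exact(self):
        layout = self.small_layout(n_initial=1)
        movie, plan = self.render_noiseless(L0=50.0, layout=layout)
        gt = movie.ground_truth
        i = int(round(5.0 / layout.frame_interval_min))  # 5 min: on the plateau
        (cy, cx) = gt.centers_by_cycle[13][0]
        yy, xx = np.mgrid[0:layout.height, 0:layout.width]
        disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= (
            layout.reporter_radius_factor * gt.nuclear_radius_px) ** 2
        assert movie.frames[i, 1][disk].mean() == pytest.approx(
            layout.enrichment_max * 50.0, rel=1e-12)

    def test_rendering_linearity_in_light_pool(self):
        m1, _ = self.render_noiseless(L0=50.0)
        m2, _ = self.render_noiseless(L0=100.0)
        assert np.allclose(m2.frames[:, 1], 2.0 * m1.frames[:, 1])
        assert np.allclose(m2.frames[:, 0], m1.frames[:, 0])  # histone unchanged

    def test_hundred_nuclei_give_hundred_components(self):
        layout = pc.MovieLayout(height=256, width=256, frame_interval_s=60.0,
                                nuclear_radius_um=2.4, n_initial=100)
        movie, plan = self.render_noiseless(layout=layout, n_cycles=1)
        frame = movie.frames[2, 0]  # interphase histone frame
        binary = frame > layout.histone_background + layout.histone_amplitude / 2
        assert label(binary).max() == 100

    def test_mitosis_frames_are_low_contrast(self):
        movie, plan = self.render_noiseless()
        times = movie.times_min
        cv = lambda img: img.std() / img.mean()
        inter = [cv(movie.frames[i, 0]) for i, t in enumerate(times)
                 if plan.phase_at(t)[0] == "interphase"]
        mito = [cv(movie.frames[i, 0]) for i, t in enumerate(times)
                if plan.phase_at(t)[0] == "mitosis"]
        assert mito and max(mito) < 0.1 * min(inter)

    def test_trajectory_plan_mismatch_rejected(self):
        plan = pc.make_cycle_plan(2, [8.0, 10.0], 3.0)
        short = pc.make_cycle_plan(1, [5.0], 3.0)
        params = pc.KineticParams(schedule=pc.RateSchedule.constant(0.0), L0=1.0)
        traj = pc.simulate_kinetics(params, short)
        noise = pc.NoiseParams(seed=0, photons_per_unit=0.0, read_sigma=0.0)
        with pytest.raises(ValueError, match="cover"):
            pc.render_movie(traj, plan, self.small_layout(), noise)

    def test_noise_is_seed_reproducible(self):
        plan = pc.make_cycle_plan(1, [6.0], 3.0)
        params = pc.KineticParams(schedule=pc.RateSchedule.constant(0.0), L0=50.0)
        traj = pc.simulate_kinetics(params, plan)
        layout = self.small_layout()
        a = pc.render_movie(traj, plan, layout, pc.NoiseParams(seed=5))
        b = pc.render_movie(traj, plan, layout, pc.NoiseParams(seed=5))
        c = pc.render_movie(traj, plan, layout, pc.NoiseParams(seed=6))
        assert np.array_equal(a.frames, b.frames)
        assert not np.array_equal(a.frames, c.frames)
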