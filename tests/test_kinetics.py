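"""Pulse-chase rate estimation, lifetime fits, classification, group stats."""

import itertools
import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import studentized_range

import pulsechase as pc
from pulsechase.simulate import CONVERT_488, RESTORE_405


def chase_estimate(params, plan, t_conv, t_rest, enrichment=2.0):
    """Run the two-pool simulation and feed perfect peak reads into the
    estimator (the enrichment factor cancels in the ratio)."""
    ev = [pc.PhotoswitchEvent(t_conv, CONVERT_488),
          pc.PhotoswitchEvent(t_rest, RESTORE_405)]
    traj = pc.simulate_kinetics(params, plan, ev)
    conv, rest = traj.event_records
    return pc.dronpa_rate(
        I_preconvert=enrichment * conv.L_before,
        I_pre405=enrichment * rest.L_before,
        I_post405=enrichment * rest.L_after,
        delta_t=t_rest - t_conv,
        eps_off=params.eps_off, eps_on=params.eps_on)


class TestDronpaRate:
    def test_no_loss_gives_zero_rate(self):
        est = pc.dronpa_rate(100.0, 0.0, 100.0, 10.0)
        assert est.ratio == pytest.approx(1.0)
        assert est.k == 0.0
        assert est.flag == "no_decay"

    def test_constant_rate_recovered_from_simulation(self):
        plan = pc.make_cycle_plan(2, [8.0, 60.0], 3.0)
        params = pc.KineticParams(schedule=pc.RateSchedule.constant(0.1), L0=100.0)
        est = chase_estimate(params, plan, 4.0, 14.0)
        assert est.k == pytest.approx(0.1, abs=1e-6)

    @pytest.mark.parametrize("s", [0.0, 0.5, 5.0])
    def test_synthesis_does_not_bias_estimate(self, s):
        plan = pc.make_cycle_plan(2, [8.0, 60.0], 3.0)
        params = pc.KineticParams(synthesis_rate=s,
                                  schedule=pc.RateSchedule.constant(0.1), L0=100.0)
        est = chase_estimate(params, plan, 4.0, 14.0)
        assert est.k == pytest.approx(0.1, abs=1e-6)

    def test_partial_switching_corrected(self):
        plan = pc.make_cycle_plan(2, [8.0, 60.0], 3.0)
        perfect = pc.KineticParams(schedule=pc.RateSchedule.constant(0.08), L0=100.0)
        partial = pc.KineticParams(schedule=pc.RateSchedule.constant(0.08), L0=100.0,
                                   eps_off=0.8, eps_on=0.8)
        k_perfect = chase_estimate(perfect, plan, 4.0, 14.0).k
        k_partial = chase_estimate(partial, plan, 4.0, 14.0).k
        assert k_partial == pytest.approx(k_perfect, abs=1e-3)

    def test_no_recovery_flagged(self):
        est = pc.dronpa_rate(100.0, 50.0, 45.0, 10.0)
        assert est.flag == "no_recovery"
        assert est.k is None

    def test_nonpositive_converted_pool_rejected(self):
        with pytest.raises(ValueError, match="converted"):
            pc.dronpa_rate(0.0, 1.0, 2.0, 10.0)

    def test_estimator_identity_on_time_varying_rate(self):
        # k_hat * delta_t equals the integral of k over the chase interval
        sched = pc.RateSchedule(k_base=0.02, k_max=0.25, t_half=12.0, steepness=2.0)
        plan = pc.make_cycle_plan(2, [8.0, 60.0], 3.0)
        params = pc.KineticParams(synthesis_rate=1.0, schedule=sched, L0=100.0)
        est = chase_estimate(params, plan, 4.0, 16.0)
        K = quad(sched, 4.0, 16.0, limit=200)[0]
        assert est.k * est.delta_t == pytest.approx(K, abs=1e-3)


class TestRateTrajectory:
    def test_empty_event_log_gives_empty_trajectory(self, demo_trace):
        assert pc.rate_trajectory(demo_trace, []) == []

    def test_unpaired_events_rejected(self, demo_trace):
        with pytest.raises(ValueError, match="unpaired|without prior"):
            pc.rate_trajectory(demo_trace, [pc.PhotoswitchEvent(5.0, CONVERT_488)])

    def test_switch_schedule_rates_low_then_high(self, demo_config, demo_trace,
                                                 demo_movie):
        rates = pc.rate_trajectory(demo_trace, demo_movie.event_log)
        traj = demo_movie.ground_truth.trajectory
        ks = []
        for r in rates:
            assert r.flag == "ok"
            t0, t1 = r.t_mid - r.delta_t / 2, r.t_mid + r.delta_t / 2
            sel = (traj.time >= t0) & (traj.time <= t1)
            k_true = traj.k[sel].mean()
            assert r.k == pytest.approx(k_true, rel=0.15)
            ks.append(r.k)
        assert ks[-1] > 3 * max(ks[:-1])  # late jump under the switch schedule


class TestDecayFit:
    def test_exact_exponential_lifetime(self):
        t = np.arange(0.0, 10.0 + 1e-9, 1.0)
        I = 100.0 * np.exp(-t / 5.0)
        fit = pc.fit_decay_time(t, I, smooth=1)
        assert fit.tau == pytest.approx(5.0, rel=1e-12)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.flag == "ok"

    def test_constant_series_flagged_stable(self):
        t = np.arange(10.0)
        fit = pc.fit_decay_time(t, np.full(10, 3.0))
        assert math.isinf(fit.tau)
        assert fit.flag == "stable"

    def test_onset_found_after_plateau(self):
        t = np.arange(0.0, 20.0, 0.5)
        I = np.where(t < 6.0, 50.0, 50.0 * np.exp(-(t - 6.0) / 4.0))
        fit = pc.fit_decay_time(t, I, smooth=1)
        assert fit.t_onset == pytest.approx(6.0, abs=0.51)
        assert fit.tau == pytest.approx(4.0, rel=1e-6)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            pc.fit_decay_time(np.arange(3.0), np.array([3.0, 2.0, 1.0]))

    def test_noisy_recovery_within_ten_percent(self):
        errs = []
        for rep in range(20):
            noise = pc.NoiseParams(seed=rep)
            rng = np.random.default_rng(np.random.SeedSequence([rep, 60]))
            t, I = pc.decay_trace(6.0, duration=30.0, noise=noise, rng=rng)
            errs.append(abs(pc.fit_decay_time(t, I).tau - 6.0) / 6.0)
        assert np.median(errs) <= 0.10


def step_rates(lo=0.01, hi=0.2):
    ts = [10.0, 22.0, 36.0, 55.0]
    ks = [lo, lo, lo, hi]
    return [pc.RateEstimate(delta_t=12.0, ratio=None, k=k, t_mid=t)
            for t, k in zip(ts, ks)]


class TestClassifySchedule:
    def test_step_function_is_switch(self):
        fit = pc.classify_schedule(step_rates(), cycle_length=13.0)
        assert fit.klass == "switch"
        assert fit.abruptness >= fit.threshold

    def test_shallow_ramp_is_gradual(self):
        ts = np.array([10.0, 22.0, 36.0, 55.0])
        rates = [pc.RateEstimate(delta_t=12.0, ratio=None,
                                 k=0.01 + 0.002 * t, t_mid=t) for t in ts]
        fit = pc.classify_schedule(rates, cycle_length=13.0)
        assert fit.klass == "gradual"

    def test_degenerate_rates_flagged_zero_amplitude(self):
        rates = [pc.RateEstimate(delta_t=12.0, ratio=None, k=0.05, t_mid=t)
                 for t in (10.0, 22.0, 36.0)]
        fit = pc.classify_schedule(rates, cycle_length=13.0)
        assert fit.klass == "gradual"
        assert "zero_amplitude" in fit.flags
        assert fit.abruptness == 0.0

    def test_too_few_estimates_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            pc.classify_schedule(step_rates()[:2], cycle_length=13.0)


def anova_direct(groups):
    """Textbook one-way ANOVA: F = (SSB/(g-1)) / (SSW/(N-g))."""
    all_vals = np.concatenate([np.asarray(v, float) for v in groups.values()])
    grand = all_vals.mean()
    ssb = sum(len(v) * (np.mean(v) - grand) ** 2 for v in groups.values())
    ssw = sum(((np.asarray(v) - np.mean(v)) ** 2).sum() for v in groups.values())
    g, N = len(groups), all_vals.size
    msb, msw = ssb / (g - 1), ssw / (N - g)
    if msb == 0:
        return 0.0, 1.0
    from scipy.stats import f as fdist
    F = msb / msw
    return F, float(fdist.sf(F, g - 1, N - g))


def tukey_direct(groups, alpha=0.05):
    names = sorted(groups)
    k = len(names)
    N = sum(len(v) for v in groups.values())
    means = {g: np.mean(groups[g]) for g in names}
    ssw = sum(((np.asarray(groups[g]) - means[g]) ** 2).sum() for g in names)
    df = N - k
    msw = ssw / df
    qcrit = studentized_range.ppf(1 - alpha, k, df)
    rows = []
    for g1, g2 in itertools.combinations(names, 2):
        diff = means[g2] - means[g1]
        se = math.sqrt(msw * (1 / len(groups[g1]) + 1 / len(groups[g2])) / 2)
        p = float(studentized_range.sf(abs(diff) / se, k, df)) if se > 0 else 1.0
        rows.append((g1, g2, diff, diff - qcrit * se, diff + qcrit * se, p))
    return rows


DATASETS = [
    {"g1": [1.0, 2.0, 3.0], "g2": [1.0, 2.0, 3.0]},
    {"a": [4.0, 5.0, 6.0], "b": [7.0, 8.0, 9.0], "c": [10.0, 11.0, 12.0]},
    {"wt": [3.1, 2.8, 3.4, 3.0], "tribbles_def": [5.2, 6.1, 5.7],
     "third_arm_del": [9.8, 11.2, 10.4]},
]


class TestCompareGroups:
    def test_identical_groups_give_f_zero_p_one(self):
        cmp = pc.compare_groups(DATASETS[0])
        assert cmp.f_statistic == pytest.approx(0.0, abs=1e-12)
        assert cmp.p_value == pytest.approx(1.0)

    def test_equally_spaced_groups_match_textbook_formula(self):
        # SSB/(g-1) = 54/2 = 27, SSW/(N-g) = 6/6 = 1, hence F = 27
        cmp = pc.compare_groups(DATASETS[1])
        assert cmp.f_statistic == pytest.approx(27.0, abs=1e-12)
        assert (cmp.df_between, cmp.df_within) == (2, 6)

    @pytest.mark.parametrize("data", DATASETS)
    def test_anova_and_tukey_match_direct_formulas(self, data):
        cmp = pc.compare_groups(data)
        F, p = anova_direct(data)
        assert cmp.f_statistic == pytest.approx(F, abs=1e-9)
        assert cmp.p_value == pytest.approx(p, abs=1e-9)
        for row, d in zip(cmp.tukey.itertuples(index=False), tukey_direct(data)):
            assert (row.group1, row.group2) == (d[0], d[1])
            assert row.meandiff == pytest.approx(d[2], abs=1e-9)
            assert row.lower == pytest.approx(d[3], abs=1e-9)
            assert row.upper == pytest.approx(d[4], abs=1e-9)
            assert row.p_adj == pytest.approx(d[5], abs=1e-9)

    def test_single_value_group_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            pc.compare_groups({"a": [1.0], "b": [2.0, 3.0]})

    def test_infinite_lifetimes_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="non-finite"):
            cmp = pc.compare_groups({"a": [1.0, 2.0, math.inf], "b": [2.0, 3.0]})
        assert len(cmp.values["a"]) == 2
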