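"""Ensemble statistics: population curves, lifetime fits, yield,
classification and the barrier--lifetime machinery (on synthetic inputs)."""

import math
from dataclasses import replace

import numpy as np
import pytest

from phytohop.model import Coordinates, ModelError
from phytohop.photoanalysis import (DecayFit, PopulationCurve,
                                    classify_trajectory, fit_exponential_decay,
                                    _fit_delayed_exponential, quantum_yield,
                                    hop_geometry_stats, state_populations,
                                    stratify_by_hbond, summarize_ensemble,
                                    wilson_interval)
from phytohop.shdynamics import HopEvent, SHTrajectory


def synthetic_trajectory(hop_time_ps, t_max_ps=10.0, dt_rec_fs=10.0,
                         final_theta6=5.0, theta6_at_hop=88.0, seed=0,
                         initial_theta6=0.0, r0=2.9):
    """Minimal trajectory object: S1 until the hop, S0 after."""
    times = np.arange(0.0, t_max_ps * 1000.0 + dt_rec_fs, dt_rec_fs)
    active = (times < hop_time_ps * 1000.0).astype(int) \
        if hop_time_ps is not None else np.ones_like(times, dtype=int)
    theta6 = np.where(active == 1, initial_theta6, final_theta6)
    hops = []
    if hop_time_ps is not None:
        hops = [HopEvent(time_fs=hop_time_ps * 1000.0, from_state=1,
                         to_state=0, gap_ev=0.1,
                         coordinates=Coordinates(theta6_at_hop, -10.0, 3.5),
                         accepted=True, frustrated=False)]
    final_state = 0 if hop_time_ps is not None else 1
    return SHTrajectory(
        times_fs=times, theta6_deg=theta6,
        theta5_deg=np.zeros_like(times), r_hb_A=np.full_like(times, r0),
        active_state=active, pop_s1=active.astype(float),
        gap_ev=np.full_like(times, 1.0), energy_kcal=np.zeros_like(times),
        hop_events=hops, final_state=final_state,
        final_coordinates=Coordinates(float(theta6[-1]), 0.0, r0),
        initial_coordinates=Coordinates(initial_theta6, 0.0, r0), seed=seed)


class TestStatePopulations:
    def test_all_on_s1(self):
        trajs = [synthetic_trajectory(None) for _ in range(5)]
        curve = state_populations(trajs, n_boot=50)
        np.testing.assert_allclose(curve.p_s1, 1.0)
        np.testing.assert_allclose(curve.p_s0, 0.0)

    def test_hand_counted_staircase(self):
        trajs = [synthetic_trajectory(t) for t in (1.0, 2.0, 3.0)]
        curve = state_populations(trajs, n_boot=50)

        def at(t_ps):
            return curve.p_s1[np.searchsorted(curve.times_fs, t_ps * 1000.0)]

        assert at(0.5) == pytest.approx(1.0)
        assert at(1.5) == pytest.approx(2.0 / 3.0)
        assert at(2.5) == pytest.approx(1.0 / 3.0)
        assert at(3.5) == pytest.approx(0.0)

    def test_fractions_sum_to_one_and_band_contains_estimate(self):
        trajs = [synthetic_trajectory(t) for t in np.linspace(0.5, 6.0, 20)]
        curve = state_populations(trajs, n_boot=200)
        np.testing.assert_allclose(curve.p_s1 + curve.p_s0, 1.0)
        assert np.all(curve.ci_lo <= curve.p_s1 + 1e-12)
        assert np.all(curve.ci_hi >= curve.p_s1 - 1e-12)

    def test_empty_input_errors(self):
        with pytest.raises(ModelError):
            state_populations([])


class TestExponentialFit:
    def test_exact_exponential_recovered(self):
        t = np.arange(0, 10000.0, 10.0)
        curve = PopulationCurve(times_fs=t, p_s1=np.exp(-t / 1000.0),
                                ci_lo=np.zeros_like(t), ci_hi=np.ones_like(t),
                                n_trajectories=1)
        fit = fit_exponential_decay(curve)
        assert fit.tau_ps == pytest.approx(1.0, abs=1e-6)
        assert fit.t0_ps == pytest.approx(0.0, abs=1e-6)

    def test_known_tau_staircase_recovery(self):
        rng = np.random.default_rng(8)
        hop_times = rng.exponential(2.0, size=2000)
        trajs = [synthetic_trajectory(min(t, 19.9), t_max_ps=20.0)
                 for t in hop_times]
        curve = state_populations(trajs, n_boot=10)
        fit = fit_exponential_decay(curve)
        assert fit.tau_ps == pytest.approx(2.0, rel=0.08)

    def test_increasing_population_rejected(self):
        t = np.arange(0, 1000.0, 10.0)
        curve = PopulationCurve(times_fs=t, p_s1=np.linspace(0.2, 1.0, len(t)),
                                ci_lo=np.zeros_like(t), ci_hi=np.ones_like(t),
                                n_trajectories=1)
        with pytest.raises(ModelError):
            fit_exponential_decay(curve)

    def test_ci_coverage_on_known_tau_ensembles(self):
        """The bootstrap 95% CI on tau must cover the truth in >=90% of
        repeated synthetic experiments."""
        rng = np.random.default_rng(123)
        tau_true = 2.0
        hits = 0
        reps = 100
        t_ps = np.arange(0, 750) * 20.0 / 1000.0
        for _ in range(reps):
            hop_times = rng.exponential(tau_true, size=150)
            states = np.stack([
                (t_ps < min(t, 14.9)).astype(int) for t in hop_times])
            taus = []
            for _ in range(200):
                pop = states[rng.integers(0, 150, 150)].mean(axis=0)
                taus.append(_fit_delayed_exponential(t_ps, pop)[0])
            lo, hi = np.percentile(taus, [2.5, 97.5])
            hits += lo <= tau_true <= hi
        assert hits / reps >= 0.9


class TestClassification:
    def test_reactive_ccw_by_definition(self):
        t = synthetic_trajectory(1.0, final_theta6=150.0)
        out = classify_trajectory(t)
        assert out == {"outcome": "reactive", "direction": "ccw"}

    def test_nonreactive_small_angle(self):
        t = synthetic_trajectory(1.0, final_theta6=5.0)
        assert classify_trajectory(t)["outcome"] == "nonreactive"

    def test_unresolved_still_on_s1(self):
        t = synthetic_trajectory(None)
        assert classify_trajectory(t)["outcome"] == "unresolved"

    def test_clockwise_direction_detected(self):
        t = synthetic_trajectory(1.0, final_theta6=-150.0,
                                 theta6_at_hop=-88.0)
        assert classify_trajectory(t)["direction"] == "cw"


class TestQuantumYield:
    def test_all_reactive(self):
        trajs = [synthetic_trajectory(1.0, final_theta6=150.0)
                 for _ in range(10)]
        phi, _ = quantum_yield(trajs)
        assert phi == 1.0

    def test_wilson_interval_hand_check(self):
        phi, ci = quantum_yield(
            [synthetic_trajectory(1.0, final_theta6=150.0)] * 3
            + [synthetic_trajectory(1.0, final_theta6=5.0)] * 17)
        assert phi == pytest.approx(0.15)
        z = 1.959963984540054
        n, ph = 20, 0.15
        centre = (ph + z * z / (2 * n)) / (1 + z * z / n)
        half = z * math.sqrt(ph * (1 - ph) / n + z * z / (4 * n * n)) \
            / (1 + z * z / n)
        assert ci[0] == pytest.approx(centre - half, abs=1e-12)
        assert ci[1] == pytest.approx(centre + half, abs=1e-12)

    def test_yield_invariant_under_reordering(self):
        rng = np.random.default_rng(4)
        trajs = [synthetic_trajectory(1.0, final_theta6=150.0 if b else 5.0)
                 for b in rng.random(30) < 0.3]
        phi1, _ = quantum_yield(trajs)
        rng.shuffle(trajs)
        phi2, _ = quantum_yield(trajs)
        assert phi1 == phi2

    def test_zero_resolved_errors(self):
        with pytest.raises(ModelError):
            quantum_yield([synthetic_trajectory(None)])


class TestHopGeometry:
    def test_single_hop_median(self):
        t = synthetic_trajectory(1.0, theta6_at_hop=88.0)
        stats = hop_geometry_stats([t])
        assert stats["medians"]["theta6_abs_deg"] == pytest.approx(88.0)

    def test_histogram_counts_equal_hops(self):
        trajs = [synthetic_trajectory(1.0, theta6_at_hop=85.0 + i)
                 for i in range(7)]
        stats = hop_geometry_stats(trajs)
        assert len(stats["hops"]) == 7


class TestStratification:
    def test_single_stratum_equals_whole_fit(self):
        rng = np.random.default_rng(2)
        trajs = [synthetic_trajectory(min(t, 9.9), r0=2.8)
                 for t in rng.exponential(2.0, 200)]
        out = stratify_by_hbond(trajs, r_cut=3.3, n_boot=10)
        assert out["free"] is None
        from phytohop.photoanalysis import fit_ensemble_lifetime
        whole = fit_ensemble_lifetime(trajs, n_boot=10)
        assert out["hbonded"].tau_ps == pytest.approx(whole.tau_ps, rel=1e-6)

    def test_planted_two_population_mixture_recovered(self):
        rng = np.random.default_rng(3)
        fast = [synthetic_trajectory(min(t, 9.9), r0=4.5)
                for t in rng.exponential(0.5, 400)]
        slow = [synthetic_trajectory(min(t, 9.9), r0=2.8)
                for t in rng.exponential(2.2, 400)]
        out = stratify_by_hbond(fast + slow, r_cut=3.3, n_boot=40)
        assert out["hbonded"].tau_ps == pytest.approx(2.2, rel=0.15)
        assert out["free"].tau_ps == pytest.approx(0.5, rel=0.15)
        assert out["hbonded"].ci_tau_ps[0] <= 2.2 <= out["hbonded"].ci_tau_ps[1]


class TestCalibration:
    def test_loss_scores_target_match_best(self):
        from phytohop.photoanalysis import calibration_loss

        perfect = {"tau_a_ps": 2.24, "tau_b_ps": 0.48, "phi_a": 0.15,
                   "hop_theta6_deg": 90.0, "n_cw": 0}
        off = dict(perfect, tau_a_ps=4.0)
        cw = dict(perfect, n_cw=2)
        assert calibration_loss(perfect) < 1e-12
        assert calibration_loss(off) > calibration_loss(perfect)
        assert calibration_loss(cw) >= 20.0

    def test_calibrate_returns_audit_trail(self, params_a):
        from phytohop.photoanalysis import calibrate_model

        res = calibrate_model(params_a, budget=1, n_traj=60, seed=3)
        assert set(res) >= {"params_a", "params_b", "achieved", "loss",
                            "loss_history", "converged"}
        hist = res["loss_history"]
        assert all(b <= a + 1e-12 for a, b in zip(hist, hist[1:]))
        # the barrier stays pinned during calibration
        from phytohop.model import torsional_barrier
        assert torsional_barrier(res["params_a"], "S1") == pytest.approx(
            1.6, abs=0.01)


class TestSummarize:
    def test_counts_add_up(self):
        trajs = ([synthetic_trajectory(1.0, final_theta6=150.0)] * 2
                 + [synthetic_trajectory(1.0, final_theta6=4.0)] * 5
                 + [synthetic_trajectory(None)] * 3)
        s = summarize_ensemble(trajs)
        assert s.n_total == 10
        assert (s.n_reactive + s.n_nonreactive + s.n_unresolved
                + s.n_failed) == 10
        assert s.quantum_yield == pytest.approx(2 / 7)
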