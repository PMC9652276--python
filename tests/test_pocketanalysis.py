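"""Pocket analyses: dip test against an LP oracle, contact tables, H-bond
probabilities, clustering recovery and the censored lifetime estimator."""

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace
from scipy.optimize import linprog

from phytohop._diptest import dip_statistic, dip_test
from phytohop.model import ModelError
from phytohop.pocketanalysis import (contact_count_probabilities,
                                     distance_distributions,
                                     estimate_relaxation_lifetime,
                                     first_passage_times,
                                     hbond_probability_table, pca_cluster)
from phytohop.pocketsynth import (GeneratorConfig, generate_early_ensemble,
                                  generate_relaxation_replicas)


def _branch_lp(xs, lower, upper, curvature):
    """Minimal band half-width for a monotone fit of one branch: curvature
    +1 demands convexity, -1 concavity (second differences in x)."""
    n = xs.size
    c = np.zeros(n + 1)
    c[-1] = 1.0
    A_ub, b_ub = [], []
    for i in range(n):  # band constraints
        row = np.zeros(n + 1)
        row[i], row[-1] = 1.0, -1.0
        A_ub.append(row); b_ub.append(upper[i])
        row = np.zeros(n + 1)
        row[i], row[-1] = -1.0, -1.0
        A_ub.append(row); b_ub.append(-lower[i])
    for i in range(n - 1):  # monotone
        row = np.zeros(n + 1)
        row[i], row[i + 1] = 1.0, -1.0
        A_ub.append(row); b_ub.append(0.0)
    for i in range(1, n - 1):
        dx1 = xs[i] - xs[i - 1]
        dx2 = xs[i + 1] - xs[i]
        if dx1 <= 0 or dx2 <= 0:
            continue
        row = np.zeros(n + 1)
        row[i - 1] = 1.0 / dx1
        row[i] = -(1.0 / dx1 + 1.0 / dx2)
        row[i + 1] = 1.0 / dx2
        A_ub.append(-curvature * row); b_ub.append(0.0)
    res = linprog(c, A_ub=np.array(A_ub), b_ub=np.array(b_ub),
                  bounds=[(None, None)] * n + [(0, None)], method="highs")
    return res.fun if res.success else np.inf


def dip_lp_oracle(x):
    """Paired-branch dip by linear programming: for every candidate mode
    point, the minimal band half-widths of a convex fit to the ECDF on the
    points left of the mode and a concave fit on the points right of it;
    minimized over modes of the larger of the two."""
    xs = np.sort(np.asarray(x, float))
    n = xs.size
    lower = np.arange(n) / n
    upper = (np.arange(n) + 1.0) / n
    best = np.inf
    for m in range(n):
        left = _branch_lp(xs[:m + 1], lower[:m + 1], upper[:m + 1], +1)
        right = _branch_lp(xs[m:], lower[m:], upper[m:], -1)
        best = min(best, max(left, right))
    return best


class TestDipStatistic:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_lp_oracle_on_small_samples(self, seed):
        rng = np.random.default_rng(seed)
        if seed % 2:
            x = np.concatenate([rng.normal(0, 1, 12), rng.normal(6, 1, 13)])
        else:
            x = rng.normal(0, 1, 25)
        assert dip_statistic(x) == pytest.approx(dip_lp_oracle(x), abs=1e-6)

    def test_unimodal_small_bimodal_large(self):
        rng = np.random.default_rng(5)
        uni = rng.normal(0, 1, 800)
        bi = np.concatenate([rng.normal(0, 1, 400), rng.normal(8, 1, 400)])
        assert dip_statistic(bi) > 5 * dip_statistic(uni)

    def test_planted_mixture_detected(self):
        rng = np.random.default_rng(6)
        x = np.concatenate([rng.normal(0, 1, 500), rng.normal(4, 1, 500)])
        d, p = dip_test(x, seed=1)
        assert p < 0.05
        _, p_uni = dip_test(rng.normal(0, 1, 1000), seed=1)
        assert p_uni > 0.05


class TestDistanceDistributions:
    def test_planted_bimodality_flags(self):
        rng = np.random.default_rng(7)
        n = 2000
        df = pd.DataFrame({
            "time_us": np.arange(n) * 1e-4,
            "OD_Arg466": np.concatenate([rng.normal(3.0, 0.5, n // 2),
                                         rng.normal(7.0, 0.5, n - n // 2)]),
            "ND_Tyr263": rng.normal(3.0, 0.3, n),
        })
        out = distance_distributions(df, ["OD_Arg466", "ND_Tyr263"], seed=2)
        assert out["OD_Arg466"]["bimodal"]
        assert not out["ND_Tyr263"]["bimodal"]

    def test_unknown_pair_listed(self):
        df = pd.DataFrame({"time_us": np.arange(200) * 1e-4,
                           "OD_Arg466": np.random.default_rng(0).normal(3, 1, 200)})
        with pytest.raises(ModelError, match="valid names"):
            distance_distributions(df, ["nope"])


class TestContacts:
    def test_all_contacts_closed(self):
        df = pd.DataFrame({"Asp207_Arg466_c1": np.full(100, 2.5),
                           "Asp207_Arg466_c2": np.full(100, 2.5)})
        table = contact_count_probabilities(df)
        np.testing.assert_allclose(table.probabilities, [0.0, 0.0, 1.0])

    def test_hand_counted_four_frames(self):
        df = pd.DataFrame({"Asp207_Arg466_c1": [2.9, 2.9, 3.1, 2.5],
                           "Asp207_Arg466_c2": [2.9, 3.1, 3.1, 2.5]})
        table = contact_count_probabilities(df)
        np.testing.assert_allclose(table.probabilities, [0.25, 0.25, 0.5])
        assert table.probabilities.sum() == pytest.approx(1.0, abs=1e-12)

    def test_early_stronger_salt_bridge_than_late(self):
        cfg = GeneratorConfig()
        early = generate_early_ensemble(cfg, 4000, seed=1)
        reps = generate_relaxation_replicas(
            replace(cfg, replica_length_us=4.0), seed=2, n_replicas=10)
        late = pd.concat([r[r.hidden_state == "late"] for r in reps])
        p_early = contact_count_probabilities(early).probabilities
        p_late = contact_count_probabilities(late).probabilities
        assert p_early[2] > p_late[2]

    def test_missing_columns(self):
        with pytest.raises(ModelError):
            contact_count_probabilities(pd.DataFrame({"x": [1.0]}))

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({"Asp207_Arg466_c1": rng.uniform(2, 4, 500),
                           "Asp207_Arg466_c2": rng.uniform(2, 4, 500)})
        p1 = contact_count_probabilities(df).probabilities
        p2 = contact_count_probabilities(
            df.sample(frac=1.0, random_state=1)).probabilities
        np.testing.assert_allclose(p1, p2)


class TestHbondTable:
    def test_always_true_indicator(self):
        df = pd.DataFrame({"water_bridge_OD": np.ones(50, dtype=int)})
        tab = hbond_probability_table(
            df, {"w": ("indicator", "water_bridge_OD", None)})
        assert tab.loc["w", "probability"] == 1.0

    def test_hand_counted_toy_table(self):
        df = pd.DataFrame({"ND_Tyr263": [3.0, 3.2, 3.6, 4.0, 2.9,
                                         3.4, 3.8, 3.1, 5.0, 3.45]})
        tab = hbond_probability_table(
            df, {"nd": ("distance", "ND_Tyr263", 3.5)})
        assert tab.loc["nd", "probability"] == pytest.approx(0.6)

    def test_pyrrole_water_takeover_in_late_state(self):
        cfg = GeneratorConfig()
        early = generate_early_ensemble(cfg, 3000, seed=4)
        reps = generate_relaxation_replicas(
            replace(cfg, replica_length_us=4.0), seed=5, n_replicas=10)
        late = pd.concat([r[r.hidden_state == "late"] for r in reps])
        te = hbond_probability_table(early)
        tl = hbond_probability_table(late)
        # Tyr263...N_D dominates early; the pyrrole water replaces it late
        assert te.loc["ND_Tyr263", "probability"] \
            > te.loc["pyrrole_water_D", "probability"]
        assert tl.loc["pyrrole_water_D", "probability"] \
            > tl.loc["ND_Tyr263", "probability"]


class TestClustering:
    def test_k1_trivial(self):
        cfg = GeneratorConfig()
        df = generate_early_ensemble(cfg, 300, seed=1)
        res = pca_cluster(df, K=1)
        assert set(res.labels) == {0}
        np.testing.assert_allclose(res.weights, [1.0])

    def test_planted_gaussians_recovered(self):
        rng = np.random.default_rng(11)
        centres = np.array([[0, 0, 0], [6, 0, 0], [0, 6, 0]], dtype=float)
        labels_true = rng.choice(3, size=1500, p=[0.5, 0.3, 0.2])
        X = centres[labels_true] + rng.normal(0, 1, (1500, 3))
        df = pd.DataFrame(X, columns=["OD_His290", "OD_water",
                                      "Tyr263_Asp207"]).abs() + 0.1
        # keep geometry: use raw values as features via explicit columns
        df = pd.DataFrame(X, columns=["f1", "f2", "f3"])
        res = pca_cluster(df, feature_columns=["f1", "f2", "f3"], K=3)
        from sklearn.metrics import adjusted_rand_score
        assert adjusted_rand_score(labels_true, res.labels) > 0.95

    def test_weights_invariant_under_feature_reordering(self):
        cfg = GeneratorConfig()
        df = generate_early_ensemble(cfg, 1200, seed=6)
        cols = [c for c in df.columns if c in
                ("OD_water", "Tyr263_Asp207", "ND_Tyr263", "OD_Arg466")]
        r1 = pca_cluster(df, feature_columns=cols, K=3)
        r2 = pca_cluster(df, feature_columns=cols[::-1], K=3)
        assert sorted(np.round(r1.weights, 6)) == sorted(np.round(r2.weights, 6))

    def test_k_exceeding_frames_errors(self):
        df = generate_early_ensemble(GeneratorConfig(), 5, seed=0)
        with pytest.raises(ModelError):
            pca_cluster(df, K=10)


class TestRelaxationLifetime:
    def _replicas_from_times(self, times, horizon=2.0, interval=1e-4):
        """Build minimal replica tables with known switch times."""
        reps = []
        grid = np.arange(0, horizon, interval)
        for t in times:
            late = grid >= t
            df = pd.DataFrame({
                "time_us": grid,
                "Tyr263_Asp207": np.where(late, 5.5, 2.7),
            })
            reps.append(df)
        return reps

    def test_deterministic_switch_recovered(self):
        reps = self._replicas_from_times([0.4] * 20)
        fit = estimate_relaxation_lifetime(reps)
        assert fit.tau_us == pytest.approx(0.4, abs=1e-3)
        assert fit.n_events == 20

    def test_censored_mle_against_known_parameter(self):
        rng = np.random.default_rng(9)
        times = rng.exponential(1.0, 200)
        reps = self._replicas_from_times(times, horizon=2.0, interval=2e-3)
        fit = estimate_relaxation_lifetime(reps)
        assert fit.n_censored == int(np.sum(times >= 2.0))
        assert fit.tau_us == pytest.approx(1.0, rel=0.15)
        assert fit.ci_us[0] < 1.0 < fit.ci_us[1]

    def test_estimator_bias_small_at_large_n(self):
        rng = np.random.default_rng(10)
        times = rng.exponential(0.4, 500)
        reps = self._replicas_from_times(times, horizon=2.0, interval=1e-3)
        fit = estimate_relaxation_lifetime(reps)
        assert abs(fit.tau_us - 0.4) / 0.4 < 0.05

    def test_no_events_errors(self):
        reps = self._replicas_from_times([10.0] * 6, horizon=1.0)
        with pytest.raises(ModelError, match="censoring-only"):
            estimate_relaxation_lifetime(reps)

    def test_too_few_replicas(self):
        with pytest.raises(ModelError):
            estimate_relaxation_lifetime(self._replicas_from_times([0.4] * 3))
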