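"""Ensemble statistics of the photochemical step.

Populations, exponential lifetime fits, quantum yield, mechanism
classification, hop-geometry statistics, H-bond stratification and the
barrier--lifetime law, computed from lists of surface-hopping trajectories.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import norm

from .model import ModelParameters, ModelError, scale_d6_barrier, torsional_barrier, wrap_angle
from .sampling import sample_initial_conditions
from .shdynamics import SHSettings, SHTrajectory, counter_seeds, run_ensemble


@dataclass
class PopulationCurve:
    """Fraction of trajectories on each state vs time, with bootstrap CI."""

    times_fs: np.ndarray
    p_s1: np.ndarray
    ci_lo: np.ndarray
    ci_hi: np.ndarray
    n_trajectories: int

    @property
    def p_s0(self):
        return 1.0 - self.p_s1


@dataclass
class DecayFit:
    """Delayed-exponential fit of the S1 population:
    P(t) = 1 for t < t0, exp(-(t - t0)/tau) for t >= t0."""

    tau_ps: float
    t0_ps: float
    residual_norm: float
    ci_tau_ps: tuple = (float("nan"), float("nan"))


@dataclass
class EnsembleSummary:
    n_total: int
    n_reactive: int
    n_nonreactive: int
    n_unresolved: int
    n_failed: int
    quantum_yield: float
    qy_ci: tuple
    n_ccw: int
    n_cw: int
    mean_hop_gap_ev: float

    def to_dict(self):
        return {
            "n_total": self.n_total, "n_reactive": self.n_reactive,
            "n_nonreactive": self.n_nonreactive,
            "n_unresolved": self.n_unresolved, "n_failed": self.n_failed,
            "quantum_yield": self.quantum_yield,
            "qy_ci_low": self.qy_ci[0], "qy_ci_high": self.qy_ci[1],
            "n_ccw": self.n_ccw, "n_cw": self.n_cw,
            "mean_hop_gap_ev": self.mean_hop_gap_ev,
        }


def _valid(trajectories: Sequence[SHTrajectory]):
    return [t for t in trajectories if t.valid]


def state_populations(trajectories: Sequence[SHTrajectory],
                      n_boot: int = 1000, seed: int = 0) -> PopulationCurve:
    """Fraction on S1 at each stored time, with a 95% bootstrap band over
    trajectories (the S0 fraction is its exact complement)."""
    trajs = _valid(trajectories)
    if not trajs:
        raise ModelError("no valid trajectories")
    states = np.stack([t.active_state for t in trajs])  # (n, nt)
    times = trajs[0].times_fs
    p_s1 = states.mean(axis=0)
    rng = np.random.default_rng(seed)
    n = len(trajs)
    idx = rng.integers(0, n, size=(n_boot, n))
    boot = states[idx].mean(axis=1)  # (n_boot, nt)
    lo, hi = np.percentile(boot, [2.5, 97.5], axis=0)
    lo = np.minimum(lo, p_s1)
    hi = np.maximum(hi, p_s1)
    return PopulationCurve(times_fs=times, p_s1=p_s1, ci_lo=lo, ci_hi=hi,
                           n_trajectories=n)


def _fit_delayed_exponential(t_ps: np.ndarray, pop: np.ndarray) -> tuple:
    """Least-squares (tau, t0, residual_norm) for the delayed exponential."""

    def model(theta):
        tau, t0 = theta
        return np.where(t_ps < t0, 1.0, np.exp(-(t_ps - t0) / tau))

    # initial guesses: time to reach 1/e, onset of decay
    below = np.nonzero(pop <= math.exp(-1))[0]
    tau0 = t_ps[below[0]] if len(below) else max(t_ps[-1], 0.1)
    started = np.nonzero(pop <= 0.95)[0]
    t00 = t_ps[started[0]] if len(started) else 0.0
    res = least_squares(lambda th: model(th) - pop,
                        x0=[max(tau0, 1e-3), max(t00, 0.0)],
                        bounds=([1e-6, 0.0], [np.inf, max(t_ps[-1], 1e-3)]),
                        xtol=1e-14, ftol=1e-14, gtol=1e-14)
    tau, t0 = res.x
    return float(tau), float(t0), float(np.linalg.norm(res.fun))


def fit_exponential_decay(curve: PopulationCurve) -> DecayFit:
    """Fit the S1 population with a latency + single-exponential decay."""
    t_ps = curve.times_fs / 1000.0
    if curve.p_s1[-1] > curve.p_s1[0]:
        raise ModelError("S1 population is not decreasing overall")
    tau, t0, rn = _fit_delayed_exponential(t_ps, curve.p_s1)
    return DecayFit(tau_ps=tau, t0_ps=t0, residual_norm=rn)


def fit_ensemble_lifetime(trajectories: Sequence[SHTrajectory],
                          n_boot: int = 200, seed: int = 0) -> DecayFit:
    """Population curve + delayed-exponential fit + bootstrap 95% CI on tau."""
    trajs = _valid(trajectories)
    curve = state_populations(trajs, n_boot=10, seed=seed)
    fit = fit_exponential_decay(curve)
    states = np.stack([t.active_state for t in trajs])
    t_ps = curve.times_fs / 1000.0
    rng = np.random.default_rng(seed + 1)
    taus = []
    n = len(trajs)
    for _ in range(n_boot):
        pop = states[rng.integers(0, n, size=n)].mean(axis=0)
        try:
            taus.append(_fit_delayed_exponential(t_ps, pop)[0])
        except Exception:
            continue
    if taus:
        lo, hi = np.percentile(taus, [2.5, 97.5])
        fit = replace(fit, ci_tau_ps=(float(lo), float(hi)))
    return fit


def classify_trajectory(traj: SHTrajectory, reactive_threshold_deg: float = 120.0,
                        stability_ps: float = 0.5) -> dict:
    """Classify one trajectory: reactive/nonreactive (+ ccw/cw direction).

    Reactive: the final |theta6| lies beyond the threshold on the product
    side and stays there for the last ``stability_ps``.  Direction: sign of
    the theta6 displacement from the Franck-Condon value at the first
    accepted S1->S0 hop.  Trajectories still on S1 are 'unresolved'.
    """
    if not traj.valid:
        return {"outcome": "failed", "direction": None}
    if traj.final_state != 0:
        return {"outcome": "unresolved", "direction": None}
    t6 = np.abs(wrap_angle(traj.theta6_deg))
    dt_rec = traj.times_fs[1] - traj.times_fs[0]
    n_window = max(1, int(round(stability_ps * 1000.0 / dt_rec)))
    tail = t6[-n_window:]
    reactive = bool(np.all(tail >= reactive_threshold_deg))
    direction = None
    hops = [h for h in traj.accepted_hops if h.from_state == 1]
    if hops:
        disp = hops[0].coordinates.theta6 - traj.initial_coordinates.theta6
        direction = "ccw" if wrap_angle(disp) > 0 else "cw"
    return {"outcome": "reactive" if reactive else "nonreactive",
            "direction": direction}


def wilson_interval(k: int, n: int, conf: float = 0.95) -> tuple:
    """Wilson score interval for a binomial proportion."""
    if n == 0:
        raise ModelError("no resolved trajectories")
    z = norm.ppf(0.5 + conf / 2.0)
    phat = k / n
    denom = 1.0 + z * z / n
    centre = (phat + z * z / (2 * n)) / denom
    half = z * math.sqrt(phat * (1 - phat) / n + z * z / (4 * n * n)) / denom
    return (max(0.0, centre - half), min(1.0, centre + half))


def quantum_yield(trajectories: Sequence[SHTrajectory], **classify_kw) -> tuple:
    """Reactive fraction among resolved trajectories with Wilson 95% CI."""
    outcomes = [classify_trajectory(t, **classify_kw)["outcome"]
                for t in trajectories]
    n_reac = outcomes.count("reactive")
    n_non = outcomes.count("nonreactive")
    n = n_reac + n_non
    if n == 0:
        raise ModelError("no resolved trajectories")
    return n_reac / n, wilson_interval(n_reac, n)


def summarize_ensemble(trajectories: Sequence[SHTrajectory],
                       **classify_kw) -> EnsembleSummary:
    outcomes = [classify_trajectory(t, **classify_kw) for t in trajectories]
    kinds = [o["outcome"] for o in outcomes]
    n_reac, n_non = kinds.count("reactive"), kinds.count("nonreactive")
    n_unres, n_fail = kinds.count("unresolved"), kinds.count("failed")
    dirs = [o["direction"] for o in outcomes if o["outcome"] == "reactive"]
    gaps = [h.gap_ev for t in _valid(trajectories)
            for h in t.accepted_hops if h.from_state == 1]
    phi, ci = quantum_yield(trajectories, **classify_kw)
    return EnsembleSummary(
        n_total=len(trajectories), n_reactive=n_reac, n_nonreactive=n_non,
        n_unresolved=n_unres, n_failed=n_fail,
        quantum_yield=phi, qy_ci=ci,
        n_ccw=dirs.count("ccw"), n_cw=dirs.count("cw"),
        mean_hop_gap_ev=float(np.mean(gaps)) if gaps else float("nan"),
    )


def hop_geometry_stats(trajectories: Sequence[SHTrajectory],
                       **classify_kw) -> dict:
    """Per-hop records of the accepted S1->S0 transitions with medians and a
    reactive/nonreactive split."""
    rows = []
    for t in _valid(trajectories):
        outcome = classify_trajectory(t, **classify_kw)["outcome"]
        for h in t.accepted_hops:
            if h.from_state == 1:
                rows.append((h.time_fs, h.coordinates.theta6,
                             h.coordinates.theta5, h.coordinates.r_hb,
                             h.gap_ev, outcome))
    if not rows:
        raise ModelError("no accepted S1->S0 hops in the ensemble")
    df = pd.DataFrame(rows, columns=["time_fs", "theta6_deg", "theta5_deg",
                                     "r_hb_A", "gap_ev", "outcome"])
    med = {
        "theta6_abs_deg": float(np.median(np.abs(df.theta6_deg))),
        "theta5_deg": float(np.median(df.theta5_deg)),
        "gap_ev": float(np.median(df.gap_ev)),
    }
    by_outcome = {
        k: float(np.median(np.abs(g.theta6_deg)))
        for k, g in df.groupby("outcome")
    }
    return {"hops": df, "medians": med, "median_theta6_by_outcome": by_outcome}


def stratify_by_hbond(trajectories: Sequence[SHTrajectory], r_cut: float = 3.3,
                      n_boot: int = 100, seed: int = 0) -> dict:
    """Split trajectories by initial H-bond distance (< r_cut: bonded) and
    fit the S1 lifetime per stratum.  Absent strata are reported as None."""
    bonded, free = [], []
    for t in _valid(trajectories):
        (bonded if t.initial_coordinates.r_hb < r_cut else free).append(t)
    out = {}
    for name, group in (("hbonded", bonded), ("free", free)):
        out[name] = (fit_ensemble_lifetime(group, n_boot=n_boot, seed=seed)
                     if group else None)
    return out


# ---------------------------------------------------------------------------
# barrier--lifetime law
# ---------------------------------------------------------------------------

@dataclass
class BarrierScanResult:
    table: pd.DataFrame          # barrier, tau_ps, ci_lo, ci_hi, n
    slope: float                 # d ln(tau/ps) / d barrier
    intercept: float
    r_squared: float
    cov: np.ndarray

    def extrapolate(self, barrier: float) -> dict:
        """Predicted tau (ps) at ``barrier`` with a 95% prediction interval
        from the fit covariance."""
        x = np.array([1.0, barrier])
        mu = self.intercept + self.slope * barrier
        var = float(x @ self.cov @ x)
        z = 1.959963984540054
        return {"tau_ps": math.exp(mu),
                "tau_lo_ps": math.exp(mu - z * math.sqrt(var)),
                "tau_hi_ps": math.exp(mu + z * math.sqrt(var))}


def simulate_lifetime(params: ModelParameters, n_traj: int, seed: int,
                      settings: Optional[SHSettings] = None,
                      n_boot: int = 100) -> tuple:
    """Sample ICs, run an ensemble, fit the S1 lifetime.  Returns
    (DecayFit, trajectories)."""
    settings = settings or SHSettings()
    ics = sample_initial_conditions(params, n_traj, seed)
    trajs = run_ensemble(params, ics, settings, counter_seeds(seed + 7, n_traj))
    return fit_ensemble_lifetime(trajs, n_boot=n_boot, seed=seed), trajs


def lifetime_barrier_scan(params: ModelParameters, barriers: Iterable[float],
                          n_per_point: int = 150, seed: int = 0,
                          t_max_ps: Optional[dict] = None) -> BarrierScanResult:
    """Scale the S1 barrier to each requested height, run an ensemble and fit
    tau; then weighted linear regression of ln(tau) on the barrier.

    The per-point horizon grows with the expected lifetime; a dict
    ``t_max_ps`` may override it per barrier.
    """
    barriers = sorted(barriers)
    if len(barriers) < 3:
        raise ModelError("need at least 3 barrier points")
    rows = []
    for i, b in enumerate(barriers):
        pb = scale_d6_barrier(params, b)
        horizon = (t_max_ps or {}).get(b) if t_max_ps else None
        if horizon is None:
            horizon = float(np.clip(15.0 * math.exp(0.9 * (b - barriers[0])),
                                    10.0, 120.0))
        st = SHSettings(t_max_ps=horizon)
        fit, _ = simulate_lifetime(pb, n_per_point, seed + 1000 * i,
                                   settings=st, n_boot=60)
        rows.append((b, fit.tau_ps, fit.ci_tau_ps[0], fit.ci_tau_ps[1],
                     n_per_point))
    tab = pd.DataFrame(rows, columns=["barrier_kcal", "tau_ps", "ci_lo_ps",
                                      "ci_hi_ps", "n"])
    if tab.tau_ps.isna().any() or len(tab) < 3:
        raise ModelError("fewer than 3 converged scan points")
    x = tab.barrier_kcal.to_numpy()
    y = np.log(tab.tau_ps.to_numpy())
    sig = (np.log(tab.ci_hi_ps) - np.log(tab.ci_lo_ps)).to_numpy() / (2 * 1.96)
    sig = np.where(np.isfinite(sig) & (sig > 1e-6), sig, 0.1)
    w = 1.0 / sig ** 2
    X = np.column_stack([np.ones_like(x), x])
    W = np.diag(w)
    cov = np.linalg.inv(X.T @ W @ X)
    beta = cov @ X.T @ W @ y
    yhat = X @ beta
    ybar = np.average(y, weights=w)
    ss_res = np.sum(w * (y - yhat) ** 2)
    ss_tot = np.sum(w * (y - ybar) ** 2)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return BarrierScanResult(table=tab, slope=float(beta[1]),
                             intercept=float(beta[0]), r_squared=float(r2),
                             cov=cov)


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

DEFAULT_TARGETS = {
    "barrier_kcal": 1.6,   # relaxed S1 barrier, set A
    "tau_a_ps": 2.24,      # S1 lifetime, set A
    "tau_b_ps": 0.48,      # S1 lifetime, set B
    "phi_a": 0.15,         # quantum yield, set A
    "hop_theta6_deg": 90.0,  # pooled hop-geometry median |theta6|
}


def _solve_lambda_for_barrier(params: ModelParameters, barrier: float,
                              lo: float = 0.2, hi: float = 6.0) -> ModelParameters:
    """Adjust lambda_hb (at s6 = 1) so the relaxed S1 barrier equals
    ``barrier``; the barrier increases monotonically with lambda_hb."""
    from scipy.optimize import brentq

    def f(lam):
        return torsional_barrier(replace(params, lambda_hb=lam), "S1") - barrier

    lam = brentq(f, lo, hi, xtol=1e-9)
    return replace(params, lambda_hb=float(lam))


def evaluate_targets(params_a: ModelParameters, params_b: ModelParameters,
                     n_traj: int = 200, seed: int = 0,
                     t_max_a: float = 15.0, t_max_b: float = 6.0) -> dict:
    """Run both ensembles and measure every calibration observable."""
    fit_a, trajs_a = simulate_lifetime(params_a, n_traj, seed,
                                       SHSettings(t_max_ps=t_max_a), n_boot=30)
    fit_b, trajs_b = simulate_lifetime(params_b, n_traj, seed + 31,
                                       SHSettings(t_max_ps=t_max_b), n_boot=30)
    phi, phi_ci = quantum_yield(trajs_a)
    hops = hop_geometry_stats(trajs_a)
    summ = summarize_ensemble(trajs_a)
    return {
        "barrier_kcal": torsional_barrier(params_a, "S1"),
        "tau_a_ps": fit_a.tau_ps, "tau_b_ps": fit_b.tau_ps,
        "phi_a": phi, "phi_ci": phi_ci,
        "hop_theta6_deg": hops["medians"]["theta6_abs_deg"],
        "n_cw": summ.n_cw,
        "single_hop_fraction": float(np.mean(
            [sum(1 for h in t.accepted_hops if h.from_state == 1) == 1
             for t in trajs_a if t.valid])),
    }


def calibration_loss(achieved: dict, targets: dict = None) -> float:
    """Documented weighted loss: squared relative errors of the lifetimes and
    quantum yield plus a quadratic penalty on the hop-geometry median (scale
    10 deg) and a hard penalty for any clockwise trajectory."""
    t = dict(DEFAULT_TARGETS, **(targets or {}))
    loss = ((achieved["tau_a_ps"] / t["tau_a_ps"] - 1.0) ** 2
            + (achieved["tau_b_ps"] / t["tau_b_ps"] - 1.0) ** 2
            + (achieved["phi_a"] / t["phi_a"] - 1.0) ** 2
            + ((achieved["hop_theta6_deg"] - t["hop_theta6_deg"]) / 10.0) ** 2)
    loss += 10.0 * achieved.get("n_cw", 0)
    return float(loss)


def calibrate_model(initial_params: ModelParameters,
                    targets: dict = None, budget: int = 40,
                    n_traj: int = 150, seed: int = 0,
                    d_hb_b: float = 1.0,
                    loss_threshold: float = 0.05, verbose: bool = False) -> dict:
    """Derivative-free calibration of (w0, sigma_w, gamma, T_excited, D_hb_B,
    I_theta) against the lifetime/yield/hop-geometry targets.

    At every iterate lambda_hb is re-solved so the relaxed S1 barrier stays
    pinned at its target; set B shares all parameters except a weak H-bond
    well D_hb.  Coordinate search with shrinking multiplicative steps; the
    accepted-iterate loss sequence is returned for audit.
    """
    t = dict(DEFAULT_TARGETS, **(targets or {}))

    def build(vec):
        w0, gamma, t_ex, i6, d_b = vec
        pa = replace(initial_params, w0=w0, gamma=gamma, T_excited=t_ex,
                     I_theta6=i6, I_theta5=i6, s6=1.0)
        pa = _solve_lambda_for_barrier(pa, t["barrier_kcal"])
        pb = replace(pa, D_hb=d_b)
        return pa, pb

    def loss_of(vec, eval_seed):
        pa, pb = build(vec)
        ach = evaluate_targets(pa, pb, n_traj=n_traj, seed=eval_seed)
        return calibration_loss(ach, t), ach

    x = np.array([initial_params.w0, initial_params.gamma,
                  initial_params.T_excited, initial_params.I_theta6, d_hb_b])
    best_loss, best_ach = loss_of(x, seed)
    history = [best_loss]
    steps = np.array([1.3, 1.5, 1.15, 1.4, 1.4])
    n_eval = 1
    while n_eval < budget and best_loss > loss_threshold:
        improved = False
        for k in range(len(x)):
            for direction in (1.0, -1.0):
                if n_eval >= budget:
                    break
                trial = x.copy()
                trial[k] = trial[k] * steps[k] ** direction
                L, ach = loss_of(trial, seed)
                n_eval += 1
                if verbose:
                    print(f"eval {n_eval}: {trial} -> {L:.4f}")
                if L < best_loss:
                    x, best_loss, best_ach = trial, L, ach
                    history.append(best_loss)
                    improved = True
                    break
        if not improved:
            steps = 1.0 + (steps - 1.0) * 0.5
            if np.all(steps < 1.02):
                break
    pa, pb = build(x)
    result = {"params_a": pa, "params_b": pb, "achieved": best_ach,
              "loss": best_loss, "loss_history": history,
              "converged": best_loss <= loss_threshold}
    if not result["converged"]:
        result["message"] = ("calibration loss above threshold after budget; "
                             "best-found parameters returned")
    return result
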