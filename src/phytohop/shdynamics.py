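"""Fewest-switches surface hopping with local diabatization and energy-based
decoherence.

The engine propagates all trajectories of an ensemble in lockstep with
vectorized numpy operations; a single trajectory is the n = 1 special case,
so `run_trajectory(params, ic, seed)` is bitwise identical to the same member
of `run_ensemble`.  Each trajectory owns an independent random stream seeded
from its own seed, so ensembles are order-independent and reproducible.

Scheme per time step (dt = 0.1 fs by default):

1. one BAOAB Langevin step on the active adiabatic surface (gamma = 0
   reduces exactly to velocity Verlet);
2. electronic coefficients advanced by local diabatization: the 2x2 rotation
   between the adiabatic bases at t and t+dt is built from the mixing angles,
   the propagator is the exact exponential of the trapezoidal local-diabatic
   Hamiltonian, and the result is transformed back -- unitary to machine
   precision;
3. fewest-switches hop decision from the population flux out of the active
   state, optionally gated by a maximum allowed S0/S1 gap (the 0.5 eV
   variant);
4. accepted hops rescale the momentum along the gradient-difference
   direction to conserve total energy; energetically frustrated hops leave
   everything unchanged and are recorded;
5. energy-based decoherence damps the non-active amplitude with time
   constant (hbar/|dE|)(1 + C/E_kin).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .constants import HBAR, KB, KCAL_PER_EV, KCAL_PER_HARTREE, KCAL_TO_AKMA, AKMA_TO_KCAL
from .model import DEG, Coordinates, ModelError, ModelParameters, _adiabats, wrap_angle
from .sampling import InitialConditions, _masses

_RNG_CHUNK = 2048  # steps of per-trajectory random numbers drawn at once


@dataclass(frozen=True)
class SHSettings:
    """Numerical settings of the surface-hopping propagation."""

    dt: float = 0.1                    # fs
    t_max_ps: float = 15.0
    decoherence_C: float = 0.1         # hartree-equivalent energy constant
    max_hop_gap_ev: Optional[float] = None  # forbid hops above this gap
    gamma: Optional[float] = None      # 1/ps; overrides params.gamma if set
    rescale_mode: str = "hbond"        # hop-energy redistribution: "hbond"
                                       # (H-bond rupture coordinate),
                                       # "isotropic", or "graddiff"
    record_stride: int = 100           # steps between stored frames
    stop_window_ps: float = 0.5        # time settled in a well before stopping
    reactant_well_deg: float = 45.0
    product_well_deg: float = 120.0

    def __post_init__(self):
        if self.dt <= 0 or self.t_max_ps <= 0:
            raise ModelError("dt and t_max must be positive")


@dataclass
class HopEvent:
    time_fs: float
    from_state: int
    to_state: int
    gap_ev: float
    coordinates: Coordinates
    accepted: bool
    frustrated: bool


@dataclass
class SHTrajectory:
    """Stored (strided) record of one surface-hopping trajectory."""

    times_fs: np.ndarray
    theta6_deg: np.ndarray
    theta5_deg: np.ndarray
    r_hb_A: np.ndarray
    active_state: np.ndarray
    pop_s1: np.ndarray
    gap_ev: np.ndarray
    energy_kcal: np.ndarray
    hop_events: list
    final_state: int
    final_coordinates: Coordinates
    initial_coordinates: Coordinates
    seed: int
    valid: bool = True
    stopped_early: bool = False

    @property
    def accepted_hops(self):
        return [h for h in self.hop_events if h.accepted]


# ---------------------------------------------------------------------------
# component operations (pure functions, vectorized over trajectories)
# ---------------------------------------------------------------------------

def fssh_hop_decision(pop_before: np.ndarray, pop_after: np.ndarray,
                      active: np.ndarray, gap_ev: np.ndarray,
                      xi: np.ndarray, max_hop_gap_ev: Optional[float] = None):
    """Fewest-switches decision: hop proposed where the uniform draw ``xi``
    falls below the population flux out of the active state; hops with
    gap > max_hop_gap_ev are forbidden.  Returns a boolean array."""
    pa_before = np.where(active == 1, pop_before, 1.0 - pop_before)
    pa_after = np.where(active == 1, pop_after, 1.0 - pop_after)
    prob = np.clip((pa_before - pa_after) / np.maximum(pa_before, 1e-30), 0.0, 1.0)
    proposed = xi < prob
    if max_hop_gap_ev is not None:
        proposed = proposed & (gap_ev <= max_hop_gap_ev)
    return proposed


def apply_hop(p: np.ndarray, masses: np.ndarray, d_vec: np.ndarray,
              delta_e: np.ndarray):
    """Momentum rescaling along the gradient-difference direction.

    Solves 0.5*sum((p+lam*d)^2/m) = 0.5*sum(p^2/m) - delta_e for lam (taking
    the smaller-|lam| root).  Returns (p_new, accepted mask); where the hop
    is frustrated the momentum is returned unchanged.

    ``delta_e`` is E_target - E_current in kcal/mol; momenta in internal
    (amu A^2 rad/fs) units, d_vec per-radian gradients.
    """
    de = delta_e * KCAL_TO_AKMA
    a = 0.5 * np.sum(d_vec * d_vec / masses[:, None], axis=0)
    b = np.sum(p * d_vec / masses[:, None], axis=0)
    disc = b * b - 4.0 * a * de
    ok = (disc >= 0.0) & (a > 0.0)
    sq = np.sqrt(np.maximum(disc, 0.0))
    lam1 = (-b + sq) / (2.0 * np.maximum(a, 1e-300))
    lam2 = (-b - sq) / (2.0 * np.maximum(a, 1e-300))
    lam = np.where(np.abs(lam1) <= np.abs(lam2), lam1, lam2)
    p_new = np.where(ok, p + lam * d_vec, p)
    return p_new, ok


def apply_decoherence(c: np.ndarray, active: np.ndarray, gap: np.ndarray,
                      e_kin: np.ndarray, dt: float, C_kcal: float) -> np.ndarray:
    """Energy-based decoherence: damp the non-active amplitude with time
    constant (hbar/|dE|)(1 + C/E_kin), then restore the norm via the active
    amplitude.  ``gap`` in kcal/mol; ``e_kin`` floored at 1e-8 kcal/mol."""
    ek = np.maximum(e_kin, 1e-8)
    tau = (HBAR / np.maximum(np.abs(gap), 1e-30)) * (1.0 + C_kcal / ek)
    damp = np.exp(-dt / tau)
    other = 1 - active
    n = c.shape[0]
    idx = np.arange(n)
    c = c.copy()
    c[idx, other] *= damp
    p_other = np.abs(c[idx, other]) ** 2
    p_act = np.abs(c[idx, active]) ** 2
    target = np.maximum(1.0 - p_other, 0.0)
    scale = np.sqrt(target / np.maximum(p_act, 1e-300))
    c[idx, active] *= scale
    return c


def _ld_propagate(c: np.ndarray, e0_old, e1_old, e0_new, e1_new,
                  dalpha: np.ndarray, dt: float) -> np.ndarray:
    """Local-diabatization step for the 2-state coefficients (vectorized).

    The adiabatic basis at t is frozen as the locally diabatic basis; the
    Hamiltonian there is diag(E(t)) at t and Z diag(E(t+dt)) Z^T at t+dt with
    Z the basis rotation by ``dalpha``; the trapezoidal average is
    exponentiated exactly (2x2 Hermitian) and the result rotated into the new
    adiabatic basis.
    """
    ca, cb = np.cos(dalpha), np.sin(dalpha)
    # H_new in the frozen basis: Z diag(e_new) Z^T, Z = [[ca, -cb], [cb, ca]]
    h00 = 0.5 * (e0_old + ca * ca * e0_new + cb * cb * e1_new)
    h11 = 0.5 * (e1_old + cb * cb * e0_new + ca * ca * e1_new)
    h01 = 0.5 * (ca * cb * (e0_new - e1_new))
    # exact exponential exp(-i H dt / hbar) for 2x2 real-symmetric H
    tau = dt / HBAR
    a = 0.5 * (h00 + h11)
    d = 0.5 * (h00 - h11)
    rho = np.sqrt(d * d + h01 * h01)
    cosr = np.cos(rho * tau)
    sinc = np.where(rho > 1e-300, np.sin(rho * tau) / np.maximum(rho, 1e-300), tau)
    phase = np.exp(-1j * a * tau)
    u00 = phase * (cosr - 1j * sinc * d)
    u11 = phase * (cosr + 1j * sinc * d)
    u01 = phase * (-1j * sinc * h01)
    b0 = u00 * c[:, 0] + u01 * c[:, 1]
    b1 = u01 * c[:, 0] + u11 * c[:, 1]
    # rotate into the adiabatic basis at t+dt: c_new = Z^T b
    c_new = np.empty_like(c)
    c_new[:, 0] = ca * b0 + cb * b1
    c_new[:, 1] = -cb * b0 + ca * b1
    return c_new


# ---------------------------------------------------------------------------
# ensemble engine
# ---------------------------------------------------------------------------

def run_ensemble(params: ModelParameters, ics: InitialConditions,
                 settings: SHSettings, seeds: Sequence[int]) -> list:
    """Propagate one independent surface-hopping trajectory per initial
    condition (in lockstep) and return a list of SHTrajectory."""
    n = len(ics)
    if n == 0:
        return []
    if len(seeds) != n:
        raise ModelError("need exactly one seed per initial condition")

    dt = settings.dt
    n_steps = int(round(settings.t_max_ps * 1000.0 / dt))
    gamma_fs = (params.gamma if settings.gamma is None else settings.gamma) / 1000.0
    masses = _masses(params)
    m = masses[:, None]
    C_kcal = settings.decoherence_C * KCAL_PER_HARTREE
    stop_steps = max(1, int(round(settings.stop_window_ps * 1000.0 / dt)))

    q = np.stack([ics.theta6_deg * DEG, ics.theta5_deg * DEG,
                  np.asarray(ics.r_hb_A, dtype=float)])
    p = np.stack([np.asarray(ics.p_theta6, dtype=float),
                  np.asarray(ics.p_theta5, dtype=float),
                  np.asarray(ics.p_r, dtype=float)])
    active = np.full(n, ics.active_state, dtype=np.int64)
    c = np.zeros((n, 2), dtype=complex)
    c[:, ics.active_state] = 1.0

    from ._engine import pack_params, run_chunk

    e0, e1, _, _, alpha = _adiabats(params, q[0], q[1], q[2])
    e0 = np.atleast_1d(np.asarray(e0, dtype=float)).copy()
    e1 = np.atleast_1d(np.asarray(e1, dtype=float)).copy()
    alpha = np.atleast_1d(np.asarray(alpha, dtype=float)).copy()
    alive = np.ones(n, dtype=np.bool_)
    well_count = np.zeros(n, dtype=np.int64)
    invalid = np.zeros(n, dtype=np.bool_)

    n_rec = n_steps // settings.record_stride + 1
    rec = np.zeros((6, n, n_rec), dtype=np.float32)
    rec_active = np.zeros((n, n_rec), dtype=np.int8)
    times = np.arange(n_rec) * settings.record_stride * dt

    max_hops = 256
    hop_data = np.zeros((n, max_hops, 8), dtype=np.float64)
    hop_count = np.zeros(n, dtype=np.int64)

    pv = pack_params(params)
    if settings.gamma is not None:
        pv[17] = settings.gamma
    cre = np.ascontiguousarray(c.real)
    cim = np.ascontiguousarray(c.imag)

    # initial record (k = 0)
    kin0 = 0.5 * np.sum(p * p / m, axis=0) * AKMA_TO_KCAL
    rec[0, :, 0] = q[0] / DEG
    rec[1, :, 0] = q[1] / DEG
    rec[2, :, 0] = q[2]
    rec[3, :, 0] = np.abs(c[:, 1]) ** 2
    rec[4, :, 0] = (e1 - e0) / KCAL_PER_EV
    rec[5, :, 0] = np.where(active == 1, e1, e0) + kin0
    rec_active[:, 0] = active

    rngs = [np.random.default_rng(int(s)) for s in seeds]
    buf_normal = np.empty((_RNG_CHUNK, 3, n))
    buf_uni = np.empty((_RNG_CHUNK, n))
    use_gate = settings.max_hop_gap_ev is not None
    max_gap = settings.max_hop_gap_ev if use_gate else 0.0

    step0 = 0
    while step0 < n_steps and np.any(alive):
        for i, rng in enumerate(rngs):
            buf_normal[:, :, i] = rng.standard_normal((_RNG_CHUNK, 3))
            buf_uni[:, i] = rng.random(_RNG_CHUNK)
        step0 = run_chunk(
            pv, masses, dt, gamma_fs, C_kcal, max_gap, use_gate,
            {"graddiff": 0, "isotropic": 1, "hbond": 2}[settings.rescale_mode],
            settings.record_stride, stop_steps,
            settings.reactant_well_deg * DEG, settings.product_well_deg * DEG,
            step0, _RNG_CHUNK, n_steps,
            q, p, cre, cim, active, alive, well_count,
            e0, e1, alpha,
            buf_normal, buf_uni,
            rec, rec_active, hop_data, hop_count, invalid)

    # fill remaining grid records with the frozen state
    last_k = step0 // settings.record_stride
    for k in range(last_k + 1, n_rec):
        rec[:, :, k] = rec[:, :, last_k]
        rec_active[:, k] = rec_active[:, last_k]

    c = cre + 1j * cim
    hop_log = []
    for i in range(n):
        events = []
        for hrow in hop_data[i, :hop_count[i]]:
            accepted = hrow[7] > 0.5
            events.append(HopEvent(
                time_fs=float(hrow[0]),
                from_state=int(hrow[1]), to_state=int(hrow[2]),
                gap_ev=float(hrow[3]),
                coordinates=Coordinates(wrap_angle(hrow[4] / DEG),
                                        wrap_angle(hrow[5] / DEG),
                                        float(hrow[6])),
                accepted=bool(accepted), frustrated=bool(not accepted)))
        hop_log.append(events)

    out = []
    for i in range(n):
        fin = Coordinates(wrap_angle(q[0, i] / DEG), wrap_angle(q[1, i] / DEG),
                          float(q[2, i]))
        ini = Coordinates(float(ics.theta6_deg[i]), float(ics.theta5_deg[i]),
                          float(ics.r_hb_A[i]))
        out.append(SHTrajectory(
            times_fs=times.copy(),
            theta6_deg=rec[0, i].astype(float),
            theta5_deg=rec[1, i].astype(float),
            r_hb_A=rec[2, i].astype(float),
            active_state=rec_active[i].astype(int),
            pop_s1=rec[3, i].astype(float),
            gap_ev=rec[4, i].astype(float),
            energy_kcal=rec[5, i].astype(float),
            hop_events=hop_log[i],
            final_state=int(active[i]),
            final_coordinates=fin,
            initial_coordinates=ini,
            seed=int(seeds[i]),
            valid=not bool(invalid[i]),
            stopped_early=not bool(alive[i]),
        ))
    return out


def run_trajectory(params: ModelParameters, ic: InitialConditions,
                   settings: SHSettings, seed: int) -> SHTrajectory:
    """Propagate a single trajectory (bitwise identical to the corresponding
    ensemble member with the same seed)."""
    if len(ic) != 1:
        raise ModelError("run_trajectory expects a single initial condition")
    return run_ensemble(params, ic, settings, [seed])[0]


@dataclass
class TrajectoryState:
    """Instantaneous phase-space + electronic state of a single trajectory
    (internal units: radians, angstrom, amu A^2 rad/fs)."""

    q: np.ndarray          # (3,) theta6, theta5 [rad], r [A]
    p: np.ndarray          # (3,) conjugate momenta
    c: np.ndarray          # (2,) complex coefficients, |c|^2 sums to 1
    active: int
    e0: float
    e1: float
    alpha: float
    time_fs: float = 0.0


def make_state(params: ModelParameters, theta6_deg: float, theta5_deg: float,
               r_hb: float, p=(0.0, 0.0, 0.0), active: int = 1) -> TrajectoryState:
    q = np.array([theta6_deg * DEG, theta5_deg * DEG, r_hb])
    e0, e1, _, _, alpha = _adiabats(params, q[0], q[1], q[2])
    c = np.zeros(2, dtype=complex)
    c[active] = 1.0
    return TrajectoryState(q=q, p=np.asarray(p, dtype=float), c=c,
                           active=active, e0=float(e0), e1=float(e1),
                           alpha=float(alpha))


def propagate_step(state: TrajectoryState, params: ModelParameters,
                   settings: SHSettings, rng: np.random.Generator) -> TrajectoryState:
    """One nuclear (BAOAB on the active surface) + electronic (local
    diabatization) step; hop decision and decoherence are separate
    operations.  Preserves the electronic norm to machine precision."""
    dt = settings.dt
    m = _masses(params)
    gamma_fs = (params.gamma if settings.gamma is None else settings.gamma) / 1000.0
    q, p = state.q.copy(), state.p.copy()
    _, _, g0, g1, _ = _adiabats(params, q[0], q[1], q[2])
    f = -(np.array(g1) if state.active == 1 else np.array(g0)) * KCAL_TO_AKMA
    p = p + 0.5 * dt * f
    q = q + 0.5 * dt * p / m
    if gamma_fs > 0:
        c1 = math.exp(-gamma_fs * dt)
        kT = KB * (params.T_excited if state.active == 1 else params.T)
        p = c1 * p + np.sqrt((1 - c1 * c1) * kT * KCAL_TO_AKMA * m) * rng.standard_normal(3)
    q = q + 0.5 * dt * p / m
    e0n, e1n, g0n, g1n, alpha_n = _adiabats(params, q[0], q[1], q[2])
    fn = -(np.array(g1n) if state.active == 1 else np.array(g0n)) * KCAL_TO_AKMA
    p = p + 0.5 * dt * fn
    if not (np.isfinite(e0n) and np.isfinite(e1n)):
        raise ModelError("non-finite energies during propagation")
    dalpha = float(np.mod(alpha_n - state.alpha + 0.5 * math.pi, math.pi)
                   - 0.5 * math.pi)
    c_new = _ld_propagate(state.c[None, :], state.e0, state.e1,
                          e0n, e1n, np.array([dalpha]), dt)[0]
    return TrajectoryState(q=q, p=p, c=c_new, active=state.active,
                           e0=float(e0n), e1=float(e1n), alpha=float(alpha_n),
                           time_fs=state.time_fs + dt)


def counter_seeds(master_seed: int, n: int) -> np.ndarray:
    """Independent per-trajectory seeds derived from a master seed."""
    ss = np.random.SeedSequence(master_seed)
    return np.array([int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(n)])
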