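"""Ground-state thermal sampling and vertical-excitation initial conditions.

Stands in for the ground-state QM/MM-MD trajectories used to seed the
surface-hopping swarm: velocity-Verlet dynamics on the lower adiabatic
surface with a Bussi-type stochastic velocity-rescaling thermostat, followed
by uniform extraction of (coordinates, momenta) frames as S1 initial
conditions.

Momentum units: p_theta = I * dtheta/dt in amu*A^2*rad/fs for the torsions,
p_r = m * dr/dt in amu*A/fs for the H-bond stretch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
import pandas as pd

from .constants import KB, KCAL_TO_AKMA, AKMA_TO_KCAL
from .model import DEG, ModelParameters, ModelError, _adiabats, wrap_angle

FRAME_COLUMNS = ["time_fs", "theta6_deg", "theta5_deg", "r_hb_A",
                 "p_theta6", "p_theta5", "p_r", "energy_kcal"]


@dataclass(frozen=True)
class EnsembleSpec:
    """Protocol for one ground-state sampling run.

    ``variant`` selects the packaged parameter set ("set-A": full-strength
    His290 H-bond; "set-B": weak H-bond).  ``duration`` includes the
    equilibration period; frames are recorded afterwards at a fixed stride
    chosen to yield ``n_frames`` frames.
    """

    variant: Literal["set-A", "set-B"] = "set-A"
    n_frames: int = 2000
    dt: float = 0.1            # fs
    duration: float = 20.0     # ps
    equilibration: float = 10.0  # ps
    seed: int = 0
    thermostat_tau: float = 100.0  # fs

    def __post_init__(self):
        if self.n_frames < 1:
            raise ModelError("n_frames must be >= 1")
        if not (self.duration > self.equilibration >= 0):
            raise ModelError("need duration > equilibration >= 0")
        if self.dt <= 0:
            raise ModelError("dt must be positive")


def _masses(params: ModelParameters) -> np.ndarray:
    return np.array([params.I_theta6, params.I_theta5, params.m_r])


def _s0_energy_forces(params: ModelParameters, q: np.ndarray):
    """Ground-surface energy and forces; q has shape (3, n) in rad/rad/A."""
    E0, _, g0, _, _ = _adiabats(params, q[0], q[1], q[2])
    return E0, -np.stack(g0)


def bussi_rescale_factor(kin: np.ndarray, kT: float, ndof: int, c: float,
                         r1: np.ndarray, rsum: np.ndarray) -> np.ndarray:
    """Stochastic velocity-rescaling factor alpha (canonical sampling).

    ``kin`` current kinetic energy, ``c`` = exp(-dt/tau), ``r1`` a standard
    normal draw and ``rsum`` a chi-squared(ndof-1) draw per system.
    """
    kin = np.maximum(kin, 1e-300)
    kbar = 0.5 * ndof * kT
    a2 = (c + (1.0 - c) * kbar * (r1 ** 2 + rsum) / (ndof * kin)
          + 2.0 * r1 * np.sqrt(c * (1.0 - c) * kbar / (ndof * kin)))
    return np.sqrt(np.maximum(a2, 0.0))


def ground_state_md(params: ModelParameters, spec: EnsembleSpec,
                    x0: np.ndarray | None = None) -> pd.DataFrame:
    """Run thermostatted dynamics on S0 and return recorded frames.

    Velocity-Verlet integration with the stochastic velocity-rescaling
    thermostat at ``params.T``; frames recorded after ``spec.equilibration``
    at a fixed stride.  Bitwise reproducible for a given seed.
    """
    rng = np.random.default_rng(spec.seed)
    m = _masses(params)[:, None]
    dt = spec.dt
    n_steps = int(round(spec.duration * 1000.0 / dt))
    n_equil = int(round(spec.equilibration * 1000.0 / dt))
    record_steps = n_steps - n_equil
    stride = max(1, record_steps // spec.n_frames)

    if x0 is None:
        q = np.array([[0.0], [0.0], [params.r0_hb]])
    else:
        q = np.asarray(x0, dtype=float).reshape(3, -1).copy()
        q[:2] *= DEG
    n = q.shape[1]
    kT = KB * params.T
    sigma_p = np.sqrt(np.maximum(kT, 1e-300) * KCAL_TO_AKMA * m)
    p = rng.standard_normal((3, n)) * sigma_p

    E, f = _s0_energy_forces(params, q)
    f = f * KCAL_TO_AKMA  # kcal/mol/rad -> amu A^2 rad/fs^2 when divided by I
    c_th = math.exp(-dt / spec.thermostat_tau)

    rows = []
    rec = 0
    for step in range(1, n_steps + 1):
        p = p + 0.5 * dt * f
        q = q + dt * p / m
        E, fk = _s0_energy_forces(params, q)
        if np.any(np.abs(E) > 1e6) or not np.all(np.isfinite(E)):
            raise ModelError(f"ground-state integration diverged at step {step}")
        f = fk * KCAL_TO_AKMA
        p = p + 0.5 * dt * f
        # thermostat (velocity rescaling; canonical)
        kin = 0.5 * np.sum(p * p / m, axis=0)
        r1 = rng.standard_normal(n)
        rsum = rng.chisquare(2, size=n)  # ndof - 1 = 2
        alpha = bussi_rescale_factor(kin * AKMA_TO_KCAL, kT, 3, c_th, r1, rsum)
        p = p * alpha
        if step > n_equil and (step - n_equil) % stride == 0 and rec < spec.n_frames:
            kin_kcal = 0.5 * np.sum(p * p / m, axis=0) * AKMA_TO_KCAL
            for j in range(n):
                rows.append((step * dt, wrap_angle(q[0, j] / DEG),
                             wrap_angle(q[1, j] / DEG), q[2, j],
                             p[0, j], p[1, j], p[2, j],
                             float(E[j] + kin_kcal[j])))
            rec += 1
    return pd.DataFrame(rows, columns=FRAME_COLUMNS)


@dataclass(frozen=True)
class InitialConditions:
    """Vertical-excitation initial conditions: frames promoted to S1."""

    theta6_deg: np.ndarray
    theta5_deg: np.ndarray
    r_hb_A: np.ndarray
    p_theta6: np.ndarray
    p_theta5: np.ndarray
    p_r: np.ndarray
    active_state: int = 1  # S1

    def __len__(self):
        return len(self.theta6_deg)


def draw_initial_conditions(frames: pd.DataFrame, n: int, seed: int,
                            with_replacement: bool = False) -> InitialConditions:
    """Sample ``n`` frames (coordinates and momenta) as S1 initial conditions.

    Sampling is uniform without replacement by default; the electronic state
    is set to S1 with coefficient vector (0, 1).
    """
    if len(frames) == 0:
        raise ModelError("empty frame set")
    if not with_replacement and n > len(frames):
        raise ModelError(f"requested {n} draws from {len(frames)} frames "
                         "without replacement")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(frames), size=n, replace=with_replacement)
    sub = frames.iloc[idx]
    return InitialConditions(
        theta6_deg=sub["theta6_deg"].to_numpy(float),
        theta5_deg=sub["theta5_deg"].to_numpy(float),
        r_hb_A=sub["r_hb_A"].to_numpy(float),
        p_theta6=sub["p_theta6"].to_numpy(float),
        p_theta5=sub["p_theta5"].to_numpy(float),
        p_r=sub["p_r"].to_numpy(float),
    )


def sample_initial_conditions(params: ModelParameters, n: int, seed: int,
                              spec: EnsembleSpec | None = None,
                              n_chains: int = 4) -> InitialConditions:
    """Convenience: run ground-state sampling (several independent chains in
    lockstep) and draw ``n`` vertical-excitation initial conditions."""
    spec = spec or EnsembleSpec(seed=seed)
    spec = replace(spec, seed=seed)
    x0 = np.tile(np.array([[0.0], [0.0], [params.r0_hb]]), (1, n_chains))
    frames = ground_state_md(params, spec, x0=x0)
    return draw_initial_conditions(frames, n, seed + 1)
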