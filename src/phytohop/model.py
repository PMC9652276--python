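"""Reduced-dimensional two-state model of biliverdin D-ring photoisomerization.

The model replaces the atomistic chromophore-in-protein potential with three
coordinates:

* ``theta6`` -- the C15=C16 double-bond torsion (D6) whose counterclockwise
  rotation drives isomerization, degrees, periodic on (-180, 180];
* ``theta5`` -- the adjacent C14-C15 single-bond torsion (D5), degrees; the
  hula-twist partner of D6;
* ``r_hb``  -- the D-ring carbonyl ... His290 hydrogen-bond distance, angstrom.

Two diabatic electronic states are used: a reactant diabat ``V11`` with its
torsional minimum at the planar (Pr-like) geometry, and a product diabat
``V22`` offset by the vertical excitation energy at the Franck-Condon point
and descending toward the isomerized well.  They cross near theta6 = 90 deg,
where a Gaussian diabatic coupling of magnitude ``w0`` opens the funnel for
nonadiabatic decay.  State-common terms carry the hydrogen-bond Morse well,
the planarity stabilization (the stronger the H-bond, the stiffer the planar
D6 well and the higher the excited-state torsional barrier), the hula-twist
bilinear coupling, and a smooth one-sided term that places the product well
exclusively on the positive-theta6 (counterclockwise) side.

All public functions accept angles in degrees and distances in angstrom;
energies are kcal/mol.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from importlib import resources
from typing import Literal

import numpy as np
import yaml

DEG = math.pi / 180.0

# sharpness (in sin theta6) of the smooth switch that confines the product
# well to the counterclockwise side; see _diabats
_ASYM_EPS = 0.08


def wrap_angle(theta_deg):
    """Map an angle in degrees to the principal branch (-180, 180]."""
    wrapped = np.mod(np.asarray(theta_deg, dtype=float) + 180.0, 360.0) - 180.0
    # np.mod returns -180 for inputs of exactly +180 + 360k; fix the branch end
    wrapped = np.where(wrapped == -180.0, 180.0, wrapped)
    if np.ndim(theta_deg) == 0:
        return float(wrapped)
    return wrapped


class ModelError(ValueError):
    """Invalid model input (non-finite or out-of-domain parameter/coordinate)."""


@dataclass(frozen=True)
class Coordinates:
    """A point (theta6, theta5, r_hb) in the reduced configuration space.

    Angles in degrees on the principal branch (-180, 180]; r_hb > 0 angstrom.
    Fields may be scalars or equally-shaped numpy arrays.
    """

    theta6: float
    theta5: float
    r_hb: float

    def __post_init__(self):
        t6 = np.asarray(self.theta6, dtype=float)
        t5 = np.asarray(self.theta5, dtype=float)
        r = np.asarray(self.r_hb, dtype=float)
        if not (np.all(np.isfinite(t6)) and np.all(np.isfinite(t5)) and np.all(np.isfinite(r))):
            raise ModelError("non-finite coordinate")
        if np.any(r <= 0):
            raise ModelError("r_hb must be strictly positive")
        object.__setattr__(self, "theta6", wrap_angle(self.theta6))
        object.__setattr__(self, "theta5", wrap_angle(self.theta5))

    def as_array(self) -> np.ndarray:
        return np.array([self.theta6, self.theta5, self.r_hb], dtype=float)


@dataclass(frozen=True)
class ModelParameters:
    """All constants of the two-state diabatic torsional model plus bath settings.

    Energies kcal/mol, distances angstrom, angles degrees, inertias amu*A^2,
    friction 1/ps, temperatures K.
    """

    E_vert: float = 40.8       # vertical excitation energy at the FC point
    V6_S1: float = 21.6        # excited-diabat D6 torsional amplitude
    V6_S0: float = 60.0        # ground-diabat D6 torsional amplitude
    V5: float = 6.0            # D5 torsional amplitude
    chi: float = 2.5           # bilinear hula-twist D5-D6 coupling
    theta6_CI: float = 90.0    # seam location (deg)
    w0: float = 1.0            # diabatic-coupling peak magnitude
    sigma_w: float = 15.0      # coupling width in theta6 (deg)
    D_hb: float = 6.0          # H-bond Morse well depth
    a_hb: float = 2.0          # Morse range (1/A)
    r0_hb: float = 2.9         # Morse equilibrium distance (A)
    lambda_hb: float = 1.6     # planarity coupling (dimensionless)
    s6: float = 1.0            # D6 barrier scale factor on the S1 diabat
    v_asym: float = 10.0       # one-sided (ccw-only) product-well amplitude
    I_theta6: float = 40.0     # D6 torsional inertia
    I_theta5: float = 40.0     # D5 torsional inertia
    m_r: float = 10.0          # H-bond stretch reduced mass (amu)
    gamma: float = 0.5         # Langevin bath friction (1/ps)
    T: float = 300.0           # bath temperature (K)
    T_excited: float = 600.0   # bath temperature while on S1 (K); emulates the
                               # vibrationally hot chromophore after excitation
    r_wall: float = 6.0        # onset of the soft pocket-confinement wall (A)
    k_wall: float = 2.0        # quartic wall stiffness (kcal/mol/A^4)

    def __post_init__(self):
        vals = {f.name: getattr(self, f.name) for f in fields(self)}
        for name, v in vals.items():
            if not np.isfinite(v):
                raise ModelError(f"non-finite parameter {name!r}")
        nonneg = ("V6_S1 V6_S0 V5 theta6_CI w0 sigma_w D_hb a_hb lambda_hb "
                  "s6 v_asym gamma T T_excited k_wall").split()
        for name in nonneg:
            if vals[name] < 0:
                raise ModelError(f"parameter {name!r} must be non-negative")
        for name in ("I_theta6", "I_theta5", "m_r", "r0_hb", "sigma_w", "r_wall"):
            if vals[name] <= 0:
                raise ModelError(f"parameter {name!r} must be positive")

    # -- config-file round trip ------------------------------------------------

    def to_dict(self) -> dict:
        return {f.name: float(getattr(self, f.name)) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ModelError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in d.items()})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ModelParameters":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def load_parameters(name: str = "set-A") -> ModelParameters:
    """Load a packaged parameter set ("set-A", "set-B") or a YAML file path."""
    key = name.lower().replace("_", "-")
    packaged = {"set-a": "set_a.yaml", "set-b": "set_b.yaml"}
    if key in packaged:
        ref = resources.files("phytohop.params") / packaged[key]
        with resources.as_file(ref) as p:
            return ModelParameters.from_yaml(p)
    return ModelParameters.from_yaml(name)


@dataclass(frozen=True)
class ElectronicStructureResult:
    """Adiabatic energies, gradients and mixing angle at one geometry.

    Gradients are with respect to (theta6 [deg], theta5 [deg], r_hb [A]).
    """

    E0: float
    E1: float
    gap: float
    gap_ev: float
    grad0: np.ndarray
    grad1: np.ndarray
    mixing_angle: float


# ---------------------------------------------------------------------------
# low-level vectorized potential kernels (radians, used by the dynamics engine)
# ---------------------------------------------------------------------------

def _morse_depth(p: ModelParameters, r):
    """H-bond well depth function: D_hb at r0, -> 0 when broken; and d/dr."""
    e = np.exp(-p.a_hb * (r - p.r0_hb))
    depth = p.D_hb * e * (2.0 - e)
    ddepth_dr = p.D_hb * (-p.a_hb) * e * 2.0 * (1.0 - e)
    return depth, ddepth_dr


def _diabats(p: ModelParameters, t6, t5, r):
    """Diabatic matrix elements and their gradients (angles in radians).

    Returns (V11, V22, V12, g11, g22, g12) with each g* a tuple of the three
    partial derivatives (per radian, per radian, per angstrom).
    """
    s6r, c6 = np.sin(t6), np.cos(t6)
    s5, c5 = np.sin(t5), np.cos(t5)
    depth, ddepth = _morse_depth(p, r)

    # state-common part
    over = np.maximum(r - p.r_wall, 0.0)
    wall = p.k_wall * over ** 4
    dwall = 4.0 * p.k_wall * over ** 3
    # planarity stabilization restricted to the cis (reactant) side:
    # ((1+cos t6)/2)^2 is 1 at the planar Pr geometry, 1/4 at the seam and 0
    # at the isomerized geometry, where the H-bond is lost
    cisfac = ((1.0 + c6) / 2.0) ** 2
    dcis = -s6r * (1.0 + c6) / 2.0
    plan = (1.0 + p.lambda_hb * cisfac)
    # smooth one-sided wall excluding the clockwise (negative-theta6) product
    # side: ~ (v_asym/2)(1-cos t6) for t6 < 0, ~ 0 for t6 > 0
    q = 1.0 / (1.0 + np.exp(s6r / _ASYM_EPS))
    asym = 0.5 * p.v_asym * (1.0 - c6) * q
    dasym = 0.5 * p.v_asym * (s6r * q
                              - (1.0 - c6) * (c6 / _ASYM_EPS) * q * (1.0 - q))
    common = (-plan * depth + wall
              + p.V5 * s5 ** 2
              + p.chi * s6r * s5
              + asym)
    dc_dt6 = (-p.lambda_hb * dcis * depth
              + p.chi * c6 * s5
              + dasym)
    dc_dt5 = 2.0 * p.V5 * s5 * c5 + p.chi * s6r * c5
    dc_dr = -plan * ddepth + dwall

    half0 = 0.5 * p.V6_S0
    half1 = 0.5 * p.V6_S1 * p.s6
    V11 = common + half0 * (1.0 - c6)
    V22 = common + p.E_vert - half1 * (1.0 - c6)
    g11 = (dc_dt6 + half0 * s6r, dc_dt5, dc_dr)
    g22 = (dc_dt6 - half1 * s6r, dc_dt5, dc_dr)

    # Gaussian coupling in the wrapped angular distance from the seam
    dtheta = np.mod(t6 - p.theta6_CI * DEG + math.pi, 2.0 * math.pi) - math.pi
    sig = p.sigma_w * DEG
    V12 = p.w0 * np.exp(-0.5 * (dtheta / sig) ** 2)
    dV12_dt6 = -(dtheta / sig ** 2) * V12
    g12 = (dV12_dt6, np.zeros_like(V12), np.zeros_like(V12))
    return V11, V22, V12, g11, g22, g12


def _adiabats(p: ModelParameters, t6, t5, r):
    """Adiabatic energies/gradients/mixing angle (radians in, per-radian grads)."""
    V11, V22, V12, g11, g22, g12 = _diabats(p, t6, t5, r)
    mean = 0.5 * (V11 + V22)
    diff = 0.5 * (V22 - V11)
    rho = np.sqrt(diff ** 2 + V12 ** 2)
    E0 = mean - rho
    E1 = mean + rho
    rho_safe = np.maximum(rho, 1e-300)
    grads0, grads1 = [], []
    for k in range(3):
        gmean = 0.5 * (g11[k] + g22[k])
        gdiff = 0.5 * (g22[k] - g11[k])
        grho = (diff * gdiff + V12 * g12[k]) / rho_safe
        grads0.append(gmean - grho)
        grads1.append(gmean + grho)
    alpha = 0.5 * np.arctan2(2.0 * V12, V11 - V22)
    return E0, E1, grads0, grads1, alpha


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def diabatic_hamiltonian(params: ModelParameters, x: Coordinates) -> np.ndarray:
    """Evaluate the 2x2 symmetric diabatic energy matrix at ``x`` (kcal/mol)."""
    V11, V22, V12, *_ = _diabats(params, np.asarray(x.theta6) * DEG,
                                 np.asarray(x.theta5) * DEG,
                                 np.asarray(x.r_hb))
    H = np.array([[V11, V12], [V12, V22]], dtype=float)
    if not np.all(np.isfinite(H)):
        raise ModelError("non-finite diabatic matrix")
    return H


def adiabatic_surfaces(params: ModelParameters, x: Coordinates) -> ElectronicStructureResult:
    """Adiabatic energies, analytic gradients and mixing angle at ``x``.

    Gradients are per degree for the torsions and per angstrom for r_hb.
    """
    from .constants import KCAL_PER_EV

    E0, E1, g0, g1, alpha = _adiabats(params, x.theta6 * DEG, x.theta5 * DEG, x.r_hb)
    scale = np.array([DEG, DEG, 1.0])
    grad0 = np.array([g0[0], g0[1], g0[2]], dtype=float) * scale
    grad1 = np.array([g1[0], g1[1], g1[2]], dtype=float) * scale
    gap = float(E1 - E0)
    return ElectronicStructureResult(
        E0=float(E0), E1=float(E1), gap=gap, gap_ev=gap / KCAL_PER_EV,
        grad0=grad0, grad1=grad1, mixing_angle=float(alpha),
    )


def _relaxed_profile(params: ModelParameters, state: int, grid_deg: np.ndarray):
    """Relaxed adiabatic energy along theta6: inner (theta5, r) minimization.

    The inner problem is separable and solved in closed form: the H-bond
    coordinate relaxes to r0 (both the Morse term and the planarity term are
    deepest there and the wall is zero), and the hula-twist/D5 part
    V5*sin^2(t5) + chi*sin(t6)*sin(t5) is quadratic in sin(t5) with minimizer
    sin(t5*) = -chi*sin(t6)/(2 V5), clipped to [-1, 1].
    """
    t6 = grid_deg * DEG
    if params.V5 > 0:
        u = np.clip(-params.chi * np.sin(t6) / (2.0 * params.V5), -1.0, 1.0)
    else:  # degenerate: theta5 term purely linear in sin(theta5)
        u = -np.sign(params.chi * np.sin(t6))
    t5 = np.arcsin(u)
    r = np.full_like(t6, params.r0_hb)
    E0, E1, *_ = _adiabats(params, t6, t5, r)
    return (E0, E1)[state], np.degrees(t5), r


def diabatic_crossing_angle(params: ModelParameters) -> float:
    """theta6 (deg, ccw side) where the two diabats cross: the state-common
    terms cancel, leaving (V6_S0 + V6_S1*s6)/2 * (1 - cos t6) = E_vert."""
    amp = 0.5 * (params.V6_S0 + params.V6_S1 * params.s6)
    if amp <= 0 or params.E_vert / amp > 2.0:
        raise ModelError("diabats do not cross: torsional amplitudes too "
                         "small for the vertical excitation energy")
    return math.degrees(math.acos(1.0 - params.E_vert / amp))


def torsional_barrier(params: ModelParameters, state: Literal["S0", "S1"] = "S1",
                      grid_step: float = 0.25) -> float:
    """Relaxed torsional barrier (kcal/mol) along theta6 on one adiabatic surface.

    A theta6 grid from -45 deg up to the photochemical funnel (the
    minimum-gap point of the relaxed adiabatic profiles, which coincides
    with the diabatic crossing when the coupling vanishes) is relaxed over
    (theta5, r_hb); the barrier is the largest climb of the relaxed profile
    travelling from the Franck-Condon side toward the funnel.
    Deterministic.
    """
    istate = {"S0": 0, "S1": 1}[state]
    grid = np.arange(-45.0, 140.0 + grid_step, grid_step)
    prof0, _, _ = _relaxed_profile(params, 0, grid)
    prof1, _, _ = _relaxed_profile(params, 1, grid)
    if not (np.all(np.isfinite(prof0)) and np.all(np.isfinite(prof1))):
        raise ModelError("non-finite relaxed profile")
    pos = np.nonzero(grid >= 0.0)[0]
    gap = (prof1 - prof0)[pos]
    j = int(np.argmin(gap))
    i_funnel = int(pos[j])
    # continuous funnel angle by parabolic interpolation of the gap minimum
    # (an endpoint snapped to the grid would quantize the barrier)
    theta_f = grid[i_funnel]
    if 0 < j < len(gap) - 1:
        denom = gap[j - 1] - 2.0 * gap[j] + gap[j + 1]
        if denom > 0:
            theta_f += 0.5 * grid_step * (gap[j - 1] - gap[j + 1]) / denom
    scan = np.append(grid[grid < theta_f], theta_f)
    profile, _, _ = _relaxed_profile(params, istate, scan)
    # activation barrier seen travelling from the Franck-Condon side to the
    # funnel: largest climb above the running minimum of the relaxed profile
    climb = profile - np.minimum.accumulate(profile)
    return float(np.max(climb))


def scale_d6_barrier(params: ModelParameters, target: float,
                     tol: float = 0.005, s6_lo: float = 0.1,
                     s6_hi: float = 20.0) -> ModelParameters:
    """Return a copy of ``params`` with ``s6`` adjusted so that the relaxed S1
    barrier equals ``target`` kcal/mol (within ``tol``).  Only ``s6`` changes.

    In the physically used range the barrier decreases with s6 (a larger
    excited-diabat torsional amplitude steepens the descent toward the seam);
    a coarse geometric scan locates a bracketing interval which is then
    refined by bisection.
    """
    if not (np.isfinite(target) and target > 0):
        raise ModelError("target barrier must be positive and finite")

    def barrier_at(s6):
        return torsional_barrier(replace(params, s6=s6), "S1")

    b_now = torsional_barrier(params, "S1")
    if abs(b_now - target) <= tol:
        return params

    scan = np.geomspace(s6_lo, s6_hi, 25)
    barriers = np.array([barrier_at(s) for s in scan])
    sign = np.sign(barriers - target)
    cross = np.nonzero(sign[:-1] * sign[1:] <= 0)[0]
    if len(cross) == 0:
        raise ModelError(
            f"target barrier {target} kcal/mol unreachable with s6 in "
            f"[{s6_lo}, {s6_hi}] (scan range {barriers.min():.3f}.."
            f"{barriers.max():.3f})")
    i = int(cross[0])
    lo, hi = float(scan[i]), float(scan[i + 1])
    b_lo = barriers[i]
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        b_mid = barrier_at(mid)
        if abs(b_mid - target) <= tol:
            return replace(params, s6=mid)
        if (b_mid > target) == (b_lo > target):
            lo, b_lo = mid, b_mid
        else:
            hi = mid
    raise ModelError("barrier bisection did not converge")


def locate_conical_intersection(params: ModelParameters,
                                gap_threshold: float = None,
                                full_circle: bool = False) -> Coordinates:
    """Locate the minimum-gap point of the adiabatic surfaces.

    A 1-degree scan over theta6 (with theta5 and r_hb relaxed on the ground
    surface) is refined by a bounded 1-D search.  By default the scan covers
    the counterclockwise branch theta6 in [0, 180] deg, where the model places
    the photochemical funnel; the clockwise-side diabatic crossing (where the
    coupling Gaussian has decayed) is dynamically inaccessible behind the
    exclusion wall and is only examined with ``full_circle=True``.  If
    ``gap_threshold`` is given and the minimal gap found exceeds it, a
    diagnostic error is raised naming the minimal gap reached.
    """
    if full_circle:
        grid = np.arange(-180.0, 180.0, 1.0)
    else:
        grid = np.arange(0.0, 180.0 + 1.0, 1.0)

    def gap_of(t6_deg):
        prof0, t5, r = _relaxed_profile(params, 0, np.atleast_1d(t6_deg))
        prof1, _, _ = _relaxed_profile(params, 1, np.atleast_1d(t6_deg))
        return float(prof1[0] - prof0[0])

    prof0, _, _ = _relaxed_profile(params, 0, grid)
    prof1, _, _ = _relaxed_profile(params, 1, grid)
    gaps = prof1 - prof0
    i = int(np.argmin(gaps))
    lo, hi = grid[i] - 1.0, grid[i] + 1.0
    from scipy.optimize import minimize_scalar
    res = minimize_scalar(gap_of, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-10})
    t6_star = float(res.x)
    gap_star = float(res.fun)
    if gap_threshold is not None and gap_star > gap_threshold:
        raise ModelError(
            f"no adiabatic gap below {gap_threshold} kcal/mol found; "
            f"minimal gap reached: {gap_star:.6g} kcal/mol at theta6 = {t6_star:.2f} deg")
    _, t5_star, r_star = _relaxed_profile(params, 0, np.atleast_1d(t6_star))
    return Coordinates(theta6=wrap_angle(t6_star), theta5=float(t5_star[0]),
                       r_hb=float(r_star[0]))
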