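"""Compiled inner loop of the surface-hopping engine.

Mirrors, trajectory by trajectory, the component operations defined in
`shdynamics` (BAOAB nuclear step on the active adiabatic surface, local
diabatization of the electronic coefficients, fewest-switches hop decision,
gradient-difference velocity rescaling, energy-based decoherence).  The
kernel advances all trajectories of an ensemble through one chunk of steps;
per-trajectory random numbers are pre-drawn outside so every trajectory owns
an independent, reproducible stream.
"""

import math

import numpy as np
from numba import njit

from .constants import AKMA_TO_KCAL, HBAR, KB, KCAL_PER_EV, KCAL_TO_AKMA

# indices into the packed parameter vector
_PKEYS = ("E_vert", "V6_S1", "V6_S0", "V5", "chi", "theta6_CI", "w0",
          "sigma_w", "D_hb", "a_hb", "r0_hb", "lambda_hb", "s6", "v_asym",
          "I_theta6", "I_theta5", "m_r", "gamma", "T", "T_excited",
          "r_wall", "k_wall")
_ASYM_EPS = 0.08
_DEG = math.pi / 180.0


def pack_params(params) -> np.ndarray:
    return np.array([getattr(params, k) for k in _PKEYS], dtype=np.float64)


@njit(cache=True, inline="always")
def _pot(pv, t6, t5, r):
    """Adiabatic energies, gradients (per rad / per A) and mixing angle."""
    (E_vert, V6_S1, V6_S0, V5, chi, theta6_CI, w0, sigma_w, D_hb, a_hb,
     r0_hb, lambda_hb, s6f, v_asym, I6, I5, m_r, gamma, T, T_ex,
     r_wall, k_wall) = (pv[0], pv[1], pv[2], pv[3], pv[4], pv[5], pv[6],
                        pv[7], pv[8], pv[9], pv[10], pv[11], pv[12], pv[13],
                        pv[14], pv[15], pv[16], pv[17], pv[18], pv[19],
                        pv[20], pv[21])
    s6 = math.sin(t6); c6 = math.cos(t6)
    s5 = math.sin(t5); c5 = math.cos(t5)
    e = math.exp(-a_hb * (r - r0_hb))
    depth = D_hb * e * (2.0 - e)
    ddepth = D_hb * (-a_hb) * e * 2.0 * (1.0 - e)
    over = r - r_wall
    if over > 0.0:
        wall = k_wall * over ** 4
        dwall = 4.0 * k_wall * over ** 3
    else:
        wall = 0.0
        dwall = 0.0
    cisfac = ((1.0 + c6) / 2.0) ** 2
    dcis = -s6 * (1.0 + c6) / 2.0
    plan = 1.0 + lambda_hb * cisfac
    q = 1.0 / (1.0 + math.exp(s6 / _ASYM_EPS))
    asym = 0.5 * v_asym * (1.0 - c6) * q
    dasym = 0.5 * v_asym * (s6 * q
                            - (1.0 - c6) * (c6 / _ASYM_EPS) * q * (1.0 - q))
    common = -plan * depth + wall + V5 * s5 * s5 + chi * s6 * s5 + asym
    dc_dt6 = -lambda_hb * dcis * depth + chi * c6 * s5 + dasym
    dc_dt5 = 2.0 * V5 * s5 * c5 + chi * s6 * c5
    dc_dr = -plan * ddepth + dwall

    half0 = 0.5 * V6_S0
    half1 = 0.5 * V6_S1 * s6f
    V11 = common + half0 * (1.0 - c6)
    V22 = common + E_vert - half1 * (1.0 - c6)
    g11_t6 = dc_dt6 + half0 * s6
    g22_t6 = dc_dt6 - half1 * s6

    dtheta = (t6 - theta6_CI * _DEG + math.pi) % (2.0 * math.pi) - math.pi
    sig = sigma_w * _DEG
    V12 = w0 * math.exp(-0.5 * (dtheta / sig) ** 2)
    dV12_t6 = -(dtheta / (sig * sig)) * V12

    mean = 0.5 * (V11 + V22)
    diff = 0.5 * (V22 - V11)
    rho = math.sqrt(diff * diff + V12 * V12)
    e0 = mean - rho
    e1 = mean + rho
    rho_s = rho if rho > 1e-300 else 1e-300

    gmean_t6 = 0.5 * (g11_t6 + g22_t6)
    gdiff_t6 = 0.5 * (g22_t6 - g11_t6)
    grho_t6 = (diff * gdiff_t6 + V12 * dV12_t6) / rho_s
    g0_t6 = gmean_t6 - grho_t6
    g1_t6 = gmean_t6 + grho_t6
    # theta5 and r enter only the state-common part
    g0_t5 = dc_dt5
    g1_t5 = dc_dt5
    g0_r = dc_dr
    g1_r = dc_dr
    alpha = 0.5 * math.atan2(2.0 * V12, V11 - V22)
    return e0, e1, g0_t6, g0_t5, g0_r, g1_t6, g1_t5, g1_r, alpha


@njit(cache=True)
def run_chunk(pv, masses, dt, gamma_fs, c_kcal, max_gap_ev, use_gap_gate,
              rescale_mode,
              record_stride, stop_steps, well_lo_rad, well_hi_rad,
              step0, nchunk, nsteps_total,
              q, p, cre, cim, active, alive, well_count,
              e0a, e1a, alpha_a,
              normals, uniforms,
              rec, rec_active, hop_data, hop_count, invalid):
    """Advance every live trajectory through up to ``nchunk`` steps.

    Returns the index of the last global step executed.
    """
    n = q.shape[1]
    c1 = math.exp(-gamma_fs * dt)
    csig = math.sqrt(1.0 - c1 * c1)
    kT0 = KB * pv[18] * KCAL_TO_AKMA
    kT1 = KB * pv[19] * KCAL_TO_AKMA
    last = step0
    for j in range(nchunk):
        step = step0 + j + 1
        if step > nsteps_total:
            break
        last = step
        any_alive = False
        for i in range(n):
            if not alive[i]:
                continue
            any_alive = True
            m0 = masses[0]; m1 = masses[1]; m2 = masses[2]
            act = active[i]
            # stored gradients of the active surface were kept in e0a..; we
            # re-evaluate the potential at the current point for the force
            (e0, e1, g0t6, g0t5, g0r, g1t6, g1t5, g1r,
             alpha) = _pot(pv, q[0, i], q[1, i], q[2, i])
            if act == 1:
                f0 = -g1t6 * KCAL_TO_AKMA
                f1 = -g1t5 * KCAL_TO_AKMA
                f2 = -g1r * KCAL_TO_AKMA
            else:
                f0 = -g0t6 * KCAL_TO_AKMA
                f1 = -g0t5 * KCAL_TO_AKMA
                f2 = -g0r * KCAL_TO_AKMA
            p0 = p[0, i] + 0.5 * dt * f0
            p1 = p[1, i] + 0.5 * dt * f1
            p2 = p[2, i] + 0.5 * dt * f2
            q0 = q[0, i] + 0.5 * dt * p0 / m0
            q1 = q[1, i] + 0.5 * dt * p1 / m1
            q2 = q[2, i] + 0.5 * dt * p2 / m2
            if gamma_fs > 0.0:
                kT = kT1 if act == 1 else kT0
                p0 = c1 * p0 + csig * math.sqrt(kT * m0) * normals[j, 0, i]
                p1 = c1 * p1 + csig * math.sqrt(kT * m1) * normals[j, 1, i]
                p2 = c1 * p2 + csig * math.sqrt(kT * m2) * normals[j, 2, i]
            q0 = q0 + 0.5 * dt * p0 / m0
            q1 = q1 + 0.5 * dt * p1 / m1
            q2 = q2 + 0.5 * dt * p2 / m2
            (e0n, e1n, g0t6n, g0t5n, g0rn, g1t6n, g1t5n, g1rn,
             alpha_n) = _pot(pv, q0, q1, q2)
            if not (math.isfinite(e0n) and math.isfinite(e1n)):
                invalid[i] = True
                alive[i] = False
                continue
            if act == 1:
                p0 = p0 + 0.5 * dt * (-g1t6n * KCAL_TO_AKMA)
                p1 = p1 + 0.5 * dt * (-g1t5n * KCAL_TO_AKMA)
                p2 = p2 + 0.5 * dt * (-g1rn * KCAL_TO_AKMA)
            else:
                p0 = p0 + 0.5 * dt * (-g0t6n * KCAL_TO_AKMA)
                p1 = p1 + 0.5 * dt * (-g0t5n * KCAL_TO_AKMA)
                p2 = p2 + 0.5 * dt * (-g0rn * KCAL_TO_AKMA)

            # --- local diabatization of the electronic coefficients
            dalpha = (alpha_n - alpha_a[i] + 0.5 * math.pi) % math.pi \
                - 0.5 * math.pi
            ca = math.cos(dalpha); cb = math.sin(dalpha)
            h00 = 0.5 * (e0a[i] + ca * ca * e0n + cb * cb * e1n)
            h11 = 0.5 * (e1a[i] + cb * cb * e0n + ca * ca * e1n)
            h01 = 0.5 * (ca * cb * (e0n - e1n))
            tauu = dt / HBAR
            am = 0.5 * (h00 + h11)
            dm = 0.5 * (h00 - h11)
            rho = math.sqrt(dm * dm + h01 * h01)
            cosr = math.cos(rho * tauu)
            sinc = math.sin(rho * tauu) / rho if rho > 1e-300 else tauu
            phr = math.cos(-am * tauu)
            phi = math.sin(-am * tauu)
            # u00 = phase*(cosr - i*sinc*dm), u11 = phase*(cosr + i*sinc*dm),
            # u01 = phase*(-i*sinc*h01), phase = phr + i*phi
            u00r = phr * cosr + phi * sinc * dm
            u00i = phi * cosr - phr * sinc * dm
            u11r = phr * cosr - phi * sinc * dm
            u11i = phi * cosr + phr * sinc * dm
            # u01 = phase * (-i sinc h01) = (phr + i phi)(-i sinc h01)
            u01r = phi * sinc * h01
            u01i = -phr * sinc * h01
            c0r = cre[i, 0]; c0i = cim[i, 0]
            c1r_ = cre[i, 1]; c1i_ = cim[i, 1]
            b0r = u00r * c0r - u00i * c0i + u01r * c1r_ - u01i * c1i_
            b0i = u00r * c0i + u00i * c0r + u01r * c1i_ + u01i * c1r_
            b1r = u01r * c0r - u01i * c0i + u11r * c1r_ - u11i * c1i_
            b1i = u01r * c0i + u01i * c0r + u11r * c1i_ + u11i * c1r_
            pop1_before = c1r_ * c1r_ + c1i_ * c1i_
            # rotate into new adiabatic basis: c_new = Z^T b
            n0r = ca * b0r + cb * b1r
            n0i = ca * b0i + cb * b1i
            n1r = -cb * b0r + ca * b1r
            n1i = -cb * b0i + ca * b1i
            pop1_after = n1r * n1r + n1i * n1i

            # --- fewest-switches hop decision
            gap = e1n - e0n
            gap_ev = gap / KCAL_PER_EV
            if act == 1:
                pa_b = pop1_before
                pa_a = pop1_after
            else:
                pa_b = 1.0 - pop1_before
                pa_a = 1.0 - pop1_after
            prob = (pa_b - pa_a) / (pa_b if pa_b > 1e-30 else 1e-30)
            if prob < 0.0:
                prob = 0.0
            elif prob > 1.0:
                prob = 1.0
            proposed = uniforms[j, i] < prob
            if proposed and use_gap_gate and gap_ev > max_gap_ev:
                proposed = False
            if proposed:
                target = 1 - act
                if target == 1:
                    de = gap
                else:
                    de = -gap
                if rescale_mode == 2:
                    # release/draw the gap energy along the H-bond rupture
                    # coordinate only
                    cc = de * KCAL_TO_AKMA
                    pr2 = p2 * p2 - 2.0 * m2 * cc
                    accepted = pr2 >= 0.0
                    if accepted:
                        sgn = 1.0 if p2 >= 0.0 else -1.0
                        p2 = sgn * math.sqrt(pr2)
                        active[i] = target
                        act = target
                elif rescale_mode == 1:
                    kin_int = 0.5 * (p0 * p0 / m0 + p1 * p1 / m1
                                     + p2 * p2 / m2)
                    cc = de * KCAL_TO_AKMA
                    accepted = kin_int > cc and kin_int > 0.0
                    if accepted:
                        s = math.sqrt(1.0 - cc / kin_int)
                        p0 *= s; p1 *= s; p2 *= s
                        active[i] = target
                        act = target
                else:
                    d0 = g1t6n - g0t6n
                    d1 = g1t5n - g0t5n
                    d2 = g1rn - g0rn
                    aa = 0.5 * (d0 * d0 / m0 + d1 * d1 / m1 + d2 * d2 / m2)
                    bb = p0 * d0 / m0 + p1 * d1 / m1 + p2 * d2 / m2
                    cc = de * KCAL_TO_AKMA
                    disc = bb * bb - 4.0 * aa * cc
                    accepted = disc >= 0.0 and aa > 0.0
                    if accepted:
                        sq = math.sqrt(disc)
                        lam1 = (-bb + sq) / (2.0 * aa)
                        lam2 = (-bb - sq) / (2.0 * aa)
                        lam = lam1 if abs(lam1) <= abs(lam2) else lam2
                        p0 = p0 + lam * d0
                        p1 = p1 + lam * d1
                        p2 = p2 + lam * d2
                        active[i] = target
                        act = target
                hc = hop_count[i]
                if hc < hop_data.shape[1]:
                    hop_data[i, hc, 0] = step * dt
                    hop_data[i, hc, 1] = 1 - target
                    hop_data[i, hc, 2] = target
                    hop_data[i, hc, 3] = gap_ev
                    hop_data[i, hc, 4] = q0
                    hop_data[i, hc, 5] = q1
                    hop_data[i, hc, 6] = q2
                    hop_data[i, hc, 7] = 1.0 if accepted else 0.0
                    hop_count[i] = hc + 1

            # --- energy-based decoherence
            kin = 0.5 * (p0 * p0 / m0 + p1 * p1 / m1 + p2 * p2 / m2) \
                * AKMA_TO_KCAL
            ek = kin if kin > 1e-8 else 1e-8
            taud = (HBAR / (gap if gap > 1e-30 else 1e-30)) \
                * (1.0 + c_kcal / ek)
            damp = math.exp(-dt / taud)
            if act == 1:
                n0r *= damp; n0i *= damp
                p_other = n0r * n0r + n0i * n0i
                p_act = n1r * n1r + n1i * n1i
                tgt = 1.0 - p_other
                if tgt < 0.0:
                    tgt = 0.0
                sc = math.sqrt(tgt / (p_act if p_act > 1e-300 else 1e-300))
                n1r *= sc; n1i *= sc
            else:
                n1r *= damp; n1i *= damp
                p_other = n1r * n1r + n1i * n1i
                p_act = n0r * n0r + n0i * n0i
                tgt = 1.0 - p_other
                if tgt < 0.0:
                    tgt = 0.0
                sc = math.sqrt(tgt / (p_act if p_act > 1e-300 else 1e-300))
                n0r *= sc; n0i *= sc

            # --- commit
            q[0, i] = q0; q[1, i] = q1; q[2, i] = q2
            p[0, i] = p0; p[1, i] = p1; p[2, i] = p2
            cre[i, 0] = n0r; cim[i, 0] = n0i
            cre[i, 1] = n1r; cim[i, 1] = n1i
            e0a[i] = e0n; e1a[i] = e1n; alpha_a[i] = alpha_n

            # --- stop condition: settled on S0 in a well
            t6w = abs((q0 + math.pi) % (2.0 * math.pi) - math.pi)
            if act == 0 and (t6w <= well_lo_rad or t6w >= well_hi_rad):
                well_count[i] += 1
            else:
                well_count[i] = 0
            if well_count[i] >= stop_steps:
                alive[i] = False

        if step % record_stride == 0:
            k = step // record_stride
            for i in range(n):
                (e0, e1, _, _, _, _, _, _, _) = _pot(pv, q[0, i], q[1, i],
                                                     q[2, i])
                kin = 0.5 * (p[0, i] ** 2 / masses[0] + p[1, i] ** 2 / masses[1]
                             + p[2, i] ** 2 / masses[2]) * AKMA_TO_KCAL
                rec[0, i, k] = q[0, i] / _DEG
                rec[1, i, k] = q[1, i] / _DEG
                rec[2, i, k] = q[2, i]
                rec[3, i, k] = cre[i, 1] ** 2 + cim[i, 1] ** 2
                rec[4, i, k] = (e1 - e0) / KCAL_PER_EV
                rec[5, i, k] = (e1 if active[i] == 1 else e0) + kin
                rec_active[i, k] = active[i]
        if not any_alive:
            break
    return last
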