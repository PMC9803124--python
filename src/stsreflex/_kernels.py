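"""Numerical kernels for the planar STS simulator.

Everything here operates on plain ndarrays/scalars so the same functions serve
both the object API and the hot rollout loop. When numba is importable the
kernels are JIT-compiled; otherwise they run as ordinary Python (identical
results, slower).

Mechanics formulation: each body's CoM (and every attached point) is written as

    p = (q0, q1) + sum_k c_k * u(phi_k + d_k),      u(t) = (sin t, cos t)

with body orientations phi = S q linear in the generalized coordinates, so the
mass matrix, bias forces and point Jacobians are all closed-form sums of sines
and cosines. The equations of motion are M(q) qdd = Q_applied - h(q, qd) with
h the centrifugal+gravity generalized force.
"""

from __future__ import annotations

import math

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if len(args) == 1 and callable(args[0]):
            return args[0]

        def deco(fn):
            return fn

        return deco


DEG = math.pi / 180.0

# ---------------------------------------------------------------------------
# Feedback channel indices (BodyFeedback array layout)
# ---------------------------------------------------------------------------
FB_THETA = 0        # torso pitch (reported hip angle), rad
FB_OMEGA = 1        # torso pitch rate, rad/s
FB_ALPHA = 2        # torso pitch acceleration (low-pass filtered), rad/s^2
FB_PX = 3           # torso CoM x, m
FB_PY = 4           # torso CoM y, m
FB_VX = 5           # torso CoM vx, m/s
FB_VY = 6           # torso CoM vy, m/s
FB_AX = 7           # torso CoM ax (filtered), m/s^2
FB_AY = 8           # torso CoM ay (filtered), m/s^2
FB_PPX = 9          # pelvis x, m
FB_PVX = 10         # pelvis vx, m/s
FB_PAX = 11         # pelvis ax (filtered), m/s^2
FB_KNEE = 12        # knee angle (side average), rad
FB_KNEEVEL = 13     # knee angular velocity, rad/s
FB_ANKLE = 14       # ankle angle (side average), rad
FB_SHANK_X = 15     # shank inclination w.r.t. +x axis, rad
FB_FEET_X = 16      # calcaneus landmark x (side average), m
FB_VTALUS_Y = 17    # talus vertical velocity, m/s
FB_VTOES_X = 18     # toes horizontal velocity, m/s
FB_VTOES_Y = 19     # toes vertical velocity, m/s
FB_PTALUS_X = 20    # talus x, m
FB_PTOES_X = 21     # toes x, m
FB_PPY = 22         # pelvis y, m
FB_ANKLEVEL = 23    # ankle angular velocity, rad/s
N_FB = 24

# rollout termination codes
TERM_COMPLETED = 0
TERM_FELL = 1
TERM_DIVERGED = 2


# ---------------------------------------------------------------------------
# Kinematics helpers
# ---------------------------------------------------------------------------
@njit(cache=False)
def body_orientations(S, q):
    """phi = S @ q (orientation of every body, rad)."""
    nb = S.shape[0]
    ndof = S.shape[1]
    phi = np.zeros(nb)
    for b in range(nb):
        acc = 0.0
        for j in range(ndof):
            acc += S[b, j] * q[j]
        phi[b] = acc
    return phi


@njit(cache=False)
def point_pos_vel(q, qd, phi, phid, n, tb, tc, td):
    """Position and velocity of a point given its term list."""
    px = q[0]
    py = q[1]
    vx = qd[0]
    vy = qd[1]
    for t in range(n):
        k = tb[t]
        ang = phi[k] + td[t]
        s = math.sin(ang)
        c = math.cos(ang)
        px += tc[t] * s
        py += tc[t] * c
        vx += tc[t] * phid[k] * c
        vy -= tc[t] * phid[k] * s
    return px, py, vx, vy


@njit(cache=False)
def point_acc(qdd, phi, phid, phidd, n, tb, tc, td):
    """Acceleration of a point given generalized accelerations."""
    ax = qdd[0]
    ay = qdd[1]
    for t in range(n):
        k = tb[t]
        ang = phi[k] + td[t]
        s = math.sin(ang)
        c = math.cos(ang)
        ax += tc[t] * (phidd[k] * c - phid[k] * phid[k] * s)
        ay += tc[t] * (-phidd[k] * s - phid[k] * phid[k] * c)
    return ax, ay


@njit(cache=False)
def point_jacobian(S, phi, n, tb, tc, td, J):
    """Fill the 2 x ndof Jacobian of a point. J must be zeroed by the caller."""
    ndof = S.shape[1]
    J[0, 0] = 1.0
    J[1, 1] = 1.0
    for t in range(n):
        k = tb[t]
        ang = phi[k] + td[t]
        fx = math.cos(ang)
        fy = -math.sin(ang)
        for j in range(2, ndof):
            s = S[k, j]
            if s != 0.0:
                J[0, j] += tc[t] * s * fx
                J[1, j] += tc[t] * s * fy


@njit(cache=False)
def dynamics_terms(q, qd, S, mass, inertia, ct_n, ct_b, ct_c, ct_d, g):
    """Mass matrix M and bias h such that M qdd = Q_applied - h."""
    nb = S.shape[0]
    ndof = S.shape[1]
    phi = body_orientations(S, q)
    phid = body_orientations(S, qd)
    M = np.zeros((ndof, ndof))
    h = np.zeros(ndof)
    J = np.zeros((2, ndof))
    for b in range(nb):
        for i in range(2):
            for j in range(ndof):
                J[i, j] = 0.0
        point_jacobian(S, phi, ct_n[b], ct_b[b], ct_c[b], ct_d[b], J)
        # centrifugal CoM acceleration at qdd = 0
        a0x = 0.0
        a0y = 0.0
        for t in range(ct_n[b]):
            k = ct_b[b, t]
            ang = phi[k] + ct_d[b, t]
            w2 = phid[k] * phid[k]
            a0x -= ct_c[b, t] * w2 * math.sin(ang)
            a0y -= ct_c[b, t] * w2 * math.cos(ang)
        mb = mass[b]
        for i in range(ndof):
            ji0 = J[0, i]
            ji1 = J[1, i]
            if ji0 != 0.0 or ji1 != 0.0:
                for j in range(i, ndof):
                    M[i, j] += mb * (ji0 * J[0, j] + ji1 * J[1, j])
                # bias: m J^T a0  minus gravity m J^T (0, -g)
                h[i] += mb * (ji0 * a0x + ji1 * (a0y + g))
        Ib = inertia[b]
        for i in range(2, ndof):
            si = S[b, i]
            if si != 0.0:
                for j in range(max(i, 2), ndof):
                    sj = S[b, j]
                    if sj != 0.0:
                        M[i, j] += Ib * si * sj
    for i in range(ndof):
        for j in range(i):
            M[i, j] = M[j, i]
    return M, h


@njit(cache=False)
def contact_normal_force(depth, ddot, khc, chc):
    """Hunt-Crossley normal force, clamped non-negative."""
    if depth <= 0.0:
        return 0.0
    f = khc * depth**1.5 * (1.0 + 1.5 * chc * ddot)
    if f < 0.0:
        f = 0.0
    return f


@njit(cache=False)
def contact_forces(
    q,
    qd,
    S,
    cp_n,
    cp_b,
    cp_c,
    cp_d,
    cp_body,
    cp_radius,
    cp_plane,
    seat_y,
    seat_xmin,
    seat_xmax,
    khc,
    chc,
    mu,
    veps,
    Q,
    forces,
):
    """Accumulate generalized contact forces into Q.

    forces is (ncp, 3) output: normal force, tangential force, penetration.
    """
    ncp = cp_radius.shape[0]
    ndof = S.shape[1]
    phi = body_orientations(S, q)
    phid = body_orientations(S, qd)
    J = np.zeros((2, ndof))
    for p in range(ncp):
        px, py, vx, vy = point_pos_vel(
            q, qd, phi, phid, cp_n[p], cp_b[p], cp_c[p], cp_d[p]
        )
        r = cp_radius[p]
        if cp_plane[p] == 1:
            depth = seat_y - (py - r)
            in_span = seat_xmin <= px <= seat_xmax
        else:
            depth = r - py
            in_span = True
        forces[p, 2] = depth
        if depth <= 0.0 or not in_span:
            forces[p, 0] = 0.0
            forces[p, 1] = 0.0
            continue
        fn = contact_normal_force(depth, -vy, khc, chc)
        b = cp_body[p]
        # material slip velocity of the sphere's lowest point
        v_slip = vx + phid[b] * r
        ft = -mu * fn * math.tanh(v_slip / veps)
        forces[p, 0] = fn
        forces[p, 1] = ft
        for i in range(2):
            for j in range(ndof):
                J[i, j] = 0.0
        point_jacobian(S, phi, cp_n[p], cp_b[p], cp_c[p], cp_d[p], J)
        torque = r * ft  # tangential force acts at the sphere bottom
        for j in range(ndof):
            Q[j] += J[0, j] * ft + J[1, j] * fn + S[b, j] * torque


# ---------------------------------------------------------------------------
# Muscle kernels
# ---------------------------------------------------------------------------
@njit(cache=False)
def joint_passive_torques(q, qd, jnt_lo, jnt_hi, kd, klim, dlim, Q):
    """Viscous joint damping plus soft range-of-motion stops (both sides)."""
    for side in range(2):
        base = 3 + 3 * side
        for j in range(3):
            i = base + j
            tau = -kd * qd[i]
            if q[i] > jnt_hi[j]:
                tau += -klim * (q[i] - jnt_hi[j]) - dlim * qd[i]
            elif q[i] < jnt_lo[j]:
                tau += -klim * (q[i] - jnt_lo[j]) - dlim * qd[i]
            Q[i] += tau


@njit(cache=False)
def force_length(L, fl_gamma):
    d = L - 1.0
    return math.exp(-(d * d) / fl_gamma)


@njit(cache=False)
def force_velocity(v, vmax):
    """Hill force-velocity; v > 0 lengthening, in excursion-scale units/s."""
    if v < 0.0:
        if v <= -vmax:
            return 0.0
        return (vmax + v) / (vmax - 4.0 * v)
    return 1.0 + 0.8 * v / (v + 0.13 * vmax)


@njit(cache=False)
def passive_force(L, fp_k):
    # engages beyond the slack length 1.2 (well past optimal), as in
    # physiological parallel-elastic curves
    d = L - 1.2
    if d <= 0.0:
        return 0.0
    return fp_k * d * d


@njit(cache=False)
def muscle_force_kernel(a, L, v, fmax, fl_gamma, vmax, fp_k):
    f = fmax * (a * force_length(L, fl_gamma) * force_velocity(v, vmax) + passive_force(L, fp_k))
    if f < 0.0:
        f = 0.0
    return f


@njit(cache=False)
def activation_step(a, stim, dt, tau_act, tau_dea):
    """Exact first-order excitation-activation step."""
    if stim >= a:
        tau = tau_act
    else:
        tau = tau_dea
    return a + (stim - a) * (1.0 - math.exp(-dt / tau))


@njit(cache=False)
def fiber_lengths(q, qd, side, arms_ext, sexc, Lm, Vm):
    """Normalized fiber length/velocity per channel for one side (0=L, 1=R)."""
    C = arms_ext.shape[0]
    base = 3 + 3 * side
    for m in range(C):
        acc = 0.0
        accv = 0.0
        for j in range(3):
            acc += arms_ext[m, j] * q[base + j]
            accv += arms_ext[m, j] * qd[base + j]
        Lm[m] = 1.0 + acc / sexc[m]
        Vm[m] = accv / sexc[m]


# ---------------------------------------------------------------------------
# Reflex controller kernels
# ---------------------------------------------------------------------------
@njit(cache=False)
def stimulation_kernel(
    fb, Lm, G, A0, pref, klen, L0, phase, ctrl_phases, rf_idx, a_min, out
):
    """Phase-dependent reflex stimulation law.

    A_m = A0[m,n] + sum_s k_{s,m,n} * x_s + k_l,m (L_m - L0,m), clamped to
    [a_min, 1]. Routed signals x_s depend on the phase; position signals have
    the per-phase optimizable reference subtracted. In phase 1 only the rectus
    femoris receives vestibular terms.
    """
    n = phase - 1
    C = out.shape[0]
    s0 = 0.0
    s1 = 0.0
    s2 = 0.0
    s3 = 0.0
    s4 = 0.0
    s5 = 0.0
    nsig = 6
    if phase == 1:
        s0 = fb[FB_THETA] - pref[0, 0]
        s1 = fb[FB_OMEGA]
        s2 = fb[FB_ALPHA]
        nsig = 3
    elif ctrl_phases == 4 and phase == 4:
        s0 = fb[FB_PX] - pref[3, 0]
        s1 = fb[FB_PPX] - pref[3, 1]
        s2 = fb[FB_VX]
        s3 = fb[FB_PVX]
        s4 = fb[FB_AX]
        s5 = fb[FB_PAX]
    else:
        s0 = fb[FB_PX] - pref[n, 0]
        s1 = fb[FB_PY] - pref[n, 1]
        s2 = fb[FB_VX]
        s3 = fb[FB_VY]
        s4 = fb[FB_AX]
        s5 = fb[FB_AY]
    for m in range(C):
        a = A0[n, m] + klen[m] * (Lm[m] - L0[m])
        if phase != 1 or m == rf_idx:
            a += G[n, m, 0] * s0 + G[n, m, 1] * s1 + G[n, m, 2] * s2
            if nsig == 6:
                a += G[n, m, 3] * s3 + G[n, m, 4] * s4 + G[n, m, 5] * s5
        if a < a_min:
            a = a_min
        elif a > 1.0:
            a = 1.0
        out[m] = a
    return 0


@njit(cache=False)
def phase_transition(phase, fb, ctrl_phases, thr_hip_up, thr_knee, thr_hip_ext):
    """Non-returning phase machine; at most one transition per call."""
    if phase == 1:
        if fb[FB_THETA] > thr_hip_up:
            return 2
        return phase
    if ctrl_phases == 2:
        return phase
    if phase == 2:
        if (
            fb[FB_PX] >= fb[FB_FEET_X]
            and fb[FB_VX] <= 0.0
            and fb[FB_SHANK_X] < 0.5 * math.pi
        ):
            return 3
        return phase
    if phase == 3:
        if fb[FB_KNEE] <= thr_knee and fb[FB_THETA] <= thr_hip_ext:
            return 4
        return phase
    return phase


# ---------------------------------------------------------------------------
# Cost kernels (quadratic excess beyond each penalized threshold, * dt)
# ---------------------------------------------------------------------------
N_RULES_4P = 20
N_RULES_2P = 12

_A = 11.0 * DEG       # hip extension bound
_H8 = 8.0 * DEG       # stance hip band
_H44 = 44.0 * DEG
_H77 = 77.0 * DEG
_K11 = 11.0 * DEG
_K15 = 15.0 * DEG
_W10 = 10.0 * DEG     # deg/s -> rad/s



@njit(cache=False)
def _pen(excess, cap):
    """Squared violation with saturation (keeps impact transients bounded)."""
    if excess > cap:
        excess = cap
    return excess * excess


@njit(cache=False)
def cost_step_4p(fb, phase, dt, a_thr, vcap, w, out):
    """Accumulate phase-dependent penalty increments (4-phase controller)."""
    hip = fb[FB_THETA]
    if phase == 1:
        ax = fb[FB_AX]
        if ax <= a_thr:
            d = a_thr - ax
            out[0] += w[0] * _pen(d, vcap) * dt
        v = fb[FB_VTOES_Y]
        if v > 0.2:
            d = v - 0.2
            out[1] += w[1] * _pen(d, vcap) * dt
    elif phase == 2:
        v = fb[FB_PVX]
        if v <= 0.0:
            out[2] += w[2] * _pen(-v, vcap) * dt
        v = fb[FB_VTALUS_Y]
        if v > 0.1:
            d = v - 0.1
            out[3] += w[3] * _pen(d, vcap) * dt
        v = fb[FB_VTOES_X]
        if v > 0.15:
            d = v - 0.15
            out[4] += w[4] * _pen(d, vcap) * dt
        if hip < -_A:
            d = -_A - hip
            out[5] += w[5] * _pen(d, vcap) * dt
        k = fb[FB_KNEE]
        if k < 0.0:
            out[6] += w[6] * _pen(-k, vcap) * dt
        if fb[FB_PY] < fb[FB_PPY]:
            d = fb[FB_PPY] - fb[FB_PY]
            out[7] += w[7] * _pen(d, vcap) * dt
    elif phase == 3:
        if fb[FB_PY] < fb[FB_PPY]:
            d = fb[FB_PPY] - fb[FB_PY]
            out[8] += w[8] * _pen(d, vcap) * dt
        if fb[FB_PX] > fb[FB_PTOES_X]:
            d = fb[FB_PX] - fb[FB_PTOES_X]
            out[9] += w[9] * _pen(d, vcap) * dt
        v = fb[FB_VTALUS_Y]
        if v > 0.1:
            d = v - 0.1
            out[10] += w[10] * _pen(d, vcap) * dt
        v = fb[FB_VTOES_Y]
        if v > 0.15:
            d = v - 0.15
            out[11] += w[11] * _pen(d, vcap) * dt
        if hip < -_A:
            d = -_A - hip
            out[12] += w[12] * _pen(d, vcap) * dt
        v = fb[FB_PVX]
        if v <= 0.0:
            out[13] += w[13] * _pen(-v, vcap) * dt
    else:
        if fb[FB_PY] < fb[FB_PPY]:
            d = fb[FB_PPY] - fb[FB_PY]
            out[14] += w[14] * _pen(d, vcap) * dt
        v = fb[FB_VTALUS_Y]
        if v > 0.1:
            d = v - 0.1
            out[15] += w[15] * _pen(d, vcap) * dt
        v = fb[FB_VTOES_Y]
        if v > 0.3:
            d = v - 0.3
            out[16] += w[16] * _pen(d, vcap) * dt
        if fb[FB_PPX] < fb[FB_PTALUS_X]:
            d = fb[FB_PTALUS_X] - fb[FB_PPX]
            out[17] += w[17] * _pen(d, vcap) * dt
        if fb[FB_PX] > fb[FB_PTOES_X]:
            d = fb[FB_PX] - fb[FB_PTOES_X]
            out[18] += w[18] * _pen(d, vcap) * dt
        if hip > _H8:
            d = hip - _H8
            out[19] += w[19] * _pen(d, vcap) * dt
        elif hip < -_H8:
            d = -_H8 - hip
            out[19] += w[19] * _pen(d, vcap) * dt
    return 0


@njit(cache=False)
def cost_step_2p(fb, phase, dt, a_thr, vcap, w, out):
    """Accumulate penalty increments (2-phase controller, merged-phase groups)."""
    hip = fb[FB_THETA]
    if phase == 1:
        ax = fb[FB_AX]
        if ax <= a_thr:
            d = a_thr - ax
            out[0] += w[0] * _pen(d, vcap) * dt
        v = fb[FB_VTOES_Y]
        if v > 0.2:
            d = v - 0.2
            out[1] += w[1] * _pen(d, vcap) * dt
        return 0
    if hip > _H44:
        v = fb[FB_VX]
        if v <= 0.0:
            out[2] += w[2] * _pen(-v, vcap) * dt
        v = fb[FB_PVX]
        if v <= 0.0:
            out[3] += w[3] * _pen(-v, vcap) * dt
    if _H8 < hip < _H77:
        # progress requirements: hip must extend at >= 10 deg/s, knee at >= 0
        # (flexion-positive convention: extension velocity = -omega)
        wv = fb[FB_OMEGA]
        if -wv < _W10:
            d = wv + _W10
            out[4] += w[4] * _pen(d, vcap) * dt
        kv = fb[FB_KNEEVEL]
        if kv > 0.0:
            out[5] += w[5] * _pen(kv, vcap) * dt
    if hip <= _H8:
        if hip < -_H8:
            d = -_H8 - hip
            out[6] += w[6] * _pen(d, vcap) * dt
        k = fb[FB_KNEE]
        if k >= _K11:
            d = k - _K11
            out[7] += w[7] * _pen(d, vcap) * dt
    if fb[FB_PY] < fb[FB_PPY]:
        d = fb[FB_PPY] - fb[FB_PY]
        out[8] += w[8] * _pen(d, vcap) * dt
    k = fb[FB_KNEE]
    if k < -_K15:
        d = -_K15 - k
        out[9] += w[9] * _pen(d, vcap) * dt
    v = fb[FB_VTALUS_Y]
    if v > 0.1:
        d = v - 0.1
        out[10] += w[10] * _pen(d, vcap) * dt
    v = fb[FB_VTOES_Y]
    if v > 0.3:
        d = v - 0.3
        out[11] += w[11] * _pen(d, vcap) * dt
    return 0


# ---------------------------------------------------------------------------
# Feedback assembly
# ---------------------------------------------------------------------------
@njit(cache=False)
def assemble_feedback(
    q,
    qd,
    qdd,
    S,
    ct_n,
    ct_b,
    ct_c,
    ct_d,
    pelvis_h,
    cp_n,
    cp_b,
    cp_c,
    cp_d,
    tal_n,
    tal_b,
    tal_c,
    tal_d,
    filt,
    alpha_f,
    fb,
):
    """Fill the feedback vector fb (length N_FB) and update filter state.

    filt holds the filtered acceleration channels
    [alpha_torso, a_torso_x, a_torso_y, a_pelvis_x]; pass alpha_f = 1 for
    unfiltered (instantaneous) output.
    """
    phi = body_orientations(S, q)
    phid = body_orientations(S, qd)
    phidd = body_orientations(S, qdd)
    # torso CoM (body 0 CoM terms)
    px, py, vx, vy = point_pos_vel(q, qd, phi, phid, ct_n[0], ct_b[0], ct_c[0], ct_d[0])
    ax, ay = point_acc(qdd, phi, phid, phidd, ct_n[0], ct_b[0], ct_c[0], ct_d[0])
    # pelvis landmark: hip + pelvis_h * u(phi_torso)
    ang = phi[0]
    s = math.sin(ang)
    c = math.cos(ang)
    ppx = q[0] + pelvis_h * s
    ppy = q[1] + pelvis_h * c
    pvx = qd[0] + pelvis_h * phid[0] * c
    pax = qdd[0] + pelvis_h * (phidd[0] * c - phid[0] * phid[0] * s)
    # filter accel channels
    filt[0] += alpha_f * (qdd[2] - filt[0])
    filt[1] += alpha_f * (ax - filt[1])
    filt[2] += alpha_f * (ay - filt[2])
    filt[3] += alpha_f * (pax - filt[3])

    fb[FB_THETA] = phi[0]
    fb[FB_OMEGA] = phid[0]
    fb[FB_ALPHA] = filt[0]
    fb[FB_PX] = px
    fb[FB_PY] = py
    fb[FB_VX] = vx
    fb[FB_VY] = vy
    fb[FB_AX] = filt[1]
    fb[FB_AY] = filt[2]
    fb[FB_PPX] = ppx
    fb[FB_PVX] = pvx
    fb[FB_PAX] = filt[3]
    fb[FB_PPY] = ppy
    fb[FB_KNEE] = 0.5 * (q[4] + q[7])
    fb[FB_KNEEVEL] = 0.5 * (qd[4] + qd[7])
    fb[FB_ANKLE] = 0.5 * (q[5] + q[8])
    fb[FB_ANKLEVEL] = 0.5 * (qd[5] + qd[8])
    # shank inclination w.r.t. +x axis (bodies 2 and 5 are the shanks)
    fb[FB_SHANK_X] = 0.5 * math.pi - 0.5 * (phi[2] + phi[5])
    # calcaneus landmarks are contact points 1 (left) and 3 (right)
    cx_sum = 0.0
    tvx = 0.0
    tvy = 0.0
    tpx = 0.0
    for side in range(2):
        pcx, pcy, pcvx, pcvy = point_pos_vel(
            q, qd, phi, phid, cp_n[1 + 2 * side], cp_b[1 + 2 * side],
            cp_c[1 + 2 * side], cp_d[1 + 2 * side],
        )
        cx_sum += pcx
        ptx, pty, ptvx, ptvy = point_pos_vel(
            q, qd, phi, phid, cp_n[2 * side], cp_b[2 * side],
            cp_c[2 * side], cp_d[2 * side],
        )
        tpx += ptx
        tvx += ptvx
        tvy += ptvy
    fb[FB_FEET_X] = 0.5 * cx_sum
    fb[FB_VTOES_X] = 0.5 * tvx
    fb[FB_VTOES_Y] = 0.5 * tvy
    fb[FB_PTOES_X] = 0.5 * tpx
    # talus (ankle joint) landmarks
    apx = 0.0
    avy = 0.0
    for side in range(2):
        tx, ty, tvx2, tvy2 = point_pos_vel(
            q, qd, phi, phid, tal_n[side], tal_b[side], tal_c[side], tal_d[side]
        )
        apx += tx
        avy += tvy2
    fb[FB_PTALUS_X] = 0.5 * apx
    fb[FB_VTALUS_Y] = 0.5 * avy
    return 0


# ---------------------------------------------------------------------------
# Full rollout
# ---------------------------------------------------------------------------
@njit(cache=False)
def rollout(
    # model
    S, mass, inertia, ct_n, ct_b, ct_c, ct_d, g,
    cp_n, cp_b, cp_c, cp_d, cp_body, cp_radius, cp_plane,
    seat_y, seat_xmin, seat_xmax, khc, chc, mu, veps,
    tal_n, tal_b, tal_c, tal_d, pelvis_h,
    # muscles
    arms_ext, fmax, sexc, vmax, tau_act, tau_dea, a_min, fl_gamma, fp_k,
    # passive joint structures
    jnt_lo, jnt_hi, jnt_kd, jnt_klim, jnt_dlim,
    # controller
    ctrl_phases, G, A0, pref, klen, L0, rf_idx,
    thr_hip_up, thr_knee, thr_hip_ext,
    # cost
    a_thr, vcap, weights, k_fall, horizon_pen,
    # sim
    q0, qd0, dt, nsteps, rec_stride, alpha_f,
    fall_hip_y, fall_pitch,
    # outputs
    rec_t, rec_q, rec_qd, rec_act, rec_stim, rec_seatF, rec_groundF,
    rec_fb, rec_phase, phase_entry, cost_acc,
):
    """Simulate the reflex-controlled model; returns (n_rec, t_end, term_code).

    Records every rec_stride-th step. cost_acc has len(weights) + 1 slots; the
    last slot receives the early-termination penalty.
    """
    ndof = S.shape[1]
    C = fmax.shape[0]
    ncp = cp_radius.shape[0]
    q = q0.copy()
    qd = qd0.copy()
    qdd = np.zeros(ndof)
    act = np.full(C, a_min)
    stim = np.zeros(C)
    fb = np.zeros(N_FB)
    filt = np.zeros(4)
    LmL = np.zeros(C)
    VmL = np.zeros(C)
    LmR = np.zeros(C)
    VmR = np.zeros(C)
    Lm_mean = np.zeros(C)
    cforces = np.zeros((ncp, 3))
    phase = 1
    for i in range(4):
        phase_entry[i] = -1.0
    phase_entry[0] = 0.0
    term = TERM_COMPLETED
    n_rec = 0
    t = 0.0
    for step in range(nsteps):
        t = step * dt
        assemble_feedback(
            q, qd, qdd, S, ct_n, ct_b, ct_c, ct_d, pelvis_h,
            cp_n, cp_b, cp_c, cp_d, tal_n, tal_b, tal_c, tal_d,
            filt, alpha_f, fb,
        )
        new_phase = phase_transition(
            phase, fb, ctrl_phases, thr_hip_up, thr_knee, thr_hip_ext
        )
        if new_phase != phase:
            phase = new_phase
            phase_entry[phase - 1] = t
        # muscle state
        fiber_lengths(q, qd, 0, arms_ext, sexc, LmL, VmL)
        fiber_lengths(q, qd, 1, arms_ext, sexc, LmR, VmR)
        for m in range(C):
            Lm_mean[m] = 0.5 * (LmL[m] + LmR[m])
        stimulation_kernel(
            fb, Lm_mean, G, A0, pref, klen, L0, phase, ctrl_phases,
            rf_idx, a_min, stim,
        )
        for m in range(C):
            act[m] = activation_step(act[m], stim[m], dt, tau_act[m], tau_dea[m])
        # generalized forces
        Q = np.zeros(ndof)
        for m in range(C):
            fL = muscle_force_kernel(
                act[m], LmL[m], VmL[m], fmax[m], fl_gamma, vmax[m], fp_k
            )
            fR = muscle_force_kernel(
                act[m], LmR[m], VmR[m], fmax[m], fl_gamma, vmax[m], fp_k
            )
            for j in range(3):
                r = arms_ext[m, j]
                if r != 0.0:
                    Q[3 + j] -= r * fL
                    Q[6 + j] -= r * fR
        joint_passive_torques(q, qd, jnt_lo, jnt_hi, jnt_kd, jnt_klim, jnt_dlim, Q)
        contact_forces(
            q, qd, S, cp_n, cp_b, cp_c, cp_d, cp_body, cp_radius, cp_plane,
            seat_y, seat_xmin, seat_xmax, khc, chc, mu, veps, Q, cforces,
        )
        # cost increments
        if ctrl_phases == 4:
            cost_step_4p(fb, phase, dt, a_thr, vcap, weights, cost_acc)
        else:
            cost_step_2p(fb, phase, dt, a_thr, vcap, weights, cost_acc)
        # record
        if step % rec_stride == 0:
            rec_t[n_rec] = t
            for j in range(ndof):
                rec_q[n_rec, j] = q[j]
                rec_qd[n_rec, j] = qd[j]
            for m in range(C):
                rec_act[n_rec, m] = act[m]
                rec_stim[n_rec, m] = stim[m]
            rec_seatF[n_rec] = cforces[4, 0]
            rec_groundF[n_rec] = (
                cforces[0, 0] + cforces[1, 0] + cforces[2, 0] + cforces[3, 0]
            )
            for k in range(N_FB):
                rec_fb[n_rec, k] = fb[k]
            rec_phase[n_rec] = phase
            n_rec += 1
        # dynamics, reduced to the left/right-symmetric subspace (the
        # controller is symmetric, so the motion is too; projecting keeps the
        # two sides bitwise identical)
        M, hbias = dynamics_terms(q, qd, S, mass, inertia, ct_n, ct_b, ct_c, ct_d, g)
        rhs = Q - hbias
        Mr = np.zeros((6, 6))
        rr = np.zeros(6)
        for a in range(6):
            ia0 = a
            ia1 = a + 3 if a >= 3 else -1
            rr[a] = rhs[ia0] + (rhs[ia1] if ia1 >= 0 else 0.0)
            for bcol in range(6):
                jb0 = bcol
                jb1 = bcol + 3 if bcol >= 3 else -1
                v = M[ia0, jb0]
                if jb1 >= 0:
                    v += M[ia0, jb1]
                if ia1 >= 0:
                    v += M[ia1, jb0]
                    if jb1 >= 0:
                        v += M[ia1, jb1]
                Mr[a, bcol] = v
        udd = np.linalg.solve(Mr, rr)
        for j in range(3):
            qdd[j] = udd[j]
        for j in range(3, 6):
            qdd[j] = udd[j]
            qdd[j + 3] = udd[j]
        for j in range(ndof):
            # kick, then drift with the velocity midpoint (2nd-order positions)
            q[j] += dt * (qd[j] + 0.5 * dt * qdd[j])
            qd[j] += dt * qdd[j]
        # divergence / fall checks
        bad = False
        for j in range(ndof):
            if not (-1.0e6 < q[j] < 1.0e6) or not (-1.0e4 < qd[j] < 1.0e4):
                bad = True
        if bad:
            term = TERM_DIVERGED
            t = t + dt
            break
        if q[1] < fall_hip_y or abs(q[2]) > fall_pitch:
            term = TERM_FELL
            t = t + dt
            break
    if term != TERM_COMPLETED:
        remaining = horizon_pen - t
        if remaining < 0.0:
            remaining = 0.0
        cost_acc[len(weights)] += k_fall * remaining
    return n_rec, t, term
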