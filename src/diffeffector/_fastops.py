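"""Fused graph nodes with hand-derived backward passes.

These are pure performance shortcuts used inside the per-timestep hot
loop; each is mathematically identical to a composition of primitive
:mod:`diffeffector.autodiff` ops (the test suite asserts the
equivalence) but creates a single graph node instead of dozens.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, as_tensor, data_of, is_tensor


def fused_arm_kinematics(q, qdot, l1: float, l2: float):
    """Endpoint [px, py, vx, vy] of the two-link arm as one node."""
    qd = data_of(q)
    qdd = data_of(qdot)
    q1, q2 = qd[..., 0], qd[..., 1]
    qd1, qd2 = qdd[..., 0], qdd[..., 1]
    s1, c1 = np.sin(q1), np.cos(q1)
    s12, c12 = np.sin(q1 + q2), np.cos(q1 + q2)
    j11 = -(l1 * s1 + l2 * s12)
    j12 = -l2 * s12
    j21 = l1 * c1 + l2 * c12
    j22 = l2 * c12
    px = j21  # l1*c1 + l2*c12
    py = l1 * s1 + l2 * s12
    vx = j11 * qd1 + j12 * qd2
    vy = j21 * qd1 + j22 * qd2
    out = np.stack([px, py, vx, vy], axis=-1)
    if not (is_tensor(q) or is_tensor(qdot)):
        return out
    q, qdot = as_tensor(q), as_tensor(qdot)

    def backward(g):
        gpx, gpy, gvx, gvy = g[..., 0], g[..., 1], g[..., 2], g[..., 3]
        if q.requires_grad:
            qdsum = qd1 + qd2
            gq1 = gpx * j11 + gpy * j21 - gvx * vy + gvy * vx
            gq2 = (gpx * j12 + gpy * j22
                   + qdsum * (-gvx * j22 + gvy * j12))
            q._accumulate(np.stack([gq1, gq2], axis=-1))
        if qdot.requires_grad:
            gqd1 = gvx * j11 + gvy * j21
            gqd2 = gvx * j12 + gvy * j22
            qdot._accumulate(np.stack([gqd1, gqd2], axis=-1))

    return Tensor(out, _parents=(q, qdot), _backward=backward)


def fused_two_link_dynamics(q, qdot, torque, params):
    """Joint accelerations of the planar two-link chain as one node
    (same math as :func:`diffeffector.core_kinematics.two_link_dynamics`)."""
    qd_ = data_of(q)
    qdd_ = data_of(qdot)
    tau_ = data_of(torque)
    m1, m2 = params.masses
    lc1, lc2 = params.cog
    i1, i2 = params.inertias
    l1 = params.lengths[0]
    Bv = params.viscosity
    q2 = qd_[..., 1]
    qd1, qd2 = qdd_[..., 0], qdd_[..., 1]
    t1, t2 = tau_[..., 0], tau_[..., 1]
    e = i2 + m2 * lc2 * lc2
    a = i1 + e + m1 * lc1 * lc1 + m2 * l1 * l1
    b = m2 * l1 * lc2
    c2, s2 = np.cos(q2), np.sin(q2)
    m11 = a + 2.0 * b * c2
    m12 = e + b * c2
    m22 = e
    h = b * s2
    rhs1 = t1 + h * qd2 * (2.0 * qd1 + qd2) - Bv[0, 0] * qd1 - Bv[0, 1] * qd2
    rhs2 = t2 - h * qd1 * qd1 - Bv[1, 0] * qd1 - Bv[1, 1] * qd2
    det = m11 * m22 - m12 * m12
    qdd1 = (m22 * rhs1 - m12 * rhs2) / det
    qdd2 = (m11 * rhs2 - m12 * rhs1) / det
    out = np.stack([qdd1, qdd2], axis=-1)
    if not (is_tensor(q) or is_tensor(qdot) or is_tensor(torque)):
        return out
    q_t, qd_t, tau_t = as_tensor(q), as_tensor(qdot), as_tensor(torque)

    def backward(g):
        g1, g2 = g[..., 0], g[..., 1]
        if tau_t.requires_grad:
            gt1 = (g1 * m22 - g2 * m12) / det
            gt2 = (-g1 * m12 + g2 * m11) / det
            tau_t._accumulate(np.stack([gt1, gt2], axis=-1))
        if qd_t.requires_grad:
            dr1_d1 = 2.0 * h * qd2 - Bv[0, 0]
            dr1_d2 = 2.0 * h * (qd1 + qd2) - Bv[0, 1]
            dr2_d1 = -2.0 * h * qd1 - Bv[1, 0]
            dr2_d2 = -Bv[1, 1]
            gqd1 = (g1 * (m22 * dr1_d1 - m12 * dr2_d1)
                    + g2 * (m11 * dr2_d1 - m12 * dr1_d1)) / det
            gqd2 = (g1 * (m22 * dr1_d2 - m12 * dr2_d2)
                    + g2 * (m11 * dr2_d2 - m12 * dr1_d2)) / det
            qd_t._accumulate(np.stack([gqd1, gqd2], axis=-1))
        if q_t.requires_grad:
            dm11 = -2.0 * b * s2
            dm12 = -b * s2
            ddet = dm11 * m22 - 2.0 * m12 * dm12
            dh = b * c2
            dr1 = dh * qd2 * (2.0 * qd1 + qd2)
            dr2 = -dh * qd1 * qd1
            dq2_1 = ((m22 * dr1 - dm12 * rhs2 - m12 * dr2) - qdd1 * ddet) / det
            dq2_2 = ((dm11 * rhs2 + m11 * dr2 - dm12 * rhs1 - m12 * dr1)
                     - qdd2 * ddet) / det
            gq2 = g1 * dq2_1 + g2 * dq2_2
            q_t._accumulate(np.stack([np.zeros_like(gq2), gq2], axis=-1))

    return Tensor(out, _parents=(q_t, qd_t, tau_t), _backward=backward)


def fused_activation_step(action, a_prev, dt: float, tau_act: np.ndarray,
                          tau_deact: np.ndarray):
    """One Euler step of the first-order activation ODE with
    activation-scaled time constants, clipped to [0, 1]."""
    u_raw = data_of(action)
    a = data_of(a_prev)
    u = np.clip(u_raw, 0.0, 1.0)
    rising = u > a
    scale = 0.5 + 1.5 * a
    tau = np.where(rising, tau_act * scale, tau_deact / scale)
    raw = a + dt * (u - a) / tau
    out = np.clip(raw, 0.0, 1.0)
    if not (is_tensor(action) or is_tensor(a_prev)):
        return out
    action_t = as_tensor(action)
    a_prev_t = as_tensor(a_prev)
    in_range = (raw >= 0.0) & (raw <= 1.0)
    u_in = (u_raw >= 0.0) & (u_raw <= 1.0)

    def backward(g):
        gi = g * in_range
        if action_t.requires_grad:
            action_t._accumulate(gi * u_in * dt / tau)
        if a_prev_t.requires_grad:
            # tau depends on a through the activation-level scaling
            d_rising = (-tau - (u - a) * tau_act * 1.5) / (tau * tau)
            d_falling = (-scale + (u - a) * 1.5) / tau_deact
            a_prev_t._accumulate(gi * (1.0 + dt * np.where(rising, d_rising, d_falling)))

    return Tensor(out, _parents=(action_t, a_prev_t), _backward=backward)


def fused_gru_gates(xx, hx, h, n: int):
    """GRU gate nonlinearity as one node.

    ``xx = obs @ Wx + b`` and ``hx = h @ Wh`` hold the reset/update/
    candidate blocks side by side; returns the new hidden state
    ``(1 - z) * tanh(xx_n + r * hx_n) + z * h``.
    """
    xxd, hxd, hd = data_of(xx), data_of(hx), data_of(h)
    r = 1.0 / (1.0 + np.exp(-(xxd[..., 0:n] + hxd[..., 0:n])))
    z = 1.0 / (1.0 + np.exp(-(xxd[..., n:2 * n] + hxd[..., n:2 * n])))
    hxn = hxd[..., 2 * n:]
    cand = np.tanh(xxd[..., 2 * n:] + r * hxn)
    out = (1.0 - z) * cand + z * hd
    if not (is_tensor(xx) or is_tensor(hx) or is_tensor(h)):
        return out
    xx_t, hx_t, h_t = as_tensor(xx), as_tensor(hx), as_tensor(h)

    def backward(g):
        gz = g * (hd - cand) * z * (1.0 - z)
        gn = g * (1.0 - z) * (1.0 - cand * cand)
        gr = gn * hxn * r * (1.0 - r)
        if xx_t.requires_grad:
            xx_t._accumulate(np.concatenate([gr, gz, gn], axis=-1))
        if hx_t.requires_grad:
            hx_t._accumulate(np.concatenate([gr, gz, gn * r], axis=-1))
        if h_t.requires_grad:
            h_t._accumulate(g * z)

    return Tensor(out, _parents=(xx_t, hx_t, h_t), _backward=backward)


def fused_hill_force(lnorm, vnorm, activation, fmax: np.ndarray,
                     fl_gamma: np.ndarray, pas_k: np.ndarray, pas_eps: np.ndarray,
                     pas_slack: np.ndarray, fv_af: np.ndarray, fv_flen: np.ndarray,
                     passive_enabled: bool = True):
    """``fmax * max(clip(a) * FL(l) * FV(v) + FP(l), 0)`` as one node."""
    l = data_of(lnorm)
    v = data_of(vnorm)
    a_raw = data_of(activation)
    a = np.clip(a_raw, 0.0, 1.0)
    # active force-length (Gaussian)
    d = l - 1.0
    fl = np.exp(-(d * d) / fl_gamma)
    dfl = fl * (-2.0 * d / fl_gamma)
    # force-velocity
    neg = v <= 0.0
    vs = np.minimum(v, 0.0)
    denom = 1.0 - vs / fv_af
    short = np.maximum((1.0 + v) / denom, 0.0)
    dshort = np.where(short > 0.0, (1.0 + 1.0 / fv_af) / (denom * denom), 0.0)
    c = np.maximum(v, 0.0) * (2.0 + 2.0 / fv_af) / (fv_flen - 1.0)
    lng = (1.0 + c * fv_flen) / (1.0 + c)
    dlng = (2.0 + 2.0 / fv_af) / ((1.0 + c) * (1.0 + c))
    fv = np.where(neg, short, lng)
    dfv = np.where(neg, dshort, dlng)
    # passive
    if passive_enabled:
        expo = np.exp(pas_k * (l - pas_slack) / pas_eps)
        denom_p = np.exp(pas_k) - 1.0
        fp_raw = (expo - 1.0) / denom_p
        fp = np.maximum(fp_raw, 0.0)
        dfp = np.where(fp_raw > 0.0, (pas_k / pas_eps) * expo / denom_p, 0.0)
    else:
        fp = 0.0
        dfp = 0.0
    total = a * fl * fv + fp
    pos = total > 0.0
    out = fmax * np.maximum(total, 0.0)
    if not (is_tensor(lnorm) or is_tensor(vnorm) or is_tensor(activation)):
        return out
    l_t, v_t, a_t = as_tensor(lnorm), as_tensor(vnorm), as_tensor(activation)

    def backward(g):
        gp = g * fmax * pos
        if a_t.requires_grad:
            a_in = (a_raw >= 0.0) & (a_raw <= 1.0)
            a_t._accumulate(gp * fl * fv * a_in)
        if l_t.requires_grad:
            l_t._accumulate(gp * (a * dfl * fv + dfp))
        if v_t.requires_grad:
            v_t._accumulate(gp * (a * fl * dfv))

    return Tensor(out, _parents=(l_t, v_t, a_t), _backward=backward)
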