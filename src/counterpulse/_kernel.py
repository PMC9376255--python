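"""Fixed-step RK4 kernel for the closed-loop model.

The system is an ODE in (chamber volumes, valve opening states, transvalvular
flows, terminal capacitor pressures, device pocket volume); node pressures
and branch flows of the rigid resistive tree are solved algebraically inside
the right-hand side through precomputed affine maps:

    [p_root, p_device_node, p_outlet_1..nt] =
        A8 @ p_cap + b_av * Q_AV + b_dev * q_dev

Transvalvular flow carries the blood-column inertance of the orifice
(Mynard-type valve): L·dQ/dt = dp − (b/s²)·Q·|Q|, with the flow relaxed
exponentially to zero while the opening state sits below a small gate (a
closed valve passes no flow; the gate also bounds the stiffness of the
orifice term).  The device flow is eliminated linearly, so no iteration is
needed per step.  The kernel is compiled with numba when available; the
identical code runs as plain Python otherwise.
"""

import math

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap


#: state layout: [V_LA, V_LV, s_MV, s_AV, Q_MV, Q_AV, p_cap * nt, x_dev]
N_HEAD = 6

#: auxiliary layout: [P_LA, P_LV, p_root, p_nd, q_dev, p_sr, p_ven, Q_ven]
#:                   + p_out*nt + q_term*nt
N_AUX_HEAD = 8


@njit(cache=True)
def _activation(tc, t_onset, t_sys, peak_frac, rise_power, T):
    rel = (tc - t_onset) % T
    if rel < 0.0:
        rel += T
    if rel > t_sys:
        return 0.0
    tp = peak_frac * t_sys
    if rel <= tp:
        e = 0.5 * (1.0 - math.cos(math.pi * rel / tp))
        if rise_power != 1.0:
            e = e ** rise_power
        return e
    return 0.5 * (1.0 + math.cos(math.pi * (rel - tp) / (t_sys - tp)))


@njit(cache=True)
def _rhs(t, y, dy, aux, T, lv, la, mv, av, A8, b_av, b_dev,
         Rp, Rd, Cc, R_ven, dev, gc, pa_mean):
    # chamber param layout: [A_pas, B_pas, V0, E_act, t_onset, t_sys, peak_frac, rise_power]
    # valve param layout:   [K_open, K_close, bernoulli, L, gate, tau]
    # dev layout: [active, lam, C_sr, R_sr, p_act, dt_act, t_on, t_off, k1, k2, p_ref]
    nt = Rp.shape[0]
    V_LA = y[0]
    V_LV = y[1]
    sMV = y[2]
    sAV = y[3]
    Qmv = y[4]
    Qav = y[5]
    x = y[N_HEAD + nt]
    tc = t % T

    e_la = _activation(tc, la[4], la[5], la[6], la[7], T)
    e_lv = _activation(tc, lv[4], lv[5], lv[6], lv[7], T)
    P_LA = la[0] * (math.exp(la[1] * (V_LA - la[2])) - 1.0) + e_la * la[3] * (V_LA - la[2])
    P_LV = lv[0] * (math.exp(lv[1] * (V_LV - lv[2])) - 1.0) + e_lv * lv[3] * (V_LV - lv[2])

    # device pressure source at the current normalized actuation time
    active = dev[0] > 0.5
    p_sr = 0.0
    if active:
        tn = t - math.floor((t - dev[5]) / T) * T - dev[5]
        g = gc[0] * pa_mean * pa_mean + gc[1] * pa_mean + gc[2] * dev[4] + gc[3] \
            + gc[4] * pa_mean * dev[4]
        if g < 0.0:
            g = 0.0
        elif g > 1.0 - 1e-9:
            g = 1.0 - 1e-9
        if tn <= dev[6]:
            p_sr = g * pa_mean * (1.0 - math.exp(-dev[8] * tn))
        elif tn <= dev[7]:
            p_on = g * pa_mean * (1.0 - math.exp(-dev[8] * dev[6]))
            e2 = math.exp(-dev[9] * (dev[7] - dev[6]))
            p_sr = (p_on / (1.0 - e2)) * math.exp(-dev[9] * (tn - dev[6])) \
                - p_on * e2 / (1.0 - e2)

    # linear device-flow elimination (q_dev is the flow injected at the node)
    a_r = 0.0
    a_d = 0.0
    for i in range(nt):
        a_r += A8[0, i] * y[N_HEAD + i]
        a_d += A8[1, i] * y[N_HEAD + i]
    if active:
        q_dev = (dev[10] + dev[1] * p_sr + x / dev[2] - a_d - b_av[1] * Qav) \
            / (dev[3] + b_dev[1])
    else:
        q_dev = 0.0

    p_root = a_r + b_av[0] * Qav + b_dev[0] * q_dev
    p_nd = a_d + b_av[1] * Qav + b_dev[1] * q_dev

    # venous node (no storage): collects all distal Windkessel flows into LA
    num = P_LA / R_ven
    den = 1.0 / R_ven
    for i in range(nt):
        num += y[N_HEAD + i] / Rd[i]
        den += 1.0 / Rd[i]
    p_ven = num / den
    Qven = (p_ven - P_LA) / R_ven

    # valve dynamics: opening state driven by the transvalvular gradient,
    # flow carrying the orifice blood-column inertance
    dpm = P_LA - P_LV
    dpa = P_LV - p_root

    if dpm > 0.0:
        dy[2] = (1.0 - sMV) * mv[0] * dpm
    else:
        dy[2] = sMV * mv[1] * dpm
    if dpa > 0.0:
        dy[3] = (1.0 - sAV) * av[0] * dpa
    else:
        dy[3] = sAV * av[1] * dpa

    if sMV > mv[4]:
        dy[4] = (dpm - mv[2] / (sMV * sMV) * Qmv * abs(Qmv)) / mv[3]
    else:
        dy[4] = -Qmv / mv[5]
    if sAV > av[4]:
        dy[5] = (dpa - av[2] / (sAV * sAV) * Qav * abs(Qav)) / av[3]
    else:
        dy[5] = -Qav / av[5]

    # derivatives of volumes and capacitor pressures
    dy[0] = Qven - Qmv
    dy[1] = Qmv - Qav

    for i in range(nt):
        p_out = b_av[2 + i] * Qav + b_dev[2 + i] * q_dev
        for j in range(nt):
            p_out += A8[2 + i, j] * y[N_HEAD + j]
        q_term = (p_out - y[N_HEAD + i]) / Rp[i]
        dy[N_HEAD + i] = (q_term - (y[N_HEAD + i] - p_ven) / Rd[i]) / Cc[i]
        aux[N_AUX_HEAD + i] = p_out
        aux[N_AUX_HEAD + nt + i] = q_term

    if active:
        dy[N_HEAD + nt] = -q_dev
    else:
        dy[N_HEAD + nt] = 0.0

    aux[0] = P_LA
    aux[1] = P_LV
    aux[2] = p_root
    aux[3] = p_nd
    aux[4] = q_dev
    aux[5] = p_sr
    aux[6] = p_ven
    aux[7] = Qven


@njit(cache=True)
def run_fixed_step(y0, n_steps, dt, T, lv, la, mv, av, A8, b_av, b_dev,
                   Rp, Rd, Cc, R_ven, dev, gc, pa_mean0, rec_stride, out):
    """Integrate n_steps of RK4, recording every rec_stride steps.

    Returns -1 on success, else the index of the first step at which the
    state became non-finite.  The mean aortic-root pressure driving the
    device source is re-estimated at each completed cycle from the running
    cycle average (bench characterization used a static loop pressure).
    """
    n = y0.shape[0]
    nt = Rp.shape[0]
    y = y0.copy()
    k1 = np.empty(n)
    k2 = np.empty(n)
    k3 = np.empty(n)
    k4 = np.empty(n)
    yt = np.empty(n)
    aux = np.empty(N_AUX_HEAD + 2 * nt)

    pa_mean = pa_mean0
    psum = 0.0
    pcnt = 0
    cyc = 0
    rec = 0

    for step in range(n_steps + 1):
        t = step * dt
        _rhs(t, y, k1, aux, T, lv, la, mv, av, A8, b_av, b_dev,
             Rp, Rd, Cc, R_ven, dev, gc, pa_mean)

        if step % rec_stride == 0 or step == n_steps:
            out[rec, 0] = t
            out[rec, 1] = y[0]
            out[rec, 2] = y[1]
            out[rec, 3] = aux[0]
            out[rec, 4] = aux[1]
            out[rec, 5] = y[2]
            out[rec, 6] = y[3]
            out[rec, 7] = y[4]
            out[rec, 8] = y[5]
            out[rec, 9] = aux[2]
            out[rec, 10] = aux[3]
            out[rec, 11] = aux[4]
            out[rec, 12] = y[N_HEAD + nt]
            out[rec, 13] = aux[5]
            out[rec, 14] = aux[6]
            out[rec, 15] = aux[7]
            for i in range(nt):
                out[rec, 16 + i] = y[N_HEAD + i]
                out[rec, 16 + nt + i] = aux[N_AUX_HEAD + nt + i]
                out[rec, 16 + 2 * nt + i] = aux[N_AUX_HEAD + i]
            rec += 1

        if step == n_steps:
            break

        psum += aux[2]
        pcnt += 1

        half = 0.5 * dt
        for i in range(n):
            yt[i] = y[i] + half * k1[i]
        _rhs(t + half, yt, k2, aux, T, lv, la, mv, av, A8, b_av, b_dev,
             Rp, Rd, Cc, R_ven, dev, gc, pa_mean)
        for i in range(n):
            yt[i] = y[i] + half * k2[i]
        _rhs(t + half, yt, k3, aux, T, lv, la, mv, av, A8, b_av, b_dev,
             Rp, Rd, Cc, R_ven, dev, gc, pa_mean)
        for i in range(n):
            yt[i] = y[i] + dt * k3[i]
        _rhs(t + dt, yt, k4, aux, T, lv, la, mv, av, A8, b_av, b_dev,
             Rp, Rd, Cc, R_ven, dev, gc, pa_mean)
        for i in range(n):
            y[i] = y[i] + dt / 6.0 * (k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i])

        # valve states are invariant in [0,1]; clip discrete round-off
        if y[2] < 0.0:
            y[2] = 0.0
        elif y[2] > 1.0:
            y[2] = 1.0
        if y[3] < 0.0:
            y[3] = 0.0
        elif y[3] > 1.0:
            y[3] = 1.0

        ok = True
        for i in range(n):
            if not math.isfinite(y[i]):
                ok = False
        if not ok:
            return step

        # cycle boundary: refresh the device's loop-pressure estimate
        new_cyc = int(math.floor(((step + 1) * dt) / T + 1e-9))
        if new_cyc > cyc:
            cyc = new_cyc
            if pcnt > 0:
                pa_mean = psum / pcnt
            psum = 0.0
            pcnt = 0

    return -1
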