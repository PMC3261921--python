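"""Numba-compiled fixed-step RK4 integration kernels.

The kernels operate on a flat float64 parameter vector ``P`` (see index
constants below) so a single compiled signature serves every scenario:
bare membrane, X conductance, background synaptic noise, and the plasticity
loop with calcium and kinase/phosphatase dynamics.

Voltage-dependent gate curves (steady states and time constants) are
pre-tabulated on a fine voltage grid and linearly interpolated inside the
inner loop; this removes ~30 exp() calls per RK4 step and is the main
performance lever.
"""
import numpy as np
from numba import njit

# parameter-vector indices
P_C, P_GL, P_EL = 0, 1, 2
P_GNA, P_ENA, P_GK, P_EK, P_PHI = 3, 4, 5, 6, 7
P_GX, P_XP, P_XVH, P_XK, P_XTAU, P_HASINACT, P_XIVH, P_XIK, P_XITAU, P_EX, P_XINST = \
    8, 9, 10, 11, 12, 13, 14, 15, 16, 17, 18
P_I = 19
P_RATE_E, P_JUMP_E, P_TAU_E, P_E_E = 20, 21, 22, 23
P_RATE_I, P_JUMP_I, P_TAU_I, P_E_I = 24, 25, 26, 27
P_USE_NOISE = 28
P_USE_LOOP, P_GCAL, P_UVH, P_UK, P_UTAU, P_ECA, P_CAB, P_TAUCA, P_CAFAC = \
    29, 30, 31, 32, 33, 34, 35, 36, 37
P_VK, P_VP, P_KK, P_KP, P_NH, P_GSUP = 38, 39, 40, 41, 42, 43
NPARAMS = 44

# gate-table rows
T_MINF, T_HINF, T_HTAU, T_NINF, T_NTAU, T_XINF, T_XIINF, T_UINF = range(8)
NTABS = 8
TAB_V0 = -150.0
TAB_V1 = 80.0
TAB_DV = 0.01

SPIKE_DETECT_V = 0.0     # mV, upward-crossing detection level
REFRACTORY_MS = 2.0


@njit(cache=True)
def sigmoid(z):
    if z > 35.0:
        return 1.0
    if z < -35.0:
        return 0.0
    return 1.0 / (1.0 + np.exp(-z))


@njit(cache=True)
def _m_inf(V):
    # fast sodium activation, instantaneous
    dv = V + 35.0
    if abs(dv) < 1e-7:
        am = 1.0
    else:
        am = 0.1 * dv / (1.0 - np.exp(-dv / 10.0))
    bm = 4.0 * np.exp(-(V + 60.0) / 18.0)
    return am / (am + bm)


@njit(cache=True)
def _h_rates(V):
    ah = 0.07 * np.exp(-(V + 58.0) / 20.0)
    bh = 1.0 / (1.0 + np.exp(-(V + 28.0) / 10.0))
    return ah, bh


@njit(cache=True)
def _n_rates(V):
    dv = V + 34.0
    if abs(dv) < 1e-7:
        an = 0.1
    else:
        an = 0.01 * dv / (1.0 - np.exp(-dv / 10.0))
    bn = 0.125 * np.exp(-(V + 44.0) / 80.0)
    return an, bn


@njit(cache=True)
def build_tables(P):
    """Tabulate gate curves for the parameter vector on the fixed V grid."""
    n = int(round((TAB_V1 - TAB_V0) / TAB_DV)) + 2
    T = np.empty((NTABS, n))
    phi = P[P_PHI]
    for i in range(n):
        V = TAB_V0 + i * TAB_DV
        T[T_MINF, i] = _m_inf(V)
        ah, bh = _h_rates(V)
        T[T_HINF, i] = ah / (ah + bh)
        T[T_HTAU, i] = 1.0 / (phi * (ah + bh))
        an, bn = _n_rates(V)
        T[T_NINF, i] = an / (an + bn)
        T[T_NTAU, i] = 1.0 / (phi * (an + bn))
        T[T_XINF, i] = sigmoid((V - P[P_XVH]) / P[P_XK])
        T[T_XIINF, i] = sigmoid((V - P[P_XIVH]) / P[P_XIK]) \
            if P[P_HASINACT] != 0.0 else 1.0
        T[T_UINF, i] = sigmoid((V - P[P_UVH]) / P[P_UK])
    return T


@njit(cache=True, inline="always")
def _ipow(base, p):
    if p == 1:
        return base
    if p == 2:
        return base * base
    if p == 3:
        return base * base * base
    return (base * base) * (base * base)


@njit(cache=True)
def _akp_rates(Ca, vK, vP, KK, KP, nH):
    """Hill-activated kinase/phosphatase macroscopic rates (ms^-1)."""
    cK = (Ca / KK) ** nH
    cP = (Ca / KP) ** nH
    RK = vK * cK / (1.0 + cK)
    RP = vP * cP / (1.0 + cP)
    return RK, RP


@njit(cache=True, fastmath=True, inline="always")
def _deriv(V, h, n, x, xi, u, Ca, fphi, ge, gi, P, T, xp):
    """Time derivatives of the full state; unused blocks return 0."""
    # table lookup with linear interpolation, clamped to the grid
    pos = (V - TAB_V0) / TAB_DV
    if pos < 0.0:
        pos = 0.0
    elif pos > T.shape[1] - 2:
        pos = float(T.shape[1] - 2)
    i0 = int(pos)
    w = pos - i0
    m = T[T_MINF, i0] + w * (T[T_MINF, i0 + 1] - T[T_MINF, i0])
    h_inf = T[T_HINF, i0] + w * (T[T_HINF, i0 + 1] - T[T_HINF, i0])
    h_tau = T[T_HTAU, i0] + w * (T[T_HTAU, i0 + 1] - T[T_HTAU, i0])
    n_inf = T[T_NINF, i0] + w * (T[T_NINF, i0 + 1] - T[T_NINF, i0])
    n_tau = T[T_NTAU, i0] + w * (T[T_NTAU, i0 + 1] - T[T_NTAU, i0])
    x_inf = T[T_XINF, i0] + w * (T[T_XINF, i0 + 1] - T[T_XINF, i0])

    dh = (h_inf - h) / h_tau
    dn = (n_inf - n) / n_tau

    I_Na = P[P_GNA] * m * m * m * h * (V - P[P_ENA])
    I_K = P[P_GK] * (n * n) * (n * n) * (V - P[P_EK])
    I_L = P[P_GL] * (V - P[P_EL])

    # X conductance
    gx = P[P_GSUP] * fphi if P[P_USE_LOOP] != 0.0 else P[P_GX]
    if P[P_XINST] != 0.0:
        xg = x_inf
        dx = 0.0
    else:
        xg = x
        dx = (x_inf - x) / P[P_XTAU]
    if P[P_HASINACT] != 0.0:
        xi_inf = T[T_XIINF, i0] + w * (T[T_XIINF, i0 + 1] - T[T_XIINF, i0])
        dxi = (xi_inf - xi) / P[P_XITAU]
        gate = _ipow(xg, xp) * xi
    else:
        dxi = 0.0
        gate = _ipow(xg, xp)
    I_X = gx * gate * (V - P[P_EX])

    I_CaL = 0.0
    du = 0.0
    dCa = 0.0
    dfphi = 0.0
    if P[P_USE_LOOP] != 0.0:
        u_inf = T[T_UINF, i0] + w * (T[T_UINF, i0 + 1] - T[T_UINF, i0])
        du = (u_inf - u) / P[P_UTAU]
        I_CaL = P[P_GCAL] * u * u * (V - P[P_ECA])
        # inward (negative) I_CaL raises Ca; P_CAFAC converts µA/cm² to µM/ms
        dCa = -P[P_CAFAC] * I_CaL + (P[P_CAB] - Ca) / P[P_TAUCA]
        RK, RP = _akp_rates(Ca, P[P_VK], P[P_VP], P[P_KK], P[P_KP], P[P_NH])
        dfphi = RK * (1.0 - fphi) - RP * fphi

    I_syn = 0.0
    if P[P_USE_NOISE] != 0.0:
        I_syn = ge * (V - P[P_E_E]) + gi * (V - P[P_E_I])

    dV = (P[P_I] - I_L - I_Na - I_K - I_X - I_CaL - I_syn) / P[P_C]
    return dV, dh, dn, dx, dxi, du, dCa, dfphi


@njit(cache=True)
def steady_gates(V, P):
    """Exact steady-state values of h, n, x, xi, u at potential V."""
    ah, bh = _h_rates(V)
    an, bn = _n_rates(V)
    h = ah / (ah + bh)
    n = an / (an + bn)
    x = sigmoid((V - P[P_XVH]) / P[P_XK])
    xi = sigmoid((V - P[P_XIVH]) / P[P_XIK]) if P[P_HASINACT] != 0.0 else 1.0
    u = sigmoid((V - P[P_UVH]) / P[P_UK])
    return h, n, x, xi, u


@njit(cache=True, fastmath=True)
def run_model(P, T, dt, n_steps, V0, fphi0, seed, record_every, max_spikes,
              spike_cap):
    """Integrate the model with fixed-step RK4.

    Returns (rec, spikes, n_spikes, status, t_end, final_state) where
    ``rec`` has columns [V, x, h, n, xi, Ca, fphi] sampled every
    ``record_every`` steps (row 0 = initial state) and status is
    0 = completed, 1 = stopped at max_spikes, 2 = non-finite state.
    """
    np.random.seed(seed)
    h, n, x, xi, u = steady_gates(V0, P)
    V = V0
    Ca = P[P_CAB]
    fphi = fphi0
    ge = 0.0
    gi = 0.0
    xp = int(P[P_XP])

    n_rec = n_steps // record_every + 1
    rec = np.empty((n_rec, 7))
    spikes = np.empty(spike_cap)
    n_spk = 0
    rec[0, 0] = V
    rec[0, 1] = x
    rec[0, 2] = h
    rec[0, 3] = n
    rec[0, 4] = xi
    rec[0, 5] = Ca
    rec[0, 6] = fphi
    irec = 1

    use_noise = P[P_USE_NOISE] != 0.0
    lam_e = P[P_RATE_E] * dt
    lam_i = P[P_RATE_I] * dt
    dec_e = np.exp(-dt / P[P_TAU_E]) if use_noise else 1.0
    dec_i = np.exp(-dt / P[P_TAU_I]) if use_noise else 1.0

    last_spike = -1e9
    status = 0
    t = 0.0
    for step in range(1, n_steps + 1):
        Vp = V
        # RK4 on the smooth part; synaptic conductances decay analytically
        d1 = _deriv(V, h, n, x, xi, u, Ca, fphi, ge, gi, P, T, xp)
        d2 = _deriv(V + 0.5 * dt * d1[0], h + 0.5 * dt * d1[1],
                    n + 0.5 * dt * d1[2], x + 0.5 * dt * d1[3],
                    xi + 0.5 * dt * d1[4], u + 0.5 * dt * d1[5],
                    Ca + 0.5 * dt * d1[6], fphi + 0.5 * dt * d1[7],
                    ge, gi, P, T, xp)
        d3 = _deriv(V + 0.5 * dt * d2[0], h + 0.5 * dt * d2[1],
                    n + 0.5 * dt * d2[2], x + 0.5 * dt * d2[3],
                    xi + 0.5 * dt * d2[4], u + 0.5 * dt * d2[5],
                    Ca + 0.5 * dt * d2[6], fphi + 0.5 * dt * d2[7],
                    ge, gi, P, T, xp)
        d4 = _deriv(V + dt * d3[0], h + dt * d3[1], n + dt * d3[2],
                    x + dt * d3[3], xi + dt * d3[4], u + dt * d3[5],
                    Ca + dt * d3[6], fphi + dt * d3[7], ge, gi, P, T, xp)
        V = V + dt / 6.0 * (d1[0] + 2.0 * d2[0] + 2.0 * d3[0] + d4[0])
        h = h + dt / 6.0 * (d1[1] + 2.0 * d2[1] + 2.0 * d3[1] + d4[1])
        n = n + dt / 6.0 * (d1[2] + 2.0 * d2[2] + 2.0 * d3[2] + d4[2])
        x = x + dt / 6.0 * (d1[3] + 2.0 * d2[3] + 2.0 * d3[3] + d4[3])
        xi = xi + dt / 6.0 * (d1[4] + 2.0 * d2[4] + 2.0 * d3[4] + d4[4])
        u = u + dt / 6.0 * (d1[5] + 2.0 * d2[5] + 2.0 * d3[5] + d4[5])
        Ca = Ca + dt / 6.0 * (d1[6] + 2.0 * d2[6] + 2.0 * d3[6] + d4[6])
        fphi = fphi + dt / 6.0 * (d1[7] + 2.0 * d2[7] + 2.0 * d3[7] + d4[7])

        # clamp gating variables against round-off excursions
        if x < 0.0:
            x = 0.0
        elif x > 1.0:
            x = 1.0
        if fphi < 0.0:
            fphi = 0.0
        elif fphi > 1.0:
            fphi = 1.0

        if use_noise:
            ge *= dec_e
            gi *= dec_i
            ne = np.random.poisson(lam_e)
            ni = np.random.poisson(lam_i)
            if ne > 0:
                ge += ne * P[P_JUMP_E]
            if ni > 0:
                gi += ni * P[P_JUMP_I]

        t = step * dt
        if not np.isfinite(V):
            status = 2
            break

        if Vp < SPIKE_DETECT_V <= V and (t - last_spike) > REFRACTORY_MS:
            ts = t - dt + dt * (SPIKE_DETECT_V - Vp) / (V - Vp)
            if n_spk < spike_cap:
                spikes[n_spk] = ts
            n_spk += 1
            last_spike = ts

        if step % record_every == 0 and irec < n_rec:
            rec[irec, 0] = V
            rec[irec, 1] = x
            rec[irec, 2] = h
            rec[irec, 3] = n
            rec[irec, 4] = xi
            rec[irec, 5] = Ca
            rec[irec, 6] = fphi
            irec += 1

        if max_spikes > 0 and n_spk >= max_spikes:
            status = 1
            break

    final = np.empty(8)
    final[0] = V
    final[1] = h
    final[2] = n
    final[3] = x
    final[4] = xi
    final[5] = u
    final[6] = Ca
    final[7] = fphi
    return rec[:irec], spikes[:min(n_spk, spike_cap)], n_spk, status, t, final


# ---------------------------------------------------------------------------
# Reduced integrate-and-fire kernel (membrane + X activation only).
# theory codes: 0 threshold (instantaneous x), 1 pre-spike buildup,
# 2 post-spike relaxation (activation a pure function of time),
# 3 pre/post (relaxation early in the ISI, buildup near threshold).
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=True, inline="always")
def _iaf_deriv(theory, V, x, C, gL, EL, gx, p, xVh, xk, xtau, EX, I, x_r):
    x_inf = sigmoid((V - xVh) / xk)
    if theory == 0:
        xg = x_inf
        dx = 0.0
    elif theory == 2:
        xg = x
        dx = (x_r - x) / xtau      # pure-time relaxation toward ISI level
    else:
        xg = x
        dx = (x_inf - x) / xtau    # buildup/relaxation toward local target
    dV = (I - gL * (V - EL) - gx * _ipow(xg, p) * (V - EX)) / C
    return dV, dx


@njit(cache=True, fastmath=True)
def iaf_isi(theory, C, gL, EL, gx, p, xVh, xk, xtau, EX, I,
            V_r, V_s, load_A, load_B, dt, max_ms, n_settle):
    """Steady-state ISI duration (ms) of the reduced model; inf if no spike.

    Integrates reset-to-threshold cycles until the ISI converges.  The AP
    excursion itself is not integrated: for the post and pre/post theories
    the activation reached at threshold maps to the next cycle's start
    through the affine loading x_start = load_A + load_B * x_threshold
    (precomputed from the AP waveform; load_A = 0, load_B = 1 keeps the
    activation untouched across the excursion).
    """
    x_r = sigmoid((V_r - xVh) / xk)
    if theory == 2 or theory == 3:
        # start from the spike-loaded level of a previously resting gate
        x0 = load_A + load_B * x_r
    else:
        x0 = x_r
    T_prev = -1.0
    T = np.inf
    x_start = x0
    nmax = int(max_ms / dt)
    for cyc in range(n_settle):
        V = V_r
        x = x_start
        t = 0.0
        crossed = False
        for i in range(nmax):
            dV1, dx1 = _iaf_deriv(theory, V, x, C, gL, EL, gx, p, xVh, xk,
                                  xtau, EX, I, x_r)
            dV2, dx2 = _iaf_deriv(theory, V + 0.5 * dt * dV1,
                                  x + 0.5 * dt * dx1, C, gL, EL, gx, p,
                                  xVh, xk, xtau, EX, I, x_r)
            dV3, dx3 = _iaf_deriv(theory, V + 0.5 * dt * dV2,
                                  x + 0.5 * dt * dx2, C, gL, EL, gx, p,
                                  xVh, xk, xtau, EX, I, x_r)
            dV4, dx4 = _iaf_deriv(theory, V + dt * dV3, x + dt * dx3, C, gL,
                                  EL, gx, p, xVh, xk, xtau, EX, I, x_r)
            Vn = V + dt / 6.0 * (dV1 + 2 * dV2 + 2 * dV3 + dV4)
            xn = x + dt / 6.0 * (dx1 + 2 * dx2 + 2 * dx3 + dx4)
            if xn < 0.0:
                xn = 0.0
            elif xn > 1.0:
                xn = 1.0
            if Vn >= V_s:
                t = t + dt * (V_s - V) / (Vn - V)
                crossed = True
                break
            V = Vn
            x = xn
            t = t + dt
        if not crossed:
            return np.inf
        T = t
        if theory == 2 or theory == 3:
            # activation carried through the (un-integrated) AP excursion
            x_start = load_A + load_B * x
        else:
            x_start = x_r
        if T_prev > 0.0 and abs(T - T_prev) < 1e-9 * max(T, 1.0):
            break
        T_prev = T
    return T


@njit(cache=True)
def _iaf_replay_end(theory, x0, C, gL, EL, gx, p, xVh, xk, xtau, EX, I,
                    x_r, V_r, V_s, dt, nmax):
    """Activation value when V reaches V_s, starting one ISI at (V_r, x0)."""
    V = V_r
    x = x0
    for i in range(nmax):
        dV1, dx1 = _iaf_deriv(theory, V, x, C, gL, EL, gx, p, xVh, xk, xtau,
                              EX, I, x_r)
        dV2, dx2 = _iaf_deriv(theory, V + 0.5 * dt * dV1, x + 0.5 * dt * dx1,
                              C, gL, EL, gx, p, xVh, xk, xtau, EX, I, x_r)
        dV3, dx3 = _iaf_deriv(theory, V + 0.5 * dt * dV2, x + 0.5 * dt * dx2,
                              C, gL, EL, gx, p, xVh, xk, xtau, EX, I, x_r)
        dV4, dx4 = _iaf_deriv(theory, V + dt * dV3, x + dt * dx3, C, gL, EL,
                              gx, p, xVh, xk, xtau, EX, I, x_r)
        V = V + dt / 6.0 * (dV1 + 2 * dV2 + 2 * dV3 + dV4)
        x = x + dt / 6.0 * (dx1 + 2 * dx2 + 2 * dx3 + dx4)
        if x < 0.0:
            x = 0.0
        elif x > 1.0:
            x = 1.0
        if V >= V_s:
            break
    return x


@njit(cache=True)
def iaf_trajectory_kernel(theory, C, gL, EL, gx, p, xVh, xk, xtau, EX, I,
                          V_r, V_s, load_A, load_B, dt, max_ms):
    """One steady-state ISI trajectory: arrays (t, V, x).

    Settles to the periodic orbit first, then replays one ISI.  The initial
    activation is recovered by replaying the settled cycle once more.
    """
    x_r = sigmoid((V_r - xVh) / xk)
    T = iaf_isi(theory, C, gL, EL, gx, p, xVh, xk, xtau, EX, I, V_r, V_s,
                load_A, load_B, dt, max_ms, 12)
    nmax = int(max_ms / dt)
    ts = np.empty(nmax + 1)
    Vs = np.empty(nmax + 1)
    xs = np.empty(nmax + 1)
    if not np.isfinite(T):
        return ts[:0], Vs[:0], xs[:0]
    V = V_r
    if theory == 2 or theory == 3:
        x = load_A + load_B * x_r
        for _ in range(8):
            xT = _iaf_replay_end(theory, x, C, gL, EL, gx, p, xVh, xk, xtau,
                                 EX, I, x_r, V_r, V_s, dt, nmax)
            x = load_A + load_B * xT
    else:
        x = x_r
    ts[0] = 0.0
    Vs[0] = V
    xs[0] = x
    m = 1
    for i in range(nmax):
        dV1, dx1 = _iaf_deriv(theory, V, x, C, gL, EL, gx, p, xVh, xk, xtau,
                              EX, I, x_r)
        dV2, dx2 = _iaf_deriv(theory, V + 0.5 * dt * dV1, x + 0.5 * dt * dx1,
                              C, gL, EL, gx, p, xVh, xk, xtau, EX, I, x_r)
        dV3, dx3 = _iaf_deriv(theory, V + 0.5 * dt * dV2, x + 0.5 * dt * dx2,
                              C, gL, EL, gx, p, xVh, xk, xtau, EX, I, x_r)
        dV4, dx4 = _iaf_deriv(theory, V + dt * dV3, x + dt * dx3, C, gL, EL,
                              gx, p, xVh, xk, xtau, EX, I, x_r)
        V = V + dt / 6.0 * (dV1 + 2 * dV2 + 2 * dV3 + dV4)
        x = x + dt / 6.0 * (dx1 + 2 * dx2 + 2 * dx3 + dx4)
        if x < 0.0:
            x = 0.0
        elif x > 1.0:
            x = 1.0
        ts[m] = (i + 1) * dt
        Vs[m] = V
        xs[m] = x
        m += 1
        if V >= V_s:
            break
    return ts[:m], Vs[:m], xs[:m]
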