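"""Numba core: coupled integration of the full neuron network.

One fixed-step loop advances every unit's dendrite chain (RK4), spike
generator (RK4 Hodgkin-Huxley or FitzHugh-Nagumo) and presynaptic
above-detection-level state.  Synaptic coupling follows the pulse-train
synapse contract: the current a connection injects at time t equals
sign * amplitude whenever the source axon was above the detection level
at t - delay, which makes the in-loop coupling exactly the delayed
rectangular pulse train that :func:`sacgen.synapse.spikes_to_pulses`
produces offline.

Unit kinds: 0 = basic HH, 1 = modified HH, 2 = FHN tonic integrator.
All per-unit parameters arrive as flat arrays; results are spike times,
level-crossing times (for pulse-train reconstruction) and subsampled
dendrite/axon traces.
"""

import numpy as np
from numba import njit

from .axon import _rates

MAX_SPIKES = 4000


@njit(cache=True)
def _hh_step(v, n, m, h, i_m, dt, modified, speed, g_k, g_na, e_k, e_na,
             e_l, g_l, c_m, v_rp):
    # RK4 on the 4-state HH system with i_m frozen over the step
    def rhs(v_, n_, m_, h_):
        a_n, b_n, a_m, b_m, a_h, b_h = _rates(v_, v_rp, modified)
        dv = (i_m - g_k * n_ ** 4 * (v_ - e_k)
              - g_na * m_ ** 3 * h_ * (v_ - e_na) - g_l * (v_ - e_l)) / c_m
        dn = speed * (a_n * (1.0 - n_) - b_n * n_)
        dm = speed * (a_m * (1.0 - m_) - b_m * m_)
        dh = speed * (a_h * (1.0 - h_) - b_h * h_)
        return dv, dn, dm, dh

    k1 = rhs(v, n, m, h)
    k2 = rhs(v + 0.5 * dt * k1[0], n + 0.5 * dt * k1[1],
             m + 0.5 * dt * k1[2], h + 0.5 * dt * k1[3])
    k3 = rhs(v + 0.5 * dt * k2[0], n + 0.5 * dt * k2[1],
             m + 0.5 * dt * k2[2], h + 0.5 * dt * k2[3])
    k4 = rhs(v + dt * k3[0], n + dt * k3[1], m + dt * k3[2], h + dt * k3[3])
    v += dt / 6.0 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
    n = min(max(n + dt / 6.0 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1]), 0.0), 1.0)
    m = min(max(m + dt / 6.0 * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2]), 0.0), 1.0)
    h = min(max(h + dt / 6.0 * (k1[3] + 2 * k2[3] + 2 * k3[3] + k4[3]), 0.0), 1.0)
    return v, n, m, h


@njit(cache=True)
def run_network(
    dt,
    n_steps,
    kind,               # int64[nu]
    # dendrite (uniform compartment count)
    vd,                 # float64[nu, ncomp] state, modified in place
    d_cm, d_req, d_ra, d_vth,
    # HH axon
    hh_state,           # float64[nu, 4] (v, n, m, h)
    hh_speed,
    g_k, g_na, e_k, e_na, e_l, g_l, a_cm, v_rp,
    # FHN units
    fhn_state,          # float64[nu, 3] (v, w, q)
    f_a, f_b, f_eps, f_speed, f_gain, f_qgain, f_irest,
    f_scale, f_offset,
    # connections
    conn_src, conn_dst, conn_w,     # w = sign * amplitude
    conn_delay,                     # int64[nc] in steps
    conn_level,                     # float64[nc], per-connection pulse level
    detection_level,                # float64[nu], unit pulse-width level
    spike_level,                    # float64, spike-recording level
    # scripted drives
    drive,              # float64[nu, n_steps]
    # recording
    rec_every,
):
    nu = kind.shape[0]
    ncomp = vd.shape[1]
    nc = conn_src.shape[0]
    max_delay = 1
    for c in range(nc):
        if conn_delay[c] + 1 > max_delay:
            max_delay = conn_delay[c] + 1
    hist = np.zeros((nc, max_delay), dtype=np.uint8)

    n_rec = n_steps // rec_every + 1
    rec_dend = np.empty((nu, n_rec))
    rec_axon = np.empty((nu, n_rec))
    spike_t = np.full((nu, MAX_SPIKES), np.nan)
    spike_n = np.zeros(nu, dtype=np.int64)
    up_t = np.full((nu, MAX_SPIKES), np.nan)
    down_t = np.full((nu, MAX_SPIKES), np.nan)
    up_n = np.zeros(nu, dtype=np.int64)
    down_n = np.zeros(nu, dtype=np.int64)

    axon_v = np.empty(nu)
    for u in range(nu):
        if kind[u] == 2:
            axon_v[u] = f_scale[u] * fhn_state[u, 0] + f_offset[u]
        else:
            axon_v[u] = hh_state[u, 0]
        rec_dend[u, 0] = vd[u, ncomp - 1]
        rec_axon[u, 0] = axon_v[u]

    i_syn = np.zeros(nu)
    # dendrite RK4 work buffers, reused every step
    dk1 = np.empty(ncomp)
    dk2 = np.empty(ncomp)
    dk3 = np.empty(ncomp)
    dk4 = np.empty(ncomp)
    dtmp = np.empty(ncomp)
    for k in range(n_steps):
        # 1. synaptic currents from delayed above-level states
        for u in range(nu):
            i_syn[u] = drive[u, k]
        slot_now = k % max_delay
        for c in range(nc):
            slot = (k - conn_delay[c]) % max_delay
            if k >= conn_delay[c] and hist[c, slot] == 1:
                i_syn[conn_dst[c]] += conn_w[c]

        # 2. advance each unit
        for u in range(nu):
            # dendrite RK4, input frozen over the step
            i_in = i_syn[u]
            cm = d_cm[u]
            req = d_req[u]
            ra = d_ra[u]
            vth = d_vth[u]
            y = vd[u]
            for stage in range(4):
                if stage == 0:
                    for j in range(ncomp):
                        dtmp[j] = y[j]
                    kk = dk1
                elif stage == 1:
                    for j in range(ncomp):
                        dtmp[j] = y[j] + 0.5 * dt * dk1[j]
                    kk = dk2
                elif stage == 2:
                    for j in range(ncomp):
                        dtmp[j] = y[j] + 0.5 * dt * dk2[j]
                    kk = dk3
                else:
                    for j in range(ncomp):
                        dtmp[j] = y[j] + dt * dk3[j]
                    kk = dk4
                for j in range(ncomp):
                    dv = -(dtmp[j] - vth) / req
                    if j > 0:
                        dv -= (dtmp[j] - dtmp[j - 1]) / ra
                    if j < ncomp - 1:
                        dv -= (dtmp[j] - dtmp[j + 1]) / ra
                    if j == 0:
                        dv += i_in
                    kk[j] = dv / cm
            for j in range(ncomp):
                y[j] += dt / 6.0 * (dk1[j] + 2 * dk2[j] + 2 * dk3[j] + dk4[j])

            i_m = (y[ncomp - 1] - vth) / ra
            v_prev = axon_v[u]
            if kind[u] == 2:
                v, w, q = fhn_state[u, 0], fhn_state[u, 1], fhn_state[u, 2]
                i_tot = f_irest[u] + f_gain[u] * i_m + f_qgain[u] * q
                sp = f_speed[u]
                for _ in range(2):
                    dv1 = sp * (v - v ** 3 / 3.0 - w + i_tot)
                    dw1 = sp * f_eps[u] * (v + f_a[u] - f_b[u] * w)
                    vm = v + 0.25 * dt * dv1
                    wm = w + 0.25 * dt * dw1
                    dv2 = sp * (vm - vm ** 3 / 3.0 - wm + i_tot)
                    dw2 = sp * f_eps[u] * (vm + f_a[u] - f_b[u] * wm)
                    v += 0.5 * dt * dv2
                    w += 0.5 * dt * dw2
                q += dt * i_m
                fhn_state[u, 0], fhn_state[u, 1], fhn_state[u, 2] = v, w, q
                axon_v[u] = f_scale[u] * v + f_offset[u]
            else:
                v, n, m, h = _hh_step(
                    hh_state[u, 0], hh_state[u, 1], hh_state[u, 2],
                    hh_state[u, 3], i_m, dt, kind[u] == 1, hh_speed[u],
                    g_k, g_na, e_k, e_na, e_l, g_l, a_cm, v_rp)
                hh_state[u, 0], hh_state[u, 1] = v, n
                hh_state[u, 2], hh_state[u, 3] = m, h
                axon_v[u] = v

            # 3. level crossings: spikes at spike_level, presynaptic
            # pulse state at the unit's detection level
            if axon_v[u] >= spike_level and v_prev < spike_level:
                tc = (k + (spike_level - v_prev) / (axon_v[u] - v_prev)) * dt
                if spike_n[u] < MAX_SPIKES:
                    spike_t[u, spike_n[u]] = tc
                    spike_n[u] += 1
            lvl = detection_level[u]
            above = axon_v[u] >= lvl
            if above and v_prev < lvl:
                tc = (k + (lvl - v_prev) / (axon_v[u] - v_prev)) * dt
                if up_n[u] < MAX_SPIKES:
                    up_t[u, up_n[u]] = tc
                    up_n[u] += 1
            elif (not above) and v_prev >= lvl:
                tc = (k + (lvl - v_prev) / (axon_v[u] - v_prev)) * dt
                if down_n[u] < MAX_SPIKES:
                    down_t[u, down_n[u]] = tc
                    down_n[u] += 1

        # presynaptic state per connection (levels differ per connection)
        for c in range(nc):
            hist[c, slot_now] = (
                1 if axon_v[conn_src[c]] >= conn_level[c] else 0)

        if (k + 1) % rec_every == 0:
            r = (k + 1) // rec_every
            for u in range(nu):
                rec_dend[u, r] = vd[u, ncomp - 1]
                rec_axon[u, r] = axon_v[u]

    return (rec_dend, rec_axon, spike_t, spike_n, up_t, up_n, down_t, down_n)
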