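"""Numba inner loop of the simulator.

One clock-driven pass over substeps of ``dt`` (default 0.1 ms).  Per
substep: exponential relaxation of every neuron under its frozen
conductances, delivery of delayed long-range events, feedforward Poisson
events, then cascade resolution if any neuron sits at/above threshold.

Two synapse modes share the kernel:

* ``tau_fast == 0`` (the formal instantaneous limit): recurrent fast events
  are exact voltage jumps and all causally linked firing is resolved within
  a single instant (an MFE), largest voltage surplus first;
* ``tau_fast > 0``: fast events increment decaying conductance states and
  threshold crossings fire once per substep, so "events" spread over a few
  ms as in the finite-timescale robustness checks.

Feedforward input is sampled inside the kernel by population superposition:
the summed Poisson rate of a group is sampled per substep and events are
assigned to member neurons (by rejection against the sinusoidal per-neuron
rate for phased stimulus groups).  This is distribution-exact and keeps the
~1e6 drive events per simulated second out of Python.
"""

import numpy as np
from numba import njit

STATUS_OK = 0
STATUS_NONFINITE = 1


@njit(cache=True)
def run_network(
    n_sub, dt,
    tau_V, tau_slow, tau_ref, V_L, V_E, V_I, V_T, V_reset,
    tau_fast_E, tau_fast_I,
    V, g_slow, g_fE, g_fI, refrac,
    pop,                               # (N,) int8: 0=E 1=I
    inst_indptr, inst_idx, inst_wf, inst_ws,    # sender-indexed, same-instant
    dly_indptr, dly_idx, dly_wf, dly_ws, delay_sub,   # delayed long-range
    e_ids, i_ids, lam_bkg_E, lam_bkg_I, S_drive_E, S_drive_I,
    grp_ptr, grp_ids, grp_lam1, grp_SC, grp_SS, grp_pop,
    omega_rad, phases, phase_free, onset_ms,
    ev_ptr, ev_neuron,                 # pre-sampled input events (optional)
    samp_sub, clus, inv_count, mon_ids,
    vtimes_out, vmean_out, vmon_out,
    seed,
):
    np.random.seed(seed)
    N = V.shape[0]
    instant = tau_fast_E == 0.0 and tau_fast_I == 0.0
    use_delay = delay_sub > 0 and dly_idx.shape[0] > 0
    D = delay_sub if delay_sub > 0 else 1
    buf_wf = np.zeros((D, N))
    buf_ws = np.zeros((D, N))
    gdec = np.exp(-dt / tau_slow)
    gdec_h = np.exp(-0.5 * dt / tau_slow)
    fdec_E = np.exp(-dt / tau_fast_E) if tau_fast_E > 0 else 0.0
    fdec_I = np.exp(-dt / tau_fast_I) if tau_fast_I > 0 else 0.0
    fdec_Eh = np.exp(-0.5 * dt / tau_fast_E) if tau_fast_E > 0 else 0.0
    fdec_Ih = np.exp(-0.5 * dt / tau_fast_I) if tau_fast_I > 0 else 0.0

    cap = 1 << 14
    sp_t = np.empty(cap)
    sp_i = np.empty(cap, np.int64)
    n_sp = 0
    status = STATUS_OK
    err_t = -1.0

    n_grp = grp_ptr.shape[0] - 1

    for i in range(n_sub):
        t0 = i * dt
        t1 = t0 + dt
        tmid = t0 + 0.5 * dt
        tmin_cross = t1

        # --- relaxation under frozen conductances -----------------------
        for n in range(N):
            if refrac[n] >= t1:
                V[n] = V_reset
                g_slow[n] *= gdec
                if not instant:
                    g_fE[n] *= fdec_E
                    g_fI[n] *= fdec_I
                continue
            a = t0
            if refrac[n] > t0:
                a = refrac[n]
                V[n] = V_reset
            h = t1 - a
            # conductances at the substep midpoint (second order in decay)
            gE = g_slow[n] * gdec_h + (0.0 if instant else g_fE[n] * fdec_Eh)
            gI = 0.0 if instant else g_fI[n] * fdec_Ih
            gtot = 1.0 + gE + gI
            Vinf = (V_L + gE * V_E + gI * V_I) / gtot
            Vold = V[n]
            Vnew = Vinf + (Vold - Vinf) * np.exp(-gtot * h / tau_V)
            if Vnew != Vnew:
                status = STATUS_NONFINITE
                err_t = t1
                break
            if Vnew >= V_T and Vold < V_T:
                tc = a + h * (V_T - Vold) / (Vnew - Vold)
                if tc < tmin_cross:
                    tmin_cross = tc
            V[n] = Vnew
            g_slow[n] *= gdec
            if not instant:
                g_fE[n] *= fdec_E
                g_fI[n] *= fdec_I
        if status != STATUS_OK:
            break

        # --- delayed long-range deliveries ------------------------------
        if use_delay:
            r = i % D
            for n in range(N):
                w = buf_wf[r, n]
                if w > 0.0 and refrac[n] < t1:
                    if instant:
                        V[n] = V_E + (V[n] - V_E) * np.exp(-w / tau_V)
                    else:
                        g_fE[n] += w / tau_fast_E
                ws = buf_ws[r, n]
                if ws > 0.0:
                    g_slow[n] += ws / tau_slow
                buf_wf[r, n] = 0.0
                buf_ws[r, n] = 0.0

        # --- feedforward input events -----------------------------------
        if ev_neuron.shape[0] > 0:
            # pre-sampled event times, quantized to their substep
            for p in range(ev_ptr[i], ev_ptr[i + 1]):
                n = ev_neuron[p]
                w = S_drive_E if pop[n] == 0 else S_drive_I
                if refrac[n] < t1 and w > 0.0:
                    if instant:
                        V[n] = V_E + (V[n] - V_E) * np.exp(-w / tau_V)
                    else:
                        g_fE[n] += w / tau_fast_E
        for b in range(2):
            ids = e_ids if b == 0 else i_ids
            lam = lam_bkg_E if b == 0 else lam_bkg_I
            w = S_drive_E if b == 0 else S_drive_I
            if lam <= 0.0 or w <= 0.0 or ids.shape[0] == 0:
                continue
            K = np.random.poisson(lam)
            for _ in range(K):
                n = ids[np.random.randint(ids.shape[0])]
                if refrac[n] < t1:
                    if instant:
                        V[n] = V_E + (V[n] - V_E) * np.exp(-w / tau_V)
                    else:
                        g_fE[n] += w / tau_fast_E
        if tmid >= onset_ms:
            for gidx in range(n_grp):
                lo = grp_ptr[gidx]
                hi = grp_ptr[gidx + 1]
                nmem = hi - lo
                if nmem == 0:
                    continue
                lam1 = grp_lam1[gidx]
                if phase_free:
                    lam = lam1 * nmem
                else:
                    s = np.sin(omega_rad * tmid)
                    c = np.cos(omega_rad * tmid)
                    lam = lam1 * (nmem + s * grp_SC[gidx] - c * grp_SS[gidx])
                if lam <= 0.0:
                    continue
                w = S_drive_E if grp_pop[gidx] == 0 else S_drive_I
                K = np.random.poisson(lam)
                for _ in range(K):
                    if phase_free:
                        n = grp_ids[lo + np.random.randint(nmem)]
                    else:
                        # rejection against 1 + sin(omega (t - phi_l)) in [0, 2]
                        while True:
                            n = grp_ids[lo + np.random.randint(nmem)]
                            wt = 1.0 + np.sin(omega_rad * (tmid - phases[n]))
                            if 2.0 * np.random.random() < wt:
                                break
                    if refrac[n] < t1 and w > 0.0:
                        if instant:
                            V[n] = V_E + (V[n] - V_E) * np.exp(-w / tau_V)
                        else:
                            g_fE[n] += w / tau_fast_E

        # --- threshold crossings ----------------------------------------
        found = False
        for n in range(N):
            if V[n] >= V_T and refrac[n] < t1:
                found = True
                break
        if found:
            t_sp = tmin_cross
            fired = np.zeros(N, np.bool_)
            pending = np.zeros(N)
            if instant:
                # resolve the whole multiple-firing event at one instant:
                # largest voltage surplus fires first, uniform among ties
                while True:
                    best = -1
                    best_s = -1.0
                    n_tie = 0
                    for n in range(N):
                        if fired[n] or refrac[n] >= t1:
                            continue
                        s = V[n] - V_T
                        if s >= 0.0:
                            if s > best_s:
                                best = n
                                best_s = s
                                n_tie = 1
                            elif s == best_s:
                                n_tie += 1
                                if np.random.randint(n_tie) == 0:
                                    best = n
                    if best < 0:
                        break
                    if n_sp >= cap:
                        cap2 = cap * 2
                        nt = np.empty(cap2)
                        ni = np.empty(cap2, np.int64)
                        nt[:cap] = sp_t
                        ni[:cap] = sp_i
                        sp_t = nt
                        sp_i = ni
                        cap = cap2
                    sp_t[n_sp] = t_sp
                    sp_i[n_sp] = best
                    n_sp += 1
                    fired[best] = True
                    rev = V_E if pop[best] == 0 else V_I
                    for p in range(inst_indptr[best], inst_indptr[best + 1]):
                        tgt = inst_idx[p]
                        if fired[tgt] or refrac[tgt] >= t1:
                            continue
                        wf = inst_wf[p]
                        if wf > 0.0:
                            V[tgt] = rev + (V[tgt] - rev) * np.exp(-wf / tau_V)
                        pending[tgt] += inst_ws[p]
                    if use_delay:
                        rr = i % D
                        for p in range(dly_indptr[best], dly_indptr[best + 1]):
                            tgt = dly_idx[p]
                            buf_wf[rr, tgt] += dly_wf[p]
                            buf_ws[rr, tgt] += dly_ws[p]
                    V[best] = V_reset
                    refrac[best] = t_sp + tau_ref
            else:
                # finite fast timescales: all current crossers fire this
                # substep; their conductance influence unfolds over later
                # substeps
                for n in range(N):
                    if V[n] >= V_T and refrac[n] < t1 and not fired[n]:
                        if n_sp >= cap:
                            cap2 = cap * 2
                            nt = np.empty(cap2)
                            ni = np.empty(cap2, np.int64)
                            nt[:cap] = sp_t
                            ni[:cap] = sp_i
                            sp_t = nt
                            sp_i = ni
                            cap = cap2
                        sp_t[n_sp] = t_sp
                        sp_i[n_sp] = n
                        n_sp += 1
                        fired[n] = True
                        for p in range(inst_indptr[n], inst_indptr[n + 1]):
                            tgt = inst_idx[p]
                            wf = inst_wf[p]
                            if wf > 0.0:
                                if pop[n] == 0:
                                    g_fE[tgt] += wf / tau_fast_E
                                else:
                                    g_fI[tgt] += wf / tau_fast_I
                            pending[tgt] += inst_ws[p]
                        if use_delay:
                            rr = i % D
                            for p in range(dly_indptr[n], dly_indptr[n + 1]):
                                tgt = dly_idx[p]
                                buf_wf[rr, tgt] += dly_wf[p]
                                buf_ws[rr, tgt] += dly_ws[p]
                        V[n] = V_reset
                        refrac[n] = t_sp + tau_ref
            for n in range(N):
                if pending[n] > 0.0:
                    g_slow[n] += pending[n] / tau_slow

        # --- voltage sampling -------------------------------------------
        if samp_sub > 0 and (i + 1) % samp_sub == 0:
            row = (i + 1) // samp_sub - 1
            if row < vtimes_out.shape[0]:
                vtimes_out[row] = t1
                for n in range(N):
                    vmean_out[row, clus[n], pop[n]] += V[n] * inv_count[clus[n], pop[n]]
                for m in range(mon_ids.shape[0]):
                    vmon_out[row, m] = V[mon_ids[m]]

    return sp_t[:n_sp], sp_i[:n_sp], status, err_t
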