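"""Independent oracles used by the test suite.

These deliberately avoid the package's own event-resolution code paths:
the cascade oracle integrates the finite-fast-timescale conductance ODE by
brute force, and the cross-covariance oracle is a literal double loop over
neuron pairs and lags.
"""

import numpy as np


def finite_tau_cascades(V0, is_E, W_fast, params, tau_fast,
                        steps_per_tau=50, horizon_tau=80.0):
    """Brute-force finite-tau_fast simulation of cascade instants.

    Vectorized over a batch of instances: ``V0`` is (n_cases, N), ``W_fast``
    is (n_cases, N, N) [receiver, sender].  Every neuron at/above threshold
    fires (once; it is then clamped at reset for the whole window, emulating
    tau_ref >> tau_fast); each spike injects a decaying conductance
    ``w/tau * exp(-t/tau)`` toward the sender-type reversal into its
    targets.  Returns the (n_cases, N) boolean fired matrix.

    Integration is exponential-Euler with the conductance evaluated at the
    substep midpoint (second-order accurate), dt = tau/steps_per_tau.
    """
    V = np.array(V0, dtype=float)
    n_cases, N = V.shape
    fired = np.zeros((n_cases, N), bool)
    gE = np.zeros((n_cases, N))
    gI = np.zeros((n_cases, N))
    dt = tau_fast / steps_per_tau
    n_steps = int(round(horizon_tau * steps_per_tau))
    decay = np.exp(-dt / tau_fast)
    half = np.exp(-0.5 * dt / tau_fast)
    is_E = np.atleast_2d(np.asarray(is_E, bool))
    if is_E.shape[0] == 1 and n_cases > 1:
        is_E = np.broadcast_to(is_E, (n_cases, N))
    W_E = W_fast * is_E[:, None, :]         # columns of E senders
    W_I = W_fast * (~is_E)[:, None, :]

    def fire_pass():
        # repeatedly fire anyone at/above threshold (new conductance takes
        # effect from the next substep)
        while True:
            new = (~fired) & (V >= params.V_T)
            if not new.any():
                return
            fired[new] = True
            spikes = new.astype(float)
            gE[...] += np.einsum("cnm,cm->cn", W_E, spikes) / tau_fast
            gI[...] += np.einsum("cnm,cm->cn", W_I, spikes) / tau_fast
            V[new] = params.V_reset

    fire_pass()
    for _ in range(n_steps):
        gEm = gE * half
        gIm = gI * half
        gtot = 1.0 + gEm + gIm
        Vinf = (params.V_L + gEm * params.V_E + gIm * params.V_I) / gtot
        V[...] = Vinf + (V - Vinf) * np.exp(-gtot * dt / params.tau_V)
        V[fired] = params.V_reset
        gE *= decay
        gI *= decay
        fire_pass()
    return fired


def direct_crosscov(raster, Q, Qp, A, B, tau_max, dt, T_bins):
    """Literal double-loop cross-covariance over ordered neuron pairs.

    Returns (tau_bins, raw, mean_subtracted); raw entries are integers
    (times dt applied by the caller's convention is NOT included here).
    """
    g = raster.geometry
    L = int(round(tau_max / dt))

    def train(pop, j, k, l):
        m = ((raster.pop == pop) & (raster.j == j) & (raster.k == k)
             & (raster.l == l))
        x = np.zeros(T_bins, dtype=np.int64)
        for t in raster.t[m]:
            b = min(int(t // dt), T_bins - 1)
            x[b] += 1
        return x

    def neurons(pop):
        n = g.N_E if pop == 0 else g.N_I
        for j in range(g.n_orientations):
            for k in range(g.n_hypercolumns):
                for l in range(n):
                    yield j, k, l

    raw = np.zeros(2 * L + 1)
    ms = np.zeros(2 * L + 1)
    for j, k, l in neurons(Q):
        x = train(Q, j, k, l)
        xm = x - x.mean()
        for jp, kp, lp in neurons(Qp):
            if (jp == j) != bool(A) or (kp == k) != bool(B):
                continue
            if Q == Qp and (j, k, l) == (jp, kp, lp):
                continue
            y = train(Qp, jp, kp, lp)
            ym = y - y.mean()
            for li, lag in enumerate(range(-L, L + 1)):
                s = 0.0
                sm = 0.0
                for t in range(max(0, lag), T_bins + min(0, lag)):
                    s += x[t] * y[t - lag]
                    sm += xm[t] * ym[t - lag]
                raw[li] += s
                ms[li] += sm
    return np.arange(-L, L + 1), raw, ms


def single_neuron_renewal_rate(w_drive, eta_hz, params, duration_ms, rng):
    """Monte-Carlo renewal oracle for one neuron under constant-rate Poisson
    drive delivered by the exponential jump rule, with exact leak decay
    between arrivals (event-driven, no substepping)."""
    t = 0.0
    V = 0.0
    n_spikes = 0
    lam = eta_hz / 1000.0
    jump = np.exp(-w_drive / params.tau_V)
    while t < duration_ms:
        dt = rng.exponential(1.0 / lam)
        t += dt
        V *= np.exp(-dt / params.tau_V)          # leak toward V_L = 0
        V = params.V_E + (V - params.V_E) * jump
        if V >= params.V_T:
            n_spikes += 1
            V = params.V_reset
            t += params.tau_ref
    return 1000.0 * n_spikes / duration_ms
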