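"""Single-neuron dynamics and cascade resolution at a time instant.

The fast synapses of the model are taken in the formal limit of zero decay
time, ordered so that the refractory period dominates the fast timescale
(``tau_ref >> tau_fast``).  In that limit a presynaptic spike delivers its
whole conductance-time instantaneously and the membrane equation can be
integrated across the event in closed form: during the delta event the leak
and slow terms contribute zero measure, leaving

    tau_V dV/dt = -w delta(t) (V - V_rev)
    =>  V+ = V_rev + (V- - V_rev) exp(-w / tau_V).

Because the jump is exponential rather than additive it can never overshoot
the synaptic reversal potential, which keeps voltages inside
``[V_I, V_T]`` without clipping.

A *multiple-firing event* (MFE) is the transitive closure of threshold
crossings triggered by one initiating spike within a single instant: each
emitted spike jumps its fast postsynaptic targets, possibly pushing further
neurons over threshold; recruited inhibition pulls the rest of the
population away from threshold and terminates the barrage.  Because
``tau_ref >> tau_fast`` each neuron fires at most once per instant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import NeuronParams, SynapticKernels

#: default substep (ms) for exponential integration between events
DEFAULT_SUBSTEP = 0.1


@dataclass
class NeuronState:
    """Dynamical variables of one neuron.

    ``g_slow`` is the summed slow excitatory conductance; since every slow
    kernel shares one decay time it is a single exponential state.
    ``refractory_until`` is an absolute time (ms); the neuron ignores all
    input and holds ``V = V_reset`` until then.
    """

    V: float
    g_slow: float = 0.0
    refractory_until: float = -np.inf
    is_E: bool = True


@dataclass
class CascadeResult:
    """Outcome of resolving one instant's cascade."""

    fired_E: list[int] = field(default_factory=list)
    fired_I: list[int] = field(default_factory=list)
    order: list[int] = field(default_factory=list)     # global firing order
    surpluses: list[float] = field(default_factory=list)  # V - V_T at firing
    V_pre: np.ndarray | None = None
    V_post: np.ndarray | None = None
    g_slow_increment: np.ndarray | None = None         # summed slow weights,
    # to be converted to a conductance jump (divide by tau_slow) after the
    # instant

    @property
    def magnitude(self) -> int:
        return len(self.fired_E) + len(self.fired_I)


def voltage_jump(v: float, w: float, reversal: float, tau_V: float = 20.0):
    """Apply an instantaneous fast synaptic event of weight ``w``.

    Exact integral of the membrane equation across a delta conductance of
    area ``w``: the voltage moves strictly toward ``reversal`` and never
    past it.  Inhibition is encoded by choosing the inhibitory reversal,
    not by a negative weight.  Accepts scalars or arrays.
    """
    w = np.asarray(w, dtype=float)
    if np.any(w < 0):
        raise ValueError("synaptic weights are nonnegative; use the reversal "
                         "potential to encode inhibition")
    out = reversal + (np.asarray(v, dtype=float) - reversal) * np.exp(-w / tau_V)
    return out if out.ndim else float(out)


def relax(
    state: NeuronState,
    params: NeuronParams,
    kernels: SynapticKernels,
    dt: float,
    t0: float = 0.0,
    substep: float = DEFAULT_SUBSTEP,
    threshold: bool = True,
) -> tuple[NeuronState, float | None]:
    """Advance one neuron from absolute time ``t0`` to ``t0 + dt`` under leak
    + decaying slow conductance, with no fast events inside the interval.

    Integrates with exponential substeps of at most ``substep`` ms, freezing
    ``g_slow`` over each substep (it decays exactly between substeps).  If
    the voltage would cross ``V_T`` the crossing time is located by linear
    interpolation inside the substep and the state is returned at the
    crossing (``V = V_T``) together with the absolute crossing time;
    otherwise the second return value is ``None``.  While refractory the
    neuron is held at ``V_reset`` (its ``g_slow`` still decays) and resumes
    integrating when the refractory clock expires.
    """
    if dt < 0:
        raise ValueError("dt must be nonnegative")
    t_end = t0 + dt
    t = t0
    V, g = state.V, state.g_slow
    if state.refractory_until > t:
        hold_until = min(t_end, state.refractory_until)
        g *= np.exp(-(hold_until - t) / kernels.tau_slow)
        V = params.V_reset
        t = hold_until
    while t < t_end - 1e-12:
        h = min(substep, t_end - t)
        # conductance frozen at its substep-midpoint value (second order in
        # the slow decay), exact exponential step for the membrane
        gm = g * np.exp(-0.5 * h / kernels.tau_slow)
        Vinf = (params.V_L + gm * params.V_E) / (1.0 + gm)
        decay = np.exp(-(1.0 + gm) * h / params.tau_V)
        V_new = Vinf + (V - Vinf) * decay
        if threshold and V_new >= params.V_T:
            frac = (params.V_T - V) / (V_new - V)
            t_cross = t + frac * h
            g_cross = g * np.exp(-frac * h / kernels.tau_slow)
            new = NeuronState(V=params.V_T, g_slow=g_cross,
                              refractory_until=state.refractory_until,
                              is_E=state.is_E)
            return new, t_cross
        V = V_new
        g *= np.exp(-h / kernels.tau_slow)
        t += h
    new = NeuronState(V=V, g_slow=g,
                      refractory_until=state.refractory_until,
                      is_E=state.is_E)
    return new, None


def apply_reset(state: NeuronState, t: float, params: NeuronParams) -> NeuronState:
    """Reset after a spike emitted at absolute time ``t``.

    Voltage goes to ``V_reset`` and the neuron ignores all synaptic input
    until ``t + tau_ref``.
    """
    return NeuronState(V=params.V_reset, g_slow=state.g_slow,
                       refractory_until=t + params.tau_ref, is_E=state.is_E)


def resolve_cascade(
    V: np.ndarray,
    is_E: np.ndarray,
    W_fast: np.ndarray,
    W_slow: np.ndarray,
    params: NeuronParams,
    rng: np.random.Generator,
    refractory: np.ndarray | None = None,
    initiating: int | None = None,
) -> CascadeResult:
    """Resolve all firing at a single instant, starting from a supra-threshold
    neuron.

    Parameters
    ----------
    V : (N,) voltages at the instant; at least one non-refractory entry must
        be at or above threshold (the initiating spike).
    is_E : (N,) bool, population tag per neuron.
    W_fast, W_slow : (N, N) weight matrices, ``W[receiver, sender]``.
    refractory : (N,) bool, neurons currently refractory (ignore input,
        cannot fire).
    initiating : optional index asserted to be at/above threshold.

    Within the instant the supra-threshold neuron with the largest voltage
    surplus fires first (ties broken by a per-instant random permutation
    drawn from ``rng``); its fast weights are applied immediately as jumps
    (E senders toward ``V_E``, I senders toward ``V_I``) to all
    non-refractory, not-yet-fired targets, and its slow weights are
    accumulated, to be added to the targets' ``g_slow`` only after the
    instant (the slow kernel delivers zero conductance in zero time).
    Each neuron fires at most once.
    """
    N = V.shape[0]
    V = V.astype(float).copy()
    V_pre = V.copy()
    refractory = np.zeros(N, bool) if refractory is None else refractory.astype(bool)
    if initiating is not None:
        if refractory[initiating] or V[initiating] < params.V_T:
            raise ValueError("initiating neuron is not eligible to fire")
    fired = np.zeros(N, bool)
    priority = rng.permutation(N)          # per-instant tie-break
    g_inc = np.zeros(N)
    order: list[int] = []
    surpluses: list[float] = []
    for _ in range(N + 1):
        eligible = (~fired) & (~refractory) & (V >= params.V_T)
        if not eligible.any():
            break
        idx = np.flatnonzero(eligible)
        surplus = V[idx] - params.V_T
        best = idx[np.lexsort((priority[idx], -surplus))[0]]
        fired[best] = True
        order.append(int(best))
        surpluses.append(float(V[best] - params.V_T))
        rev = params.V_E if is_E[best] else params.V_I
        targets = (~fired) & (~refractory)
        w = W_fast[:, best]
        hit = targets & (w > 0)
        V[hit] = rev + (V[hit] - rev) * np.exp(-w[hit] / params.tau_V)
        if is_E[best]:
            g_inc += W_slow[:, best]
        V[best] = params.V_reset
    else:  # pragma: no cover - impossible while each neuron fires once
        raise RuntimeError("cascade failed to terminate")
    fired_idx = order
    return CascadeResult(
        fired_E=[i for i in fired_idx if is_E[i]],
        fired_I=[i for i in fired_idx if not is_E[i]],
        order=order,
        surpluses=surpluses,
        V_pre=V_pre,
        V_post=V,
        g_slow_increment=g_inc,
    )
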