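"""Membrane and synaptic constants.

Voltages are dimensionless: the leak reversal is 0 and the firing threshold
is 1, so a unit of voltage is the rest-to-threshold distance.  Times are in
milliseconds throughout the package; rates are in Hz.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class NeuronParams:
    """Constants of the conductance-based integrate-and-fire membrane.

    The membrane obeys

        tau_V dV/dt = -(V - V_L) - g_E(t) (V - V_E) - g_I(t) (V - V_I)

    where g_E collects the feedforward, fast-recurrent and slow (NMDA-like)
    excitatory conductances and g_I the fast inhibitory conductance.  On
    crossing ``V_T`` the neuron fires, is reset to ``V_reset`` and is held
    there for the absolute refractory period ``tau_ref``.
    """

    V_L: float = 0.0
    V_E: float = 14.0 / 3.0
    V_I: float = -2.0 / 3.0
    V_T: float = 1.0
    V_reset: float = 0.0
    tau_V: float = 20.0      # membrane time constant, ms
    tau_ref: float = 1.0     # absolute refractory period, ms

    def __post_init__(self) -> None:
        if not (self.V_I < self.V_L <= self.V_reset < self.V_T < self.V_E):
            raise ValueError(
                "reversal ordering violated: need V_I < V_L <= V_reset < V_T < V_E"
            )
        if self.tau_V <= 0:
            raise ValueError("tau_V must be positive")
        if self.tau_ref < 0:
            raise ValueError("tau_ref must be nonnegative")


@dataclass(frozen=True)
class SynapticKernels:
    """Synaptic conductance time courses.

    All kernels are unit-integral alpha functions with instantaneous rise,
    i.e. ``alpha(t) = exp(-t/tau)/tau`` for ``t >= 0``, so a synaptic weight
    W delivers total conductance-time W regardless of tau.  The fast
    (AMPA/GABA-A-like) decay times default to the formal limit
    ``tau_fast -> 0+``, in which a fast event of weight w becomes an
    instantaneous voltage jump (see :func:`mfesim.core.voltage_jump`); the
    slow (NMDA-like) excitatory kernel keeps a finite decay time.
    """

    tau_slow: float = 128.0   # slow excitatory decay, ms
    tau_fast_E: float = 0.0   # 0 = instantaneous-jump limit
    tau_fast_I: float = 0.0

    def __post_init__(self) -> None:
        if self.tau_slow <= 0:
            raise ValueError("tau_slow must be positive")
        if self.tau_fast_E < 0 or self.tau_fast_I < 0:
            raise ValueError("fast decay times must be nonnegative")
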