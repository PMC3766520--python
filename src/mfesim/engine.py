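"""Hybrid clock-driven/cascade simulation loop.

The engine advances the whole network on substeps of 0.1 ms (exponential
integration with conductances frozen per substep), delivers feedforward
Poisson events and delayed long-range events, and resolves every threshold
crossing as a same-instant cascade — a multiple-firing event — via the
rules of :mod:`mfesim.core`.  All randomness (initial conditions, drive,
within-instant tie-breaks) derives from one master seed, and a run is
bit-reproducible given its configuration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp

from . import _kernels
from .drive import DriveParams, StimulusSpec, NO_STIMULUS
from .network import Network, POP_E, POP_I
from .params import NeuronParams, SynapticKernels
from .raster import SpikeRaster, VoltageTrace


@dataclass(frozen=True)
class SimConfig:
    """Run configuration.

    ``v_sample_ms = 0`` disables voltage sampling.  ``monitor`` lists global
    neuron indices whose full voltage traces are recorded (cluster means are
    always recorded when sampling is on).  Initial voltages are uniform on
    ``[V_reset, 0.95 V_T]`` unless overridden — randomized below threshold
    to avoid startup synchrony.  ``stim_onset_ms`` delays the stimulus
    relative to run start (the background drive is always on).
    """

    duration_ms: float = 1000.0
    seed: int = 0
    substep_ms: float = 0.1
    v_sample_ms: float = 1.0
    monitor: tuple[int, ...] = ()
    stim_onset_ms: float = 0.0
    ic_low: float | None = None
    ic_high: float | None = None
    regime_name: str = ""

    def __post_init__(self):
        if self.duration_ms <= 0:
            raise ValueError("duration must be positive")
        if self.substep_ms <= 0:
            raise ValueError("substep must be positive")
        if self.v_sample_ms < 0:
            raise ValueError("sampling interval must be nonnegative")


class SimulationError(RuntimeError):
    """Numerical failure inside the engine, with diagnostic state."""

    def __init__(self, msg, t=None, state=None):
        super().__init__(msg)
        self.t = t
        self.state = state


def _sender_csc(W: sp.spmatrix):
    """Sender-indexed (indptr, targets, weights) from a [receiver, sender]
    matrix."""
    csc = W.tocsc()
    return (csc.indptr.astype(np.int64), csc.indices.astype(np.int64),
            csc.data.astype(np.float64))


def _split_structures(net: Network, delay_sub: int):
    """Partition edges into same-instant and delayed delivery structures.

    With zero horizontal delay everything is delivered within the instant;
    otherwise cross-hypercolumn (long-range) edges, fast and slow, are
    routed through the delay ring buffer.
    """
    fast = net.W_fast.tocoo()
    slow = net.W_slow.tocoo()
    long_range = net.k[fast.row] != net.k[fast.col]
    if delay_sub <= 0 or not long_range.any():
        inst_f = net.W_fast
        inst_s = net.W_slow
        dly_f = sp.csc_matrix(net.W_fast.shape)
        dly_s = sp.csc_matrix(net.W_fast.shape)
    else:
        keep = ~long_range
        shape = net.W_fast.shape
        inst_f = sp.csc_matrix((fast.data[keep], (fast.row[keep], fast.col[keep])), shape=shape)
        inst_s = sp.csc_matrix((slow.data[keep], (slow.row[keep], slow.col[keep])), shape=shape)
        dly_f = sp.csc_matrix((fast.data[long_range], (fast.row[long_range], fast.col[long_range])), shape=shape)
        dly_s = sp.csc_matrix((slow.data[long_range], (slow.row[long_range], slow.col[long_range])), shape=shape)
    # fast and slow matrices are built from identical coordinate arrays, so
    # their canonical CSC orderings are aligned entry for entry and one
    # index walk serves both
    return inst_f, inst_s, dly_f, dly_s


def _stim_groups(net: Network, driveP: DriveParams, stimulus: StimulusSpec,
                 substep: float):
    """Per (targeted cluster, population) superposition-sampling tables."""
    ids_all, ptr, lam1, SC, SS, gpop = [], [0], [], [], [], []
    phases = stimulus.phases(net.geometry)
    omega_rad = 2.0 * np.pi * stimulus.omega / 1000.0
    for (j, k), _c in sorted(stimulus.targets.items()):
        for pop in (POP_E, POP_I):
            c = stimulus.contrast(pop, j, k)
            if c == 0.0:
                continue
            ids = net.neurons_in(j, k, pop)
            ids_all.append(ids)
            ptr.append(ptr[-1] + ids.size)
            lam1.append(c * driveP.eta_bkg(pop) * substep / 1000.0)
            SC.append(float(np.sum(np.cos(omega_rad * phases[ids]))))
            SS.append(float(np.sum(np.sin(omega_rad * phases[ids]))))
            gpop.append(pop)
    ids_cat = (np.concatenate(ids_all).astype(np.int64) if ids_all
               else np.empty(0, np.int64))
    return (np.asarray(ptr, np.int64), ids_cat, np.asarray(lam1),
            np.asarray(SC), np.asarray(SS), np.asarray(gpop, np.int8),
            omega_rad, phases)


def run_simulation(
    network: Network,
    drive: DriveParams,
    stimulus: StimulusSpec = NO_STIMULUS,
    config: SimConfig = SimConfig(),
    params: NeuronParams | None = None,
    kernels: SynapticKernels | None = None,
    input_events: list[np.ndarray] | None = None,
) -> tuple[SpikeRaster, VoltageTrace]:
    """Simulate the network and return its spike raster and voltage trace.

    By default the feedforward Poisson input is sampled internally from the
    drive/stimulus rate law (seeded by the config).  ``input_events``
    instead supplies one array of spike times (ms) per neuron — e.g. from
    :func:`mfesim.drive.sample_input_spikes` — so the identical input
    realization can be replayed across configurations (used for
    integration-convergence checks)."""
    params = params or NeuronParams()
    kernels = kernels or SynapticKernels()
    net = network
    geom = net.geometry
    N = net.n_neurons
    dt = config.substep_ms
    n_sub = int(round(config.duration_ms / dt))

    ss = np.random.SeedSequence(config.seed)
    ic_ss, kernel_ss = ss.spawn(2)
    rng_ic = np.random.default_rng(ic_ss)
    lo = params.V_reset if config.ic_low is None else config.ic_low
    hi = 0.95 * params.V_T if config.ic_high is None else config.ic_high
    V = rng_ic.uniform(lo, hi, size=N)
    g_slow = np.zeros(N)
    g_fE = np.zeros(N)
    g_fI = np.zeros(N)
    refrac = np.full(N, -1.0)
    kernel_seed = int(kernel_ss.generate_state(1, np.uint32)[0] % (2**31))

    delay_sub = int(round(net.connectivity.horizontal_delay_ms / dt))
    inst_f, inst_s, dly_f, dly_s = _split_structures(net, delay_sub)
    ii, ix, iwf = _sender_csc(inst_f)
    _, _, iws = _sender_csc(inst_s)
    di, dx, dwf = _sender_csc(dly_f)
    _, _, dws = _sender_csc(dly_s)

    e_ids = np.flatnonzero(net.pop == POP_E).astype(np.int64)
    i_ids = np.flatnonzero(net.pop == POP_I).astype(np.int64)
    lam_bkg_E = drive.eta_bkg_E / 1000.0 * dt * e_ids.size
    lam_bkg_I = drive.eta_bkg_I / 1000.0 * dt * i_ids.size
    (gptr, gids, glam1, gSC, gSS, gpop, omega_rad, phases) = _stim_groups(
        net, drive, stimulus, dt)
    if input_events is not None:
        if len(input_events) != N:
            raise ValueError("input_events must list one array per neuron")
        ev_t = np.concatenate([np.asarray(e, float) for e in input_events])
        ev_n = np.concatenate([np.full(len(e), i, np.int64)
                               for i, e in enumerate(input_events)])
        order = np.argsort(ev_t, kind="stable")
        ev_sub = np.clip((ev_t[order] / dt).astype(np.int64), 0, n_sub - 1)
        ev_neuron = ev_n[order]
        ev_ptr = np.searchsorted(ev_sub, np.arange(n_sub + 1)).astype(np.int64)
        lam_bkg_E = lam_bkg_I = 0.0    # replayed events replace sampling
        gptr = np.zeros(1, np.int64)
        gids = np.empty(0, np.int64)
        glam1 = np.empty(0)
        gSC = np.empty(0)
        gSS = np.empty(0)
        gpop = np.empty(0, np.int8)
    else:
        ev_ptr = np.zeros(n_sub + 1, np.int64)
        ev_neuron = np.empty(0, np.int64)

    samp_sub = int(round(config.v_sample_ms / dt)) if config.v_sample_ms > 0 else 0
    n_samp = n_sub // samp_sub if samp_sub else 0
    clus = net.cluster_of().astype(np.int64)
    counts = np.zeros((geom.n_clusters, 2))
    np.add.at(counts, (clus, net.pop.astype(int)), 1.0)
    inv_count = np.where(counts > 0, 1.0 / np.maximum(counts, 1), 0.0)
    mon_ids = np.asarray(config.monitor, np.int64)
    vtimes = np.zeros(n_samp)
    vmean = np.zeros((n_samp, geom.n_clusters, 2))
    vmon = np.zeros((n_samp, mon_ids.size))

    sp_t, sp_i, status, err_t = _kernels.run_network(
        n_sub, dt,
        params.tau_V, kernels.tau_slow, params.tau_ref,
        params.V_L, params.V_E, params.V_I, params.V_T, params.V_reset,
        kernels.tau_fast_E, kernels.tau_fast_I,
        V, g_slow, g_fE, g_fI, refrac,
        net.pop.astype(np.int8),
        ii, ix, iwf, iws,
        di, dx, dwf, dws, delay_sub,
        e_ids, i_ids, lam_bkg_E, lam_bkg_I,
        drive.S_drive_E, drive.S_drive_I,
        gptr, gids, glam1, gSC, gSS, gpop,
        omega_rad, phases, stimulus.phase_free, config.stim_onset_ms,
        ev_ptr, ev_neuron,
        samp_sub, clus, inv_count, mon_ids,
        vtimes, vmean, vmon,
        kernel_seed,
    )
    if status != _kernels.STATUS_OK:
        raise SimulationError(
            f"non-finite voltage at t={err_t} ms", t=err_t,
            state={"V": V, "g_slow": g_slow, "refrac": refrac})

    order = np.argsort(sp_t, kind="stable")
    sp_t = sp_t[order]
    sp_i = sp_i[order]
    raster = SpikeRaster(
        t=sp_t, pop=net.pop[sp_i], j=net.j[sp_i], k=net.k[sp_i],
        l=net.l[sp_i], geometry=geom, duration=config.duration_ms,
        seed=config.seed)
    trace = VoltageTrace(times=vtimes, cluster_mean=vmean, monitored=vmon,
                         monitor_ids=mon_ids, geometry=geom)
    return raster, trace


def run_trials(
    network: Network,
    drive: DriveParams,
    stimulus: StimulusSpec,
    base_config: SimConfig,
    n_trials: int,
    seed_list=None,
) -> list[SpikeRaster]:
    """Repeat a stimulus run with independent seeds; identical network and
    stimulus, rasters aligned on the common stimulus-onset time."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if seed_list is None:
        seed_list = [base_config.seed + 1000 * i for i in range(n_trials)]
    if len(seed_list) != n_trials:
        raise ValueError("seed_list length must equal n_trials")
    if len(set(seed_list)) != len(seed_list):
        warnings.warn("duplicate seeds across trials", stacklevel=2)
    out = []
    for s in seed_list:
        cfg = replace(base_config, seed=int(s))
        raster, _ = run_simulation(network, drive, stimulus, cfg)
        out.append(raster)
    return out
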