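"""Feedforward drive: background and drifting-grating Poisson input.

Every neuron receives an independent Poisson spike train whose events are
delivered as instantaneous fast excitatory jumps of weight ``S_drive^Q``.
The rate of the train for neuron ``(Q, j, k, l)`` is

    eta(t) = eta_bkg^Q + C_{Q,j,k} * eta_bkg^Q * (1 + sin(2 pi omega (t - phi_l) / 1000))

where ``C`` is the effective contrast of the grating as seen by the
cluster (zero for untargeted clusters), ``omega`` the temporal frequency of
the grating in Hz, and ``phi_l`` the neuron's spatial-phase preference,
uniform over one grating period within each cluster.  The excitatory
population receives three times the contrast of the inhibitory one
(``C_E = 3 C_I``), standing in for orientation-tuned feedback.  A
phase-free variant replaces the sinusoid by its time average, leaving the
total rate constant at ``eta_bkg * (1 + C)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import NetworkGeometry, POP_E, POP_I


@dataclass(frozen=True)
class DriveParams:
    """Background rates (Hz) and feedforward jump weights per population.

    The drive weight of the E population is conventionally about half the
    recurrent E-to-E fast strength; shipped regimes respect that coupling
    (see :mod:`mfesim.regimes`).
    """

    eta_bkg_E: float = 400.0
    eta_bkg_I: float = 400.0
    S_drive_E: float = 0.0
    S_drive_I: float = 0.0

    def __post_init__(self):
        if self.eta_bkg_E < 0 or self.eta_bkg_I < 0:
            raise ValueError("background rates must be nonnegative")
        if self.S_drive_E < 0 or self.S_drive_I < 0:
            raise ValueError("drive weights must be nonnegative")

    def eta_bkg(self, pop: int) -> float:
        return self.eta_bkg_E if pop == POP_E else self.eta_bkg_I

    def S_drive(self, pop: int) -> float:
        return self.S_drive_E if pop == POP_E else self.S_drive_I


@dataclass(frozen=True)
class StimulusSpec:
    """A drifting-grating stimulus: targeted clusters and their contrasts.

    ``targets`` maps ``(j, k)`` cluster coordinates to the E-population
    contrast ``C_E``; inhibitory neurons in a targeted cluster see
    ``C_I = C_E / 3`` unless ``ci_ratio`` is overridden.  ``omega`` is the
    grating temporal frequency in Hz; per-neuron phases are drawn uniformly
    over one period from ``phase_seed``.  With ``phase_free`` the sinusoid
    is dropped and the stimulus rate is the constant ``C * eta_bkg``
    (time-average of the phased variant).
    """

    targets: dict[tuple[int, int], float] = field(default_factory=dict)
    omega: float = 4.0
    ci_ratio: float = 3.0          # C_E / C_I for targeted clusters
    phase_free: bool = False
    phase_seed: int = 0

    def __post_init__(self):
        for (j, k), c in self.targets.items():
            if c < 0:
                raise ValueError(f"contrast for cluster ({j},{k}) is negative")
        if self.omega <= 0:
            raise ValueError("omega must be positive")

    def contrast(self, pop: int, j: int, k: int) -> float:
        c_e = self.targets.get((j, k), 0.0)
        return c_e if pop == POP_E else c_e / self.ci_ratio

    @property
    def period_ms(self) -> float:
        return 1000.0 / self.omega

    def phases(self, geometry: NetworkGeometry) -> np.ndarray:
        """Per-neuron phase phi_l (ms), uniform over one grating period."""
        rng = np.random.default_rng(self.phase_seed)
        return rng.uniform(0.0, self.period_ms, size=geometry.n_neurons)


NO_STIMULUS = StimulusSpec()


def drive_rate(pop, j, k, t, drive: DriveParams,
               stimulus: StimulusSpec = NO_STIMULUS,
               phi: float | np.ndarray = 0.0):
    """Instantaneous feedforward Poisson rate (Hz) of one neuron.

    ``t`` (ms) and ``phi`` may be arrays (broadcast).  For untargeted
    clusters this is the constant background rate; for targeted ones the
    grating adds ``C * eta_bkg * (1 + sin(...))``, which is nonnegative for
    all phases.
    """
    t = np.asarray(t, dtype=float)
    eta = drive.eta_bkg(pop)
    c = stimulus.contrast(pop, j, k)
    if c == 0.0:
        out = np.broadcast_to(np.asarray(eta, float), np.broadcast(t, phi).shape).copy()
    elif stimulus.phase_free:
        out = eta + c * eta * np.ones_like(t + phi)
    else:
        ang = 2.0 * np.pi * stimulus.omega * (t - phi) / 1000.0
        out = eta + c * eta * (1.0 + np.sin(ang))
    return out if out.ndim else float(out)


def sample_input_spikes(rate_fn, horizon: float, seed, rate_max: float | None = None,
                        n_neurons: int = 1) -> list[np.ndarray]:
    """Sample inhomogeneous Poisson spike times on ``[0, horizon)`` ms by
    thinning.

    ``rate_fn(neuron_index, t_array) -> Hz`` must be bounded by ``rate_max``
    on the horizon (estimated by dense evaluation when not given, with a 1 %
    safety margin check).  Trains are independent across neurons and
    reproducible per ``(seed, neuron)`` via spawned generator streams.
    """
    if horizon < 0:
        raise ValueError("horizon must be nonnegative")
    streams = np.random.SeedSequence(seed).spawn(n_neurons)
    out = []
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        if rate_max is None:
            probe = rate_fn(i, np.linspace(0.0, horizon, 4097))
            sup = float(np.max(probe)) * 1.01 if np.size(probe) else 0.0
        else:
            sup = float(rate_max)
        if sup < 0 or not np.isfinite(sup):
            raise ValueError("rate bound must be finite and nonnegative")
        if sup == 0.0:
            out.append(np.empty(0))
            continue
        lam_ms = sup / 1000.0
        n_cand = rng.poisson(lam_ms * horizon)
        cand = np.sort(rng.uniform(0.0, horizon, size=n_cand))
        rates = np.asarray(rate_fn(i, cand), dtype=float)
        if np.any(rates < 0):
            raise ValueError("negative rate")
        if np.any(rates > sup * (1 + 1e-9)):
            raise ValueError("rate exceeds the stated bound; thinning invalid")
        keep = rng.uniform(0.0, sup, size=n_cand) < rates
        out.append(cand[keep])
    return out
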