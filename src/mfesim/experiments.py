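"""Scripted benchmark protocols and synthetic fixture generators.

The protocols wrap the simulator into the standard characterization runs:
spontaneous background activity (orientation-pattern episodes,
cross-covariance, spike-triggered voltage), iso-oriented surround
suppression (rates versus number of stimulated same-orientation clusters),
and the contrast x size sweep.  ``make_planted_raster`` generates
homogeneous-Poisson rasters with synchronous events of known times and
sizes planted in, for testing the MFE detector without the simulator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__ as _version
from .analysis import (CrossCovResult, RateCurves, SummaryStats, band_power,
                       crosscovariance, dominance_episodes, lfp_psd,
                       population_rate, rate_curves, trial_cv)
from .drive import StimulusSpec
from .engine import SimConfig, run_simulation, run_trials
from .network import Network, build_network, POP_E, POP_I
from .raster import SpikeRaster, VoltageTrace
from .regimes import Regime, REFERENCE

#: default contrasts of the contrast x size sweep (E-population values)
DEFAULT_CONTRASTS = (0.7500, 0.3750, 0.1875, 0.0938)

#: analysis burn-in (ms) excluded from steady-state statistics
BURN_IN_MS = 500.0


def _build(regime: Regime, build_seed: int = 0) -> Network:
    return build_network(regime.geometry, regime.connectivity, seed=build_seed)


def write_manifest(directory: str | Path, payload: dict) -> Path:
    """Echo the full run configuration (bit-exact re-run recipe)."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    payload = dict(payload, mfesim_version=_version)
    p = d / "manifest.yaml"
    p.write_text(yaml.safe_dump(payload, sort_keys=True))
    return p


@dataclass
class BackgroundResult:
    raster: SpikeRaster
    trace: VoltageTrace
    summary: SummaryStats
    crosscov: dict[tuple[int, int], CrossCovResult]   # (Qp, A) -> C(E,Qp,A,0)
    rate_E: float
    rate_I: float


def background_protocol(regime: Regime = REFERENCE, duration: float = 10000.0,
                        seed: int = 0, build_seed: int = 0,
                        tau_max: float = 500.0,
                        monitor: tuple[int, ...] = ()) -> BackgroundResult:
    """Background-only run with the spontaneous-pattern analysis pipeline.

    Returns per-orientation activity and dominance episodes, plus the
    cross-hypercolumn spike cross-covariances C(E, Q', A, 0, tau) for
    A in {0, 1} and Q' in {E, I}.
    """
    if duration < 2 * tau_max + BURN_IN_MS:
        raise ValueError("duration too short for the requested lag range")
    net = _build(regime, build_seed)
    cfg = SimConfig(duration_ms=duration, seed=seed, monitor=monitor,
                    regime_name=regime.name)
    raster, trace = run_simulation(net, regime.drive, config=cfg,
                                   params=regime.neuron, kernels=regime.kernels)
    summary = dominance_episodes(raster, t_start=BURN_IN_MS)
    xc = {}
    for Qp in (POP_E, POP_I):
        for A in (0, 1):
            xc[(Qp, A)] = crosscovariance(raster, POP_E, Qp, A, 0,
                                          tau_max=tau_max)
    return BackgroundResult(
        raster=raster, trace=trace, summary=summary, crosscov=xc,
        rate_E=population_rate(raster, POP_E, t_start=BURN_IN_MS),
        rate_I=population_rate(raster, POP_I, t_start=BURN_IN_MS))


def stimulus_for(n_stim: int, contrast: float, center: tuple[int, int] = (0, 0),
                 n_hypercolumns: int = 8, phase_seed: int = 0) -> StimulusSpec:
    """Grating stimulus targeting ``n_stim`` same-orientation clusters
    (the center cluster plus its nearest hypercolumn neighbors by index)."""
    j, k0 = center
    if not 1 <= n_stim <= n_hypercolumns:
        raise ValueError("n_stim must be in 1..n_hypercolumns")
    ks = [(k0 + d) % n_hypercolumns for d in range(n_stim)]
    return StimulusSpec(targets={(j, k): contrast for k in ks},
                        phase_seed=phase_seed)


def surround_suppression_protocol(
    regime: Regime = REFERENCE, contrast: float = 0.75,
    n_stim_list=(1, 8), duration: float = 8000.0, seed: int = 0,
    build_seed: int = 0, center: tuple[int, int] = (0, 0),
    onset_ms: float = 500.0,
) -> tuple[dict[int, SpikeRaster], RateCurves]:
    """Stimulate ``n`` same-orientation clusters for each ``n`` in
    ``n_stim_list`` and report center-cluster steady-state rates with the
    I-population MFE/nonMFE decomposition."""
    net = _build(regime, build_seed)
    runs: dict[int, SpikeRaster] = {}
    for i, n in enumerate(n_stim_list):
        stim = stimulus_for(n, contrast, center, regime.geometry.n_hypercolumns)
        cfg = SimConfig(duration_ms=duration, seed=seed + 101 * i,
                        stim_onset_ms=onset_ms, regime_name=regime.name)
        raster, _ = run_simulation(net, regime.drive, stim, cfg,
                                   params=regime.neuron, kernels=regime.kernels)
        runs[n] = raster
    curves = rate_curves(runs, center, t_start=onset_ms + BURN_IN_MS)
    return runs, curves


@dataclass
class ContrastSizeResult:
    contrasts: tuple[float, ...]
    n_stim: tuple[int, ...]
    rate_E: np.ndarray            # (n_contrasts, n_sizes) center-cluster E rate

    def peak_size(self, ci: int) -> int:
        """Stimulus size (number of clusters) of maximal E response."""
        return int(self.n_stim[int(np.argmax(self.rate_E[ci]))])


def contrast_size_sweep(
    regime: Regime = REFERENCE, contrasts=DEFAULT_CONTRASTS,
    n_stim_list=(1, 2, 4, 8), duration: float = 6000.0, seed: int = 0,
    build_seed: int = 0, center: tuple[int, int] = (0, 0),
    onset_ms: float = 500.0,
) -> ContrastSizeResult:
    """Center-cluster E rate across stimulus contrast and size."""
    if any(c <= 0 for c in contrasts):
        raise ValueError("contrasts must be positive")
    net = _build(regime, build_seed)
    out = np.zeros((len(contrasts), len(n_stim_list)))
    for ci, c in enumerate(contrasts):
        for ni, n in enumerate(n_stim_list):
            stim = stimulus_for(n, c, center, regime.geometry.n_hypercolumns)
            cfg = SimConfig(duration_ms=duration,
                            seed=seed + 7919 * ci + 101 * ni,
                            stim_onset_ms=onset_ms, regime_name=regime.name)
            raster, _ = run_simulation(net, regime.drive, stim, cfg,
                                       params=regime.neuron,
                                       kernels=regime.kernels)
            out[ci, ni] = population_rate(raster, POP_E, *center,
                                          t_start=onset_ms + BURN_IN_MS)
    return ContrastSizeResult(tuple(contrasts), tuple(n_stim_list), out)


# ---------------------------------------------------------------------------
# synthetic fixtures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedRasterSpec:
    """Homogeneous-Poisson raster with synchronous events planted in.

    ``events`` is a list of ``(time_ms, e_size, i_size)``; each event adds
    one spike to ``e_size`` distinct E neurons and ``i_size`` distinct I
    neurons at that time.
    """

    N_E: int = 128
    N_I: int = 128
    rate_hz: float = 5.0
    duration: float = 10000.0
    events: tuple[tuple[float, int, int], ...] = ()
    seed: int = 0

    def __post_init__(self):
        for t, e, i in self.events:
            if not 0.0 <= t < self.duration:
                raise ValueError(f"event time {t} outside the raster duration")
            if e > self.N_E or i > self.N_I:
                raise ValueError("planted event size exceeds the population")


def make_planted_raster(spec: PlantedRasterSpec) -> tuple[SpikeRaster, list]:
    """Generate the fixture raster and return it with its ground truth.

    The null part is exact homogeneous Poisson per neuron; planted events
    add synchronous spikes at the stated times to randomly chosen neurons.
    Ground truth entries are ``(time_ms, e_size, i_size)``.
    """
    rng = np.random.default_rng(spec.seed)
    from .network import NetworkGeometry
    geom = NetworkGeometry(1, 1, spec.N_E, spec.N_I)
    ts, pops, ls = [], [], []
    for pop, n in ((POP_E, spec.N_E), (POP_I, spec.N_I)):
        lam = spec.rate_hz / 1000.0 * spec.duration
        counts = rng.poisson(lam, size=n)
        tot = int(counts.sum())
        ts.append(rng.uniform(0.0, spec.duration, size=tot))
        pops.append(np.full(tot, pop))
        ls.append(np.repeat(np.arange(n), counts))
    for t, e_size, i_size in spec.events:
        for pop, size, n in ((POP_E, e_size, spec.N_E), (POP_I, i_size, spec.N_I)):
            if size == 0:
                continue
            picks = rng.choice(n, size=size, replace=False)
            ts.append(np.full(size, t))
            pops.append(np.full(size, pop))
            ls.append(picks)
    t = np.concatenate(ts)
    pop = np.concatenate(pops)
    l = np.concatenate(ls)
    order = np.argsort(t, kind="stable")
    raster = SpikeRaster(t=t[order], pop=pop[order],
                         j=np.zeros(t.size, np.int32)[order],
                         k=np.zeros(t.size, np.int32)[order],
                         l=l[order], geometry=geom, duration=spec.duration,
                         seed=spec.seed)
    return raster, list(spec.events)


# ---------------------------------------------------------------------------
# qualitative regime checklist
# ---------------------------------------------------------------------------

@dataclass
class ChecklistReport:
    """Recomputed qualitative benchmark statuses for a regime."""

    background_rates: bool
    episodes_50_500ms: bool
    e_surround_suppression: bool
    gamma_elevation: bool
    cv_drop: bool
    details: dict = field(default_factory=dict)

    def passed(self, names=None) -> bool:
        names = names or ("background_rates", "episodes_50_500ms",
                          "e_surround_suppression", "gamma_elevation",
                          "cv_drop")
        return all(getattr(self, n) for n in names)


def evaluate_checklist(
    regime: Regime = REFERENCE, seed: int = 0, build_seed: int = 0,
    bkg_duration: float = 10000.0, drive_duration: float = 8000.0,
    contrast: float = 0.75, n_bkg_seeds: int = 3,
    gamma_contrast: float = 0.375, n_trials: int = 6,
    trial_duration: float = 3000.0,
    gamma_band: tuple[float, float] = (25.0, 90.0),
    suppression_drop: float = 0.20,
) -> ChecklistReport:
    """Recompute the shipped regime's qualitative statuses.

    * background E/I rates plausible (E in 0.5-10 Hz, I in 2-40 Hz, I > E);
    * median background-pattern episode duration within 50-500 ms, with
      episodes pooled over ``n_bkg_seeds`` independent runs (episode counts
      per run are modest and an occasional long winner-take-all epoch is
      possible, so the pooled median is the robust summary);
    * center-cluster E rate at 8 stimulated same-orientation clusters at
      least ``suppression_drop`` below the 1-cluster rate (grating at
      ``contrast``);
    * gamma-band PSD of the center-cluster mean E voltage elevated under a
      full-field grating at ``gamma_contrast`` relative to background;
    * post-onset trial-to-trial CV below the pre-onset CV.
    """
    net = _build(regime, build_seed)
    geom = regime.geometry

    # background runs: rates from the first; episodes pooled over all
    durations = []
    bkg_trace = None
    rE = rI = 0.0
    for s in range(n_bkg_seeds):
        cfg = SimConfig(duration_ms=bkg_duration, seed=seed + 10 * s,
                        regime_name=regime.name)
        bkg_raster, tr = run_simulation(net, regime.drive, config=cfg,
                                        params=regime.neuron,
                                        kernels=regime.kernels)
        if s == 0:
            bkg_trace = tr
            rE = population_rate(bkg_raster, POP_E, t_start=BURN_IN_MS)
            rI = population_rate(bkg_raster, POP_I, t_start=BURN_IN_MS)
        summ = dominance_episodes(bkg_raster, t_start=BURN_IN_MS)
        durations.append(summ.episode_durations)
    durations = np.concatenate(durations)
    tau_persist = float(np.median(durations)) if durations.size else float("nan")
    rates_ok = (0.5 <= rE <= 10.0) and (2.0 <= rI <= 40.0) and rI > rE
    episodes_ok = durations.size >= 3 and 50.0 <= tau_persist <= 500.0

    # surround suppression: steady-state rates vary considerably between
    # realizations in this near-critical regime, so the drop is assessed
    # on rates averaged over independent runs
    r1s, r8s = [], []
    for s in range(2):
        _, curves = surround_suppression_protocol(
            regime, contrast=contrast, n_stim_list=(1, 8),
            duration=drive_duration, seed=seed + 1 + 30 * s,
            build_seed=build_seed)
        r1s.append(curves.rate_E[0])
        r8s.append(curves.rate_E[-1])
    r1 = float(np.mean(r1s))
    r8 = float(np.mean(r8s))
    suppression_ok = r8 <= (1.0 - suppression_drop) * r1 and r1 > 0

    # gamma elevation under a full-field grating
    stim = stimulus_for(geom.n_hypercolumns, gamma_contrast, (0, 0),
                        geom.n_hypercolumns)
    cfg_d = SimConfig(duration_ms=bkg_duration, seed=seed + 2,
                      stim_onset_ms=0.0, regime_name=regime.name)
    _, drv_trace = run_simulation(net, regime.drive, stim, cfg_d,
                                  params=regime.neuron, kernels=regime.kernels)
    burn = int(BURN_IN_MS / max(bkg_trace.sample_interval, 1e-9))
    f_b, p_b = lfp_psd(bkg_trace.lfp(0, 0)[burn:], bkg_trace.sample_interval)
    f_d, p_d = lfp_psd(drv_trace.lfp(0, 0)[burn:], drv_trace.sample_interval)
    g_b = band_power(f_b, p_b, *gamma_band)
    g_d = band_power(f_d, p_d, *gamma_band)
    gamma_ok = g_d > g_b

    # trial CV drop at onset (single-cluster grating)
    stim1 = stimulus_for(1, contrast, (0, 0), geom.n_hypercolumns)
    onset = trial_duration / 2.0
    cfg_t = SimConfig(duration_ms=trial_duration, seed=seed + 3,
                      stim_onset_ms=onset, v_sample_ms=0.0,
                      regime_name=regime.name)
    trials = run_trials(net, regime.drive, stim1, cfg_t, n_trials)
    pre = trial_cv(trials, (0.0, onset), POP_E, 0, 0)
    post = trial_cv(trials, (onset, trial_duration), POP_E, 0, 0)
    cv_ok = (np.isfinite(post.median) and np.isfinite(pre.median)
             and post.median < pre.median)

    return ChecklistReport(
        background_rates=bool(rates_ok),
        episodes_50_500ms=bool(episodes_ok),
        e_surround_suppression=bool(suppression_ok),
        gamma_elevation=bool(gamma_ok),
        cv_drop=bool(cv_ok),
        details={
            "rate_E_bkg": rE, "rate_I_bkg": rI,
            "n_episodes": int(durations.size), "tau_persist": tau_persist,
            "rate_E_n1": float(r1), "rate_E_n8": float(r8),
            "gamma_bkg": g_b, "gamma_driven": g_d,
            "cv_pre": pre.median, "cv_post": post.median,
        })
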