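"""Statistics over spike rasters and voltage traces.

Implements the multiple-firing-event (MFE) "95 % rule", spike binning,
cross-covariance and spike-triggered voltage summaries, the LFP-proxy power
spectrum, trial-to-trial variability and rate decompositions.

The 95 % rule: if all neurons of a population of size ``n`` fired
independently and uniformly in time at the observed mean rate, the spike
count of a time bin would be binomial.  A bin whose count strictly exceeds
the 95th percentile of that null is an *MFE-bin*; spikes inside MFE-bins
are *MFE-spikes*, the rest *nonMFE-spikes*, and the MFE-spike fraction
measures how inhomogeneous (bursty) the population output is.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal, stats

from .network import NetworkGeometry, POP_E, POP_I
from .raster import SpikeRaster, VoltageTrace


# ---------------------------------------------------------------------------
# binning
# ---------------------------------------------------------------------------

@dataclass
class BinnedCounts:
    """Per-(population, cluster) spike counts on a regular time grid.

    ``counts`` has shape ``(2, n_clusters, n_bins)``; bins are left-closed
    right-open, ``[i*bin_ms, (i+1)*bin_ms)``.
    """

    counts: np.ndarray
    bin_ms: float
    geometry: NetworkGeometry

    @property
    def n_bins(self) -> int:
        return self.counts.shape[2]

    def population(self, pop: int, j: int | None = None,
                   k: int | None = None) -> np.ndarray:
        """Summed counts of one population over a cluster selection."""
        g = self.geometry
        sel = np.ones(g.n_clusters, bool)
        if j is not None:
            sel &= (np.arange(g.n_clusters) % g.n_orientations) == j
        if k is not None:
            sel &= (np.arange(g.n_clusters) // g.n_orientations) == k
        return self.counts[pop][sel].sum(axis=0)


def bin_spikes(raster: SpikeRaster, bin_ms: float = 1.0,
               duration: float | None = None) -> BinnedCounts:
    """Bin a raster into per-population, per-cluster counts."""
    if bin_ms <= 0:
        raise ValueError("bin_ms must be positive")
    g = raster.geometry
    dur = raster.duration if duration is None else duration
    if dur <= 0:
        dur = float(raster.t.max()) + bin_ms if len(raster) else bin_ms
    n_bins = int(np.ceil(dur / bin_ms))
    counts = np.zeros((2, g.n_clusters, n_bins), dtype=np.int64)
    if len(raster):
        b = np.floor(raster.t / bin_ms).astype(np.int64)
        b = np.clip(b, 0, n_bins - 1)
        c = raster.k * g.n_orientations + raster.j
        np.add.at(counts, (raster.pop, c, b), 1)
    return BinnedCounts(counts=counts, bin_ms=bin_ms, geometry=g)


# ---------------------------------------------------------------------------
# MFE detection (95 % rule)
# ---------------------------------------------------------------------------

@dataclass
class MFEEvent:
    """One detected multiple-firing event (a flagged bin or run of bins)."""

    bin_index: int
    t_start: float
    t_end: float
    magnitude_E: int
    magnitude_I: int
    pop: int | None = None        # population whose counts triggered detection

    @property
    def magnitude(self) -> int:
        return self.magnitude_E + self.magnitude_I


def mfe_cutoff(n_neurons: int, mean_rate_hz: float, bin_ms: float = 1.0,
               percentile: float = 0.95) -> int:
    """Binomial null cutoff of the 95 % rule.

    Returns the smallest integer ``c`` with ``Binomial(n, p).cdf(c) >=
    percentile`` where ``p = rate * bin / 1000`` (clipped to 1); a bin is an
    MFE-bin iff its count strictly exceeds ``c``.
    """
    if not 0.0 < percentile < 1.0:
        raise ValueError("percentile must be in (0, 1)")
    if n_neurons < 1:
        raise ValueError("need at least one neuron")
    if mean_rate_hz < 0:
        raise ValueError("rate must be nonnegative")
    p = min(mean_rate_hz * bin_ms / 1000.0, 1.0)
    if p == 0.0:
        return 0
    return int(stats.binom.ppf(percentile, n_neurons, p))


def detect_mfes(counts: np.ndarray, cutoff: int, bin_ms: float = 1.0,
                merge_adjacent: bool = False,
                counts_other: np.ndarray | None = None,
                pop: int | None = None) -> list[MFEEvent]:
    """Flag MFE-bins of one population's count series (strictly above the
    cutoff) and return one event per flagged bin, or per maximal run of
    flagged bins when merging.

    ``counts_other`` optionally supplies the companion population's counts
    so events carry both magnitudes (the triggering population's count goes
    into ``magnitude_E``/``magnitude_I`` according to ``pop``).
    """
    counts = np.asarray(counts)
    flagged = counts > cutoff
    other = np.zeros_like(counts) if counts_other is None else np.asarray(counts_other)
    events: list[MFEEvent] = []
    idx = np.flatnonzero(flagged)
    if idx.size == 0:
        return events
    if merge_adjacent:
        splits = np.flatnonzero(np.diff(idx) > 1) + 1
        runs = np.split(idx, splits)
    else:
        runs = [np.array([i]) for i in idx]
    for run in runs:
        own = int(counts[run].sum())
        oth = int(other[run].sum())
        mag_E, mag_I = (own, oth) if pop in (None, POP_E) else (oth, own)
        events.append(MFEEvent(
            bin_index=int(run[0]), t_start=run[0] * bin_ms,
            t_end=(run[-1] + 1) * bin_ms,
            magnitude_E=mag_E, magnitude_I=mag_I, pop=pop))
    return events


def mfe_spike_fraction(counts: np.ndarray, cutoff: int) -> float:
    """Fraction of spikes lying in MFE-bins; 0 when there are no spikes."""
    counts = np.asarray(counts)
    total = counts.sum()
    if total == 0:
        return 0.0
    return float(counts[counts > cutoff].sum() / total)


def population_rate(raster: SpikeRaster, pop: int, j: int | None = None,
                    k: int | None = None, t_start: float = 0.0,
                    t_end: float | None = None) -> float:
    """Time-averaged per-neuron firing rate (Hz) of a population."""
    sub = raster.select(pop=pop, j=j, k=k)
    t_end = raster.duration if t_end is None else t_end
    n_spk = int(np.sum((sub.t >= t_start) & (sub.t < t_end)))
    g = raster.geometry
    n_per = g.N_E if pop == POP_E else g.N_I
    n_clusters = (1 if j is not None else g.n_orientations) * \
                 (1 if k is not None else g.n_hypercolumns)
    return 1000.0 * n_spk / (n_per * n_clusters * (t_end - t_start))


# ---------------------------------------------------------------------------
# cross-covariance
# ---------------------------------------------------------------------------

@dataclass
class CrossCovResult:
    """Lagged product-sums over neuron pairs of an (A, B) class.

    ``raw`` is ``C(Q,Q',A,B,tau) = dt * sum_t sum_pairs m(t) m'(t - tau)``
    (nonnegative); ``mean_subtracted`` applies the same pair sum to demeaned
    binned trains, which is the variant that can resolve anticorrelation.
    """

    tau: np.ndarray
    raw: np.ndarray
    mean_subtracted: np.ndarray
    Q: int
    Qp: int
    A: int
    B: int
    dt: float


def _xcorr_pair(x: np.ndarray, y: np.ndarray, max_lag: int) -> np.ndarray:
    """c[lag] = sum_t x[t] y[t - lag] over the full overlap, lag in
    [-max_lag, max_lag].  Direct method: exact in float64 for small-integer
    trains."""
    full = np.correlate(x, y, mode="full")   # index T-1 <-> lag 0
    T = y.shape[0]
    return full[T - 1 - max_lag: T + max_lag]


def crosscovariance(raster: SpikeRaster, Q: int, Qp: int, A: int, B: int,
                    tau_max: float = 500.0, dt: float = 1.0,
                    duration: float | None = None) -> CrossCovResult:
    """Cross-covariance of spiking between all ordered neuron pairs whose
    orientation match equals ``A`` and hypercolumn match equals ``B``.

    Pairs with the same trigger and target neuron (possible only when
    ``Q == Qp`` and ``A == B == 1``) are excluded.  Implemented over
    per-cluster aggregate trains; the same-cluster self-pair correction is
    computed from per-neuron autocorrelations.
    """
    if tau_max % dt != 0:
        raise ValueError("tau_max must be a multiple of dt")
    g = raster.geometry
    binned = bin_spikes(raster, dt, duration=duration)
    L = int(round(tau_max / dt))
    T = binned.n_bins
    if T <= L:
        raise ValueError("raster shorter than the requested lag range")
    nc = g.n_clusters
    cj = np.arange(nc) % g.n_orientations
    ck = np.arange(nc) // g.n_orientations
    same_j = cj[:, None] == cj[None, :]
    same_k = ck[:, None] == ck[None, :]
    klass = (same_j == bool(A)) & (same_k == bool(B))
    pairs = np.argwhere(klass)
    if pairs.size == 0:
        raise ValueError(f"no cluster pairs in class (A={A}, B={B}) "
                         f"for this geometry")
    X = binned.counts[Q].astype(np.float64)      # (nc, T) trigger pop
    Y = binned.counts[Qp].astype(np.float64)
    Xm = X - X.mean(axis=1, keepdims=True)
    Ym = Y - Y.mean(axis=1, keepdims=True)
    raw = np.zeros(2 * L + 1)
    ms = np.zeros(2 * L + 1)
    for c, cp in pairs:
        raw += _xcorr_pair(X[c], Y[cp], L)
        ms += _xcorr_pair(Xm[c], Ym[cp], L)
    if Q == Qp and A == 1 and B == 1:
        raw -= _self_pair_auto(raster, Q, L, dt, T)
        ms -= _self_pair_auto_demeaned(raster, Q, L, dt, T)
    tau = np.arange(-L, L + 1) * dt
    return CrossCovResult(tau=tau, raw=raw * dt, mean_subtracted=ms * dt,
                          Q=Q, Qp=Qp, A=A, B=B, dt=dt)


def _neuron_trains(raster: SpikeRaster, Q: int, dt: float, T: int):
    sub = raster.select(pop=Q)
    ids = sub.neuron_ids()
    bins = np.clip(np.floor(sub.t / dt).astype(np.int64), 0, T - 1)
    order = np.lexsort((bins, ids))
    ids, bins = ids[order], bins[order]
    cut = np.flatnonzero(np.diff(ids)) + 1
    return np.split(bins, cut)


def _self_pair_auto(raster: SpikeRaster, Q: int, L: int, dt: float,
                    T: int) -> np.ndarray:
    """sum over neurons of the raw autocorrelation of their binned train,
    from binned spike-time differences (exact)."""
    out = np.zeros(2 * L + 1)
    for bins in _neuron_trains(raster, Q, dt, T):
        u, cnt = np.unique(bins, return_counts=True)
        d = u[:, None] - u[None, :]
        w = cnt[:, None] * cnt[None, :]
        m = np.abs(d) <= L
        np.add.at(out, d[m] + L, w[m])
    return out


def _self_pair_auto_demeaned(raster: SpikeRaster, Q: int, L: int, dt: float,
                             T: int) -> np.ndarray:
    """sum over neurons of sum_t (x[t]-xbar)(x[t-tau]-xbar) over the full
    overlap (matching ``_xcorr_pair`` of each demeaned train with itself)."""
    out = np.zeros(2 * L + 1)
    lags = np.arange(-L, L + 1)
    for bins in _neuron_trains(raster, Q, dt, T):
        u, cnt = np.unique(bins, return_counts=True)
        n = cnt.sum()
        xbar = n / T
        d = u[:, None] - u[None, :]
        w = cnt[:, None] * cnt[None, :]
        m = np.abs(d) <= L
        raw = np.zeros(2 * L + 1)
        np.add.at(raw, d[m] + L, w[m])
        # partial sums of x over the overlap windows:
        # S_hi(tau) = sum_{t=max(0,tau)}^{T-1+min(0,tau)} x[t] etc. via
        # cumulative counts over sorted bins
        cum = np.cumsum(cnt)

        def between(lo, hi):  # sum of x[t] for lo <= t <= hi
            a = np.searchsorted(u, lo, side="left")
            b = np.searchsorted(u, hi, side="right")
            return (cum[b - 1] if b > 0 else 0) - (cum[a - 1] if a > 0 else 0)

        for ii, tau in enumerate(lags):
            lo_t, hi_t = max(0, tau), T - 1 + min(0, tau)
            s_x = between(lo_t, hi_t)
            s_y = between(lo_t - tau, hi_t - tau)
            n_ov = T - abs(tau)
            out[ii] += raw[ii] - xbar * (s_x + s_y) + n_ov * xbar * xbar
    return out


# ---------------------------------------------------------------------------
# spike-triggered voltage distribution
# ---------------------------------------------------------------------------

@dataclass
class STVResult:
    """Distribution of target-population voltages at lags around trigger
    spikes; per-lag slices sum to the trigger x target count (times dt)."""

    tau: np.ndarray
    v_edges: np.ndarray
    density: np.ndarray          # (n_tau, n_vbins)
    mean: np.ndarray             # per-lag mean voltage
    sd: np.ndarray
    n_triggers: int


def spike_triggered_voltage(
    raster: SpikeRaster, trace: VoltageTrace, Q: int, Qp: int, A: int, B: int,
    tau_max: float = 50.0, v_edges: np.ndarray | None = None,
    max_triggers: int = 20000, rng: np.random.Generator | None = None,
) -> STVResult:
    """Histogram of target-subset voltages at lag ``tau`` from each trigger
    spike of population ``Q``.

    Targets are the monitored neurons of ``trace`` belonging to population
    ``Qp`` and to clusters in the (A, B) class of the trigger's cluster.
    Lags run on the trace's sampling grid over ``[-tau_max, tau_max]``.
    """
    if trace.monitored.shape[1] == 0:
        raise ValueError("trace carries no monitored per-neuron voltages")
    dt = trace.sample_interval
    if dt <= 0:
        raise ValueError("trace needs at least two samples")
    g = raster.geometry
    mon = trace.monitor_ids
    cs = g.cluster_size
    mon_cluster = mon // cs
    within = mon % cs
    mon_pop = np.where(within < g.N_E, POP_E, POP_I)
    mon_j = (mon_cluster % g.n_orientations)
    mon_k = (mon_cluster // g.n_orientations)
    L = int(round(tau_max / dt))
    tau = np.arange(-L, L + 1) * dt
    if v_edges is None:
        v_edges = np.linspace(-2.0 / 3.0, 1.0, 65)
    sub = raster.select(pop=Q)
    t_lo, t_hi = trace.times[0] + tau_max, trace.times[-1] - tau_max
    keep = (sub.t >= t_lo) & (sub.t <= t_hi)
    trig_t = sub.t[keep]
    trig_j = sub.j[keep]
    trig_k = sub.k[keep]
    trig_id = sub.neuron_ids()[keep]
    if trig_t.size > max_triggers:
        rng = rng or np.random.default_rng(0)
        pick = rng.choice(trig_t.size, size=max_triggers, replace=False)
        trig_t, trig_j, trig_k = trig_t[pick], trig_j[pick], trig_k[pick]
        trig_id = trig_id[pick]
    n_trig = trig_t.size
    density = np.zeros((tau.size, v_edges.size - 1))
    mean = np.full(tau.size, np.nan)
    sd = np.full(tau.size, np.nan)
    if n_trig == 0:
        return STVResult(tau, v_edges, density, mean, sd, 0)
    trig_row = np.round((trig_t - trace.times[0]) / dt).astype(np.int64)
    trig_row = np.clip(trig_row, 0, trace.times.size - 1)
    V = trace.monitored
    for ii, lag_bins in enumerate(range(-L, L + 1)):
        rows = np.clip(trig_row - lag_bins, 0, trace.times.size - 1)
        vals_all = []
        for jj, kk, rr, tid in zip(trig_j, trig_k, rows, trig_id):
            tgt = ((mon_pop == Qp)
                   & ((mon_j == jj) == bool(A))
                   & ((mon_k == kk) == bool(B))
                   & (mon != tid))
            if tgt.any():
                vals_all.append(V[rr, tgt])
        if not vals_all:
            continue
        vals = np.concatenate(vals_all)
        density[ii], _ = np.histogram(vals, bins=v_edges)
        mean[ii] = vals.mean()
        sd[ii] = vals.std()
    return STVResult(tau, v_edges, density, mean, sd, n_trig)


# ---------------------------------------------------------------------------
# LFP-proxy spectrum, trial CV, rate curves
# ---------------------------------------------------------------------------

def lfp_psd(trace_values: np.ndarray, sample_ms: float,
            window_ms: float = 512.0):
    """Power spectral density of an LFP-proxy trace, averaged over
    nonoverlapping windows of ``window_ms`` (boxcar, no detrending beyond
    the per-window mean removal disabled: a constant trace keeps all its
    power at DC).

    Returns ``(freqs_hz, psd)``.
    """
    x = np.asarray(trace_values, float)
    nper = int(round(window_ms / sample_ms))
    if x.shape[0] < nper:
        raise ValueError("trace shorter than one analysis window")
    fs = 1000.0 / sample_ms
    freqs, psd = signal.welch(x, fs=fs, window="boxcar", nperseg=nper,
                              noverlap=0, detrend=False)
    return freqs, psd


def band_power(freqs: np.ndarray, psd: np.ndarray, f_lo: float,
               f_hi: float) -> float:
    """Mean PSD within [f_lo, f_hi] Hz (the gamma band by default use)."""
    m = (freqs >= f_lo) & (freqs <= f_hi)
    return float(psd[m].mean())


@dataclass
class TrialCV:
    cv: np.ndarray               # per-neuron CV (NaN where mean count is 0)
    active: np.ndarray           # bool, neurons with nonzero mean count
    median: float                # population median over active neurons

    @property
    def n_silent(self) -> int:
        return int((~self.active).sum())


def trial_cv(rasters: list[SpikeRaster], window: tuple[float, float],
             pop: int = POP_E, j: int | None = None,
             k: int | None = None) -> TrialCV:
    """Trial-to-trial coefficient of variation of per-neuron spike counts in
    a time window.

    CV = SD/mean (ddof=1) of each neuron's count across trials; neurons
    with zero mean count are reported separately rather than as NaN noise.
    """
    if len(rasters) < 2:
        raise ValueError("need at least two trials")
    t0, t1 = window
    for r in rasters:
        if t0 < 0 or t1 > r.duration:
            raise ValueError("window outside trial duration")
    g = rasters[0].geometry
    n_per = g.N_E if pop == POP_E else g.N_I
    njj = 1 if j is not None else g.n_orientations
    nkk = 1 if k is not None else g.n_hypercolumns
    n_neur = n_per * njj * nkk
    counts = np.zeros((len(rasters), n_neur))
    for ti, r in enumerate(rasters):
        sub = r.select(pop=pop, j=j, k=k)
        m = (sub.t >= t0) & (sub.t < t1)
        # contiguous per-neuron index within the selection
        key = sub.l[m].astype(np.int64)
        if njj > 1:
            key = key + n_per * sub.j[m]
        if nkk > 1:
            key = key + n_per * njj * sub.k[m]
        np.add.at(counts, (ti, key), 1)
    mean = counts.mean(axis=0)
    sd = counts.std(axis=0, ddof=1)
    active = mean > 0
    cv = np.full(n_neur, np.nan)
    cv[active] = sd[active] / mean[active]
    med = float(np.median(cv[active])) if active.any() else float("nan")
    return TrialCV(cv=cv, active=active, median=med)


# ---------------------------------------------------------------------------
# background-pattern episodes
# ---------------------------------------------------------------------------

@dataclass
class SummaryStats:
    """Per-orientation activity and dominance-episode summary of a
    background run.

    An *episode* is a maximal stretch during which one orientation's
    smoothed summed E activity exceeds the runner-up's by at least
    ``margin`` (a declared operational convention — the underlying patterns
    are random and often ill-defined) and that lasts at least
    ``min_duration_ms``.  The episode-length distribution summarizes the
    persistence timescale of spontaneous patterns.
    """

    activity: np.ndarray          # (n_orientations, n_bins) smoothed E counts
    bin_ms: float
    episode_durations: np.ndarray # ms
    episode_orientations: np.ndarray
    tau_persist: float            # median episode duration, ms

    @property
    def n_episodes(self) -> int:
        return self.episode_durations.size


def dominance_episodes(raster: SpikeRaster, bin_ms: float = 1.0,
                       smooth_ms: float = 25.0, margin: float = 1.0,
                       min_duration_ms: float = 25.0,
                       gap_merge_ms: float | None = None,
                       t_start: float = 500.0) -> SummaryStats:
    """Detect orientation-dominance episodes in background activity.

    ``margin`` is in units of smoothed spikes per bin summed over the
    orientation's clusters; the default requires the leading orientation to
    exceed the runner-up by one spike per ms on average over the smoothing
    window.  Sub-margin dips shorter than ``gap_merge_ms`` (default: the
    smoothing window) do not split an episode of one orientation —
    without this hysteresis, threshold chatter at the margin fragments a
    sustained pattern into spurious short episodes.
    """
    g = raster.geometry
    binned = bin_spikes(raster, bin_ms)
    i0 = int(np.floor(t_start / bin_ms))
    act = np.stack([binned.population(POP_E, j=j)[i0:]
                    for j in range(g.n_orientations)]).astype(float)
    w = max(1, int(round(smooth_ms / bin_ms)))
    kern = np.ones(w) / w
    sm = np.stack([np.convolve(a, kern, mode="same") for a in act])
    order = np.argsort(sm, axis=0)
    lead = order[-1]
    gap = np.take_along_axis(sm, order[-1][None], 0)[0] - \
        np.take_along_axis(sm, order[-2][None], 0)[0] if g.n_orientations > 1 \
        else sm[0]
    dominant = gap >= margin
    durations, oris = [], []
    if dominant.any():
        # label = leading orientation while dominant, -1 otherwise; an
        # episode is a maximal run of one label >= min_duration, after
        # bridging sub-margin gaps shorter than gap_merge_ms between runs
        # of the same orientation
        label = np.where(dominant, lead, -1)
        change = np.flatnonzero(np.diff(label)) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [label.size]))
        runs = [(a, b, int(label[a])) for a, b in zip(starts, ends)
                if label[a] >= 0]
        max_gap = (smooth_ms if gap_merge_ms is None else gap_merge_ms) / bin_ms
        merged: list[list] = []
        for a, b, o in runs:
            if merged and merged[-1][2] == o and a - merged[-1][1] <= max_gap:
                merged[-1][1] = b
            else:
                merged.append([a, b, o])
        for a, b, o in merged:
            if (b - a) * bin_ms >= min_duration_ms:
                durations.append((b - a) * bin_ms)
                oris.append(o)
    durations = np.asarray(durations, float)
    tau = float(np.median(durations)) if durations.size else float("nan")
    return SummaryStats(activity=sm, bin_ms=bin_ms,
                        episode_durations=durations,
                        episode_orientations=np.asarray(oris, int),
                        tau_persist=tau)


@dataclass
class RateCurves:
    """Center-cluster rates per stimulation condition (Fig-5c-style)."""

    n_stim: np.ndarray
    rate_E: np.ndarray
    rate_I: np.ndarray
    rate_I_mfe: np.ndarray
    rate_I_nonmfe: np.ndarray


def rate_curves(runs: dict[int, SpikeRaster], center: tuple[int, int],
                t_start: float = 500.0, bin_ms: float = 1.0,
                percentile: float = 0.95) -> RateCurves:
    """Time-averaged per-neuron rates of the center cluster versus number of
    stimulated clusters, with the I rate split into MFE- and nonMFE-spike
    rates by the 95 % rule."""
    j, k = center
    ns = sorted(runs)
    rE, rI, rIm, rIn = [], [], [], []
    for n in ns:
        raster = runs[n]
        g = raster.geometry
        t_end = raster.duration
        span = t_end - t_start
        rE.append(population_rate(raster, POP_E, j, k, t_start, t_end))
        rate_i = population_rate(raster, POP_I, j, k, t_start, t_end)
        rI.append(rate_i)
        binned = bin_spikes(raster, bin_ms)
        i0 = int(np.floor(t_start / bin_ms))
        ci = binned.counts[POP_I, g.cluster_index(j, k), i0:]
        cutoff = mfe_cutoff(g.N_I, rate_i, bin_ms, percentile)
        frac = mfe_spike_fraction(ci, cutoff)
        rIm.append(rate_i * frac)
        rIn.append(rate_i * (1.0 - frac))
    return RateCurves(np.asarray(ns), np.asarray(rE), np.asarray(rI),
                      np.asarray(rIm), np.asarray(rIn))
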