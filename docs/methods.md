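# Methods

## Model

`mfesim` simulates a ~2 mm² patch of superficial visual cortex as a network
of conductance-based integrate-and-fire point neurons. The patch is a 2-D
array of *clusters* (orientation domains): `J = 3` orientations in each of
`K = 8` hypercolumns, every cluster containing `N_E = 128` excitatory and
`N_I = 128` inhibitory cells (24 clusters, 6144 neurons by default).

Each membrane obeys

    tau_V dV/dt = -(V - V_L) - g_input (V - V_E)
                  - g_slow (V - V_E) - g_fastE (V - V_E) - g_fastI (V - V_I)

with dimensionless voltages `V_L = 0`, `V_E = 14/3`, `V_I = -2/3`, threshold
`V_T = 1`, reset `V_reset = 0`, and `tau_V = 20 ms`. On crossing threshold a
neuron fires, is reset, and is held at reset for the absolute refractory
period `tau_ref = 1 ms`, during which it ignores synaptic input.

Synaptic conductances are unit-integral alpha kernels with instantaneous
rise: a weight `W` always delivers total conductance-time `W`. The slow
(NMDA-like) excitatory kernel decays with `tau_slow = 128 ms`; because all
slow kernels share one decay time, each neuron's slow conductance is a
single exponential state that jumps by `W/tau_slow` per afferent spike. The
fast (AMPA / GABA-A-like) kernels are taken in the formal limit
`tau_fast -> 0+`, ordered so that `tau_ref >> tau_fast`. In that limit a
fast event of weight `w` becomes an exact voltage jump,

    V  ->  V_rev + (V - V_rev) exp(-w / tau_V),

the closed-form integral of the membrane equation across a delta
conductance. The jump moves the voltage strictly toward the synaptic
reversal and can never overshoot it, so voltages stay in `[V_I, V_T]`
without clipping. Finite fast timescales (`tau_fast ~ 2 ms`) are supported
as an option; there fast events increment decaying conductance states
instead of jumping the voltage.

### Multiple-firing events (MFEs)

With instantaneous fast synapses, all firing causally triggered by one
threshold crossing happens at a single instant: each spike jumps its
postsynaptic targets, possibly pushing more neurons over threshold, until
recruited inhibition (or exhaustion) stops the barrage. The cascade
resolver processes the instant iteratively:

1. among non-refractory, not-yet-fired neurons at/above threshold, the one
   with the **largest voltage surplus** fires next (ties broken uniformly
   at random per instant);
2. its fast weights are applied immediately as jumps to all eligible
   targets (already-fired and refractory neurons ignore them, since
   `tau_ref >> tau_fast`);
3. its slow weights are accumulated and added to the targets' slow
   conductances only after the instant (a slow kernel delivers zero
   conductance in zero time);
4. each neuron fires at most once per instant.

The source model constrains only that the E/I identity of successive
crossings matters; the largest-surplus rule is our deterministic
refinement, and the test suite verifies that the resulting fired sets equal
brute-force simulation of the finite-`tau_fast` conductance equations as
`tau_fast -> 0` (1000 random ≤ 6-neuron instances, `tau_fast` down to
10⁻⁴ ms). Instances in which some voltage lands within 5·10⁻³ of threshold
are excluded from that comparison: the zero-timescale limit is
discontinuous on that measure-zero boundary, so no finite-accuracy oracle
can adjudicate it.

### Connectivity

Whether two neurons connect, and at what strength, depends only on their
types (Q', Q), orientation match (delta_jj') and hypercolumn match
(delta_kk'). Connection probabilities are keyed by the *presynaptic* type —
0.20 from E cells and 0.50 from I cells within a cluster (I cells arborize
more densely), halved for pairs in different clusters of one hypercolumn.
Across hypercolumns only E cells project, only to same-orientation
clusters, with the same halved probability (no separate long-range
probability is specified by the source model; strength is controlled
independently). The reading of 0.20/0.50 as sender-based is a documented
choice; the text does not disambiguate. Within a hypercolumn there are 6
strengths (`S_fast^{QQ'}` and `S_slow^{QE}`); across hypercolumns 4
(`L_fast^{QE}`, `L_slow^{QE}`). Slow weights from I senders are
identically zero (no slow inhibition). All hypercolumn pairs are treated
as adjacent. An optional horizontal synaptic delay (tested at 10 ms)
applies to all long-range deliveries.

### Feedforward drive

Every neuron receives an independent Poisson train delivered through the
fast-E jump rule with weight `S_drive^Q`. The rate is

    eta(t) = eta_bkg^Q + C_{Q,j,k} eta_bkg^Q (1 + sin(2 pi omega (t - phi_l)/1000))

with `omega = 4 Hz` (grating temporal frequency), per-neuron spatial phases
`phi_l` uniform over one period, contrast `C` nonzero only for targeted
clusters and `C_E = 3 C_I`. A phase-free variant replaces the sinusoid by
its time average (constant `eta_bkg (1 + C)`). Background rates for E and
I are exposed separately but default equal (400 Hz); the model text leaves
this open.

## Numerical scheme

The engine advances the whole network on fixed substeps of 0.1 ms.
Within a substep each neuron is relaxed with the exact exponential step of
the membrane equation under frozen conductances, the conductances being
evaluated at the substep midpoint (second-order accurate in the slow
decay). Threshold crossings during relaxation are located by linear
interpolation inside the substep; the earliest crossing time stamps the
cascade, and all spikes of one cascade share that timestamp.

Feedforward arrivals are delivered at the boundary of the substep that
contains them. Jumps toward a common reversal compose exactly (weights
add), so this equals event-time delivery up to a ≤ 0.1 ms quantization.
Rather than materializing ~10⁶ input events per simulated second, the
kernel samples the *summed* Poisson rate of each homogeneous group per
substep and assigns events to member neurons (by rejection against the
per-neuron sinusoidal weight for phased stimuli) — exact in distribution
by the superposition property. For convergence studies the engine also
accepts an explicit per-neuron list of input spike times, so the identical
input realization can be replayed at different substep sizes.

Convergence: with a frozen input realization and recurrence weak enough
that the population response is locked to the input (the shipped
`subcritical-reference` regime), halving the substep changes the total
spike count of a 10 s run by < 0.5 %, and with recurrence off entirely by
< 0.1 %. In near-critical MFE regimes trajectories are chaotic — substep
halving there changes *which* cascades occur (as any perturbation does)
while leaving rates and MFE statistics unchanged; a per-spike convergence
criterion is not meaningful in that setting, which is why the reference
condition for the numerical check is subcritical.

All randomness — initial voltages (uniform in `[V_reset, 0.95 V_T]`, to
avoid startup synchrony), drive sampling, within-instant tie-breaks —
derives from one master seed, and runs are bit-reproducible. The first
500 ms of every run are excluded from steady-state analysis (burn-in; our
convention). Slow-conductance increments addressed to refractory targets
are dropped along with fast input, matching the rule that a refractory
neuron ignores synaptic input.

## Analysis conventions

**95 % rule.** If all `n` neurons of a population fired independently and
uniformly at the observed mean rate `r`, a 1 ms bin's spike count would be
`Binomial(n, r·bin/1000)`. The cutoff is the smallest integer `c` with
`CDF(c) >= 0.95`; a bin is an MFE-bin iff its count **strictly exceeds**
`c`. The rate entering the null is the time-averaged population rate over
the analyzed epoch (the estimation window is not specified by the source
model). For finite fast timescales the bin should be comparable to or
larger than `tau_fast` (we use 3 ms at `tau_fast = 2 ms`); with
instantaneous synapses 1 ms bins pin each MFE to one bin.

**Cross-covariance.** `C(Q,Q',A,B,tau) = dt * sum over ordered neuron
pairs with delta_jj' = A, delta_kk' = B of sum_t m(t) m'(t - tau)`, on
1 ms binned trains over the full overlap (linear, not circular), with
self-pairs excluded when they coincide. The raw product sum is nonnegative
by construction and cannot express anticorrelation, so the mean-subtracted
variant (same pair sum over demeaned trains) is computed alongside and is
the default for interpretation; both are returned. The estimator
aggregates per-cluster trains and corrects same-cluster classes with
per-neuron autocorrelations; it is bit-exact against a literal double loop
for the raw variant (integer arithmetic in float64).

**Spike-triggered voltage (STV).** The distribution of target-subset
membrane voltages at lags around each trigger spike, over monitored
neurons of the chosen (A, B) class; per-lag mean and SD summarize the
histograms. Triggers are subsampled (default cap 20 000) for tractability.

**LFP proxy and spectra.** The LFP proxy is the population-averaged
subthreshold voltage of a cluster (E population by default). PSDs average
periodograms over nonoverlapping 512 ms boxcar windows (frequency
resolution ≈ 1.95 Hz), without detrending, so a constant trace keeps all
power at DC. Gamma band: 25–90 Hz.

**Background-pattern episodes.** Per-orientation summed E activity is
smoothed with a 25 ms boxcar; an episode is a maximal stretch in which one
orientation exceeds the runner-up by ≥ 1 spike/ms (summed over its 8
clusters, i.e. ~1 Hz/neuron) for at least 25 ms. Sub-margin dips shorter
than the smoothing window do not split an episode of one orientation
(hysteresis — without it, threshold chatter at the margin fragments a
sustained pattern into spurious short pieces). The margin and the episode
definition are declared operational conventions — the underlying patterns
are random and often ill-defined. The episode-duration median estimates
the persistence timescale `tau_persist`.

**Trial variability.** CV = SD/mean (ddof = 1) of per-neuron spike counts
across trials in a window; neurons with zero mean count are reported
separately rather than as NaNs. The population summary is the median over
active neurons.

## The shipped regime

The coupling strengths of the published model are not in its main text, so
the `reference` regime is this package's own calibration, tuned against
the qualitative benchmark checklist under the stated constraints
(`S_drive_E ≈ 0.5 S_fast_EE`, `eta_bkg` in 250–500 Hz):

| group | values |
|---|---|
| local fast | `S_EE = 0.60`, `S_IE = 0.53`, `S_EI = 1.25`, `S_II = 0.40` |
| local slow | `S_slow_EE = 2.00`, `S_slow_IE = 1.00` |
| long-range | `L_EE = 0.15`, `L_IE = 0.45`, `L_slow_EE = 1.00`, `L_slow_IE = 0.70` |
| drive | `eta_bkg = 400 Hz` (E and I), `S_drive_E = 0.30`, `S_drive_I = 0.24` |

Calibration followed the published recipe: background rates and
EPSP-scale jumps first, then competitive adjustment of excitation against
inhibition. The decisive competition is between fast E-E cascade growth
(`S_EE`) and I recruitment (`S_IE`, `S_EI`): too little inhibition gives
near-synchronous population spikes, slightly too much extinguishes firing;
the biologically styled region between them is narrow. Slow E-E coupling
(`S_slow_*`, `L_slow_EE`) sustains orientation patterns; slow long-range
drive onto I (`L_slow_IE`) is the delayed negative feedback that releases
a dominant orientation — with it too weak the network locks into a single
pattern for seconds. In this regime background rates are ~1.5–2.5 Hz (E)
and ~10–19 Hz (I); episode durations pool to a median near 70–120 ms with
occasional multi-second winner-take-all epochs (the pooled median over
three 10 s runs is the robust summary and is what the checklist tests).
Surround-suppression rates are likewise averaged over two independent
runs in the checklist, because the driven steady state is strongly
realization-dependent near criticality.

Benchmark protocols at desk scale:

* *Surround suppression*: drifting grating at contrast 0.75 on 1 vs 8
  same-orientation clusters, 8 s runs; center E rate drops (15–90 %
  depending on realization). The checklist pass convention is a ≥ 20 %
  drop ("significant" is not quantified by the source model); the
  directional comparison is the robust assertion. The I population's
  MFE-spike rate decreases with stimulus size in every realization
  observed, while total I rate may go either way — both behaviors are
  documented outcomes of the model class, governed by the MFE-spike
  fraction under single-cluster drive.
* *Gamma elevation*: full-field grating (all 8 hypercolumns, contrast
  0.375), 10 s; gamma-band power of the center-cluster E-mean voltage
  rises by ~30–50 % over background. Single-cluster drive does not yield a
  robust elevation in this regime: the driven cluster's rhythm is diluted
  by ongoing background patterns elsewhere, and the comparison flips sign
  between realizations.
* *Variance reduction*: 6 trials of 3 s, single-cluster grating at
  contrast 0.75 with onset at 1.5 s; the population-median per-neuron CV
  drops from ~1.5 to ~1.0.
* *Contrast × size sweep*: contrasts 0.7500/0.3750/0.1875/0.0938 across
  1–8 stimulated clusters.

A second, weakly coupled `subcritical-reference` regime (quarter-strength
couplings, strong drive) is shipped purely as the reference condition for
numerical-convergence checks; it is not a biological calibration. The
`single-cluster-mfe` regime isolates one cluster with prominent MFEs for
mechanism demonstrations and engine tests.

## What the synthetic fixtures do and do not show

`make_planted_raster` generates homogeneous-Poisson null rasters with
synchronous events of known times and sizes planted in. Against these the
MFE detector's null calibration (flagged-bin fraction ≤ 5 % + 3σ over 100
seeds) and sensitivity (events ≥ 3× cutoff always recovered) are exact,
because the fixture realizes the detector's null hypothesis literally.
Real (and simulated) spike trains violate that null — refractoriness,
burstiness, rate drift — so detector performance there is characterized
only qualitatively; in particular the flagged fraction in background
regimes exceeds the nominal 5 % precisely because the network is *not*
firing independently, which is what the MFE-spike fraction measures.

## Known limitations

* The cluster topology is all-to-all at the hypercolumn level: no spatial
  kernels, no retinotopy, no realistic orientation map.
* Coupling values are a package calibration, not the published regime;
  quantitative figures (rates, episode statistics, suppression depth)
  characterize this calibration only.
* Near-critical regimes make some qualitative outcomes
  realization-dependent (depth of surround suppression, direction of the
  total-I-rate change); tests assert the robust directions and document
  the variable ones.
* Input arrival times are quantized to 0.1 ms; analyses at finer temporal
  resolution than the substep are not meaningful.
* The natural-image surround protocol and avalanche power-law exponent
  estimation are out of scope.
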