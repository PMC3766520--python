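"""Raster statistics: binning, the 95 % rule, cross-covariance, STV, PSD,
trial variability and rate decompositions."""

import numpy as np
import pytest
from scipy import stats

import mfesim as m
from mfesim.analysis import (band_power, bin_spikes, crosscovariance,
                             detect_mfes, dominance_episodes, lfp_psd,
                             mfe_cutoff, mfe_spike_fraction, rate_curves,
                             spike_triggered_voltage, trial_cv)
from mfesim.network import POP_E, POP_I

from _oracles import direct_crosscov


def _raster(ts, pops, js, ks, ls, geom, dur):
    order = np.argsort(ts, kind="stable")
    return m.SpikeRaster(np.asarray(ts, float)[order],
                         np.asarray(pops)[order], np.asarray(js)[order],
                         np.asarray(ks)[order], np.asarray(ls)[order],
                         geometry=geom, duration=dur)


class TestBinning:
    def test_left_closed_right_open(self):
        g = m.NetworkGeometry(1, 1, 4, 4)
        r = _raster([0.2, 0.9, 1.0], [0] * 3, [0] * 3, [0] * 3, [0, 1, 2],
                    g, 2.0)
        b = bin_spikes(r, 1.0)
        assert b.counts[POP_E, 0].tolist() == [2, 1]

    def test_single_bin_equals_total(self):
        g = m.NetworkGeometry(1, 1, 4, 4)
        r = _raster([0.1, 3.3, 7.7], [0] * 3, [0] * 3, [0] * 3, [0] * 3,
                    g, 8.0)
        b = bin_spikes(r, 8.0)
        assert b.counts.sum() == 3 and b.n_bins == 1

    def test_counts_conserve_raster_size(self, rng):
        g = m.NetworkGeometry(2, 2, 8, 8)
        n = 500
        r = _raster(rng.uniform(0, 100, n), rng.integers(0, 2, n),
                    rng.integers(0, 2, n), rng.integers(0, 2, n),
                    rng.integers(0, 8, n), g, 100.0)
        assert bin_spikes(r, 1.0).counts.sum() == n


class TestCutoff:
    def test_zero_rate_cutoff_zero(self):
        assert mfe_cutoff(128, 0.0) == 0

    def test_exact_binomial_enumeration(self):
        # oracle: explicit CDF accumulation
        n, p, q = 128, 5.0 * 1.0 / 1000.0, 0.95
        cdf, c = 0.0, 0
        while True:
            cdf += stats.binom.pmf(c, n, p)
            if cdf >= q:
                break
            c += 1
        assert mfe_cutoff(128, 5.0, 1.0) == c == 2

    def test_count_equal_to_cutoff_not_flagged(self):
        cut = mfe_cutoff(128, 5.0, 1.0)
        ev = detect_mfes(np.array([cut, cut + 1, cut]), cut)
        assert len(ev) == 1 and ev[0].bin_index == 1

    def test_invalid_percentile(self):
        with pytest.raises(ValueError):
            mfe_cutoff(128, 5.0, percentile=1.5)


class TestDetect:
    def test_null_flagging_rate_bounded(self, rng):
        n, rate, T = 128, 5.0, 20000
        p = rate / 1000.0
        counts = rng.binomial(n, p, size=T)
        cut = mfe_cutoff(n, rate)
        frac = np.mean(counts > cut)
        tail = 1.0 - stats.binom.cdf(cut, n, p)
        assert frac <= 0.05 + 3 * np.sqrt(tail * (1 - tail) / T)

    def test_planted_events_recovered_exactly(self):
        spec = m.PlantedRasterSpec(rate_hz=3.0, duration=8000.0,
                                   events=((1000.5, 30, 25),
                                           (3000.5, 30, 0),
                                           (6000.5, 30, 10)), seed=4)
        raster, truth = m.make_planted_raster(spec)
        b = bin_spikes(raster, 1.0)
        cut = mfe_cutoff(128, 3.0)
        ev = detect_mfes(b.counts[POP_E, 0], cut)
        big = [e for e in ev if e.magnitude_E >= 3 * max(cut, 1)]
        assert sorted(e.bin_index for e in big) == [1000, 3000, 6000]

    def test_empty_raster_no_events(self):
        assert detect_mfes(np.zeros(100, int), 2) == []

    def test_merge_adjacent_runs(self):
        counts = np.array([0, 5, 6, 0, 4, 0])
        ev = detect_mfes(counts, 2, merge_adjacent=True)
        assert len(ev) == 2
        assert ev[0].magnitude_E == 11 and ev[0].t_end - ev[0].t_start == 2.0


class TestFraction:
    def test_all_spikes_in_flagged_bins(self):
        assert mfe_spike_fraction(np.array([0, 50, 0]), 2) == 1.0

    def test_no_spikes_gives_zero(self):
        assert mfe_spike_fraction(np.zeros(10, int), 2) == 0.0

    def test_fraction_decreases_with_stricter_percentile(self, rng):
        counts = rng.binomial(128, 0.005, size=10000)
        fr = [mfe_spike_fraction(counts, mfe_cutoff(128, 5.0, percentile=q))
              for q in (0.9, 0.99, 0.999)]
        assert fr[0] >= fr[1] >= fr[2]


class TestCrossCovariance:
    GEOM = m.NetworkGeometry(n_hypercolumns=2, n_orientations=2, N_E=2, N_I=1)

    def test_empty_raster_identically_zero(self):
        r = _raster([], [], [], [], [], self.GEOM, 1000.0)
        out = crosscovariance(r, POP_E, POP_E, 1, 0, tau_max=50.0)
        assert np.all(out.raw == 0.0)

    def test_two_single_spikes_offset(self):
        # spikes offset by 7 ms in same-orientation clusters of different
        # hypercolumns: raw C(E,E,1,0) is nonzero exactly at +-7
        r = _raster([100.0, 107.0], [0, 0], [0, 0], [0, 1], [0, 0],
                    self.GEOM, 1000.0)
        out = crosscovariance(r, POP_E, POP_E, 1, 0, tau_max=20.0, dt=1.0)
        nz = out.tau[out.raw > 0]
        assert set(nz.tolist()) == {-7.0, 7.0}

    def test_symmetric_for_equal_populations(self, rng):
        n = 400
        r = _raster(rng.uniform(0, 2000, n), np.zeros(n, int),
                    rng.integers(0, 2, n), rng.integers(0, 2, n),
                    rng.integers(0, 2, n), self.GEOM, 2000.0)
        out = crosscovariance(r, POP_E, POP_E, 1, 0, tau_max=50.0)
        assert np.allclose(out.raw, out.raw[::-1])
        assert np.allclose(out.mean_subtracted, out.mean_subtracted[::-1])

    @pytest.mark.parametrize("Q,Qp,A,B", [
        (POP_E, POP_E, 1, 0), (POP_E, POP_I, 0, 0),
        (POP_E, POP_E, 1, 1), (POP_I, POP_I, 1, 1), (POP_E, POP_I, 0, 1)])
    def test_matches_double_loop_oracle(self, rng, Q, Qp, A, B):
        n = 300
        pops = rng.integers(0, 2, n)
        ls = np.where(pops == POP_E, rng.integers(0, 2, n), 0)
        r = _raster(rng.uniform(0, 1000, n), pops,
                    rng.integers(0, 2, n), rng.integers(0, 2, n),
                    ls, self.GEOM, 1000.0)
        out = crosscovariance(r, Q, Qp, A, B, tau_max=20.0, dt=1.0)
        _, raw, ms = direct_crosscov(r, Q, Qp, A, B, 20.0, 1.0, 1000)
        assert np.array_equal(out.raw, raw)            # bit-exact
        assert np.allclose(out.mean_subtracted, ms, atol=1e-9)

    def test_flat_for_independent_poisson_populations(self, rng):
        # mean-subtracted C between two independent homogeneous populations
        # stays within 4 sigma of zero everywhere
        n = 4000
        r = _raster(rng.uniform(0, 20000, n), np.zeros(n, int),
                    rng.integers(0, 2, n), rng.integers(0, 2, n),
                    rng.integers(0, 2, n), self.GEOM, 20000.0)
        out = crosscovariance(r, POP_E, POP_E, 0, 0, tau_max=100.0)
        ms = out.mean_subtracted
        assert np.all(np.abs(ms - ms.mean()) < 4 * ms.std() + 1e-9)

    def test_record_order_invariance(self, rng):
        n = 200
        ts = rng.uniform(0, 1000, n)
        args = (np.zeros(n, int), rng.integers(0, 2, n),
                rng.integers(0, 2, n), rng.integers(0, 2, n))
        r1 = _raster(ts, *args, self.GEOM, 1000.0)
        perm = rng.permutation(n)
        r2 = m.SpikeRaster(r1.t[perm], r1.pop[perm], r1.j[perm], r1.k[perm],
                           r1.l[perm], self.GEOM, 1000.0)
        a = crosscovariance(r1, POP_E, POP_E, 1, 0, tau_max=20.0)
        b = crosscovariance(r2, POP_E, POP_E, 1, 0, tau_max=20.0)
        assert np.array_equal(a.raw, b.raw)

    def test_missing_class_raises(self):
        g = m.NetworkGeometry(1, 1, 4, 4)
        r = _raster([1.0], [0], [0], [0], [0], g, 100.0)
        with pytest.raises(ValueError):
            crosscovariance(r, POP_E, POP_E, 1, 0, tau_max=10.0)


class TestSTV:
    GEOM = m.NetworkGeometry(2, 2, 2, 2)

    def _trace(self, values):
        times = np.arange(values.shape[0], dtype=float)
        mon = np.arange(self.GEOM.n_neurons)
        return m.VoltageTrace(times, np.zeros((len(times),
                                               self.GEOM.n_clusters, 2)),
                              values, mon, self.GEOM)

    def test_no_triggers_empty(self):
        r = _raster([], [], [], [], [], self.GEOM, 100.0)
        tr = self._trace(np.full((100, self.GEOM.n_neurons), 0.3))
        out = spike_triggered_voltage(r, tr, POP_E, POP_E, 1, 0, tau_max=5.0)
        assert out.n_triggers == 0 and out.density.sum() == 0

    def test_single_trigger_point_mass(self):
        r = _raster([50.0], [0], [0], [0], [0], self.GEOM, 100.0)
        tr = self._trace(np.full((100, self.GEOM.n_neurons), 0.3))
        out = spike_triggered_voltage(r, tr, POP_E, POP_E, 1, 0, tau_max=5.0)
        assert np.allclose(out.mean, 0.3)
        # all mass in the bin containing 0.3
        vb = np.digitize(0.3, out.v_edges) - 1
        assert np.all(out.density[:, vb] == out.density.sum(axis=1))

    def test_same_orientation_targets_sit_higher(self):
        # construct voltages where same-orientation targets are nearer
        # threshold; STV mean for A=1 exceeds A=0
        vals = np.zeros((200, self.GEOM.n_neurons))
        j_of = (np.arange(self.GEOM.n_neurons) // self.GEOM.cluster_size) % 2
        vals[:, j_of == 0] = 0.8
        vals[:, j_of == 1] = 0.2
        tr = self._trace(vals)
        r = _raster([100.0, 120.0], [0, 0], [0, 0], [0, 1], [0, 1],
                    self.GEOM, 200.0)
        hi = spike_triggered_voltage(r, tr, POP_E, POP_E, 1, 0, tau_max=5.0)
        lo = spike_triggered_voltage(r, tr, POP_E, POP_E, 0, 0, tau_max=5.0)
        assert np.nanmean(hi.mean) > np.nanmean(lo.mean)

    def test_missing_voltage_samples_rejected(self):
        r = _raster([50.0], [0], [0], [0], [0], self.GEOM, 100.0)
        tr = m.VoltageTrace(np.arange(100.0),
                            np.zeros((100, self.GEOM.n_clusters, 2)),
                            np.zeros((100, 0)), np.array([], int), self.GEOM)
        with pytest.raises(ValueError):
            spike_triggered_voltage(r, tr, POP_E, POP_E, 1, 0)


class TestPSD:
    def test_constant_trace_all_power_at_dc(self):
        f, p = lfp_psd(np.full(4096, 0.42), 1.0, window_ms=512)
        assert p[0] > 0
        assert np.all(p[1:] < 1e-20 * p[0])

    def test_injected_40hz_peak(self):
        t = np.arange(4096)
        x = 0.05 * np.sin(2 * np.pi * 40.0 * t / 1000.0)
        f, p = lfp_psd(x, 1.0, window_ms=512)
        assert f[np.argmax(p)] == pytest.approx(40.0, abs=1000.0 / 512)

    def test_frequency_resolution(self):
        f, p = lfp_psd(np.random.default_rng(0).normal(size=2048), 1.0, 512)
        assert f[1] - f[0] == pytest.approx(1000.0 / 512)

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            lfp_psd(np.zeros(100), 1.0, window_ms=512)


class TestTrialCV:
    GEOM = m.NetworkGeometry(1, 1, 8, 8)

    def _trials_from_counts(self, counts, rng):
        # counts: (n_trials, n_neurons) spike counts in [0, 1000)
        out = []
        for row in counts:
            ts, ls = [], []
            for l, c in enumerate(row):
                ts.append(rng.uniform(0, 1000, c))
                ls.append(np.full(c, l))
            t = np.concatenate(ts) if ts else np.array([])
            l = np.concatenate(ls).astype(int) if ls else np.array([], int)
            out.append(_raster(t, np.zeros(t.size, int), np.zeros(t.size, int),
                               np.zeros(t.size, int), l, self.GEOM, 1000.0))
        return out

    def test_identical_counts_cv_zero(self, rng):
        counts = np.tile(np.array([3, 5, 0, 2, 7, 1, 4, 6]), (4, 1))
        trials = self._trials_from_counts(counts, rng)
        out = trial_cv(trials, (0.0, 1000.0), POP_E, 0, 0)
        assert np.allclose(out.cv[out.active], 0.0)
        assert out.n_silent == 1

    def test_poisson_counts_cv_inverse_sqrt_lambda(self, rng):
        lam = 25.0
        counts = rng.poisson(lam, size=(200, 8))
        trials = self._trials_from_counts(counts, rng)
        out = trial_cv(trials, (0.0, 1000.0), POP_E, 0, 0)
        assert np.median(out.cv[out.active]) == pytest.approx(
            lam ** -0.5, rel=0.15)

    def test_fewer_than_two_trials_rejected(self, rng):
        trials = self._trials_from_counts(np.array([[1] * 8]), rng)
        with pytest.raises(ValueError):
            trial_cv(trials, (0.0, 1000.0))

    def test_window_outside_duration_rejected(self, rng):
        trials = self._trials_from_counts(np.ones((2, 8), int), rng)
        with pytest.raises(ValueError):
            trial_cv(trials, (500.0, 2000.0))


class TestRateCurves:
    def test_decomposition_partitions_total(self, rng):
        g = m.NetworkGeometry(2, 1, 16, 16)
        runs = {}
        for n in (1, 2):
            size = 600
            runs[n] = _raster(rng.uniform(0, 3000, size),
                              rng.integers(0, 2, size),
                              np.zeros(size, int),
                              rng.integers(0, 2, size),
                              rng.integers(0, 16, size), g, 3000.0)
        out = rate_curves(runs, (0, 0), t_start=500.0)
        assert np.allclose(out.rate_I_mfe + out.rate_I_nonmfe, out.rate_I)
        assert out.n_stim.tolist() == [1, 2]


class TestEpisodes:
    def test_constructed_dominance_recovered(self):
        g = m.NetworkGeometry(2, 3, 4, 4)
        ts, js = [], []
        # orientation 1 dominates 1000-1200 ms at 20 spikes/ms; orientation
        # 2 dominates 1500-1900 ms; background elsewhere is silent
        for t0, t1, j in ((1000, 1200, 1), (1500, 1900, 2)):
            n = (t1 - t0) * 4
            ts.append(np.linspace(t0, t1, n, endpoint=False))
            js.append(np.full(n, j))
        t = np.concatenate(ts)
        j = np.concatenate(js)
        n = t.size
        r = _raster(t, np.zeros(n, int), j, np.zeros(n, int),
                    np.zeros(n, int), g, 3000.0)
        s = dominance_episodes(r, t_start=500.0, margin=1.0)
        assert s.n_episodes == 2
        assert s.episode_orientations.tolist() == [1, 2]
        assert s.episode_durations[0] == pytest.approx(200.0, abs=30.0)
        assert s.episode_durations[1] == pytest.approx(400.0, abs=30.0)
        assert 50.0 <= s.tau_persist <= 500.0
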