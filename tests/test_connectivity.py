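"""Functional-connectivity estimators and adjacency assembly.

Each estimator is checked against hand computations, analytic oracles, and
an independent brute-force implementation (direct DFT cross-spectra, direct
double-loop wavelet convolution, direct complex-mean PLV).
"""

import numpy as np
import pytest

from stgcn_eeg.bands import ALPHA, BETA, FULL, BandSpec
from stgcn_eeg.connectivity import (DegenerateEstimateError, SpectralParams,
                                    WaveletSpec, adjacency, band_bin_mask,
                                    instantaneous_phase, ipc, morlet_cwt, msc,
                                    pearson, pli, plv, wavelet_coherence,
                                    epoch_adjacencies)
from stgcn_eeg.preprocess import MiniEpoch
from stgcn_eeg.synthetic import rayleigh_null_mean


class TestPearson:
    @pytest.mark.parametrize("x,y,expected", [
        ([1, 2, 3], [2, 4, 6], 1.0),
        ([1, 2, 3], [3, 2, 1], -1.0),
        ([1, 0, 1, 0], [1, 1, 0, 0], 0.0),
    ])
    def test_hand_values(self, x, y, expected):
        assert pearson(np.array(x, float), np.array(y, float)) \
            == pytest.approx(expected)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            pearson(np.ones(5), np.arange(5.0))


class TestCoherence:
    def test_self_coherence_is_one(self, rng):
        x = rng.standard_normal(25)
        assert msc(x, x, FULL) == pytest.approx(1.0)

    def test_independent_noise_low_on_long_fixture(self, rng):
        # 8+ Welch sub-segments: expected coherence ~ 1/n_subsegments
        vals = [msc(rng.standard_normal(60), rng.standard_normal(60), FULL)
                for _ in range(200)]
        assert np.mean(vals) < 0.35

    def test_lti_relation_gives_high_coherence(self):
        # delayed scaled copy of a narrowband signal: an LTI relation, so
        # coherence ~ 1 in the band that carries the power
        t = np.arange(400) / 100.0
        rng = np.random.default_rng(7)
        x = np.sin(2 * np.pi * 20 * t) + 0.01 * rng.standard_normal(t.size)
        y = 0.6 * np.sin(2 * np.pi * 20 * (t - 0.02)) \
            + 0.01 * rng.standard_normal(t.size)
        assert msc(x, y, BETA) > 0.95

    def test_single_segment_degenerate(self, rng):
        with pytest.raises(DegenerateEstimateError):
            msc(rng.standard_normal(12), rng.standard_normal(12), FULL)

    def test_matches_direct_dft_welch_oracle(self, rng):
        """Independent re-implementation: explicit Hann-windowed DFT segments."""
        x = rng.standard_normal(25)
        y = rng.standard_normal(25)
        spec = SpectralParams()
        nseg, step = spec.nperseg, spec.nperseg - spec.noverlap
        win = 0.5 - 0.5 * np.cos(2 * np.pi * np.arange(nseg) / nseg)  # hann
        starts = range(0, 25 - nseg + 1, step)
        def seg_ffts(v):
            out = []
            for s in starts:
                seg = v[s:s + nseg]
                seg = seg - seg.mean()          # constant detrend
                out.append(np.fft.rfft(seg * win))
            return np.array(out)
        Fx, Fy = seg_ffts(x), seg_ffts(y)
        Sxy = np.mean(Fx * np.conj(Fy), axis=0)
        Sxx = np.mean(np.abs(Fx) ** 2, axis=0)
        Syy = np.mean(np.abs(Fy) ** 2, axis=0)
        freqs = np.fft.rfftfreq(nseg, d=0.01)
        mask = band_bin_mask(freqs, FULL)
        want = np.mean(np.abs(Sxy[mask]) ** 2 / (Sxx[mask] * Syy[mask]))
        got = msc(x, y, FULL)
        assert got == pytest.approx(want, rel=1e-8)

    def test_narrow_band_uses_nearest_bin(self):
        # the 12-sample Welch grid has no bin inside 0.5-4 Hz; the nearest
        # non-DC bin must be used instead of returning NaN
        rng = np.random.default_rng(0)
        v = msc(rng.standard_normal(25), rng.standard_normal(25),
                BandSpec("Delta", 0.5, 4.0))
        assert np.isfinite(v) and 0 <= v <= 1


class TestImaginaryCoherency:
    def test_identical_signals_give_zero(self, rng):
        x = rng.standard_normal(25)
        assert ipc(x, x, FULL) == pytest.approx(0.0, abs=1e-12)

    def test_quarter_cycle_shift_high(self):
        # 25 Hz sinusoid, quarter cycle = 1 sample at 100 Hz
        t = np.arange(200) / 100.0
        rng = np.random.default_rng(1)
        x = np.sin(2 * np.pi * 25 * t) + 0.05 * rng.standard_normal(t.size)
        y = np.sin(2 * np.pi * 25 * t - np.pi / 2) \
            + 0.05 * rng.standard_normal(t.size)
        assert ipc(x, y, BandSpec("hi", 20, 30)) > 0.8

    def test_independent_noise_near_zero(self, rng):
        vals = [ipc(rng.standard_normal(60), rng.standard_normal(60), FULL)
                for _ in range(200)]
        assert np.mean(vals) < 0.3


class TestWaveletCoherence:
    def test_self_coherence_is_one(self, rng):
        x = rng.standard_normal(25)
        assert wavelet_coherence(x, x) == pytest.approx(1.0)

    def test_constant_lag_narrowband_high(self):
        t = np.arange(25) / 100.0
        x = np.cos(2 * np.pi * 20 * t)
        y = np.cos(2 * np.pi * 20 * t - 0.8)
        assert wavelet_coherence(x, y, band=BETA) > 0.9

    def test_independent_noise_well_below_coherent_level(self, rng):
        # 25-sample windows carry a small-sample coherence bias, so the
        # null sits well above 0; it must still separate cleanly from the
        # phase-locked level (> 0.9, previous test)
        vals = [wavelet_coherence(rng.standard_normal(25),
                                  rng.standard_normal(25), band=BETA)
                for _ in range(100)]
        assert np.mean(vals) < 0.85

    def test_smoothing_disabled_degenerate(self, rng):
        with pytest.raises(DegenerateEstimateError):
            wavelet_coherence(rng.standard_normal(25),
                              rng.standard_normal(25),
                              wspec=WaveletSpec(smooth_len=1))

    def test_cwt_phase_tracks_analytic_frequency(self):
        t = np.arange(25) / 100.0
        x = np.cos(2 * np.pi * 10 * t)
        W = morlet_cwt(x[None], np.array([10.0]), 100.0)
        slope = np.polyfit(t[5:20],
                           np.unwrap(np.angle(W[0, 0]))[5:20], 1)[0]
        assert slope == pytest.approx(2 * np.pi * 10, rel=0.05)

    def test_matches_double_loop_oracle(self, rng):
        """Brute-force CWT (explicit double loop) + explicit smoothing."""
        x = rng.standard_normal(16)
        y = rng.standard_normal(16)
        freqs = np.array([15.0, 30.0])
        wspec = WaveletSpec(freqs=freqs, smooth_len=5, smooth_periods=0.0)
        fs, w0 = 100.0, 6.0
        T = x.size

        def cwt_brute(v, f):
            s = w0 / (2 * np.pi * f)
            half = min(int(np.ceil(4 * s * fs)), T - 1)
            out = np.zeros(T, complex)
            for t in range(T):
                for m in range(-half, half + 1):
                    u = t + m
                    if 0 <= u < T:
                        tau = m / fs
                        psi = (np.pi ** -0.25) * np.exp(
                            1j * w0 * tau / s - (tau / s) ** 2 / 2)
                        out[t] += v[u] * np.conj(psi) / (fs * np.sqrt(s))
            return out

        per_freq = []
        for f in freqs:
            Wx, Wy = cwt_brute(x, f), cwt_brute(y, f)
            n_valid = T - 5 + 1
            vals = []
            for t0 in range(n_valid):
                sl = slice(t0, t0 + 5)
                num = np.mean(Wx[sl] * np.conj(Wy[sl]))
                dxx = np.mean(np.abs(Wx[sl]) ** 2)
                dyy = np.mean(np.abs(Wy[sl]) ** 2)
                vals.append(abs(num) / np.sqrt(dxx * dyy))
            per_freq.append(np.mean(vals))
        want = float(np.mean(per_freq))
        got = wavelet_coherence(x, y, wspec=wspec)
        assert got == pytest.approx(want, rel=1e-8)


class TestPhase:
    def test_cosine_phase_slope(self):
        t = np.arange(500) / 100.0
        ps = instantaneous_phase(np.cos(2 * np.pi * 7 * t), dt=0.01)
        slope = np.polyfit(t[50:-50], np.unwrap(ps.phi)[50:-50], 1)[0]
        assert slope == pytest.approx(2 * np.pi * 7, rel=0.01)

    def test_sine_lags_cosine_by_quarter_cycle(self):
        t = np.arange(500) / 100.0
        pc = instantaneous_phase(np.cos(2 * np.pi * 5 * t), dt=0.01)
        psn = instantaneous_phase(np.sin(2 * np.pi * 5 * t), dt=0.01)
        diff = np.angle(np.exp(1j * (pc.phi - psn.phi)))[50:-50]
        assert np.median(diff) == pytest.approx(np.pi / 2, abs=0.05)

    def test_amplitude_invariance(self, rng):
        x = rng.standard_normal(200)
        a = instantaneous_phase(x, dt=0.01)
        b = instantaneous_phase(2.0 * x, dt=0.01)
        np.testing.assert_allclose(a.phi, b.phi, atol=1e-12)

    def test_zero_signal_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            instantaneous_phase(np.zeros(10), dt=0.01)


class TestPLV:
    def test_constant_offset_gives_one(self, rng):
        phi = rng.uniform(-np.pi, np.pi, 50)
        assert plv(phi, phi + 0.7) == pytest.approx(1.0)
        assert plv(phi, phi) == pytest.approx(1.0)

    def test_uniform_null_matches_rayleigh_mean(self, rng):
        # E[PLV] for N=25 iid uniform phase differences = sqrt(pi)/(2 sqrt(25))
        n, reps = 25, 10_000
        d = rng.uniform(-np.pi, np.pi, (reps, n))
        sample = np.abs(np.mean(np.exp(1j * d), axis=1)).mean()
        assert sample == pytest.approx(rayleigh_null_mean(n), rel=0.05)
        # the implementation agrees with the direct complex mean
        one = plv(d[0], np.zeros(n))
        assert one == pytest.approx(abs(np.mean(np.exp(1j * d[0]))), rel=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            plv(np.zeros(5), np.zeros(6))


class TestPLI:
    def test_identical_phases_give_zero(self, rng):
        phi = rng.uniform(-np.pi, np.pi, 30)
        assert pli(phi, phi) == pytest.approx(0.0)

    def test_constant_positive_lag_gives_one(self, rng):
        phi = rng.uniform(-1.0, 1.0, 30)
        assert pli(phi + np.pi / 4, phi) == pytest.approx(1.0)

    def test_symmetric_lags_cancel(self):
        phi = np.zeros(10)
        lag = np.array([0.3, -0.3] * 5)
        assert pli(phi + lag, phi) == pytest.approx(0.0)

    def test_swap_invariance(self, rng):
        a = rng.uniform(-np.pi, np.pi, 40)
        b = rng.uniform(-np.pi, np.pi, 40)
        assert pli(a, b) == pytest.approx(pli(b, a))


class TestAdjacency:
    def test_identical_channels_give_all_ones_plv(self, rng):
        x = rng.standard_normal(25)
        X = np.tile(x, (5, 1))
        A = adjacency(X, "PLV")
        off = A.W[~np.eye(5, dtype=bool)]
        np.testing.assert_allclose(off, 1.0, atol=1e-9)

    def test_independent_noise_pli_low(self, rng):
        vals = []
        for _ in range(30):
            A = adjacency(rng.standard_normal((6, 25)), "PLI")
            vals.append(A.W[np.triu_indices(6, 1)].mean())
        assert np.mean(vals) < 0.25

    @pytest.mark.parametrize("method", ["PC", "MSC", "IPC", "WC", "PLV", "PLI"])
    def test_symmetric_zero_diagonal_in_range(self, method, rng):
        X = rng.standard_normal((6, 25))
        A = adjacency(X, method)
        np.testing.assert_allclose(A.W, A.W.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(A.W), 0.0)
        assert A.W.min() >= -1e-12 and A.W.max() <= 1 + 1e-9

    def test_pc_rectification_keeps_signed_raw(self, rng):
        x = rng.standard_normal(25)
        X = np.stack([x, -x, rng.standard_normal(25)])
        A = adjacency(X, "PC")
        assert A.signed_raw[0, 1] == pytest.approx(-1.0)
        assert A.W[0, 1] == pytest.approx(1.0)

    def test_pairwise_entries_match_scalar_estimators(self, rng):
        X = rng.standard_normal((4, 25))
        A = adjacency(X, "WC")
        want = wavelet_coherence(X[1], X[3])
        assert A.W[1, 3] == pytest.approx(want, rel=1e-10)
        A2 = adjacency(X, "MSC")
        assert A2.W[0, 2] == pytest.approx(msc(X[0], X[2], FULL), rel=1e-10)

    def test_phase_measures_amplitude_invariant(self, rng):
        X = rng.standard_normal((4, 25))
        scales = np.array([1.0, 3.0, 0.2, 7.0])[:, None]
        for method in ("PLV", "PLI"):
            a = adjacency(X, method).W
            b = adjacency(X * scales, method).W
            np.testing.assert_allclose(a, b, atol=1e-9)

    def test_epoch_context_slices_full_epoch_phases(self, rng):
        import scipy.signal

        samples = rng.standard_normal((3, 200))
        stack = epoch_adjacencies(samples, [0, 25], 25, "PLV")
        phases = np.angle(scipy.signal.hilbert(samples, axis=1))
        mini = MiniEpoch(X=samples[:, 25:50], start=25)
        direct = adjacency(mini, "PLV", phases=phases)
        np.testing.assert_allclose(stack[1], direct.W, atol=1e-12)

    def test_unknown_method_rejected(self, rng):
        with pytest.raises(ValueError, match="unknown FC method"):
            adjacency(rng.standard_normal((3, 25)), "XY")


def test_wc_frequency_grid_respects_resolution():
    ws = WaveletSpec()
    grid = ws.band_freqs(FULL, 25, 100.0)
    # 2 smoothing periods must fit twice into 25 samples at 100 Hz -> 16 Hz
    assert grid.min() == pytest.approx(16.0)
    assert grid.max() == pytest.approx(48.0)
    # long segments resolve the whole band
    grid_long = ws.band_freqs(FULL, 1200, 100.0)
    assert grid_long.min() == pytest.approx(0.5)
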