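"""Wavelet phase, pairwise coherence, summaries, and n:m coupling."""

import warnings

import numpy as np
import pytest
from scipy import stats

from smanet import (
    Epoch,
    pairwise_wpc,
    ppc,
    ppc_map,
    summarize_wpc,
    wavelet_phase,
    wpc,
)
from smanet.coherence import WPCSet, _window_grid
from smanet.io import TEN_TWENTY_19

FS = 512.0


def brute_force_wpc(p1, p2, window_s):
    """Windowed |mean resultant| with explicit loops over valid samples."""
    centers = _window_grid(p1.n_samples, p1.fs, window_s)
    out = np.full((p1.freqs.size, centers.size), np.nan)
    for i, f in enumerate(p1.freqs):
        half = max(window_s, 4.0 / f) / 2.0
        for w, c in enumerate(centers):
            a = max(0, round((c - half) * p1.fs))
            b = min(p1.n_samples, round((c + half) * p1.fs))
            acc, n = 0.0 + 0.0j, 0
            for t in range(a, b):
                if p1.valid_mask[i, t] and p2.valid_mask[i, t]:
                    acc += np.exp(1j * (p1.phases[i, t] - p2.phases[i, t]))
                    n += 1
            if n:
                out[i, w] = abs(acc) / n
    return out


def direct_morlet_phase(s, fs, freqs, omega0=6.0):
    """Independent phase oracle: explicit FFT-domain Morlet filtering."""
    s = np.asarray(s, float)
    n = s.size
    w = 2 * np.pi * np.fft.fftfreq(n, 1 / fs)
    S = np.fft.fft(s)
    phases = np.empty((len(freqs), n))
    for i, f in enumerate(freqs):
        scale = omega0 * fs / (2 * np.pi * f)
        kernel = np.exp(-0.5 * (scale * w / fs - omega0) ** 2)
        phases[i] = np.angle(np.fft.ifft(S * kernel))
    return phases


class TestWaveletPhase:
    def test_phase_ramp_of_tone(self):
        """Phase at the tone's frequency advances by 2 pi f / fs per sample."""
        t = np.arange(8192) / FS
        p = wavelet_phase(np.cos(2 * np.pi * 10 * t), FS, np.array([5.0, 10.0, 20.0]))
        row = np.unwrap(p.phases[1][p.valid_mask[1]])
        slope = np.diff(row).mean() * FS / (2 * np.pi)
        assert abs(slope - 10.0) / 10.0 < 0.01

    def test_constant_phase_offset(self):
        t = np.arange(8192) / FS
        p1 = wavelet_phase(np.cos(2 * np.pi * 10 * t), FS, np.array([10.0]))
        p2 = wavelet_phase(np.cos(2 * np.pi * 10 * t + np.pi / 2), FS, np.array([10.0]))
        d = (p2.phases[0] - p1.phases[0])[p1.valid_mask[0]]
        assert np.angle(np.exp(1j * d)).mean() == pytest.approx(np.pi / 2, abs=0.01)

    def test_noise_phases_uniform(self, rng):
        """White-noise phase occupies (-pi, pi] uniformly (KS distance)."""
        p = wavelet_phase(rng.standard_normal(100_000), FS, np.array([20.0]))
        ph = p.phases[0][p.valid_mask[0]]
        d, _ = stats.kstest(ph, stats.uniform(loc=-np.pi, scale=2 * np.pi).cdf)
        assert d < 0.05

    def test_phases_in_half_open_interval(self, rng):
        p = wavelet_phase(rng.standard_normal(2048), FS)
        assert np.all(p.phases > -np.pi) and np.all(p.phases <= np.pi)

    def test_edges_masked_per_frequency(self, rng):
        p = wavelet_phase(rng.standard_normal(4096), FS, np.array([2.0, 50.0]))
        # lower frequency -> wider cone of influence
        assert p.T[0] < p.T[1]
        assert not p.valid_mask[0, 0] and not p.valid_mask[0, -1]

    def test_too_short_series_masks_row_with_warning(self, rng):
        with pytest.warns(UserWarning, match="3 cycles"):
            p = wavelet_phase(rng.standard_normal(600), FS, np.array([1.0, 100.0]))
        assert p.T[0] == 0
        assert p.T[1] > 0

    def test_matches_independent_fft_morlet(self):
        """Phases lock to an explicitly built FFT-domain Morlet filter.

        The discrete transform carries a small constant per-frequency offset
        (sub-sample alignment) which cancels in every phase-difference
        quantity downstream; up to that offset the phases must agree tightly.
        """
        rng = np.random.default_rng(9)
        s = rng.standard_normal(4096)
        freqs = np.array([8.0, 20.0, 40.0])
        p = wavelet_phase(s, FS, freqs)
        ref = direct_morlet_phase(s, FS, freqs)
        for i in range(len(freqs)):
            diff = np.angle(np.exp(1j * (p.phases[i] - ref[i])))[p.valid_mask[i]]
            resultant = np.mean(np.exp(1j * diff))
            assert np.abs(resultant) > 0.98   # tiny jitter around the offset
            assert abs(np.angle(resultant)) < 0.25  # offset itself is small


class TestWPC:
    def test_identical_phases_give_one_exactly(self, rng):
        p = wavelet_phase(rng.standard_normal(4096), FS, np.array([5.0, 15.0]))
        m = wpc(p, p)
        assert np.nanmin(m) == 1.0 and np.nanmax(m) == 1.0

    def test_constant_lag_gives_one(self):
        t = np.arange(8192) / FS
        p1 = wavelet_phase(np.cos(2 * np.pi * 12 * t), FS, np.array([12.0]))
        p2 = wavelet_phase(np.cos(2 * np.pi * 12 * t + 1.1), FS, np.array([12.0]))
        assert np.nanmin(wpc(p1, p2)) > 0.999

    def test_independent_noise_near_rayleigh_null(self, rng):
        p1 = wavelet_phase(rng.standard_normal(30_000), FS, np.array([40.0]))
        p2 = wavelet_phase(rng.standard_normal(30_000), FS, np.array([40.0]))
        m = wpc(p1, p2, window_s=20.0)
        assert np.nanmean(m) < 0.15

    def test_bounds_and_nan_for_empty_windows(self, rng):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            # 600 samples < 3 cycles at 1 Hz -> that row is fully masked
            p1 = wavelet_phase(rng.standard_normal(600), FS, np.array([1.0, 30.0]))
            p2 = wavelet_phase(rng.standard_normal(600), FS, np.array([1.0, 30.0]))
        m = wpc(p1, p2, window_s=0.25)
        valid = m[~np.isnan(m)]
        assert np.all(valid >= 0.0) and np.all(valid <= 1.0)
        assert np.all(np.isnan(m[0]))
        assert np.any(~np.isnan(m[1]))

    def test_mismatched_grids_rejected(self, rng):
        p1 = wavelet_phase(rng.standard_normal(2048), FS, np.array([5.0]))
        p2 = wavelet_phase(rng.standard_normal(2048), FS, np.array([6.0]))
        with pytest.raises(ValueError):
            wpc(p1, p2)

    def test_matches_brute_force_resultant(self, rng):
        """Prefix-sum windowing equals the explicit loop to 1e-10."""
        freqs = np.array([5.0, 11.0, 23.0])
        p1 = wavelet_phase(rng.standard_normal(2000), FS, freqs)
        p2 = wavelet_phase(rng.standard_normal(2000), FS, freqs)
        fast = wpc(p1, p2, window_s=0.5)
        slow = brute_force_wpc(p1, p2, 0.5)
        np.testing.assert_allclose(fast, slow, atol=1e-10)

    def test_null_scales_as_inverse_sqrt_T(self):
        """Mean null WPC follows the Rayleigh T^{-1/2} law across window sizes."""
        rng = np.random.default_rng(42)
        f = np.array([32.0])
        T_samples = [100, 1000, 10_000]
        means = []
        for T in T_samples:
            vals = []
            for _ in range(20):
                a = wavelet_phase(rng.standard_normal(T + 4000), FS, f)
                b = wavelet_phase(rng.standard_normal(T + 4000), FS, f)
                vals.append(np.nanmean(wpc(a, b, window_s=T / FS)))
            means.append(np.mean(vals))
        slope = np.polyfit(np.log(T_samples), np.log(means), 1)[0]
        assert abs(slope + 0.5) < 0.1


class TestPairwiseAndSummary:
    @pytest.fixture(scope="class")
    def small_set(self):
        rng = np.random.default_rng(11)
        shared = rng.standard_normal(6000)
        chans = ["Fp1", "Fz", "Cz"]
        phases = [
            (c, wavelet_phase(shared + 0.5 * rng.standard_normal(6000), FS,
                              np.arange(1.0, 31.0)))
            for c in chans
        ]
        return pairwise_wpc(phases)

    def test_symmetry_and_unit_diagonal(self, small_set):
        np.testing.assert_array_equal(
            small_set.pair("Fp1", "Cz"), small_set.pair("Cz", "Fp1")
        )
        d = small_set.pair("Fz", "Fz")
        assert np.nanmin(d) == 1.0

    def test_ordered_pair_count_is_n_squared(self, small_set):
        assert small_set.n_pairs == 9

    def test_summary_missing_electrode_named(self, small_set):
        with pytest.raises(ValueError, match="Fp2"):
            summarize_wpc(small_set, (1.0, 10.0), montage=TEN_TWENTY_19)

    def test_constant_coherence_averages_to_itself(self):
        """All pair matrices at constant c -> every summary level equals c."""
        n = 19
        freqs = np.arange(1.0, 31.0)
        centers = np.arange(0.5, 19.5, 0.5)
        c = 0.37
        mats = {}
        chans = list(TEN_TWENTY_19)
        for i, ci in enumerate(chans):
            for j, cj in enumerate(chans):
                mats[(ci, cj)] = np.full((freqs.size, centers.size), c)
        wset = WPCSet(chans, freqs, centers, mats, FS, 1.0, 20.0)
        summary = summarize_wpc(wset, Epoch("ictal", 2.0, 18.0))
        for band in summary.bands:
            np.testing.assert_allclose(summary.per_electrode[band], c)
            assert summary.per_seizure[band] == pytest.approx(c)
        assert len(mats) == 361
        assert summary.per_electrode[summary.bands[0]].size == 19

    def test_per_electrode_excludes_self_pair(self):
        """Diagonal 1.0 must not leak into the 18-entry row averages."""
        freqs = np.arange(1.0, 31.0)
        centers = np.arange(0.5, 9.5, 0.5)
        chans = list(TEN_TWENTY_19)
        mats = {}
        for ci in chans:
            for cj in chans:
                value = 1.0 if ci == cj else 0.2
                mats[(ci, cj)] = np.full((freqs.size, centers.size), value)
        wset = WPCSet(chans, freqs, centers, mats, FS, 1.0, 10.0)
        summary = summarize_wpc(wset, (1.5, 8.5))
        for band in summary.bands:
            np.testing.assert_allclose(summary.per_electrode[band], 0.2)


class TestPPC:
    def test_locked_phases(self, rng):
        th = rng.uniform(-np.pi, np.pi, 10_000)
        assert ppc(th, th, 1, 1) == pytest.approx(1.0)
        assert ppc(th, th + 0.7, 1, 1) == pytest.approx(1.0)
        # theta2 = (n/m) theta1 with n=3, m=1
        assert ppc(th, 3 * th, 3, 1) == pytest.approx(1.0)

    def test_independent_uniform_null(self, rng):
        th1 = rng.uniform(-np.pi, np.pi, 100_000)
        th2 = rng.uniform(-np.pi, np.pi, 100_000)
        assert ppc(th1, th2) < 0.01

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            ppc(np.array([]), np.array([]))
        with pytest.raises(ValueError):
            ppc(np.zeros(5), np.zeros(4))
        with pytest.raises(ValueError):
            ppc(np.zeros(5), np.zeros(5), n=0)


class TestPPCMap:
    def test_peak_at_driven_harmonic(self):
        """13 Hz phase driving a 65 Hz tone peaks at (13, 65) +- one step."""
        rng = np.random.default_rng(5)
        t = np.arange(60_000) / FS
        phi = 2 * np.pi * 13 * t
        slow = np.cos(phi) + 0.3 * rng.standard_normal(t.size)
        fast = np.cos(phi) + np.cos(5 * phi) + 0.3 * rng.standard_normal(t.size)
        ps = wavelet_phase(slow, FS, np.arange(1.0, 31.0))
        pf = wavelet_phase(fast, FS, np.arange(1.0, 101.0))
        f1, f2, val = ppc_map(ps, pf).peak()
        assert abs(f1 - 13.0) <= 1.0
        assert abs(f2 - 65.0) <= 1.0
        assert val > 0.9

    def test_independent_channels_near_null(self, rng):
        a = wavelet_phase(rng.standard_normal(50_000), FS, np.arange(4.0, 29.0, 4.0))
        b = wavelet_phase(rng.standard_normal(50_000), FS, np.arange(32.0, 100.0, 8.0))
        pm = ppc_map(a, b, f_slow_range=(4.0, 28.0), f_fast_range=(32.0, 96.0))
        assert np.nanmax(pm.values) < 0.1

    def test_self_map_diagonal_is_one(self, rng):
        p = wavelet_phase(rng.standard_normal(20_000), FS, np.arange(10.0, 41.0, 10.0))
        pm = ppc_map(p, p, f_slow_range=(10.0, 40.0), f_fast_range=(10.0, 40.0))
        for k, f in enumerate(pm.f_slow):
            j = np.argmin(np.abs(pm.f_fast - f))
            assert pm.n[k, j] == 1 and pm.m[k, j] == 1
            assert pm.values[k, j] == pytest.approx(1.0)
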