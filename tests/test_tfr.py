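"""Core time-frequency representation: analytic signals, the cone-kernel
distribution and the window-selection criterion."""

import numpy as np
import pytest

from tfca import (
    ZAMDConfig,
    analytic_signal,
    interference_penalty,
    renyi_entropy_penalty,
    select_windows,
    zamd_auto,
    zamd_cross,
)
from tfca.tfr import TFRGrid

from oracles import zamd_direct, wigner_ville


def tone(f0, n=600, fs=2.0):
    return np.cos(2 * np.pi * f0 * np.arange(n) / fs)


class TestAnalyticSignal:
    def test_real_part_is_input(self, rng):
        x = rng.standard_normal(256)
        assert np.allclose(analytic_signal(x).real, x)

    def test_cosine_becomes_complex_exponential(self):
        n, fs, f0 = 600, 2.0, 0.05
        t = np.arange(n) / fs
        za = analytic_signal(np.cos(2 * np.pi * f0 * t))
        expected = np.exp(1j * 2 * np.pi * f0 * t)
        interior = slice(50, -50)
        assert np.allclose(za[interior], expected[interior], atol=1e-2)

    def test_negative_frequencies_suppressed(self, rng):
        za = analytic_signal(rng.standard_normal(512))
        spec = np.fft.fft(za)
        neg = spec[257:]  # strictly negative frequencies
        assert np.abs(neg).max() < 1e-10 * np.abs(spec).max()

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            analytic_signal(np.array([1.0, np.nan, 2.0]))


class TestZAMD:
    def test_matches_direct_evaluation(self, rng):
        """Vectorised implementation equals the brute-force evaluation of the
        defining equation, for cross and auto, with and without time
        smoothing (L_g = 1 is the no-cone-smoothing limit)."""
        x = analytic_signal(rng.standard_normal(128))
        y = analytic_signal(rng.standard_normal(128))
        for l_g in (1, 9):
            cfg = ZAMDConfig(l_h=15, l_g=l_g, n_freq_bins=32)
            ref = zamd_direct(x, y, cfg.l_h, cfg.l_g, cfg.n_freq_bins)
            got = zamd_cross(x, y, cfg).values
            assert np.abs(got - ref).max() < 1e-8 * np.abs(ref).max()
            ref_auto = zamd_direct(x, x, cfg.l_h, cfg.l_g, cfg.n_freq_bins)
            got_auto = zamd_auto(x, cfg).values
            assert np.abs(got_auto - ref_auto).max() < 1e-8 * np.abs(ref_auto).max()

    def test_conjugate_symmetry_under_swap(self, rng, small_cfg):
        x = analytic_signal(rng.standard_normal(200))
        y = analytic_signal(rng.standard_normal(200))
        sxy = zamd_cross(x, y, small_cfg).values
        syx = zamd_cross(y, x, small_cfg).values
        assert np.abs(sxy - np.conj(syx)).max() < 1e-9 * np.abs(sxy).max()

    def test_auto_is_real(self, rng):
        x = analytic_signal(rng.standard_normal(600))
        tfr = zamd_auto(x)
        assert np.isrealobj(tfr.values)

    def test_tone_ridge_at_tone_frequency(self):
        tfr = zamd_auto(analytic_signal(tone(0.05)))
        mid = tfr.values[300]
        f_peak = tfr.f_axis[np.argmax(mid)]
        df = tfr.f_axis[1] - tfr.f_axis[0]
        assert abs(f_peak - 0.05) <= df

    def test_time_frequency_covariance(self):
        """Shifting a signal in time and modulating it translates the
        distribution by (t0, f0): S_zz(t, f) = S_xx(t - t0, f - f0)."""
        fs, n = 2.0, 600
        t = np.arange(n) / fs
        t0_samp, f0 = 100, 0.1  # t0 = 50 s; 0.1 Hz is exactly 50 grid bins
        cfg = ZAMDConfig(n_freq_bins=500)
        # Gaussian-enveloped tone well inside the record, so boundary
        # truncation touches only numerically-zero tails.
        env = np.exp(-((t - 75.0) ** 2) / (2 * 10.0**2))
        x = env * np.exp(1j * 2 * np.pi * 0.05 * t)
        z = np.concatenate([np.zeros(t0_samp, complex), x[:-t0_samp]]) * np.exp(
            1j * 2 * np.pi * f0 * t
        )
        sx = zamd_auto(x, cfg)
        sz = zamd_auto(z, cfg)
        df = sx.f_axis[1] - sx.f_axis[0]
        k0 = int(round(f0 / df))
        assert abs(k0 * df - f0) < 1e-12  # modulation is on-grid
        a = sz.values[t0_samp:, k0:]
        b = sx.values[: n - t0_samp, :-k0]
        assert np.abs(a - b).max() < 1e-6 * np.abs(sx.values).max()

    def test_cross_terms_suppressed_vs_wigner(self):
        """Two tones: the cone kernel keeps the midpoint interference below
        20% of the auto-term peaks, while the Wigner-Ville interference is
        comparable to the auto terms."""
        n, fs = 256, 2.0
        t = np.arange(n) / fs
        x = analytic_signal(np.cos(2 * np.pi * 0.1 * t) + np.cos(2 * np.pi * 0.4 * t))
        cfg = ZAMDConfig(l_h=127, l_g=127, n_freq_bins=128)
        z = zamd_auto(x, cfg)
        w = wigner_ville(x)
        wf = np.fft.fftfreq(n, 1 / fs) / 2  # lag-doubling grid
        mid = n // 2

        def level(values, f_axis, f):
            k = np.argmin(np.abs(f_axis - f))
            return np.abs(values[mid - 20 : mid + 20, k]).max()

        z_cross = level(z.values, z.f_axis, 0.25)
        z_auto = min(level(z.values, z.f_axis, 0.1), level(z.values, z.f_axis, 0.4))
        w_cross = level(w, wf, 0.25)
        w_auto = min(level(w, wf, 0.1), level(w, wf, 0.4))
        assert z_cross < 0.2 * z_auto
        assert w_cross > 0.5 * w_auto

    def test_rejects_short_signal(self):
        with pytest.raises(ValueError, match="shorter"):
            zamd_auto(analytic_signal(np.ones(100)), ZAMDConfig())

    def test_rejects_even_windows(self):
        with pytest.raises(ValueError):
            ZAMDConfig(l_h=448)


class TestPenalties:
    def _grid(self, values):
        nt, nf = values.shape
        return TFRGrid(values, np.arange(nt) / 2.0, np.arange(nf) * 0.01)

    def test_renyi_point_mass_is_zero_bits(self):
        v = np.zeros((8, 8))
        v[3, 4] = 5.0
        assert renyi_entropy_penalty(self._grid(v)) == pytest.approx(0.0)

    def test_renyi_uniform_is_log2_n(self):
        v = np.ones((8, 16))
        assert renyi_entropy_penalty(self._grid(v)) == pytest.approx(np.log2(8 * 16))

    def test_tone_more_concentrated_than_noise(self, rng):
        cfg = ZAMDConfig(l_h=63, l_g=63, n_freq_bins=64)
        tfr_tone = zamd_auto(analytic_signal(tone(0.25, 200)), cfg)
        noise = rng.standard_normal(200)
        tfr_noise = zamd_auto(analytic_signal(noise), cfg)
        assert renyi_entropy_penalty(tfr_tone) < renyi_entropy_penalty(tfr_noise)

    def test_interference_single_ridge_counts_one(self):
        cfg = ZAMDConfig(l_h=63, l_g=63, n_freq_bins=64)
        tfr = zamd_auto(analytic_signal(tone(0.25, 300)), cfg)
        ip = interference_penalty(tfr)
        assert 0.8 <= ip <= 1.3

    def test_wigner_interference_exceeds_zamd(self):
        n, fs = 256, 2.0
        t = np.arange(n) / fs
        x = analytic_signal(np.cos(2 * np.pi * 0.1 * t) + np.cos(2 * np.pi * 0.4 * t))
        cfg = ZAMDConfig(l_h=127, l_g=127, n_freq_bins=128)
        z = zamd_auto(x, cfg)
        w = wigner_ville(x)
        wgrid = TFRGrid(np.abs(w), np.arange(n) / fs, np.abs(np.fft.fftfreq(n, 1 / fs) / 2))
        assert interference_penalty(wgrid) > interference_penalty(z)

    def test_renyi_rejects_empty(self):
        with pytest.raises(ValueError):
            renyi_entropy_penalty(self._grid(np.zeros((4, 4))))


class TestSelectWindows:
    def test_singleton_grid_returns_that_point(self):
        x = tone(0.25, 200)
        best, audit = select_windows(x, [63], [31], n_freq_bins=64)
        assert best == (63, 31)
        assert set(audit) == {(63, 31)}

    def test_argmin_independent_of_grid_order(self):
        x = tone(0.25, 160) + tone(0.4, 160)
        grid_h, grid_g = [31, 63], [15, 41]
        best1, audit1 = select_windows(x, grid_h, grid_g, n_freq_bins=64)
        best2, audit2 = select_windows(x, grid_h[::-1], grid_g[::-1], n_freq_bins=64)
        assert best1 == best2
        assert audit1 == audit2

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            select_windows(tone(0.25, 100), [], [31])
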