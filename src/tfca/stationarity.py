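"""Sphericity-based stationarity testing of power and cross-phase spectra.

A record is split into ``M`` equal non-overlapping segments and a spectrum is
estimated per segment.  At each frequency the test statistic is

    T(w) = log( arithmetic mean of S_m(w) / geometric mean of S_m(w) )

which is zero iff the segment spectra are identical at ``w`` (arithmetic-
geometric mean inequality), i.e. iff the signal is stationary there.  The
spectra are evaluated per analysis bin (the per-segment power averaged over
the bin's Fourier frequencies; bins 0-0.1, 0.1-0.2, 0.2-0.3, 0.3-0.4 Hz by
default), the statistic is compared to Monte-Carlo critical values, and the
record is declared nonstationary when any bin rejects.

The phase variant replaces the per-segment power spectrum by the argument of
the cross spectrum of a signal pair, mapped to [0, 2*pi) so the values are
nonnegative as the statistic requires; its null ensemble is a correlated
pair (white noise and its high-passed copy) rather than white noise, because
the cross phase of uncorrelated signals is meaningless.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.signal.windows import hann

__all__ = [
    "StationarityConfig",
    "StationarityResult",
    "sphericity_statistic",
    "segment_power_spectra",
    "segment_cross_phase_spectra",
    "mc_critical_values",
    "test_stationarity_power",
    "test_stationarity_phase",
]

_DEFAULT_BINS = ((0.0, 0.1), (0.1, 0.2), (0.2, 0.3), (0.3, 0.4))


@dataclass(frozen=True)
class StationarityConfig:
    """Segmentation, bins and calibration settings of the test.

    ``alpha_per_bin`` = 0.0125 gives an overall size of about
    1 - (1 - 0.0125)^4 ~= 4.9% over the four default bins.
    """

    m_segments: int = 5
    bins: Sequence[tuple[float, float]] = _DEFAULT_BINS
    alpha_per_bin: float = 0.0125
    n_mc: int = 2000
    seed: int = 0
    fs: float = 2.0

    def __post_init__(self) -> None:
        if self.m_segments < 2:
            raise ValueError("need at least 2 segments")
        b = sorted(self.bins)
        for (l1, h1), (l2, h2) in zip(b, b[1:]):
            if l2 < h1:
                raise ValueError("bins must not overlap")
        if not 0 < self.alpha_per_bin < 1:
            raise ValueError("alpha_per_bin must lie in (0, 1)")


@dataclass
class StationarityResult:
    statistic: np.ndarray  # per bin
    critical_value: np.ndarray  # per bin
    rejected: np.ndarray  # per bin
    bins: Sequence[tuple[float, float]]

    @property
    def nonstationary(self) -> bool:
        """Overall decision: nonstationary iff any bin rejects."""
        return bool(np.any(self.rejected))


def sphericity_statistic(segment_values: np.ndarray) -> float:
    """log(arithmetic mean / geometric mean) of M nonnegative values.

    Zero iff all values are equal; grows with their spread; invariant to a
    common positive scaling.
    """
    v = np.asarray(segment_values, dtype=float)
    if np.any(v < 0):
        raise ValueError("segment spectra must be nonnegative")
    if np.all(v == 0):
        warnings.warn("all-zero segment spectra: statistic defined as 0")
        return 0.0
    am = v.mean()
    with np.errstate(divide="ignore"):
        gm = np.exp(np.mean(np.log(v)))
    if gm == 0:
        return float(np.inf)
    return float(np.log(am / gm))


def segment_power_spectra(x: np.ndarray, m_segments: int, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Hanning-tapered periodogram of each of M equal segments.

    Returns (freqs, S) with S of shape (..., M, n_freq); positive
    frequencies only.  Accepts a batch of records in the leading axes.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    seg_len = n // m_segments
    if seg_len < 32:
        raise ValueError(
            f"segments of {seg_len} samples are too short; need >= 32 "
            f"(record of {n} samples split {m_segments} ways)"
        )
    segs = x[..., : seg_len * m_segments].reshape(*x.shape[:-1], m_segments, seg_len)
    w = hann(seg_len, sym=False)
    spec = np.fft.rfft(segs * w, axis=-1)
    S = (np.abs(spec) ** 2) / (w**2).sum()
    freqs = np.fft.rfftfreq(seg_len, d=1.0 / fs)
    return freqs[1:], S[..., 1:]  # drop DC


def segment_cross_phase_spectra(
    x: np.ndarray, y: np.ndarray, m_segments: int, fs: float
) -> tuple[np.ndarray, np.ndarray]:
    """Per-segment cross-spectral phase arg(S_xy) mapped to [0, 2*pi).

    Segments whose cross-spectral magnitude is negligible (< 1e-12 of the
    total cross power) contribute phase 0 with a warning, since the phase of
    a near-zero cross spectrum is meaningless.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal shape")
    n = x.shape[-1]
    seg_len = n // m_segments
    if seg_len < 32:
        raise ValueError("segments too short; need >= 32 samples each")
    shape = (*x.shape[:-1], m_segments, seg_len)
    xs = x[..., : seg_len * m_segments].reshape(shape)
    ys = y[..., : seg_len * m_segments].reshape(shape)
    w = hann(seg_len, sym=False)
    X = np.fft.rfft(xs * w, axis=-1)
    Y = np.fft.rfft(ys * w, axis=-1)
    Sxy = np.conj(X) * Y
    mag = np.abs(Sxy)
    floor = 1e-12 * np.maximum(mag.sum(axis=(-2, -1), keepdims=True), 1e-300)
    phase = np.mod(np.angle(Sxy), 2 * np.pi)
    # round-off can land an exactly-zero phase infinitesimally below 2*pi
    phase = np.where(phase > 2 * np.pi - 1e-9, 0.0, phase)
    n_tiny = int((mag < floor).sum())
    if n_tiny:
        warnings.warn(f"{n_tiny} near-zero cross-spectral values: phase set to 0")
        phase = np.where(mag < floor, 0.0, phase)
    freqs = np.fft.rfftfreq(seg_len, d=1.0 / fs)
    return freqs[1:], phase[..., 1:]


def _bin_statistics(freqs: np.ndarray, S: np.ndarray, bins) -> np.ndarray:
    """Statistic per analysis bin: the per-segment spectra are first averaged
    over the bin's Fourier frequencies (the spectrum "at" the bin centre
    frequency), then the across-segment statistic is taken.  Aggregating the
    power first reduces the chi-squared scatter of raw periodogram ordinates
    and is what gives the test its power.  Vectorised over leading batch
    axes of S (shape ``(..., M, n_freq)``)."""
    out = []
    for f_lo, f_hi in bins:
        sel = (freqs > f_lo) & (freqs <= f_hi)
        if not sel.any():
            raise ValueError(f"no Fourier frequencies inside bin ({f_lo}, {f_hi}]")
        binned = S[..., sel].mean(axis=-1)  # (..., M)
        am = binned.mean(axis=-1)
        with np.errstate(divide="ignore"):
            gm = np.exp(np.log(np.maximum(binned, 1e-300)).mean(axis=-1))
        out.append(np.log(np.maximum(am, 1e-300) / gm))
    return np.stack(out, axis=-1)


def mc_critical_values(
    cfg: StationarityConfig,
    null_generator: Callable[[np.random.Generator], np.ndarray | tuple[np.ndarray, np.ndarray]],
    record_length: int,
) -> np.ndarray:
    """Per-bin (1 - alpha) quantiles of the statistic under the null.

    ``null_generator(rng)`` returns a record (power test) or a pair of
    records (phase test) of ``record_length`` samples.  Reproducible from
    ``cfg.seed``.
    """
    if cfg.n_mc < 100:
        raise ValueError("n_mc must be at least 100")
    rng = np.random.default_rng(cfg.seed)
    stats = np.empty((cfg.n_mc, len(cfg.bins)))
    for i in range(cfg.n_mc):
        out = null_generator(rng)
        if isinstance(out, tuple):
            freqs, S = segment_cross_phase_spectra(out[0], out[1], cfg.m_segments, cfg.fs)
        else:
            freqs, S = segment_power_spectra(out, cfg.m_segments, cfg.fs)
        stats[i] = _bin_statistics(freqs, S, cfg.bins)
    if np.ptp(stats, axis=0).min() == 0:
        raise ValueError("degenerate null generator: constant statistic")
    return np.quantile(stats, 1 - cfg.alpha_per_bin, axis=0)


def _default_power_null(record_length: int):
    def gen(rng: np.random.Generator) -> np.ndarray:
        return rng.standard_normal(record_length)

    return gen


def _default_phase_null(record_length: int, fs: float):
    from .synthetic import make_correlated_pair_highpass

    def gen(rng: np.random.Generator):
        seed = int(rng.integers(0, 2**31 - 1))
        return make_correlated_pair_highpass(seed, fs=fs, duration=record_length / fs)

    return gen


def test_stationarity_power(
    x: np.ndarray,
    cfg: StationarityConfig | None = None,
    critical_values: np.ndarray | None = None,
) -> StationarityResult:
    """Stationarity test of a record's power spectrum.

    Critical values default to a white-Gaussian-noise Monte Carlo calibrated
    with the exact same segmentation and bin aggregation.
    """
    cfg = cfg or StationarityConfig()
    x = np.asarray(x, dtype=float)
    freqs, S = segment_power_spectra(x, cfg.m_segments, cfg.fs)
    stat = _bin_statistics(freqs, S, cfg.bins)
    if critical_values is None:
        critical_values = mc_critical_values(cfg, _default_power_null(x.size), x.size)
    critical_values = np.asarray(critical_values, dtype=float)
    rejected = stat > critical_values
    return StationarityResult(stat, critical_values, rejected, cfg.bins)


def test_stationarity_phase(
    x: np.ndarray,
    y: np.ndarray,
    cfg: StationarityConfig | None = None,
    critical_values: np.ndarray | None = None,
) -> StationarityResult:
    """Stationarity test of the cross-spectral phase of a pair.

    The null ensemble is white noise paired with its high-pass filtered copy
    (correlated, as a meaningful cross phase requires).
    """
    cfg = cfg or StationarityConfig()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    freqs, S = segment_cross_phase_spectra(x, y, cfg.m_segments, cfg.fs)
    if np.all(S < 1e-9):
        # identical (or perfectly in-phase) pair: every segment phase is the
        # same value, the spread statistic is degenerate
        warnings.warn("all cross phases are zero: statistic degenerate, returning 0")
        zeros = np.zeros(len(cfg.bins))
        return StationarityResult(zeros, np.full(len(cfg.bins), np.inf), zeros > 0, cfg.bins)
    stat = _bin_statistics(freqs, S, cfg.bins)
    if critical_values is None:
        critical_values = mc_critical_values(cfg, _default_phase_null(x.size, cfg.fs), x.size)
    critical_values = np.asarray(critical_values, dtype=float)
    rejected = stat > critical_values
    return StationarityResult(stat, critical_values, rejected, cfg.bins)
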