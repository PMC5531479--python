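"""Raw 200 Hz recordings -> 2 Hz beat-averaged, detrended ABP/CBFV segments.

Cardiac pulsatility dominates raw ABP and CBFV; the slow oscillations that
carry autoregulatory information are recovered by averaging each signal over
the intervals between consecutive ECG R peaks (Pan-Tompkins detection),
resampling the per-beat means to a uniform 2 Hz grid with a cubic spline
(discarding eight interpolated samples at each end, where the spline is
unreliable), and removing the linear trend per physiological state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.interpolate import CubicSpline

__all__ = [
    "RawRecording",
    "BeatSeries",
    "detect_qrs",
    "beat_average_resample",
    "detrend_linear",
    "find_etco2_plateau",
    "extract_state_segments",
    "process_segment",
]


@dataclass
class RawRecording:
    """Multichannel raw record: ABP (mmHg), CBFV (cm/s), ECG (a.u.),
    EtCO2 (mmHg), all sampled at ``fs`` (200 Hz nominal)."""

    fs: float
    abp: np.ndarray
    cbfv: np.ndarray
    ecg: np.ndarray
    etco2: np.ndarray

    def __post_init__(self) -> None:
        lengths = {len(self.abp), len(self.cbfv), len(self.ecg), len(self.etco2)}
        if len(lengths) != 1:
            raise ValueError(f"channel lengths differ: {sorted(lengths)}")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        for name in ("abp", "cbfv", "ecg", "etco2"):
            ch = getattr(self, name)
            if np.isnan(ch).any():
                raise ValueError(f"channel {name} contains NaN gaps; bridge or reject first")

    @property
    def duration(self) -> float:
        return len(self.abp) / self.fs

    @property
    def time(self) -> np.ndarray:
        return np.arange(len(self.abp)) / self.fs


@dataclass
class BeatSeries:
    """Beat-averaged 2 Hz ABP/CBFV segment for one physiological state,
    detrended and trimmed of interpolation edges."""

    fs: float
    abp: np.ndarray
    cbfv: np.ndarray
    state_label: str
    t0: float = 0.0

    @property
    def duration(self) -> float:
        return len(self.abp) / self.fs


def detect_qrs(ecg: np.ndarray, fs: float) -> np.ndarray:
    """Pan-Tompkins R-peak detection; returns peak times in seconds.

    Band-pass (5-15 Hz), differentiate, square, moving-window integrate
    (150 ms), adaptive dual-threshold peak picking with refractory period,
    then refine each detection to the extremum of the band-passed ECG.
    Polarity-insensitive thanks to the squaring stage.
    """
    ecg = np.asarray(ecg, dtype=float)
    if ecg.size == 0:
        raise ValueError("empty ECG signal")
    if fs < 100:
        raise ValueError("Pan-Tompkins requires fs >= 100 Hz")
    if ecg.size < 10 * fs:
        raise ValueError("need at least 10 s of ECG")
    if np.ptp(ecg) == 0 or np.isnan(ecg).any():
        raise ValueError("QRS detection failed on channel ecg: flat or NaN signal")

    sos = signal.butter(2, [5, 15], btype="bandpass", fs=fs, output="sos")
    bp = signal.sosfiltfilt(sos, ecg)
    deriv = np.gradient(bp)
    sq = deriv**2
    win = max(1, int(round(0.150 * fs)))
    integ = np.convolve(sq, np.ones(win) / win, mode="same")

    # Adaptive threshold: running estimates of signal and noise peaks.
    refractory = int(round(0.25 * fs))
    peaks, _ = signal.find_peaks(integ, distance=refractory)
    if peaks.size == 0:
        raise ValueError("QRS detection failed on channel ecg: no peaks found")
    spk = np.max(integ[peaks[: max(1, len(peaks) // 10)]])
    npk = np.median(integ[peaks]) * 0.1
    detections = []
    for p in peaks:
        thr = npk + 0.25 * (spk - npk)
        if integ[p] > thr:
            detections.append(p)
            spk = 0.125 * integ[p] + 0.875 * spk
        else:
            npk = 0.125 * integ[p] + 0.875 * npk
    if len(detections) < 2:
        raise ValueError("QRS detection failed on channel ecg: fewer than 2 beats")

    # Refine to the |band-passed| extremum within +/-80 ms.
    half = int(round(0.080 * fs))
    refined = []
    for p in detections:
        lo, hi = max(0, p - half), min(len(bp), p + half + 1)
        refined.append(lo + int(np.argmax(np.abs(bp[lo:hi]))))
    refined = np.unique(refined)
    times = refined / fs

    ibis = np.diff(times)
    bad = (ibis < 0.3) | (ibis > 2.0)
    if bad.any():
        warnings.warn(f"{int(bad.sum())} implausible inter-beat intervals (outside 0.3-2.0 s)")
    return times


def beat_average_resample(
    x: np.ndarray, fs: float, beat_times: np.ndarray, fs_out: float = 2.0, trim: int = 8
) -> tuple[np.ndarray, float]:
    """Average ``x`` within R-R intervals and resample to a uniform grid.

    Per-beat means are placed at the midpoints of their R-R intervals
    (unbiased for linear trends), cubic-spline interpolated to an ``fs_out``
    grid, and ``trim`` samples are discarded at each end.  Returns
    (series, t_start) with ``t_start`` the time of the first retained sample.
    """
    x = np.asarray(x, dtype=float)
    beat_times = np.asarray(beat_times, dtype=float)
    if beat_times.size < 3:
        raise ValueError("need at least 3 beats to resample")
    if np.any(np.diff(beat_times) <= 0):
        raise ValueError("beat times must be strictly increasing")

    idx = np.clip((beat_times * fs).astype(int), 0, x.size)
    means, mids = [], []
    for a, b in zip(idx[:-1], idx[1:]):
        if b > a:
            means.append(x[a:b].mean())
            # samples a..b-1 span [a/fs, (b-1)/fs]; their mean represents the
            # midpoint of that span (exact for linear trends)
            mids.append(0.5 * (a + b - 1) / fs)
    if len(means) < 3:
        raise ValueError("fewer than 3 non-empty beat intervals")
    mids = np.asarray(mids)
    spline = CubicSpline(mids, np.asarray(means))
    step = 1.0 / fs_out
    t0 = np.ceil(mids[0] / step) * step
    grid = np.arange(t0, mids[-1] + 1e-9, step)
    out = spline(grid)
    if out.size <= 2 * trim:
        raise ValueError("segment too short after edge trimming")
    return out[trim : out.size - trim], float(grid[trim])


def detrend_linear(x: np.ndarray) -> np.ndarray:
    """Remove the least-squares regression line (idempotent projection)."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    return signal.detrend(x, type="linear")


def find_etco2_plateau(
    etco2: np.ndarray,
    fs: float,
    window_s: float = 60.0,
    tolerance_mmhg: float = 2.0,
    min_duration_s: float = 240.0,
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Locate normocapnic baseline and hypercapnic plateau from EtCO2.

    The hypercapnic plateau is the longest run whose rolling 60-s median
    stays within +/-``tolerance_mmhg`` of the elevated EtCO2 level; the
    baseline is the longest such run near the initial level that ends before
    the plateau.  Returns ((t0, t1) normo, (t0, t1) hyper) in seconds.
    """
    etco2 = np.asarray(etco2, dtype=float)
    win = max(1, int(round(window_s * fs)))
    from scipy.ndimage import median_filter

    smooth = median_filter(etco2, size=win, mode="nearest")
    base_level = np.median(smooth[: max(win, int(120 * fs))])
    high_level = np.percentile(smooth, 98)
    if high_level - base_level < 2 * tolerance_mmhg:
        raise ValueError(
            "no EtCO2 plateau found (no clear elevation); supply manual segment markers"
        )

    def longest_run(mask: np.ndarray) -> tuple[int, int] | None:
        best, cur = None, None
        for i, m in enumerate(np.append(mask, False)):
            if m and cur is None:
                cur = i
            elif not m and cur is not None:
                if best is None or i - cur > best[1] - best[0]:
                    best = (cur, i)
                cur = None
        return best

    hyper_run = longest_run(np.abs(smooth - high_level) <= tolerance_mmhg)
    if hyper_run is None or (hyper_run[1] - hyper_run[0]) / fs < min_duration_s:
        raise ValueError("no EtCO2 plateau of sufficient duration; supply manual markers")
    normo_mask = np.abs(smooth - base_level) <= tolerance_mmhg
    normo_mask[hyper_run[0] :] = False
    normo_run = longest_run(normo_mask)
    if normo_run is None or (normo_run[1] - normo_run[0]) / fs < min_duration_s:
        raise ValueError("no normocapnic baseline of sufficient duration; supply manual markers")
    return (
        (normo_run[0] / fs, normo_run[1] / fs),
        (hyper_run[0] / fs, hyper_run[1] / fs),
    )


def process_segment(rec: RawRecording, t_start: float, t_end: float, label: str) -> BeatSeries:
    """Full chain for one state segment: QRS detection, beat averaging of ABP
    and CBFV, 2 Hz resampling, edge trimming, linear detrending."""
    i0, i1 = int(t_start * rec.fs), int(t_end * rec.fs)
    if i1 - i0 < 10 * rec.fs:
        raise ValueError("segment shorter than 10 s")
    beats = detect_qrs(rec.ecg[i0:i1], rec.fs)
    abp, t0 = beat_average_resample(rec.abp[i0:i1], rec.fs, beats)
    cbfv, _ = beat_average_resample(rec.cbfv[i0:i1], rec.fs, beats)
    n = min(abp.size, cbfv.size)
    return BeatSeries(
        fs=2.0,
        abp=detrend_linear(abp[:n]),
        cbfv=detrend_linear(cbfv[:n]),
        state_label=label,
        t0=t_start + t0,
    )


def extract_state_segments(
    rec: RawRecording,
    markers: dict[str, tuple[float, float]] | None = None,
    min_duration_s: float = 240.0,
) -> tuple[BeatSeries, BeatSeries]:
    """Extract the normocapnia and hypercapnia (plateau) segments.

    ``markers`` maps state name -> (t_start, t_end) seconds and always
    overrides the automatic EtCO2 plateau detection.
    """
    if markers is not None:
        windows = {k: tuple(v) for k, v in markers.items()}
        if set(windows) != {"normocapnia", "hypercapnia"}:
            raise ValueError("markers must name exactly 'normocapnia' and 'hypercapnia'")
    else:
        normo, hyper = find_etco2_plateau(rec.etco2, rec.fs, min_duration_s=min_duration_s)
        windows = {"normocapnia": normo, "hypercapnia": hyper}
    for state, (a, b) in windows.items():
        if b - a < min_duration_s:
            raise ValueError(f"{state} segment shorter than {min_duration_s} s")
    return (
        process_segment(rec, *windows["normocapnia"], "normocapnia"),
        process_segment(rec, *windows["hypercapnia"], "hypercapnia"),
    )
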