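"""Synthetic signals for validating the time-frequency estimators.

Everything the validation experiments need is generated here: the
multi-component calibration chirps used to select the ZAMD windows and to
demonstrate coherence localisation, the two-component phase-test pair with
known imposed phase shifts, band-pass filtered Gaussian noise pairs for
Monte-Carlo threshold calibration, the correlated white/high-passed pair
used to calibrate the phase-stationarity test, and surrogate ABP/CBFV-like
pairs with an imposed phase lag and coherence level for parameter-recovery
studies.

All generators are deterministic given their seed and specification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.signal import butter, sosfiltfilt

__all__ = [
    "ChirpComponent",
    "PhaseTestSpec",
    "NoisePairSpec",
    "analytic_chirp",
    "calibration_components_a",
    "calibration_components_b",
    "make_calibration_a",
    "make_calibration_b",
    "make_phase_test_pair",
    "make_noise_pair",
    "make_correlated_pair_highpass",
    "make_surrogate_hemodynamics",
]


@dataclass(frozen=True)
class ChirpComponent:
    """A linear-frequency chirp: instantaneous frequency moves linearly from
    ``f_start`` to ``f_end`` (Hz) between ``t_start`` and ``t_end`` (s)."""

    f_start: float
    f_end: float
    t_start: float = 0.0
    t_end: float = 300.0
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.f_start <= 0 or self.f_end <= 0:
            raise ValueError("chirp frequencies must be positive")
        if self.t_end <= self.t_start:
            raise ValueError("t_end must exceed t_start")

    def instantaneous_frequency(self, t: np.ndarray) -> np.ndarray:
        frac = (np.asarray(t) - self.t_start) / (self.t_end - self.t_start)
        return self.f_start + (self.f_end - self.f_start) * frac


def _check_fs_duration(fs: float, duration: float) -> None:
    if fs <= 0 or duration <= 0:
        raise ValueError("fs and duration must be positive")


def analytic_chirp(comp: ChirpComponent, fs: float, duration: float) -> np.ndarray:
    """Complex (analytic) realisation of a linear chirp, exp(j*2*pi*phi(t))
    with phi'(t) the linear instantaneous frequency."""
    _check_fs_duration(fs, duration)
    t = np.arange(int(round(duration * fs))) / fs
    rate = (comp.f_end - comp.f_start) / (comp.t_end - comp.t_start)
    tau = t - comp.t_start
    phase = 2 * np.pi * (comp.f_start * tau + 0.5 * rate * tau**2)
    return comp.amplitude * np.exp(1j * phase)


#: The four calibration components: a 0.01 Hz sinusoid plus three chirps
#: sweeping 0.03->0.01, 0.03->0.05 and 0.05->0.07 Hz over the record.
_CALIB_SWEEPS = [(0.01, 0.01), (0.03, 0.01), (0.03, 0.05), (0.05, 0.07)]


def calibration_components_a(
    fs: float = 2.0, duration: float = 300.0, amplitudes: Sequence[float] | None = None
) -> list[np.ndarray]:
    """The four analytic components of calibration signal A."""
    _check_fs_duration(fs, duration)
    if fs < 2:
        raise ValueError("fs must be at least 2 Hz to resolve the components")
    amplitudes = [1.0] * 4 if amplitudes is None else list(amplitudes)
    comps = []
    for (f0, f1), a in zip(_CALIB_SWEEPS, amplitudes):
        c = ChirpComponent(f0, f1, 0.0, duration, a)
        comps.append(analytic_chirp(c, fs, duration))
    return comps


def make_calibration_a(
    fs: float = 2.0, duration: float = 300.0, amplitudes: Sequence[float] | None = None
) -> np.ndarray:
    """Calibration signal A: 0.01 Hz sinusoid + three linear chirps
    (0.03->0.01, 0.03->0.05, 0.05->0.07 Hz) spanning the record."""
    return np.sum([c.real for c in calibration_components_a(fs, duration, amplitudes)], axis=0)


def _gate(t: np.ndarray, t_off: float, ramp: float) -> np.ndarray:
    """Unit gate that is 1 for t < t_off - ramp, rolls off with a cosine ramp
    and is exactly 0 from t_off on."""
    g = np.ones_like(t)
    g[t >= t_off] = 0.0
    sel = (t >= t_off - ramp) & (t < t_off)
    g[sel] = 0.5 * (1 + np.cos(np.pi * (t[sel] - (t_off - ramp)) / ramp))
    return g


def calibration_components_b(
    fs: float = 2.0,
    duration: float = 300.0,
    gate_off: float = 180.0,
    gate_ramp: float = 10.0,
) -> list[np.ndarray]:
    """The three analytic components of calibration signal B: the sinusoid,
    the 0.03->0.05 Hz chirp, and the 0.05->0.07 Hz chirp gated off at
    ``gate_off`` seconds (cosine ramp ending exactly at the gate)."""
    _check_fs_duration(fs, duration)
    if fs < 2:
        raise ValueError("fs must be at least 2 Hz to resolve the components")
    t = np.arange(int(round(duration * fs))) / fs
    full = calibration_components_a(fs, duration)
    gated = full[3] * _gate(t, gate_off, gate_ramp)
    return [full[0], full[2], gated]


def make_calibration_b(
    fs: float = 2.0, duration: float = 300.0, gate_off: float = 180.0
) -> np.ndarray:
    """Calibration signal B: three components shared with signal A, the
    third (0.05->0.07 Hz chirp) present only before ``gate_off`` (180 s)."""
    return np.sum([c.real for c in calibration_components_b(fs, duration, gate_off)], axis=0)


@dataclass(frozen=True)
class PhaseTestSpec:
    """Two-component phase-recovery experiment.

    ``x`` is the sum of two chirps (0.06->0.05 and 0.03->0.003 Hz over the
    record); ``y`` adds a constant phase ``theta1`` to the first component
    and a linear phase ramp ``theta2_slope * t`` to the second, applied to
    the analytic components before taking the real part.
    """

    theta1: float = np.pi / 4
    theta2_slope: float = np.pi / 600.0
    duration: float = 300.0
    fs: float = 2.0
    comp1: ChirpComponent = ChirpComponent(0.06, 0.05)
    comp2: ChirpComponent = ChirpComponent(0.03, 0.003)

    def __post_init__(self) -> None:
        if not (-np.pi < self.theta1 <= np.pi):
            raise ValueError("theta1 must lie in (-pi, pi]")
        _check_fs_duration(self.fs, self.duration)

    def t_axis(self) -> np.ndarray:
        return np.arange(int(round(self.duration * self.fs))) / self.fs

    def true_phase_1(self, t: np.ndarray) -> np.ndarray:
        """Imposed phase of component 1 (rad), constant theta1."""
        return np.full_like(np.asarray(t, dtype=float), self.theta1)

    def true_phase_2(self, t: np.ndarray) -> np.ndarray:
        """Imposed phase of component 2 (rad), the linear ramp theta2(t)."""
        return self.theta2_slope * np.asarray(t, dtype=float)


def make_phase_test_pair(spec: PhaseTestSpec | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Build the two-component phase-test pair (x, y).

    Returns real signals; ``y`` leads ``x`` by ``theta1`` on component 1 and
    by ``theta2(t)`` on component 2.  Ground truth is available from the
    spec's ``true_phase_*`` methods.
    """
    spec = spec or PhaseTestSpec()
    dur = min(spec.comp1.t_end, spec.comp2.t_end)
    if spec.duration > dur:
        raise ValueError("duration exceeds the component definitions")
    f1 = spec.comp1.instantaneous_frequency(spec.t_axis())
    f2 = spec.comp2.instantaneous_frequency(spec.t_axis())
    if np.min(np.abs(f1 - f2)) < 0.005:
        warnings.warn("component bands overlap: cross-terms may corrupt the phase maps")
    a1 = analytic_chirp(spec.comp1, spec.fs, spec.duration)
    a2 = analytic_chirp(spec.comp2, spec.fs, spec.duration)
    t = spec.t_axis()
    x = a1.real + a2.real
    y = (a1 * np.exp(1j * spec.theta1) + a2 * np.exp(1j * spec.theta2_slope * t)).real
    return x, y


@dataclass(frozen=True)
class NoisePairSpec:
    """Independent Gaussian noise pair, band-pass filtered (zero-phase,
    4th-order Butterworth) to the analysed frequency range."""

    duration: float = 300.0
    fs: float = 2.0
    band_low: float = 0.02
    band_high: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.band_low < self.band_high < self.fs / 2:
            raise ValueError("require 0 < band_low < band_high < fs/2")
        _check_fs_duration(self.fs, self.duration)


def make_noise_pair(spec: NoisePairSpec) -> tuple[np.ndarray, np.ndarray]:
    """Two independent realisations of band-passed Gaussian noise."""
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * spec.fs))
    sos = butter(4, [spec.band_low, spec.band_high], btype="bandpass", fs=spec.fs, output="sos")
    x = sosfiltfilt(sos, rng.standard_normal(n))
    y = sosfiltfilt(sos, rng.standard_normal(n))
    return x, y


def make_correlated_pair_highpass(
    seed: int,
    fs: float = 2.0,
    duration: float = 300.0,
    cutoff: float = 0.05,
    order: int = 2,
) -> tuple[np.ndarray, np.ndarray]:
    """White Gaussian noise and its high-pass filtered copy.

    The high-pass filter mimics the dynamic pressure-to-flow relationship,
    giving a correlated pair whose cross phase is well defined; used as the
    null ensemble when calibrating the phase-stationarity test.
    """
    _check_fs_duration(fs, duration)
    n = int(round(duration * fs))
    if n < 1:
        raise ValueError("duration too short")
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    sos = butter(order, cutoff, btype="highpass", fs=fs, output="sos")
    y = sosfiltfilt(sos, x)
    return x, y


def make_surrogate_hemodynamics(
    phase_lag_deg: float | Callable[[np.ndarray], np.ndarray] = 0.0,
    coh_level: float = 0.95,
    seed: int = 0,
    fs: float = 2.0,
    duration: float = 300.0,
    band: tuple[float, float] = (0.02, 0.35),
    abp_mean: float = 90.0,
    abp_std: float = 5.0,
    cbfv_mean: float = 70.0,
    cbfv_std: float = 4.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Surrogate ABP/CBFV pair with an imposed phase lead and coherence.

    The "ABP" is band-limited Gaussian noise; the "CBFV" is the analytic ABP
    advanced by ``phase_lag_deg`` (positive = CBFV leads ABP; a constant or a
    callable of time in degrees) and mixed with independent band-limited
    noise so the magnitude-squared coherence is approximately ``coh_level``.
    Realistic means are added; the estimators detrend them away.  These
    surrogates reproduce only the second-order structure the estimators
    assume, not cardiovascular physiology.
    """
    if not 0 <= coh_level <= 1:
        raise ValueError("coh_level must lie in [0, 1]")
    _check_fs_duration(fs, duration)
    from scipy.signal import hilbert

    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    sos = butter(4, list(band), btype="bandpass", fs=fs, output="sos")
    s = sosfiltfilt(sos, rng.standard_normal(n))
    s = s / s.std()
    t = np.arange(n) / fs
    phi = np.deg2rad(phase_lag_deg(t) if callable(phase_lag_deg) else phase_lag_deg)
    shifted = (hilbert(s) * np.exp(1j * phi)).real
    noise = sosfiltfilt(sos, rng.standard_normal(n))
    noise = noise / noise.std()
    flow = np.sqrt(coh_level) * shifted + np.sqrt(1 - coh_level) * noise
    abp = abp_mean + abp_std * s
    cbfv = cbfv_mean + cbfv_std * flow
    return abp, cbfv
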