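"""Monte-Carlo calibration of coherence significance thresholds.

Both thresholds are the 95th percentile of the coherence observed between
pairs of independent band-pass filtered Gaussian noise:

* time-frequency: the percentile is computed pointwise over the T-F plane
  (t < 300 s, 0.02 < f < 0.35 Hz) and summarised by its mean over the
  interior region (the percentile dips near the record boundaries); the
  calibrated value is ~0.9.
* spectral (Welch): the percentile of the pooled in-band coherence values;
  the calibrated value is ~0.38.  With a single segment and no smoothing the
  Welch coherence is identically 1, which is why the multi-segment averaged
  estimator is required at all.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .coherence import SmoothingKernel, tf_coherence
from .spectral import WelchConfig, welch_transfer
from .synthetic import NoisePairSpec, make_noise_pair
from .tfr import ZAMDConfig

__all__ = [
    "ThresholdResult",
    "calibrate_tfcoh_threshold",
    "calibrate_scoh_threshold",
]


@dataclass
class ThresholdResult:
    """Calibrated threshold with its provenance.

    ``percentile_map`` is the pointwise 95th percentile restricted to the
    calibration region (time x frequency); ``scalar_threshold`` its mean over
    the interior (margins excluded)."""

    scalar_threshold: float
    percentile_map: np.ndarray
    t_axis: np.ndarray
    f_axis: np.ndarray
    n_reps: int
    seed: int
    interior_time_margin_s: float
    interior_freq_margin_hz: float

    def interior_mask(self) -> tuple[np.ndarray, np.ndarray]:
        t_ok = (self.t_axis >= self.t_axis[0] + self.interior_time_margin_s) & (
            self.t_axis <= self.t_axis[-1] - self.interior_time_margin_s
        )
        f_ok = (self.f_axis >= self.f_axis[0] + self.interior_freq_margin_hz) & (
            self.f_axis <= self.f_axis[-1] - self.interior_freq_margin_hz
        )
        return t_ok, f_ok

    @property
    def boundary_mean(self) -> float:
        """Mean of the percentile map over the excluded time margins."""
        t_ok, f_ok = self.interior_mask()
        return float(self.percentile_map[~t_ok][:, f_ok].mean())


def calibrate_tfcoh_threshold(
    n_reps: int = 10_000,
    noise_spec: NoisePairSpec | None = None,
    cfg: ZAMDConfig | None = None,
    kernel: SmoothingKernel | None = None,
    seed: int = 0,
    percentile: float = 95.0,
    region: tuple[float, float] = (0.02, 0.35),
    time_margin_s: float = 30.0,
    freq_margin_hz: float = 0.01,
) -> ThresholdResult:
    """Pointwise 95th percentile of null time-frequency coherence.

    Each repetition draws an independent band-passed Gaussian noise pair,
    computes its TF coherence, and contributes one sample per (t, f) point in
    the calibration region.  The scalar threshold is the interior mean of the
    percentile map (``time_margin_s`` at each end and ``freq_margin_hz`` at
    each band edge excluded, where the boundary effect depresses the
    percentile).
    """
    if n_reps < 100:
        raise ValueError("need at least 100 repetitions")
    base = noise_spec or NoisePairSpec()
    cfg = cfg or ZAMDConfig(fs=base.fs)
    kernel = kernel or SmoothingKernel()
    rng = np.random.default_rng(seed)
    stack = None
    sel = None
    for i in range(n_reps):
        spec_i = NoisePairSpec(
            duration=base.duration,
            fs=base.fs,
            band_low=base.band_low,
            band_high=base.band_high,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        x, y = make_noise_pair(spec_i)
        coh = tf_coherence(x, y, cfg, kernel)
        if stack is None:
            sel = (coh.f_axis > region[0]) & (coh.f_axis < region[1])
            if not sel.any():
                raise ValueError("calibration region outside the frequency grid")
            stack = np.empty((n_reps, coh.values.shape[0], int(sel.sum())), dtype=np.float32)
            t_axis = coh.t_axis
            f_axis = coh.f_axis[sel]
        stack[i] = coh.values[:, sel]
    pmap = np.percentile(stack, percentile, axis=0)
    result = ThresholdResult(
        scalar_threshold=0.0,
        percentile_map=pmap,
        t_axis=t_axis,
        f_axis=f_axis,
        n_reps=n_reps,
        seed=seed,
        interior_time_margin_s=time_margin_s,
        interior_freq_margin_hz=freq_margin_hz,
    )
    t_ok, f_ok = result.interior_mask()
    result.scalar_threshold = float(pmap[t_ok][:, f_ok].mean())
    return result


def calibrate_scoh_threshold(
    n_reps: int = 10_000,
    welch_cfg: WelchConfig | None = None,
    noise_spec: NoisePairSpec | None = None,
    seed: int = 0,
    percentile: float = 95.0,
    region: tuple[float, float] = (0.02, 0.35),
    batch: int = 200,
) -> float:
    """95th percentile of pooled Welch coherence between independent noise
    pairs, under the transfer-function configuration."""
    if n_reps < 100:
        raise ValueError("need at least 100 repetitions")
    cfg = welch_cfg or WelchConfig()
    base = noise_spec or NoisePairSpec()
    from scipy.signal import butter, sosfiltfilt

    rng = np.random.default_rng(seed)
    n = int(round(base.duration * base.fs))
    sos = butter(4, [base.band_low, base.band_high], btype="bandpass", fs=base.fs, output="sos")
    pooled = []
    done = 0
    while done < n_reps:
        b = min(batch, n_reps - done)
        x = sosfiltfilt(sos, rng.standard_normal((b, n)), axis=-1)
        y = sosfiltfilt(sos, rng.standard_normal((b, n)), axis=-1)
        freqs, scoh, _ = welch_transfer(x, y, cfg)
        sel = (freqs > region[0]) & (freqs < region[1])
        pooled.append(scoh[:, sel].ravel())
        done += b
    return float(np.percentile(np.concatenate(pooled), percentile))
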