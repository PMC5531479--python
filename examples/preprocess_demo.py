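"""From a raw 200 Hz multichannel recording to analysis-ready 2 Hz series.

Builds a synthetic 15-minute session (pulsatile ABP/CBFV with a slow
0.05 Hz oscillation, a 1 Hz ECG, EtCO2 stepping into a hypercapnic
plateau), then runs the full preprocessing chain: QRS detection, beat
averaging, 2 Hz spline resampling, edge trimming and detrending, with the
state segments located automatically from the EtCO2 plateau.
"""

import numpy as np

from tfca import RawRecording, extract_state_segments

fs, duration = 200.0, 900.0
n = int(duration * fs)
t = np.arange(n) / fs
rng = np.random.default_rng(0)

beats = np.arange(0.5, duration, 1.0)
impulses = np.zeros(n)
impulses[(beats * fs).astype(int)] = 1.0
tq = np.arange(-0.05, 0.05, 1 / fs)
qrs = np.exp(-(tq**2) / (2 * 0.008**2)) * np.cos(2 * np.pi * 12 * tq)
ecg = np.convolve(impulses, qrs, mode="same")

abp = 90 + 5 * np.sin(2 * np.pi * 0.05 * t) + 10 * np.sin(2 * np.pi * 1.0 * t)
cbfv = 70 + 4 * np.sin(2 * np.pi * 0.05 * t + 0.6) + 8 * np.sin(2 * np.pi * 1.0 * t)
etco2 = np.where(t < 420, 37.0, 48.0) + 0.2 * rng.standard_normal(n)
from scipy.ndimage import uniform_filter1d

etco2 = uniform_filter1d(etco2, int(20 * fs))

rec = RawRecording(fs=fs, abp=abp, cbfv=cbfv, ecg=ecg, etco2=etco2)
normo, hyper = extract_state_segments(rec)

for seg in (normo, hyper):
    print(
        f"{seg.state_label}: {seg.duration:.0f} s at {seg.fs:.0f} Hz, "
        f"starts {seg.t0:.1f} s into the session, "
        f"ABP sd {seg.abp.std():.2f} mmHg (pulsatility removed, slow wave kept)"
    )

print(
    "\nThe 1 Hz cardiac pulsation is averaged out beat by beat while the"
    " 0.05 Hz autoregulatory oscillation survives; both states give"
    " equal-rate, detrended series ready for the coherence estimators."
)
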