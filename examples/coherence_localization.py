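"""Coherence is high exactly where two signals share components.

Calibration signal A holds four components (a 0.01 Hz sinusoid and three
chirps); signal B shares three of them, one only for the first 3 minutes.
The time-frequency coherence map should light up only on the shared
component trajectories.
"""

import numpy as np

from tfca import ChirpComponent, chirp_corridor, make_calibration_a, make_calibration_b, tf_coherence

a = make_calibration_a()
b = make_calibration_b()
coh = tf_coherence(a, b)

t = np.arange(a.size) / 2.0
shared = [
    ("0.01 Hz sinusoid", ChirpComponent(0.01, 0.01), 300.0),
    ("chirp 0.03->0.05 Hz", ChirpComponent(0.03, 0.05), 300.0),
    ("chirp 0.05->0.07 Hz (off at 180 s)", ChirpComponent(0.05, 0.07), 180.0),
]
common = np.zeros_like(coh.values, dtype=bool)
for name, comp, t_end in shared:
    region = chirp_corridor(coh.t_axis, coh.f_axis, comp.instantaneous_frequency(t), 0.02)
    region[t > t_end + 15] = False
    frac = (coh.values[region] > 0.9).mean()
    print(f"{name}: {frac:.0%} of its corridor above the 0.9 threshold")
    common |= region

analysed = (coh.f_axis > 0.02) & (coh.f_axis < 0.35)
outside = 100 * (coh.values[(~common) & analysed[None, :]] > 0.9).mean()
print(f"outside all shared components: {outside:.1f}% above threshold")
print(
    "\nSignificant coherence concentrates on the shared trajectories; the"
    " small leak outside is threshold false positives plus smoothing spill."
)
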