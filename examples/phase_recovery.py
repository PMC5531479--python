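"""Recovering known phase shifts from a two-component test pair.

x is the sum of two chirps (0.06->0.05 Hz and 0.03->0.003 Hz over 5 min);
y adds a constant 45-degree phase to the first component and a linear
0->90-degree ramp to the second. The masked time-frequency phase map should
hand both back.
"""

import numpy as np

from tfca import (
    PhaseTestSpec,
    chirp_corridor,
    component_time_course,
    exclude_wrap_regions,
    make_phase_test_pair,
    tf_coherence,
    tf_phase,
)

spec = PhaseTestSpec()
x, y = make_phase_test_pair(spec)
coh = tf_coherence(x, y)
pmap = exclude_wrap_regions(tf_phase(coh, 0.9))

t = spec.t_axis()
for name, comp, truth in (
    ("constant 45 deg", spec.comp1, np.rad2deg(spec.true_phase_1(t))),
    ("ramp 0->90 deg", spec.comp2, np.rad2deg(spec.true_phase_2(t))),
):
    region = chirp_corridor(coh.t_axis, coh.f_axis, comp.instantaneous_frequency(t), 0.01)
    region &= coh.f_axis[None, :] >= 0.02  # analysed range only
    course = component_time_course(pmap, region)
    rmse = np.sqrt(np.nanmean((course - truth) ** 2))
    covered = np.mean(~np.isnan(course))
    print(f"{name}: RMSE {rmse:.2f} deg over {covered:.0%} of the record")

print(
    "\nRMSE of a couple of degrees means the estimator tracks both a fixed"
    " and a drifting phase relationship; the ramp's coverage is partial"
    " because its chirp leaves the analysed 0.02-0.35 Hz range late in the"
    " record."
)
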