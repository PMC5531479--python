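"""A simulated cohort study: does hypercapnia lower the ABP->CBFV phase lead?

Twenty surrogate subjects are given a 40-degree CBFV lead in normocapnia
and a 20-degree lead in hypercapnia (weakened autoregulation). The full
pipeline runs per subject/state and the paired Wilcoxon tests compare the
states, exactly as a real cohort would be analysed.
"""

from tfca import make_surrogate_hemodynamics, run_cohort, summarize_median_iqr
from tfca.preprocess import detrend_linear

subjects = {}
for sid in range(20):
    normo = make_surrogate_hemodynamics(40.0, 0.95, seed=100 + sid)
    hyper = make_surrogate_hemodynamics(20.0, 0.95, seed=900 + sid)
    subjects[f"s{sid:02d}"] = {
        "normocapnia": tuple(detrend_linear(v) for v in normo),
        "hypercapnia": tuple(detrend_linear(v) for v in hyper),
    }

df, comparisons, failures = run_cohort(subjects)
assert not failures

for band in ("VLF", "LF", "HF"):
    col = f"aTFPS_{band}"
    wide = df.pivot(index="subject", columns="state")[col]
    mn, in_ = summarize_median_iqr(wide["normocapnia"])
    mh, ih = summarize_median_iqr(wide["hypercapnia"])
    p = comparisons[col]["p"]
    print(f"aTFPS {band}: normo {mn:.1f} [{in_:.1f}] deg vs hyper {mh:.1f} [{ih:.1f}] deg, p = {p:.2g}")

print(
    "\nMedians recover the imposed 40 and 20 degree leads and the paired"
    " Wilcoxon test flags the decrease in every band - the qualitative"
    " signature of impaired dynamic autoregulation under hypercapnia."
)
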