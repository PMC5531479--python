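# Methods

This note records the model, the estimators, the defaults and the numerical
choices behind `tfca`, including the places where the design was genuinely
open and what the synthetic experiments do and do not demonstrate.

## Signal model and preprocessing

The object of study is the relation between slow (< 0.35 Hz) oscillations of
arterial blood pressure (ABP) and cerebral blood flow velocity (CBFV).
Raw 200 Hz recordings are dominated by cardiac pulsatility, so both channels
are averaged within R–R intervals (Pan–Tompkins QRS detection on the ECG:
5–15 Hz band-pass, derivative, squaring, 150 ms integration, adaptive
dual threshold with a 250 ms refractory period, peak refinement within
±80 ms). Each beat mean is placed at the midpoint of its interval — an
unbiased convention for linear trends, and the boundary convention is
`(first + last sample)/2` of the interval so ramps are reproduced exactly —
then cubic-spline interpolated to a uniform 2 Hz grid. Eight samples are
discarded at each end, where the spline extrapolates from one-sided
information. Segments are linearly detrended per physiological state.

State segmentation uses manual markers when given; otherwise the hypercapnic
plateau is the longest stretch whose 60-s rolling median EtCO₂ stays within
±2 mmHg of the elevated level, and the normocapnic baseline is the analogous
stretch at the initial level, each at least 240 s (300 s is the nominal
design length; 240 s still carries five half-overlapping Welch segments with
acceptable degradation).

## The two-window cone-kernel distribution

The cross distribution of analytic signals x, y is

    S_xy(t,f) = Σ_τ h(τ) e^(−j2πfτ) · avg_{|u−t| ≤ |τ|/2} [ g(u−t) x(u+τ/2) y*(u−τ/2) ]

with both windows Hanning: `h` (length `L_h`) sets frequency resolution,
`g` (length `L_g`) the smoothing inside the cone. Discretely, lag τ = 2m
samples, so `N` frequency bins span `[0, fs/2)` at spacing `fs/(2N)`
(`N = 512` by default; the DC bin is outside every analysis band). The
cone average is normalised by the g-mass over the full cone support — the
canonical 1/|τ|-weighted cone kernel; an unnormalised cone sum makes the
null coherence distribution so heavy-tailed that no threshold calibration
is possible. At the record ends the cone is truncated without
renormalisation, which produces the deliberate boundary attenuation visible
in all maps. Auto distributions use conjugate symmetry of the lag kernel
and are exactly real.

Window lengths default to `L_h = 449`, `L_g = 513` samples at 2 Hz. The
selection criterion `Q = REP + IP` is implemented (3rd-order Rényi entropy
of the normalised |TFR| in bits, plus the mean count of local maxima per
frequency slice above 1% of the global peak) but its argmin depends on
those two conventions and on the search grid, so the defaults are pinned
rather than re-derived per analysis.

## Coherence, its smoothing and its threshold

Quadratic distributions give |coherence| ≡ 1 pointwise without further
smoothing, so cross and auto distributions are convolved with a common 2-D
Gaussian before the ratio is formed. Defaults: σ_t = 10 s, σ_f = 0.0125 Hz,
truncated at ±4σ, applied as periodic (circular) convolution. These values
are the minimal smoothing that bounds the estimator: σ_f below the
distribution's ~0.0045 Hz resolution cell leaves the null unbounded, while
heavier smoothing drives the significance threshold well below 0.9 and
erodes time–frequency support. Circular convolution preserves mass and
constants exactly and reproduces the empirically observed *depression* of
the null percentile at the record edges (zero-padded or renormalised
borders cancel in the ratio and instead elevate the edges).

Coherence is defined only where both smoothed auto spectra carry genuine
power — above `rel_floor` (default 10⁻³, i.e. 30 dB) of their grid maximum.
Without this floor, regions with no signal content evaluate 0/0 leakage to
ratios near 1 and the localisation property is lost. For strongly
1/f-distributed data whose HF power is genuinely more than 30 dB below the
VLF peak, lower the floor. No Gaussian makes a cone-kernel distribution
exactly positive semidefinite, so the ratio can exceed 1 on ~2·10⁻⁴ of null
grid points; values are clipped to 1 and the raw overflow fraction is kept
on the map as a diagnostic.

The significance threshold is calibrated by Monte Carlo: pairs of
independent Gaussian noise, band-passed 0.02–0.35 Hz (zero-phase 4th-order
Butterworth — the analysed range; the calibration is insensitive to the
exact band because coherence is scale-free), 95th percentile pointwise over
the plane, summarised by its mean over the interior (30 s time margins and
0.01 Hz band-edge margins excluded). With 500 repetitions the interior mean
is 0.906; `T_h = 0.9` is the package default.

## Phase maps and their summaries

The phase map is `arg` of the conjugated smoothed cross distribution, so
positive phase means the second input (CBFV) leads the first (ABP) —
equivalently, for `y = x·e^{jθ}` on an analytic component, the recovered
phase is +θ. Phase is kept only where coherence ≥ `T_h`. Because phase
lives on (−π, π], a true difference drifting across ±180° produces a region
holding extreme values of both signs; 8-connected components of the
extreme-phase subset (|phase| > 160°, both signs present) are excised from
the valid mask before averaging. `aTFPS` is the arithmetic mean of the
surviving phases in a band, in degrees (a circular mean is available;
arithmetic is the default because wrap regions have already been removed).
Component time courses average the valid phases along frequency inside a
corridor around a component's instantaneous-frequency trajectory,
intersected with the analysed 0.02–0.35 Hz range.

On the two-component phase-test pair (chirps 0.06→0.05 Hz and
0.03→0.003 Hz; imposed 45° constant and π·t/600 ramp) the recovered courses
have RMSE 1.45° and 1.68°. The ramp's chirp leaves the analysed range after
~200 s (under one cycle of signal remains and analytic-signal leakage
dominates), so its course covers ~2/3 of the record; extending the corridor
to near-DC inflates the RMSE to ~8° for reasons intrinsic to sub-resolution
frequencies, not to the estimator.

## Welch baseline

Five 100-s Hanning segments tile a 300-s record at 50% overlap (the overlap
is implied by the counts, not free). Auto spectra and the cross-spectral
*magnitude* are smoothed across frequency with (¼, ½, ¼) before the
coherence ratio — magnitude smoothing keeps the estimator exactly bounded
by Cauchy–Schwarz and its Monte-Carlo null 95th percentile is 0.395,
matching the 0.38 significance convention; smoothing the complex cross
instead yields 0.34. The phase is taken from the complex-smoothed cross
spectrum, which is what a phase average requires, with the same
CBFV-leads-positive sign convention. `SPS` is the phase at the band's
coherence maximum (ties resolved toward the lower frequency); `aSCoh` below
0.38 flags a band where the spectral phase is not interpretable. With one
300-s segment and no smoothing the coherence is identically 1 — the
single-segment degenerate case the tests document.

## Stationarity test

The record is split into M = 5 equal segments (60 s at 2 Hz; M is a config
choice, not a printed constant) and a Hanning periodogram computed per
segment. The per-segment power is averaged within each analysis bin (0–0.1,
0.1–0.2, 0.2–0.3, 0.3–0.4 Hz) and the statistic log(AM/GM) taken across
segments per bin; aggregating power before the statistic is essential —
applied per raw Fourier ordinate the χ²₂ scatter swamps any realistic
alternative (8.6% rejection against a 2× variance step versus 18% with bin
aggregation, 73% against a 4× step). Critical values are per-bin
(1 − 0.0125) quantiles from Monte Carlo of the matching null — white
Gaussian noise for the power test; white noise paired with its 2nd-order
Butterworth 0.05 Hz high-passed copy for the phase variant, whose per-
segment cross phase is mapped to [0, 2π) (round-off at the 0/2π seam is
snapped to 0, and an identically-zero phase field returns a degenerate zero
statistic with a warning). A record is nonstationary when any bin rejects;
under the null the overall rate is 1 − (1 − 0.0125)⁴ ≈ 4.9%, verified at
2,000 replications.

## Surrogate hemodynamics

`make_surrogate_hemodynamics` draws band-limited Gaussian "ABP", advances
its analytic signal by the requested phase (constant or a function of
time), and mixes in independent band-limited noise with weights √c and
√(1−c) so the realised magnitude-squared coherence is ≈ c. Means and scales
(90 ± 5 mmHg, 70 ± 4 cm/s) are cosmetic; the estimators detrend them away.
These surrogates reproduce exactly the second-order structure the
estimators assume — a stationary, spectrally flat (in band) linear relation
plus incoherent noise. They contain no cardiac cycle, no respiratory peak,
no 1/f power distribution, no nonlinearity and no nonstationarity, so
passing recovery tests demonstrates estimator correctness, not robustness
to real physiology. Imposed constant leads of 0–40° at coherence 0.95 are
recovered by `aTFPS` within ±5° in every band, and a 20-subject cohort with
a 40°→20° lead decrease is detected by the paired Wilcoxon test at
p < 0.01.

## Group statistics

Paired Wilcoxon signed-rank (zero differences dropped; exact null up to 25
informative pairs, continuity-corrected normal approximation above —
relevant at cohort sizes around 50), Friedman ANOVA with Bonferroni-adjusted
pairwise Wilcoxon post-hocs at α = 0.017, the Pitman–Morgan test for equal
variances of paired estimates (t-test of the correlation between pair sums
and differences, n − 2 df; at zero pair correlation its decisions agree
with the variance-ratio F test), Spearman rank correlation, and
median [IQR] summaries with linear-interpolation (type-7) quantiles.

## Problem sizes and reproducibility

The validation experiments run at the study's own scale — 300-s records at
2 Hz, 500 repetitions for the time–frequency threshold and 10,000 for the
Welch threshold, 2,000–4,000 replications for test-size checks — except
that generic estimator properties (boundedness, symmetry) are exercised on
a reduced 64-bin grid where the full window lengths are irrelevant. Every
stochastic component takes an explicit integer seed; identical seeds give
bit-identical outputs, and pipeline records carry a hash of the full
configuration.

## Known limitations

- The wrap-exclusion rule automates what is ultimately a judgment call;
  phase fields genuinely concentrated near ±180° lose area to it.
- The coherence bound is enforced, not intrinsic: the overflow diagnostic
  should be inspected when smoothing parameters are changed.
- The power floor defining "no genuine power" is global over the map; data
  with extreme spectral tilt need a per-band floor or a lower default.
- Beat-averaged sampling at 2 Hz aliases any coupling above 1 Hz into the
  analysed range; the estimators assume the preprocessing chain has removed
  pulsatile content.
- Automatic EtCO₂ segmentation expects a clean step-and-plateau profile;
  irregular breathing protocols need manual markers.
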