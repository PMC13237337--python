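# Methods

## Signal chain

A swept test presents clicks at 20/s while the contralateral elicitor
level traces a triangle, 40 → 110 → 40 dB FPL over 8 s, repeated 15 times
(2400 clicks). The per-click analysis and the LGF reduction follow a fixed
chain; every constant below is exposed in `PipelineConfig` or the
preprocessing module and printed by the CLI's `--help`.

**Windowing.** Each click epoch is located by peak search within ±2 ms of
its scheduled time; the analysis window starts *at* the peak sample
(which carries ramp weight 0) and lasts 1.20 ms with 0.146-ms
raised-cosine onset/offset ramps — 115 samples and 14-sample ramps at
96 kHz, using round-half-away-from-zero so these counts are reproducible.
"Flattop" here means a unity plateau with cosine tapers (a Tukey-style
window), not the spectral flat-top family: the shape is dictated by the
requirement that the onset ramp remove the incident peak while passing the
reflected energy that arrives from ~82 µs (2·1.4 cm / 344 m/s) onward.
Phases are referenced to the window start, making them comparable across
clicks. Windowed segments are zero-padded to fs/100 Hz samples (960) and
Fourier transformed; bins 500…1500 Hz are DFT indices 5…15.

**Detrending.** Per bin, the 15 sweeps are concatenated into one
2400-point series; real and imaginary parts are separately fit by a
weighted cubic smoothing spline with parameter 1e-9, the fit subtracted,
and the fit's mean added back. The spline convention is
p·Σwᵢ(yᵢ−f(xᵢ))² + (1−p)·∫(f″)² with x in click-index units, i.e.
roughness weight λ = (1−p)/p per unit spacing (scipy's
`make_smoothing_spline` with that λ). Under this convention the
operator's measured −3 dB cutoffs at 20 samples/s are 0.454 Hz for
p = 0.001 and 0.0144 Hz for p = 1e-9 — matching the asymptotic
smoothing-spline response |H(ω)| = 1/(1+λω⁴) — and these are the values
`smoother_cutoff` reports (the script rounds them to 0.45 and 0.014).
This convention was fixed *a priori* because no other unit choice brings
both parameters' cutoffs into the working range simultaneously.

**Weights.** Artifact control is a binary robust rule: per click position
and bin, the deviation of each sweep's value from the across-sweep median
is scored against 1.4826 × the median absolute deviation; a click whose
median score across the 11 bins exceeds 3 gets weight 0, as do clicks
flagged missing during epoching. Real sessions need graded weights less
than outlier excision; a binary rule is transparent and testable.

**Averaging, smoothing, normalizing.** Weighted mean across sweeps, then
per-bin spline smoothing at p = 0.001 (weights carried into the spline;
zero-weight clicks are interpolated through). The complex baseline is the
mean of the first three and last three smoothed responses — taken where
the elicitor sits at its 40-dB floor — and the whole trajectory is divided
by it, so any static probe/transducer transfer function cancels exactly.

**Total change.** TC = |z − 1| per bin, averaged across the 11 bins; the
dB form is 20·log10(1+TC), chosen so baseline maps to 0 dB and the value
stays finite (the convention for "dB re baseline" was otherwise open).
The signed path-length alternative ∫k√(ẋ²+ẏ²)dt is implemented with first
differences and trapezoidal accumulation, the sign k flipping at the
argmax of the closed-form TC (first index on ties); on smooth reflex
trajectories the two agree at the peak to within a few percent, the
path-length form exceeding the chord form by the trajectory's curvature.

**Features.** Peak (first argmax) → max TC and delay re the 4-s apex; the
time axis is shifted by −delay and mapped to levels through the triangle
(clamped to the sweep support — levels are never extrapolated beyond
40–110 dB). The criterion is applied to *linear* TC as
10^(−12/20) ≈ 0.2512 of the peak, since "−12 dB / 74.9 % reduction" is an
amplitude ratio; crossings are linearly interpolated in (level, TC), and
with multiple crossings the ones adjacent to the peak are used, which is
robust to sub-threshold wiggles. Absent crossings flag the thresholds
rather than guessing.

## Synthetic sessions

The simulator emulates what the paradigm measures, not an individual ear.

**Middle ear.** A series resonator Z(f) = r + i2πfm + k/(i2πf), resonance
1000 Hz (within the 800–1200 Hz range typical of adult ears), Q = 1.5.
Reflex activation a ∈ [0,1] raises stiffness to k(1 + a·Δk_max),
Δk_max = 0.4, shifting the resonance up ~18 % at full activation.

**Measurement model.** Template ear-canal clicks are rendered as a
band-limited incident pulse (windowed sinc, 18-kHz cutoff) plus the
internal-reflection train Γe/(1 − g_sΓe), where Γ = (Z−Zs)/(Z+Zs) is the
eardrum reflectance (source impedance Zs = 2r), e the round-trip delay
phase (82 µs), and g_s = 0.5 the probe-side reflectance. The per-click
complex response is *defined* as the standard window+bin analysis of this
template, relative to the a = 0 template. This single definition serves
both simulation paths: the direct path interpolates it on a dense
activation grid, and the waveform path renders the same templates into a
96-kHz pressure trace, so binning the waveforms reproduces the direct
matrix to within float32 storage precision. Defining the ground truth
through the measurement model is deliberate: an 11-bin target spaced
100 Hz apart is not resolvable through a 1.2-ms window (the windowed-bin
map has numerical rank ≈ 6 of 22), so no rendering could reproduce
bin-by-bin values prescribed independently of the window. The lumped
relative change R(f,a) = [Z_a/(Z_a+Zs)]/[Z_0/(Z_0+Zs)] remains available
as the theoretical primitive and shows the same signature the rendered
model inherits: SPL rise below resonance, fall above it, non-monotonic
growth near it.

**Reflex dynamics.** Steady-state activation is logistic in level,
a∞(L) = 1/(1+e^−(L−L50)s) with L50 = 99 dB FPL and s = 0.2 dB⁻¹; a(t)
relaxes toward a∞(L(t−d)) with neural delay d = 150 ms and time constants
τ_attack = 0.1 s / τ_release = 1.2 s (exponential-Euler substeps with
midpoint level sampling; unconditionally stable, refinement-invariant to
<1e-4). Swept sweeps start from a = 0 — the analysis treats sweeps as
repeats, and the ≲1 % physical residual at the sweep end is deliberately
not carried over. The discrete paradigm *is* one continuous timeline, so
activation from loud bursts lingers into the next sequence's baseline
click; that residual is a real mechanism by which the discrete paradigm
underestimates total change.

**Defaults as study conditions.** The defaults above were calibrated once
against the population medians the paradigm reports on human ears —
maximum total change ≈ 2 dB, onset/offset thresholds ≈ 88/73 dB FPL,
hysteresis ≈ −15 dB — and then frozen. One compromise is documented
rather than hidden: with single-pole release dynamics, the slow release
needed for −15 dB hysteresis skews the LGF so the 0.46-Hz smoother
displaces the TC peak; the measured delay at defaults is ~450 ms, larger
than the 100–210 ms typical of human recordings, although the neural
delay parameter itself (150 ms) is in that range. Matching both delay and
hysteresis would need release dynamics with more than one pole.

**Noise.** Per click and bin, additive complex Gaussian noise of SD 0.05
(relative to the unit baseline); a slow real gain drift (SD 0.02, spline
through knots every 60 s, within the detrender's stopband); optional rare
loud glitches for exercising the weights. All randomness derives from one
integer seed through named substreams; identical seeds give bit-identical
sessions. The waveform path carries an independent white-noise realization
matched in average per-bin magnitude, as a physical recording would.

**Population priors.** Synthetic subjects draw f0 ~ N(1000, 75) Hz,
Δk_max ~ N(0.4, 0.08), L50 ~ N(99, 4) dB, s ~ N(0.2, 0.025) dB⁻¹,
d ~ N(150, 40) ms, τ_attack ~ N(0.1, 0.015) s, τ_release ~ N(1.2, 0.15) s,
truncated to physical ranges. These spreads keep every subject's reflex
measurable within the sweep while separating subjects clearly — the
regime in which the paradigm's repeatability claim applies.

**What the simulator does not emulate.** Individual ear-canal acoustics
beyond one length/delay, probe reinsertion between tests (repeats differ
only in noise and drift seeds), ipsilateral/bilateral elicitation,
tensor-tympani vs stapedius contributions, and any mechanism behind the
slow trend (treated as exogenous drift, not reflex buildup). Passing
tests therefore demonstrate that the *analysis* recovers what this model
family encodes at realistic noise — not that human data will be as tame.

## Statistics

ICC(C,k) is computed from the two-way subjects × tests ANOVA as
(MS_rows − MS_error)/MS_rows; column (test-order) main effects cancel by
construction. Degenerate tables return defined values instead of raising.
The robust fit is IRLS with Tukey bisquare (c = 4.685), MAD scale,
iterated to weight convergence (statsmodels RLM underneath); the slope CI
is asymptotic from the robust covariance at the 95 % level, and R² is
computed from the final weighted sums of squares — stated explicitly since
no universal robust-R² convention exists. An exactly collinear fit drives
the MAD scale to zero; that is reported as converged.

## Problem sizes in the test suite

The suite simulates full-size single tests (15 sweeps) where a single
session suffices, a 2-sweep session for waveform-path checks, 20 seeded
sessions for noise-robustness of the five measures, and a
30-subject × 4-repeat population for the repeatability harness — sizes
chosen to make every statistical check meaningful on one CPU within a few
minutes.
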