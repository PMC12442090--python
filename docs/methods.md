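# Methods

`brspike` analyses slow electrical oscillations of proteinoid microspheres
and proteinoid–bacteriorhodopsin complexes recorded as open-circuit voltage
time series (1 Hz sampling, millivolt scale, periods of hundreds to
thousands of seconds), together with the wavelength-dependent photoresponse,
boolean response classification, random-walk spatialization, and the
electrochemical (CV/EIS) characterisation of the material. This note
records the models, the defaults and why, and what the synthetic data do
and do not establish.

## Synthetic recordings

A recording is modelled as a cycle-wise sinusoid with additive white noise:

    V(t) = A_k sin(2π (t − t_k)/P_k + φ) + η(t),   t in cycle k

with per-cycle draws A_k ~ N(μ_A, σ_A) truncated at 0 and
P_k ~ N(μ_P, σ_P) truncated at 0.5 μ_P, and η(t) iid N(0, σ_η). Per-cycle
(rather than per-sample) resampling makes the event-level amplitude/period
statistics that the analysis reports directly recoverable: each cycle is
one "event", its onset-to-onset interval is exactly P_k, its peak height
above baseline exactly A_k. Truncations prevent degenerate (negative-
amplitude or near-zero-period) cycles. The inter-event-interval
distribution is an assumption — only mean ± SD values are available per
condition, so Normal-per-cycle is the simplest consistent choice.

Per-condition presets (amplitude μ ± σ in mV, period μ ± σ in s) carry the
published summary statistics for both groups — e.g. complex channels:
dark 10.77 ± 2.21 / 2641.80 ± 88.76, green 7.31 ± 1.49 / 645.23 ± 16.32,
blue 3.64 ± 2.69 / 647.23 ± 14.38, yellow 3.99 ± 2.25 / 662.48 ± 11.60,
red 1.68 ± 1.06 / 649.61 ± 11.47 — with strongly suppressed proteinoid-only
amplitudes under light (0.21–0.33 mV). Noise SD presets encode the
observed ordering of noise across conditions: green 0.3 mV < blue = yellow
0.8 mV < dark 1.5 mV. Red is not quantified anywhere; we place it in the
blue/yellow tier (0.8 mV) since descriptions put red's noise above green's.
All presets are overridable per call.

Occasional large transients (such as a ~100 mV excursion on a single
channel) are modelled as isolated half-sine pulses of width 60 s injected
at Poisson-placed times; the default rate is 0 so statistics tests are not
contaminated unless a test asks for outliers.

What the generator does *not* emulate: baseline drift, 1/f noise,
channel-to-channel covariance, waveform asymmetry (rise ≠ decay), and
light-onset transients. Passing parameter-recovery tests therefore shows
the analysis chain is unbiased for the assumed signal class, not that it is
robust to every feature of laboratory recordings.

## Spike detection

The detection procedure is the package's own design (no published
procedure exists for these tables):

1. **Baseline**: centred rolling median. The window defaults to 5× the
   dominant period (estimated by a plain FFT argmax); a window spanning a
   non-integer number of cycles leaves a phase-locked median bias of up to
   ~0.1 A at the peaks, while integer multiples cancel it. Fallback 3000 s
   when no period is estimable.
2. **Smoothing**: a quadratic Savitzky–Golay filter (window ≈ period/10)
   is applied to the detrended trace before peak extraction. A broad
   oscillation peak passes a local quadratic essentially unchanged
   (relative error ~(ωh)⁴/24 ≈ 4·10⁻⁴ at h = P/20) while the noise that
   biases a per-cycle maximum upward (max-of-noise effect, ~+3% at the
   green preset) is suppressed.
3. **Peaks**: local maxima with prominence ≥ 3× a robust noise SD and
   separation ≥ half the dominant period (one event per cycle). The noise
   SD uses the first-difference MAD estimator
   1.4826·median|ΔV|/√2 — differencing removes the slow oscillation, so
   the estimate tracks the noise floor rather than the signal amplitude.
4. **Event geometry**: amplitude = smoothed detrended value at the peak;
   onset/offset = nearest preceding/following baseline crossings; duration
   = offset − onset; period = onset-to-onset between consecutive events.
   Plateau maxima resolve to their leftmost sample. Events within half a
   baseline window of either trace edge are dropped (the centred median is
   computed over a partial window there and is biased).

With these defaults, 20 synthetic green-preset channels of 86,400 s
recover the generating amplitude mean within 3 SEM and the period mean and
SD to within a few tenths of a percent (see `tests/test_synthdata.py`).

Summary statistics use the sample SD (n−1). Group summaries pool all
events across channels for mean ± SD and range; the median-range is the
(min, max) of per-channel medians, mirroring the published table layout.

## Periodicity

The pipeline is: zero-phase 4th-order Butterworth low-pass at 0.1 Hz
(forward–backward, so ~8th-order magnitude response and no phase delay),
mean removal, DFT zero-padded to the next power of two ≥ 4× the trace
length, and S(f) = |F(f)|². The dominant frequency f₀ is the argmax over
f > 1/duration (excluding DC and sub-record frequencies); τ = 1/f₀ exactly.
Zero-padding interpolates the spectral grid to ~1.9 µHz at 86,400 samples,
which is what makes f₀ land on 0.00155/0.00151 Hz at 5 decimal places for
the 645.23 s and 662.48 s reference periods. No window is applied by
default (a Hann option exists); for a single dominant line and long
records, leakage does not move the argmax.

The autocorrelation is computed through the Wiener–Khintchine theorem —
inverse FFT of the power spectrum, zero-padded to ≥ 2n so the circular
product realises the linear lag sum — and normalised to R(0) = 1. The
characteristic period is read off as the first local maximum after the
first zero crossing. A direct O(n²) lag-sum implementation is kept as an
independent route and the two agree to < 10⁻⁸ (tested at n = 512).

One-way ANOVA implements the textbook decomposition
F = MS_between/MS_within with p from F(k−1, N−k); it is cross-checked
against `scipy.stats.f_oneway`. A zero within-variance case returns a
flagged infinite-F result rather than raising. The coefficient of
variation is 100·s/μ with sample SD.

## Photoresponse

Molar photon energy: E = h c N_A / λ (CODATA constants, thermochemical
calorie 4184 J); 520 nm gives 54.98 kcal/mol. A `rounded` mode rounds to
integer kcal/mol, reproducing the conventional 55 − 20 = 35 kcal/mol
stored-energy bookkeeping for green light exactly; the default keeps full
precision (34.98, a 0.02 kcal/mol difference the rounded figure hides).
The retinal isomerization cost defaults to 20 kcal/mol; stored energy is
linear in it with slope −1 and may go negative (flagged) for long
wavelengths.

The wavelength sensitivity curve S(λ) = A₀ exp(−(λ−λ_max)²/(2σ²)) is fit
by least squares with a deterministic initializer (A₀ = max amplitude,
λ_max = its wavelength, σ = half the wavelength span). With four
conditions (470/520/580/630 nm) the fit is over-determined by one point;
a brute-force grid search oracle in the tests confirms the optimiser finds
the global basin (λ_max in the green band). The decomposition of λ_max
into an intrinsic value plus protein and electrostatic shifts has no
assignable values and is not fitted.

The hierarchy check (green > blue ≈ yellow > red) treats blue ≈ yellow as
agreement within 20% relative by default.

## Boolean classification

Thresholds: θ_H = 5.0 mV, θ_L = 1.0 mV, P_threshold = 650 s, σ_P < 20 s,
σ_A < 0.3 A. Boundary semantics are literal: strong iff A ≥ θ_H, stable
and complex use strict `<`. The optimal-light rule is the priority chain
Green ≻ Blue∧Yellow ≻ Blue ≻ Yellow ≻ Red over the four per-wavelength
response bits, and the 16-row truth table is its exhaustive enumeration
(Green optimal in 8 rows). The response bit R_x is not formally defined in
the source material; we interpret it as the medium-or-strong indicator
(A ≥ θ_L), since all four conditions are at-least-medium responders in the
classification table; a strict-strong rule (A ≥ θ_H) is selectable in
`BooleanConfig`.

## Random walk

Each spike event is one step: r(t+Δt) = r(t) + A(cos θ, sin θ), step length
equal to the event amplitude (a millivolt-scaled virtual displacement —
physical micrometres are presentation only and not modelled). The
direction source is configurable: the instantaneous (analytic-signal)
phase of a designated reference channel at the event times, or seeded
uniform angles; the exact multi-channel phase rule used originally is
unspecified, so the seeded-uniform mode is the default for all quantitative
tests. Displacement D(t) is the Euclidean distance from the origin;
the effective diffusion coefficient is the Einstein estimator
D_eff = ⟨D(t)²⟩/(4t) at the final common step. For isotropic unit steps
E[D(n)²] = n, so D_eff → 0.25, which the Monte-Carlo tests verify at 10⁴
walks. A log-log slope > 1.5 of the ensemble MSD flags ballistic
(straight-line) ensembles where the diffusive summary is meaningless.

## Electrochemistry

CV peaks: the cycle is split at the switching potential (potential
argmax); i_pa is the forward maximum, i_pc the reverse minimum, i_sp the
current at switching. Baseline-referenced variants subtract a linear
baseline extrapolated from the first 10% of the forward sweep (no
published baseline rule exists; this is the conventional choice). A sweep
whose forward maximum does not exceed that baseline by ≥ 5% of the current
range — e.g. a pure capacitive box — raises, since there is no faradaic
peak to measure. The Nicholson relation is exposed as the affine
current-ratio (i_pc)₀/i_pa + 0.485 (i_sp)₀/i_pa + 0.086. The kinetic Ψ
values sometimes tabulated alongside (0.565, −0.368) are *not* reproduced:
the mapping from this ratio to those numbers (sign and normalisation) is
not derivable from the available description, so the package reports the
ratio and labels it as such.

Impedance model: Z(ω) = R1 + (R2 ∥ Z_CPE2) + (R3 ∥ Z_CPE3) + σ_w/√(jω)
with Z_CPE = 1/(Q(jω)ⁿ), parallel blocks combined by reciprocal addition,
Warburg in series after both blocks, and the principal branch of √(jω)
(equivalent to σ(1−j)/√(2ω): −45° phase at all frequencies). Fitting
minimises stacked (Re, Im) residuals weighted by 1/|Z| with bounds
enforcing passivity (R ≥ 0, Q, σ_w > 0, 0 ≤ n ≤ 1) via trust-region least
squares; the fit is deterministic given the initializer. Noiseless
synthetic spectra are recovered to < 0.1%, 1% multiplicative noise to < 5%
on the resistive/ideality parameters; degenerate (purely resistive) data
pin the unused elements at their bounds with a warning. Spectrum
summaries report per-label Z′/Z″ ranges, mean/max/min |Z| and mean phase;
for exactly two labels the percent difference is
100·(mean₂ − mean₁)/mean₁ with the first (insertion-order) label as
reference.

## Pipeline and reproducibility

The CLI runs generate → low-pass → spike detection → spectra → boolean →
walk, writing CSV/JSON artefacts plus a manifest (package version, seed,
config hash, completed stages) that is written even on failure. One
master seed drives everything; per-stage seeds derive from it by stable
hashing of the stage name, and per-channel generator seeds by
`SeedSequence.spawn`, so any stage or channel can be regenerated in
isolation. Floats are serialized at 6 significant digits, making output
directories byte-stable under a fixed seed.

## Problem sizes and numerical choices

Parameter-recovery tests use 20 channels × 86,400 s (the per-condition
session scale); hierarchy and pipeline tests use 3 channels × 43,200 s and
1–2 channels × 6,000 s respectively, which keeps the full suite under
~10 s while leaving every statistical margin (3 SEM, 5%) intact.
Monte-Carlo diffusion checks use 10⁴ walks × 64 steps (the estimator's
accuracy depends on walk count, not walk length). Known numerical edges:
the DFT argmax resolves to the zero-padded grid (~2 µHz), so τ is accurate
to ~1 s at 600-s periods; SG smoothing slightly rounds sharp (non-
sinusoidal) pulses, so tests of triangular pulses disable it; the circuit
fit is a local optimiser — recovery is guaranteed from initializers within
roughly a factor of a few of the truth, not from arbitrary starts.

## Known limitations

- Event detection assumes one dominant oscillation per trace; mixtures of
  well-separated periods will be summarised by the stronger component.
- The published per-channel raw statistics cannot be reproduced from
  printed summaries alone; all table-shaped outputs are validated by
  parameter recovery on synthetic data.
- The ANOVA non-significance of per-wavelength periods is validated at the
  within-group spread implied by the published F statistic, because the
  printed group SDs are inconsistent with a non-significant result at any
  plausible per-group n (see `tests/test_spectral.py`).
- No anomalous-diffusion fitting, no Butler–Volmer kinetics, no
  Kramers–Kronig testing, no photocycle chemistry.
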