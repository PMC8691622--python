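# Methods

## The spectral decomposition

The core object is a two-dimensional descriptive model of the
trial-averaged LFP power spectrum over stimulus spatial frequency (SF,
cycles/degree) and oscillatory frequency (f, Hz): an aperiodic baseline
`k/(f^a + b) + c` plus three Gaussian gamma components (LG, MG, HG) whose
peak frequency follows a Naka–Rushton sigmoid of SF and whose amplitude
follows a difference of Gaussians (DoG) of SF. Assumptions worth making
explicit:

* The baseline is SF-independent. Its four parameters (k, a, b, c), the
  spectral bandwidths σ_i, the sigmoid parameters (K_{0,i}, K_i, n_i), the
  shared half-saturation constant SF₀, and the DoG parameters are all
  constant across SF; only μ_i(SF) and W_i(SF) vary with the stimulus.
* The baseline form is a ratio with an additive offset; the alternative
  reading with `b` outside the denominator is not implemented — `b` inside
  keeps Baseline(f) monotonically decreasing for any a > 0, which is the
  defining constraint.
* DoG amplitudes are constrained non-negative and the evaluated weight is
  floored at zero: a negative spectral bump is unphysical. The raw
  (unfloored) value is available via `eval_weight(..., floor=False)` for
  diagnostics.
* Each component's peak-frequency path is confined to its band window (LG
  25–45, MG 45–65, HG 65–100 Hz). Internally the sigmoid is parameterized
  by its two endpoint frequencies μ(0) and μ(∞), each box-bounded inside
  the window; monotonicity of the sigmoid then confines the whole path, and
  it enforces μ_LG < μ_MG < μ_HG at every SF without ordering constraints.

### Fitting

Bounded trust-region least squares (`scipy.optimize.least_squares`, TRF,
`x_scale="jac"`) on the flattened SF × f grid, equally weighted. Default
fitted range 20–120 Hz. Multi-start with `restarts` seeded initial points
(default 20): restart 0 is fully data-driven (baseline from the low-f
margin, component amplitudes and centers from the baseline-subtracted band
maxima), the rest jitter amplitudes, centers and shape parameters within
bounds. The lowest-MSE solution wins. On noiseless model-generated grids
the fit recovers gof ≥ 0.999 with μ_i(SF) within 0.5 Hz; repeated-fit
studies in the test suite use 5 restarts purely to bound runtime — the
data-driven restart almost always wins.

Goodness of fit is variance explained, `1 − SS_res/SS_tot`, over the
flattened grid; it is undefined (raised) for constant data.

### Component counting

Per component, SNR = max over the *sampled* SFs of the fitted weight,
divided by the mean blank-condition power inside the component's band.
A component counts as present iff SNR > 3, strictly: a component at
exactly 3.0 is absent. Because the max is taken over the sampled SF grid
rather than a dense one, the measured SNR can only under-reach the value a
dense grid would give (the default presets are calibrated on a dense grid,
so their measured SNR is slightly below the nominal 6).

### Site selection

`site_snr` = SD of the per-trial response under stimulation / SD under
blank, with inclusion again strictly > 3. A zero blank SD is flagged
degenerate and the site excluded rather than reported as infinite.

## Spectral estimation

Multitaper PSD with Slepian tapers (`scipy.signal.windows.dpss`,
unit-energy), NW = 3, K = 5, over the 300–2000 ms post-onset window
(1.7 s → Rayleigh 0.59 Hz, half-bandwidth ≈ 1.76 Hz). Each windowed trial
is mean-subtracted before tapering to keep DC leakage out of the low
frequencies. One-sided density scaling: `sum(psd)·df` ≈ windowed variance.

Coherence pools cross- and auto-spectra jointly over tapers and trials —
there is no per-trial coherence — and is rejected in the degenerate
1-trial × 1-taper case where it is identically 1. Spike trains are
binarized at the LFP sampling rate for spike–field coherence; trials with
no spikes in the window are excluded with a recorded count. The shuffle
control permutes spike-trial identity within each stimulus condition
(≥ 2 trials per condition required) and averages the recomputed SFC over
shuffles.

Phase-locking profiles band-pass the LFP (zero-phase 3rd-order
Butterworth, ± 4 Hz around each center — matched to the multitaper
half-bandwidth scale), take the Hilbert (analytic-signal) phase, bin spike
phases into 16 equal bins over (−π, π], normalize counts by phase-bin
occupancy, and report `(max rate − mean rate)/mean rate`. For a rate
r₀(1 + m cos φ) this index estimates m (the finite-bin bias at 16 bins is
≈ 0.6%, far below the sampling noise).

## The synthetic world

The generator emulates the experimental design: 0.4 s pre-stimulus, 2 s
stimulus, 0.4 s post-stimulus trials at 500 Hz; 10 grating SFs log-spaced
0.03–2.5 cpd; blank trials are baseline-only traces for the full trial
duration (the cleanest testable reading of an undefined "blank
condition"; their number and duration are configurable).

LFP synthesis is frequency-domain spectral shaping: complex-Gaussian rfft
coefficients scaled so the expected one-sided PSD equals the model
spectrum, then inverse-transformed. This guarantees — by construction, not
calibration — that the mean multitaper PSD of many trials converges to the
generating model, which is exactly what the fitting stage assumes. It does
**not** reproduce burstiness, cross-frequency coupling, nonstationarity
within the stimulus epoch, or line noise; a green fit-recovery test
establishes estimator correctness under the model's own assumptions, not
robustness to real-data pathologies.

Default ground truth (`three_gamma_default`):

* Baseline k = 2·10⁴, a = 2, b = 0, c = 0.5 (power in μV²/Hz-scaled units).
* Peak-frequency sigmoids: LG 35 → 25 Hz (declining with SF), MG
  50 → 58 Hz, HG 72 → 80 Hz; n = 2, shared SF₀ = 0.3 cpd; σ = 4/5/6 Hz.
* DoG shapes solved numerically (once, up front) so the tuning metrics on
  the default SF sampling match the reported physiology — cutoff SF
  0.68 / 0.33 / 0.09 cpd and SF selectivity 0.77 / 0.54 / ≈ 0 for
  LG / MG / HG: σ₁ = 0.4716 / 0.2014 / 0.0764 cpd, A₂/A₁ =
  0.8522 / 0.7864 / 0, σ₂ = 0.15 / 0.10 / — cpd. Note the HG truth
  selectivity is exactly 0 *on the sampled range* (its amplitude peaks at
  SF = 0, below the lowest sampled SF).
* Component amplitudes scaled so each active component's SNR (dense-grid
  max weight / mean blank-band baseline power) is exactly 6 — comfortably
  above the counting threshold of 3, matching a clearly-present component.
* Spike locking targets m = 0.8 per component; spikes are thinned
  inhomogeneous Poisson, base rate 20 Hz, with phase taken from the same
  ± 4 Hz filter convention the measurement uses (centered on the
  component's μ at the stimulus SF when known).
* Laminar profiles: Gaussian in ReD with peaks 0.2 / 0.4 / 0.5 (LG
  superficial, HG mid input layer, MG between), width 0.12 ReD,
  multiplicative log-normal channel noise (SD 0.1 by default);
  24 channels at 0.1 mm.
* Edge/surface contrasts in log-power space (power is positive and
  approximately lognormal across trials): per-band standardized effect
  d = +1 for LG (higher at edge) and −1 for MG/HG (higher on surface),
  log-power SD 1; MUA control features d = 0.3 per time bin (rate SD
  5 Hz about 20 Hz). With one site these effects put the optimal gamma
  decoder near 81% correct and the MUA decoder near 60%, bracketing the
  reported contrast without being fitted to it.

## Laminar alignment

Anchors: Cha1 = channel with the lowest SF selectivity (shallowest on
ties) → ReD 0.5; Cha2 = uppermost channel with MUA SNR > 3 whose three
consecutive deeper channels also exceed 3, with the surface reference
0.050 mm above it → ReD 0; Cha3 = the symmetric deepest channel, the
white-matter reference 0.050 mm below it → ReD 1. ReD is piecewise linear
in physical depth on the two segments surface→Cha1 and Cha1→white matter
(only the three anchor values are prescribed; linear interpolation is the
least-structured completion). Channels outside [surface, white matter] are
clipped and flagged; sessions whose Cha1 falls outside [Cha2, Cha3] are
rejected with a diagnostic. Depth profiles default to stored/raw band
power at each band's best SF (blank-subtracted when available); peak
location ties resolve to the shallower channel.

The bootstrap resamples sessions with replacement (resample size = session
count, default 10,000 draws), computes mean peak ReD per band per draw,
and reports one-sided p = proportion of draws with mean(X) > mean(Y),
strictly — under exact ties across all draws this yields p = 0 in both
directions, which is noted in the API docs rather than patched with
jitter.

## Decoder

Implemented exactly in the published sign convention
`P(edge|X) = 1/(1 + exp(X·W + w0))` (the conventional logistic differs
only by W → −W, w0 → −w0; an equivalence test pins this down), boundary
rule p ≥ 0.5 → edge. Objective: mean cross-entropy + λ/(2m)·Σ|W_j|,
intercept unpenalized. The L1 term is handled exactly by the smooth convex
reformulation W = W⁺ − W⁻ with W± ≥ 0 under L-BFGS-B. Features are
z-scored on training statistics by default (power and rate features have
incommensurate scales; without standardization a shared λ is meaningless).
Splits are stratified 60/15/25; λ is selected by validation MSE between
predicted probability and label over 20 log-spaced values in [0.001, 40]
("cross-validation" is read as the single 15% validation split), then the
winner is refit on train+validation before test evaluation. Site-count
accuracy curves fix λ = 0.1, the setting used for the published curves.

## Numerical choices and degenerate inputs

* Fit bounds: a ∈ [0.3, 6], σ_i ∈ [1, 20] Hz, amplitudes ≤ 5× grid max,
  SF-profile widths ∈ [0.005, 2·max SF] cpd; `max_nfev` 400 per restart.
* Tuning metrics are computed on the fitted continuous curve (DoG when its
  gof > 0.5, else a shape-preserving PCHIP interpolant) over a 10⁴-point
  grid spanning the sampled SF range; curves that never fall to
  half-maximum are censored at the largest sampled SF and flagged, never
  extrapolated. Selectivity is clipped to [0, 1].
* Probabilities are clipped at exp(±30) in the decoder; the loss clips p
  at 10⁻¹²; degenerate contracts (constant data in gof, zero blank SD,
  all-equal laminar powers, all-empty spike trials) raise or flag rather
  than returning silently wrong numbers.
* Determinism: every stochastic routine takes a seed (or a Generator) and
  is byte-identical on repeat; the CLI writes the resolved config and its
  digest next to every output.

## Known limitations

* The synthetic LFP is stationary Gaussian within each epoch; see above
  for what that does not test.
* The laminar generator places anchors at fixed channel offsets; probe
  angle and cortical-thickness variability enter only through ReD noise.
* The fit treats all SF conditions with equal weight regardless of trial
  count (the weighting is unspecified; equal weighting is the simplest
  defensible choice and is what the tests calibrate).
* Only the descriptive decomposition is implemented — no Bayesian
  inference over parameters and no information-criterion selection of the
  component count (the count is fixed at 3 and pruned by SNR).
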