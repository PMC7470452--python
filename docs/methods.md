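# Methods

## Model and assumptions

The cochlea-plus-return-path between a stimulating electrode *j* and a
recording electrode *k* is treated as a lumped, linear, time-invariant
two-block ladder:

    Z(s) = Z₁(s) + R₂·Z_CPE2(s) / (R₂ + Z_CPE2(s)),     Z_CPEi(s) = 1/(Yᵢ sᵖⁱ)

with two variants for block 1: `PARALLEL_RCPE1` (R₁ ∥ CPE₁, the circuit
used for spectrum fitting) and `BARE_CPE1` (CPE₁ alone, the circuit whose
pulse response has the simplest closed form). Both variants are supported
everywhere; step responses use `R(1 − E_{p,1}(−tᵖ/(RY)))` for a parallel
block and `tᵖ/(Y Γ(p+1))` for a bare CPE, which are the exact inverse
Laplace transforms of `Z_block(s)/s`. The model is linear: electrode
polarization nonlinearity and amplitude-dependent impedance are outside its
scope, as is any volume-conduction geometry — the blocks are phenomenological
lumps (common return path vs intracochlear path).

Interfaces accept frequencies in Hz and convert to ω = 2πf internally; all
Laplace-domain math is in rad/s. `(jω)^p` uses the principal branch, so the
CPE phase is exactly −90·p degrees. Nyquist output is (Re Z, −Im Z).

## Transient responses

A cathodic-leading biphasic pulse is the step superposition
(−1, +2, −1)·i_amp at delays (0, T₀, 2T₀); arbitrary piecewise-constant
stimuli decompose the same way (left-closed/right-open segments, the value
at a breakpoint is the new level). Responses are evaluated on uniform
grids, by default 64 points per phase over [0, 3T₀], which is also the
default RMS-analysis window; when delays are grid-aligned the step kernel
is evaluated once and index-shifted, which also makes the p = 1 ramp
cancellation after the pulse exact in floating point. At the switch
instants the closed form is evaluated by its right limit; `v(0) = 0` and
`v(t<0) = 0` by causality.

The RMS relative error between two waveforms is RMS(difference) divided by
max |reference| over the analysis window. The normalisation is a package
choice (peak-to-peak was the logged alternative); with it, the
simulate → fit → re-simulate consistency loop at 1 % spectral noise yields
mean/max relative errors of ~0.2 %/~0.3–0.5 % (computed by
`scripts/acceptance.py`).

## Mittag–Leffler evaluation

`E_{α,β}(z)` is needed for α ∈ (0,1], β ∈ {1, α+1}, z ∈ [−10⁶, 0], target
1e−10 absolute. Three routes, chosen by per-call error estimates:

1. **Taylor series** with term-ratio stopping; accepted when the estimated
   cancellation error `2e−16 × max|term| + tail` is ≤ 1e−12.
2. **Algebraic asymptotic expansion** `−Σ_{l≥1} z^{−l}/Γ(β−αl)`, truncated
   where the smooth reflection-formula envelope
   `|z|^{−l} Γ(1+αl−β)/π` reaches its minimum; the omitted envelope value is
   the error estimate. Coefficients within 1e−8 of a Γ pole are treated as
   zero (the sine factor makes both the true value and its floating-point
   evaluation unreliable there) with their envelope bound charged to the
   estimate.
3. **Spectral inversion integral** (adaptive quadrature of
   `(1/π)∫₀^∞ e^{−u} u^{α−β} [u^α sin π(1−β) + x sin π(1−β+α)] /
   (u^{2α} + 2u^α x cos πα + x²) du`, valid for 0 < α < 1, z = −x < 0,
   β ≤ 1) for the intermediate band where neither estimate clears 1e−12;
   β > 1 is first reduced through `E_{α,β}(z) = (E_{α,β−α}(z) − 1/Γ(β−α))/z`.

α = 1 reduces to `e^z`, `(e^z−1)/z`, or Kummer's function. Validation: the
overflow-free identity `E_{1/2,1}(−x) = e^{x²}erfc(x) = erfcx(x)` against
`scipy.special.erfcx` across twelve decades, the β-shift identity across
route boundaries, and complete monotonicity (positivity/decrease) of
`E_{α,1}(−x)`.

## Numerical inverse Laplace transform

The de Hoog–Knight–Stokes quotient-difference accelerated Fourier method is
the default (vectorised over the time grid; per-point scaled period T = 2t,
tolerance 1e−14, 2M+1 = 81 evaluations), with Abate–Valkó fixed Talbot
(M = 28, near-optimal for double precision) as the alternative. Both reach
~1e−8–1e−12 relative error on smooth transforms.

`v(t)` has vertical-tangent `tᵖ` cusps at 0, T₀, 2T₀, where a direct
inversion of `I(s)·Z(s)` degrades algebraically (measured ~1e−4–1e−2 of
peak within 0.1·T₀ of a cusp). The oracle `pulse_response_numeric`
therefore factors the exact delay operators of I(s) out of the Bromwich
integral (time-shift theorem) and inverts the step kernel `Z(s)/s`
numerically — mathematically the same inversion, but accurate (~2e−10 of
peak) uniformly, including at the cusps.

## Spectrum fitting

`fit_spectrum` minimises the stacked real/imaginary residual with modulus
weighting `wᵢ = 1/|Z_meas,i|²` by default (the whitening weight for
proportional EIS noise; unit weighting available) using bounded
trust-region least squares. R's and Y's are optimised in log₁₀ space
(bounds 1e−3–1e9 Ω, 1e−12–1e3 S·sᵖ; p ∈ [0,1]), which linearises the
positivity constraints and conditions the many-decade scales. Standard
errors come from the Jacobian at the optimum, mapped back from log space.

Three deterministic starts are tried and the lowest cost kept: a heuristic
(low-frequency |Z| minus the near-zero-phase plateau splits the blocks,
corner frequencies from geometric band means, p = 0.8), its block-swapped
copy, and a generic even split with corners at the third-points of the log
band. The swapped/generic starts exist because the two parallel blocks are
structurally interchangeable and the heuristic can mis-assign the arcs on
strongly asymmetric or merged-arc spectra. Fitted parallel-variant blocks
are canonically ordered so block 1 carries the lower corner frequency,
matching its physical role as the low-frequency common path. An optional
seeded random multistart exists but is off by default: on noisy spectra it
occasionally trades parameter accuracy for marginally lower cost. Fits
require ≥ 8 points spanning ≥ 2 decades; non-convergence is flagged, never
silent. No automatic choice between circuit variants is made — both can be
fitted and their residual norms compared.

## Synthetic study conditions

The generator emulates a 16-contact lateral-wall array with working
odd-numbered electrodes 3–15, sweeps of 10 Hz–100 kHz at 10
points/decade (41 points), and proportional complex Gaussian EIS noise
`Z(1 + σ(ε₁ + iε₂))` with σ = 0.01 by default. Ground-truth parameters
(defaults of `CorpusSpec`):

| parameter | default | rationale |
|---|---|---|
| R₁ | 500 Ω | low-frequency \|Z\| in the several-hundred-ohm range |
| Y₁, p₁ | 1.79e−5 S·s^p, 0.9 | block-1 corner ≈ 30 Hz: low-frequency polarization visible at 10–100 Hz |
| R₂ base | 250 Ω | adjacent-pair hill peak ≈ 195 Ω |
| Y₂ base, p₂ | 4.5e−8 S·s^p, 0.9 | adjacent block-2 corner ≈ 50 kHz |
| λ_R, λ_Y | 8, 4 index units | hill/valley decay; λ_Y < λ_R lowers distant corners, producing the high-frequency fan-out |
| σ | 0.01 | percent-level EIS instrument noise |

These were fixed once, from two design inputs: qualitative shape targets
(two-arc Nyquist, near-zero-phase plateau between 1 and 10 kHz — the
defaults give min |phase| ≈ 7° at 1.6 kHz — low-frequency |Z| dispersion
0.21 across recording electrodes vs 0.90 at 100 kHz) and a Cramér–Rao
identifiability scan over the realistic corner/exponent/resistance space so
that the corpus is as informative as the band allows. Distances are
electrode-index differences; the true distance scaling of the decay
constants is a free phenomenological choice, not an anatomical claim.

What the generator does **not** emulate: specimen-to-specimen variability,
day-to-day drift, instrument bias errors, electrode contact impedance, and
any nonlinearity. Passing the end-to-end tests therefore shows the
pipeline is consistent and well-conditioned under the stated noise model —
not that the circuit family fits any particular cochlea.

Pseudo-measured waveforms add white noise scaled to the waveform peak and
are tagged `measured`; Butterworth conditioning is a zero-phase (forward–
backward) low-pass, default order 4 (only the cutoff, 6.25 MHz, is given
by the recording protocol it mirrors; the order is an assumption), and
requires the sampling rate to exceed twice the cutoff.

## Precision limits worth knowing

At σ = 1 % proportional noise on the default 41-point sweep, the Fisher
information of the six-parameter fit bounds the per-fit precision of Y₁ at
about 2.8 % (the Y₁–p₁ correlation is the culprit; R₁ ≈ 0.9 %, θ₁ ≈ 0.5 %).
The across-pair coefficient of variation of fitted Y₁ consequently sits at
2.4–3.2 % — at the bound, not above it. Any tighter reproducibility claim
for Y₁ under these conditions is unattainable regardless of optimizer; the
test suite documents this as an expected failure of one block-1 constancy
assertion, with R₁ and θ₁ passing.

## Spread metrics

`spread_profile` normalises peak |v| per recording electrode by the maximum
across electrodes (the normalisation reference is a package choice). The
half-max spread width counts recording electrodes with normalized amplitude
≥ 0.5 — a simple monotone scalar for duration sweeps. The asymmetry index
is |phase-2 peak| / |phase-1 peak| of the transient. "Stimulation
frequency" is ambiguous between sine amplitude and pulse spectral content,
so both a sine mode (`sine_spread_profile`, steady-state |Z| ratios) and a
pulse mode (`spread_profile`) are provided.

## Problem sizes

Default test and acceptance runs use: 20 random circuits × 512-point grids
for oracle equivalence, 50 Monte-Carlo replicates for parameter recovery,
the full 42-pair corpus for profile reproduction, four phase durations
(100/10/1/0.5 µs) for the spread sweep, and 1000 randomized stimuli for the
charge-balance/causality invariants. The whole acceptance script completes
in ~10 s on one CPU.

## Known limitations

* The circuit family is lumped and linear; it cannot represent
  amplitude-dependent or electrochemically nonlinear behaviour.
* Block labeling for the parallel variant is by corner frequency; two
  blocks with nearly equal corners are not separately identifiable.
* The Mittag–Leffler implementation is specialised to real z ≤ 0 and
  α ∈ (0,1] (all this model needs); it is not a general complex-plane
  evaluator.
* De Hoog inversion of transforms with delay factors loses accuracy near
  waveform cusps; use the step-kernel factorisation (as
  `pulse_response_numeric` does) for such signals.
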