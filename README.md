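# cochlear-eis

Electrochemical impedance spectroscopy (EIS) of the implanted cochlea, and
what it predicts about electrical stimulus spread.

A cochlear-implant electrode array injects charge-balanced biphasic current
pulses into an electrolyte-filled duct, so the stimulus spreads along the
cochlea instead of staying focused on one neural population. The
*transimpedance* Z(s) between a stimulating electrode *j* and a recording
electrode *k* — complex, frequency-dependent, measurable with a standard
impedance analyzer from 10 Hz to 100 kHz — captures that spread completely
for a linear medium. This package is for implant researchers and
neural-interface engineers who want to go from measured (or synthesised)
transimpedance spectra to predicted spread-induced voltage waveforms under
arbitrary pulse shapes, without re-measuring for every stimulus.

## Model

Each electrode pair is modelled as two blocks in series, each a resistor in
parallel with a constant phase element (CPE),

    Z_CPE(ω) = 1 / (Y (jω)^p),        θ = −90·p°,

where `Y` (S·s^p) is the admittance magnitude at 1 rad/s and `p ∈ [0, 1]`.
Block 1 (R₁, Y₁, p₁) is the common return path through the temporal bone —
identical for every pair, hence spread-independent. Block 2 (R₂, Y₂, p₂) is
the intracochlear path: R₂ forms a hill peaking at the stimulating
electrode, Y₂ a valley dipping there.

For a cathodic-leading biphasic pulse of amplitude `i_amp` and phase
duration `T₀`, with transform `I(s) = −(i_amp/s)(1 − e^{−sT₀})²`, the
spread-induced voltage follows in closed form from `V(s) = I(s)·Z(s)`:

    v(t) = −i_amp [ f(t) − 2 f(t−T₀) u(t−T₀) + f(t−2T₀) u(t−2T₀) ],
    f(t) = t^{p₁} / (Y₁ Γ(p₁+1))  +  (t^{p₂}/Y₂) E_{p₂, p₂+1}(−t^{p₂} / (Y₂R₂)),

where `E_{α,β}(z) = Σ z^l / Γ(αl+β)` is the Mittag–Leffler function (the
`p = 1` limit recovers the classical capacitor ramp and `R(1 − e^{−t/RC})`).
A numerical inverse-Laplace oracle (de Hoog, fixed Talbot) cross-checks the
closed form, and a fitting module replaces the proprietary
equivalent-circuit software step with bounded complex least squares.

Because no specimen recordings are deposited, a synthetic-data module
generates the full study conditions: a lateral-wall array with working
odd-numbered electrodes 3–15, 10 Hz–100 kHz sweeps at 10 points/decade,
hill/valley block-2 profiles, proportional complex EIS noise, and
pseudo-measured waveforms with Butterworth conditioning.

## Worked example

```sh
cochlear-eis synth corpus  --seed 1 --out params.json
cochlear-eis synth spectra --seed 1 --noise 0.01 --out spectra.csv
cochlear-eis fit --spectra spectra.csv --out fits.json --profiles profiles.csv
cochlear-eis simulate --params fits.json --stim 3 --rec 5 --out wf.csv
cochlear-eis spread   --params fits.json --stim 15 --out sweep.csv
```

prints

```
wrote 42 pair models to params.json
wrote 42 spectra to spectra.csv
fitted 42 spectra (42 converged) -> fits.json
peak |v| = 155.898 mV -> wf.csv
half-max spread width by duration (us):
  100 us -> 4 electrodes
  10 us -> 3 electrodes
  1 us -> 2 electrodes
  0.5 us -> 2 electrodes
```

Reading the output: the fit recovered all 42 electrode-pair circuits from
1 %-noise spectra (e.g. R₁ = 497.1 Ω vs the ground-truth 500 Ω in
`profiles.csv`). The 800 µA, 32 µs/phase pulse between electrodes 3 → 5
peaks at 155.9 mV. The duration sweep shows the central claim: shortening
the phase from 100 µs to 0.5 µs halves the number of electrodes that see at
least half of the maximum spread voltage, because short pulses concentrate
their spectrum where distant-electrode transimpedances roll off.

The same operations are available as a library:

```python
from cochlear_eis import (CorpusSpec, generate_parameter_matrix,
                          BiphasicPulse, pulse_response)
models = generate_parameter_matrix(spec=CorpusSpec(seed=1))
wf = pulse_response(models[min(models)], BiphasicPulse(800e-6, 32e-6))
```

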