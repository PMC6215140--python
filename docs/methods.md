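# Methods

This note documents the models behind `muxrec`, the defaults and why
they were chosen, the numerical choices, and what the synthetic-data
tests do and do not demonstrate.

## Electrode–tissue interface

The interface is a Randles network: access resistance `Rs` in series
with (`Rp` ∥ CPE), optionally shunted by the instrumentation input
capacitance `Cin`. The CPE impedance is `1/(Y0 (jω)^α)`; `α = 1`
collapses it to an ideal capacitor `Y0`. The one-sided thermal voltage
PSD at the terminal is `4 k T Re[Z(f)]`. By default `Cin` is *not*
included in impedance or noise predictions so they remain properties
of the electrode alone; passing `include_cin=True` adds the shunt.

Two shipped parameter sets, `MICROWIRE_LIKE` (Rs = 12 kΩ, Rp = 50 MΩ,
Y0 = 2 nS·s^α, α = 0.85) and `SILICON_ARRAY_LIKE` (8 kΩ, 20 MΩ,
5 nS·s^α, 0.90), are **assumptions**, not fits to any particular
measurement: they were chosen once so that the high-frequency noise
density stays below the ~20 nV/√Hz typical of penetrating
microelectrodes, and give WIS-sampled thermal noise of ~9 µV rms at
M = 20. A reported high-frequency phase roll-off sometimes seen in
vivo (attributable to an extra parallel capacitance of unclear
physical origin) is deliberately not modeled. The default temperature
is 300 K everywhere.

**EIS fitting** minimizes a combined residual of `log10|Z|` and phase
in degrees/100, which puts the two channels on comparable scales
(standard electrochemical-impedance practice). `Rs`, `Rp`, `Y0` vary
on a log10 scale with positivity enforced by bounds; `α ∈ (0, 1]`. A
spectrum with no phase structure cannot constrain the CPE branch: the
fit then flags `Y0`/`α` as unidentifiable and only `Rs + Rp` is
meaningful. Spectra spanning under two decades trigger a degeneracy
warning. lmfit's `least_squares` backend does the optimization.

## NEB theory and aliasing

`NEB = ∫₀^∞ |H(f)|² df` with H normalized to unit DC gain. Voltage
sampling is modeled by the single pole at the settling bandwidth
`f_bw = −ln(ε)/(2π Ts)` — exactly the response from which the closed
form `NEB_vs = π f_bw/2` follows — and WIS by the sinc `|sinc(f Ts)|`
with `NEB_wis = 1/(2 Ts)`. The "traditional" single-channel reference
for the NEB ratios is a single pole at the AP bandwidth `fch/3` (the
per-channel rate is taken as 3× the AP bandwidth).

Two timing conventions are exposed and labeled: *idealized* theory
uses `Ts = 1/fs` (no conversion overhead), *simulation* timing uses
`Ts = 1/fs − Tconv`. All per-sample noise variances are
`∫ S(f)|H(f)|² df`: everything aliases into the samples, the sampling
response only weights it.

Numerical integration uses a trapezoid on a grid with ≥ 32 points per
sinc period; the truncated tail is estimated by flat continuation of
the PSD endpoint under the mean-square envelope of the response
(`S/(2(πfTs)²)` for WIS, `S(f_bw/f)²` for the pole) and added to the
result. If that tail estimate exceeds 0.5% of the total the function
refuses and names the support it needs, rather than silently
under-integrating.

## Synthetic scenes

A scene is ground truth for testing the chain: per-electrode DC
offsets uniform in ±50 mV (the distribution is an assumption; only the
1–50 mV scale is established, and offsets are treated as already
differential against the reference), homogeneous-Poisson spike trains
(default 20 Hz) of biphasic negative-leading cosine-windowed templates
(default 300 µV peak, 1 ms — configurable; real waveform shapes vary),
Gaussian "biological" background band-limited to 0.3–7.5 kHz (default
8 µV rms, matching the 5–10 µV typically quoted for the AP band), and
an electrode thermal realization spectrally shaped to `4kT Re[Z]` by
filtering white Gaussian noise with the square root of the target PSD
in the frequency domain. Every component draws from an independent
seeded substream, so any subset of components reproduces exactly.

What the generator does **not** emulate: the in-vivo low-frequency
excess noise above the thermal prediction, electrode drift and motion
artifacts, biophysical waveform diversity, correlated network
activity. Tests that pass on these scenes therefore validate the
*acquisition and analysis chain* under known truth, not performance on
real tissue: the measured in-vivo SNRs of such systems (≈ 2) reflect
biology, not the simulator's regime.

The multiplexed input visits electrodes 0..M−1 round-robin at fs; each
slot follows that electrode's own trajectory, so the waveform is a
staircase dominated by offset differences — the reason offset
cancellation must precede the 60 dB gain.

## Front-end behavioral model

Per slot: (1) the LNA output settles toward
`lna_gain·(v_electrode − coarse_correction)` as a single pole at
7.5 MHz during Tconv, with the residual carried over from the previous
slot's settled value; (2) the integrator is reset and the slot's
remaining `Ts` window is averaged (sub-slot numerical averaging on the
rendered grid, default 10× oversampling of fs — at 600 kHz this makes
Tconv exactly one grid sample of 166.7 ns); (3) the fine correction is
subtracted at the GM input and the result scaled by
`wis_gain = GM·Ts/CIN_adc`; (4) a mid-tread 9-bit quantizer over
±0.9 V clamps and flags out-of-range values (v = 0 → code 256, +FS →
511, −FS → 0). Unless GM is pinned explicitly, it is derived as
`wis_gain_design·CIN_adc/Ts` (≈ 40 µS at Ts = 1.5 µs) so the 60 dB
passband contract holds for any timing.

Noise is injected at the sample level: one Gaussian per acquired
sample with variance `density²·NEB_wis = density²/(2Ts)` for the LNA
(8.7 nV/√Hz default) and `4kT·R_on/(2Ts)` for the 160 Ω multiplexer
switch. This is exact for white densities by the WIS NEB and avoids
synthesizing multi-MHz electronics noise. Within-slot signal content
is passed unfiltered by the LNA pole (the rendered Nyquist is far
below 7.5 MHz); the pole only governs slot-boundary settling, which is
where it matters (channel isolation: a residual of `exp(−2π·7.5 MHz·
166 ns) ≈ 4×10⁻⁴`, further diluted ~70× by integration averaging).
Charge injection, clock feedthrough, transistor nonlinearity and
common-mode effects are out of scope; the ADC is ideal by default with
an optional static-nonlinearity hook exercised by the linearity tests.

The coarse DAC uses an offset-binary map `(code − 7.5)·LSB` spanning
exactly ±65 mV (codes 7/8 bracket zero, LSB ≈ 8.67 mV): a 16-code DAC
cannot simultaneously have a 10 mV LSB, span ±65 mV and bracket zero,
and the span is what the saturation behavior depends on. The physical
weak-inversion map — code-steered current imbalance on 50 µA branches
through `((CF+CS+CP)/CS)·n·UT·ln(ID1b/ID1a)` (≈ 6.8 mV per 4 µA LSB
step) — is available as `mode="physical"` with a scale option. The
fine DAC is the analogous `(code − 15.5)·LSB` over ±57 mV at the GM
input (0.368 mV electrode-referred steps at gain 10); the
weak-inversion width-ratio formula `n·UT·ln(W1a/W1b)` is exposed
separately. An exact zero correction (for ideal-calibration baselines)
uses the half-LSB midpoint codes 7.5/15.5.

## Binary-search calibration

The codes are found from averaged ADC data only (default 64 samples
per trial, ≈ 2.1 ms at 30 kHz/channel — comfortably inside the 1 s
recalibration period), MSB-first over the 4 coarse bits and then the 5
fine bits: exactly 9 trial settings per electrode per epoch versus 512
for an exhaustive scan.

Two subtleties make the search land on the *nearest* code per stage
rather than the floor: (a) during coarse trials the ADC is hard-
clamped (a coarse LSB is ~2500 ADC codes), so only sign information
exists and a digital threshold cannot implement the half-LSB rounding
offset; instead the fine DAC is parked near −coarse_LSB/2 during the
coarse stage, with a small digital threshold correction absorbing the
fine DAC's own quantization of that bias point. (b) the fine stage
shifts its digital mid-code threshold by half a fine step. Ties at
exact half-LSB points resolve by ADC rounding. The final residual is
≤ half a fine step (≈ 0.18 mV electrode-referred) for any offset
within ±65 mV; offsets outside the correctable range rail the codes
and set a `saturated` flag. A response that *rises* with increasing
correction (mis-wired polarity) is detected from the unclamped trial
observations and raised as an error.

Because the coarse/fine ranges are redundant (the fine span exceeds
half a coarse LSB), a joint scan of all 512 pairs can occasionally
beat the hierarchical optimum by a fraction of a fine step by pairing
a non-nearest coarse code with a luckier fine phase; no nine-trial
procedure can observe this. The search is therefore exactly
equivalent to the exhaustive search applied stage-wise, and within one
fine step of the joint-scan optimum — both properties are tested.

Recalibration runs at t = 0 and every period (default 1 s), codes held
in between; under offset drift the residual is bounded by one fine
step plus the intra-epoch drift.

## Analysis metrics

Demultiplexing de-interleaves by the slot→electrode map and refers
codes to the electrode via `(code − mid)·LSB/passband_gain`; optional
integer-factor downsampling drops samples. The AP band-pass is a
zero-phase 4th-order Butterworth (0.8–4 kHz default) applied
forward–backward. Detection uses negative-going threshold crossings
(extracellular APs lead negative; the threshold's sign selects
polarity) with a 1 ms refractory lockout and snippets cut 0.4 ms
before to 1.0 ms after the crossing; "hoop" time–amplitude windows
gate acceptance. `SNR = (max W̄ − min W̄)/SD_ε` with `SD_ε` the standard
deviation over all entries of the snippet-minus-mean matrix; it is
gain-invariant and flagged infinite when `SD_ε = 0`. Noise floors
excise the event windows before taking the rms. Welch spectra use
Hann windows, 50% overlap, 4096-point segments. The NEF uses the
standard `V_rms·sqrt(2I/(π·UT·4kT·BW))` with UT = 25.85 mV, T = 300 K
— constants that conventionally vary between groups, so NEF values are
treated as a consistency range rather than an exact target. THD sums
Hann-windowed FFT power in ±2 bins around each harmonic. DNL/INL use
the code-density histogram of a slightly overdriven sine normalized by
the arcsine density, with amplitude/offset fitted to the cumulative
histogram, end bins excluded (they absorb clipping) and INL under the
endpoint-fit convention; never-exercised codes are reported missing.

## Problem sizes in the shipped tests

The test suite and acceptance checks run at sizes chosen to make the
statistical tolerances comfortable: Monte-Carlo WIS variance uses
≥ 20 000 windowed samples (≈ 1% standard error on the variance against
a 5% tolerance); spectral-shaping checks use 1 s at 2.4 MHz; the
grounded-input noise budget uses 0.1 s at M = 20 (60 000 codes); the
noisy-calibration study uses 100 seeded trials; histogram linearity
uses 512 000 equidistributed-phase samples. Deterministic closed-form
checks are instant.

## Known limitations

Single-ended-equivalent signals (no CMRR); ideal ADC timing (the
overlap of conversion with the next slot's Tconv does not affect
values and is not modeled explicitly); no power model beyond the
NEB-proportionality argument; no transistor-level effects; electrode
presets are plausible assumptions rather than fitted devices; the
spike-sorting stops at time–amplitude windows (no clustering).
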