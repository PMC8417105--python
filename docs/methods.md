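# Methods

`nc3sim` emulates the digital behaviour of an autonomous head-mounted
bidirectional neural interface: a device that records multichannel
extracellular/EMG signals, detects physiological events on-board, and
delivers constant-current stimulation contingent on those events, with
everything logged to a removable store. The emulator reproduces the
*control semantics* of such a device — what gets detected, when a pulse
is or is not delivered, what lands in the record — not its analog
electronics.

## Timebase

All timestamps are integer ticks of a 10 µs master clock. This tick is
the greatest common divisor of every module clock: ADC sample periods
(200/100/50 µs for 5/10/20 kSps), the network step (100 µs), and the
minimum stimulus phase width (10 µs). Integer ticks make every event
time exact, every run bit-reproducible, and every test assertable to
equality. The real device does not publish its internal timestamp
resolution; 10 µs is this package's choice.

## Front-end model

Only the code-domain behaviour of the recording chain is observable to
the control logic, so the model is deliberately minimal:

- a first-order 0.07 Hz high-pass on each physiological input;
- the amplifier bandpass, implemented as a first-order high-pass section
  cascaded with a second-order Butterworth low-pass (the hardware's
  filter topology is unpublished; only the corner frequencies are
  treated as contract);
- quantization: additive i.i.d. Gaussian noise at 2.4 µV RMS, clipping
  at the ±5 mV input range, round-to-nearest to signed 16-bit codes
  (LSB ≈ 0.1526 µV). The 192× hardware gain is folded into this mapping.
- fast settle: codes forced to 0 for a configurable 200–3,200 µs window
  after each stimulus, with the blanking intervals reported so detection
  ignores them;
- an 8-slot IIR filter bank (single channels or channel differences,
  optional rectification, optional hold-last-value artifact
  suppression).

## Event generators and spike discrimination

Eight generators emit timestamped events either on schedules (fixed
period; uniform or exponential random gaps, rounded to ticks and floored
at one tick) or as window discriminators. Discriminator semantics are
pinned as follows, because classic hardware leaves them implicit: a
crossing is a sign change of `sample − threshold` between consecutive
samples (no interpolation); each time-amplitude window tests the single
sample at exactly `crossing + delay` against closed amplitude bounds;
crossings within the dead time (default 1 ms) of a previous accepted
event, or inside a blanking interval, are ignored. The hardware always
uses one or two windows; this implementation additionally accepts zero
windows (plain threshold detection), which is useful for
minimum-latency loops and costs nothing. Trigger gating supports count
rules over the half-open lookback `(t − L, t]` and inside/outside level
windows.

## Stimulus scheduling

All six output pins share one current source, which forces the central
scheduling invariant: at most one anodal/cathodal pin pair carries
current at any tick. Pulses that would overlap are serialized; switching
pin pairs costs 0.4 ms, so two 0.4 ms waveforms fired together land
0.8 ms apart leading edge to leading edge. IPI is onset-to-onset; IPI = 0
is burst mode (back-to-back pulses, same pins, no gap — 20 × 0.1 ms
pulses in 2 ms). Three protection mechanisms drop (never delay)
triggers, logging each drop with a reason:

- **global refractory** (configurable, 10 ms in the multi-loop spinal
  paradigm): a train whose onset falls within the half-open window after
  a previous train's onset is dropped, across all channels. Trains of
  the *same* trigger are exempt from each other — they interleave —
  since the refractory exists to stop stimulus-evoked activity from
  re-triggering stimulation, not to break multi-waveform conditions.
- **sliding 1 s rate cap**: 500 pulses/s for normal (<1 mA) amplitudes;
  full-amplitude (≥1 mA, ≥0.4 ms) trains are supply-limited to 350/s at
  ±60 V compliance or 700/s at ±50 V. Pulses within one burst are exempt
  while the burst runs but count in the window afterwards.
- trigger gate rules (above).

Dropping rather than delaying preserves closed-loop latency semantics: a
stimulus delivered late is a different experiment.

The monitor channel renders V = I·R into the chosen load, clipped at the
compliance voltage, flagging compliance-limited pulses.

## Fixed-point network engine

The on-board integrate-and-fire network is emulated bit-faithfully: all
potentials, weights, bias strength and threshold are signed 16-bit µV
values; the two PSP decay constants and bias chance are Q16 fractions.
Decay keeps the most significant 16 bits of the 32-bit product,
implemented as `floor(p·d / 2^16)` with floor toward −∞ (arithmetic
shift). Truncation toward zero is the plausible alternative reading;
floor is pinned here and cross-checked state-for-state against an
unbounded-integer reference over 10,000-step runs. Weight delivery
saturates at the int16 bounds (wraparound would create spurious spikes).
Bias spikes add the bias strength to both potentials, treated as a
normal incoming weight. The bias PRNG is one xorshift32 stream per unit
(the hardware's generator is unpublished); the top 16 bits of each draw
are compared against the bias chance. External events enter as sources
−1…−8 on the next 0.1 ms step boundary, one step of effective latency.
A unit fires when `slow − fast` strictly exceeds θ, resets both
potentials, and its spike re-emerges after the conduction delay (≤35
steps). Because the decay floors each step, sub-threshold superposition
holds only to within one LSB per step — the property suite bounds this
rather than asserting exact linearity.

## Synthetic scenarios

The generator produces everything the emulator can be tested against
without hardware:

- Poisson spike trains with absolute refractory, rendered as a
  parametric biphasic 0.6 ms template (−0.3 mV peak by default) scaled
  per channel, plus Gaussian noise. Real spike shapes vary by electrode
  and unit; the template is user-overridable and no claim is made that
  detection performance on it transfers to any particular preparation.
- Stimulus artifacts in two regimes, matching what a clipped AC-coupled
  amplifier does: sub-range artifacts are brief biphasic transients
  confined to <2 ms; over-range artifacts saturate at ±5 mV and recover
  exponentially with τ = 1/(2π·f_low), so recovery time scales with the
  inverse of the high-pass setting (≈73 ms to reach 1% at a 10 Hz low
  cut). The coupling gain (µV per µA, per channel) is an
  order-of-magnitude choice exposed in the scenario config; the exponent
  form is this package's model — the hardware literature states only the
  1/f_low proportionality.
- Stimulus-evoked spikes at configurable probability, latency (the fast
  excitatory response band is 1–10 ms) and uniform jitter, respecting
  unit refractoriness and flagged in the ground truth.
- A three-muscle EMG scenario for the multi-loop spinal paradigm:
  per-channel activity bursts (1 Hz, 0.3 s) gating 60 Hz motor-unit
  potential trains (triphasic ~6 ms template, 0.8 mV peak) at noise
  RMS = peak/10 — the stated detection condition for the loop tests.

Ground truth is exhaustive (every non-noise deviation is attributable to
a listed event) and generation is bit-identical under a fixed seed. What
passing tests show is that the *control logic* behaves correctly under
these statistics; they say nothing about detection performance on real
tissue, electrode drift, correlated noise, or non-stationary rates,
none of which the generator models.

## Closed-loop runner and session format

The runner processes one ADC sample per iteration on a common sample
grid (all enabled channels at one rate): discriminator channels are
filtered sample-by-sample with a biquad stepper that matches the
vectorized scipy filter state-for-state, quantized with pre-drawn noise,
and fed to the streaming discriminators; accepted triggers are gated and
scheduled immediately; scheduled pulses write artifacts and evoked
spikes into strictly future samples and open fast-settle windows. This
gives exact agreement between what the loop saw and what the session
records, and a closed-loop latency of one waveform delay plus the window
confirmation time (zero for threshold-only detection, i.e. within one
sample period of the crossing).

Sessions are an open chunked container (magic, version, CRC32-protected
chunks: JSON header with the config snapshot, int16 analog runs with
start ticks, JSON record lists) holding the four timestamp classes —
digital events, condition transitions, stimulus events, network events —
interleaved with the analog data in time order. The real device's
on-card layout is unpublished; the fidelity target is information
content, and the format is deterministic to the byte under a fixed seed,
which the suite asserts.

## Problem sizes and numerical choices

Tests and the acceptance script run seconds-long scenarios (0.5–6 s at
5–20 kSps, 1–3 channels, ≤20-unit networks for state-for-state checks,
10,000-step engine runs, 10⁵ random fixed-point pairs), sizes chosen so
the whole suite completes in well under a minute on one core while still
exercising every rule at its boundaries. Statistical assertions use
3σ bounds on their exact sampling distributions; exact-arithmetic
assertions (tick arithmetic, fixed-point engine, storage budget, session
round-trips) use equality. Seeds are fixed in tests; every stochastic
component draws from an independent stream derived from
`(seed, component)` so modules are reproducible in isolation.

## Known limitations

- No electrode/tissue electrochemistry, charge-density accounting, or
  amplifier fidelity beyond corner frequencies; no power, thermal, or
  communication-link modelling.
- Window discriminators test single samples, not spans; sub-sample
  interpolation is not performed. Both are flagged choices.
- The closed-loop runner requires a single common sample rate;
  mixed-rate recording is supported by the offline paths only.
- The artifact model is additive and channel-independent; real artifacts
  couple through shared references and can be non-linear near
  saturation.
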