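# nc3sim

A software emulator of an autonomous, head-mounted bidirectional
brain-computer interface for **closed-loop activity-dependent
stimulation** — the class of device that records multichannel
extracellular or EMG signals, detects spikes or muscle activity
on-board, and delivers constant-current stimulation contingent on what
it detects, running unattended for hours.

It is written for neural-engineering researchers who want to prototype,
debug or teach closed-loop paradigms (spike-triggered stimulation,
EMG-triggered spinal stimulation, network-in-the-loop bridging) at a
desk, with bit-reproducible runs and exhaustive ground truth, before or
instead of committing animal time to them.

## What is modelled

- **Front end** — per-channel 0.07 Hz high-pass, adjustable bandpass
  (0.1–2,000 Hz low cut, 100–20,000 Hz high cut), 16-bit ±5 mV
  quantization with 2.4 µV RMS noise, post-stimulus fast-settle
  blanking, 3-axis accelerometer, 8-slot IIR filter bank.
- **Event generators** — eight, each a fixed/uniform/exponential
  interval timer or a *dual time-amplitude window discriminator*: a
  threshold crossing counts as a spike only if the samples at one or two
  configured delays fall inside their amplitude windows. Triggers can be
  gated by event counts in a lookback window or by analog levels.
- **Stimulator** — six pairable outputs sharing one current source
  (5 µA–10 mA, 0.01–10 ms per phase, biphasic, asymmetric allowed).
  Overlapping trains are interleaved (0.4 ms channel switch ⇒ 0.8 ms
  leading-edge separation), IPI = 0 gives 10 kHz bursts, and a sliding
  rate cap (500/s normal, 350/s at ±60 V full amplitude, 700/s at ±50 V)
  plus a global refractory period (10 ms in the multi-loop paradigm)
  drop excess triggers with logged reasons.
- **Network engine** — a fixed-point integrate-and-fire spiking network
  (≤256 units, ≤2,000 weights, 10,000 updates/s). Each unit keeps fast
  and slow leaky integrators decayed by Q16 constants (keeping the top
  16 bits of each product); a unit fires when slow − fast exceeds θ,
  resets, and its spike re-emerges after a conduction delay (≤3.5 ms).
  Event generators feed sources −1…−8; spikes of the first 8 units
  trigger generators back. Emulation is bit-faithful and checked
  state-for-state against a big-integer reference.
- **Sessions** — analog int16 runs interleaved with timestamped records
  (digital events, condition transitions, stimulus events, network
  events) in a CRC-protected chunked file, byte-deterministic under a
  fixed seed, with summary reports (counts, envelopes, event-triggered
  sweeps).
- **Synthetic scenarios** — Poisson spike trains with templates, EMG
  burst scenarios, stimulus artifacts (brief biphasic when inside the
  ±5 mV range; saturating with recovery τ = 1/(2π·f_low) when not) and
  probabilistic stimulus-evoked responses, all with exhaustive ground
  truth. Everything is generated; no data files are required.

See `docs/methods.md` for the model details, parameter defaults and
known limitations.

## Worked example: a spike-triggered stimulation loop

One recording channel at 20 kSps carries a synthetic unit firing at
8 Hz. A falling-threshold discriminator triggers a 1 mA biphasic pulse
(0.2 ms/phase) 0.1 ms after each detected spike; stimulation feeds back
into the recording as an artifact plus fast-settle blanking, under a
10 ms global refractory.

```python
from nc3sim import *

disc = WindowDiscSpec(threshold=-800, polarity="falling", dead_time_ticks=200)
gen = EventGeneratorSpec(0, "window_discriminator", source=0, discriminator=disc)
pulse = StimWaveform(0, phase1_ua=1000.0, phase1_ticks=20,
                     phase2_ua=-1000.0, phase2_ticks=20, delay_ticks=10)
cond = StimCondition(0, (pulse,), trigger_map={0: (0,)})
config = DeviceConfig(
    channels=[ChannelConfig(0, sample_rate=20000)],
    bandpass=(500.0, 5000.0),
    event_generators=[gen],
    conditions=[cond],
    seed=7,
    refractory_ms=10.0,
    fast_settle_us=400.0,
)
scenario = ScenarioSpec(
    duration_s=2.0, fs=20000.0, n_channels=1,
    neurons=(NeuronModel(0, rate_hz=8.0),),
    noise_rms_mv=0.01,
    artifact=ArtifactModel(coupling_uv_per_ua=(2.0,), highpass_fl_hz=500.0),
    seed=7,
)
result = run_closed_loop(config, scenario, session_path="demo.nc3")
print(f"ground-truth spikes : {len(result.truth.spike_times[0])}")
print(f"discriminator events: {len(result.trigger_events)}")
print(f"pulses delivered    : {len(result.pulses)}")
print(f"triggers dropped    : {len(result.rejected)}")
first = result.pulses[0]
print(f"first loop latency  : {(first.onset - first.trigger_ts) * 10} µs")
```

prints

```
ground-truth spikes : 12
discriminator events: 12
pulses delivered    : 12
triggers dropped    : 0
first loop latency  : 100 µs
```

Every ground-truth spike was detected, every detection produced exactly
one stimulus (none fell inside the refractory of another), and the pulse
left the (shared) current source one waveform delay — 10 ticks = 100 µs
— after the threshold-crossing sample. `demo.nc3` now holds the
filtered, quantized channel with the 400 µs post-stimulus blanking and
all event/stimulus records; `nc3sim summarize demo.nc3` prints the
counts and `nc3sim export demo.nc3 --outdir out/` emits flat int16 +
TSV for external tools.

The same loop is available from the shell: `nc3sim validate <config>`,
`nc3sim run --config <config> --scenario <scenario> --out <session>`.

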