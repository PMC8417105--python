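"""Synthetic-scenario generation: spikes, EMG, artifacts, evoked responses.

Closes the loop without hardware: produces ground-truth multichannel
extracellular or EMG traces in mV, injects stimulus artifacts consistent
with the recording chain (brief biphasic transients while the input stays
inside the ±5 mV amplifier range; saturating steps that recover with the
high-pass time constant when it does not), and inserts stimulus-evoked
spikes at configurable probability, latency and jitter.

Every deviation from the additive Gaussian noise floor is attributable to
a listed spike, artifact or evoked event, and generation is bit-identical
under a fixed seed — properties the rest of the test suite leans on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .stimulator import PulseInstance

AMP_RANGE_MV = 5.0


def default_spike_template(fs: float, peak_mv: float = -0.3) -> np.ndarray:
    """Biphasic extracellular spike: 0.6 ms, negative peak then positive
    overshoot.  Parametric stand-in for recorded waveforms; real spike
    shapes vary with electrode and unit and may be substituted."""
    t = np.arange(0, 0.6e-3, 1.0 / fs)
    w = np.exp(-(((t - 0.15e-3) / 0.08e-3) ** 2)) - 0.45 * np.exp(
        -(((t - 0.35e-3) / 0.12e-3) ** 2)
    )
    return peak_mv * w / np.max(np.abs(w))


def default_muap_template(fs: float, peak_mv: float = 0.8) -> np.ndarray:
    """Motor-unit action potential: triphasic, ~6 ms support."""
    t = np.arange(0, 6e-3, 1.0 / fs)
    w = (
        0.5 * np.exp(-(((t - 1.2e-3) / 0.5e-3) ** 2))
        - np.exp(-(((t - 2.2e-3) / 0.7e-3) ** 2))
        + 0.4 * np.exp(-(((t - 3.6e-3) / 1.0e-3) ** 2))
    )
    return peak_mv * w / np.max(np.abs(w))


@dataclass(frozen=True)
class NeuronModel:
    """Ground-truth unit: Poisson firing shaped onto recording channels."""

    unit_id: int
    rate_hz: float
    refractory_ms: float = 2.0
    template: Optional[np.ndarray] = None  # mV at scenario rate
    coupling: tuple[float, ...] = (1.0,)  # per-channel amplitude scale

    def __post_init__(self) -> None:
        if self.rate_hz < 0:
            raise ValueError(f"rate_hz must be >= 0, got {self.rate_hz}")


@dataclass(frozen=True)
class ArtifactModel:
    """Stimulus-artifact coupling from the stimulator into the amplifiers.

    ``coupling_uv_per_ua`` scales pulse current to the voltage seen at
    each recording channel.  When the coupled amplitude stays within the
    ±5 mV input range the artifact is a brief (<2 ms) biphasic transient;
    when it exceeds the range the amplifier saturates and the recorded
    artifact is a ±5 mV step decaying with the high-pass time constant
    τ = 1/(2π·fl), so recovery scales with 1/fl.
    """

    coupling_uv_per_ua: tuple[float, ...] = (1.0,)
    highpass_fl_hz: float = 500.0
    tail_ms: float = 0.3  # sub-range transient tail, confined to < 2 ms


@dataclass(frozen=True)
class EvokedSpec:
    """Stimulus-evoked response of one unit: probability, latency, jitter."""

    unit_id: int
    probability: float
    latency_ms: float = 2.0
    jitter_ms: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError(f"probability {self.probability} outside [0, 1]")
        if self.latency_ms < 0 or self.jitter_ms < 0:
            raise ValueError("latency and jitter must be >= 0")


@dataclass(frozen=True)
class ScenarioSpec:
    duration_s: float
    fs: float = 20000.0
    n_channels: int = 1
    neurons: tuple[NeuronModel, ...] = ()
    noise_rms_mv: float = 0.02
    artifact: Optional[ArtifactModel] = None
    evoked: tuple[EvokedSpec, ...] = ()
    seed: int = 0


@dataclass
class GroundTruth:
    """Exhaustive account of everything placed into the traces."""

    spike_times: dict[int, list[int]] = field(default_factory=dict)  # samples
    evoked_flags: dict[int, list[bool]] = field(default_factory=dict)
    burst_windows: list[tuple[int, int]] = field(default_factory=list)


def poisson_train(
    rate_hz: float,
    duration_s: float,
    refractory_s: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Spike times (s) of a Poisson process with absolute refractory."""
    if rate_hz <= 0:
        return np.array([])
    times = []
    t = 0.0
    while True:
        t += rng.exponential(1.0 / rate_hz) + refractory_s
        if t >= duration_s:
            return np.array(times)
        times.append(t)


def _add_template(
    trace: np.ndarray, template: np.ndarray, start: int, scale: float
) -> None:
    n = len(trace)
    if start >= n or start + len(template) <= 0:
        return
    a, b = max(start, 0), min(start + len(template), n)
    trace[a:b] += scale * template[a - start : b - start]


def synthesize_recording(
    spec: ScenarioSpec,
    rng: Optional[np.random.Generator] = None,
) -> tuple[np.ndarray, GroundTruth]:
    """Generate (n_channels, n_samples) mV traces plus ground truth.

    Poisson spike trains with absolute refractory per unit, templates
    summed onto channels per coupling, then i.i.d. Gaussian noise.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_s * spec.fs))
    traces = np.zeros((spec.n_channels, n))
    truth = GroundTruth()
    for nm in spec.neurons:
        template = (
            nm.template
            if nm.template is not None
            else default_spike_template(spec.fs)
        )
        times_s = poisson_train(
            nm.rate_hz, spec.duration_s, nm.refractory_ms / 1000.0, rng
        )
        samples = [int(round(t * spec.fs)) for t in times_s]
        truth.spike_times[nm.unit_id] = samples
        truth.evoked_flags[nm.unit_id] = [False] * len(samples)
        for s in samples:
            for ch in range(spec.n_channels):
                scale = nm.coupling[ch] if ch < len(nm.coupling) else 0.0
                if scale:
                    _add_template(traces[ch], template, s, scale)
    if spec.noise_rms_mv > 0:
        traces += rng.normal(0.0, spec.noise_rms_mv, size=traces.shape)
    return traces, truth


def stimulus_artifact_traces(
    shape: tuple[int, int],
    fs: float,
    pulses: Sequence[PulseInstance],
    model: ArtifactModel,
    tick_us: int = 10,
) -> np.ndarray:
    """Artifact-only traces for the given pulses (additive by construction).

    Sub-range artifacts replicate the biphasic pulse shape plus a short
    exponential tail, all confined within 2 ms of onset.  Saturating
    artifacts are a full-scale step from onset decaying as
    ``exp(−t/τ)`` with τ = 1/(2π·fl).
    """
    art = np.zeros(shape)
    n_ch, n = shape
    ticks_per_sample = int(round(1_000_000 / fs)) // tick_us
    tau_s = 1.0 / (2.0 * np.pi * model.highpass_fl_hz)
    two_ms = int(round(2e-3 * fs))
    for p in pulses:
        s0 = p.onset // ticks_per_sample
        for ch in range(n_ch):
            k = (
                model.coupling_uv_per_ua[ch]
                if ch < len(model.coupling_uv_per_ua)
                else 0.0
            ) / 1000.0  # µV/µA → mV/µA
            if k == 0.0:
                continue
            a1, a2 = k * p.phase1_ua, k * p.phase2_ua
            if max(abs(a1), abs(a2)) <= AMP_RANGE_MV:
                # brief biphasic transient, < 2 ms total
                w1 = max(p.phase1_ticks // ticks_per_sample, 1)
                w2 = max(p.phase2_ticks // ticks_per_sample, 1)
                seg = np.concatenate([np.full(w1, a1), np.full(w2, a2)])
                tail_n = int(round(model.tail_ms * 1e-3 * fs))
                if tail_n:
                    tail = a2 * np.exp(
                        -np.arange(1, tail_n + 1) / (0.1e-3 * fs)
                    )
                    seg = np.concatenate([seg, tail])
                seg = seg[: two_ms - 1]
                _add_template(art[ch], seg, s0, 1.0)
            else:
                # amplifier saturates: step at ±full-scale, high-pass recovery
                sign = np.sign(a1) if a1 else 1.0
                t = np.arange(n - s0) / fs
                art[ch, s0:] += sign * AMP_RANGE_MV * np.exp(-t / tau_s)
    return art


def inject_stimulus_artifact(
    traces: np.ndarray,
    fs: float,
    pulses: Sequence[PulseInstance],
    model: ArtifactModel,
    tick_us: int = 10,
) -> np.ndarray:
    """Return traces with stimulus artifacts added (input left untouched)."""
    return traces + stimulus_artifact_traces(
        traces.shape, fs, pulses, model, tick_us
    )


def evoke_responses(
    pulses: Sequence[PulseInstance],
    evoked: Sequence[EvokedSpec],
    spec: ScenarioSpec,
    truth: GroundTruth,
    rng: np.random.Generator,
    tick_us: int = 10,
) -> dict[int, list[int]]:
    """Draw stimulus-evoked spikes (fast excitatory response, 1–10 ms).

    For each pulse and responsive unit, with the configured probability a
    spike is inserted at latency ± uniform jitter, skipped when it would
    violate the unit's refractory against an existing spike.  Evoked
    spikes are appended to the ground truth with their flag set; returns
    the added spike samples per unit (callers render them onto traces).
    """
    added: dict[int, list[int]] = {}
    samples_per_tick = spec.fs * tick_us / 1_000_000
    for ev in evoked:
        refr = next(
            (nm.refractory_ms for nm in spec.neurons if nm.unit_id == ev.unit_id),
            2.0,
        )
        refr_samp = int(round(refr * 1e-3 * spec.fs))
        existing = sorted(truth.spike_times.get(ev.unit_id, []))
        for p in pulses:
            if rng.random() >= ev.probability:
                continue
            jitter = rng.uniform(-ev.jitter_ms, ev.jitter_ms) if ev.jitter_ms else 0.0
            lat_s = max(ev.latency_ms + jitter, 0.0) * 1e-3
            s = int(round(p.onset * samples_per_tick + lat_s * spec.fs))
            if any(abs(s - e) < refr_samp for e in existing):
                continue
            existing.append(s)
            existing.sort()
            truth.spike_times.setdefault(ev.unit_id, []).append(s)
            truth.evoked_flags.setdefault(ev.unit_id, []).append(True)
            added.setdefault(ev.unit_id, []).append(s)
    return added


@dataclass(frozen=True)
class EmgScenarioSpec:
    """Three-muscle EMG scenario for the multi-loop spinal paradigm.

    Each channel carries motor-unit potential trains gated by activity
    bursts, emulating volitional muscle activity that three independent
    discriminator→stimulation loops can lock onto.
    """

    duration_s: float = 5.0
    fs: float = 5000.0
    n_channels: int = 3
    burst_rate_hz: float = 1.0
    burst_len_s: float = 0.3
    muap_rate_hz: float = 60.0  # within bursts
    muap_peak_mv: float = 0.8
    noise_rms_mv: float = 0.08  # peak/10
    seed: int = 0


def synthesize_emg_scenario(
    spec: EmgScenarioSpec,
    rng: Optional[np.random.Generator] = None,
) -> tuple[np.ndarray, GroundTruth]:
    """Burst-modulated motor-unit potential trains on three channels.

    Bursts occur independently per channel at ``burst_rate_hz``; within a
    burst, motor-unit potentials fire at ``muap_rate_hz`` with a 5 ms
    refractory.  Ground truth lists per-channel potential times (unit id
    = channel) and the burst windows (sample index ranges).
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_s * spec.fs))
    traces = np.zeros((spec.n_channels, n))
    truth = GroundTruth()
    template = default_muap_template(spec.fs, spec.muap_peak_mv)
    for ch in range(spec.n_channels):
        truth.spike_times[ch] = []
        truth.evoked_flags[ch] = []
        burst_starts = poisson_train(
            spec.burst_rate_hz, spec.duration_s, spec.burst_len_s, rng
        )
        if len(burst_starts) == 0:  # guarantee at least one burst
            burst_starts = np.array([rng.uniform(0, spec.duration_s * 0.5)])
        for b0 in burst_starts:
            b1 = min(b0 + spec.burst_len_s, spec.duration_s)
            truth.burst_windows.append(
                (int(round(b0 * spec.fs)), int(round(b1 * spec.fs)))
            )
            mu_times = b0 + poisson_train(
                spec.muap_rate_hz, b1 - b0, 5e-3, rng
            )
            for t in mu_times:
                s = int(round(t * spec.fs))
                truth.spike_times[ch].append(s)
                truth.evoked_flags[ch].append(False)
                _add_template(traces[ch], template, s, 1.0)
    if spec.noise_rms_mv > 0:
        traces += rng.normal(0.0, spec.noise_rms_mv, size=traces.shape)
    return traces, truth
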