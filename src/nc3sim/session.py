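"""Session recording format and the closed-loop experiment runner.

A session file holds the digitized analog channels interleaved, in
timestamp order, with the four classes of timestamp records the device
logs: digital events (generator hits), condition transitions, stimulus
events and network events.  The on-card layout of the real instrument is
unpublished, so the format here is an open chunked container — magic,
version, then self-describing chunks each protected by CRC32 — whose
fidelity target is the *information content*, not byte compatibility.

Layout::

    magic b"NC3S" | u16 version
    chunk := tag(4s) | u32 payload_len | payload | u32 crc32(payload)
    tags:  HEAD  JSON header (config snapshot, tick_us, channel map)
           ANLG  u16 channel | u64 start_tick | u32 n | n × int16 LE
           RECS  JSON list of [timestamp, class, source]

Everything is deterministic under a fixed seed and config, down to the
byte level, which the test suite asserts.
"""

from __future__ import annotations

import json
import struct
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import snn as snn_mod
from .config import DeviceConfig, validate_config
from .events import (
    KIND_CONDITION,
    KIND_DIGITAL,
    KIND_NETWORK,
    KIND_STIM,
    EventRecord,
    generate_interval_events,
)
from .frontend import AdcModel, adc_noise, bandpass_sos, highpass_sos, quantize_samples
from .stimulator import (
    PulseInstance,
    SchedulerState,
    StimCondition,
    schedule_pulses,
    sequence_conditions,
)
from .synth import (
    EmgScenarioSpec,
    GroundTruth,
    ScenarioSpec,
    default_spike_template,
    stimulus_artifact_traces,
    synthesize_emg_scenario,
    synthesize_recording,
)

MAGIC = b"NC3S"
VERSION = 1

_RECORD_CLASSES = (KIND_DIGITAL, KIND_CONDITION, KIND_STIM, KIND_NETWORK)


class SessionFormatError(IOError):
    pass


@dataclass
class SessionHeader:
    tick_us: int = 10
    channel_map: dict[int, int] = field(default_factory=dict)  # id → rate
    config: Optional[dict] = None
    start_tick: int = 0

    def to_json(self) -> str:
        return json.dumps(
            {
                "tick_us": self.tick_us,
                "channel_map": {str(k): v for k, v in self.channel_map.items()},
                "config": self.config,
                "start_tick": self.start_tick,
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "SessionHeader":
        d = json.loads(text)
        return cls(
            tick_us=d["tick_us"],
            channel_map={int(k): v for k, v in d["channel_map"].items()},
            config=d.get("config"),
            start_tick=d.get("start_tick", 0),
        )


@dataclass(frozen=True)
class AnalogBlock:
    channel_id: int
    start_tick: int
    codes: np.ndarray  # int16


def _chunk(tag: bytes, payload: bytes) -> bytes:
    return tag + struct.pack("<I", len(payload)) + payload + struct.pack(
        "<I", zlib.crc32(payload)
    )


def write_session(
    path: str | Path,
    header: SessionHeader,
    blocks: Sequence[AnalogBlock] = (),
    records: Sequence[EventRecord] = (),
) -> None:
    """Write a session file with blocks and records interleaved in time order.

    Raises on out-of-order input or an unknown record class.
    """
    items: list[tuple[int, int, object]] = []
    prev = -1
    for b in blocks:
        if b.start_tick < prev:
            raise ValueError("analog blocks out of order")
        prev = b.start_tick
        items.append((b.start_tick, 0, b))
    prev = -1
    for r in records:
        if r.kind not in _RECORD_CLASSES:
            raise ValueError(f"unknown record class {r.kind!r}")
        if r.timestamp < prev:
            raise ValueError("records out of order")
        prev = r.timestamp
        items.append((r.timestamp, 1, r))
    items.sort(key=lambda it: (it[0], it[1]))

    with open(path, "wb") as fh:
        fh.write(MAGIC + struct.pack("<H", VERSION))
        fh.write(_chunk(b"HEAD", header.to_json().encode()))
        pending: list[EventRecord] = []

        def flush_records() -> None:
            if pending:
                payload = json.dumps(
                    [
                        [r.timestamp, _RECORD_CLASSES.index(r.kind), r.source]
                        for r in pending
                    ]
                ).encode()
                fh.write(_chunk(b"RECS", payload))
                pending.clear()

        for _, which, obj in items:
            if which == 1:
                pending.append(obj)
            else:
                flush_records()
                b = obj
                codes = np.asarray(b.codes, dtype="<i2")
                payload = (
                    struct.pack("<HQI", b.channel_id, b.start_tick, len(codes))
                    + codes.tobytes()
                )
                fh.write(_chunk(b"ANLG", payload))
        flush_records()


def read_session(
    path: str | Path,
) -> tuple[SessionHeader, list[AnalogBlock], list[EventRecord]]:
    """Exact inverse of :func:`write_session`; validates CRCs and version."""
    data = Path(path).read_bytes()
    if data[:4] != MAGIC:
        raise SessionFormatError("not a session file (bad magic)")
    (version,) = struct.unpack_from("<H", data, 4)
    if version != VERSION:
        raise SessionFormatError(f"unknown version {version}")
    off = 6
    header: Optional[SessionHeader] = None
    blocks: list[AnalogBlock] = []
    records: list[EventRecord] = []
    while off < len(data):
        if off + 8 > len(data):
            raise SessionFormatError(
                f"truncated chunk header; last valid offset {off}"
            )
        tag = data[off : off + 4]
        (plen,) = struct.unpack_from("<I", data, off + 4)
        end = off + 8 + plen + 4
        if end > len(data):
            raise SessionFormatError(
                f"truncated chunk {tag!r}; last valid offset {off}"
            )
        payload = data[off + 8 : off + 8 + plen]
        (crc,) = struct.unpack_from("<I", data, off + 8 + plen)
        if crc != zlib.crc32(payload):
            raise SessionFormatError(
                f"checksum mismatch in chunk {tag!r} at offset {off}"
            )
        if tag == b"HEAD":
            header = SessionHeader.from_json(payload.decode())
        elif tag == b"ANLG":
            ch, start, n = struct.unpack_from("<HQI", payload)
            codes = np.frombuffer(payload, dtype="<i2", offset=14, count=n)
            blocks.append(AnalogBlock(ch, start, codes.copy()))
        elif tag == b"RECS":
            for ts, cls, src in json.loads(payload.decode()):
                records.append(EventRecord(ts, src, _RECORD_CLASSES[cls]))
        else:
            raise SessionFormatError(f"unknown chunk tag {tag!r} at offset {off}")
        off = end
    if header is None:
        raise SessionFormatError("missing header chunk")
    return header, blocks, records


def summarize_session(
    header: SessionHeader,
    blocks: Sequence[AnalogBlock],
    records: Sequence[EventRecord],
    n_envelope_bins: int = 100,
    sweep_source: Optional[tuple[str, int]] = None,
    sweep_channel: Optional[int] = None,
    sweep_pre_ticks: int = 100,
    sweep_post_ticks: int = 500,
) -> dict:
    """Counts, per-channel envelopes, and optional event-triggered sweeps.

    Mirrors the instrument's monitoring display: event occurrences per
    generator, stimulus occurrences per output, min/max data envelopes
    per channel, and fixed-width data sweeps aligned on the timestamps of
    a chosen event source.
    """
    gen_counts: dict[int, int] = {}
    stim_counts: dict[int, int] = {}
    cond_transitions = []
    net_counts: dict[int, int] = {}
    for r in records:
        if r.kind == KIND_DIGITAL:
            gen_counts[r.source] = gen_counts.get(r.source, 0) + 1
        elif r.kind == KIND_STIM:
            stim_counts[r.source] = stim_counts.get(r.source, 0) + 1
        elif r.kind == KIND_CONDITION:
            cond_transitions.append((r.timestamp, r.source))
        elif r.kind == KIND_NETWORK:
            net_counts[r.source] = net_counts.get(r.source, 0) + 1

    envelopes: dict[int, dict] = {}
    per_channel: dict[int, list[AnalogBlock]] = {}
    for b in blocks:
        per_channel.setdefault(b.channel_id, []).append(b)
    for ch, blist in per_channel.items():
        codes = np.concatenate([b.codes for b in blist])
        bins = np.array_split(codes, min(n_envelope_bins, max(len(codes), 1)))
        envelopes[ch] = {
            "min": np.array([b.min() for b in bins if len(b)]),
            "max": np.array([b.max() for b in bins if len(b)]),
        }

    summary = {
        "generator_event_counts": gen_counts,
        "stimulus_counts": stim_counts,
        "network_event_counts": net_counts,
        "condition_transitions": cond_transitions,
        "envelopes": envelopes,
    }

    if sweep_source is not None:
        kind, source = sweep_source
        if sweep_channel not in per_channel:
            raise ValueError(f"unknown sweep channel {sweep_channel}")
        rate = header.channel_map[sweep_channel]
        tps = (1_000_000 // rate) // header.tick_us
        codes = np.concatenate([b.codes for b in per_channel[sweep_channel]])
        times = [r.timestamp for r in records if r.kind == kind and r.source == source]
        if not times and kind not in _RECORD_CLASSES:
            raise ValueError(f"unknown sweep source kind {kind!r}")
        pre, post = sweep_pre_ticks // tps, sweep_post_ticks // tps
        sweeps = []
        for t in times:
            i = t // tps
            if i - pre >= 0 and i + post <= len(codes):
                sweeps.append(codes[i - pre : i + post])
        summary["sweeps"] = np.array(sweeps)
        summary["sweep_offset_samples"] = pre
    return summary


# ---------------------------------------------------------------------------
# closed-loop runner
# ---------------------------------------------------------------------------


class _SosStream:
    """Per-sample IIR cascade (direct form II transposed), for the
    streaming path of the loop.  Matches scipy's sosfilt state-for-state
    so the in-loop filtered signal equals the vectorized recording pass."""

    def __init__(self, sos: np.ndarray):
        self.sos = np.asarray(sos, dtype=float)
        self.z = np.zeros((self.sos.shape[0], 2))

    def push(self, x: float) -> float:
        for s in range(self.sos.shape[0]):
            b0, b1, b2, _, a1, a2 = self.sos[s]
            z0, z1 = self.z[s]
            y = b0 * x + z0
            self.z[s, 0] = b1 * x - a1 * y + z1
            self.z[s, 1] = b2 * x - a2 * y
            x = y
        return x


class _DiscriminatorStream:
    """Streaming dual time-amplitude window discriminator.

    Threshold crossings are detected sample by sample; a crossing becomes
    an event once the samples at every window delay have arrived and fall
    inside their boxes.  Dead time gates *crossings* relative to the last
    accepted event, and crossings inside blanking intervals are dropped.
    """

    def __init__(self, spec, ticks_per_sample: int, gen_id: int):
        self.spec = spec
        self.tps = ticks_per_sample
        self.gen_id = gen_id
        self.delays = []
        for w in spec.windows:
            if w.delay_ticks % ticks_per_sample:
                raise ValueError(
                    f"window delay {w.delay_ticks} not a multiple of the "
                    f"sample period {ticks_per_sample}"
                )
            self.delays.append(w.delay_ticks // ticks_per_sample)
        self.max_delay = max(self.delays, default=0)
        self.prev: Optional[int] = None
        self.codes: list[int] = []
        self.pending: list[int] = []  # crossing sample indices
        self.last_accept: Optional[int] = None

    def push(
        self, code: int, blanking: Sequence[tuple[int, int]]
    ) -> Optional[EventRecord]:
        i = len(self.codes)
        self.codes.append(code)
        spec = self.spec
        crossed = False
        if self.prev is not None:
            if spec.polarity == "rising":
                crossed = self.prev < spec.threshold <= code
            else:
                crossed = self.prev > spec.threshold >= code
        self.prev = code
        if crossed:
            t = i * self.tps
            dead = (
                self.last_accept is not None
                and t - self.last_accept < spec.dead_time_ticks
            )
            blanked = any(lo <= t < hi for lo, hi in blanking)
            if not dead and not blanked:
                self.pending.append(i)
        out: Optional[EventRecord] = None
        still: list[int] = []
        for c in self.pending:
            if i - c < self.max_delay:
                still.append(c)
                continue
            ok = all(
                w.amp_min <= self.codes[c + d] <= w.amp_max
                for w, d in zip(spec.windows, self.delays)
            )
            t = c * self.tps
            if ok and (
                self.last_accept is None
                or t - self.last_accept >= spec.dead_time_ticks
            ):
                self.last_accept = t
                out = EventRecord(t, self.gen_id)
        self.pending = still
        return out


@dataclass
class ClosedLoopResult:
    config: DeviceConfig
    scenario: ScenarioSpec
    codes: dict[int, np.ndarray]
    records: list[EventRecord]
    trigger_events: list[EventRecord]
    pulses: list[PulseInstance]
    rejected: list
    truth: GroundTruth
    blanking: list[tuple[int, int]]
    snn_raster: list[tuple[int, int]]


def run_closed_loop(
    config: DeviceConfig,
    scenario: ScenarioSpec,
    evoked: Sequence = (),
    session_path: Optional[str | Path] = None,
) -> ClosedLoopResult:
    """Single-pass tick loop wiring scenario → front-end → events (→ SNN)
    → stimulator, with stimulation feeding back into the scenario.

    All enabled channels must share one sample rate (the loop runs on the
    common ADC sample grid).  Discriminators see the same filtered,
    quantized signal the session records; scheduled stimuli inject
    artifacts and evoked spikes into the *future* of the raw traces and
    open fast-settle blanking windows, so detection and stimulation
    interact exactly once per sample.  The closed-loop latency from a
    threshold-crossing sample to pulse onset is the waveform delay plus
    at most the window-confirmation time (zero for threshold-only
    discriminators).
    """
    config = validate_config(config)
    tb = config.timebase
    enabled = config.enabled_channels()
    if not enabled:
        raise ValueError("no enabled channels")
    rates = {c.sample_rate for c in enabled}
    if len(rates) > 1:
        raise ValueError("closed loop requires a single common sample rate")
    fs = rates.pop()
    if abs(fs - scenario.fs) > 1e-9:
        raise ValueError(
            f"scenario rate {scenario.fs} != channel rate {fs}"
        )
    tps = tb.ticks_per_sample(fs)
    n = int(round(scenario.duration_s * fs))
    total_ticks = n * tps

    rng_synth = config.rng_stream("synth")
    rng_evoked = config.rng_stream("evoked")
    adc = AdcModel()

    if isinstance(scenario, EmgScenarioSpec):
        traces, truth = synthesize_emg_scenario(scenario, rng_synth)
    else:
        traces, truth = synthesize_recording(scenario, rng_synth)
    if traces.shape[0] < len(enabled):
        raise ValueError(
            f"scenario provides {traces.shape[0]} channels for "
            f"{len(enabled)} enabled channels"
        )
    noise = {
        c.channel_id: adc_noise(config.rng_stream(f"adc{c.channel_id}"), n, adc)
        for c in enabled
    }

    # condition schedule (a record-only session may have no conditions)
    if config.conditions:
        segments, cond_records = sequence_conditions(config.conditions, total_ticks)
    else:
        segments, cond_records = [], []
    seg_idx = 0

    # pre-computed interval-generator events
    interval_events: list[EventRecord] = []
    disc_gens = []
    snn_out_gens = set()
    for g in config.event_generators:
        if g.mode in ("fixed_interval", "uniform_interval", "exponential_interval"):
            interval_events.extend(
                generate_interval_events(
                    g, total_ticks, config.rng_stream(f"gen{g.gen_id}")
                )
            )
        elif g.mode == "window_discriminator":
            disc_gens.append(g)
        elif g.mode == "snn_output":
            snn_out_gens.add(g.gen_id)
    interval_events.sort()
    iev_idx = 0

    # streaming front-end + discriminator per discriminator generator
    low, high = config.bandpass
    sos = np.vstack([highpass_sos(0.07, fs), bandpass_sos(low, high, fs)])
    streams = []
    for g in disc_gens:
        streams.append(
            (
                g,
                _SosStream(sos),
                _DiscriminatorStream(g.discriminator, tps, g.gen_id),
            )
        )

    # SNN
    snn_state = None
    step_ticks = tb.snn_step_ticks
    next_snn_step = 1
    pending_ext: dict[int, set[int]] = {}  # step → generator ids
    snn_raster: list[tuple[int, int]] = []
    if config.snn is not None:
        snn_state = snn_mod.SnnState(config.snn, seed=config.seed)

    sched = SchedulerState(
        refractory_ticks=tb.ms_to_ticks(config.refractory_ms),
        compliance_v=config.compliance_v,
    )
    gate_history: list[EventRecord] = []
    pulses: list[PulseInstance] = []
    rejected: list = []
    trigger_events: list[EventRecord] = []
    blanking: list[tuple[int, int]] = []
    evoked_template = default_spike_template(scenario.fs)

    def note_external(ev: EventRecord) -> None:
        if snn_state is not None:
            step = ev.timestamp // step_ticks + 1
            pending_ext.setdefault(step, set()).add(ev.source)

    def active_condition(tick: int) -> Optional[StimCondition]:
        nonlocal seg_idx
        if not segments:
            return None
        while seg_idx + 1 < len(segments) and tick >= segments[seg_idx][1]:
            seg_idx += 1
        start, end, cid = segments[seg_idx]
        if start <= tick < end:
            for c in config.conditions:
                if c.condition_id == cid:
                    return c
        return None

    def fire_trigger(ev: EventRecord, sample_i: int) -> None:
        """Gate + schedule one trigger; apply stimulus feedback."""
        cond = active_condition(ev.timestamp)
        if cond is None or ev.source not in cond.trigger_map:
            return
        new_pulses, rej = schedule_pulses(
            [ev], cond, sched, history=gate_history
        )
        rejected.extend(rej)
        if not new_pulses:
            return
        pulses.extend(new_pulses)
        art_model = getattr(scenario, "artifact", None)
        for p in new_pulses:
            s0 = p.onset // tps
            if art_model is not None:
                art = stimulus_artifact_traces(
                    (traces.shape[0], traces.shape[1]),
                    fs,
                    [p],
                    art_model,
                    tb.tick_us,
                )
                # feedback is causal: never rewrite consumed samples
                cut = sample_i + 1
                traces[:, cut:] += art[:, cut:]
            if config.fast_settle_us is not None:
                blanking.append(
                    (p.onset, p.onset + tb.us_to_ticks(config.fast_settle_us))
                )
            for ev_spec in evoked:
                if rng_evoked.random() >= ev_spec.probability:
                    continue
                jit = (
                    rng_evoked.uniform(-ev_spec.jitter_ms, ev_spec.jitter_ms)
                    if ev_spec.jitter_ms
                    else 0.0
                )
                lat = max(ev_spec.latency_ms + jit, 0.0)
                s = s0 + int(round(lat * 1e-3 * fs))
                if s <= sample_i or s >= n:
                    continue
                truth.spike_times.setdefault(ev_spec.unit_id, []).append(s)
                truth.evoked_flags.setdefault(ev_spec.unit_id, []).append(True)
                nm = next(
                    (
                        m
                        for m in getattr(scenario, "neurons", ())
                        if m.unit_id == ev_spec.unit_id
                    ),
                    None,
                )
                tmpl = (
                    nm.template
                    if nm is not None and nm.template is not None
                    else evoked_template
                )
                coupling = nm.coupling if nm is not None else (1.0,)
                for ch in range(traces.shape[0]):
                    scale = coupling[ch] if ch < len(coupling) else 0.0
                    if scale:
                        lo = max(s, sample_i + 1)
                        hi = min(s + len(tmpl), n)
                        if lo < hi:
                            traces[ch, lo:hi] += scale * tmpl[lo - s : hi - s]

    for i in range(n):
        tick = i * tps

        # interval-generator events due at or before this sample's tick
        while (
            iev_idx < len(interval_events)
            and interval_events[iev_idx].timestamp <= tick
        ):
            ev = interval_events[iev_idx]
            iev_idx += 1
            trigger_events.append(ev)
            note_external(ev)
            fire_trigger(ev, i)

        # SNN steps whose boundary falls at or before this tick
        if snn_state is not None:
            while next_snn_step * step_ticks <= tick:
                step = next_snn_step
                flags = [False] * 8
                for gid in pending_ext.pop(step, ()):
                    if gid < 8:
                        flags[gid] = True
                fired = snn_mod.step_network(snn_state, flags)
                for u in fired:
                    snn_raster.append((step, int(u)))
                    if int(u) in snn_out_gens:
                        ev = EventRecord(step * step_ticks, int(u))
                        trigger_events.append(ev)
                        fire_trigger(ev, i)
                next_snn_step += 1

        # discriminators on this sample
        for g, sos_stream, disc in streams:
            ch = g.source
            y = sos_stream.push(traces[ch, i])
            code = int(
                quantize_samples(
                    np.array([y]), adc, noise_mv=noise[ch][i : i + 1]
                )[0]
            )
            ev = disc.push(code, blanking[-8:])
            if ev is not None:
                trigger_events.append(ev)
                note_external(ev)
                fire_trigger(ev, i)

    # recording pass: full front-end chain on the final raw traces
    from scipy.signal import sosfilt

    codes_out: dict[int, np.ndarray] = {}
    for c in enabled:
        filtered = sosfilt(sos, traces[c.channel_id])
        codes = quantize_samples(filtered, adc, noise_mv=noise[c.channel_id])
        if blanking:
            codes = codes.copy()
            for lo, hi in blanking:
                first = -(-lo // tps)
                last = -(-hi // tps)
                codes[max(first, 0) : min(last, n)] = 0
        codes_out[c.channel_id] = codes

    records: list[EventRecord] = sorted(
        cond_records
        + trigger_events
        + [EventRecord(p.onset, p.pins[0], KIND_STIM) for p in pulses]
        + snn_mod.raster_to_records(snn_raster, step_ticks)
    )

    result = ClosedLoopResult(
        config=config,
        scenario=scenario,
        codes=codes_out,
        records=records,
        trigger_events=sorted(trigger_events),
        pulses=pulses,
        rejected=rejected,
        truth=truth,
        blanking=blanking,
        snn_raster=snn_raster,
    )
    if session_path is not None:
        save_result(result, session_path)
    return result


def save_result(result: ClosedLoopResult, path: str | Path) -> None:
    """Write a closed-loop result as a session file."""
    from .configfile import config_to_dict

    header = SessionHeader(
        tick_us=result.config.timebase.tick_us,
        channel_map={
            c.channel_id: c.sample_rate
            for c in result.config.enabled_channels()
        },
        config=config_to_dict(result.config),
    )
    blocks = [
        AnalogBlock(ch, 0, codes) for ch, codes in sorted(result.codes.items())
    ]
    write_session(path, header, blocks, result.records)


def export_events_tsv(records: Sequence[EventRecord], path: str | Path) -> None:
    """Tab-separated event export: timestamp_ticks, source, kind."""
    with open(path, "w") as fh:
        fh.write("timestamp_ticks\tsource\tkind\n")
        for r in records:
            fh.write(f"{r.timestamp}\t{r.source}\t{r.kind}\n")
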