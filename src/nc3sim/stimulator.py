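"""Six-channel constant-current stimulator emulation.

All six output pins share one programmable current source, so only one
anodal/cathodal pin pair can carry current at any instant.  Triggered
pulse trains that would overlap are therefore *interleaved*: a pulse that
arrives while the source is busy is delayed until the source frees, plus
a channel switch time (0.4 ms typical) when the pin pair changes.  Two
0.4 ms waveforms fired by the same trigger thus land 0.8 ms apart,
leading edge to leading edge.

Further semantics:

* inter-pulse interval (IPI) is onset-to-onset within a train; IPI = 0
  selects burst mode — back-to-back pulses on the same pins with no gap
  (20 pulses of 0.1 ms complete within 2 ms, a 10 kHz burst);
* a global refractory period (10 ms in the multi-loop spinal paradigm)
  drops any pulse train whose onset falls within the window after a
  previous train's onset, across all channels, so stimulus-evoked
  responses cannot re-trigger stimulation; trains belonging to the same
  trigger are interleaved rather than dropped;
* a sliding 1 s rate cap drops (never delays) excess triggers: 500
  pulses/s at normal amplitudes, 350 at full-amplitude trains under
  ±60 V compliance, 700 under ±50 V; pulses inside one burst train are
  exempt while the burst runs but count in the window afterwards.

Dropped triggers are logged with a reason, never raised.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .events import KIND_CONDITION, KIND_STIM, EventRecord, GateRule, gate_trigger

AMPLITUDE_RANGE_UA = (5.0, 10000.0)
WIDTH_RANGE_TICKS = (1, 1000)  # 0.01–10 ms at the 10 µs tick
TICKS_PER_SECOND = 100_000
DEFAULT_SWITCH_TICKS = 40  # 0.4 ms
DEFAULT_RATE_CAP = 500
FULL_AMPLITUDE_CAPS = {60: 350, 50: 700}


class WaveformError(ValueError):
    pass


@dataclass(frozen=True)
class StimWaveform:
    """Parametric biphasic waveform: delay, two phases, count, IPI, pins.

    Phases may be asymmetric in amplitude and width but must have
    opposite signs (net charge of a symmetric pulse is zero).  ``pins``
    is ``(anodal, cathodal)`` for differential output or ``(pin, None)``
    for single-ended.
    """

    waveform_id: int
    phase1_ua: float
    phase1_ticks: int
    phase2_ua: float
    phase2_ticks: int
    delay_ticks: int = 0
    count: int = 1
    ipi_ticks: int = 0
    pins: tuple[int, Optional[int]] = (0, 1)

    @property
    def pulse_ticks(self) -> int:
        """Duration of one biphasic pulse (phases are contiguous)."""
        return self.phase1_ticks + self.phase2_ticks

    @property
    def burst_mode(self) -> bool:
        return self.ipi_ticks == 0 and self.count > 1


def validate_waveform(w: StimWaveform) -> StimWaveform:
    """Check amplitude/width/pin constraints; returns the waveform."""
    lo, hi = AMPLITUDE_RANGE_UA
    for name, amp in (("phase1", w.phase1_ua), ("phase2", w.phase2_ua)):
        if not lo <= abs(amp) <= hi:
            raise WaveformError(
                f"{name} amplitude {amp} µA outside {lo}–{hi} µA"
            )
    if w.phase1_ua * w.phase2_ua >= 0:
        raise WaveformError("phases must have opposite signs")
    wlo, whi = WIDTH_RANGE_TICKS
    for name, width in (("phase1", w.phase1_ticks), ("phase2", w.phase2_ticks)):
        if not wlo <= width <= whi:
            raise WaveformError(
                f"{name} width {width} ticks outside {wlo}–{whi} "
                f"(0.01–10 ms)"
            )
    if not 0 <= w.waveform_id <= 5:
        raise WaveformError(f"waveform_id {w.waveform_id} outside 0–5")
    anodal, cathodal = w.pins
    if cathodal is not None and anodal == cathodal:
        raise WaveformError(f"anodal pin equals cathodal pin ({anodal})")
    for p in w.pins:
        if p is not None and not 0 <= p <= 5:
            raise WaveformError(f"pin {p} outside 0–5")
    if w.delay_ticks < 0 or w.count < 1 or w.ipi_ticks < 0:
        raise WaveformError("delay, count and ipi must be non-negative (count >= 1)")
    return w


@dataclass(frozen=True)
class StimCondition:
    """One of up to eight stimulation conditions.

    ``trigger_map`` maps event-generator ids to the waveform ids they
    trigger; ``gate_rules`` optionally attaches acceptance rules per
    generator id.
    """

    condition_id: int
    waveforms: tuple[StimWaveform, ...]
    trigger_map: dict[int, tuple[int, ...]] = field(default_factory=dict)
    gate_rules: dict[int, tuple[GateRule, ...]] = field(default_factory=dict)
    duration_ticks: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0 <= self.condition_id <= 7:
            raise WaveformError(f"condition_id {self.condition_id} outside 0–7")
        if len(self.waveforms) > 6:
            raise WaveformError(
                f"condition {self.condition_id}: {len(self.waveforms)} "
                f"waveforms exceeds 6"
            )
        ids = {w.waveform_id for w in self.waveforms}
        for gen, wf_ids in self.trigger_map.items():
            missing = set(wf_ids) - ids
            if missing:
                raise WaveformError(
                    f"trigger_map references unknown waveforms {sorted(missing)}"
                )

    def waveform(self, waveform_id: int) -> StimWaveform:
        for w in self.waveforms:
            if w.waveform_id == waveform_id:
                return w
        raise KeyError(waveform_id)


@dataclass(frozen=True)
class PulseInstance:
    """A concrete scheduled pulse on the shared current source."""

    onset: int  # ticks
    phase1_ua: float
    phase1_ticks: int
    phase2_ua: float
    phase2_ticks: int
    pins: tuple[int, Optional[int]]
    waveform_id: int
    trigger_ts: int
    compliance_limited: bool = False

    @property
    def end(self) -> int:
        return self.onset + self.phase1_ticks + self.phase2_ticks


@dataclass
class SchedulerState:
    """Mutable scheduler bookkeeping carried across trigger batches."""

    refractory_ticks: int = 0
    switch_ticks: int = DEFAULT_SWITCH_TICKS
    compliance_v: int = 60
    rate_cap: Optional[int] = None  # None → per-waveform cap
    busy_until: int = 0
    last_pins: Optional[tuple[int, Optional[int]]] = None
    refractory_until: int = 0
    pulse_log: list[int] = field(default_factory=list)  # onsets, sorted


def rate_cap_for(w: StimWaveform, compliance_v: int) -> int:
    """Sustained pulses-per-second limit for a waveform.

    Full-amplitude pulses (≥1 mA, ≥0.4 ms total) are limited by the
    stimulator supply: 350/s at ±60 V, 700/s at ±50 V.  Normal-amplitude
    pulses are limited to 500/s.
    """
    full = abs(w.phase1_ua) >= 1000.0 and w.pulse_ticks >= 40
    if full and compliance_v in FULL_AMPLITUDE_CAPS:
        return FULL_AMPLITUDE_CAPS[compliance_v]
    return DEFAULT_RATE_CAP


def schedule_pulses(
    triggers: Sequence[EventRecord],
    condition: StimCondition,
    state: SchedulerState,
    level_sources: Optional[dict[int, float]] = None,
    history: Optional[list[EventRecord]] = None,
) -> tuple[list[PulseInstance], list[tuple[EventRecord, str]]]:
    """Turn accepted trigger events into concrete pulses.

    ``triggers`` must be sorted by timestamp; ties between waveforms of
    one trigger are broken by ascending waveform id (first-come-first-
    served interleaving).  ``history`` is the accepted-trigger list the
    count gate rules look back over; passing it in lets a caller carry
    gating history across batches (it is extended in place).  Returns the
    scheduled pulses and a log of ``(trigger, reason)`` for every dropped
    train.
    """
    pulses: list[PulseInstance] = []
    rejected: list[tuple[EventRecord, str]] = []
    accepted_history: list[EventRecord] = history if history is not None else []

    for trig in triggers:
        wf_ids = condition.trigger_map.get(trig.source)
        if wf_ids is None:
            continue
        rules = condition.gate_rules.get(trig.source, ())
        ok, reason = gate_trigger(trig, rules, accepted_history, level_sources)
        if not ok:
            rejected.append((trig, reason))
            continue
        # Refractory as it stood before this trigger: trains belonging to
        # the same trigger interleave instead of blocking each other.
        refractory_before = state.refractory_until
        any_train = False
        for wf_id in sorted(wf_ids):
            w = condition.waveform(wf_id)
            train_onset = trig.timestamp + w.delay_ticks
            # interleave shift of the first pulse determines the train onset
            first_onset = _next_slot(state, train_onset, w.pins)
            if first_onset < refractory_before:
                rejected.append(
                    (trig, f"refractory: waveform {wf_id} onset {first_onset} "
                           f"< {refractory_before}")
                )
                continue
            cap = state.rate_cap or rate_cap_for(w, state.compliance_v)
            window_lo = first_onset - TICKS_PER_SECOND
            in_window = sum(1 for t in state.pulse_log if window_lo < t <= first_onset)
            if in_window >= cap:
                rejected.append(
                    (trig, f"rate_cap: {in_window} pulses in past 1 s >= {cap}")
                )
                continue
            any_train = True
            onset = first_onset
            for k in range(w.count):
                if k > 0:
                    nominal = (
                        first_onset + k * w.ipi_ticks
                        if w.ipi_ticks > 0
                        else pulses[-1].end
                    )
                    onset = _next_slot(state, nominal, w.pins)
                pulses.append(
                    PulseInstance(
                        onset=onset,
                        phase1_ua=w.phase1_ua,
                        phase1_ticks=w.phase1_ticks,
                        phase2_ua=w.phase2_ua,
                        phase2_ticks=w.phase2_ticks,
                        pins=w.pins,
                        waveform_id=wf_id,
                        trigger_ts=trig.timestamp,
                    )
                )
                state.busy_until = onset + w.pulse_ticks
                state.last_pins = w.pins
                state.pulse_log.append(onset)
            if state.refractory_ticks > 0:
                state.refractory_until = max(
                    state.refractory_until,
                    first_onset + state.refractory_ticks,
                )
        if any_train:
            accepted_history.append(trig)
    return pulses, rejected


def _next_slot(
    state: SchedulerState, onset: int, pins: tuple[int, Optional[int]]
) -> int:
    """First tick at/after ``onset`` when the shared source is free.

    Switching pin pairs costs ``switch_ticks`` after the previous pulse
    ends; same-pin pulses may abut with no gap.
    """
    if onset >= state.busy_until:
        return onset
    gap = state.switch_ticks if state.last_pins not in (None, pins) else 0
    return state.busy_until + gap


def sequence_conditions(
    conditions: Sequence[StimCondition],
    total_ticks: int,
) -> tuple[list[tuple[int, int, int]], list[EventRecord]]:
    """Time-based progression through the configured conditions.

    Each condition runs for its ``duration_ticks`` (a ``None`` duration
    holds until the end of the session); exactly one condition is active
    at any tick.  Returns ``(segments, transition_records)`` with
    segments as ``(start, end, condition_id)`` half-open intervals and one
    condition-transition record per segment start (including the initial
    one at tick 0).
    """
    if not conditions:
        raise ValueError("at least one condition is required")
    if len(conditions) > 8:
        raise WaveformError(f"{len(conditions)} conditions exceeds 8")
    segments: list[tuple[int, int, int]] = []
    records: list[EventRecord] = []
    t = 0
    for i, cond in enumerate(conditions):
        if t >= total_ticks:
            break
        end = (
            total_ticks
            if cond.duration_ticks is None or i == len(conditions) - 1
            else min(t + cond.duration_ticks, total_ticks)
        )
        segments.append((t, end, cond.condition_id))
        records.append(EventRecord(t, cond.condition_id, KIND_CONDITION))
        t = end
    return segments, records


def render_monitor_trace(
    pulses: Sequence[PulseInstance],
    load_ohms: float,
    compliance_v: float,
    fs: float,
    duration_ticks: int,
    tick_us: int = 10,
) -> tuple[np.ndarray, list[bool]]:
    """Voltage on the stimulus-monitor channel: V = I·R, clipped to compliance.

    Returns the sampled voltage trace (volts) and one flag per pulse
    marking compliance-limited delivery (commanded current could not be
    driven through the load).
    """
    if load_ohms <= 0:
        raise ValueError(f"load_ohms must be positive, got {load_ohms}")
    ticks_per_sample = int(round(1_000_000 / fs)) // tick_us
    n = duration_ticks // ticks_per_sample + 1
    trace = np.zeros(n)
    flags: list[bool] = []
    for p in pulses:
        limited = False
        t0 = p.onset
        for amp, width in (
            (p.phase1_ua, p.phase1_ticks),
            (p.phase2_ua, p.phase2_ticks),
        ):
            v = amp * 1e-6 * load_ohms
            if abs(v) > compliance_v:
                limited = True
                v = np.sign(v) * compliance_v
            first = -(-t0 // ticks_per_sample)
            last = -(-(t0 + width) // ticks_per_sample)
            trace[max(first, 0) : min(last, n)] = v
            t0 += width
        flags.append(limited)
    return trace, flags


def pulse_records(pulses: Sequence[PulseInstance]) -> list[EventRecord]:
    """Stimulus-event records (one per pulse) for the session stream."""
    return [
        EventRecord(p.onset, p.pins[0], KIND_STIM) for p in pulses
    ]
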