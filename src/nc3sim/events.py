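"""Event generators, dual time-amplitude window discrimination, gating.

The control firmware runs up to eight *event generators*.  Each either
emits events on a schedule (fixed period, or random gaps drawn uniform or
exponential) or acts as a *window discriminator*: a threshold crossing on
a sampled signal is accepted as a spike only if the samples at one or two
configured delays after the crossing fall inside their amplitude windows.
Accepted events may then be gated by history or signal-level rules before
triggering stimulation.

Semantics pinned here (the classic hardware leaves them implicit):

* a crossing is a sign change of ``sample − threshold`` between
  consecutive samples, with the configured polarity; no sub-sample
  interpolation;
* each window tests the single sample at exactly ``crossing + delay``,
  amplitude bounds closed;
* crossings within ``dead_time`` of a previous *accepted* event, or
  inside a blanking interval, are ignored (default dead time 1 ms);
* count-rule lookback is the half-open interval ``(t − L, t]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

# Record kinds, matching the four timestamp classes of the session format.
KIND_DIGITAL = "digital_event"
KIND_CONDITION = "condition_transition"
KIND_STIM = "stimulus_event"
KIND_NETWORK = "network_event"


@dataclass(frozen=True, order=True)
class EventRecord:
    """A timestamped discrete event; totally ordered by (timestamp, source)."""

    timestamp: int  # ticks
    source: int  # generator id / stim channel / condition id / unit index
    kind: str = KIND_DIGITAL

    def __post_init__(self) -> None:
        if self.timestamp < 0:
            raise ValueError(f"negative timestamp {self.timestamp}")


@dataclass(frozen=True)
class Window:
    """One time-amplitude box: sample at ``delay_ticks`` after the crossing
    must lie in ``[amp_min, amp_max]`` (closed)."""

    delay_ticks: int
    amp_min: int
    amp_max: int

    def __post_init__(self) -> None:
        if self.delay_ticks <= 0:
            raise ValueError("window delay must be positive")
        if self.amp_min > self.amp_max:
            raise ValueError(f"amp_min {self.amp_min} > amp_max {self.amp_max}")


@dataclass(frozen=True)
class WindowDiscSpec:
    """Threshold + up to two time-amplitude windows + dead time.

    ``windows`` may be empty for a plain threshold detector; the hardware
    always uses one or two windows, but threshold-only mode is useful for
    minimum-latency loops and costs nothing to support.
    """

    threshold: int
    polarity: str = "rising"  # "rising" | "falling"
    windows: tuple[Window, ...] = ()
    dead_time_ticks: int = 100  # 1 ms at the default 10 µs tick

    def __post_init__(self) -> None:
        if self.polarity not in ("rising", "falling"):
            raise ValueError(f"unknown polarity {self.polarity!r}")
        if len(self.windows) > 2:
            raise ValueError("at most two windows")
        delays = [w.delay_ticks for w in self.windows]
        if sorted(delays) != delays or len(set(delays)) != len(delays):
            raise ValueError("window delays must be strictly increasing")
        if self.dead_time_ticks < 0:
            raise ValueError("dead_time must be >= 0")


@dataclass(frozen=True)
class EventGeneratorSpec:
    """One of the eight firmware event generators."""

    gen_id: int
    mode: str  # fixed_interval | uniform_interval | exponential_interval |
    #            window_discriminator | snn_output
    period_ticks: Optional[int] = None  # fixed mode
    uniform_ticks: Optional[tuple[int, int]] = None  # uniform mode [lo, hi]
    mean_ticks: Optional[float] = None  # exponential mode
    source: Optional[int | tuple[str, int]] = None  # channel, or ("slot", id)
    discriminator: Optional[WindowDiscSpec] = None

    def __post_init__(self) -> None:
        if not 0 <= self.gen_id <= 7:
            raise ValueError(f"gen_id {self.gen_id} outside 0–7")
        modes = (
            "fixed_interval",
            "uniform_interval",
            "exponential_interval",
            "window_discriminator",
            "snn_output",
        )
        if self.mode not in modes:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "fixed_interval" and (
            self.period_ticks is None or self.period_ticks <= 0
        ):
            raise ValueError("fixed_interval needs positive period_ticks")
        if self.mode == "uniform_interval":
            if self.uniform_ticks is None:
                raise ValueError("uniform_interval needs uniform_ticks")
            lo, hi = self.uniform_ticks
            if lo <= 0 or hi < lo:
                raise ValueError(f"bad uniform bounds [{lo}, {hi}]")
        if self.mode == "exponential_interval" and (
            self.mean_ticks is None or self.mean_ticks <= 0
        ):
            raise ValueError("exponential_interval needs positive mean_ticks")
        if self.mode == "window_discriminator" and self.discriminator is None:
            raise ValueError("window_discriminator needs a discriminator spec")


def generate_interval_events(
    spec: EventGeneratorSpec,
    duration_ticks: int,
    rng: Optional[np.random.Generator] = None,
) -> list[EventRecord]:
    """Emit scheduled events over ``[0, duration]``.

    The first event falls one gap after session start.  Random gaps are
    drawn i.i.d. (uniform on [lo, hi] or exponential with the given mean)
    and rounded to whole ticks, floored at one tick so events keep
    strictly increasing timestamps.
    """
    if spec.mode == "fixed_interval":
        p = spec.period_ticks
        return [
            EventRecord(t, spec.gen_id)
            for t in range(p, duration_ticks + 1, p)
        ]
    if rng is None:
        raise ValueError(f"{spec.mode} requires an rng")
    events: list[EventRecord] = []
    t = 0
    while True:
        if spec.mode == "uniform_interval":
            lo, hi = spec.uniform_ticks
            gap = int(np.rint(rng.uniform(lo, hi)))
        elif spec.mode == "exponential_interval":
            gap = int(np.rint(rng.exponential(spec.mean_ticks)))
        else:
            raise ValueError(f"{spec.mode} is not an interval mode")
        t += max(gap, 1)
        if t > duration_ticks:
            return events
        events.append(EventRecord(t, spec.gen_id))


def discriminate_spikes(
    codes: np.ndarray,
    spec: WindowDiscSpec,
    ticks_per_sample: int,
    blanking: Sequence[tuple[int, int]] = (),
    gen_id: int = 0,
) -> list[EventRecord]:
    """Run the dual time-amplitude window discriminator over a trace.

    Sample ``i`` sits at tick ``i * ticks_per_sample``.  An event is
    emitted at the crossing sample iff every configured window accepts the
    sample at its delay; delays must be whole samples.  Events inside
    blanking intervals (half-open, in ticks) or within the dead time of
    the previous accepted event are suppressed.
    """
    x = np.asarray(codes)
    delays_samp = []
    for w in spec.windows:
        if w.delay_ticks % ticks_per_sample:
            raise ValueError(
                f"window delay {w.delay_ticks} ticks is not a multiple of "
                f"the sample period ({ticks_per_sample} ticks)"
            )
        delays_samp.append(w.delay_ticks // ticks_per_sample)

    above = x >= spec.threshold
    if spec.polarity == "rising":
        crossings = np.flatnonzero(~above[:-1] & above[1:]) + 1
    else:
        below = x <= spec.threshold
        crossings = np.flatnonzero(~below[:-1] & below[1:]) + 1

    events: list[EventRecord] = []
    last_accept = None
    n = len(x)
    for i in crossings:
        t = int(i) * ticks_per_sample
        if last_accept is not None and t - last_accept < spec.dead_time_ticks:
            continue
        if any(lo <= t < hi for lo, hi in blanking):
            continue
        ok = True
        for w, d in zip(spec.windows, delays_samp):
            j = i + d
            if j >= n or not (w.amp_min <= x[j] <= w.amp_max):
                ok = False
                break
        if ok:
            events.append(EventRecord(t, gen_id))
            last_accept = t
    return events


@dataclass(frozen=True)
class GateRule:
    """Trigger-acceptance rule.

    ``count_in_window``: reject when the number of history events in
    ``(t − lookback, t]`` reaches ``max_events`` (or falls short of
    ``min_events``).  ``level_inside`` / ``level_outside``: require the
    current value of ``source`` to lie inside / outside ``[min, max]``.
    """

    kind: str  # count_in_window | level_inside | level_outside
    lookback_ticks: Optional[int] = None
    max_events: Optional[int] = None
    min_events: Optional[int] = None
    source: Optional[int] = None
    level_min: Optional[float] = None
    level_max: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind == "count_in_window":
            if self.lookback_ticks is None or self.lookback_ticks <= 0:
                raise ValueError("count rule needs positive lookback_ticks")
            if self.max_events is None and self.min_events is None:
                raise ValueError("count rule needs max_events or min_events")
        elif self.kind in ("level_inside", "level_outside"):
            if self.level_min is None or self.level_max is None:
                raise ValueError("level rule needs level_min and level_max")
        else:
            raise ValueError(f"unknown gate kind {self.kind!r}")


def gate_trigger(
    candidate: EventRecord,
    rules: Sequence[GateRule],
    history: Sequence[EventRecord] = (),
    level_sources: Optional[dict[int, float]] = None,
) -> tuple[bool, Optional[str]]:
    """Accept the candidate iff every rule passes.

    ``history`` must be sorted by timestamp; ``level_sources`` maps source
    ids to their current analog value.  Returns ``(accepted, reason)``
    with ``reason`` naming the failed rule on rejection.  An empty rule
    list accepts.
    """
    t = candidate.timestamp
    for rule in rules:
        if rule.kind == "count_in_window":
            lo = t - rule.lookback_ticks
            count = sum(1 for e in history if lo < e.timestamp <= t)
            if rule.max_events is not None and count >= rule.max_events:
                return False, f"count_in_window: {count} >= {rule.max_events}"
            if rule.min_events is not None and count < rule.min_events:
                return False, f"count_in_window: {count} < {rule.min_events}"
        else:
            if level_sources is None or rule.source not in level_sources:
                return False, f"{rule.kind}: source {rule.source} unavailable"
            v = level_sources[rule.source]
            inside = rule.level_min <= v <= rule.level_max
            if rule.kind == "level_inside" and not inside:
                return False, f"level_inside: {v} outside [{rule.level_min}, {rule.level_max}]"
            if rule.kind == "level_outside" and inside:
                return False, f"level_outside: {v} inside [{rule.level_min}, {rule.level_max}]"
    return True, None


def merge_event_streams(*streams: Sequence[EventRecord]) -> list[EventRecord]:
    """Merge per-source streams into one stream sorted by (timestamp, source)."""
    merged: list[EventRecord] = []
    for s in streams:
        merged.extend(s)
    merged.sort()
    return merged
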