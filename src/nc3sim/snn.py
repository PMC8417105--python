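"""Fixed-point integrate-and-fire spiking neural network.

Emulates, bit for bit, the on-board network engine: up to 256 units and
2,000 connection weights, updated 10,000 times per simulated second.
Unit potentials, weights, bias strength and the firing threshold are
signed 16-bit values in µV; the two PSP decay constants and the bias
chance are Q16 fixed-point fractions in [0, 1).  Each unit keeps a fast
and a slow leaky integrator; their difference is an alpha-like PSP, and
a unit fires when ``slow − fast`` strictly exceeds the threshold θ, after
which both potentials reset to zero and the spike enters a delay queue
(conduction delay up to 35 steps = 3.5 ms).

Update order within one 0.1 ms step:

1. decay: each potential becomes ``floor(p · d / 2^16)`` — the most
   significant 16 bits of the 32-bit product, with arithmetic-shift
   (floor toward −∞) semantics for negative potentials;
2. spike delivery: for every delayed spike due this step, the connection
   weight is added to the target's fast *and* slow potentials with
   saturating int16 arithmetic (no wraparound);
3. bias: per unit, one pseudo-random Q16 draw; if it is below the bias
   chance, the bias strength is added to both potentials;
4. threshold: units with ``slow − fast > θ`` enqueue a spike and zero
   both potentials.

External spikes from the eight event generators enter as sources −1…−8
and are delivered in sub-step 2 of the step they are presented to
(:func:`route_io` maps an event at tick T to the next step boundary, so
an event always acts one step later).  The bias PRNG is one xorshift32
stream per unit, seeded from the session seed; the top 16 bits of each
draw are compared against the bias chance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .events import KIND_NETWORK, EventRecord

MAX_UNITS = 256
MAX_CONNECTIONS = 2000
MAX_DELAY_STEPS = 35  # 3.5 ms at 0.1 ms per step
STEPS_PER_SECOND = 10_000
N_EXTERNAL = 8
N_OUTPUT_UNITS = 16  # spikes of the first 16 units are recorded
N_IO_UNITS = 8  # the first 8 units map to the event generators

INT16_MIN, INT16_MAX = -32768, 32767
Q16_MAX = 65535


class NetworkError(ValueError):
    pass


@dataclass(frozen=True)
class SnnGlobals:
    """Global parameters shared by every unit."""

    conduction_delay: int = 10  # steps
    fast_decay: int = 32768  # Q16
    slow_decay: int = 58982  # Q16
    bias_chance: int = 0  # Q16
    bias_strength: int = 0  # µV, int16
    threshold: int = 1000  # µV, int16

    def __post_init__(self) -> None:
        if not 1 <= self.conduction_delay <= MAX_DELAY_STEPS:
            raise NetworkError(
                f"conduction_delay {self.conduction_delay} steps outside "
                f"1–{MAX_DELAY_STEPS} (3.5 ms max)"
            )
        for name in ("fast_decay", "slow_decay", "bias_chance"):
            v = getattr(self, name)
            if not 0 <= v <= Q16_MAX:
                raise NetworkError(f"{name} {v} outside Q16 range 0–{Q16_MAX}")
        for name in ("bias_strength", "threshold"):
            v = getattr(self, name)
            if not INT16_MIN <= v <= INT16_MAX:
                raise NetworkError(f"{name} {v} outside int16 range")


@dataclass(frozen=True)
class Connection:
    """Weighted connection; negative sources −1…−8 are the event generators."""

    source: int
    target: int
    weight: int  # µV, int16

    def __post_init__(self) -> None:
        if self.source < -N_EXTERNAL:
            raise NetworkError(
                f"source {self.source}: external sources are −1…−{N_EXTERNAL}"
            )
        if not INT16_MIN <= self.weight <= INT16_MAX:
            raise NetworkError(f"weight {self.weight} outside int16 range")


@dataclass(frozen=True)
class SnnNetwork:
    n_units: int
    globals: SnnGlobals = field(default_factory=SnnGlobals)
    connections: tuple[Connection, ...] = ()


def build_network(
    n_units: int,
    connections: Iterable[tuple[int, int, int]] | Iterable[Connection] = (),
    globals: Optional[SnnGlobals] = None,
) -> SnnNetwork:
    """Validate a network description.

    Raises :class:`NetworkError` for more than 256 units, more than 2,000
    connections, external sources outside −1…−8, targets out of range, or
    a conduction delay above 3.5 ms.
    """
    if not 1 <= n_units <= MAX_UNITS:
        raise NetworkError(f"n_units {n_units} outside 1–{MAX_UNITS}")
    conns = tuple(
        c if isinstance(c, Connection) else Connection(*c) for c in connections
    )
    if len(conns) > MAX_CONNECTIONS:
        raise NetworkError(
            f"{len(conns)} connections exceeds {MAX_CONNECTIONS}"
        )
    for c in conns:
        if c.source >= n_units:
            raise NetworkError(f"source unit {c.source} >= n_units {n_units}")
        if not 0 <= c.target < n_units:
            raise NetworkError(f"target unit {c.target} outside 0–{n_units - 1}")
    g = globals if globals is not None else SnnGlobals()
    return SnnNetwork(n_units=n_units, globals=g, connections=conns)


def decay_fixed_point(p: int, d: int) -> int:
    """One fixed-point decay: most significant 16 bits of the product.

    ``floor(p · d / 2^16)`` with floor toward −∞, matching an arithmetic
    right shift of the signed 32-bit product.
    """
    return (int(p) * int(d)) >> 16


def _saturate(v: np.ndarray) -> np.ndarray:
    return np.clip(v, INT16_MIN, INT16_MAX)


class SnnState:
    """Mutable engine state: potentials, delay queues, per-unit PRNG."""

    def __init__(self, net: SnnNetwork, seed: int = 0):
        self.net = net
        n = net.n_units
        self.v_fast = np.zeros(n, dtype=np.int64)
        self.v_slow = np.zeros(n, dtype=np.int64)
        d = net.globals.conduction_delay
        # ring buffer: queue[q, u] — spike fired by unit u, due when the
        # ring pointer reaches row q
        self.queue = np.zeros((d, n), dtype=bool)
        self.qhead = 0
        self.step_count = 0
        # per-unit xorshift32 states (never zero)
        ss = np.random.SeedSequence([seed & 0x7FFFFFFF, 0x534E4E])
        self.prng_state = ss.generate_state(n, dtype=np.uint32) | 1
        # incoming connections grouped by source for fast delivery
        self._by_source: dict[int, list[tuple[int, int]]] = {}
        for c in net.connections:
            self._by_source.setdefault(c.source, []).append((c.target, c.weight))

    def _draw_bias(self) -> np.ndarray:
        """One xorshift32 draw per unit; top 16 bits are the Q16 value."""
        x = self.prng_state
        x ^= (x << np.uint32(13)) & np.uint32(0xFFFFFFFF)
        x ^= x >> np.uint32(17)
        x ^= (x << np.uint32(5)) & np.uint32(0xFFFFFFFF)
        self.prng_state = x
        return (x >> np.uint32(16)).astype(np.int64)


def step_network(
    state: SnnState,
    external_spikes: Optional[Sequence[bool]] = None,
) -> np.ndarray:
    """Advance the network one 0.1 ms step.

    ``external_spikes`` holds the eight generator flags delivered this
    step (sources −1…−8).  Returns the indices (within the first 16
    units) that fired this step.
    """
    net = state.net
    g = net.globals
    fd, sd = g.fast_decay, g.slow_decay

    # 1. decay, keeping the most significant 16 bits of the product
    state.v_fast = (state.v_fast * fd) >> 16
    state.v_slow = (state.v_slow * sd) >> 16

    # 2. delayed spike delivery with saturating int16 addition
    due = state.queue[state.qhead]
    sources: list[int] = [int(u) for u in np.flatnonzero(due)]
    if external_spikes is not None:
        sources.extend(
            -(i + 1) for i, flag in enumerate(external_spikes[:N_EXTERNAL]) if flag
        )
    for src in sources:
        for target, weight in state._by_source.get(src, ()):
            state.v_fast[target] = min(
                INT16_MAX, max(INT16_MIN, state.v_fast[target] + weight)
            )
            state.v_slow[target] = min(
                INT16_MAX, max(INT16_MIN, state.v_slow[target] + weight)
            )

    # 3. bias spikes: one pseudo-random Q16 draw per unit per step
    draws = state._draw_bias()
    if g.bias_chance > 0:
        hit = draws < g.bias_chance
        if hit.any():
            state.v_fast = _saturate(state.v_fast + hit * g.bias_strength)
            state.v_slow = _saturate(state.v_slow + hit * g.bias_strength)

    # 4. threshold: slow − fast strictly above θ fires and resets
    fired = (state.v_slow - state.v_fast) > g.threshold
    state.queue[state.qhead] = False  # slot now holds spikes due in d steps
    state.queue[state.qhead, fired] = True
    state.v_fast[fired] = 0
    state.v_slow[fired] = 0

    state.qhead = (state.qhead + 1) % state.queue.shape[0]
    state.step_count += 1
    out = np.flatnonzero(fired[: min(N_OUTPUT_UNITS, net.n_units)])
    return out


def run_network(
    net: SnnNetwork,
    n_steps: int,
    external: Optional[np.ndarray] = None,
    seed: int = 0,
) -> list[tuple[int, int]]:
    """Run ``n_steps`` updates; returns a raster of (step, unit) spikes
    for the first 16 units.  ``external`` is an (n_steps, 8) flag array.
    One simulated second is exactly 10,000 steps."""
    state = SnnState(net, seed=seed)
    raster: list[tuple[int, int]] = []
    for t in range(n_steps):
        ext = external[t] if external is not None else None
        for u in step_network(state, ext):
            raster.append((t, int(u)))
    return raster


def route_events_to_steps(
    events: Sequence[EventRecord], n_steps: int, step_ticks: int
) -> np.ndarray:
    """Map generator events to per-step external spike flags.

    An event from generator g at tick T becomes an external spike from
    source −(g+1) on the *next* step boundary: step ``T // step_ticks + 1``.
    """
    flags = np.zeros((n_steps, N_EXTERNAL), dtype=bool)
    for e in events:
        if not 0 <= e.source < N_EXTERNAL:
            raise ValueError(f"generator id {e.source} outside 0–7")
        step = e.timestamp // step_ticks + 1
        if step < n_steps:
            flags[step, e.source] = True
    return flags


def raster_to_records(
    raster: Sequence[tuple[int, int]], step_ticks: int
) -> list[EventRecord]:
    """Network-event records for the session: spikes of units 0–15."""
    return [
        EventRecord(step * step_ticks, unit, KIND_NETWORK)
        for step, unit in raster
        if unit < N_OUTPUT_UNITS
    ]


def output_activations(
    raster: Sequence[tuple[int, int]], step_ticks: int
) -> list[EventRecord]:
    """Spikes of units 0–7 delivered back as event-generator activations."""
    return [
        EventRecord(step * step_ticks, unit)
        for step, unit in raster
        if unit < N_IO_UNITS
    ]
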