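"""Master timebase and experiment-configuration validation.

Everything downstream of the config works in integer *ticks* of the master
clock (default 10 µs), so that module clocks — ADC sampling at 5/10/20 kSps
(200/100/50 µs), the network simulation step (100 µs) and the minimum
stimulus phase width (10 µs) — are exact integer multiples and every event
timestamp is an exact integer.  No wall-clock time appears anywhere.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

SUPPORTED_SAMPLE_RATES = (5000, 10000, 20000)
SNN_STEP_US = 100
MAX_EVENT_GENERATORS = 8
MAX_CONDITIONS = 8
MAX_WAVEFORMS_PER_CONDITION = 6


class ConfigError(ValueError):
    """Raised when a configuration violates a device constraint.

    The message always names the offending field.
    """


@dataclass(frozen=True)
class Timebase:
    """Master clock: all timestamps are integer multiples of ``tick_us``."""

    tick_us: int = 10

    def __post_init__(self) -> None:
        if self.tick_us <= 0:
            raise ConfigError(f"tick_us: must be positive, got {self.tick_us}")
        for rate in SUPPORTED_SAMPLE_RATES:
            period_us = 1_000_000 // rate
            if period_us * rate != 1_000_000 or period_us % self.tick_us:
                raise ConfigError(
                    f"tick_us: {self.tick_us} does not divide the "
                    f"{rate} Sps sample period ({period_us} µs)"
                )
        if SNN_STEP_US % self.tick_us:
            raise ConfigError(
                f"tick_us: {self.tick_us} does not divide the network step "
                f"({SNN_STEP_US} µs)"
            )

    def ticks_per_sample(self, sample_rate: int) -> int:
        """Sample period of an ADC channel, in ticks."""
        if sample_rate not in SUPPORTED_SAMPLE_RATES:
            raise ConfigError(
                f"sample_rate: {sample_rate} not in {SUPPORTED_SAMPLE_RATES}"
            )
        return (1_000_000 // sample_rate) // self.tick_us

    @property
    def snn_step_ticks(self) -> int:
        """Network simulation step (0.1 ms) in ticks."""
        return SNN_STEP_US // self.tick_us

    @property
    def ticks_per_second(self) -> int:
        return 1_000_000 // self.tick_us

    def ms_to_ticks(self, ms: float) -> int:
        return int(round(ms * 1000.0 / self.tick_us))

    def us_to_ticks(self, us: float) -> int:
        return int(round(us / self.tick_us))

    def s_to_ticks(self, s: float) -> int:
        return int(round(s * 1_000_000 / self.tick_us))


@dataclass(frozen=True)
class ChannelConfig:
    """One recording channel of the biosignal front-end."""

    channel_id: int
    mode: str = "single_ended"  # "differential" | "single_ended"
    sample_rate: int = 20000
    enabled: bool = True

    def __post_init__(self) -> None:
        if self.mode not in ("differential", "single_ended"):
            raise ConfigError(f"mode: unknown channel mode {self.mode!r}")
        if self.sample_rate not in SUPPORTED_SAMPLE_RATES:
            raise ConfigError(
                f"sample_rate: {self.sample_rate} not in "
                f"{SUPPORTED_SAMPLE_RATES}"
            )
        if self.channel_id < 0:
            raise ConfigError(f"channel_id: must be non-negative")


@dataclass
class DeviceConfig:
    """Complete experiment description.

    ``event_generators``, ``conditions`` and ``snn`` hold specs from the
    :mod:`~nc3sim.events`, :mod:`~nc3sim.stimulator` and :mod:`~nc3sim.snn`
    modules; they are kept untyped here to avoid circular imports and are
    validated by :func:`validate_config`.
    """

    channels: list[ChannelConfig]
    timebase: Timebase = field(default_factory=Timebase)
    bandpass: tuple[float, float] = (0.1, 5000.0)
    event_generators: list = field(default_factory=list)
    conditions: list = field(default_factory=list)
    snn: Optional[object] = None
    seed: int = 0
    refractory_ms: float = 10.0
    compliance_v: int = 60
    fast_settle_us: Optional[float] = None
    validated: bool = False

    def rng_stream(self, component: str) -> np.random.Generator:
        """Independent, reproducible random stream for one component.

        Streams are derived from ``(seed, crc32(component))`` so each
        stochastic module is reproducible in isolation.
        """
        return np.random.default_rng(
            np.random.SeedSequence([self.seed, zlib.crc32(component.encode())])
        )

    def enabled_channels(self) -> list[ChannelConfig]:
        return [c for c in self.channels if c.enabled]


def validate_config(config: DeviceConfig) -> DeviceConfig:
    """Check every device constraint and return the normalized config.

    Validation is idempotent: validating an already-validated config
    returns an equal object.  Raises :class:`ConfigError` naming the
    offending field on any violation.
    """
    enabled = config.enabled_channels()
    n_diff = sum(1 for c in enabled if c.mode == "differential")
    n_single = sum(1 for c in enabled if c.mode == "single_ended")
    # 16 bipolar or 32 unipolar front-end inputs; a differential channel
    # consumes two inputs.
    if 2 * n_diff + n_single > 32:
        raise ConfigError(
            f"channels: channel-count violation — {n_diff} differential + "
            f"{n_single} single-ended exceeds the 16-differential/"
            f"32-single-ended amplifier budget"
        )
    ids = [c.channel_id for c in config.channels]
    if len(set(ids)) != len(ids):
        raise ConfigError("channels: duplicate channel_id")

    low, high = config.bandpass
    if not (0.1 <= low <= 2000.0):
        raise ConfigError(f"bandpass: low_cut {low} Hz outside [0.1, 2000]")
    if not (100.0 <= high <= 20000.0):
        raise ConfigError(f"bandpass: high_cut {high} Hz outside [100, 20000]")
    if low >= high:
        raise ConfigError(f"bandpass: low_cut {low} >= high_cut {high}")
    if enabled:
        min_rate = min(c.sample_rate for c in enabled)
        if high >= min_rate / 2:
            raise ConfigError(
                f"bandpass: Nyquist violation — high_cut {high} Hz is not "
                f"below half the lowest sample rate ({min_rate} Sps)"
            )
    if len(config.event_generators) > MAX_EVENT_GENERATORS:
        raise ConfigError(
            f"event_generators: {len(config.event_generators)} exceeds "
            f"{MAX_EVENT_GENERATORS}"
        )
    if len(config.conditions) > MAX_CONDITIONS:
        raise ConfigError(
            f"conditions: {len(config.conditions)} exceeds {MAX_CONDITIONS}"
        )
    for cond in config.conditions:
        waveforms = getattr(cond, "waveforms", [])
        if len(waveforms) > MAX_WAVEFORMS_PER_CONDITION:
            raise ConfigError(
                f"conditions: condition {getattr(cond, 'condition_id', '?')} "
                f"has {len(waveforms)} waveforms, exceeds "
                f"{MAX_WAVEFORMS_PER_CONDITION}"
            )
    if config.refractory_ms < 0:
        raise ConfigError(f"refractory_ms: must be >= 0")
    if config.compliance_v not in (50, 60):
        raise ConfigError(
            f"compliance_v: {config.compliance_v} not in (50, 60)"
        )
    if config.fast_settle_us is not None and not (
        200 <= config.fast_settle_us <= 3200
    ):
        raise ConfigError(
            f"fast_settle_us: {config.fast_settle_us} outside [200, 3200]"
        )
    return replace(config, validated=True) if not config.validated else config


def storage_budget(
    n_channels: int,
    rates: int | Sequence[int],
    duration_s: float,
    bytes_per_sample: int = 2,
) -> int:
    """Analog-payload storage requirement, in bytes.

    ``rates`` may be a single rate applied to all channels or one rate per
    channel.  Exact integer arithmetic when all inputs are integral;
    timestamp-record overhead is not included (it depends on event rates
    and is reported separately by the session writer).
    """
    if n_channels <= 0:
        raise ValueError(f"n_channels must be positive, got {n_channels}")
    if duration_s <= 0:
        raise ValueError(f"duration_s must be positive, got {duration_s}")
    if bytes_per_sample <= 0:
        raise ValueError(
            f"bytes_per_sample must be positive, got {bytes_per_sample}"
        )
    if np.isscalar(rates):
        rate_list = [rates] * n_channels
    else:
        rate_list = list(rates)
        if len(rate_list) != n_channels:
            raise ValueError(
                f"rates has {len(rate_list)} entries for {n_channels} channels"
            )
    total = 0
    for r in rate_list:
        if r <= 0:
            raise ValueError(f"rate must be positive, got {r}")
        total += int(r * duration_s) * bytes_per_sample
    return total
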