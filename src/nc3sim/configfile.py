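"""Structured-text experiment configuration: dict/YAML round-trip.

One YAML (or plain dict) document describes the whole experiment, in
four groups mirroring the instrument's setup tabs: record settings,
event generators, stimulation conditions, and the spiking network.  Time
quantities in the file are in the natural units named by the key suffix
(``_ms``, ``_us``, ``_hz``); everything is converted to integer ticks on
load.
"""

from __future__ import annotations

from typing import Any, Optional

import yaml

from .config import ChannelConfig, ConfigError, DeviceConfig, Timebase, validate_config
from .events import EventGeneratorSpec, GateRule, Window, WindowDiscSpec
from .snn import Connection, SnnGlobals, SnnNetwork, build_network
from .stimulator import StimCondition, StimWaveform


def _window_from_dict(d: dict, tb: Timebase) -> Window:
    return Window(
        delay_ticks=tb.ms_to_ticks(d["delay_ms"]),
        amp_min=int(d["amp_min"]),
        amp_max=int(d["amp_max"]),
    )


def _disc_from_dict(d: dict, tb: Timebase) -> WindowDiscSpec:
    return WindowDiscSpec(
        threshold=int(d["threshold"]),
        polarity=d.get("polarity", "rising"),
        windows=tuple(_window_from_dict(w, tb) for w in d.get("windows", [])),
        dead_time_ticks=tb.ms_to_ticks(d.get("dead_time_ms", 1.0)),
    )


def generator_from_dict(d: dict, tb: Timebase) -> EventGeneratorSpec:
    mode = d["mode"]
    kwargs: dict[str, Any] = {"gen_id": int(d["gen_id"]), "mode": mode}
    if mode == "fixed_interval":
        kwargs["period_ticks"] = tb.ms_to_ticks(d["period_ms"])
    elif mode == "uniform_interval":
        lo, hi = d["range_ms"]
        kwargs["uniform_ticks"] = (tb.ms_to_ticks(lo), tb.ms_to_ticks(hi))
    elif mode == "exponential_interval":
        kwargs["mean_ticks"] = d["mean_ms"] * 1000.0 / tb.tick_us
    elif mode == "window_discriminator":
        kwargs["source"] = d["source"]
        kwargs["discriminator"] = _disc_from_dict(d["discriminator"], tb)
    return EventGeneratorSpec(**kwargs)


def waveform_from_dict(d: dict, tb: Timebase) -> StimWaveform:
    pins = d.get("pins", [0, 1])
    return StimWaveform(
        waveform_id=int(d["waveform_id"]),
        phase1_ua=float(d["phase1_ua"]),
        phase1_ticks=tb.ms_to_ticks(d["phase1_ms"]),
        phase2_ua=float(d["phase2_ua"]),
        phase2_ticks=tb.ms_to_ticks(d["phase2_ms"]),
        delay_ticks=tb.ms_to_ticks(d.get("delay_ms", 0.0)),
        count=int(d.get("count", 1)),
        ipi_ticks=tb.ms_to_ticks(d.get("ipi_ms", 0.0)),
        pins=(pins[0], pins[1] if len(pins) > 1 else None),
    )


def _gate_from_dict(d: dict, tb: Timebase) -> GateRule:
    kw = dict(kind=d["kind"])
    if "lookback_ms" in d:
        kw["lookback_ticks"] = tb.ms_to_ticks(d["lookback_ms"])
    for k in ("max_events", "min_events", "source", "level_min", "level_max"):
        if k in d:
            kw[k] = d[k]
    return GateRule(**kw)


def condition_from_dict(d: dict, tb: Timebase) -> StimCondition:
    return StimCondition(
        condition_id=int(d["condition_id"]),
        waveforms=tuple(waveform_from_dict(w, tb) for w in d.get("waveforms", [])),
        trigger_map={
            int(k): tuple(v) for k, v in d.get("trigger_map", {}).items()
        },
        gate_rules={
            int(k): tuple(_gate_from_dict(r, tb) for r in v)
            for k, v in d.get("gate_rules", {}).items()
        },
        duration_ticks=(
            tb.s_to_ticks(d["duration_s"]) if "duration_s" in d else None
        ),
    )


def snn_from_dict(d: dict) -> SnnNetwork:
    g = d.get("globals", {})
    return build_network(
        n_units=int(d["n_units"]),
        connections=[tuple(c) for c in d.get("connections", [])],
        globals=SnnGlobals(
            conduction_delay=int(g.get("conduction_delay_steps", 10)),
            fast_decay=int(g.get("fast_decay", 32768)),
            slow_decay=int(g.get("slow_decay", 58982)),
            bias_chance=int(g.get("bias_chance", 0)),
            bias_strength=int(g.get("bias_strength", 0)),
            threshold=int(g.get("threshold", 1000)),
        ),
    )


def config_from_dict(d: dict) -> DeviceConfig:
    tb = Timebase(int(d.get("tick_us", 10)))
    channels = [
        ChannelConfig(
            channel_id=int(c["channel_id"]),
            mode=c.get("mode", "single_ended"),
            sample_rate=int(c.get("sample_rate", 20000)),
            enabled=bool(c.get("enabled", True)),
        )
        for c in d.get("channels", [])
    ]
    cfg = DeviceConfig(
        channels=channels,
        timebase=tb,
        bandpass=tuple(d.get("bandpass_hz", (0.1, 5000.0))),
        event_generators=[
            generator_from_dict(g, tb) for g in d.get("event_generators", [])
        ],
        conditions=[condition_from_dict(c, tb) for c in d.get("conditions", [])],
        snn=snn_from_dict(d["snn"]) if d.get("snn") else None,
        seed=int(d.get("seed", 0)),
        refractory_ms=float(d.get("refractory_ms", 10.0)),
        compliance_v=int(d.get("compliance_v", 60)),
        fast_settle_us=d.get("fast_settle_us"),
    )
    return validate_config(cfg)


def config_to_dict(cfg: DeviceConfig) -> dict:
    """Inverse of :func:`config_from_dict` (up to key defaults)."""
    tb = cfg.timebase

    def ticks_ms(t: int) -> float:
        return t * tb.tick_us / 1000.0

    d: dict[str, Any] = {
        "tick_us": tb.tick_us,
        "channels": [
            {
                "channel_id": c.channel_id,
                "mode": c.mode,
                "sample_rate": c.sample_rate,
                "enabled": c.enabled,
            }
            for c in cfg.channels
        ],
        "bandpass_hz": list(cfg.bandpass),
        "seed": cfg.seed,
        "refractory_ms": cfg.refractory_ms,
        "compliance_v": cfg.compliance_v,
        "fast_settle_us": cfg.fast_settle_us,
        "event_generators": [],
        "conditions": [],
    }
    for g in cfg.event_generators:
        gd: dict[str, Any] = {"gen_id": g.gen_id, "mode": g.mode}
        if g.mode == "fixed_interval":
            gd["period_ms"] = ticks_ms(g.period_ticks)
        elif g.mode == "uniform_interval":
            gd["range_ms"] = [ticks_ms(g.uniform_ticks[0]), ticks_ms(g.uniform_ticks[1])]
        elif g.mode == "exponential_interval":
            gd["mean_ms"] = g.mean_ticks * tb.tick_us / 1000.0
        elif g.mode == "window_discriminator":
            disc = g.discriminator
            gd["source"] = g.source
            gd["discriminator"] = {
                "threshold": disc.threshold,
                "polarity": disc.polarity,
                "dead_time_ms": ticks_ms(disc.dead_time_ticks),
                "windows": [
                    {
                        "delay_ms": ticks_ms(w.delay_ticks),
                        "amp_min": w.amp_min,
                        "amp_max": w.amp_max,
                    }
                    for w in disc.windows
                ],
            }
        d["event_generators"].append(gd)
    for c in cfg.conditions:
        cd: dict[str, Any] = {
            "condition_id": c.condition_id,
            "waveforms": [
                {
                    "waveform_id": w.waveform_id,
                    "phase1_ua": w.phase1_ua,
                    "phase1_ms": ticks_ms(w.phase1_ticks),
                    "phase2_ua": w.phase2_ua,
                    "phase2_ms": ticks_ms(w.phase2_ticks),
                    "delay_ms": ticks_ms(w.delay_ticks),
                    "count": w.count,
                    "ipi_ms": ticks_ms(w.ipi_ticks),
                    "pins": [p for p in w.pins if p is not None],
                }
                for w in c.waveforms
            ],
            "trigger_map": {int(k): list(v) for k, v in c.trigger_map.items()},
        }
        if c.gate_rules:
            cd["gate_rules"] = {
                int(k): [
                    {
                        kk: vv
                        for kk, vv in {
                            "kind": r.kind,
                            "lookback_ms": (
                                ticks_ms(r.lookback_ticks)
                                if r.lookback_ticks
                                else None
                            ),
                            "max_events": r.max_events,
                            "min_events": r.min_events,
                            "source": r.source,
                            "level_min": r.level_min,
                            "level_max": r.level_max,
                        }.items()
                        if vv is not None
                    }
                    for r in v
                ]
                for k, v in c.gate_rules.items()
            }
        if c.duration_ticks is not None:
            cd["duration_s"] = c.duration_ticks * tb.tick_us / 1e6
        d["conditions"].append(cd)
    if cfg.snn is not None:
        g = cfg.snn.globals
        d["snn"] = {
            "n_units": cfg.snn.n_units,
            "globals": {
                "conduction_delay_steps": g.conduction_delay,
                "fast_decay": g.fast_decay,
                "slow_decay": g.slow_decay,
                "bias_chance": g.bias_chance,
                "bias_strength": g.bias_strength,
                "threshold": g.threshold,
            },
            "connections": [
                [c.source, c.target, c.weight] for c in cfg.snn.connections
            ],
        }
    return d


def load_config(path: str) -> DeviceConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigError(f"config file {path}: expected a mapping at top level")
    return config_from_dict(data)


def save_config(cfg: DeviceConfig, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=True)
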