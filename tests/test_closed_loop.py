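"""End-to-end closed-loop sessions on synthetic scenarios.

These tests wire the whole chain — scenario generation, front-end
filtering and quantization, spike discrimination, trigger gating, pulse
scheduling with feedback (artifacts, evoked spikes, fast settle) — and
check the bookkeeping identities and determinism the recording format
guarantees.
"""

import numpy as np
import pytest

from nc3sim.config import ChannelConfig, DeviceConfig
from nc3sim.events import EventGeneratorSpec, Window, WindowDiscSpec
from nc3sim.session import read_session, run_closed_loop, summarize_session
from nc3sim.snn import SnnGlobals, build_network
from nc3sim.stimulator import StimCondition, StimWaveform
from nc3sim.synth import (
    EmgScenarioSpec,
    ArtifactModel,
    EvokedSpec,
    NeuronModel,
    ScenarioSpec,
    default_spike_template,
)

FS = 20000.0


def spike_loop_config(seed=7, refractory_ms=10.0, windows=()):
    disc = WindowDiscSpec(
        threshold=-800, polarity="falling", windows=windows, dead_time_ticks=200
    )
    gen = EventGeneratorSpec(0, "window_discriminator", source=0, discriminator=disc)
    w = StimWaveform(0, 1000.0, 20, -1000.0, 20, delay_ticks=10)
    cond = StimCondition(0, (w,), trigger_map={0: (0,)})
    return DeviceConfig(
        channels=[ChannelConfig(0)],
        bandpass=(500.0, 5000.0),
        event_generators=[gen],
        conditions=[cond],
        seed=seed,
        refractory_ms=refractory_ms,
        fast_settle_us=400.0,
    )


def spike_scenario(seed=7, rate_hz=8.0, duration_s=2.0):
    return ScenarioSpec(
        duration_s=duration_s,
        fs=FS,
        n_channels=1,
        neurons=(
            NeuronModel(0, rate_hz=rate_hz, template=default_spike_template(FS)),
        ),
        noise_rms_mv=0.01,
        artifact=ArtifactModel(coupling_uv_per_ua=(2.0,), highpass_fl_hz=500.0),
        seed=seed,
    )


class TestSpikeTriggeredLoop:
    def test_delivered_pulses_equal_accepted_triggers(self):
        result = run_closed_loop(spike_loop_config(), spike_scenario())
        assert len(result.pulses) == len(result.trigger_events) - len(
            result.rejected
        )
        assert len(result.pulses) > 0

    def test_evoked_spikes_do_not_retrigger_within_refractory(self):
        # probability-1 evoked response at 3 ms: detected, but the 10 ms
        # global refractory blocks the re-triggered stimulus
        result = run_closed_loop(
            spike_loop_config(),
            spike_scenario(),
            evoked=[EvokedSpec(0, probability=1.0, latency_ms=3.0, jitter_ms=0.5)],
        )
        onsets = np.array(sorted(p.onset for p in result.pulses))
        assert np.all(np.diff(onsets) >= 1000)  # 10 ms in ticks
        assert any("refractory" in reason for _, reason in result.rejected)

    def test_closed_loop_latency_bound(self):
        # threshold-only discriminator: trigger tick is the crossing
        # sample; pulse onset is within one sample period + waveform delay
        cfg = spike_loop_config(refractory_ms=0.0)
        result = run_closed_loop(cfg, spike_scenario())
        delay = cfg.conditions[0].waveforms[0].delay_ticks
        trig_by_ts = {e.timestamp for e in result.trigger_events}
        for p in result.pulses:
            assert p.trigger_ts in trig_by_ts
            assert 0 <= p.onset - p.trigger_ts <= 5 + delay

    def test_same_seed_byte_identical_sessions(self, tmp_path):
        p1, p2 = tmp_path / "a.nc3", tmp_path / "b.nc3"
        run_closed_loop(spike_loop_config(), spike_scenario(), session_path=p1)
        run_closed_loop(spike_loop_config(), spike_scenario(), session_path=p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_session_records_match_result(self, tmp_path):
        p = tmp_path / "s.nc3"
        result = run_closed_loop(spike_loop_config(), spike_scenario(), session_path=p)
        h, blocks, records = read_session(p)
        s = summarize_session(h, blocks, records)
        assert s["generator_event_counts"].get(0, 0) == len(result.trigger_events)
        assert sum(s["stimulus_counts"].values()) == len(result.pulses)
        assert len(blocks) == 1 and len(blocks[0].codes) == int(2.0 * FS)

    def test_fast_settle_blanks_recording_after_stimuli(self):
        result = run_closed_loop(spike_loop_config(), spike_scenario())
        codes = result.codes[0]
        assert result.blanking, "expected blanking intervals"
        lo, hi = result.blanking[0]
        first = -(-lo // 5)
        last = -(-hi // 5)
        assert np.all(codes[first:last] == 0)


class TestDetectionPerformance:
    def test_dual_window_detects_95_percent_at_tenth_peak_noise(self):
        """Discriminator tuned to the known template recovers ≥95% of
        ground-truth potentials at noise RMS = template peak / 10."""
        template = default_spike_template(FS)  # −0.3 mV peak
        # the spike-band-filtered template crosses −800 one sample before
        # its −1359-code trough and rebounds to +1246 three samples later;
        # the windows box those two features with ≈3σ noise margins
        windows = (Window(5, -2300, -700), Window(20, 500, 2200))
        cfg = spike_loop_config(refractory_ms=0.0, windows=windows)
        scen = ScenarioSpec(
            duration_s=4.0,
            fs=FS,
            n_channels=1,
            neurons=(NeuronModel(0, rate_hz=6.0, template=template),),
            noise_rms_mv=0.03,  # peak/10
            seed=11,
        )
        result = run_closed_loop(cfg, scen)
        truth_samples = np.array(result.truth.spike_times[0])
        hit = 0
        trig_samples = np.array(sorted(e.timestamp // 5 for e in result.trigger_events))
        for s in truth_samples:
            if len(trig_samples) and np.min(np.abs(trig_samples - s)) <= 20:
                hit += 1
        assert len(truth_samples) >= 15
        assert hit / len(truth_samples) >= 0.95

    def test_no_false_triggers_on_pure_noise(self):
        cfg = spike_loop_config()
        scen = spike_scenario(rate_hz=0.0, duration_s=1.0)
        result = run_closed_loop(cfg, scen)
        assert result.trigger_events == []


class TestSnnInTheLoop:
    def test_snn_bridges_generator_to_stimulation(self):
        """Interval generator → SNN input unit → SNN output unit →
        snn_output generator → stimulus, with network events recorded."""
        g = SnnGlobals(
            conduction_delay=1,
            fast_decay=32768,
            slow_decay=58982,
            bias_chance=0,
            bias_strength=0,
            threshold=300,
        )
        # external source −1 (generator 0) drives unit 1; unit 1 drives
        # output unit 2 mapped to generator 2
        net = build_network(3, [(-1, 1, 1000), (1, 2, 1000)], g)
        interval = EventGeneratorSpec(0, "fixed_interval", period_ticks=2000)
        snn_out = EventGeneratorSpec(2, "snn_output")
        w = StimWaveform(0, 500.0, 20, -500.0, 20)
        cond = StimCondition(0, (w,), trigger_map={2: (0,)})
        cfg = DeviceConfig(
            channels=[ChannelConfig(0)],
            bandpass=(500.0, 5000.0),
            event_generators=[interval, snn_out],
            conditions=[cond],
            snn=net,
            seed=3,
            refractory_ms=0.0,
        )
        scen = ScenarioSpec(duration_s=0.5, fs=FS, n_channels=1, seed=3)
        result = run_closed_loop(cfg, scen)
        n_interval = sum(1 for e in result.trigger_events if e.source == 0)
        n_snn_trig = sum(1 for e in result.trigger_events if e.source == 2)
        assert n_interval == 24  # 0.5 s / 20 ms, last event beyond horizon
        assert n_snn_trig > 0
        assert len(result.pulses) == n_snn_trig
        assert len(result.snn_raster) >= n_snn_trig  # units 1 and 2 both spike

    def test_snn_demo_four_in_four_out(self):
        """Two-layer feed-forward net: four input units driven by
        generators, four output units with per-output delays triggering
        four stimulation sites; all I/O units log network events."""
        g = SnnGlobals(conduction_delay=2, threshold=300)
        conns = []
        for i in range(4):
            conns.append((-(i + 1), i, 1000))  # generator i → input unit i
            conns.append((i, 4 + i, 1000))  # input unit i → output unit 4+i
        net = build_network(8, conns, g)
        gens = [
            EventGeneratorSpec(i, "fixed_interval", period_ticks=2500 + 500 * i)
            for i in range(4)
        ] + [EventGeneratorSpec(4 + i, "snn_output") for i in range(4)]
        waveforms = tuple(
            StimWaveform(
                i, 500.0, 20, -500.0, 20, delay_ticks=10 * (i + 1),
                pins=(i, (i + 1) % 6),
            )
            for i in range(4)
        )
        cond = StimCondition(
            0, waveforms, trigger_map={4 + i: (i,) for i in range(4)}
        )
        cfg = DeviceConfig(
            channels=[ChannelConfig(0)],
            bandpass=(500.0, 5000.0),
            event_generators=gens,
            conditions=[cond],
            snn=net,
            seed=5,
            refractory_ms=0.0,
        )
        scen = ScenarioSpec(duration_s=0.5, fs=FS, n_channels=1, seed=5)
        result = run_closed_loop(cfg, scen)
        fired_units = {u for _, u in result.snn_raster}
        assert fired_units == set(range(8))  # all 8 I/O units active
        stim_pins = {p.pins for p in result.pulses}
        assert len(stim_pins) == 4  # four distinct stimulation sites
        net_events = [r for r in result.records if r.kind == "network_event"]
        assert len(net_events) == len(result.snn_raster)


def emg_loop_config(refractory_ms=10.0, with_stim=True, seed=21):
    """Three independent EMG-discriminator loops, three stimulation sites.

    The band-filtered motor-unit potential crosses −1500 codes two samples
    before its −5189-code trough and rebounds to +2261 nine samples later;
    the windows box those features with ≈3σ margins at peak/10 noise.
    """
    windows = (Window(40, -7000, -3500), Window(180, 700, 3800))
    gens = [
        EventGeneratorSpec(
            ch,
            "window_discriminator",
            source=ch,
            discriminator=WindowDiscSpec(
                threshold=-1500,
                polarity="falling",
                windows=windows,
                dead_time_ticks=200,
            ),
        )
        for ch in range(3)
    ]
    conditions = []
    if with_stim:
        waveforms = tuple(
            StimWaveform(ch, 500.0, 20, -500.0, 20, pins=(2 * ch, 2 * ch + 1))
            for ch in range(3)
        )
        conditions = [
            StimCondition(0, waveforms, trigger_map={ch: (ch,) for ch in range(3)})
        ]
    return DeviceConfig(
        channels=[ChannelConfig(ch, sample_rate=5000) for ch in range(3)],
        bandpass=(10.0, 2000.0),
        event_generators=gens,
        conditions=conditions,
        seed=seed,
        refractory_ms=refractory_ms,
    )


class TestEmgTriggeredLoops:
    def test_discriminators_detect_95_percent_of_potentials(self):
        """Each loop's discriminator recovers ≥95% of the ground-truth
        motor-unit potentials on its muscle at peak/10 noise."""
        scen = EmgScenarioSpec(duration_s=6.0, seed=21)
        cfg = emg_loop_config(with_stim=False, seed=21)
        result = run_closed_loop(cfg, scen)
        total, hit = 0, 0
        for ch in range(3):
            truth_samples = result.truth.spike_times[ch]
            trig = np.array(
                sorted(
                    e.timestamp // 20
                    for e in result.trigger_events
                    if e.source == ch
                )
            )
            for s in truth_samples:
                total += 1
                if len(trig) and np.min(np.abs(trig - s)) <= 15:  # 3 ms
                    hit += 1
        assert total >= 20
        assert hit / total >= 0.95

    def test_three_loops_respect_global_refractory(self):
        """Stimuli reach three distinct sites, yet no two pulse-train
        onsets across all loops fall closer than the 10 ms refractory."""
        scen = EmgScenarioSpec(duration_s=6.0, seed=22)
        result = run_closed_loop(emg_loop_config(seed=22), scen)
        pins = {p.pins for p in result.pulses}
        assert len(pins) == 3
        onsets = np.array(sorted(p.onset for p in result.pulses))
        assert len(onsets) >= 6
        assert np.all(np.diff(onsets) >= 1000)  # 10 ms in ticks


def test_mismatched_rates_rejected():
    cfg = spike_loop_config()
    scen = ScenarioSpec(duration_s=0.1, fs=5000.0, n_channels=1)
    with pytest.raises(ValueError, match="rate"):
        run_closed_loop(cfg, scen)
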