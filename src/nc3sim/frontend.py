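"""Analog front-end and on-chip DSP model.

Models the observable behaviour of the recording chain: a 0.07 Hz
first-order high-pass on every physiological input, the amplifier's
adjustable bandpass, 16-bit ±5 mV quantization with 2.4 µV RMS input
noise, post-stimulus fast-settle blanking, the 3-axis accelerometer, and
the 8-slot programmable IIR filter bank with rectification and artifact
suppression.

The 192× hardware gain is folded into the mV→code mapping: only the
code-domain behaviour is observable, so the gain never appears as a
separate stage.  Filter topology is first-order high-pass sections plus a
Butterworth low-pass (order 2 by default); only the corner frequencies
are contracts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import signal as sps

FRONTEND_HIGHPASS_HZ = 0.07

INT16_MIN, INT16_MAX = -32768, 32767


@dataclass(frozen=True)
class AdcModel:
    """16-bit ±5 mV converter with optional Gaussian input noise."""

    input_range_mv: float = 5.0
    resolution_bits: int = 16
    gain: float = 192.0
    noise_uv_rms: float = 2.4
    noise_enabled: bool = True

    @property
    def lsb_mv(self) -> float:
        """Quantization step: 10 mV / 2^16 ≈ 0.1526 µV."""
        return 2.0 * self.input_range_mv / 2.0**self.resolution_bits

    @property
    def code_max(self) -> int:
        return 2 ** (self.resolution_bits - 1) - 1

    @property
    def code_min(self) -> int:
        return -(2 ** (self.resolution_bits - 1))


def _check_rate(fs: float) -> None:
    if fs <= 0:
        raise ValueError(f"sample rate must be positive, got {fs}")


def highpass_sos(fc: float, fs: float, order: int = 1) -> np.ndarray:
    return sps.butter(order, fc, btype="highpass", fs=fs, output="sos")


def lowpass_sos(fc: float, fs: float, order: int = 2) -> np.ndarray:
    return sps.butter(order, fc, btype="lowpass", fs=fs, output="sos")


def bandpass_sos(
    low_cut: float, high_cut: float, fs: float, lp_order: int = 2
) -> np.ndarray:
    """First-order high-pass cascaded with a Butterworth low-pass."""
    if not (0 < low_cut < high_cut):
        raise ValueError(
            f"need 0 < low_cut < high_cut, got {low_cut}, {high_cut}"
        )
    if high_cut >= fs / 2:
        raise ValueError(
            f"Nyquist violation: high_cut {high_cut} Hz >= fs/2 = {fs / 2} Hz"
        )
    return np.vstack(
        [highpass_sos(low_cut, fs), lowpass_sos(high_cut, fs, lp_order)]
    )


def apply_frontend_highpass(
    trace_mv: np.ndarray, fs: float, fc: float = FRONTEND_HIGHPASS_HZ
) -> np.ndarray:
    """First-order high-pass applied to every physiological input.

    Removes DC in steady state; at spike-band frequencies the attenuation
    is negligible (fc/f ~ 1e-4).
    """
    _check_rate(fs)
    return sps.sosfilt(highpass_sos(fc, fs), np.asarray(trace_mv, float))


def apply_bandpass(
    trace_mv: np.ndarray,
    fs: float,
    low_cut: float,
    high_cut: float,
    lp_order: int = 2,
) -> np.ndarray:
    """Amplifier bandpass (adjustable 0.1–2000 Hz low cut, 100–20000 Hz high cut)."""
    _check_rate(fs)
    sos = bandpass_sos(low_cut, high_cut, fs, lp_order)
    return sps.sosfilt(sos, np.asarray(trace_mv, float))


def quantize_samples(
    trace_mv: np.ndarray,
    adc: AdcModel = AdcModel(),
    rng: Optional[np.random.Generator] = None,
    noise_mv: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Convert a mV trace to signed ADC codes.

    Additive Gaussian noise at the configured RMS (when enabled), then
    clipping to the ±5 mV input range, then round-to-nearest uniform
    quantization.  ``noise_mv`` may supply a pre-drawn noise trace so the
    same realization can be reused across passes; otherwise ``rng`` draws
    it.  The mapping is monotone non-decreasing in the input.
    """
    x = np.asarray(trace_mv, dtype=float)
    if adc.noise_enabled:
        if noise_mv is not None:
            x = x + noise_mv
        elif rng is not None:
            x = x + rng.normal(0.0, adc.noise_uv_rms / 1000.0, size=x.shape)
    x = np.clip(x, -adc.input_range_mv, adc.input_range_mv)
    codes = np.rint(x / adc.lsb_mv)
    return np.clip(codes, adc.code_min, adc.code_max).astype(np.int16)


def dequantize_samples(codes: np.ndarray, adc: AdcModel = AdcModel()) -> np.ndarray:
    """Codes back to mV (bin centers)."""
    return np.asarray(codes, dtype=float) * adc.lsb_mv


def adc_noise(
    rng: np.random.Generator, n: int, adc: AdcModel = AdcModel()
) -> np.ndarray:
    """Pre-draw an input-referred noise trace in mV."""
    return rng.normal(0.0, adc.noise_uv_rms / 1000.0, size=n)


def apply_fast_settle(
    codes: np.ndarray,
    fs: float,
    stim_onset_ticks: Sequence[int],
    settle_us: float,
    tick_us: int = 10,
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Blank samples for a brief window after each stimulus.

    The amplifier's fast-settle feature drives outputs to baseline for
    200–3200 µs after a stimulus; samples whose time falls in
    ``[onset, onset + settle_us)`` are replaced by code 0.  Returns the
    blanked codes and the blanking intervals (in ticks, half-open) so
    downstream spike detection can ignore them.
    """
    if not (200 <= settle_us <= 3200):
        raise ValueError(f"settle_us {settle_us} outside [200, 3200]")
    out = np.array(codes, dtype=np.int16, copy=True)
    ticks_per_sample = int(round(1_000_000 / fs)) // tick_us
    settle_ticks = int(round(settle_us / tick_us))
    intervals: list[tuple[int, int]] = []
    n = len(out)
    for onset in stim_onset_ticks:
        lo, hi = int(onset), int(onset) + settle_ticks
        intervals.append((lo, hi))
        first = -(-lo // ticks_per_sample)  # ceil
        last = -(-hi // ticks_per_sample)
        out[max(first, 0) : min(last, n)] = 0
    return out, intervals


def sample_accelerometer(
    motion_g: np.ndarray,
    fs_in: float,
    temperature_c: Optional[np.ndarray] = None,
    out_rate: int = 100,
) -> dict:
    """Accelerometer sampling: 100 Sps, ±2 g range, 10-bit codes.

    ``motion_g`` is an (n, 3) X/Y/Z trace in g at ``fs_in``.  Values are
    clipped at ±2 g then uniformly quantized to 10 bits (code 511 at
    positive full scale).  Temperature, when given, is stored as
    quarter-degree codes at the same output rate.
    """
    motion = np.atleast_2d(np.asarray(motion_g, dtype=float))
    if motion.shape[1] != 3:
        raise ValueError("motion_g must have 3 columns (X, Y, Z)")
    step = fs_in / out_rate
    if abs(step - round(step)) > 1e-9:
        raise ValueError(f"fs_in {fs_in} not an integer multiple of {out_rate}")
    idx = np.arange(0, motion.shape[0], int(round(step)), dtype=int)
    lsb = 4.0 / 1024.0
    xyz = np.clip(np.rint(np.clip(motion[idx], -2.0, 2.0) / lsb), -512, 511)
    result = {"xyz": xyz.astype(np.int16), "rate": out_rate}
    if temperature_c is not None:
        temp = np.asarray(temperature_c, dtype=float)[idx]
        result["temp"] = np.rint(temp * 4.0).astype(np.int16)
    return result


def read_raw_channel(path, meta_path=None) -> tuple[np.ndarray, dict]:
    """Read a user-supplied raw signal file: flat little-endian int16
    plus a JSON sidecar (``<path>.json`` by default) giving at least
    ``sample_rate`` and optionally ``units`` and ``channel_id``."""
    import json
    from pathlib import Path

    p = Path(path)
    codes = np.fromfile(p, dtype="<i2")
    mp = Path(meta_path) if meta_path is not None else p.with_suffix(p.suffix + ".json")
    meta = json.loads(mp.read_text()) if mp.exists() else {}
    return codes, meta


def write_raw_channel(path, codes: np.ndarray, meta: dict) -> None:
    """Inverse of :func:`read_raw_channel`."""
    import json
    from pathlib import Path

    p = Path(path)
    np.asarray(codes, dtype="<i2").tofile(p)
    p.with_suffix(p.suffix + ".json").write_text(json.dumps(meta, sort_keys=True))


@dataclass(frozen=True)
class FilterBankSlot:
    """One of the eight programmable IIR filter slots.

    ``source`` is a channel id or an ``(a, b)`` pair whose difference is
    filtered.  ``artifact_suppress`` holds the last pre-stimulus output
    for the blanking window after each stimulus.
    """

    slot_id: int
    source: int | tuple[int, int]
    band: tuple[float, float]
    order: int = 2
    rectify: bool = False
    artifact_suppress: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.slot_id <= 7:
            raise ValueError(f"slot_id {self.slot_id} outside 0–7")


def run_filter_bank(
    channel_codes: dict[int, np.ndarray],
    fs: float,
    slots: Sequence[FilterBankSlot],
    stim_onset_ticks: Sequence[int] = (),
    blank_us: float = 400.0,
    tick_us: int = 10,
) -> dict[int, np.ndarray]:
    """Run the programmable filter bank over recorded channel codes.

    Per slot: optional pairwise channel difference, IIR bandpass, optional
    full-wave rectification, optional artifact suppression (output held at
    its pre-stimulus value for ``blank_us`` after each stimulus onset).
    Returns float traces keyed by slot id.
    """
    if len(slots) > 8:
        raise ValueError(f"{len(slots)} slots configured, at most 8 allowed")
    ticks_per_sample = int(round(1_000_000 / fs)) // tick_us
    blank_ticks = int(round(blank_us / tick_us))
    out: dict[int, np.ndarray] = {}
    for slot in slots:
        if isinstance(slot.source, tuple):
            a, b = slot.source
            if a not in channel_codes or b not in channel_codes:
                raise ValueError(f"slot {slot.slot_id}: invalid source {slot.source}")
            x = channel_codes[a].astype(float) - channel_codes[b].astype(float)
        else:
            if slot.source not in channel_codes:
                raise ValueError(f"slot {slot.slot_id}: invalid source {slot.source}")
            x = channel_codes[slot.source].astype(float)
        y = sps.sosfilt(bandpass_sos(*slot.band, fs, slot.order), x)
        if slot.rectify:
            y = np.abs(y)
        if slot.artifact_suppress:
            n = len(y)
            for onset in stim_onset_ticks:
                first = -(-int(onset) // ticks_per_sample)
                last = -(-(int(onset) + blank_ticks) // ticks_per_sample)
                first, last = max(first, 0), min(last, n)
                if first < last:
                    hold = y[first - 1] if first > 0 else 0.0
                    y[first:last] = hold
        out[slot.slot_id] = y
    return out
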