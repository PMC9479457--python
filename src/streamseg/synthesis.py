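"""Rendering of narrowband-noise bursts and burst sequences to audio.

Bursts are Gaussian noise band-limited by a 10-pole Butterworth band-pass
filter (second-order-sections, causal), optionally 100%-depth sinusoidally
amplitude-modulated, shaped by 8-ms raised-cosine onset/offset ramps, and
scaled to the requested level.  Level calibration is a fixed digital
convention: 60 dB SPL maps to a digital RMS of 0.05, so relative levels are
exact while absolute SPL (a property of playback hardware) is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.io import wavfile

from .paradigm import BandSpec, SequenceTiming, sequence_duration

SAMPLE_RATE = 44_100
RAMP_MS = 8.0
#: digital RMS corresponding to 60 dB SPL
LEVEL_REF_RMS = 0.05
LEVEL_REF_DB = 60.0
FILTER_POLES = 10  # 10-pole band-pass: prototype order 5


@dataclass(frozen=True)
class Waveform:
    samples: np.ndarray  # float, full-scale +-1
    sample_rate: int = SAMPLE_RATE

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sample_rate

    def rms(self) -> float:
        return float(np.sqrt(np.mean(np.square(self.samples))))

    def level_db(self) -> float:
        """Level in dB SPL under the package calibration."""
        r = self.rms()
        if r == 0:
            return -np.inf
        return LEVEL_REF_DB + 20.0 * np.log10(r / LEVEL_REF_RMS)


def rms_for_level(level_db: float) -> float:
    return LEVEL_REF_RMS * 10.0 ** ((level_db - LEVEL_REF_DB) / 20.0)


def bandpass_sos(spec: BandSpec, sample_rate: int = SAMPLE_RATE) -> np.ndarray:
    lo = spec.center_freq - spec.bandwidth / 2.0
    hi = spec.center_freq + spec.bandwidth / 2.0
    nyq = sample_rate / 2.0
    if hi >= nyq:
        raise ValueError(f"band edge {hi} Hz exceeds Nyquist {nyq} Hz")
    return signal.butter(FILTER_POLES // 2, [lo, hi], btype="bandpass",
                         fs=sample_rate, output="sos")


def _ramp_envelope(n_samples: int, sample_rate: int, ramp_ms: float = RAMP_MS) -> np.ndarray:
    n_ramp = int(round(ramp_ms / 1000.0 * sample_rate))
    if 2 * n_ramp > n_samples:
        raise ValueError("burst too short for rise/fall ramps")
    env = np.ones(n_samples)
    t = np.linspace(0.0, np.pi / 2.0, n_ramp, endpoint=False)
    rise = np.sin(t) ** 2  # raised cosine
    env[:n_ramp] = rise
    env[n_samples - n_ramp:] = rise[::-1]
    return env


def synth_burst(
    spec: BandSpec,
    rng: np.random.Generator,
    duration_ms: float = 80.0,
    sample_rate: int = SAMPLE_RATE,
) -> Waveform:
    """Synthesize one narrowband-noise burst.

    A level of 0 dB is the silence convention and yields all-zero samples.
    """
    n = int(round(duration_ms / 1000.0 * sample_rate))
    if spec.level == 0:
        return Waveform(np.zeros(n), sample_rate)
    noise = rng.standard_normal(n)
    sos = bandpass_sos(spec, sample_rate)
    band = signal.sosfilt(sos, noise)
    if not np.all(np.isfinite(band)):
        raise RuntimeError(
            "band-pass filter went unstable; use the second-order-sections "
            "realization with a wider band or lower order"
        )
    if spec.am_rate > 0:
        t = np.arange(n) / sample_rate
        band = band * (1.0 + np.sin(2.0 * np.pi * spec.am_rate * t))  # 100% depth
    band = band * _ramp_envelope(n, sample_rate)
    r = np.sqrt(np.mean(np.square(band)))
    if r > 0:
        band = band * (rms_for_level(spec.level) / r)
    return Waveform(band, sample_rate)


def am_cycles(duration_s: float, rate_hz: float) -> float:
    """Number of modulation cycles ("looks") in a burst of given duration."""
    if duration_s < 0 or rate_hz < 0:
        raise ValueError("duration and rate must be non-negative")
    return duration_s * rate_hz


def render_sequence(
    timing: SequenceTiming,
    specs: tuple[BandSpec, BandSpec],
    rng: np.random.Generator,
    sample_rate: int = SAMPLE_RATE,
) -> Waveform:
    """Render a full trial sequence: fresh noise per burst, silence between.

    ``specs`` is the (A, B) pair of burst definitions.
    """
    if not timing.events:
        raise ValueError("empty timing: nothing to render")
    a_spec, b_spec = specs
    spans = []
    for ev in timing.events:
        i0 = int(round(ev.onset / 1000.0 * sample_rate))
        n = int(round(ev.duration / 1000.0 * sample_rate))
        spans.append((i0, i0 + n))
    n_total = max(i1 for _, i1 in spans)
    out = np.zeros(n_total)
    occupied = np.zeros(n_total, dtype=bool)
    for ev, (i0, i1) in zip(timing.events, spans):
        spec = a_spec if ev.stream == "A" else b_spec
        burst = synth_burst(spec, rng, duration_ms=ev.duration, sample_rate=sample_rate)
        if occupied[i0:i1].any():
            raise ValueError(f"burst at {ev.onset} ms overlaps an earlier burst")
        occupied[i0:i1] = True
        out[i0:i1] += burst.samples
    return Waveform(out, sample_rate)


def write_wav(w: Waveform, path) -> None:
    """Write a mono float32 WAV; refuses to clip."""
    peak = float(np.max(np.abs(w.samples))) if len(w.samples) else 0.0
    if peak > 1.0:
        raise ValueError(f"waveform clips: peak |sample| = {peak:.4f} > 1")
    wavfile.write(path, w.sample_rate, w.samples.astype(np.float32))


def read_wav(path, expect_sample_rate: int | None = SAMPLE_RATE) -> Waveform:
    rate, data = wavfile.read(path)
    if expect_sample_rate is not None and rate != expect_sample_rate:
        raise ValueError(f"sample rate {rate} Hz != expected {expect_sample_rate} Hz")
    if data.ndim != 1:
        raise ValueError("expected mono WAV")
    if data.dtype.kind == "i":
        data = data.astype(np.float64) / float(np.iinfo(data.dtype).max)
    else:
        data = data.astype(np.float64)
    return Waveform(data, rate)


def modulation_depth(w: Waveform, am_rate: float) -> float:
    """Measured (max-min)/(max+min) of the envelope at the modulation scale.

    The envelope is taken as the magnitude of the analytic signal, low-passed
    just above the modulation rate; ramps are excluded from the measurement.
    """
    env = np.abs(signal.hilbert(w.samples))
    sos = signal.butter(4, max(2.5 * am_rate, 20.0), btype="low", fs=w.sample_rate,
                        output="sos")
    env = signal.sosfiltfilt(sos, env)
    n_ramp = int(round(RAMP_MS / 1000.0 * w.sample_rate))
    core = env[n_ramp:-n_ramp]
    mx, mn = float(core.max()), float(max(core.min(), 0.0))
    return (mx - mn) / (mx + mn)
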