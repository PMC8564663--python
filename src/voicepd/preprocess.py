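"""Audio input and leading/trailing non-speech trimming.

Web-collected recordings carry dead air and handling noise at both ends:
participants start the recorder, pause, speak, then fumble for the stop
button.  Everything downstream assumes the waveform has been cut to the
span between the first and last spoken word, so this module provides a
simple energy-based endpointer: find the first and last analysis frame
whose log-energy rises above a threshold relative to the loudest frame,
requiring a minimum run of consecutive super-threshold frames so that an
isolated click cannot anchor the span.

The threshold is relative (dB below the peak frame), never absolute,
because recordings arrive from heterogeneous consumer devices with wildly
different gains.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.io import wavfile


class NoSpeechError(ValueError):
    """Raised when no frame of the input exceeds the energy threshold."""


@dataclass
class Waveform:
    """Mono audio in [-1, 1] at a known sample rate."""

    samples: np.ndarray
    rate: int
    source_path: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.rate <= 0:
            raise ValueError(f"rate must be positive, got {self.rate}")
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D array")

    @property
    def duration(self) -> float:
        return self.samples.size / self.rate

    def scaled(self, gain: float) -> "Waveform":
        return Waveform(self.samples * gain, self.rate, self.source_path)


@dataclass(frozen=True)
class SpeechSpan:
    """Start/end of detected speech, in seconds of the original file."""

    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if not 0 <= self.start_s < self.end_s:
            raise ValueError(f"invalid span [{self.start_s}, {self.end_s}]")


def read_wav(path) -> Waveform:
    """Read a PCM WAV file as a mono waveform scaled to [-1, 1].

    Multi-channel audio is averaged across channels.  Integer PCM is
    scaled by the type's full-scale magnitude (32768 for 16-bit);
    float payloads are passed through.
    """
    rate, data = wavfile.read(str(path))
    if data.size == 0:
        raise ValueError(f"zero-length audio in {path}")
    if data.ndim == 2:
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        info = np.iinfo(data.dtype)
        scale = float(max(abs(info.min), info.max + 1))
        samples = data.astype(np.float64) / scale
    else:
        samples = data.astype(np.float64)
    return Waveform(samples, int(rate), source_path=str(path))


def write_wav(path, w: Waveform) -> None:
    """Write a waveform as 16-bit PCM."""
    clipped = np.clip(w.samples, -1.0, 1.0)
    wavfile.write(str(path), w.rate, (clipped * 32767).astype(np.int16))


def frame_energies(
    samples: np.ndarray, rate: int, frame_s: float, hop_s: float
) -> np.ndarray:
    """Mean-square energy per frame (non-centered, truncating tail)."""
    frame = max(1, int(round(frame_s * rate)))
    hop = max(1, int(round(hop_s * rate)))
    n = 1 + max(0, (samples.size - frame)) // hop
    idx = np.arange(frame)[None, :] + hop * np.arange(n)[:, None]
    return np.mean(samples[idx] ** 2, axis=1)


def trim_to_speech(
    w: Waveform,
    frame_s: float = 0.025,
    hop_s: float = 0.010,
    threshold_db: float = -35.0,
    min_run: int = 5,
) -> tuple[Waveform, SpeechSpan]:
    """Trim to the span between the first and last sustained loud frames.

    A frame is "loud" when its log-energy is within ``-threshold_db`` dB of
    the loudest frame.  The span runs from the start of the first run of
    ``min_run`` consecutive loud frames to the end of the last such run;
    interior pauses are kept.

    Raises
    ------
    NoSpeechError
        If no run of ``min_run`` consecutive frames exceeds the threshold.
    """
    if w.samples.size < int(round(frame_s * w.rate)):
        raise ValueError("waveform shorter than one analysis frame")
    energies = frame_energies(w.samples, w.rate, frame_s, hop_s)
    peak = energies.max()
    if peak <= 0:
        raise NoSpeechError("no speech detected: silent input")
    loud = 10 * np.log10(energies / peak + 1e-300) > threshold_db

    run_starts = _runs_of(loud, min_run)
    if run_starts.size == 0:
        raise NoSpeechError("no speech detected: no sustained frames above threshold")
    hop = max(1, int(round(hop_s * w.rate)))
    frame = max(1, int(round(frame_s * w.rate)))
    first = run_starts[0]
    # last loud frame belonging to a qualifying run
    rev = _runs_of(loud[::-1], min_run)
    last = loud.size - 1 - rev[0]
    i0 = first * hop
    i1 = min(w.samples.size, last * hop + frame)
    span = SpeechSpan(i0 / w.rate, i1 / w.rate)
    return Waveform(w.samples[i0:i1], w.rate, w.source_path), span


def _runs_of(mask: np.ndarray, min_run: int) -> np.ndarray:
    """Start indices of runs of at least ``min_run`` consecutive True."""
    if min_run <= 1:
        return np.flatnonzero(mask)
    window = np.convolve(mask.astype(int), np.ones(min_run, dtype=int), "valid")
    return np.flatnonzero(window == min_run)
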