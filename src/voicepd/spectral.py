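"""Spectral and nonlinear dysphonia measures.

Beyond cycle-level perturbation, pathological voice shows up in the
short-term spectrum (MFCC statistics, relative band power) and in
nonlinear signal properties designed for dysphonia screening:

* RPDE — recurrence period density entropy: the normalized entropy of
  first-return times in a time-delay embedding.  A healthy, nearly
  periodic voice re-enters the same state-space neighborhood after
  almost exactly one period (a sharp return-time histogram, low
  entropy); uncertain or wandering periodicity spreads the histogram.
* DFA — detrended fluctuation analysis: the scaling exponent alpha of
  RMS fluctuation versus window size on the integrated signal,
  characterizing the stochastic self-similarity of turbulent noise
  (0.5 for white noise, 1.5 for Brownian motion).
* PPE — pitch period entropy: entropy of the whitened log-pitch
  residuals, measuring the inability to hold a constant pitch once
  smooth intonation is removed.

These nonlinear measures were designed for sustained phonation; on
running speech their stationarity assumptions are only approximate, so
extraction metadata records that they were computed on concatenated
voiced segments.
"""

from __future__ import annotations

import logging
import math

import numpy as np
from scipy import fft as sfft
from scipy import linalg, signal

from .acoustic import PitchTrack
from .preprocess import Waveform

log = logging.getLogger(__name__)


# ---------------------------------------------------------------- MFCC

def hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=float) / 700.0)


def mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=float) / 2595.0) - 1.0)


def mel_filterbank(n_mels: int, nfft: int, rate: int) -> np.ndarray:
    """Triangular mel filters spanning 0..Nyquist, (n_mels, nfft//2+1)."""
    edges_mel = np.linspace(0.0, float(hz_to_mel(rate / 2)), n_mels + 2)
    edges_hz = mel_to_hz(edges_mel)
    bins = np.floor((nfft + 1) * edges_hz / rate).astype(int)
    fb = np.zeros((n_mels, nfft // 2 + 1))
    for i in range(n_mels):
        lo, mid, hi = bins[i], bins[i + 1], bins[i + 2]
        if mid > lo:
            fb[i, lo:mid] = (np.arange(lo, mid) - lo) / (mid - lo)
        if hi > mid:
            fb[i, mid:hi] = (hi - np.arange(mid, hi)) / (hi - mid)
    return fb


def mfcc_frames(
    w: Waveform, n_coef: int = 13, frame_s: float = 0.025,
    hop_s: float = 0.010, n_mels: int = 26,
) -> np.ndarray:
    """Frame-wise MFCCs (coefficient 0 included), shape (frames, n_coef).

    Hamming-windowed power spectrum -> mel filterbank log-energies ->
    orthonormal DCT-II.
    """
    x = w.samples
    frame = int(round(frame_s * w.rate))
    hop = int(round(hop_s * w.rate))
    if x.size < frame:
        raise ValueError("input shorter than one MFCC frame")
    n_frames = 1 + (x.size - frame) // hop
    idx = np.arange(frame)[None, :] + hop * np.arange(n_frames)[:, None]
    frames = x[idx] * np.hamming(frame)
    nfft = 1 << (frame - 1).bit_length()
    power = np.abs(np.fft.rfft(frames, nfft, axis=1)) ** 2 / nfft
    fb = mel_filterbank(n_mels, nfft, w.rate)
    logmel = np.log(power @ fb.T + 1e-12)
    return sfft.dct(logmel, type=2, norm="ortho", axis=1)[:, :n_coef]


def mfcc_stats(
    w: Waveform, n_coef: int = 13, frame_s: float = 0.025,
    hop_s: float = 0.010, n_mels: int = 26, variation: str = "std",
) -> tuple[np.ndarray, np.ndarray]:
    """Per-coefficient mean and variation of the frame-wise MFCCs.

    ``variation="std"`` (default) is the standard deviation across
    frames; ``"mad"`` uses the mean absolute frame-to-frame delta
    instead.
    """
    c = mfcc_frames(w, n_coef, frame_s, hop_s, n_mels)
    if c.shape[0] < 10:
        raise ValueError(f"too few MFCC frames ({c.shape[0]} < 10)")
    mean = c.mean(axis=0)
    if variation == "std":
        var = c.std(axis=0)
    elif variation == "mad":
        var = np.abs(np.diff(c, axis=0)).mean(axis=0)
    else:
        raise ValueError(f"unknown variation kind: {variation!r}")
    return mean, var


# ------------------------------------------------------ band power

def rel_band_power(w: Waveform, edges=None) -> np.ndarray:
    """Fraction of total power in each band; sums to 1.

    Default bands cover the fundamental/low harmonics (0-500 Hz), first
    formant (500-1000), second formant (1000-2000), and the remaining
    frication band up to Nyquist.
    """
    if w.rate < 8000:
        raise ValueError("rel_band_power expects rate >= 8000 Hz")
    if edges is None:
        edges = [0.0, 500.0, 1000.0, 2000.0, w.rate / 2]
    f, psd = signal.welch(w.samples, fs=w.rate, nperseg=min(1024, w.samples.size))
    total = np.trapezoid(psd, f)
    out = np.empty(len(edges) - 1)
    for i in range(len(edges) - 1):
        m = (f >= edges[i]) & (f <= edges[i + 1])
        out[i] = np.trapezoid(psd[m], f[m]) / total
    return out / out.sum()


# ------------------------------------------------------------- RPDE

def voiced_samples(w: Waveform, pt: PitchTrack, frame_s: float = 0.040,
                   hop_s: float = 0.010) -> np.ndarray:
    """Concatenated samples of all voiced frames."""
    frame = int(round(frame_s * w.rate))
    hop = int(round(hop_s * w.rate))
    mask = np.zeros(w.samples.size, dtype=bool)
    for j in np.flatnonzero(pt.voiced):
        mask[j * hop : min(w.samples.size, j * hop + frame)] = True
    return w.samples[mask]


def rpde(
    w: Waveform,
    pt: PitchTrack | None = None,
    m: int = 4,
    tau_samples: int | None = None,
    radius: float | None = None,
    t_max_s: float = 0.02,
    max_anchors: int = 4000,
) -> float:
    """Recurrence period density entropy in [0, 1].

    The (voiced, when a pitch track is given) signal is normalized and
    time-delay embedded in dimension ``m`` with delay ``tau_samples``
    (default: first zero crossing of the autocorrelation).  For each
    anchor point the first return time into an epsilon-ball — after
    having left it — is recorded up to ``t_max_s``; the normalized
    entropy of the return-time histogram is returned (0 = perfectly
    certain periodicity).

    Returns NaN with a warning when no recurrences are found.
    """
    x = voiced_samples(w, pt) if pt is not None else w.samples
    x = np.asarray(x, dtype=float)
    sd = x.std()
    if sd == 0 or x.size < 1000:
        log.warning("rpde: degenerate or too-short input")
        return float("nan")
    x = (x - x.mean()) / sd

    if tau_samples is None:
        ac = np.correlate(x[: min(x.size, 8192)], x[: min(x.size, 8192)], "full")
        ac = ac[ac.size // 2 :]
        below = np.flatnonzero(ac < 0)
        tau_samples = int(below[0]) if below.size else max(1, w.rate // 1000)
        tau_samples = max(1, min(tau_samples, w.rate // 200))

    span = (m - 1) * tau_samples
    t_max = int(round(t_max_s * w.rate))
    n_pts = x.size - span
    if n_pts <= t_max + 1:
        log.warning("rpde: input too short for embedding")
        return float("nan")
    emb = np.lib.stride_tricks.sliding_window_view(x, span + 1)[:, :: tau_samples]

    if radius is None:
        center = emb.mean(axis=0)
        radius = 0.12 * float(np.sqrt(np.mean(np.sum((emb - center) ** 2, axis=1))))
    eps2 = radius * radius

    stride = max(1, (n_pts - t_max) // max_anchors)
    anchors = np.arange(0, n_pts - t_max, stride)
    base = emb[anchors]
    left_ball = np.zeros(anchors.size, dtype=bool)
    rec_time = np.full(anchors.size, -1, dtype=int)
    open_mask = np.ones(anchors.size, dtype=bool)
    for t in range(1, t_max + 1):
        if not open_mask.any():
            break
        d2 = np.sum((emb[anchors[open_mask] + t] - base[open_mask]) ** 2, axis=1)
        inside = d2 < eps2
        idx = np.flatnonzero(open_mask)
        returned = idx[inside & left_ball[idx]]
        rec_time[returned] = t
        open_mask[returned] = False
        left_ball[idx[~inside]] = True

    times = rec_time[rec_time > 0]
    if times.size == 0:
        log.warning("rpde: no recurrences found")
        return float("nan")
    hist = np.bincount(times, minlength=t_max + 1)[1:]
    p = hist / hist.sum()
    p = p[p > 0]
    h = float(-(p * np.log(p)).sum())
    return h / math.log(t_max)


# -------------------------------------------------------------- DFA

def dfa(w_or_x, scales: np.ndarray | None = None, order: int = 1) -> float:
    """Detrended fluctuation analysis scaling exponent alpha.

    The mean-removed signal is integrated; for each window size n the
    RMS fluctuation F(n) around a per-window polynomial trend of the
    given order (non-overlapping windows) is computed, and alpha is the
    least-squares slope of log F(n) against log n.
    """
    x = w_or_x.samples if isinstance(w_or_x, Waveform) else np.asarray(w_or_x, float)
    n = x.size
    if scales is None:
        scales = np.unique(
            np.round(np.geomspace(50, max(51, n // 4), 12)).astype(int)
        )
    scales = np.asarray([s for s in scales if order + 2 <= s <= n // 4], dtype=int)
    if scales.size < 4:
        raise ValueError("fewer than 4 usable DFA scales")
    y = np.cumsum(x - x.mean())
    fs = np.empty(scales.size)
    for i, s in enumerate(scales):
        k = n // s
        seg = y[: k * s].reshape(k, s)
        t = np.arange(s, dtype=float)
        design = np.vander(t, order + 1)
        coef, *_ = np.linalg.lstsq(design, seg.T, rcond=None)
        resid = seg.T - design @ coef
        fs[i] = math.sqrt(float(np.mean(resid**2)))
    alpha = np.polyfit(np.log(scales), np.log(fs), 1)[0]
    return float(alpha)


# -------------------------------------------------------------- PPE

def ppe(pt: PitchTrack, n_bins: int = 30, lpc_order: int = 2) -> float:
    """Pitch period entropy: normalized entropy of whitened log-pitch.

    The voiced F0 contour is mapped to semitones relative to the
    speaker's median F0 (making the measure transposition-invariant), a
    low-order linear-prediction filter removes smooth intonation trend,
    and the entropy of the residual histogram over +-2 octaves is
    normalized by ln(n_bins).  Constant pitch gives 0.
    """
    f = pt.voiced_f0
    if f.size < 50:
        raise ValueError(f"ppe needs >= 50 voiced frames, got {f.size}")
    s = 12.0 * np.log2(f / np.median(f))
    s = s - s.mean()
    if s.std() < 1e-9:
        return 0.0
    r = np.array([np.dot(s[: s.size - k], s[k:]) for k in range(lpc_order + 1)])
    if r[0] <= 0:
        return 0.0
    a = linalg.solve_toeplitz((r[:-1], r[:-1]), r[1:])
    resid = signal.lfilter(np.concatenate([[1.0], -a]), [1.0], s)[lpc_order:]
    # half-bin offset puts zero at a bin center: a perfectly steady pitch
    # must not split across a bin edge and register ln(2) of entropy
    bw = 48.0 / n_bins
    edges = np.linspace(-24.0, 24.0, n_bins + 1) - bw / 2
    hist, _ = np.histogram(resid, bins=edges)
    if hist.sum() == 0:
        return 0.0
    p = hist / hist.sum()
    p = p[p > 0]
    h = float(-(p * np.log(p)).sum())
    return max(0.0, h / math.log(n_bins))
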