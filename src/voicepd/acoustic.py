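"""Pitch tracking, glottal-cycle extraction, and perturbation features.

The dysphonia measures at the heart of voice-based PD screening are
cycle-to-cycle perturbation statistics: jitter variants on the glottal
periods T_i, shimmer variants on the cycle peak amplitudes A_i, and the
harmonics-to-noise ratio.  All of them require a pitch track and cycle
marks first, which this module computes Praat-style: short-term
normalized autocorrelation with parabolic peak interpolation for F0, a
correlation/energy voicing decision with an octave-jump guard, and cycle
marks placed at the waveform peak of each period within voiced runs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .preprocess import Waveform, frame_energies

log = logging.getLogger(__name__)


class NoVoicedSpeechError(ValueError):
    """Raised when not a single frame passes the voicing decision."""


@dataclass
class PitchTrack:
    """Frame-wise F0 plus glottal cycle marks.

    ``f0`` is NaN on unvoiced frames.  ``periods`` are successive
    differences of cycle marks within voiced runs (never across gaps);
    ``peak_amps[i]`` is the waveform peak magnitude of the cycle spanned
    by ``periods[i]``, so the two arrays align one-to-one.
    """

    frame_times: np.ndarray
    f0: np.ndarray
    voiced: np.ndarray
    cycle_times: np.ndarray
    periods: np.ndarray
    peak_amps: np.ndarray
    rate: int

    @property
    def voiced_f0(self) -> np.ndarray:
        return self.f0[self.voiced]


def _autocorr_frames(frames: np.ndarray) -> np.ndarray:
    """Normalized autocorrelation of each frame row, lag-bias corrected.

    The raw FFT autocorrelation at lag k only sums n-k products, which
    deflates the peak by (n-k)/n and would cap the apparent periodicity
    of even a perfect tone; dividing by the rectangular window's own
    autocorrelation removes that taper.
    """
    n = frames.shape[1]
    nfft = 1 << (2 * n - 1).bit_length()
    spec = np.fft.rfft(frames, nfft, axis=1)
    ac = np.fft.irfft(spec * np.conj(spec), nfft, axis=1)[:, :n]
    ac0 = ac[:, :1].copy()
    ac0[ac0 <= 0] = 1.0
    lag_bias = (n - np.arange(n)) / n
    return ac / ac0 / lag_bias


def track_pitch(
    w: Waveform,
    fmin: float = 75.0,
    fmax: float = 500.0,
    frame_s: float = 0.040,
    hop_s: float = 0.010,
    voicing_threshold: float = 0.45,
    silence_db: float = -35.0,
) -> PitchTrack:
    """Frame-wise F0 by normalized autocorrelation, plus cycle marks.

    A frame is voiced when its autocorrelation peak in the candidate lag
    range exceeds ``voicing_threshold`` and its energy is within
    ``-silence_db`` dB of the loudest frame.  F0 estimates more than an
    octave from the utterance median are re-marked unvoiced.  Cycle marks
    step through each voiced run at the local period, snapping to the
    maximum-amplitude sample of each cycle.
    """
    if not fmin < fmax < w.rate / 2:
        raise ValueError(f"need fmin < fmax < rate/2, got {fmin}, {fmax}, {w.rate}")
    x = w.samples
    frame = int(round(frame_s * w.rate))
    hop = int(round(hop_s * w.rate))
    if x.size < frame:
        raise NoVoicedSpeechError("waveform shorter than one pitch frame")
    n_frames = 1 + (x.size - frame) // hop
    idx = np.arange(frame)[None, :] + hop * np.arange(n_frames)[:, None]
    frames = x[idx]
    frames = frames - frames.mean(axis=1, keepdims=True)
    energies = np.mean(frames**2, axis=1)
    loud = 10 * np.log10(energies / max(energies.max(), 1e-300) + 1e-300) > silence_db
    loud &= energies > 1e-9  # absolute floor: numerical residue is not speech

    ac = _autocorr_frames(frames)
    lag_min = max(2, int(math.floor(w.rate / fmax)))
    lag_max = min(frame - 2, int(math.ceil(w.rate / fmin)))
    if lag_max <= lag_min:
        raise ValueError("frame too short for the requested fmin")
    window = ac[:, lag_min : lag_max + 1]
    # octave cost: prefer the shorter lag when a subharmonic ties the peak
    lags = np.arange(lag_min, lag_max + 1)
    score = window - 0.05 * np.log2(lags / lag_min)[None, :]
    peak_rel = np.argmax(score, axis=1)
    peak_lag = peak_rel + lag_min
    rows = np.arange(n_frames)
    r = window[rows, peak_rel]

    # parabolic interpolation around the integer peak
    lagf = peak_lag.astype(float)
    interior = (peak_lag > lag_min) & (peak_lag < lag_max)
    lm = ac[rows[interior], peak_lag[interior] - 1]
    l0 = ac[rows[interior], peak_lag[interior]]
    lp = ac[rows[interior], peak_lag[interior] + 1]
    denom = lm - 2 * l0 + lp
    shift = np.where(np.abs(denom) > 1e-12, 0.5 * (lm - lp) / denom, 0.0)
    lagf[interior] += np.clip(shift, -1, 1)

    voiced = (r >= voicing_threshold) & loud
    f0 = np.where(voiced, w.rate / lagf, np.nan)
    if voiced.sum() == 0:
        raise NoVoicedSpeechError("no voiced speech found")

    med = np.nanmedian(f0)
    octave_out = voiced & (np.abs(np.log2(f0 / med)) > 1.0)
    voiced &= ~octave_out
    f0[~voiced] = np.nan
    if voiced.sum() == 0:
        raise NoVoicedSpeechError("no voiced speech after octave guard")

    cycle_times, periods, amps = _cycle_marks(
        _fundamental_band(x, w.rate, float(np.nanmedian(f0))),
        w.rate, f0, voiced, hop, frame,
    )
    return PitchTrack(
        frame_times=(np.arange(n_frames) * hop + frame / 2) / w.rate,
        f0=f0,
        voiced=voiced,
        cycle_times=cycle_times,
        periods=periods,
        peak_amps=amps,
        rate=w.rate,
    )


def _fundamental_band(x: np.ndarray, rate: int, f0_med: float) -> np.ndarray:
    """Zero-phase bandpass around the median F0.

    Cycle peaks are picked on the fundamental component: on the raw
    waveform, noise makes the argmax flip between formant-ringing peaks
    a millisecond apart, which would swamp genuine period perturbation.
    The wide (0.6-1.6x) band keeps the jitter modulation sidebands.
    """
    lo = max(40.0, 0.6 * f0_med)
    hi = min(0.45 * rate, 1.6 * f0_med)
    sos = signal.butter(2, [lo, hi], btype="bandpass", fs=rate, output="sos")
    return signal.sosfiltfilt(sos, x)


def _cycle_marks(x, rate, f0, voiced, hop, frame):
    """Walk each voiced run, placing one mark per glottal cycle.

    ``x`` is the fundamental-band signal.  Marks snap to the
    maximum-amplitude sample within +-T/4 of the predicted next-mark
    position, t + T with T the local pitch period, then get a parabolic
    sub-sample refinement so that period estimates are not quantized to
    the sample grid.
    """

    def refine(k: int) -> float:
        if 1 <= k < x.size - 1:
            ym, y0, yp = abs(x[k - 1]), abs(x[k]), abs(x[k + 1])
            denom = ym - 2 * y0 + yp
            if abs(denom) > 1e-300:
                return k + float(np.clip(0.5 * (ym - yp) / denom, -0.5, 0.5))
        return float(k)

    cycle_times: list[float] = []
    periods: list[float] = []
    amps: list[float] = []
    v = np.flatnonzero(voiced)
    if v.size == 0:
        return (np.array([]),) * 3
    runs = np.split(v, np.flatnonzero(np.diff(v) > 1) + 1)
    frame_centers = (np.arange(f0.size) * hop + frame / 2)

    for run in runs:
        start = int(run[0] * hop)
        end = min(x.size, int(run[-1] * hop + frame))
        t = start
        # seed the first mark at the peak of the first cycle
        T = rate / _local_f0(f0, frame_centers, t, run)
        seg = np.abs(x[t : min(end, t + int(T) + 1)])
        if seg.size == 0:
            continue
        t = t + int(np.argmax(seg))
        run_marks = [refine(t)]
        while True:
            T = rate / _local_f0(f0, frame_centers, t, run)
            lo = t + int(0.75 * T)
            hi = t + int(1.25 * T) + 1
            if hi > end:
                break
            nxt = lo + int(np.argmax(np.abs(x[lo:hi])))
            run_marks.append(refine(nxt))
            t = nxt
        if len(run_marks) >= 4:
            # drop the first and last cycle of the run: onset transients
            # and filter edges make their periods unreliable
            marks = np.asarray(run_marks, dtype=float)[1:-1]
            p = np.diff(marks) / rate
            # amplitude of the cycle between consecutive marks
            a = np.array(
                [np.max(np.abs(x[int(marks[i]) : int(marks[i + 1]) + 1])) for i in range(p.size)]
            )
            cycle_times.extend(marks / rate)
            periods.extend(p)
            amps.extend(a)
    return np.asarray(cycle_times), np.asarray(periods), np.asarray(amps)


def _local_f0(f0, frame_centers, sample_pos, run):
    """F0 at a sample position, from the nearest voiced frame in the run."""
    centers = frame_centers[run]
    j = run[int(np.argmin(np.abs(centers - sample_pos)))]
    return f0[j]


MIN_CYCLES = 11


def pitch_features(pt: PitchTrack) -> dict[str, float]:
    """Median/mean/SD of the voiced F0 contour, in Hz."""
    f = pt.voiced_f0
    return {
        "MedianPitch": float(np.median(f)),
        "MeanPitch": float(np.mean(f)),
        "StdDevPitch": float(np.std(f)),
    }


def jitter_features(pt: PitchTrack) -> dict[str, float]:
    """Period-perturbation (jitter) family from the cycle periods T_i.

    LocalJitter       mean |T_i - T_{i-1}| / mean T
    LocalAbsoluteJitter  mean |T_i - T_{i-1}|  (seconds)
    RapJitter         mean |T_i - 3-point centered mean| / mean T
    Ppq5Jitter        same with a 5-point centered mean
    DdpJitter         mean |(T_{i+1}-T_i) - (T_i-T_{i-1})| / mean T  (= 3 x Rap)
    MeanJitter, MedianJitter  mean/median |T_i - T_{i-1}| / median T

    Returns NaN-valued entries (with a warning) when fewer than 11
    periods are available.
    """
    T = pt.periods
    names = ["MeanJitter", "MedianJitter", "LocalJitter", "LocalAbsoluteJitter",
             "RapJitter", "Ppq5Jitter", "DdpJitter"]
    if T.size < MIN_CYCLES:
        log.warning("jitter: only %d periods (<%d); features missing", T.size, MIN_CYCLES)
        return {n: float("nan") for n in names}
    d = np.abs(np.diff(T))
    mean_T = float(np.mean(T))
    med_T = float(np.median(T))
    ddiff = np.abs(np.diff(T, 2))
    return {
        "MeanJitter": float(np.mean(d)) / med_T,
        "MedianJitter": float(np.median(d)) / med_T,
        "LocalJitter": float(np.mean(d)) / mean_T,
        "LocalAbsoluteJitter": float(np.mean(d)),
        "RapJitter": _pq(T, 3) / mean_T,
        "Ppq5Jitter": _pq(T, 5) / mean_T,
        "DdpJitter": float(np.mean(ddiff)) / mean_T,
    }


def _pq(x: np.ndarray, n: int) -> float:
    """N-point perturbation quotient numerator: mean |x_i - centered n-mean|."""
    half = n // 2
    kernel = np.ones(n) / n
    smooth = np.convolve(x, kernel, mode="valid")  # centered n-point means
    return float(np.mean(np.abs(x[half : x.size - half] - smooth)))


def shimmer_features(pt: PitchTrack) -> dict[str, float]:
    """Amplitude-perturbation (shimmer) family from cycle amplitudes A_i.

    Mirrors the jitter family on amplitudes; LocaldbShimmer is the mean
    absolute base-10 log amplitude ratio in dB, and DdaShimmer equals
    3 x Apq3Shimmer.  Non-positive amplitudes are dropped with a warning.
    """
    A = pt.peak_amps
    names = ["MeanShimmer", "MedianShimmer", "LocalShimmer", "LocaldbShimmer",
             "Apq3Shimmer", "Apq5Shimmer", "Apq11Shimmer", "DdaShimmer"]
    if np.any(A <= 0):
        log.warning("shimmer: dropping %d non-positive amplitudes", int(np.sum(A <= 0)))
        A = A[A > 0]
    if A.size < MIN_CYCLES:
        log.warning("shimmer: only %d amplitudes (<%d); features missing", A.size, MIN_CYCLES)
        return {n: float("nan") for n in names}
    d = np.abs(np.diff(A))
    mean_A = float(np.mean(A))
    med_A = float(np.median(A))
    apq3 = _pq(A, 3) / mean_A
    return {
        "MeanShimmer": float(np.mean(d)) / med_A,
        "MedianShimmer": float(np.median(d)) / med_A,
        "LocalShimmer": float(np.mean(d)) / mean_A,
        "LocaldbShimmer": float(np.mean(np.abs(20 * np.log10(A[1:] / A[:-1])))),
        "Apq3Shimmer": apq3,
        "Apq5Shimmer": _pq(A, 5) / mean_A,
        "Apq11Shimmer": _pq(A, 11) / mean_A,
        "DdaShimmer": 3.0 * apq3,
    }


def hnr(
    w: Waveform,
    pt: PitchTrack,
    frame_s: float = 0.040,
    hop_s: float = 0.010,
) -> float:
    """Harmonics-to-noise ratio in dB, autocorrelation method.

    Per voiced frame the normalized autocorrelation peak r at the F0 lag
    splits signal power into a periodic part r and an aperiodic part
    1 - r, giving frame HNR = 10 log10(r / (1-r)); the mean over voiced
    frames is returned, clipped to [-20, 60] dB.
    """
    if pt.voiced.sum() < 5:
        raise NoVoicedSpeechError("need at least 5 voiced frames for HNR")
    x = w.samples
    frame = int(round(frame_s * w.rate))
    hop = int(round(hop_s * w.rate))
    n_frames = 1 + (x.size - frame) // hop
    idx = np.arange(frame)[None, :] + hop * np.arange(n_frames)[:, None]
    frames = x[idx]
    frames = frames - frames.mean(axis=1, keepdims=True)
    ac = _autocorr_frames(frames)

    vals = []
    for j in np.flatnonzero(pt.voiced[:n_frames]):
        lag = w.rate / pt.f0[j]
        lo = max(2, int(math.floor(lag)) - 1)
        hi = min(frame - 1, int(math.ceil(lag)) + 1)
        r = float(np.max(ac[j, lo : hi + 1]))
        r = min(max(r, 1e-6), 1 - 1e-9)
        vals.append(10 * math.log10(r / (1 - r)))
    return float(np.clip(np.mean(vals), -20.0, 60.0))
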