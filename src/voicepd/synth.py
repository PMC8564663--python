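"""Synthetic dysphonic voice and cohort generation.

The study data this package analyses — hundreds of home-recorded pangram
utterances from people with and without Parkinson disease — is not
publicly deposited, so this module synthesizes waveforms with the same
statistical structure the analysis relies on:

* a glottal pulse train whose cycle periods are perturbed multiplicatively
  (jitter) and whose pulse amplitudes are perturbed (shimmer),
* a slow fundamental-frequency wander (pitch instability),
* additive Gaussian noise calibrated to a target harmonics-to-noise ratio,
* vocal-tract coloring by cascaded second-order formant resonators,
* running speech approximated by several vowel-like segments separated by
  short low-energy gaps, with leading/trailing non-speech padding.

Parkinsonian dysphonia is emulated purely through these source
parameters: the PD group draws higher jitter/shimmer/pitch-drift and
lower HNR than controls.  Every synthesis step is driven by one seeded
generator, so identical parameters give bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .preprocess import Waveform, write_wav

#: Per-cycle AR(1) coefficient of the pitch wander.  Controls how
#: predictable the F0 contour is one cycle ahead: 1 would be a random
#: walk, 0 white flutter.
DRIFT_RHO = 0.9

#: Formant presets (center Hz, bandwidth Hz) for vowel-like segments.
VOWEL_FORMANTS: dict[str, list[tuple[float, float]]] = {
    "aa": [(730, 80), (1090, 90), (2440, 120)],
    "iy": [(270, 60), (2290, 100), (3010, 150)],
    "uw": [(300, 60), (870, 90), (2240, 130)],
    "eh": [(530, 70), (1840, 100), (2480, 140)],
    "ao": [(570, 80), (840, 90), (2410, 130)],
    "ah": [(640, 80), (1190, 100), (2390, 130)],
}


@dataclass
class VoiceParams:
    """Ground-truth source parameters for one synthetic voice.

    jitter_frac and shimmer_frac are the relative standard deviations of
    the cycle periods and cycle amplitudes; hnr_db is the target
    harmonics-to-noise power ratio in the 0-4 kHz band; f0_drift_sd is
    the SD (Hz) of the slow pitch wander around f0_base.
    """

    f0_base: float = 140.0
    f0_drift_sd: float = 3.0
    jitter_frac: float = 0.01
    shimmer_frac: float = 0.05
    hnr_db: float = 20.0
    formants: list[tuple[float, float]] = field(
        default_factory=lambda: list(VOWEL_FORMANTS["aa"])
    )
    duration_s: float = 2.0
    pad_pre_s: float = 0.4
    pad_post_s: float = 0.4
    n_segments: int = 1
    ambient_snr_db: float = 45.0
    seed: int = 0

    def validate(self) -> None:
        if not self.f0_base > 0:
            raise ValueError(f"f0_base must be > 0, got {self.f0_base}")
        if not 0 <= self.jitter_frac < 0.5:
            raise ValueError(f"jitter_frac must be in [0, 0.5), got {self.jitter_frac}")
        if not 0 <= self.shimmer_frac < 0.5:
            raise ValueError(
                f"shimmer_frac must be in [0, 0.5), got {self.shimmer_frac}"
            )
        if not self.duration_s > 0:
            raise ValueError(f"duration_s must be > 0, got {self.duration_s}")
        if self.pad_pre_s < 0 or self.pad_post_s < 0:
            raise ValueError("pad_pre_s/pad_post_s must be >= 0")
        if self.n_segments < 1:
            raise ValueError(f"n_segments must be >= 1, got {self.n_segments}")
        if self.f0_drift_sd < 0:
            raise ValueError(f"f0_drift_sd must be >= 0, got {self.f0_drift_sd}")


@dataclass
class CycleLog:
    """Per-cycle ground truth recorded during synthesis."""

    periods_s: np.ndarray  # actual cycle periods, seconds
    amplitudes: np.ndarray  # pulse amplitudes, linear
    f0_contour: np.ndarray  # pre-jitter cycle F0, Hz
    segment_ids: np.ndarray


def _rosenberg_pulse(phase: np.ndarray, open_frac: float = 0.4, close_frac: float = 0.16):
    """Rosenberg glottal flow evaluated at phases in [0, 1).

    A smooth rise over ``open_frac`` of the cycle and a faster cosine
    fall over ``close_frac``; zero during the closed phase.  The smooth
    closure gives the natural spectral tilt a pulse train lacks.
    """
    g = np.zeros_like(phase)
    rising = phase < open_frac
    g[rising] = 0.5 * (1 - np.cos(np.pi * phase[rising] / open_frac))
    closing = (phase >= open_frac) & (phase < open_frac + close_frac)
    g[closing] = np.cos(0.5 * np.pi * (phase[closing] - open_frac) / close_frac)
    return g


def _formant_filter(x: np.ndarray, formants, rate: int) -> np.ndarray:
    for fc, bw in formants:
        r = math.exp(-math.pi * bw / rate)
        theta = 2 * math.pi * fc / rate
        a = [1.0, -2 * r * math.cos(theta), r * r]
        # unity gain at the resonance peak
        b = [(1 - r) * math.sqrt(1 - 2 * r * math.cos(2 * theta) + r * r)]
        x = signal.lfilter(b, a, x)
    return x


def _render_segment(
    rng: np.random.Generator,
    params: VoiceParams,
    duration_s: float,
    formants,
    rate: int,
    seg_id: int,
    log: list,
) -> np.ndarray:
    """One voiced vowel-like segment; appends per-cycle truth to log."""
    n = int(round(duration_s * rate))
    out = np.zeros(n)
    t = 0.0
    drift = 0.0
    rho = DRIFT_RHO  # per-cycle AR(1): wander with stationary SD f0_drift_sd
    while True:
        drift = rho * drift + math.sqrt(1 - rho * rho) * params.f0_drift_sd * rng.standard_normal()
        f0 = max(40.0, params.f0_base + drift)
        eps = float(np.clip(rng.standard_normal(), -3, 3))
        period = (1.0 / f0) * (1.0 + params.jitter_frac * eps)
        amp = max(0.05, 1.0 + params.shimmer_frac * float(np.clip(rng.standard_normal(), -3, 3)))
        if t + period > duration_s:
            break
        k0 = int(math.ceil(t * rate))
        k1 = min(n, int(math.ceil((t + period) * rate)))
        phase = (np.arange(k0, k1) / rate - t) / period
        out[k0:k1] += amp * _rosenberg_pulse(phase)
        log.append((period, amp, f0, seg_id))
        t += period
    return _formant_filter(out, formants, rate)


def synthesize_voice(
    params: VoiceParams, rate: int = 16000, return_cycles: bool = False
):
    """Synthesize one utterance from source parameters.

    The voiced portion is split into ``n_segments`` vowel-like segments
    (distinct formant sets, 50-150 ms gaps) whose glottal cycles carry the
    requested jitter, shimmer and pitch drift; Gaussian noise is added so
    the harmonic-to-noise power ratio in the 0-4 kHz band equals
    ``hnr_db``; low-level ambient noise covers the whole recording
    including the non-speech pads.

    Returns the waveform, or ``(waveform, CycleLog)`` when
    ``return_cycles`` is true.  Deterministic given ``params.seed``.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)

    vowels = list(VOWEL_FORMANTS)
    if params.n_segments == 1:
        seg_formants = [params.formants]
        seg_durs = [params.duration_s]
        gaps = []
    else:
        order = rng.permutation(len(vowels))
        seg_formants = [
            VOWEL_FORMANTS[vowels[order[i % len(vowels)]]]
            for i in range(params.n_segments)
        ]
        w = 0.7 + 0.6 * rng.random(params.n_segments)
        seg_durs = list(params.duration_s * w / w.sum())
        gaps = list(rng.uniform(0.05, 0.15, params.n_segments - 1))

    log: list = []
    pieces = []
    voiced_mask_pieces = []
    for i, (dur, fmts) in enumerate(zip(seg_durs, seg_formants)):
        seg = _render_segment(rng, params, dur, fmts, rate, i, log)
        pieces.append(seg)
        voiced_mask_pieces.append(np.ones(seg.size, dtype=bool))
        if i < len(gaps):
            g = np.zeros(int(round(gaps[i] * rate)))
            pieces.append(g)
            voiced_mask_pieces.append(np.zeros(g.size, dtype=bool))
    speech = np.concatenate(pieces)
    voiced = np.concatenate(voiced_mask_pieces)

    # HNR calibration in the 0-4 kHz harmonic band over the voiced samples.
    # The aspiration noise itself is band-limited to that band so the
    # calibrated power ratio is exactly what an autocorrelation HNR
    # estimator is exposed to.
    sos = signal.butter(8, 4000, fs=rate, output="sos")
    harm_band_power = float(np.mean(signal.sosfilt(sos, speech)[voiced] ** 2))
    noise = signal.sosfilt(sos, rng.standard_normal(speech.size))
    noise_band_power = float(np.mean(noise[voiced] ** 2))
    if harm_band_power > 0 and params.hnr_db < 80:
        sigma = math.sqrt(
            harm_band_power * 10 ** (-params.hnr_db / 10) / noise_band_power
        )
        speech = speech + sigma * noise

    pre = np.zeros(int(round(params.pad_pre_s * rate)))
    post = np.zeros(int(round(params.pad_post_s * rate)))
    full = np.concatenate([pre, speech, post])

    # heterogeneous-device ambient noise over the entire recording
    speech_rms = math.sqrt(float(np.mean(speech**2))) or 1.0
    amb_sigma = speech_rms * 10 ** (-params.ambient_snr_db / 20)
    full = full + amb_sigma * rng.standard_normal(full.size)

    peak = np.max(np.abs(full))
    if peak > 0:
        full = full * (0.9 / peak)
    w = Waveform(full, rate)
    if not return_cycles:
        return w
    arr = np.array(log)
    cycles = CycleLog(
        periods_s=arr[:, 0].astype(float),
        amplitudes=arr[:, 1].astype(float),
        f0_contour=arr[:, 2].astype(float),
        segment_ids=arr[:, 3].astype(int),
    )
    return w, cycles


def f0_for_demographics(gender: str, age: float) -> float:
    """Mean fundamental frequency (Hz) expected for a speaker.

    Smooth population-level curves: the female F0 declines monotonically
    with age and stays above the male curve at every age; the male F0
    declines into middle age, bottoms near 45, and rises again in old
    age.  Valid for ages 18-95.
    """
    if not 18 <= age <= 95:
        raise ValueError(f"age must be in [18, 95], got {age}")
    g = gender.strip().lower()
    if g in ("female", "f", "woman"):
        return 210.0 - 0.55 * (age - 18.0)
    if g in ("male", "m", "man"):
        return 118.0 + 0.012 * (age - 45.0) ** 2
    raise ValueError(f"unknown gender label: {gender!r}")


@dataclass
class GroupVoiceStats:
    """Population mean/SD of the dysphonia source parameters for a group."""

    jitter_mean: float
    jitter_sd: float
    shimmer_mean: float
    shimmer_sd: float
    hnr_mean: float
    hnr_sd: float
    drift_mean: float
    drift_sd: float


#: Default group contrasts.  No quantitative effect sizes exist for the
#: emulated study population, so these are set to clinically plausible
#: magnitudes: PD voices roughly double the period/amplitude perturbation,
#: lose ~8 dB of HNR, and wander more in pitch.
CONTROL_STATS = GroupVoiceStats(0.008, 0.003, 0.040, 0.012, 22.0, 3.0, 3.0, 1.0)
PD_STATS = GroupVoiceStats(0.020, 0.006, 0.090, 0.025, 14.0, 3.0, 8.0, 2.5)


@dataclass
class CohortSpec:
    """Recipe for a synthetic cohort mirroring the emulated study.

    Defaults reproduce the study composition: 262 PD / 464 control
    (38.5% / 64.6% female), PD mean age 65.92 (SD 9.2) vs control 57.98
    (SD 14.2), and 7.4% of subjects recorded in a quiet lab setting
    (higher SNR) with the rest at home.
    """

    n_pd: int = 262
    n_control: int = 464
    female_frac_pd: float = 0.385
    female_frac_control: float = 0.646
    age_pd: tuple[float, float, float, float] = (65.92, 9.2, 35.0, 90.0)
    age_control: tuple[float, float, float, float] = (57.98, 14.2, 20.0, 90.0)
    pd_stats: GroupVoiceStats = field(default_factory=lambda: replace(PD_STATS))
    control_stats: GroupVoiceStats = field(default_factory=lambda: replace(CONTROL_STATS))
    lab_fraction: float = 0.074
    lab_snr_db: float = 45.0
    home_snr_db: float = 32.0
    duration_s: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_pd < 1 or self.n_control < 1:
            raise ValueError("n_pd and n_control must be >= 1")
        for name in ("female_frac_pd", "female_frac_control", "lab_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        d = dict(d)
        for key in ("pd_stats", "control_stats"):
            if key in d and isinstance(d[key], dict):
                d[key] = GroupVoiceStats(**d[key])
        for key in ("age_pd", "age_control"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


METADATA_COLUMNS = [
    "subject_id", "label", "gender", "age", "site",
    "f0_base", "jitter_frac", "shimmer_frac", "hnr_db", "seed",
]


@dataclass
class CohortManifest:
    """Result of cohort generation: metadata table plus file locations."""

    table: pd.DataFrame
    directory: Path
    csv_path: Path

    @property
    def wav_paths(self) -> list[Path]:
        return [self.directory / f"{sid}.wav" for sid in self.table["subject_id"]]


def _truncated_normal(rng, mean, sd, lo, hi):
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return x
    return float(np.clip(x, lo, hi))


def sample_voice_params(
    rng: np.random.Generator,
    stats: GroupVoiceStats,
    gender: str,
    age: float,
    duration_s: float,
    ambient_snr_db: float,
) -> VoiceParams:
    """Draw one subject's source parameters from group-level statistics."""
    f0 = _truncated_normal(rng, f0_for_demographics(gender, age), 12.0, 85.0, 380.0)
    return VoiceParams(
        f0_base=f0,
        f0_drift_sd=max(0.0, rng.normal(stats.drift_mean, stats.drift_sd)),
        jitter_frac=float(np.clip(rng.normal(stats.jitter_mean, stats.jitter_sd), 0.0, 0.3)),
        shimmer_frac=float(np.clip(rng.normal(stats.shimmer_mean, stats.shimmer_sd), 0.0, 0.3)),
        hnr_db=float(np.clip(rng.normal(stats.hnr_mean, stats.hnr_sd), 0.0, 40.0)),
        duration_s=duration_s,
        n_segments=int(rng.integers(3, 7)),
        ambient_snr_db=ambient_snr_db,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def generate_cohort(spec: CohortSpec, out_dir, write_audio: bool = True) -> CohortManifest:
    """Write one WAV per subject plus a metadata CSV.

    Exactly ``round(lab_fraction * n_total)`` subjects are flagged as lab
    recordings and receive the (higher) lab ambient SNR.  Deterministic
    given ``spec.seed``: rerunning with the same spec reproduces the
    metadata CSV byte for byte.  ``write_audio=False`` samples the same
    metadata (identical CSV) without rendering waveforms, for
    composition checks.
    """
    spec.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    n_total = spec.n_pd + spec.n_control
    n_lab = int(round(spec.lab_fraction * n_total))
    lab_idx = set(rng.choice(n_total, size=n_lab, replace=False).tolist())

    rows = []
    groups = [("pd", spec.n_pd, spec.female_frac_pd, spec.age_pd, spec.pd_stats)] + [
        ("non_pd", spec.n_control, spec.female_frac_control, spec.age_control, spec.control_stats)
    ]
    i = 0
    for label, n, female_frac, age_dist, stats in groups:
        for _ in range(n):
            gender = "female" if rng.random() < female_frac else "male"
            age = _truncated_normal(rng, *age_dist)
            site = "lab" if i in lab_idx else "home"
            snr = spec.lab_snr_db if site == "lab" else spec.home_snr_db
            params = sample_voice_params(rng, stats, gender, age, spec.duration_s, snr)
            sid = f"s{i:04d}"
            if write_audio:
                write_wav(out_dir / f"{sid}.wav", synthesize_voice(params))
            rows.append(
                dict(
                    subject_id=sid, label=label, gender=gender,
                    age=round(age, 2), site=site,
                    f0_base=round(params.f0_base, 3),
                    jitter_frac=round(params.jitter_frac, 6),
                    shimmer_frac=round(params.shimmer_frac, 6),
                    hnr_db=round(params.hnr_db, 3),
                    seed=params.seed,
                )
            )
            i += 1
    table = pd.DataFrame(rows, columns=METADATA_COLUMNS)
    csv_path = out_dir / "metadata.csv"
    table.to_csv(csv_path, index=False)
    return CohortManifest(table=table, directory=out_dir, csv_path=csv_path)
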