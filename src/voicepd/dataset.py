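"""Per-recording feature extraction and cohort assembly.

One recording yields a named 52-dimensional feature vector: 3 pitch
statistics, 7 jitter variants, 8 shimmer variants, 13 MFCC means,
13 MFCC variations, 4 relative band powers, HNR, RPDE, DFA, and PPE.
This module runs the full extraction chain (trim -> pitch track ->
feature families) per file, assembles the cohort table with labels and
covariates, and applies correlation-based feature pruning.

Pruning iterates feature pairs in the fixed order below and drops the
later-ordered member of any still-kept pair whose absolute Pearson
correlation exceeds the threshold, making the kept set reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import acoustic, spectral
from .preprocess import Waveform, read_wav, trim_to_speech

log = logging.getLogger(__name__)

#: Canonical feature ordering; pruning and reports follow it.
FEATURE_ORDER: list[str] = (
    ["MedianPitch", "MeanPitch", "StdDevPitch"]
    + ["MeanJitter", "MedianJitter", "LocalJitter", "LocalAbsoluteJitter",
       "RapJitter", "Ppq5Jitter", "DdpJitter"]
    + ["MeanShimmer", "MedianShimmer", "LocalShimmer", "LocaldbShimmer",
       "Apq3Shimmer", "Apq5Shimmer", "Apq11Shimmer", "DdaShimmer"]
    + [f"MeanMFCC_{k}" for k in range(13)]
    + [f"VariationMFCC_{k}" for k in range(13)]
    + [f"RelBandPower_{k}" for k in range(4)]
    + ["HNR", "RPDE", "DFA", "PPE"]
)
assert len(FEATURE_ORDER) == 52


def extract_features(w: Waveform, mfcc_variation: str = "std") -> dict[str, float]:
    """All 52 features for one (untrimmed) waveform.

    Features whose preconditions fail (e.g. too few cycles) are NaN.
    """
    trimmed, _ = trim_to_speech(w)
    pt = acoustic.track_pitch(trimmed)
    out: dict[str, float] = {}
    out.update(acoustic.pitch_features(pt))
    out.update(acoustic.jitter_features(pt))
    out.update(acoustic.shimmer_features(pt))

    mean, var = spectral.mfcc_stats(trimmed, variation=mfcc_variation)
    for k in range(13):
        out[f"MeanMFCC_{k}"] = float(mean[k])
        out[f"VariationMFCC_{k}"] = float(var[k])
    rbp = spectral.rel_band_power(trimmed)
    for k in range(4):
        out[f"RelBandPower_{k}"] = float(rbp[k])

    out["HNR"] = acoustic.hnr(trimmed, pt)
    out["RPDE"] = spectral.rpde(trimmed, pt)
    out["DFA"] = spectral.dfa(trimmed)
    try:
        out["PPE"] = spectral.ppe(pt)
    except ValueError as e:
        log.warning("PPE missing: %s", e)
        out["PPE"] = float("nan")
    return {name: out[name] for name in FEATURE_ORDER}


@dataclass
class Cohort:
    """Feature matrix plus labels and covariates for many subjects.

    ``X`` is indexed by subject_id with columns ``kept_features``;
    ``y`` is 1 for PD, 0 for non-PD.  ``covariates`` carries gender,
    age, and site aligned with ``X``.
    """

    X: pd.DataFrame
    y: np.ndarray
    covariates: pd.DataFrame
    kept_features: list[str]
    extraction_log: list[str] = field(default_factory=list)
    pruning_report: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.X)

    def subset(self, mask: np.ndarray) -> "Cohort":
        mask = np.asarray(mask)
        return Cohort(
            X=self.X.iloc[mask].copy() if mask.dtype == bool else self.X.iloc[mask].copy(),
            y=self.y[mask],
            covariates=self.covariates.iloc[mask].copy(),
            kept_features=list(self.kept_features),
            extraction_log=list(self.extraction_log),
            pruning_report=dict(self.pruning_report),
        )

    def to_frame(self) -> pd.DataFrame:
        out = self.X.copy()
        out["label"] = np.where(self.y == 1, "pd", "non_pd")
        for c in self.covariates.columns:
            out[c] = self.covariates[c].to_numpy()
        return out


LABEL_MAP = {"pd": 1, "non_pd": 0, "non-pd": 0, "nonpd": 0, "control": 0}


def extract_all(
    wav_paths,
    metadata: pd.DataFrame | str | Path,
    mfcc_variation: str = "std",
    drop_missing: bool = True,
) -> Cohort:
    """Extract the full feature table for a cohort of recordings.

    ``metadata`` rows (subject_id, label, gender, age, site) must align
    with ``wav_paths``.  Per-file failures are logged and the subject
    excluded; only if every file fails is an error raised.  Subjects
    with any missing (NaN) feature are dropped and logged when
    ``drop_missing`` is set, keeping the kept columns NaN-free.
    """
    if not isinstance(metadata, pd.DataFrame):
        metadata = pd.read_csv(metadata)
    wav_paths = [Path(p) for p in wav_paths]
    if len(wav_paths) != len(metadata):
        raise ValueError("metadata rows and wav paths differ in length")

    rows, keep_idx, elog = [], [], []
    for i, p in enumerate(wav_paths):
        try:
            feats = extract_features(read_wav(p), mfcc_variation=mfcc_variation)
        except Exception as e:  # per-file failure: exclude, keep going
            elog.append(f"EXCLUDED {p.name}: {type(e).__name__}: {e}")
            log.warning("excluding %s: %s", p.name, e)
            continue
        rows.append(feats)
        keep_idx.append(i)
    if not rows:
        raise RuntimeError("feature extraction failed for every recording")

    meta = metadata.iloc[keep_idx].reset_index(drop=True)
    X = pd.DataFrame(rows, columns=FEATURE_ORDER)
    X.index = pd.Index(meta["subject_id"], name="subject_id")

    if drop_missing:
        bad = X.isna().any(axis=1).to_numpy()
        for sid in X.index[bad]:
            elog.append(f"DROPPED {sid}: missing features")
        X = X.loc[~bad]
        meta = meta.loc[~bad].reset_index(drop=True)

    y = meta["label"].astype(str).str.lower().map(LABEL_MAP)
    if y.isna().any():
        raise ValueError(f"unrecognized labels: {set(meta['label'][y.isna()])}")
    cov_cols = [c for c in ("gender", "age", "site") if c in meta.columns]
    cov = meta[cov_cols].copy()
    cov.index = X.index
    return Cohort(
        X=X, y=y.to_numpy(dtype=int), covariates=cov,
        kept_features=list(FEATURE_ORDER), extraction_log=elog,
    )


def prune_correlated(cohort: Cohort, threshold: float = 0.9) -> Cohort:
    """Drop the later-ordered feature of every over-correlated pair.

    Pairs are visited in the canonical feature order; whenever both
    members are still kept and |Pearson r| > threshold, the
    later-ordered feature is dropped.  Constant columns correlate with
    nothing (r treated as 0, with a warning).  The returned cohort
    records a ``pruning_report`` mapping each dropped feature to the
    kept partner and the offending r.
    """
    if cohort.n < 3:
        raise ValueError("pruning needs at least 3 subjects")
    feats = list(cohort.kept_features)
    vals = cohort.X[feats].to_numpy()
    sd = vals.std(axis=0)
    const = sd == 0
    if const.any():
        log.warning("constant columns treated as uncorrelated: %s",
                    [f for f, c in zip(feats, const) if c])
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(vals, rowvar=False)
    corr[np.isnan(corr)] = 0.0
    corr[const, :] = 0.0
    corr[:, const] = 0.0

    kept = dict.fromkeys(feats, True)
    report: dict[str, dict] = {}
    for i, fi in enumerate(feats):
        if not kept[fi]:
            continue
        for j in range(i + 1, len(feats)):
            fj = feats[j]
            if kept[fj] and abs(corr[i, j]) > threshold:
                kept[fj] = False
                report[fj] = {"kept_partner": fi, "r": float(corr[i, j])}
    kept_list = [f for f in feats if kept[f]]
    return Cohort(
        X=cohort.X[kept_list].copy(), y=cohort.y,
        covariates=cohort.covariates, kept_features=kept_list,
        extraction_log=list(cohort.extraction_log), pruning_report=report,
    )
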