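"""Shared fixtures: synthetic waveforms and feature-space cohorts.

Audio fixtures are synthesized on the fly; modeling/experiment tests
use direct feature-space cohorts (Gaussian features with an optional
planted class effect) so they stay fast and their ground truth is
known exactly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from voicepd.dataset import Cohort
from voicepd.preprocess import Waveform


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tone():
    """Factory for pure tones: tone(freq, duration_s, rate, amp)."""

    def make(freq=150.0, duration_s=2.0, rate=16000, amp=0.8):
        t = np.arange(int(duration_s * rate)) / rate
        return Waveform(amp * np.sin(2 * np.pi * freq * t), rate)

    return make


def make_feature_cohort(
    n: int = 100,
    d: int = 8,
    effect: float = 0.0,
    pd_fraction: float = 0.36,
    informative: int = 1,
    seed: int = 0,
    gender_balanced_effect: bool = True,
) -> Cohort:
    """Gaussian feature cohort with a mean-shift class effect.

    ``effect`` is added to the first ``informative`` features of PD
    subjects; 0 gives a null cohort (labels independent of features).
    Covariates carry gender, age and site so the experiment selectors
    can be exercised; the class effect is identical across genders.
    """
    r = np.random.default_rng(seed)
    y = (r.random(n) < pd_fraction).astype(int)
    X = r.standard_normal((n, d))
    X[y == 1, :informative] += effect
    gender = np.where(r.random(n) < 0.5, "female", "male")
    age = np.clip(r.normal(60, 12, n), 20, 90).round(1)
    site = np.where(r.random(n) < 0.074, "lab", "home")
    idx = pd.Index([f"s{i:04d}" for i in range(n)], name="subject_id")
    cols = [f"feat_{j}" for j in range(d)]
    return Cohort(
        X=pd.DataFrame(X, index=idx, columns=cols),
        y=y,
        covariates=pd.DataFrame({"gender": gender, "age": age, "site": site}, index=idx),
        kept_features=cols,
    )


@pytest.fixture
def feature_cohort():
    return make_feature_cohort
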