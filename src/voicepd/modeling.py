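"""Classification under leave-one-out cross-validation.

The screening task is PD vs non-PD from the per-recording feature
vector.  Cohorts of self-selected volunteers are imbalanced (roughly
1:1.8 here), so training folds can be rebalanced by synthetic minority
oversampling (SMOTE), interpolating new minority points between nearest
minority neighbors; the SVM variant seeds only from borderline minority
points inside the margin band of a linear maximum-margin classifier.

Evaluation is leave-one-out: each subject is scored by a model fitted
on the other n-1, with feature standardization and oversampling redone
inside every training fold — oversampling before the split would leak
synthetic copies of the held-out subject into training.  Held-out
scores are pooled into a single ROC; AUC is the Mann-Whitney
probability that a random PD score exceeds a random non-PD score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import NearestNeighbors
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

ALGORITHMS = ("svm", "random_forest", "gradient_boosting", "extreme_gradient_boosting")
OVERSAMPLERS = ("none", "smote", "svm_smote")


@dataclass
class ModelSpec:
    """One classifier configuration.

    ``gradient_boosting`` is backed by LightGBM and
    ``extreme_gradient_boosting`` by XGBoost; hyperparameters default to
    the libraries' own (no tuning), overridable per spec.
    """

    algorithm: str = "extreme_gradient_boosting"
    hyperparameters: dict = field(default_factory=dict)
    oversampler: str = "none"
    smote_k: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}; one of {ALGORITHMS}")
        if self.oversampler not in OVERSAMPLERS:
            raise ValueError(f"unknown oversampler {self.oversampler!r}; one of {OVERSAMPLERS}")
        if self.smote_k < 1:
            raise ValueError(f"smote_k must be >= 1, got {self.smote_k}")

    @property
    def name(self) -> str:
        return self.algorithm if self.oversampler == "none" else f"{self.algorithm}+{self.oversampler}"


def smote_oversample(
    X: np.ndarray, y: np.ndarray, k: int = 5, seed: int = 0, variant: str = "smote"
) -> tuple[np.ndarray, np.ndarray]:
    """Balance classes by interpolated synthetic minority samples.

    Each synthetic point is x + u (x_nn - x) with u ~ U(0, 1) and x_nn
    one of the k nearest minority neighbors of a minority seed point
    (Euclidean distance on standardized features; k is capped at
    minority-1).  The ``svm_smote`` variant restricts seed points to
    minority samples inside the margin band (|decision| <= 1) of a
    linear-kernel max-margin classifier fitted on (X, y), falling back
    to all minority points if the band is empty.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("smote_oversample requires both classes present")
    minority = classes[np.argmin(counts)]
    n_needed = int(counts.max() - counts.min())
    if n_needed == 0:
        return X.copy(), y.copy()

    rng = np.random.default_rng(seed)
    min_idx = np.flatnonzero(y == minority)
    Xs = StandardScaler().fit_transform(X)
    Xmin_s = Xs[min_idx]

    if Xmin_s.shape[0] < 2:
        raise ValueError("need at least 2 minority samples to interpolate")
    k_eff = min(k, Xmin_s.shape[0] - 1)
    nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(Xmin_s)
    neighbors = nn.kneighbors(Xmin_s, return_distance=False)[:, 1:]

    if variant == "svm_smote":
        svc = SVC(kernel="linear").fit(Xs, y)
        margin = np.abs(svc.decision_function(Xs[min_idx])) <= 1.0
        seeds_local = np.flatnonzero(margin)
        if seeds_local.size == 0:
            seeds_local = np.arange(min_idx.size)
    elif variant == "smote":
        seeds_local = np.arange(min_idx.size)
    else:
        raise ValueError(f"unknown SMOTE variant {variant!r}")

    pick = rng.choice(seeds_local, size=n_needed, replace=True)
    nb_local = neighbors[pick, rng.integers(0, k_eff, size=n_needed)]
    u = rng.random((n_needed, 1))
    # interpolation is affine-invariant, so synthesize in the original space
    Xnew = X[min_idx[pick]] + u * (X[min_idx[nb_local]] - X[min_idx[pick]])
    return (
        np.vstack([X, Xnew]),
        np.concatenate([y, np.full(n_needed, minority, dtype=y.dtype)]),
    )


class FittedClassifier:
    """A fitted model exposing a monotone PD score in [0, 1].

    Tree-ensemble algorithms additionally expose their fitted boosters
    for Shapley attribution via :mod:`voicepd.attribution`.
    """

    def __init__(self, spec: ModelSpec, model, kind: str):
        self.spec = spec
        self.model = model
        self.kind = kind

    def score(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.kind == "svm":
            return expit(self.model.decision_function(X))
        import warnings

        with warnings.catch_warnings():
            # LightGBM warns about feature names on every ndarray predict
            warnings.filterwarnings("ignore", message=".*valid feature names.*")
            return self.model.predict_proba(X)[:, 1]

    def predict(self, X, threshold: float = 0.5) -> np.ndarray:
        return (self.score(X) >= threshold).astype(int)

    @property
    def is_tree_ensemble(self) -> bool:
        return self.kind != "svm"


def _make_estimator(spec: ModelSpec):
    hp = dict(spec.hyperparameters)
    if spec.algorithm == "svm":
        return SVC(kernel=hp.pop("kernel", "rbf"), random_state=spec.seed, **hp), "svm"
    if spec.algorithm == "random_forest":
        hp.setdefault("n_estimators", 100)
        return RandomForestClassifier(random_state=spec.seed, n_jobs=1, **hp), "random_forest"
    if spec.algorithm == "gradient_boosting":
        import lightgbm

        hp.setdefault("verbose", -1)
        hp.setdefault("n_jobs", 1)
        return lightgbm.LGBMClassifier(random_state=spec.seed, **hp), "lightgbm"
    if spec.algorithm == "extreme_gradient_boosting":
        import xgboost

        hp.setdefault("n_jobs", 1)
        hp.setdefault("tree_method", "hist")
        return xgboost.XGBClassifier(random_state=spec.seed, **hp), "xgboost"
    raise ValueError(f"unknown algorithm {spec.algorithm!r}")


def train_classifier(spec: ModelSpec, X, y) -> FittedClassifier:
    """Oversample per the spec, fit, and wrap with a [0, 1] score.

    Deterministic given the spec's seed.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if spec.oversampler != "none":
        X, y = smote_oversample(X, y, k=spec.smote_k, seed=spec.seed, variant=spec.oversampler)
    est, kind = _make_estimator(spec)
    est.fit(X, y)
    return FittedClassifier(spec, est, kind)


@dataclass
class CVResult:
    """Pooled leave-one-out result for one model spec."""

    subject_ids: list
    scores: np.ndarray
    labels: np.ndarray
    auc: float
    accuracy: float
    n_folds: int
    spec: ModelSpec

    def to_dict(self) -> dict:
        return {
            "spec": self.spec.name,
            "seed": self.spec.seed,
            "auc": self.auc,
            "accuracy": self.accuracy,
            "n_folds": self.n_folds,
        }


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve, ties counted half (Mann-Whitney form)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("roc_auc requires both classes present")
    ranks = rankdata(scores)
    return float((ranks[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def loocv_evaluate(spec: ModelSpec, cohort, threshold: float = 0.5) -> CVResult:
    """Leave-one-out evaluation with in-fold standardization/oversampling.

    For each subject: standardize on the remaining n-1, oversample the
    training portion only, fit, and score the held-out subject.  Pooled
    scores give AUC; accuracy is the fraction correct at the score
    threshold (default 0.5).
    """
    X = cohort.X.to_numpy(dtype=float)
    y = np.asarray(cohort.y, dtype=int)
    n = X.shape[0]
    if n < 10:
        raise ValueError(f"LOOCV needs >= 10 subjects, got {n}")
    if np.unique(y).size < 2:
        raise ValueError("LOOCV requires both classes present")

    scores = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        if np.unique(y[mask]).size < 2:
            raise ValueError("a training fold lost one class entirely")
        scaler = StandardScaler().fit(X[mask])
        clf = train_classifier(spec, scaler.transform(X[mask]), y[mask])
        scores[i] = clf.score(scaler.transform(X[i : i + 1]))[0]

    return CVResult(
        subject_ids=list(cohort.X.index),
        scores=scores,
        labels=y,
        auc=roc_auc(scores, y),
        accuracy=float(np.mean((scores >= threshold).astype(int) == y)),
        n_folds=n,
        spec=spec,
    )
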