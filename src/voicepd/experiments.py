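"""Cohort-level experiment designs.

Voice characteristics are strongly gender- and age-dependent, so a
PD classifier can accidentally learn demographics instead of disease.
The standard checks, reproduced here, are:

* stratified models — refit and evaluate on male-only, female-only,
  and age-trimmed (>= 50 years) subsets;
* recording-environment ablations — drop the small lab-recorded
  fraction entirely (experiment 1), or repeatedly drop an equally
  sized random slice of home data (experiment 2, averaged over
  repeats), and compare AUCs.  A model that leans on recording
  quality rather than voice pathology degrades in the first ablation
  but not the second.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset import Cohort
from .modeling import ModelSpec, loocv_evaluate

SELECTORS = ("all", "male", "female", "age_trimmed", "drop_lab", "drop_random_home")


@dataclass
class ExperimentPlan:
    """One selector applied to a cohort, evaluated for several models."""

    selector: str = "all"
    model_specs: list[ModelSpec] = field(default_factory=lambda: [ModelSpec()])
    min_age: float = 50.0
    drop_fraction: float = 0.07
    repeats: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.selector not in SELECTORS:
            raise ValueError(f"unknown selector {self.selector!r}; one of {SELECTORS}")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


class EmptyClassError(ValueError):
    """A selector removed one class (or everything) from the cohort."""


def select(cohort: Cohort, plan: ExperimentPlan, rng=None) -> Cohort:
    """Apply the plan's subset selector once."""
    sel = plan.selector
    if sel == "all":
        mask = np.ones(cohort.n, dtype=bool)
    elif sel in ("male", "female"):
        mask = (cohort.covariates["gender"].to_numpy() == sel)
    elif sel == "age_trimmed":
        mask = cohort.covariates["age"].to_numpy() >= plan.min_age
    elif sel == "drop_lab":
        mask = cohort.covariates["site"].to_numpy() != "lab"
    elif sel == "drop_random_home":
        if rng is None:
            rng = np.random.default_rng(plan.seed)
        home = np.flatnonzero(cohort.covariates["site"].to_numpy() == "home")
        n_drop = int(round(plan.drop_fraction * home.size))
        dropped = rng.choice(home, size=n_drop, replace=False)
        mask = np.ones(cohort.n, dtype=bool)
        mask[dropped] = False
    else:  # pragma: no cover - guarded in __post_init__
        raise ValueError(sel)
    sub = cohort.subset(mask)
    if sub.n == 0 or np.unique(sub.y).size < 2:
        raise EmptyClassError(f"selector {sel!r} left no usable two-class cohort")
    return sub


@dataclass
class ResultsBundle:
    """Grid of LOOCV metrics: model spec name -> {auc, accuracy, ...}."""

    selector: str
    results: dict[str, dict]
    n_raw: int

    def to_dict(self) -> dict:
        return {"selector": self.selector, "n_raw": self.n_raw, "results": self.results}


def run_plan(plan: ExperimentPlan, cohort: Cohort) -> ResultsBundle:
    """Evaluate every model spec on the selected sub-cohort.

    For ``drop_random_home`` the selection is redrawn ``repeats`` times
    and the metrics averaged.  Reported n values are raw subject counts
    before any oversampling; per-fold SMOTE counts are echoed as
    ``n_after_oversample`` (train-fold size after balancing).
    """
    rng = np.random.default_rng(plan.seed)
    results: dict[str, dict] = {}
    if plan.selector == "drop_random_home":
        subs = [select(cohort, plan, rng) for _ in range(plan.repeats)]
    else:
        subs = [select(cohort, plan, rng)]
    for spec in plan.model_specs:
        aucs, accs = [], []
        for sub in subs:
            res = loocv_evaluate(spec, sub)
            aucs.append(res.auc)
            accs.append(res.accuracy)
        n_raw = subs[0].n
        entry = {
            "auc": float(np.mean(aucs)),
            "accuracy": float(np.mean(accs)),
            "n_raw": n_raw,
            "repeats": len(subs),
        }
        if spec.oversampler != "none":
            counts = np.bincount(subs[0].y, minlength=2)
            entry["n_after_oversample"] = int(2 * counts.max())
        results[spec.name] = entry
    return ResultsBundle(selector=plan.selector, results=results, n_raw=subs[0].n)


def ablation_delta(results_all: ResultsBundle, results_ablated: ResultsBundle) -> dict[str, float]:
    """AUC(all) - AUC(ablated) per shared model spec.

    Positive values mean the ablation hurt.  Raises if the bundles share
    no model spec.
    """
    shared = set(results_all.results) & set(results_ablated.results)
    if not shared:
        raise ValueError("bundles share no model spec")
    return {
        name: results_all.results[name]["auc"] - results_ablated.results[name]["auc"]
        for name in sorted(shared)
    }
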