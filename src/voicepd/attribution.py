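"""Shapley attribution for tree ensembles.

A fitted tree ensemble is explained by distributing each prediction's
deviation from the expected score fairly across features (Shapley
values).  The value of a feature coalition S is the ensemble's
conditional expectation given S, evaluated per tree by the
path-dependent rule: at a node splitting on a conditioned feature the
instance's branch is followed; otherwise both subtrees are averaged,
weighted by their training cover (how many training rows reached them).

Two routes compute the same quantity:

* :func:`shapley_exact` — direct enumeration over all 2^d coalitions
  (d <= 15), the reference implementation;
* :func:`shap_explain` — the polynomial-time per-tree path algorithm,
  which tracks, along each root-to-leaf traversal, the proportion of
  feature-subset permutations that let the path be followed, and
  recovers each feature's contribution by unwinding it from the path.

The exact route is the oracle for the fast one; both satisfy the
efficiency axiom (attributions sum to prediction minus base value) by
construction of the game.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .modeling import FittedClassifier, ModelSpec, loocv_evaluate


# ------------------------------------------------------- tree containers

@dataclass
class Tree:
    """One regression tree in flat-array form.

    ``feature[i] < 0`` marks node i as a leaf with value ``value[i]``.
    ``cover[i]`` is the (weighted) number of training rows that reached
    node i.  ``cmp`` is "le" when the left branch is taken for
    x <= threshold, "lt" for x < threshold.
    """

    feature: np.ndarray
    threshold: np.ndarray
    left: np.ndarray
    right: np.ndarray
    value: np.ndarray
    cover: np.ndarray
    cmp: str = "le"

    def is_leaf(self, i: int) -> bool:
        return self.feature[i] < 0

    def goes_left(self, i: int, x: np.ndarray) -> bool:
        v = x[self.feature[i]]
        return v <= self.threshold[i] if self.cmp == "le" else v < self.threshold[i]


@dataclass
class TreeEnsemble:
    """Additive ensemble: score = base_offset + sum of tree outputs."""

    trees: list[Tree]
    base_offset: float = 0.0
    feature_names: list[str] = field(default_factory=list)
    n_features: int = 0

    def predict_raw(self, x: np.ndarray) -> float:
        total = self.base_offset
        for t in self.trees:
            i = 0
            while not t.is_leaf(i):
                i = t.left[i] if t.goes_left(i, x) else t.right[i]
            total += t.value[i]
        return float(total)


class NotTreeModelError(TypeError):
    """Raised for models without extractable trees (e.g. SVM)."""


def extract_ensemble(clf) -> TreeEnsemble:
    """Pull the fitted trees (with covers) out of a classifier.

    Supports random forests (scikit-learn), LightGBM, and XGBoost
    binary classifiers; boosted ensembles are explained in margin
    (log-odds) space, forests in probability space.
    """
    if isinstance(clf, FittedClassifier):
        if not clf.is_tree_ensemble:
            raise NotTreeModelError(
                f"{clf.kind} exposes no trees; Shapley attribution supports tree ensembles only"
            )
        model, names = clf.model, None
        return extract_ensemble(model)
    mod = type(clf).__module__
    if mod.startswith("sklearn"):
        return _from_sklearn_forest(clf)
    if mod.startswith("lightgbm"):
        return _from_lightgbm(clf)
    if mod.startswith("xgboost"):
        return _from_xgboost(clf)
    raise NotTreeModelError(f"cannot extract trees from {type(clf).__name__}")


def _from_sklearn_forest(rf) -> TreeEnsemble:
    trees = []
    k = len(rf.estimators_)
    for est in rf.estimators_:
        t = est.tree_
        val = t.value[:, 0, :]
        prob1 = val[:, 1] / np.maximum(val.sum(axis=1), 1e-300)
        trees.append(
            Tree(
                feature=t.feature.copy(),
                threshold=t.threshold.copy(),
                left=t.children_left.copy(),
                right=t.children_right.copy(),
                value=prob1 / k,
                cover=t.weighted_n_node_samples.copy(),
                cmp="le",
            )
        )
    return TreeEnsemble(trees, 0.0, n_features=rf.n_features_in_)


def _from_lightgbm(model) -> TreeEnsemble:
    booster = model.booster_ if hasattr(model, "booster_") else model
    dump = booster.dump_model()
    trees = []
    for info in dump["tree_info"]:
        feat, thr, left, right, value, cover = [], [], [], [], [], []

        def walk(node) -> int:
            idx = len(feat)
            feat.append(-1); thr.append(0.0); left.append(-1); right.append(-1)
            value.append(0.0); cover.append(0.0)
            if "leaf_value" in node and "split_feature" not in node:
                value[idx] = node["leaf_value"]
                cover[idx] = node.get("leaf_count", 1)
            else:
                feat[idx] = node["split_feature"]
                thr[idx] = node["threshold"]
                cover[idx] = node.get("internal_count", 1)
                left[idx] = walk(node["left_child"])
                right[idx] = walk(node["right_child"])
            return idx

        walk(info["tree_structure"])
        trees.append(
            Tree(np.array(feat), np.array(thr), np.array(left), np.array(right),
                 np.array(value), np.array(cover, dtype=float), cmp="le")
        )
    return TreeEnsemble(trees, 0.0, n_features=dump["max_feature_idx"] + 1)


def _from_xgboost(model) -> TreeEnsemble:
    booster = model.get_booster() if hasattr(model, "get_booster") else model
    cfg = json.loads(booster.save_config())
    base_score = float(cfg["learner"]["learner_model_param"]["base_score"])
    # binary:logistic stores base_score as a probability; margins add its log-odds
    objective = cfg["learner"]["learner_train_param"]["objective"]
    if "logistic" in objective:
        base = math.log(base_score / (1 - base_score))
    else:
        base = base_score
    trees = []
    for s in booster.get_dump(dump_format="json", with_stats=True):
        nodes = {}

        def collect(nd):
            nodes[nd["nodeid"]] = nd
            for ch in nd.get("children", []):
                collect(ch)

        collect(json.loads(s))
        order = sorted(nodes)
        remap = {nid: i for i, nid in enumerate(order)}
        n = len(order)
        feat = np.full(n, -1); thr = np.zeros(n)
        left = np.full(n, -1); right = np.full(n, -1)
        value = np.zeros(n); cover = np.zeros(n)
        for nid in order:
            nd = nodes[nid]; i = remap[nid]
            cover[i] = nd.get("cover", 1.0)
            if "leaf" in nd:
                value[i] = nd["leaf"]
            else:
                feat[i] = int(nd["split"].lstrip("f")) if nd["split"].startswith("f") else nd["split"]
                thr[i] = nd["split_condition"]
                left[i] = remap[nd["yes"]]
                right[i] = remap[nd["no"]]
        trees.append(Tree(feat, thr, left, right, value, cover, cmp="lt"))
    return TreeEnsemble(trees, base, n_features=booster.num_features())


# ------------------------------------------- conditional expectation game

def tree_conditional_expectation(tree: Tree, x: np.ndarray, conditioned) -> float:
    """E[tree(X) | X_S = x_S] under the path-dependent (cover) rule.

    At a node splitting on a conditioned feature, follow the instance's
    branch; otherwise average both subtrees weighted by training cover.
    """
    cond = set(int(f) for f in conditioned)
    n_nodes = tree.feature.size

    def rec(i: int) -> float:
        if tree.is_leaf(i):
            return float(tree.value[i])
        f = int(tree.feature[i])
        if f >= x.size:
            raise IndexError(f"tree splits on feature {f}, instance has {x.size}")
        if f in cond:
            return rec(tree.left[i] if tree.goes_left(i, x) else tree.right[i])
        l, r = tree.left[i], tree.right[i]
        cl, cr = tree.cover[l], tree.cover[r]
        tot = cl + cr
        if tot <= 0:
            return 0.5 * (rec(l) + rec(r))
        return (cl * rec(l) + cr * rec(r)) / tot

    if n_nodes == 0:
        return 0.0
    return rec(0)


def coalition_value(ensemble: TreeEnsemble, x: np.ndarray, conditioned) -> float:
    """v(S): ensemble conditional expectation for coalition S."""
    return ensemble.base_offset + sum(
        tree_conditional_expectation(t, x, conditioned) for t in ensemble.trees
    )


@dataclass
class ShapExplanation:
    """Per-feature attribution for one instance, in model-score units."""

    attributions: np.ndarray
    base_value: float
    instance_id: object = None

    @property
    def prediction(self) -> float:
        return float(self.base_value + self.attributions.sum())


def shapley_exact(model, instance, background=None) -> ShapExplanation:
    """Shapley values by full coalition enumeration (d <= 15).

    The coalition game is the path-dependent conditional expectation;
    the background distribution is the training cover statistics
    embedded in the trees (``background`` is accepted for interface
    symmetry and unused).  Exponential in d — the reference oracle for
    :func:`shap_explain`.
    """
    ensemble = model if isinstance(model, TreeEnsemble) else extract_ensemble(model)
    x = np.asarray(instance, dtype=float)
    d = x.size
    if d > 15:
        raise ValueError(
            f"{d} features is too many for exact enumeration; use shap_explain"
        )
    players = list(range(d))
    v_cache = {frozenset(): coalition_value(ensemble, x, ())}

    def v(S: frozenset) -> float:
        if S not in v_cache:
            v_cache[S] = coalition_value(ensemble, x, S)
        return v_cache[S]

    phi = np.zeros(d)
    fact = [math.factorial(i) for i in range(d + 1)]
    for j in players:
        others = [p for p in players if p != j]
        for size in range(d):
            w = fact[size] * fact[d - size - 1] / fact[d]
            for S in combinations(others, size):
                fs = frozenset(S)
                phi[j] += w * (v(fs | {j}) - v(fs))
    return ShapExplanation(attributions=phi, base_value=v(frozenset()))


# ----------------------------------------- polynomial-time tree algorithm

class _Path:
    """Feature path with permutation-weight bookkeeping (1-indexed)."""

    __slots__ = ("d", "z", "o", "w")

    def __init__(self):
        self.d: list[int] = []
        self.z: list[float] = []
        self.o: list[float] = []
        self.w: list[float] = []

    def copy(self) -> "_Path":
        p = _Path.__new__(_Path)
        p.d = self.d.copy(); p.z = self.z.copy()
        p.o = self.o.copy(); p.w = self.w.copy()
        return p


def _extend(m: _Path, pz: float, po: float, pi: int) -> None:
    l = len(m.d)
    m.d.append(pi); m.z.append(pz); m.o.append(po)
    m.w.append(1.0 if l == 0 else 0.0)
    for i in range(l - 1, -1, -1):  # i is 0-based over the old entries
        m.w[i + 1] += po * m.w[i] * (i + 1) / (l + 1)
        m.w[i] = pz * m.w[i] * (l - i) / (l + 1)


def _unwind(m: _Path, i: int) -> _Path:
    out = m.copy()
    l = len(m.d)
    n = out.w[l - 1]
    oi, zi = out.o[i], out.z[i]
    for j in range(l - 2, -1, -1):
        if oi != 0:
            t = out.w[j]
            out.w[j] = n * l / ((j + 1) * oi)
            n = t - out.w[j] * zi * (l - 1 - j) / l
        else:
            out.w[j] = out.w[j] * l / (zi * (l - 1 - j))
    for j in range(i, l - 1):
        out.d[j] = out.d[j + 1]; out.z[j] = out.z[j + 1]; out.o[j] = out.o[j + 1]
    out.d.pop(); out.z.pop(); out.o.pop(); out.w.pop()
    return out


def _unwound_sum(m: _Path, i: int) -> float:
    l = len(m.d)
    n = m.w[l - 1]
    oi, zi = m.o[i], m.z[i]
    total = 0.0
    for j in range(l - 2, -1, -1):
        if oi != 0:
            t = n * l / ((j + 1) * oi)
            total += t
            n = m.w[j] - t * zi * (l - 1 - j) / l
        else:
            total += m.w[j] * l / (zi * (l - 1 - j))
    return total


def tree_shap(tree: Tree, x: np.ndarray, n_features: int) -> np.ndarray:
    """Per-feature Shapley contributions of a single tree.

    The recursion walks every root-to-leaf path, maintaining for each
    feature on the path the fraction of coalitions in which the branch
    is followed when the feature is in (``o``) or out (``z``) of the
    coalition, together with permutation weights; at a leaf each
    feature's weight is unwound to yield its marginal contribution.
    """
    phi = np.zeros(n_features)

    def recurse(node: int, m: _Path, pz: float, po: float, pi: int) -> None:
        m = m.copy()
        _extend(m, pz, po, pi)
        if tree.is_leaf(node):
            leaf_v = float(tree.value[node])
            for i in range(1, len(m.d)):
                w = _unwound_sum(m, i)
                phi[m.d[i]] += w * (m.o[i] - m.z[i]) * leaf_v
            return
        f = int(tree.feature[node])
        l, r = int(tree.left[node]), int(tree.right[node])
        hot, cold = (l, r) if tree.goes_left(node, x) else (r, l)
        iz = io = 1.0
        k = next((idx for idx in range(1, len(m.d)) if m.d[idx] == f), None)
        if k is not None:
            iz, io = m.z[k], m.o[k]
            m = _unwind(m, k)
        cov = tree.cover[node]
        recurse(hot, m, iz * tree.cover[hot] / cov, io, f)
        recurse(cold, m, iz * tree.cover[cold] / cov, 0.0, f)

    recurse(0, _Path(), 1.0, 1.0, -1)
    return phi


def shap_explain(model, X, instance_ids=None) -> list[ShapExplanation]:
    """Path-dependent TreeSHAP explanations for every row of X.

    ``model`` may be a :class:`~voicepd.modeling.FittedClassifier`
    (tree ensembles only), a raw booster/forest, or a
    :class:`TreeEnsemble`.  Attributions are in the ensemble's native
    score space (log-odds for boosters, probability for forests) and
    satisfy additivity: base_value + sum = raw prediction.
    """
    ensemble = model if isinstance(model, TreeEnsemble) else extract_ensemble(model)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    base = coalition_value(ensemble, X[0], ())
    out = []
    for i, x in enumerate(X):
        phi = np.zeros(X.shape[1])
        for t in ensemble.trees:
            phi += tree_shap(t, x, X.shape[1])
        out.append(
            ShapExplanation(
                attributions=phi,
                base_value=base,
                instance_id=None if instance_ids is None else instance_ids[i],
            )
        )
    return out


# ------------------------------------------------------ global summaries

@dataclass
class GlobalImportance:
    """Mean |attribution| per feature, ranked descending."""

    impacts: np.ndarray
    ranking: list[int]
    feature_names: list[str] | None = None

    def top(self, k: int = 10) -> list[tuple[str, float]]:
        names = self.feature_names or [f"f{i}" for i in range(self.impacts.size)]
        return [(names[i], float(self.impacts[i])) for i in self.ranking[:k]]

    def report(self, k: int = 10) -> str:
        lines = [f"{'rank':>4}  {'feature':<22} {'mean |SHAP|':>12}"]
        for r, (name, imp) in enumerate(self.top(k), 1):
            lines.append(f"{r:>4}  {name:<22} {imp:>12.5f}")
        return "\n".join(lines)


def global_importance(explanations, feature_names=None) -> GlobalImportance:
    """Aggregate per-instance attributions into a global ranking.

    Impact of a feature = mean over instances of |attribution|; ties
    are broken stably by feature order.
    """
    if not explanations:
        raise ValueError("need at least one explanation")
    mat = np.vstack([e.attributions for e in explanations])
    impacts = np.abs(mat).mean(axis=0)
    ranking = list(np.argsort(-impacts, kind="stable"))
    return GlobalImportance(impacts=impacts, ranking=ranking, feature_names=feature_names)


def incremental_feature_curve(
    cohort, ranking, spec: ModelSpec, k_max: int, auc_tol: float = 0.01
):
    """LOOCV performance as features are added in ranked order.

    For k = 1..k_max the model is evaluated on the top-k features only;
    the saturation point is the first k whose AUC is within ``auc_tol``
    of the k_max AUC.  If the model's explanation ranking is faithful,
    the curve flattens after the handful of genuinely informative
    features.
    """
    names = [r if isinstance(r, str) else cohort.kept_features[r] for r in ranking]
    unknown = set(names) - set(cohort.kept_features)
    if unknown:
        raise ValueError(f"ranking names features not in the cohort: {unknown}")
    if k_max > len(names):
        import logging

        logging.getLogger(__name__).warning(
            "k_max=%d exceeds %d ranked features; clipping", k_max, len(names)
        )
        k_max = len(names)
    curve = []
    for k in range(1, k_max + 1):
        sub = cohort.subset(np.arange(cohort.n))
        sub.X = cohort.X[names[:k]].copy()
        sub.kept_features = names[:k]
        res = loocv_evaluate(spec, sub)
        curve.append((k, res.auc, res.accuracy))
    final_auc = curve[-1][1]
    saturation = next(k for k, a, _ in curve if a >= final_auc - auc_tol)
    return curve, saturation
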