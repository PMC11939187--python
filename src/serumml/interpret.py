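"""Feature attribution and consensus selection.

Three complementary attribution routes over a fitted classifier:

* impurity (Gini) importances from tree models;
* Shapley values via the kernel method: a weighted linear regression over
  feature coalitions whose masked entries are integrated over a background
  sample. With every coalition enumerated the solution is the exact Shapley
  vector and satisfies local accuracy (base value + contributions = model
  output) to numerical precision;
* LIME-style local surrogates: a ridge model fitted to Gaussian perturbations
  around each explained instance, kernel-weighted by proximity, aggregated
  into signed global rankings.

The consensus rule follows majority voting: features placed in the top-k by
at least two of the three methods are selected first, remaining slots filled
by ascending average rank, ties broken by ascending feature m/z.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
from sklearn.linear_model import Ridge

from .bench import make_model
from .peaks import FeatureMatrix

__all__ = ["ImportanceRanking", "ConsensusRanking", "model_importances",
           "draw_background", "shap_attributions", "shap_ranking",
           "lime_rankings", "consensus_top_k",
           "cross_validated_importance_intersection"]

TREE_MODELS = ("decision_tree", "random_forest", "lgbm", "xgboost")


def _rank_by_magnitude(feature_names: list[str], scores: np.ndarray) -> np.ndarray:
    """1-based ranks by descending |score|, ties by ascending feature m/z."""
    def _mz(name):
        try:
            return float(name)
        except ValueError:
            return name
    order = sorted(range(len(scores)), key=lambda i: (-abs(scores[i]), _mz(feature_names[i])))
    ranks = np.empty(len(scores), dtype=int)
    for r, i in enumerate(order, start=1):
        ranks[i] = r
    return ranks


@dataclass
class ImportanceRanking:
    method: str                     # "gini" | "shap" | "lime"
    feature_names: list[str]
    scores: np.ndarray              # signed for lime/shap-global, >=0 for gini
    ranks: np.ndarray               # 1-based permutation by |score|

    def top(self, k: int) -> list[str]:
        order = np.argsort(self.ranks)
        return [self.feature_names[i] for i in order[:k]]


@dataclass
class ConsensusRanking:
    selected: list[str]
    votes: dict[str, int]
    fill_rank: dict[str, float]     # average-rank ordering used for the fill


def model_importances(model, feature_names: list[str]) -> ImportanceRanking:
    """Normalized impurity (Gini) importances of a fitted tree model."""
    est = model
    if hasattr(est, "steps"):  # unwrap sklearn pipelines
        est = est.steps[-1][1]
    if not hasattr(est, "feature_importances_"):
        raise ValueError(
            "model has no feature_importances_; supported models: "
            + ", ".join(TREE_MODELS))
    scores = np.asarray(est.feature_importances_, dtype=float)
    total = scores.sum()
    if total > 0:
        scores = scores / total
    return ImportanceRanking("gini", list(feature_names), scores,
                             _rank_by_magnitude(list(feature_names), scores))


# ---------------------------------------------------------------------------
# Kernel SHAP


def draw_background(X_train: np.ndarray, n: int = 200, seed: int = 0) -> np.ndarray:
    """Draw the background sample for the kernel explainer from the training set."""
    X_train = np.asarray(X_train, float)
    if n > len(X_train):
        raise ValueError(
            f"background size {n} exceeds training set size {len(X_train)}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(X_train), size=n, replace=False)
    return X_train[idx]


def _coalition_values(model_fn, x: np.ndarray, background: np.ndarray,
                      masks: np.ndarray, chunk: int = 64) -> np.ndarray:
    """v(S) = E_background f(x masked to S) for each coalition mask row."""
    n_bg, d = background.shape
    vals = np.empty(len(masks))
    for start in range(0, len(masks), chunk):
        block = masks[start:start + chunk]
        # rows: for each coalition, every background row with S-features from x
        synth = np.repeat(background[None, :, :], len(block), axis=0)
        synth[block[:, None, :].repeat(n_bg, axis=1)] = 0.0
        synth += block[:, None, :] * x[None, None, :]
        preds = np.asarray(model_fn(synth.reshape(-1, d)), float)
        vals[start:start + chunk] = preds.reshape(len(block), n_bg).mean(axis=1)
    return vals


def shap_attributions(model_fn, background: np.ndarray, X: np.ndarray,
                      budget: int | None = None, seed: int = 0
                      ) -> tuple[np.ndarray, float]:
    """Kernel-method Shapley attributions for each row of X.

    ``model_fn`` maps an (n, d) array to positive-class probabilities. The
    coalition budget defaults to ``2**min(d, 11)`` capped at 2048; when the
    budget covers every non-trivial coalition the exact Shapley vector is
    returned. Local accuracy (base + sum of contributions = model output)
    holds by construction.

    Returns (phi, base_value) with phi of shape (n_rows, d).
    """
    background = np.atleast_2d(np.asarray(background, float))
    X = np.atleast_2d(np.asarray(X, float))
    d = X.shape[1]
    if background.shape[1] != d:
        raise ValueError("background and X feature counts differ")
    if budget is None:
        budget = min(2 ** min(d, 11), 2048)
    rng = np.random.default_rng(seed)

    n_all = 2 ** d - 2 if d <= 30 else np.inf
    exact = n_all <= budget
    if exact:
        masks = np.zeros((n_all, d), dtype=bool)
        weights = np.empty(n_all)
        row = 0
        for s in range(1, d):
            w = (d - 1) / (comb(d, s) * s * (d - s))
            for S in combinations(range(d), s):
                masks[row, list(S)] = True
                weights[row] = w
                row += 1
    else:
        # sample coalition sizes from the Shapley kernel distribution, then
        # uniform subsets within a size; uniform regression weights follow
        sizes = np.arange(1, d)
        size_p = (d - 1) / (sizes * (d - sizes))
        size_p = size_p / size_p.sum()
        draw = rng.choice(sizes, size=budget, p=size_p)
        masks = np.zeros((budget, d), dtype=bool)
        for i, s in enumerate(draw):
            masks[i, rng.choice(d, size=s, replace=False)] = True
        weights = np.ones(budget)

    base = float(np.mean(model_fn(background)))
    phi = np.empty((len(X), d))
    sw = np.sqrt(weights)
    for r, x in enumerate(X):
        fx = float(np.asarray(model_fn(x[None, :]), float)[0])
        v = _coalition_values(model_fn, x, background, masks)
        y = v - base
        # enforce efficiency by eliminating the last coefficient
        z = masks.astype(float)
        y_adj = y - z[:, -1] * (fx - base)
        Z_adj = z[:, :-1] - z[:, [-1]]
        coef, *_ = np.linalg.lstsq(Z_adj * sw[:, None], y_adj * sw, rcond=None)
        phi[r, :-1] = coef
        phi[r, -1] = (fx - base) - coef.sum()
    return phi, base


def shap_ranking(phi: np.ndarray, feature_names: list[str]) -> ImportanceRanking:
    """Global ranking: mean |contribution| per feature (signed mean as score sign)."""
    mag = np.abs(phi).mean(axis=0)
    sign = np.sign(phi.mean(axis=0))
    scores = mag * np.where(sign == 0, 1.0, sign)
    return ImportanceRanking("shap", list(feature_names), scores,
                             _rank_by_magnitude(list(feature_names), mag))


# ---------------------------------------------------------------------------
# LIME


def lime_rankings(model_fn, X: np.ndarray, feature_names: list[str],
                  explain_idx: np.ndarray | None = None,
                  n_perturbations: int = 5000, top_features: int = 10,
                  kernel_width: float | None = None, seed: int = 0
                  ) -> ImportanceRanking:
    """Global LIME ranking: per-instance sparse ridge surrogates aggregated.

    Each explained instance is perturbed with Gaussian noise at the feature
    scale of X; a ridge surrogate is fitted to the model's probabilities with
    exponential-kernel proximity weights (width 0.75*sqrt(d)); only the
    ``top_features`` largest surrogate weights per instance are kept. The
    global signed score is the mean signed weight; ranks follow mean |weight|.
    """
    X = np.asarray(X, float)
    n, d = X.shape
    std = X.std(axis=0, ddof=0)
    if np.all(std == 0):
        raise ValueError("all features have zero variance; LIME surrogate is degenerate")
    std = np.where(std == 0, 1.0, std)
    width = kernel_width if kernel_width is not None else 0.75 * np.sqrt(d)
    rng = np.random.default_rng(seed)
    if explain_idx is None:
        explain_idx = np.arange(n)
    mean = X.mean(axis=0)

    local = np.zeros((len(explain_idx), d))
    for out_i, i in enumerate(explain_idx):
        x = X[i]
        Z = x[None, :] + rng.normal(0.0, 1.0, (n_perturbations, d)) * std[None, :]
        Z[0] = x  # anchor the instance itself
        dist = np.sqrt((((Z - x) / std) ** 2).sum(axis=1))
        w = np.exp(-(dist ** 2) / (width ** 2))
        target = np.asarray(model_fn(Z), float)
        ridge = Ridge(alpha=1.0)
        ridge.fit((Z - mean) / std, target, sample_weight=w)
        coefs = ridge.coef_.copy()
        keep = np.argsort(-np.abs(coefs))[:top_features]
        sparse = np.zeros(d)
        sparse[keep] = coefs[keep]
        local[out_i] = sparse

    signed = local.mean(axis=0)
    mag = np.abs(local).mean(axis=0)
    return ImportanceRanking("lime", list(feature_names), signed,
                             _rank_by_magnitude(list(feature_names), mag))


# ---------------------------------------------------------------------------
# Consensus


def consensus_top_k(rankings: list[ImportanceRanking], k: int = 20) -> ConsensusRanking:
    """Majority-vote consensus of three rankings.

    Features in the top-k of >= 2 methods are selected outright; remaining
    slots fill by ascending average rank across methods, ties by ascending
    feature m/z.
    """
    if len(rankings) != 3:
        raise ValueError("consensus expects exactly 3 rankings")
    names = rankings[0].feature_names
    for r in rankings[1:]:
        if set(r.feature_names) != set(names):
            raise ValueError("rankings cover different feature sets")
    def _mz(name):
        try:
            return float(name)
        except ValueError:
            return name

    votes = {f: 0 for f in names}
    for r in rankings:
        for f in r.top(k):
            votes[f] += 1
    avg_rank = {
        f: float(np.mean([r.ranks[r.feature_names.index(f)] for r in rankings]))
        for f in names}

    majority = sorted([f for f, v in votes.items() if v >= 2],
                      key=lambda f: (avg_rank[f], _mz(f)))
    selected = majority[:k]
    if len(selected) < k:
        rest = sorted([f for f in names if f not in selected],
                      key=lambda f: (avg_rank[f], _mz(f)))
        selected += rest[: k - len(selected)]
    return ConsensusRanking(selected=selected, votes=votes, fill_rank=avg_rank)


def cross_validated_importance_intersection(
        fm: FeatureMatrix, models: tuple[str, ...] = TREE_MODELS,
        top_m: int = 10, seed: int = 0) -> set[str]:
    """Intersection of each tree model's top-m impurity-importance features.

    Cross-validates importances across model families: only features every
    tree model places in its top-m survive. Features a model never uses
    (zero importance) do not count toward its top-m. An empty intersection
    is returned (with a warning), not raised.
    """
    y = (np.asarray(fm.labels) == "cancer").astype(int)
    names = [f"{mz:.2f}" for mz in fm.feature_mzs]
    common: set[str] | None = None
    for name in models:
        model = make_model(name, seed=seed)
        model.fit(fm.values, y)
        ranking = model_importances(model, names)
        used = {f for f, s in zip(ranking.feature_names, ranking.scores) if s > 0}
        top = set(ranking.top(top_m)) & used
        common = top if common is None else (common & top)
    if not common:
        warnings.warn("tree-model top importance lists share no features")
        return set()
    return common
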