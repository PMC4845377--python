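"""Stochastic gradient boosting with Friedman relative influence.

Bernoulli-deviance boosting for a binary outcome, built from scratch so the
variable-importance bookkeeping is fully inspectable:

* ``F0 = log(ybar / (1 - ybar))``;
* each iteration draws a ``bag_fraction`` subsample without replacement,
  computes residuals ``r_i = y_i - expit(F(x_i))`` on the bag, fits a
  depth-limited least-squares regression tree to them, and replaces each
  terminal value by the one-step Newton estimate ``sum r / sum p(1-p)`` over
  the bag members in the leaf;
* the model is updated by ``F <- F + shrinkage * tree(x)`` for all samples.

Every internal node records its squared improvement — the reduction in the
residual sum of squares achieved by the split.  The relative influence of a
variable is the total squared improvement over all nodes splitting on it,
across all trees, normalized so the influences sum to 100%.  Matched-pair
structure is ignored here (rows are pooled), which mirrors how boosting is
conventionally applied to case-control tables and is documented as a caveat.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ascertainment import AnalysisRow, prevalence_filter, rows_to_frame
from .catalog import ConditionCatalog
from .synthetic_ehr import EDUCATION_LEVELS


class DegenerateLabelsError(ValueError):
    """All labels in one class: F0 undefined on the log-odds scale."""


class NoSplitError(ValueError):
    """Model contains no splits; relative influence is undefined."""


@dataclass
class GbmConfig:
    n_trees: int = 3000
    interaction_depth: int = 2
    shrinkage: float = 0.01
    bag_fraction: float = 0.5
    min_node: int = 10
    seed: int = 0
    include_burden: bool = False

    def __post_init__(self):
        if not 0.0 < self.shrinkage <= 1.0:
            raise ValueError("shrinkage must be in (0, 1]")
        if not 0.0 < self.bag_fraction <= 1.0:
            raise ValueError("bag_fraction must be in (0, 1]")
        if self.interaction_depth < 1:
            raise ValueError("interaction_depth must be >= 1")


@dataclass
class _Node:
    feature: int = -1               # -1 marks a leaf
    threshold: float = 0.0
    improvement: float = 0.0        # squared improvement (RSS reduction)
    value: float = 0.0
    left: "_Node | None" = None
    right: "_Node | None" = None


@dataclass
class BoostedModel:
    f0: float
    trees: list
    shrinkage: float
    feature_names: list[str]

    def decision_function(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        out = np.full(X.shape[0], self.f0)
        for tree in self.trees:
            out += self.shrinkage * _apply_tree(tree, X)
        return out

    def predict_proba(self, X) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.decision_function(X)))


def _apply_tree(node: _Node, X: np.ndarray) -> np.ndarray:
    out = np.empty(X.shape[0])
    stack = [(node, np.arange(X.shape[0]))]
    while stack:
        nd, idx = stack.pop()
        if nd.feature < 0:
            out[idx] = nd.value
            continue
        go_left = X[idx, nd.feature] <= nd.threshold
        stack.append((nd.left, idx[go_left]))
        stack.append((nd.right, idx[~go_left]))
    return out


def _best_split(codes, uniques, r, idx, min_node):
    """Exhaustive least-squares split search over all features and cut points.

    Returns (feature, threshold, improvement, left_idx, right_idx) or None.
    Improvement is the RSS reduction (S_L^2/n_L + S_R^2/n_R - S^2/n), which
    does not depend on the per-sample squared residuals.
    """
    n = idx.size
    S = float(r[idx].sum())
    base = S * S / n
    best = None
    for j in range(codes.shape[1]):
        k = uniques[j].size
        if k < 2:
            continue
        cj = codes[idx, j]
        cnt = np.bincount(cj, minlength=k)
        sums = np.bincount(cj, weights=r[idx], minlength=k)
        n_left = np.cumsum(cnt)[:-1]
        s_left = np.cumsum(sums)[:-1]
        n_right = n - n_left
        valid = (n_left >= min_node) & (n_right >= min_node)
        if not valid.any():
            continue
        with np.errstate(divide="ignore", invalid="ignore"):
            imp = s_left**2 / n_left + (S - s_left) ** 2 / n_right - base
        imp[~valid] = -np.inf
        t = int(np.argmax(imp))
        if imp[t] <= 1e-12:
            continue
        if best is None or imp[t] > best[2]:
            threshold = 0.5 * (uniques[j][t] + uniques[j][t + 1])
            best = (j, float(threshold), float(imp[t]), t)
    if best is None:
        return None
    j, threshold, improvement, t = best
    go_left = codes[idx, j] <= t
    return j, threshold, improvement, idx[go_left], idx[~go_left]


def _build_tree(codes, uniques, r, h, idx, depth, min_node) -> _Node:
    def leaf(ids) -> _Node:
        denom = max(float(h[ids].sum()), 1e-12)
        return _Node(value=float(r[ids].sum()) / denom)

    def grow(ids, remaining) -> _Node:
        if remaining == 0 or ids.size < 2 * min_node:
            return leaf(ids)
        split = _best_split(codes, uniques, r, ids, min_node)
        if split is None:
            return leaf(ids)
        j, threshold, improvement, left_ids, right_ids = split
        return _Node(
            feature=j,
            threshold=threshold,
            improvement=improvement,
            left=grow(left_ids, remaining - 1),
            right=grow(right_ids, remaining - 1),
        )

    return grow(idx, depth)


def fit_gbm(features, labels, config: GbmConfig) -> BoostedModel:
    """Fit the boosted model; ``features`` is a DataFrame or 2-D array."""
    if isinstance(features, pd.DataFrame):
        names = list(features.columns)
        X = features.to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
        names = [f"x{j}" for j in range(X.shape[1])]
    y = np.asarray(labels, dtype=float)
    if X.shape[0] != y.size:
        raise ValueError("features and labels disagree on sample count")
    ybar = float(y.mean())
    if ybar in (0.0, 1.0):
        raise DegenerateLabelsError("labels are single-class; cannot initialize log-odds")

    # Integer-encode each feature once; split search then reduces to bincounts.
    uniques, codes = [], np.empty(X.shape, dtype=np.int64)
    for j in range(X.shape[1]):
        u, inv = np.unique(X[:, j], return_inverse=True)
        uniques.append(u)
        codes[:, j] = inv

    rng = np.random.default_rng(config.seed)
    n = X.shape[0]
    bag_size = max(2 * config.min_node, int(round(config.bag_fraction * n)))
    bag_size = min(bag_size, n)

    f0 = float(np.log(ybar / (1.0 - ybar)))
    F = np.full(n, f0)
    trees: list[_Node] = []
    for _ in range(config.n_trees):
        bag = rng.permutation(n)[:bag_size]
        p = 1.0 / (1.0 + np.exp(-F[bag]))
        r = np.zeros(n)
        h = np.zeros(n)
        r[bag] = y[bag] - p
        h[bag] = p * (1.0 - p)
        tree = _build_tree(codes, uniques, r, h, bag, config.interaction_depth, config.min_node)
        trees.append(tree)
        F += config.shrinkage * _apply_tree(tree, X)
    return BoostedModel(f0=f0, trees=trees, shrinkage=config.shrinkage, feature_names=names)


@dataclass
class RIResult:
    relative_influence: dict  # variable name -> percentage
    stratum: str = ""
    variant: str = ""

    def as_series(self) -> pd.Series:
        return pd.Series(self.relative_influence).sort_values(ascending=False)

    def top(self, among: list[str] | None = None) -> str:
        pool = self.relative_influence if among is None else {
            k: v for k, v in self.relative_influence.items() if k in among
        }
        return max(pool, key=pool.get)


def relative_influence(model: BoostedModel) -> RIResult:
    """Per-variable squared-improvement totals, normalized to sum to 100%."""
    totals = np.zeros(len(model.feature_names))
    stack = list(model.trees)
    while stack:
        nd = stack.pop()
        if nd.feature >= 0:
            totals[nd.feature] += nd.improvement
            stack.append(nd.left)
            stack.append(nd.right)
    grand = totals.sum()
    if grand <= 0.0:
        raise NoSplitError("model contains no splits; relative influence undefined")
    ri = 100.0 * totals / grand
    return RIResult(relative_influence=dict(zip(model.feature_names, ri)))


def feature_frame(
    rows: list[AnalysisRow],
    condition_ids: list[str],
    include_burden: bool,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Predictor matrix for boosting: condition flags, sex, obesity, education.

    Education enters ordinally (1-4, with the unknown level as 0 plus its own
    binary indicator); sex is coded female=1.  Burden is the count of all 24
    ascertained conditions, not only those passing the prevalence filter.
    """
    df = rows_to_frame(rows)
    ordinal = {lvl: i + 1 for i, lvl in enumerate(EDUCATION_LEVELS[:4])}
    ordinal[EDUCATION_LEVELS[4]] = 0
    X = pd.DataFrame(
        {
            **{cid: df[cid] for cid in condition_ids},
            "sex": (df["sex"] == "F").astype(int),
            "obesity": df["obesity"],
            "education": df["education"].map(ordinal),
            "education_unknown": (df["education"] == "unknown").astype(int),
        }
    )
    if include_burden:
        X["burden"] = df["burden"]
    return X, df["outcome"].to_numpy()


def ri_analysis(
    rows: list[AnalysisRow],
    stratum: str,
    catalog: ConditionCatalog,
    config: GbmConfig,
    threshold: float = 0.01,
) -> tuple[RIResult, RIResult]:
    """Relative influences for one age stratum, without and with disease burden."""
    stratum_rows = [r for r in rows if r.stratum == stratum]
    if not stratum_rows:
        raise ValueError(f"no rows in stratum {stratum!r}")
    keep = prevalence_filter(stratum_rows, catalog.condition_ids, threshold)
    results = []
    for variant, include_burden in (("no_burden", False), ("with_burden", True)):
        X, y = feature_frame(stratum_rows, keep, include_burden)
        model = fit_gbm(X, y, config)
        ri = relative_influence(model)
        ri.stratum = stratum
        ri.variant = variant
        results.append(ri)
    return results[0], results[1]
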