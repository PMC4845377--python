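"""Boosting and relative influence: stump oracle, normalization, recovery."""

import numpy as np
import pandas as pd
import pytest

from mdd_comorbidity import GbmConfig, fit_gbm, relative_influence
from mdd_comorbidity.gbm_ri import DegenerateLabelsError, NoSplitError, feature_frame
from mdd_comorbidity.synthetic_ehr import simulate_stratum_features


def _brute_force_stump(X, r, min_node=1):
    """Exhaustive search of the least-squares depth-1 split."""
    n = len(r)
    best = (None, None, -np.inf)
    base = r.sum() ** 2 / n
    for j in range(X.shape[1]):
        values = np.unique(X[:, j])
        for lo, hi in zip(values, values[1:]):
            thr = 0.5 * (lo + hi)
            left = X[:, j] <= thr
            nl, nr = left.sum(), n - left.sum()
            if nl < min_node or nr < min_node:
                continue
            imp = r[left].sum() ** 2 / nl + r[~left].sum() ** 2 / nr - base
            if imp > best[2]:
                best = (j, thr, imp)
    return best


def test_single_stump_equals_exhaustive_search():
    """1 tree, depth 1, shrinkage 1, full bag reproduces the best stump."""
    rng = np.random.default_rng(7)
    X = rng.integers(0, 2, size=(40, 3)).astype(float)
    y = ((X[:, 1] + 0.2 * rng.standard_normal(40)) > 0.5).astype(int)
    cfg = GbmConfig(n_trees=1, interaction_depth=1, shrinkage=1.0,
                    bag_fraction=1.0, min_node=1, seed=0)
    model = fit_gbm(X, y, cfg)
    (tree,) = model.trees

    p0 = y.mean()
    r = y - p0
    j, thr, imp = _brute_force_stump(X, r)
    assert tree.feature == j
    assert tree.threshold == pytest.approx(thr)
    assert tree.improvement == pytest.approx(imp, rel=1e-9)
    # terminal values are the one-step Newton estimates sum r / sum p(1-p)
    left = X[:, j] <= thr
    h = p0 * (1 - p0)
    assert tree.left.value == pytest.approx(r[left].sum() / (h * left.sum()), rel=1e-9)
    assert tree.right.value == pytest.approx(r[~left].sum() / (h * (~left).sum()), rel=1e-9)


def test_four_point_dataset_oracle():
    X = np.array([[0.0], [0.0], [1.0], [1.0]])
    y = np.array([0, 0, 1, 1])
    cfg = GbmConfig(n_trees=1, interaction_depth=1, shrinkage=1.0,
                    bag_fraction=1.0, min_node=1, seed=0)
    model = fit_gbm(X, y, cfg)
    tree = model.trees[0]
    assert tree.feature == 0 and tree.threshold == pytest.approx(0.5)
    # perfect binary split: improvement = total residual sum of squares
    assert tree.improvement == pytest.approx(1.0)
    assert model.predict_proba(X)[0] < 0.5 < model.predict_proba(X)[3]


def test_single_class_labels_rejected():
    with pytest.raises(DegenerateLabelsError):
        fit_gbm(np.zeros((20, 2)), np.zeros(20), GbmConfig(n_trees=1, seed=0))


def test_near_constant_labels_initialize_f0():
    y = np.zeros(1000)
    y[0] = 1
    X = np.random.default_rng(0).integers(0, 2, size=(1000, 2)).astype(float)
    model = fit_gbm(X, y, GbmConfig(n_trees=2, seed=0))
    assert model.f0 == pytest.approx(np.log(1 / 999))


def test_training_deviance_nonincreasing_with_full_bag():
    X, y = simulate_stratum_features(
        400, {"a": 1.0, "b": -0.5}, {"a": 0.4, "b": 0.4, "c": 0.5}, intercept=-0.5, seed=2
    )
    cfg = GbmConfig(n_trees=60, interaction_depth=2, shrinkage=0.1,
                    bag_fraction=1.0, min_node=10, seed=1)
    model = fit_gbm(X, y, cfg)
    F = np.full(len(y), model.f0)
    yv = y.astype(float)

    def deviance(F):
        return float(np.mean(np.logaddexp(0.0, F) - yv * F))

    devs = [deviance(F)]
    from mdd_comorbidity.gbm_ri import _apply_tree

    Xv = X.to_numpy(dtype=float)
    for tree in model.trees:
        F = F + model.shrinkage * _apply_tree(tree, Xv)
        devs.append(deviance(F))
    assert all(b <= a + 1e-12 for a, b in zip(devs, devs[1:]))


def test_relative_influence_sums_to_100():
    X, y = simulate_stratum_features(
        600, {"a": 0.8}, {"a": 0.3, "b": 0.3, "c": 0.3}, intercept=-1.0, seed=5
    )
    model = fit_gbm(X, y, GbmConfig(n_trees=50, shrinkage=0.1, seed=4))
    ri = relative_influence(model)
    assert sum(ri.relative_influence.values()) == pytest.approx(100.0, abs=1e-6)
    assert all(v >= 0 for v in ri.relative_influence.values())


def test_only_split_variable_takes_all_influence():
    X = np.column_stack([np.repeat([0.0, 1.0], 50), np.zeros(100)])
    y = np.repeat([0, 1], 50)
    model = fit_gbm(X, y, GbmConfig(n_trees=5, shrinkage=0.5, bag_fraction=1.0,
                                    min_node=5, seed=0))
    ri = relative_influence(model)
    assert ri.relative_influence["x0"] == pytest.approx(100.0)
    assert ri.relative_influence["x1"] == 0.0


def test_no_split_model_has_undefined_ri():
    X = np.zeros((30, 2))  # no feature variation: every tree is a leaf
    y = np.tile([0, 1], 15)
    model = fit_gbm(X, y, GbmConfig(n_trees=3, seed=0))
    with pytest.raises(NoSplitError):
        relative_influence(model)


def test_predictions_invariant_to_feature_order():
    X, y = simulate_stratum_features(
        300, {"a": 1.0, "b": 0.5}, {"a": 0.4, "b": 0.4, "c": 0.3}, intercept=-0.5, seed=6
    )
    cfg = GbmConfig(n_trees=40, shrinkage=0.1, seed=11)
    m1 = fit_gbm(X, y, cfg)
    perm = X[["c", "a", "b"]]
    m2 = fit_gbm(perm, y, cfg)
    np.testing.assert_allclose(m1.predict_proba(X), m2.predict_proba(perm), atol=1e-10)
    ri1 = relative_influence(m1).relative_influence
    ri2 = relative_influence(m2).relative_influence
    for k in ("a", "b", "c"):
        assert ri1[k] == pytest.approx(ri2[k], abs=1e-9)


def test_permuted_labels_show_no_dominant_variable():
    """Permutation null: no variable's RI persists across seeds."""
    X, y = simulate_stratum_features(
        500, {"a": 1.2}, {k: 0.3 for k in "abcde"}, intercept=-0.8, seed=8
    )
    tops = []
    for seed in range(6):
        rng = np.random.default_rng(100 + seed)
        y_perm = rng.permutation(y)
        if y_perm.mean() in (0, 1):
            continue
        model = fit_gbm(X, y_perm, GbmConfig(n_trees=60, shrinkage=0.1, seed=seed))
        tops.append(relative_influence(model).top())
    assert len(set(tops)) > 1


def test_planted_signal_attains_top_condition_ri():
    X, y = simulate_stratum_features(
        3000, {"diabetes": 1.0}, {k: 0.15 for k in ("diabetes", "asthma", "ra_oa", "copd")},
        intercept=-1.2, seed=13,
    )
    model = fit_gbm(X, y, GbmConfig(n_trees=200, shrinkage=0.05, seed=21))
    assert relative_influence(model).top() == "diabetes"


def test_ranking_agrees_with_reference_boosting():
    """Advisory cross-check against an established implementation."""
    from scipy.stats import spearmanr
    from sklearn.ensemble import GradientBoostingClassifier

    names = ["a", "b", "c", "d", "e", "f"]
    X, y = simulate_stratum_features(
        2000,
        {"a": 1.2, "b": 0.8, "c": 0.4, "d": 0.2},
        {k: 0.3 for k in names},
        intercept=-0.8,
        seed=17,
    )
    ours = fit_gbm(X, y, GbmConfig(n_trees=300, interaction_depth=2,
                                   shrinkage=0.05, bag_fraction=1.0, seed=3))
    ri = relative_influence(ours).as_series()[names]

    ref = GradientBoostingClassifier(
        n_estimators=300, max_depth=2, learning_rate=0.05, random_state=3
    ).fit(X, y)
    rho = spearmanr(ri.to_numpy(), ref.feature_importances_).statistic
    assert rho >= 0.8


def test_feature_frame_encoding():
    from mdd_comorbidity import AnalysisRow

    rows = [
        AnalysisRow("a", "p1", 1, "le45", {"diabetes": True}, True, "post_graduate", "F"),
        AnalysisRow("b", "p1", 0, "le45", {"diabetes": False}, False, "unknown", "M"),
    ]
    X, y = feature_frame(rows, ["diabetes"], include_burden=True)
    assert list(X.columns) == ["diabetes", "sex", "obesity", "education",
                               "education_unknown", "burden"]
    assert X["education"].tolist() == [4, 0]
    assert X["education_unknown"].tolist() == [0, 1]
    assert X["sex"].tolist() == [1, 0]
    assert y.tolist() == [1, 0]


# ---------------------------------------------------------------------------
# ri_analysis: stratum-level fits with and without the burden covariate
# ---------------------------------------------------------------------------

def _synthetic_rows(n_pairs, eta_fn, seed, n_conditions=6):
    """Analysis rows with random condition flags and a logistic outcome."""
    from mdd_comorbidity import AnalysisRow
    from mdd_comorbidity.synthetic_ehr import EDUCATION_LEVELS

    rng = np.random.default_rng(seed)
    conds = ["diabetes", "asthma", "ra_oa", "copd", "anemia", "hypertension"][:n_conditions]
    rows = []
    for i in range(2 * n_pairs):
        flags = {c: bool(rng.random() < 0.25) for c in conds}
        education = EDUCATION_LEVELS[int(rng.integers(0, 5))]
        obesity = bool(rng.random() < 0.1)
        sex = "F" if rng.random() < 0.5 else "M"
        eta = eta_fn(flags, education, obesity)
        outcome = int(rng.random() < 1.0 / (1.0 + np.exp(-eta)))
        rows.append(
            AnalysisRow(f"s{i}", f"p{i // 2}", outcome, "le45", flags,
                        obesity, education, sex)
        )
    return rows, conds


def _mini_catalog(conds):
    from mdd_comorbidity.catalog import ConditionCatalog, ConditionEntry

    return ConditionCatalog(tuple(
        ConditionEntry(c, c, ("999",)) for c in conds
    ))


def test_ri_analysis_returns_both_variants(catalog):
    from mdd_comorbidity.gbm_ri import ri_analysis

    rows, conds = _synthetic_rows(300, lambda f, e, o: -0.2 + f["diabetes"], seed=1)
    no_burden, with_burden = ri_analysis(
        rows, "le45", _mini_catalog(conds),
        GbmConfig(n_trees=40, shrinkage=0.1, seed=0),
    )
    assert no_burden.variant == "no_burden" and with_burden.variant == "with_burden"
    assert "burden" not in no_burden.relative_influence
    assert "burden" in with_burden.relative_influence


def test_burden_as_true_driver_attains_top_ri():
    """Outcome driven by the condition count: burden takes the top influence."""
    from mdd_comorbidity.gbm_ri import ri_analysis

    rows, conds = _synthetic_rows(
        1500, lambda f, e, o: -1.5 + 0.8 * sum(f.values()), seed=2
    )
    _, with_burden = ri_analysis(
        rows, "le45", _mini_catalog(conds),
        GbmConfig(n_trees=200, shrinkage=0.05, seed=3),
    )
    assert with_burden.top() == "burden"


def test_planted_education_gradient_ranks_first():
    """A strong education gradient makes education the leading variable."""
    from mdd_comorbidity.gbm_ri import ri_analysis
    from mdd_comorbidity.synthetic_ehr import EDUCATION_LEVELS

    grad = {lvl: b for lvl, b in zip(EDUCATION_LEVELS, (1.2, 0.6, 0.0, -0.6, 0.0))}
    rows, conds = _synthetic_rows(
        1500, lambda f, e, o: -1.2 + grad[e] + 0.3 * f["diabetes"], seed=4
    )
    no_burden, _ = ri_analysis(
        rows, "le45", _mini_catalog(conds),
        GbmConfig(n_trees=200, shrinkage=0.05, seed=5),
    )
    assert no_burden.top() == "education"
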