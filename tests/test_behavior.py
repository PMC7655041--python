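"""Behavior preprocessing, family-aware CV, lasso and NBS prediction."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

import connectocomm as cc
from connectocomm.behavior import impute_masked


# ---------------------------------------------------------------------------
# preprocessing

def test_normal_scores_for_three_values():
    out = cc.preprocess_behavior([10.0, 20.0, 30.0], age=[30, 30, 30],
                                 sex=["F", "F", "F"])
    # constant confounds: residualization only removes the mean
    from scipy.stats import norm
    expected = norm.ppf([0.25, 0.5, 0.75])
    assert np.allclose(out, expected - expected.mean(), atol=1e-4)
    assert np.allclose(sorted(np.round(expected, 4)), [-0.6745, 0.0, 0.6745])


def test_residuals_orthogonal_to_confounds(rng):
    y = rng.normal(size=100)
    age = rng.uniform(22, 35, 100)
    sex = rng.choice(["F", "M"], 100)
    out = cc.preprocess_behavior(y, age, sex)
    assert abs(np.corrcoef(out, age)[0, 1]) < 1e-10
    assert abs(np.corrcoef(out, (sex == "F").astype(float))[0, 1]) < 1e-10
    # rank preservation absent confound effects
    out2 = cc.preprocess_behavior(y, np.full(100, 30.0), np.full(100, "F"))
    assert spearmanr(y, out2).statistic == pytest.approx(1.0)
    with pytest.raises(ValueError, match="constant"):
        cc.preprocess_behavior(np.ones(10), age[:10], sex[:10])


def test_vectorize_ordering_roundtrip_and_length():
    M = np.array([[0.0, 1, 2], [1, 0, 3], [2, 3, 0]])
    v = cc.vectorize_features(M)
    assert np.array_equal(v, [1, 2, 3])
    assert np.array_equal(cc.unvectorize_features(v, 3), M)
    assert len(cc.vectorize_features(np.zeros((68, 68)))) == 2278
    with pytest.raises(ValueError, match="symmetric"):
        cc.vectorize_features(np.array([[0.0, 1], [2, 0]]))


def test_impute_masked_preserves_less_efficient_ordering():
    X = np.array([[1.0, np.nan], [2.0, -3.0]])
    assert np.array_equal(impute_masked(X, "efficiency"),
                          [[1.0, 0.0], [2.0, -3.0]])
    assert np.array_equal(impute_masked(X, "si"), [[1.0, -3.0], [2.0, -3.0]])


# ---------------------------------------------------------------------------
# folds

def test_folds_never_split_families_and_balance(rng):
    for trial in range(30):
        n_fams = int(rng.integers(12, 40))
        sizes = rng.integers(1, 5, n_fams)
        fam_ids = np.repeat([f"f{i}" for i in range(n_fams)], sizes)
        k = int(rng.integers(2, 8))
        plan = cc.family_aware_folds(fam_ids, k=k, n_repetitions=2,
                                     seed=int(rng.integers(1000)))
        for rep in range(2):
            a = plan.assignments[rep]
            for f in np.unique(fam_ids):
                assert len(np.unique(a[fam_ids == f])) == 1
            counts = np.bincount(a, minlength=k)
            assert counts.max() - counts.min() <= sizes.max()


def test_singleton_families_fill_folds_evenly():
    plan = cc.family_aware_folds([f"f{i}" for i in range(10)], k=10,
                                 n_repetitions=1, seed=0)
    assert np.array_equal(np.sort(plan.assignments[0]), np.arange(10))


# ---------------------------------------------------------------------------
# lasso

@pytest.fixture(scope="module")
def linear_problem():
    rng = np.random.default_rng(777)
    n, p = 200, 60
    X = rng.normal(size=(n, p))
    y = 2 * X[:, 3] - 1.5 * X[:, 17] + X[:, 40]
    fams = [f"f{i // 2}" for i in range(n)]
    return X, y, np.array(fams)


def test_lasso_recovers_noiseless_linear_signal(linear_problem):
    X, y, fams = linear_problem
    plan = cc.family_aware_folds(fams, k=5, n_repetitions=1, seed=1)
    df = cc.lasso_predict_cv(X, y, plan, inner_k=5)
    assert df["r"].mean() > 0.99
    assert len(df) == 5


def test_lasso_null_on_permuted_labels(linear_problem, rng):
    X, y, fams = linear_problem
    y_perm = rng.permutation(y)
    plan = cc.family_aware_folds(fams, k=5, n_repetitions=1, seed=2)
    df = cc.lasso_predict_cv(X, y_perm, plan, inner_k=5)
    assert abs(df["r"].mean()) < 0.15


def test_lambda_max_gives_all_zero_coefficients(linear_problem):
    from sklearn.linear_model import Lasso

    X, y, fams = linear_problem
    Xs = (X - X.mean(0)) / X.std(0)
    yc = y - y.mean()
    lam_max = np.max(np.abs(Xs.T @ yc)) / len(y)
    m = Lasso(alpha=lam_max * (1 + 1e-10)).fit(Xs, yc)
    assert np.all(m.coef_ == 0)


def test_lasso_ignores_test_labels(linear_problem):
    """Poisoned test set: corrupting held-out labels must not change the
    fitted models (no information leak)."""
    X, y, fams = linear_problem
    plan = cc.family_aware_folds(fams, k=4, n_repetitions=1, seed=3)
    _, models_clean = cc.lasso_predict_cv(X, y, plan, inner_k=4,
                                          return_models=True)
    y_poison = y.copy()
    train0, test0 = next(iter(plan.folds(0)))
    y_poison[test0] = np.random.default_rng(5).normal(size=len(test0)) * 100
    _, models_poison = cc.lasso_predict_cv(X, y_poison, plan, inner_k=4,
                                           return_models=True)
    rep, f, coef_c, int_c = models_clean[0]
    rep_p, f_p, coef_p, int_p = models_poison[0]
    assert (rep, f) == (rep_p, f_p) == (0, 0)
    assert np.array_equal(coef_c, coef_p)
    assert int_c == int_p


# ---------------------------------------------------------------------------
# NBS

def test_t_statistic_conversion_matches_closed_form():
    from connectocomm.behavior import _edge_t_stats

    rng = np.random.default_rng(0)
    n = 100
    r_target = 0.3
    # closed form: t = r sqrt(n-2) / sqrt(1-r^2)
    t_expected = r_target * np.sqrt(n - 2) / np.sqrt(1 - r_target ** 2)
    assert t_expected == pytest.approx(3.113, abs=5e-3)
    y = rng.normal(size=n)
    ys = (y - y.mean()) / y.std()
    # build x with exact sample correlation r_target
    e = rng.normal(size=n)
    e = e - e.mean()
    e = e - (e @ ys) / (ys @ ys) * ys  # orthogonalize against standardized y
    x = r_target * ys + np.sqrt(1 - r_target ** 2) * e / e.std()
    Xs = ((x - x.mean()) / x.std())[:, None]
    t = _edge_t_stats(Xs, ys, n)
    assert t[0] == pytest.approx(t_expected, rel=1e-6)


def test_nbs_recovers_planted_component(template20, coords20):
    # with 10 near-independent planted edges the per-edge correlation is
    # sqrt(r2/10); r2=0.85 puts the expected edgewise t around 4.4, safely
    # above the selection threshold of 3.  Recovery is assessed over three
    # independent plantings: a single draw can knock one edge below the
    # threshold through chance intercorrelation.
    jaccards = []
    for base in (21, 41, 61):
        ens = cc.generate_subject_ensemble(template20, 200, edge_noise=0.4,
                                           seed=base, coords=coords20)
        X = np.vstack([cc.vectorize_features(s.sc) for s in ens])
        from connectocomm.synth import plant_connected_support
        truth = cc.GroundTruth(target_r2=0.85)
        truth.behavior_support = plant_connected_support(template20 > 0, 10,
                                                         seed=base + 1)
        truth.beta = np.ones(10)  # coherent component: comparable effects
        y, truth = cc.generate_synthetic_behavior(
            X, [s.age for s in ens], [s.sex for s in ens], truth, seed=base + 2)
        yr = cc.preprocess_behavior(y, [s.age for s in ens],
                                    [s.sex for s in ens])
        sel = cc.nbs_select_components(X, yr, n_regions=20,
                                       n_permutations=200, seed=base + 3)
        planted = set(truth.behavior_support.tolist())
        found = set(sel.pos_edges.tolist())
        jaccards.append(len(planted & found) / len(planted | found))
        assert sel.pos_p < 0.05
    assert np.median(jaccards) > 0.5


def test_nbs_selection_deterministic_only_pvalues_stochastic(template20, coords20, rng):
    X = rng.normal(size=(60, 190))
    y = X[:, :5].sum(axis=1) + 0.5 * rng.normal(size=60)
    a = cc.nbs_select_components(X, y, n_regions=20, n_permutations=50, seed=1)
    b = cc.nbs_select_components(X, y, n_regions=20, n_permutations=50, seed=999)
    assert np.array_equal(a.pos_edges, b.pos_edges)
    assert np.array_equal(a.neg_edges, b.neg_edges)


def test_nbs_predict_zero_when_no_component(rng):
    n, N = 40, 12
    p = N * (N - 1) // 2
    X = rng.normal(size=(n, p))
    y = rng.normal(size=n)
    fams = np.array([f"f{i}" for i in range(n)])
    plan = cc.family_aware_folds(fams, k=4, n_repetitions=1, seed=0)
    df = cc.nbs_predict_cv(X, y, plan, n_regions=N, t_threshold=30.0,
                           n_permutations=20, seed=1)
    assert np.all(df["r"] == 0.0)
    assert len(df) == 4


def test_nbs_component_mean_model_predicts_planted_mean(template20, coords20):
    ens = cc.generate_subject_ensemble(template20, 200, edge_noise=0.4,
                                       seed=31, coords=coords20)
    X = np.vstack([cc.vectorize_features(s.sc) for s in ens])
    from connectocomm.synth import plant_connected_support
    support = plant_connected_support(template20 > 0, 6, seed=32)
    y = X[:, support].mean(axis=1)  # exactly the component-mean model
    y = (y - y.mean()) / y.std()
    fams = [s.family_id for s in ens]
    plan = cc.family_aware_folds(fams, k=4, n_repetitions=1, seed=33)
    df = cc.nbs_predict_cv(X, y, plan, n_regions=20, n_permutations=100,
                           seed=34)
    assert df["r"].mean() > 0.95


def test_model_results_summary_counts_evaluations(linear_problem):
    X, y, fams = linear_problem
    model = cc.BehaviorPredictionModel(X, y, fams, method="lasso",
                                      predictor_tag="demo", inner_k=4)
    res = model.fit(k=4, n_repetitions=2, seed=5)
    assert len(res.fold_scores) == 8
    assert len(res.repetition_means) == 2
    text = res.summary()
    assert "demo" in text and "8 evaluations" in text
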