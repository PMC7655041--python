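"""Out-of-sample prediction of behavior from vectorized connectivity features.

Two feature-selection strategies are implemented under an identical
family-aware repeated tenfold cross-validation scheme:

* **lasso** — L1-penalized regression with the penalty tuned by a nested
  family-aware tenfold CV over a log-spaced path of 100 values from
  ``lambda_max`` down to ``0.01 * lambda_max``; the value maximizing the mean
  inner out-of-fold Pearson r is refit on the outer training set.
* **NBS regression** — edges whose Pearson association with the response
  exceeds ``|t| > 3`` are grouped into connected components on the region
  graph; the largest positive and negative components (permutation-tested)
  are summarized by their per-subject mean edge weight and entered into an
  ordinary least-squares model.

Members of the same family are never split between training and test sets.
Accuracy is the Pearson correlation between observed and predicted scores on
held-out subjects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from sklearn.linear_model import Lasso, lasso_path


# ---------------------------------------------------------------------------
# preprocessing and feature plumbing

def preprocess_behavior(raw_scores, age, sex):
    """Rank-based inverse Gaussian normalization followed by OLS
    residualization of age and sex.

    Continuous scores are mapped to normal scores ``Phi^-1(rank / (n + 1))``
    (van der Waerden), then age and sex are regressed out; the residuals are
    returned.
    """
    y = np.asarray(raw_scores, dtype=float)
    if np.unique(y).size < 2:
        raise ValueError("constant behavioral variable")
    r = stats.rankdata(y, method="average")
    z = stats.norm.ppf(r / (len(y) + 1))
    sex = np.asarray(sex)
    if sex.dtype.kind in "SUO":
        sex = (sex == sex[0]).astype(float)
    Z = np.column_stack([np.ones(len(y)), np.asarray(age, dtype=float), sex])
    beta, *_ = np.linalg.lstsq(Z, z, rcond=None)
    return z - Z @ beta


def vectorize_features(M: np.ndarray) -> np.ndarray:
    """Row-major upper triangle (i < j) of a symmetric matrix."""
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("input must be square")
    finite = np.isfinite(M)
    both = finite & finite.T
    if not np.allclose(M[both].reshape(-1), M.T[both].reshape(-1),
                       rtol=1e-10, atol=1e-12):
        raise ValueError("input must be symmetric")
    iu, ju = np.triu_indices(M.shape[0], 1)
    return M[iu, ju]


def unvectorize_features(v: np.ndarray, n: int, diag: float = 0.0) -> np.ndarray:
    """Inverse of :func:`vectorize_features`."""
    iu, ju = np.triu_indices(n, 1)
    if len(v) != len(iu):
        raise ValueError("vector length does not match n")
    M = np.full((n, n), diag)
    M[iu, ju] = v
    M[ju, iu] = v
    return M


def impute_masked(X: np.ndarray, kind: str = "efficiency") -> np.ndarray:
    """Fill masked (NaN) feature entries: 0 for efficiency-type matrices,
    the column minimum for search information (preserving the 'less
    accessible' ordering)."""
    X = np.asarray(X, dtype=float).copy()
    if not np.isnan(X).any():
        return X
    if kind == "efficiency":
        return np.nan_to_num(X, nan=0.0)
    col_min = np.nanmin(X, axis=0)
    col_min = np.where(np.isfinite(col_min), col_min, 0.0)
    idx = np.where(np.isnan(X))
    X[idx] = np.take(col_min, idx[1])
    return X


# ---------------------------------------------------------------------------
# family-aware cross-validation

@dataclass
class FoldPlan:
    """Fold assignments per repetition; every family sits wholly inside one
    fold."""

    assignments: np.ndarray  # (n_repetitions, n_subjects) ints in 0..k-1
    k: int
    n_repetitions: int
    seed: int
    family_ids: np.ndarray

    def folds(self, rep: int):
        """Yield (train_idx, test_idx) for each fold of one repetition."""
        a = self.assignments[rep]
        for f in range(self.k):
            test = np.flatnonzero(a == f)
            train = np.flatnonzero(a != f)
            yield train, test


def family_aware_folds(family_ids, k: int = 10, n_repetitions: int = 10,
                       seed: int = 0) -> FoldPlan:
    """Assign whole families to folds, greedily filling the smallest fold.

    Families are shuffled per repetition (seeded); each family goes to the
    fold with the fewest subjects so far, keeping fold sizes within the
    largest family size of one another.
    """
    family_ids = np.asarray(family_ids)
    if k < 2:
        raise ValueError("k must be >= 2")
    fams, inverse = np.unique(family_ids, return_inverse=True)
    if len(fams) < k:
        raise ValueError("need more families than folds")
    sizes = np.bincount(inverse)
    n = len(family_ids)
    if sizes.max() > 2 * n / k:
        warnings.warn("a family exceeds twice the nominal fold size")
    rng = np.random.default_rng(seed)
    assignments = np.zeros((n_repetitions, n), dtype=np.int64)
    for rep in range(n_repetitions):
        order = rng.permutation(len(fams))
        fold_sizes = np.zeros(k, dtype=np.int64)
        for fi in order:
            f = int(np.argmin(fold_sizes))
            assignments[rep, inverse == fi] = f
            fold_sizes[f] += sizes[fi]
    return FoldPlan(assignments=assignments, k=k, n_repetitions=n_repetitions,
                    seed=seed, family_ids=family_ids)


def _pearson(a, b):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


# ---------------------------------------------------------------------------
# lasso

def _standardize_fit(X):
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return mu, sd


def lasso_predict_cv(X, y, fold_plan: FoldPlan, inner_k: int = 10,
                     n_lambdas: int = 100, eps: float = 0.01,
                     return_models: bool = False):
    """Nested-CV lasso prediction.

    Per outer fold: an inner family-aware ``inner_k``-fold CV evaluates a
    decreasing log-spaced path of ``n_lambdas`` penalties from ``lambda_max``
    (the smallest penalty with an all-zero solution) down to
    ``eps * lambda_max``; the penalty maximizing the mean inner out-of-fold
    Pearson r is refit on the full outer training set.  Columns are
    standardized on training data only.

    Returns a DataFrame with one row per (repetition, fold): out-of-sample
    Pearson ``r``, ``mse`` and chosen ``lam``.  With ``return_models`` the
    fitted coefficient vectors are attached (original scale).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    rows = []
    models = []
    for rep in range(fold_plan.n_repetitions):
        for f, (train, test) in enumerate(fold_plan.folds(rep)):
            if np.unique(y[train]).size < 2:
                warnings.warn(f"constant response in rep {rep} fold {f}; skipped")
                continue
            res = _lasso_one_fold(
                X[train], y[train], X[test], fold_plan.family_ids[train],
                inner_k, n_lambdas, eps,
                seed=fold_plan.seed + 7919 * rep + 104729 * f)
            coef, intercept, lam, y_pred = res
            rows.append({
                "repetition": rep, "fold": f, "r": _pearson(y[test], y_pred),
                "mse": float(np.mean((y[test] - y_pred) ** 2)), "lam": lam,
            })
            if return_models:
                models.append((rep, f, coef, intercept))
    df = pd.DataFrame(rows)
    return (df, models) if return_models else df


def _lasso_one_fold(X_a, y_a, X_e, fam_a, inner_k, n_lambdas, eps, seed):
    mu, sd = _standardize_fit(X_a)
    Xs = (X_a - mu) / sd
    yc = y_a - y_a.mean()
    n = len(y_a)
    lam_max = np.max(np.abs(Xs.T @ yc)) / n
    if lam_max == 0:
        lam_max = 1e-12
    alphas = np.logspace(np.log10(lam_max), np.log10(eps * lam_max), n_lambdas)

    k_eff = min(inner_k, len(np.unique(fam_a)))
    inner = family_aware_folds(fam_a, k=k_eff, n_repetitions=1, seed=seed)
    scores = np.zeros((k_eff, n_lambdas))
    for fi, (itr, ite) in enumerate(inner.folds(0)):
        if np.unique(y_a[itr]).size < 2:
            continue
        m_i, s_i = _standardize_fit(X_a[itr])
        Xi = (X_a[itr] - m_i) / s_i
        yi = y_a[itr] - y_a[itr].mean()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # small-penalty path tails
            _, coefs, _ = lasso_path(Xi, yi, alphas=alphas)
        preds = ((X_a[ite] - m_i) / s_i) @ coefs  # (n_test, n_lambdas)
        yt = y_a[ite]
        if yt.std() > 0:
            pc = preds - preds.mean(axis=0)
            ytc = yt - yt.mean()
            denom = np.sqrt((pc ** 2).sum(axis=0)) * np.sqrt((ytc ** 2).sum())
            with np.errstate(invalid="ignore", divide="ignore"):
                scores[fi] = np.where(denom > 0, pc.T @ ytc / np.where(denom > 0, denom, 1.0), 0.0)
    mean_r = scores.mean(axis=0)
    best = int(np.argmax(mean_r))  # first (largest lambda) wins ties
    lam = float(alphas[best])
    model = Lasso(alpha=lam, max_iter=5000)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(Xs, yc)
    coef = model.coef_ / sd
    intercept = y_a.mean() - mu @ coef
    y_pred = X_e @ coef + intercept
    return coef, intercept, lam, y_pred


# ---------------------------------------------------------------------------
# network-based statistic

@dataclass
class NBSSelection:
    """Largest positive/negative suprathreshold connected components."""

    pos_edges: np.ndarray
    neg_edges: np.ndarray
    pos_size: int
    neg_size: int
    pos_p: float
    neg_p: float
    t_threshold: float
    n_permutations: int
    t_values: np.ndarray | None = None


def _edge_t_stats(Xs, ys, n):
    """t statistics of edgewise Pearson correlations; Xs/ys standardized."""
    r = Xs.T @ ys / n
    r = np.clip(r, -1 + 1e-15, 1 - 1e-15)
    return r * np.sqrt(n - 2) / np.sqrt(1 - r ** 2)


def _largest_component(edge_mask, iu, ju, n_regions):
    """Largest connected component (by edge count) of the suprathreshold
    edge graph.  Returns (size, edge_indices)."""
    idx = np.flatnonzero(edge_mask)
    if idx.size == 0:
        return 0, idx
    a, b = iu[idx], ju[idx]
    g = coo_matrix((np.ones(idx.size), (a, b)), shape=(n_regions, n_regions))
    _, labels = connected_components(g.tocsr(), directed=False)
    edge_labels = labels[a]
    counts = np.bincount(edge_labels)
    best = np.argmax(counts)
    return int(counts[best]), idx[edge_labels == best]


def nbs_select_components(X_train, y_train, n_regions: int,
                          t_threshold: float = 3.0,
                          n_permutations: int = 1000, seed: int = 0,
                          keep_t: bool = False) -> NBSSelection:
    """Network-based statistic feature selection.

    Each feature column's Pearson correlation with the response is converted
    to ``t = r sqrt(n-2) / sqrt(1-r^2)``; edges with ``t > 3`` (``t < -3``)
    form the positive (negative) suprathreshold graph, whose largest
    connected component is retained.  Familywise p-values are the fraction
    of label permutations producing an equal-or-larger same-sign component.
    Component selection is deterministic; only p-values are stochastic.
    """
    X = np.asarray(X_train, dtype=float)
    y = np.asarray(y_train, dtype=float)
    n, p = X.shape
    if n < 10:
        raise ValueError("need at least 10 training subjects")
    iu, ju = np.triu_indices(n_regions, 1)
    if p != len(iu):
        raise ValueError("feature count does not match N(N-1)/2")
    mu, sd = _standardize_fit(X)
    Xs = (X - mu) / sd
    ys = (y - y.mean()) / (y.std() if y.std() > 0 else 1.0)
    t = _edge_t_stats(Xs, ys, n)
    pos_size, pos_edges = _largest_component(t > t_threshold, iu, ju, n_regions)
    neg_size, neg_edges = _largest_component(t < -t_threshold, iu, ju, n_regions)

    rng = np.random.default_rng(seed)
    ge_pos = ge_neg = 0
    for _ in range(n_permutations):
        yp = ys[rng.permutation(n)]
        tp = _edge_t_stats(Xs, yp, n)
        sp, _ = _largest_component(tp > t_threshold, iu, ju, n_regions)
        sn, _ = _largest_component(tp < -t_threshold, iu, ju, n_regions)
        ge_pos += sp >= pos_size
        ge_neg += sn >= neg_size
    pos_p = ge_pos / n_permutations if pos_size > 0 else 1.0
    neg_p = ge_neg / n_permutations if neg_size > 0 else 1.0
    return NBSSelection(pos_edges=pos_edges, neg_edges=neg_edges,
                        pos_size=pos_size, neg_size=neg_size,
                        pos_p=pos_p, neg_p=neg_p, t_threshold=t_threshold,
                        n_permutations=n_permutations,
                        t_values=t if keep_t else None)


def nbs_predict_cv(X, y, fold_plan: FoldPlan, n_regions: int,
                   t_threshold: float = 3.0, n_permutations: int = 1000,
                   seed: int = 0, require_significance: bool = True,
                   alpha: float = 0.05):
    """NBS-component regression under the shared fold plan.

    Components are selected on training subjects only; per-subject mean
    weights of the positive/negative components form a (at most bivariate)
    least-squares model.  Folds with no admissible component score exactly 0.
    A component is admitted only if it exists; with ``require_significance``
    its permutation p must also fall below ``alpha``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(fold_plan.n_repetitions):
        for f, (train, test) in enumerate(fold_plan.folds(rep)):
            sel = nbs_select_components(
                X[train], y[train], n_regions, t_threshold=t_threshold,
                n_permutations=n_permutations, seed=int(rng.integers(2 ** 31)))
            cols_tr, cols_te = [], []
            for edges, size, pval in ((sel.pos_edges, sel.pos_size, sel.pos_p),
                                      (sel.neg_edges, sel.neg_size, sel.neg_p)):
                if size == 0:
                    continue
                if require_significance and pval >= alpha:
                    continue
                cols_tr.append(X[train][:, edges].mean(axis=1))
                cols_te.append(X[test][:, edges].mean(axis=1))
            row = {"repetition": rep, "fold": f,
                   "pos_size": sel.pos_size, "neg_size": sel.neg_size,
                   "pos_p": sel.pos_p, "neg_p": sel.neg_p}
            if not cols_tr:
                row.update(r=0.0, mse=float(np.mean((y[test] - y[train].mean()) ** 2)))
                rows.append(row)
                continue
            G_a = np.column_stack([np.ones(len(train))] + cols_tr)
            G_e = np.column_stack([np.ones(len(test))] + cols_te)
            if any(c.std() == 0 for c in cols_tr):
                row.update(r=0.0, mse=float(np.mean((y[test] - y[train].mean()) ** 2)))
                rows.append(row)
                continue
            beta, *_ = np.linalg.lstsq(G_a, y[train], rcond=None)
            y_pred = G_e @ beta
            row.update(r=_pearson(y[test], y_pred),
                       mse=float(np.mean((y[test] - y_pred) ** 2)))
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# model / results front end

class BehaviorPredictionModel:
    """Predict one behavioral dimension from one connectivity predictor.

    Parameters
    ----------
    X : (n_subjects, p) array
        Vectorized upper-triangle features (see :func:`vectorize_features`).
    y : (n_subjects,) array
        Behavioral scores (typically already normalized/residualized via
        :func:`preprocess_behavior`).
    family_ids : sequence
        Family labels; folds never split a family.
    method : {"lasso", "nbs"}
    n_regions : int, required for method="nbs"
    predictor_tag : optional label carried into results.
    """

    def __init__(self, X, y, family_ids, method="lasso", n_regions=None,
                 predictor_tag=None, **method_kwargs):
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y, dtype=float)
        self.family_ids = np.asarray(family_ids)
        if method not in ("lasso", "nbs"):
            raise ValueError("method must be 'lasso' or 'nbs'")
        if method == "nbs" and n_regions is None:
            raise ValueError("method='nbs' requires n_regions")
        self.method = method
        self.n_regions = n_regions
        self.predictor_tag = predictor_tag
        self.method_kwargs = method_kwargs

    def fit(self, k: int = 10, n_repetitions: int = 10, seed: int = 0,
            fold_plan: FoldPlan | None = None) -> "BehaviorPredictionResults":
        if fold_plan is None:
            fold_plan = family_aware_folds(self.family_ids, k=k,
                                           n_repetitions=n_repetitions,
                                           seed=seed)
        if self.method == "lasso":
            scores = lasso_predict_cv(self.X, self.y, fold_plan,
                                      **self.method_kwargs)
        else:
            scores = nbs_predict_cv(self.X, self.y, fold_plan,
                                    n_regions=self.n_regions, seed=seed,
                                    **self.method_kwargs)
        return BehaviorPredictionResults(self, scores, fold_plan)


class BehaviorPredictionResults:
    """Per-fold out-of-sample accuracies plus repetition-level summaries."""

    def __init__(self, model, fold_scores: pd.DataFrame, fold_plan: FoldPlan):
        self.model = model
        self.fold_scores = fold_scores
        self.fold_plan = fold_plan

    @property
    def repetition_means(self) -> pd.Series:
        return self.fold_scores.groupby("repetition")["r"].mean()

    @property
    def mean_r(self) -> float:
        return float(self.fold_scores["r"].mean())

    @property
    def mean_mse(self) -> float:
        return float(self.fold_scores["mse"].mean())

    def summary(self) -> str:
        tag = self.model.predictor_tag or "features"
        lines = [
            "Behavior prediction (family-aware repeated 10-fold CV)",
            f"  predictor: {tag}   method: {self.model.method}",
            f"  subjects: {len(self.model.y)}   features: {self.model.X.shape[1]}",
            f"  repetitions x folds: {self.fold_plan.n_repetitions} x {self.fold_plan.k}"
            f" = {len(self.fold_scores)} evaluations",
            f"  mean out-of-sample r: {self.mean_r:+.3f}",
            f"  mean squared error:   {self.mean_mse:.3f}",
            "  per-repetition mean r: "
            + ", ".join(f"{v:+.2f}" for v in self.repetition_means),
        ]
        return "\n".join(lines)
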