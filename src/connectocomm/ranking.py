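"""Statistical comparison and ranking of predictors.

Predictors (15 communication models, SC, FC) are compared on paired accuracy
distributions: one value per cross-validation repetition (behavior) or per
subject (coupling).  Tools: median-based ranking, pairwise repeated-measures
t tests with paired Cohen's d and Bonferroni correction, one-way
repeated-measures ANOVA, model/scheme grouping, and the weighted combined
behavioral + functional ranking.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .comm import MODELS, SCHEMES


def rank_by_median(distributions: pd.DataFrame) -> pd.Series:
    """Rank predictors by the median of their accuracy distribution.

    ``distributions``: columns = predictors, rows = paired observations.
    Rank 1 is the highest median; ties receive average ranks.
    """
    if distributions.shape[1] < 2:
        raise ValueError("need at least 2 predictors")
    if distributions.isna().all().any() or distributions.shape[0] == 0:
        raise ValueError("empty distribution")
    med = distributions.median(axis=0)
    ranks = stats.rankdata(-med.to_numpy(), method="average")
    return pd.Series(ranks, index=med.index, name="rank")


def pairwise_repeated_t(distributions: pd.DataFrame, alpha: float = 0.05):
    """All pairwise repeated-measures t tests with paired Cohen's d.

    Cohen's d uses the standard deviation of the paired differences (the
    repeated-measures convention).  The significance mask applies a
    Bonferroni threshold ``alpha / C(n_predictors, 2)``.  Returns a dict with
    the antisymmetric effect-size matrix ``d``, matrices ``t`` and ``p``, the
    symmetric boolean ``significant`` mask and the corrected threshold.
    Zero-variance differences yield infinite d, flagged and excluded from
    the mask.
    """
    cols = list(distributions.columns)
    m = len(cols)
    n_comp = m * (m - 1) // 2
    thr = alpha / n_comp
    d = pd.DataFrame(0.0, index=cols, columns=cols)
    t = pd.DataFrame(0.0, index=cols, columns=cols)
    p = pd.DataFrame(1.0, index=cols, columns=cols)
    sig = pd.DataFrame(False, index=cols, columns=cols)
    for a, b in combinations(cols, 2):
        diff = distributions[a].to_numpy() - distributions[b].to_numpy()
        sd = diff.std(ddof=1)
        if sd == 0:
            dd = np.inf * np.sign(diff.mean()) if diff.mean() != 0 else 0.0
            d.loc[a, b], d.loc[b, a] = dd, -dd
            continue
        tt, pp = stats.ttest_rel(distributions[a], distributions[b])
        dd = diff.mean() / sd
        d.loc[a, b], d.loc[b, a] = dd, -dd
        t.loc[a, b], t.loc[b, a] = tt, -tt
        p.loc[a, b] = p.loc[b, a] = pp
        sig.loc[a, b] = sig.loc[b, a] = bool(pp < thr)
    return {"d": d, "t": t, "p": p, "significant": sig,
            "bonferroni_alpha": thr, "n_comparisons": n_comp}


def rm_anova(accuracies: pd.DataFrame):
    """One-way repeated-measures ANOVA.

    ``accuracies``: rows = repeated units (predictors), columns = conditions
    (behavioral dimensions).  Returns ``(F, p, df_effect, df_error)`` with
    ``df_effect = k - 1`` and ``df_error = (k - 1)(n - 1)``.
    """
    A = accuracies.to_numpy(dtype=float)
    if np.isnan(A).any():
        raise ValueError("missing cells in the repeated-measures table")
    n, k = A.shape
    grand = A.mean()
    ss_cond = n * ((A.mean(axis=0) - grand) ** 2).sum()
    ss_subj = k * ((A.mean(axis=1) - grand) ** 2).sum()
    ss_tot = ((A - grand) ** 2).sum()
    ss_err = ss_tot - ss_cond - ss_subj
    df_effect = k - 1
    df_error = (k - 1) * (n - 1)
    ms_cond = ss_cond / df_effect
    ms_err = ss_err / df_error
    if ms_err == 0:
        F = 0.0 if ms_cond == 0 else np.inf
    else:
        F = ms_cond / ms_err
    p = float(stats.f.sf(F, df_effect, df_error)) if np.isfinite(F) else 0.0
    return float(F), p, df_effect, df_error


def grouped_distributions(distributions: pd.DataFrame,
                          group_by: str = "model") -> pd.DataFrame:
    """Average the 15 communication-model distributions by model or scheme.

    Predictor columns must be named ``{model}_{scheme}``; SC and FC columns
    (if present) pass through unaveraged.  ``group_by='model'`` yields one
    column per communication model (mean over the three schemes);
    ``group_by='scheme'`` one per weight definition (mean over models).
    """
    if group_by not in ("model", "scheme"):
        raise ValueError("group_by must be 'model' or 'scheme'")
    out = {}
    groups = MODELS if group_by == "model" else SCHEMES
    for g in groups:
        members = [f"{g}_{s}" for s in SCHEMES] if group_by == "model" \
            else [f"{m}_{g}" for m in MODELS]
        missing = [c for c in members if c not in distributions.columns]
        if missing:
            raise ValueError(f"missing battery members: {missing}")
        out[g] = distributions[members].mean(axis=1)
    if group_by == "model":
        for bench in ("SC", "FC"):
            if bench in distributions.columns:
                out[bench] = distributions[bench]
    return pd.DataFrame(out)


def combined_ranking(behavioral_ranks, functional_ranks,
                     weights=None) -> pd.DataFrame:
    """Weighted combined ranking tau of behavioral and functional rankings.

    ``behavioral_ranks`` is one rank Series or a list of them (e.g. lasso and
    NBS).  Default weights: equal split between behavior and function for a
    single behavioral set; 0.25 / 0.25 / 0.5 when two behavioral methods are
    supplied.  Weights must sum to 1.
    """
    if isinstance(behavioral_ranks, pd.Series):
        behavioral_ranks = [behavioral_ranks]
    ranks = list(behavioral_ranks) + [functional_ranks]
    if weights is None:
        weights = ([0.25, 0.25, 0.5] if len(behavioral_ranks) == 2
                   else [1.0 / len(ranks)] * len(ranks))
    if len(weights) != len(ranks):
        raise ValueError("one weight per rank set required")
    if abs(sum(weights) - 1.0) > 1e-9:
        raise ValueError("weights must sum to 1")
    idx = ranks[0].index
    for r in ranks[1:]:
        if not r.index.sort_values().equals(idx.sort_values()):
            raise ValueError("rank sets must cover identical predictors")
    tau = sum(w * r.reindex(idx) for w, r in zip(weights, ranks))
    out = pd.DataFrame({"tau": tau})
    for i, r in enumerate(behavioral_ranks):
        out[f"behavioral_rank_{i + 1}"] = r.reindex(idx)
    out["functional_rank"] = functional_ranks.reindex(idx)
    return out.sort_values("tau")
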