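"""Structure-function coupling: Spearman correlation between FC and each
communication / benchmark matrix over upper-triangle region pairs, at the
individual and group level, optionally stratified by anatomical connectedness
or hemisphere."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .comm import MODELS, SCHEMES, communication_battery
from .core import euclidean_distance_matrix, group_average

STRATA = ("all", "connected", "unconnected", "intrahemispheric")


def _stratum_mask(stratum, n, sc_support=None, hemispheres=None):
    iu, ju = np.triu_indices(n, 1)
    if stratum == "all":
        return np.ones(len(iu), dtype=bool)
    if stratum in ("connected", "unconnected"):
        if sc_support is None:
            raise ValueError(f"stratum {stratum!r} needs sc_support")
        conn = np.asarray(sc_support)[iu, ju] > 0
        return conn if stratum == "connected" else ~conn
    if stratum == "intrahemispheric":
        if hemispheres is None:
            raise ValueError("stratum 'intrahemispheric' needs hemisphere labels")
        h = np.asarray(hemispheres)
        return h[iu] == h[ju]
    raise ValueError(f"unknown stratum {stratum!r}")


def coupling(C_like: np.ndarray, fc: np.ndarray, stratum: str = "all",
             sc_support=None, hemispheres=None) -> float:
    """Spearman rho between a structural/communication matrix and FC.

    Computed over the selected upper-triangle entries; pairs where the
    predictor is undefined (NaN, e.g. masked search-information entries) are
    excluded pairwise.  Midranks handle ties.
    """
    C = np.asarray(C_like, dtype=float)
    fc = np.asarray(fc, dtype=float)
    if C.shape != fc.shape:
        raise ValueError("matrices must share shape")
    n = C.shape[0]
    iu, ju = np.triu_indices(n, 1)
    mask = _stratum_mask(stratum, n, sc_support, hemispheres)
    x = C[iu, ju][mask]
    y = fc[iu, ju][mask]
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 10:
        raise ValueError("fewer than 10 entries in stratum")
    rho = spearmanr(x[ok], y[ok]).statistic
    return float(rho)


def predictor_matrices(battery) -> dict:
    """The 17 predictors of one battery: 15 communication matrices plus SC
    and (sign-flipped) Euclidean distance."""
    mats = {f"{m}_{s}": battery[(m, s)] for m in MODELS for s in SCHEMES
            if (m, s) in battery.matrices}
    mats["SC"] = battery.sc
    mats["dist"] = -battery.dist  # report the distance benchmark with sign
    return mats


def coupling_battery(ensemble, density: float | None = None,
                     models=MODELS, strata=("all",)) -> pd.DataFrame:
    """Per-subject and group-level coupling for all predictors.

    For each subject, that subject's 15 communication matrices plus SC and
    Euclidean distance are correlated with the subject's FC.  The group row
    uses the battery of the group-averaged SC against group-averaged FC.
    Identical subject connectomes (common in zero-noise synthetic ensembles)
    reuse one battery.
    """
    coords = ensemble.coords
    hemis = coords["hemisphere"].to_numpy() if coords is not None else None
    rows = []
    cache_sc, cache_bat = None, None
    for subj in ensemble.subjects:
        if cache_sc is None or not np.array_equal(subj.sc, cache_sc):
            cache_sc = subj.sc
            cache_bat = communication_battery(subj.sc, coords, density, models)
        rows.extend(_coupling_rows(cache_bat, subj.fc, subj.subject_id,
                                   strata, hemis))
    g_sc = group_average([s.sc for s in ensemble.subjects])
    g_fc = group_average([s.fc for s in ensemble.subjects])
    g_bat = communication_battery(g_sc, coords, density, models)
    rows.extend(_coupling_rows(g_bat, g_fc, "GROUP", strata, hemis))
    return pd.DataFrame(rows)


def _coupling_rows(battery, fc, unit, strata, hemis):
    out = []
    support = battery.sc
    for tag, M in predictor_matrices(battery).items():
        for stratum in strata:
            out.append({
                "predictor": tag, "unit": unit, "stratum": stratum,
                "rho": coupling(M, fc, stratum, sc_support=support,
                                hemispheres=hemis),
            })
    return out


class StructureFunctionCoupling:
    """Model-style front end for the coupling analysis of an ensemble."""

    def __init__(self, ensemble, density: float | None = None,
                 models=MODELS, strata=("all",)):
        self.ensemble = ensemble
        self.density = density
        self.models = models
        self.strata = strata

    def fit(self) -> "CouplingResults":
        table = coupling_battery(self.ensemble, self.density, self.models,
                                 self.strata)
        return CouplingResults(self, table)


class CouplingResults:
    """Coupling table with individual-median and group summaries."""

    def __init__(self, model, table: pd.DataFrame):
        self.model = model
        self.table = table

    def median_individual(self, stratum: str = "all") -> pd.Series:
        t = self.table[(self.table["unit"] != "GROUP")
                       & (self.table["stratum"] == stratum)]
        return t.groupby("predictor")["rho"].median().sort_values(ascending=False)

    def group_level(self, stratum: str = "all") -> pd.Series:
        t = self.table[(self.table["unit"] == "GROUP")
                       & (self.table["stratum"] == stratum)]
        return t.set_index("predictor")["rho"].sort_values(ascending=False)

    def summary(self, stratum: str = "all") -> str:
        med = self.median_individual(stratum)
        grp = self.group_level(stratum)
        lines = [
            "Structure-function coupling (Spearman rho, upper triangle)",
            f"  subjects: {len(self.model.ensemble)}   stratum: {stratum}",
            f"  {'predictor':<10} {'median r_I':>10} {'group r_G':>10}",
        ]
        for tag in med.index:
            lines.append(f"  {tag:<10} {med[tag]:>+10.3f} {grp.get(tag, np.nan):>+10.3f}")
        return "\n".join(lines)
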