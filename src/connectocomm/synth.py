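"""Synthetic connectome / FC / behavior generators.

These generators stand in for restricted-access human neuroimaging data and
emulate the statistical features the downstream analyses rely on:

* spatially embedded sparse weighted connectomes — connection probability
  decays exponentially with interregional Euclidean distance and streamline
  weights are heavy-tailed (rounded lognormal) with a mean decreasing in
  distance;
* per-subject variation — multiplicative lognormal edge noise with a shared
  within-family component, plus optional degree-preserving rewiring;
* functional connectivity — a noisy monotone function of a chosen
  communication matrix minus a Euclidean-distance component;
* behavioral dimensions — sparse linear functions of connectivity features
  with a controlled signal fraction, plus age and sex effects;
* topologically randomized null connectomes (Maslov-Sneppen double-edge
  swaps, weights attached to edges).

Every generator is a pure function of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .core import (
    euclidean_distance_matrix,
    is_connected,
    validate_weight_matrix,
)

# Half-ellipsoid semi-axes (mm) approximating one cortical hemisphere, and the
# lateral offset of each hemisphere's center from the midline.
_HEMI_AXES = (28.0, 60.0, 45.0)
_HEMI_OFFSET = 34.0


def generate_geometry(n_regions: int, seed: int) -> pd.DataFrame:
    """Region centroids in two mirrored half-ellipsoids (hemispheres L/R).

    Returns a DataFrame with columns ``region_id, x, y, z, hemisphere``;
    left-hemisphere x-coordinates are negative, right positive.  The right
    hemisphere is the mirror image of the left, as in a bilaterally
    symmetric parcellation.
    """
    if n_regions < 10 or n_regions % 2:
        raise ValueError("n_regions must be even and >= 10")
    rng = np.random.default_rng(seed)
    half = n_regions // 2
    ax, ay, az = _HEMI_AXES
    pts = []
    while len(pts) < half:
        p = rng.uniform(-1, 1, size=3)
        if p @ p <= 1.0:
            pts.append(p)
    left = np.array(pts) * [ax, ay, az]
    left[:, 0] = -np.abs(left[:, 0]) - _HEMI_OFFSET + ax  # keep strictly x < 0
    left[:, 0] = np.minimum(left[:, 0], -1.0)
    right = left.copy()
    right[:, 0] = -right[:, 0]
    xyz = np.vstack([left, right])
    hemi = np.array(["L"] * half + ["R"] * half)
    return pd.DataFrame(
        {"region_id": np.arange(n_regions), "x": xyz[:, 0], "y": xyz[:, 1],
         "z": xyz[:, 2], "hemisphere": hemi}
    )


def generate_connectome_template(coords, target_density: float, decay_mm: float,
                                 seed: int) -> np.ndarray:
    """Spatially embedded weighted connectome template.

    Edge existence probability is proportional to ``exp(-D/decay_mm)``,
    calibrated so the expected density matches ``target_density``.  Edge
    weights are integer streamline-count surrogates, ``max(1, round(LogNormal))``
    with log-mean decreasing in distance.  Connectivity is guaranteed by
    augmenting with a random spanning tree across fragments.
    """
    if not 0 < target_density < 1:
        raise ValueError("target_density must be in (0, 1)")
    if decay_mm <= 0:
        raise ValueError("decay_mm must be positive")
    rng = np.random.default_rng(seed)
    D = euclidean_distance_matrix(coords)
    n = D.shape[0]
    iu, ju = np.triu_indices(n, 1)
    f = np.exp(-D[iu, ju] / decay_mm)
    # calibrate the scale of capped probabilities p = min(1, c*f)
    c = target_density / f.mean()
    for _ in range(50):
        p = np.minimum(1.0, c * f)
        m = p.mean()
        if abs(m - target_density) < 1e-6:
            break
        c *= target_density / m
    p = np.minimum(1.0, c * f)
    exists = rng.random(p.shape) < p

    W = np.zeros((n, n))
    d_edges = D[iu, ju]
    mu = np.log(20.0) - d_edges / (2.0 * decay_mm)
    w = np.maximum(1.0, np.round(np.exp(rng.normal(mu, 0.8))))
    W[iu[exists], ju[exists]] = w[exists]
    W = W + W.T

    # connect fragments with a random spanning tree over components
    from .core import _components

    n_comp, labels = _components(W)
    guard = 0
    while n_comp > 1:
        comps = [np.flatnonzero(labels == c) for c in range(n_comp)]
        order = rng.permutation(n_comp)
        for a, b in zip(order[:-1], order[1:]):
            i = int(rng.choice(comps[a]))
            j = int(rng.choice(comps[b]))
            wij = max(1.0, np.round(np.exp(rng.normal(np.log(20.0) - D[i, j] / (2 * decay_mm), 0.8))))
            W[i, j] = W[j, i] = wij
        n_comp, labels = _components(W)
        guard += 1
        if guard > n:
            raise ValueError("cannot achieve connectivity at requested density")
    return W


@dataclass
class Subject:
    subject_id: str
    sc: np.ndarray
    family_id: str
    age: float
    sex: str
    fc: np.ndarray | None = None
    behavior: np.ndarray | None = None


@dataclass
class SubjectEnsemble:
    """Per-subject SC (plus optional FC/behavior), shared geometry and the
    full generation manifest."""

    subjects: list
    coords: pd.DataFrame
    generation_manifest: dict = field(default_factory=dict)

    def __len__(self):
        return len(self.subjects)

    def __iter__(self):
        return iter(self.subjects)

    def phenotypes(self) -> pd.DataFrame:
        rows = []
        for s in self.subjects:
            row = {"subject_id": s.subject_id, "family_id": s.family_id,
                   "age": s.age, "sex": s.sex}
            if s.behavior is not None:
                for b, v in enumerate(np.atleast_1d(s.behavior)):
                    row[f"dim{b + 1}"] = v
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class GroundTruth:
    """Planted generative parameters recorded for recovery experiments."""

    generating_model: tuple = ("SPE", "wei")
    fc_coupling: float = 0.6       # rho: rank-correlation of FC with the model
    distance_weight: float = 0.2   # gamma: negative distance component of FC
    behavior_support: np.ndarray | None = None  # upper-triangle feature indices
    beta: np.ndarray | None = None
    target_r2: float = 0.3

    def __post_init__(self):
        if self.fc_coupling < 0 or self.distance_weight < 0:
            raise ValueError("rho and gamma must be nonnegative")
        if self.fc_coupling ** 2 + self.distance_weight ** 2 > 1:
            raise ValueError("rho^2 + gamma^2 must not exceed 1")


def generate_subject_ensemble(template: np.ndarray, n_subjects: int,
                              family_size_dist=((1, 0.5), (2, 0.3), (3, 0.2)),
                              edge_noise: float = 0.2, rewire_frac: float = 0.0,
                              seed: int = 0, coords=None) -> SubjectEnsemble:
    """Subject-level connectomes around a shared template.

    Each subject's SC multiplies the template weights by lognormal noise with
    a within-family shared component (half the variance) and an individual
    component, optionally followed by degree-preserving rewiring of a
    fraction of edges.  Ages are uniform on 22-35 and sexes balanced.
    Coordinates must be supplied separately (the template fixes N only).
    """
    template = validate_weight_matrix(template, name="template")
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    rng = np.random.default_rng(seed)
    sizes, probs = zip(*family_size_dist)
    fam_sizes = []
    while sum(fam_sizes) < n_subjects:
        fam_sizes.append(int(rng.choice(sizes, p=probs)))
    fam_sizes[-1] -= sum(fam_sizes) - n_subjects
    if fam_sizes[-1] == 0:
        fam_sizes.pop()

    n = template.shape[0]
    iu, ju = np.triu_indices(n, 1)
    support = template[iu, ju] > 0
    subjects = []
    sid = 0
    for fi, fsize in enumerate(fam_sizes):
        g_fam = rng.standard_normal(support.sum())
        for _ in range(fsize):
            g_ind = rng.standard_normal(support.sum())
            g = np.sqrt(0.5) * g_fam + np.sqrt(0.5) * g_ind
            w = template[iu, ju].copy()
            w[support] = w[support] * np.exp(edge_noise * g)
            sc = np.zeros((n, n))
            sc[iu, ju] = w
            sc = sc + sc.T
            if rewire_frac > 0:
                n_edges = int(support.sum())
                swaps = max(1, int(round(rewire_frac * n_edges)))
                sc = rewire_degree_preserving(
                    sc, n_swaps_per_edge=swaps / n_edges,
                    seed=int(rng.integers(2 ** 31)))
            subjects.append(Subject(
                subject_id=f"sub{sid:04d}", sc=sc, family_id=f"fam{fi:04d}",
                age=float(rng.integers(22, 36)), sex=str(rng.choice(["F", "M"])),
            ))
            sid += 1
    manifest = {"n_subjects": n_subjects, "edge_noise": edge_noise,
                "rewire_frac": rewire_frac, "seed": seed,
                "family_sizes": fam_sizes}
    return SubjectEnsemble(subjects=subjects, coords=coords,
                           generation_manifest=manifest)


def _rank_z(x: np.ndarray) -> np.ndarray:
    """Rank-based inverse Gaussian standardization (van der Waerden scores);
    NaNs map to the lowest score (least efficient)."""
    x = np.asarray(x, dtype=float).copy()
    nan = ~np.isfinite(x)
    if nan.any():
        x[nan] = np.nanmin(x) - 1.0 if np.isfinite(x).any() else 0.0
    r = rankdata(x, method="average")
    return norm.ppf(r / (len(x) + 1))


def generate_synthetic_fc(sc: np.ndarray, coords, truth: GroundTruth, seed: int,
                          comm_values: np.ndarray | None = None) -> np.ndarray:
    """FC as a noisy monotone function of a communication matrix.

    Upper-triangle FC = ``rho*z(C) - gamma*z(D) + sqrt(1-rho^2-gamma^2)*eps``
    with ``z`` rank-based standardization and ``eps`` standard normal, mapped
    through ``tanh`` into (-1, 1); symmetric with unit diagonal.

    ``comm_values`` short-circuits the communication computation when the
    caller already holds the generating model's matrix for this SC.
    """
    rho, gamma = truth.fc_coupling, truth.distance_weight
    D = euclidean_distance_matrix(coords)
    if comm_values is None:
        from .comm import communication_battery

        model, scheme = truth.generating_model
        bat = communication_battery(sc, coords, density=None, models=(model,))
        comm_values = bat[(model, scheme)]
    n = D.shape[0]
    iu, ju = np.triu_indices(n, 1)
    z_c = _rank_z(comm_values[iu, ju])
    z_d = _rank_z(D[iu, ju])
    rng = np.random.default_rng(seed)
    resid = np.sqrt(max(0.0, 1.0 - rho ** 2 - gamma ** 2))
    raw = rho * z_c - gamma * z_d + resid * rng.standard_normal(len(iu))
    vals = np.tanh(0.5 * raw)
    fc = np.eye(n)
    fc[iu, ju] = vals
    fc[ju, iu] = vals
    return fc


def plant_connected_support(sc_support: np.ndarray, n_edges: int, seed: int):
    """Choose a connected set of ``n_edges`` edges (upper-triangle indices)
    on the given support by greedy random growth from a seed edge."""
    n = sc_support.shape[0]
    iu, ju = np.triu_indices(n, 1)
    edge_idx = {(int(a), int(b)): k for k, (a, b) in enumerate(zip(iu, ju))}
    rng = np.random.default_rng(seed)
    adj = [set(np.flatnonzero(sc_support[v] > 0)) for v in range(n)]
    start = int(rng.integers(n))
    # ensure start has neighbors
    for _ in range(n):
        if adj[start]:
            break
        start = int(rng.integers(n))
    nodes = {start}
    chosen = []
    frontier = [(start, v) for v in adj[start]]
    while frontier and len(chosen) < n_edges:
        k = int(rng.integers(len(frontier)))
        u, v = frontier.pop(k)
        e = edge_idx[(min(u, v), max(u, v))]
        if e in chosen:
            continue
        chosen.append(e)
        if v not in nodes:
            nodes.add(v)
            frontier.extend((v, w) for w in adj[v] if
                            edge_idx[(min(v, w), max(v, w))] not in chosen)
    if len(chosen) < n_edges:
        raise ValueError("support too small for requested component size")
    return np.array(sorted(chosen))


def generate_synthetic_behavior(X: np.ndarray, ages, sexes, truth: GroundTruth,
                                seed: int, age_beta: float = 0.02,
                                sex_beta: float = 0.1):
    """Behavioral scores as a sparse linear function of connectivity features.

    ``y = X[:, S] @ beta + age*b_a + sex*b_s + eps`` with ``eps`` scaled so
    the feature term explains ``target_r2`` of the feature-plus-noise
    variance.  ``X`` is the (n_subjects, p) feature matrix the caller derived
    from the ensemble (vectorized communication / SC / FC matrices).

    Returns ``(y, truth)`` with the support and betas recorded in ``truth``.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    rng = np.random.default_rng(seed)
    if truth.behavior_support is None:
        raise ValueError("truth.behavior_support must be set")
    S = np.asarray(truth.behavior_support)
    if S.size > p:
        raise ValueError("support larger than feature count")
    if truth.beta is None:
        # one-signed effects: a coherent component, as NBS-style selection assumes
        truth.beta = 0.5 + np.abs(rng.normal(0.0, 1.0, size=S.size))
    r2 = truth.target_r2
    # rank-Gaussianize planted columns (the same inverse-normal convention the
    # behavioral preprocessing applies), so effects are comparable across
    # heavy-tailed edge weights and survive the rank transform downstream
    Xs = np.column_stack([_rank_z(X[:, j]) for j in S])
    signal = Xs @ truth.beta
    sex_num = np.asarray([1.0 if s == "F" else 0.0 for s in sexes])
    demo = age_beta * np.asarray(ages, dtype=float) + sex_beta * sex_num
    var_s = signal.var()
    if r2 <= 0:
        y = demo + rng.standard_normal(n)
    elif r2 >= 1:
        y = signal + demo
    else:
        sd_eps = np.sqrt(var_s * (1 - r2) / r2)
        y = signal + demo + rng.normal(0.0, sd_eps, size=n)
    return y, truth


def rewire_degree_preserving(W: np.ndarray, n_swaps_per_edge: float = 10,
                             seed: int = 0) -> np.ndarray:
    """Maslov-Sneppen degree-preserving randomization.

    Double-edge swaps (a,b),(c,d) -> (a,d),(c,b); weights travel with their
    edge so the degree sequence and the edge-weight multiset are preserved
    exactly.  Swaps that would disconnect the graph are rejected.
    """
    W = validate_weight_matrix(W)
    n = W.shape[0]
    iu, ju = np.triu_indices(n, 1)
    mask = W[iu, ju] > 0
    edges = [[int(a), int(b), float(w)] for a, b, w in
             zip(iu[mask], ju[mask], W[iu, ju][mask])]
    if len(edges) < 2:
        raise ValueError("too few edges to swap")
    rng = np.random.default_rng(seed)
    adj = [set() for _ in range(n)]
    for a, b, _ in edges:
        adj[a].add(b)
        adj[b].add(a)

    def connected():
        seen = {0}
        stack = [0]
        while stack:
            u = stack.pop()
            for v in adj[u]:
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        return len(seen) == n

    target = int(round(n_swaps_per_edge * len(edges)))
    done = 0
    attempts = 0
    max_attempts = 100 * max(target, 1)
    while done < target and attempts < max_attempts:
        attempts += 1
        e1, e2 = rng.integers(len(edges)), rng.integers(len(edges))
        if e1 == e2:
            continue
        a, b, w1 = edges[e1]
        c, d, w2 = edges[e2]
        if rng.random() < 0.5:
            c, d = d, c
        # propose (a,d) and (c,b)
        if len({a, b, c, d}) < 4:
            continue
        if d in adj[a] or b in adj[c]:
            continue
        adj[a].discard(b); adj[b].discard(a)
        adj[c].discard(d); adj[d].discard(c)
        adj[a].add(d); adj[d].add(a)
        adj[c].add(b); adj[b].add(c)
        if not connected():
            adj[a].discard(d); adj[d].discard(a)
            adj[c].discard(b); adj[b].discard(c)
            adj[a].add(b); adj[b].add(a)
            adj[c].add(d); adj[d].add(c)
            continue
        edges[e1] = [min(a, d), max(a, d), w1]
        edges[e2] = [min(c, b), max(c, b), w2]
        done += 1
    out = np.zeros_like(W)
    for a, b, w in edges:
        out[a, b] = out[b, a] = w
    return out
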