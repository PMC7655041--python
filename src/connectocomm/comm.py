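"""Network communication models.

Five measures of communication efficiency between region pairs:

* **SPE** — shortest path efficiency, ``1 / Lambda*`` where ``Lambda*`` is the
  minimal summed connection length (centralized optimal routing).
* **NE** — navigation efficiency: greedy geometric routing that always hops to
  the neighbor spatially closest to the target and fails when a node is
  revisited; efficiency is ``1 / Lambda`` over the realized hop sequence.
* **DE** — diffusion efficiency, ``1 / H`` with ``H`` the mean first passage
  time of a random walk on the weighted graph.
* **SI** — search information, ``log2`` of the probability that a naive random
  walker spontaneously follows the shortest path (nonpositive; larger values
  mean the efficient route is more accessible).
* **CMY** — communicability, the matrix exponential of the (strength-
  normalized) adjacency matrix: a broadcasting measure over all walks.

Each model is computed under the three weight conventions (``bin``, ``wei``,
``dis``), yielding the 15-matrix battery of :func:`communication_battery`.
Asymmetric measures (NE, DE, SI) are symmetrized as ``(C + C.T) / 2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm, solve
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .core import (
    SCHEMES,
    _components,
    build_weight_variants,
    euclidean_distance_matrix,
    is_connected,
    threshold_by_density,
    validate_weight_matrix,
    weights_to_lengths,
)

MODELS = ("SPE", "NE", "DE", "SI", "CMY")

_EQ_RTOL = 1e-9
_EQ_ATOL = 1e-12


def shortest_path_efficiency(L: np.ndarray):
    """Shortest path efficiency and a deterministic predecessor matrix.

    Returns ``(SPE, predecessors)``.  ``SPE(i,j) = 1 / Lambda*(i,j)`` with
    ``Lambda*`` the minimal summed length over paths; unreachable pairs get 0
    and the diagonal is 0.  ``predecessors[i, j]`` is the node preceding j on
    a shortest path from i (-1 where undefined); among equal-cost
    predecessors the lowest region index is chosen, so reconstructed paths
    are platform-independent.
    """
    L = np.asarray(L, dtype=float)
    finite = np.isfinite(L)
    if np.any(L[finite] < 0):
        raise ValueError("negative connection lengths")
    n = L.shape[0]
    graph = csr_matrix(np.where(finite, L, 0.0))
    lam = dijkstra(graph, directed=False)
    spe = np.zeros_like(lam)
    off = ~np.eye(n, dtype=bool)
    reach = np.isfinite(lam) & off
    spe[reach] = 1.0 / lam[reach]

    # lexicographic predecessors: pred[i,j] = min u with lam[i,u] + L[u,j] == lam[i,j]
    pred = np.full((n, n), -1, dtype=np.int64)
    for i in range(n):
        cand = lam[i][:, None] + L  # cand[u, j]
        ok = np.isclose(cand, lam[i][None, :], rtol=_EQ_RTOL, atol=_EQ_ATOL)
        ok &= np.isfinite(cand)
        has = ok.any(axis=0)
        has[i] = False
        pred[i, has] = np.argmax(ok[:, has], axis=0)
    return spe, pred


def reconstruct_path(pred: np.ndarray, i: int, j: int):
    """Node sequence of the stored shortest path i -> j, or None if unreachable."""
    if i == j:
        return [i]
    if pred[i, j] < 0:
        return None
    path = [j]
    u = j
    while u != i:
        u = int(pred[i, u])
        path.append(u)
        if len(path) > pred.shape[0]:
            raise RuntimeError("predecessor cycle")
    return path[::-1]


def navigation_efficiency(L: np.ndarray, D: np.ndarray):
    """Greedy navigation routing guided by Euclidean distance.

    From the current node, progress to the neighbor closest (in D) to the
    target; success when the target is reached, failure when a node would be
    revisited, the current node has no neighbors, or the hop count exceeds N.
    Ties between equidistant neighbors go to the lower region index.

    Returns ``(NE_asy, hops)`` where ``NE_asy(i,j) = 1 / Lambda(i,j)`` (sum of
    L over the realized hops; failures encoded as 0) and ``hops[i, j]`` is the
    number of hops of a successful navigation (-1 on failure).
    """
    L = np.asarray(L, dtype=float)
    D = np.asarray(D, dtype=float)
    n = L.shape[0]
    support = np.isfinite(L) & ~np.eye(n, dtype=bool)

    # next_hop[u, j]: the neighbor of u nearest to target j (independent of source)
    next_hop = np.full((n, n), -1, dtype=np.int64)
    for u in range(n):
        nbrs = np.flatnonzero(support[u])
        if nbrs.size == 0:
            continue
        # argmin returns the first minimum; nbrs is ascending -> lowest index wins ties
        next_hop[u] = nbrs[np.argmin(D[nbrs], axis=0)]

    lam = np.full((n, n), np.inf)
    hops = np.full((n, n), -1, dtype=np.int64)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            u, total, k = i, 0.0, 0
            visited = {i}
            while True:
                v = next_hop[u, j]
                if v < 0:
                    break
                total += L[u, v]
                k += 1
                if v == j:
                    lam[i, j] = total
                    hops[i, j] = k
                    break
                if v in visited or k > n:
                    break
                visited.add(v)
                u = v
    ne = np.zeros((n, n))
    ok = np.isfinite(lam)
    ne[ok] = 1.0 / lam[ok]
    return ne, hops


def random_walk_transition(W: np.ndarray) -> np.ndarray:
    """Row-stochastic transition matrix T(i,j) = W(i,j) / sum_u W(i,u)."""
    W = np.asarray(W, dtype=float)
    s = W.sum(axis=1)
    if np.any(s == 0):
        raise ValueError("isolated node: zero strength row")
    return W / s[:, None]


def mean_first_passage_time(T: np.ndarray) -> np.ndarray:
    """Mean first passage times of an irreducible Markov chain (in steps).

    Uses the fundamental matrix ``Z = (I - T + 1 pi^T)^{-1}``:
    ``H(i,j) = (Z(j,j) - Z(i,j)) / pi(j)``, zero diagonal.
    """
    n = T.shape[0]
    # stationary distribution: left eigenvector; for reversible chains pi ~ strength
    evals, evecs = np.linalg.eig(T.T)
    k = np.argmin(np.abs(evals - 1.0))
    pi = np.real(evecs[:, k])
    pi = pi / pi.sum()
    Z = solve(np.eye(n) - T + np.outer(np.ones(n), pi), np.eye(n))
    H = (np.diag(Z)[None, :] - Z) / pi[None, :]
    np.fill_diagonal(H, 0.0)
    return H


def diffusion_efficiency(W: np.ndarray):
    """Diffusion efficiency ``DE = 1 / H`` (mean-first-passage-time inverse).

    Returns ``(DE_asy, context)`` with context a dict holding the transition
    matrix ``T``, stationary distribution ``pi`` and passage times ``H``.
    Requires a connected graph (the walk must be irreducible).
    """
    W = validate_weight_matrix(W)
    n_comp, _ = _components(W)
    if n_comp != 1:
        raise ValueError(f"graph is fragmented into {n_comp} components")
    T = random_walk_transition(W)
    H = mean_first_passage_time(T)
    s = W.sum(axis=1)
    pi = s / s.sum()
    de = np.zeros_like(H)
    off = ~np.eye(W.shape[0], dtype=bool)
    de[off] = 1.0 / H[off]
    return de, {"T": T, "pi": pi, "H": H}


def search_information(W_wei: np.ndarray, L: np.ndarray, pred: np.ndarray | None = None,
                       *, negate: bool = False) -> np.ndarray:
    """Search information ``SI(i,j) = log2 P(Omega(i,j))``.

    ``Omega(i,j)`` is the shortest path under ``L`` and ``P`` the probability
    that a naive random walker (transition probabilities from ``W_wei``,
    regardless of L's scheme) follows it.  Values are nonpositive; larger
    means the efficient route is more accessible.  Unreachable pairs are NaN
    (masked downstream); the diagonal is 0.

    ``negate=True`` returns the conventional sign-flipped form.
    """
    T = random_walk_transition(W_wei)
    if pred is None:
        _, pred = shortest_path_efficiency(L)
    n = T.shape[0]
    with np.errstate(divide="ignore"):
        logT = np.log2(T)
    si = np.full((n, n), np.nan)
    np.fill_diagonal(si, 0.0)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            path = reconstruct_path(pred, i, j)
            if path is None:
                continue
            total = 0.0
            for u, v in zip(path[:-1], path[1:]):
                total += logT[u, v]
            si[i, j] = total
    return -si if negate else si


def communicability(W: np.ndarray, scheme: str = "wei") -> np.ndarray:
    """Communicability: matrix exponential of the adjacency matrix.

    For ``bin`` the raw 0/1 matrix is exponentiated.  For ``wei``/``dis`` the
    matrix is first normalized as ``W'(i,j) = W(i,j) / sqrt(s(i) s(j))``
    (``s`` = node strength) to attenuate the influence of high-strength nodes.
    """
    W = validate_weight_matrix(W)
    if scheme == "bin":
        A = (W > 0).astype(float)
    else:
        s = W.sum(axis=1)
        if np.any(s == 0):
            raise ValueError("isolated node: strength normalization undefined")
        A = W / np.sqrt(np.outer(s, s))
    return expm(A)


def symmetrize(C_asy: np.ndarray) -> np.ndarray:
    """Symmetric communication matrix ``C = (C_asy + C_asy.T) / 2``.

    NaN entries (masked pairs) propagate: the symmetric entry is NaN if
    either direction is undefined.
    """
    C = np.asarray(C_asy, dtype=float)
    return (C + C.T) / 2.0


@dataclass
class CommunicationBattery:
    """The per-connectome battery: 15 symmetric communication matrices keyed
    ``(model, scheme)``, plus the thresholded SC and the Euclidean distance
    matrix used as benchmarks."""

    matrices: dict = field(default_factory=dict)
    sc: np.ndarray | None = None
    dist: np.ndarray | None = None
    density: float | None = None
    n_regions: int | None = None
    nav_failures: dict = field(default_factory=dict)

    def __getitem__(self, key):
        return self.matrices[key]

    def tags(self):
        return list(self.matrices.keys())


def communication_battery(sc: np.ndarray, coords, density: float | None = None,
                          models=MODELS) -> CommunicationBattery:
    """Compute the full battery of communication matrices for one connectome.

    Applies density thresholding (if requested), builds the three weight and
    length variants, computes every model under every scheme and symmetrizes
    the asymmetric measures.  Purely deterministic.
    """
    sc = validate_weight_matrix(sc, name="sc")
    D = euclidean_distance_matrix(coords)
    if density is not None and density < 1:
        sc = threshold_by_density(sc, density)
    if not is_connected(sc):
        n_comp, _ = _components(sc)
        raise ValueError(f"thresholded connectome fragmented into {n_comp} components")
    W_bin, W_wei, W_dis = build_weight_variants(sc, D)
    weights = {"bin": W_bin, "wei": W_wei, "dis": W_dis}
    lengths = {s: weights_to_lengths(weights[s], s, D) for s in SCHEMES}

    bat = CommunicationBattery(sc=sc, dist=D, density=density, n_regions=sc.shape[0])
    preds = {}
    for s in SCHEMES:
        if "SPE" in models or "SI" in models:
            spe, pred = shortest_path_efficiency(lengths[s])
            preds[s] = pred
            if "SPE" in models:
                bat.matrices[("SPE", s)] = symmetrize(spe)
        if "NE" in models:
            ne, hops = navigation_efficiency(lengths[s], D)
            bat.nav_failures[s] = int(np.sum(hops < 0) - sc.shape[0])  # diag excluded
            bat.matrices[("NE", s)] = symmetrize(ne)
        if "DE" in models:
            de, _ = diffusion_efficiency(weights[s])
            bat.matrices[("DE", s)] = symmetrize(de)
        if "SI" in models:
            # random walks always use the streamline weights, whichever L
            si = search_information(W_wei, lengths[s], preds[s])
            bat.matrices[("SI", s)] = symmetrize(si)
        if "CMY" in models:
            bat.matrices[("CMY", s)] = communicability(weights[s], s)
    return bat
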