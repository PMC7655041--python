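"""Independent reference implementations used only to cross-check the
package.  Deliberately naive: exhaustive enumeration, step-by-step
simulation, truncated series — written without reference to the library's
algorithms."""

import numpy as np


def pairwise_distances_loop(xyz):
    n = len(xyz)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            D[i, j] = np.sqrt(sum((xyz[i][k] - xyz[j][k]) ** 2 for k in range(3)))
    return D


def shortest_path_enumeration(L):
    """Minimal summed length over ALL simple paths, by exhaustive DFS."""
    n = L.shape[0]
    best = np.full((n, n), np.inf)
    np.fill_diagonal(best, 0.0)
    nbrs = [np.flatnonzero(np.isfinite(L[u])) for u in range(n)]

    def dfs(src, u, total, visited):
        if total >= best[src, u]:
            pass
        best[src, u] = min(best[src, u], total)
        for v in nbrs[u]:
            if v not in visited and total + L[u, v] < best[src, v] + 1e-15:
                dfs(src, v, total + L[u, v], visited | {v})

    for s in range(n):
        dfs(s, s, 0.0, {s})
    return best


def greedy_navigation_simulator(L, D, i, j):
    """Step-by-step greedy navigation from i to j.  Returns (status,
    node_sequence, total_length); ties to the lowest region index."""
    n = L.shape[0]
    seq = [i]
    total = 0.0
    u = i
    visited = set([i])
    for _ in range(n + 1):
        nbrs = [v for v in range(n) if np.isfinite(L[u, v]) and v != u]
        if not nbrs:
            return "failed", seq, np.inf
        dists = [D[v, j] for v in nbrs]
        v = nbrs[int(np.argmin(dists))]
        total += L[u, v]
        seq.append(v)
        if v == j:
            return "reached", seq, total
        if v in visited:
            return "failed", seq, np.inf
        visited.add(v)
        u = v
    return "failed", seq, np.inf


def mc_hitting_time(W, i, j, n_walks, rng):
    """Monte-Carlo mean first passage time i -> j (vectorized walkers).
    Returns (mean, standard error)."""
    n = W.shape[0]
    P = W / W.sum(axis=1, keepdims=True)
    cum = np.cumsum(P, axis=1)
    pos = np.full(n_walks, i)
    steps = np.zeros(n_walks)
    active = np.ones(n_walks, dtype=bool)
    t = 0
    while active.any() and t < 100000:
        t += 1
        u = rng.random(active.sum())
        nxt = (cum[pos[active]] < u[:, None]).sum(axis=1)
        pos[active] = nxt
        idx = np.flatnonzero(active)
        hit = nxt == j
        steps[idx[hit]] = t
        active[idx[hit]] = False
    mean = steps.mean()
    se = steps.std(ddof=1) / np.sqrt(n_walks)
    return mean, se


def mc_path_probability(W, path, n_walkers, rng):
    """Probability a naive random walker's first len(path)-1 steps follow
    `path`, estimated by simulation.  Returns (p_hat, standard error)."""
    P = W / W.sum(axis=1, keepdims=True)
    cum = np.cumsum(P, axis=1)
    alive = np.ones(n_walkers, dtype=bool)
    for u, v in zip(path[:-1], path[1:]):
        n_alive = alive.sum()
        if n_alive == 0:
            break
        draws = (cum[u] < rng.random(n_alive)[:, None]).sum(axis=1)
        idx = np.flatnonzero(alive)
        alive[idx[draws != v]] = False
    p = alive.sum() / n_walkers
    se = np.sqrt(max(p * (1 - p), 1e-12) / n_walkers)
    return p, se


def communicability_series(A, n_terms=31):
    """Truncated walk-sum: sum_{k=0}^{n_terms-1} A^k / k!."""
    n = A.shape[0]
    out = np.eye(n)
    term = np.eye(n)
    for k in range(1, n_terms):
        term = term @ A / k
        out = out + term
    return out


def bfs_component_count(W):
    n = W.shape[0]
    seen = set()
    comps = 0
    for s in range(n):
        if s in seen:
            continue
        comps += 1
        stack = [s]
        seen.add(s)
        while stack:
            u = stack.pop()
            for v in np.flatnonzero(W[u] > 0):
                if v not in seen:
                    seen.add(v)
                    stack.append(int(v))
    return comps


def rm_anova_ss(A):
    """Textbook sums-of-squares one-way repeated-measures ANOVA."""
    n, k = A.shape
    grand = A.mean()
    ss_between_cond = sum(n * (A[:, c].mean() - grand) ** 2 for c in range(k))
    ss_between_subj = sum(k * (A[s].mean() - grand) ** 2 for s in range(n))
    ss_total = ((A - grand) ** 2).sum()
    ss_error = ss_total - ss_between_cond - ss_between_subj
    df1, df2 = k - 1, (k - 1) * (n - 1)
    F = (ss_between_cond / df1) / (ss_error / df2)
    return F, df1, df2


def random_connected_graph(n, density, rng, weighted=True):
    """Random symmetric weighted graph, guaranteed connected via a random
    spanning tree plus Bernoulli extra edges."""
    W = np.zeros((n, n))
    order = rng.permutation(n)
    for a, b in zip(order[:-1], order[1:]):
        W[a, b] = W[b, a] = rng.integers(1, 10) if weighted else 1
    for i in range(n):
        for j in range(i + 1, n):
            if W[i, j] == 0 and rng.random() < density:
                W[i, j] = W[j, i] = rng.integers(1, 10) if weighted else 1
    return W
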