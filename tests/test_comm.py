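"""Communication measures against closed forms and independent oracles."""

import numpy as np
import pytest

import connectocomm as cc
from connectocomm.comm import reconstruct_path
from oracles import (
    communicability_series,
    greedy_navigation_simulator,
    mc_hitting_time,
    mc_path_probability,
    random_connected_graph,
    shortest_path_enumeration,
)


def binary_path_graph(n=3):
    W = np.zeros((n, n))
    for i in range(n - 1):
        W[i, i + 1] = W[i + 1, i] = 1.0
    return W


def complete_binary(n):
    return np.ones((n, n)) - np.eye(n)


# ---------------------------------------------------------------------------
# shortest path efficiency

def test_spe_path_graph_and_direct_edge_bound(rng):
    L = cc.weights_to_lengths(binary_path_graph(3), "bin")
    spe, _ = cc.shortest_path_efficiency(L)
    assert spe[0, 2] == pytest.approx(0.5)
    W = random_connected_graph(7, 0.4, rng)
    L = cc.weights_to_lengths(W, "wei")
    spe, _ = cc.shortest_path_efficiency(L)
    on = np.isfinite(L)
    assert np.all(spe[on] >= 1.0 / L[on] - 1e-12)  # never worse than direct hop


def test_spe_matches_exhaustive_enumeration(rng):
    for _ in range(20):
        n = int(rng.integers(4, 9))
        W = random_connected_graph(n, 0.3, rng)
        L = cc.weights_to_lengths(W, "wei")
        spe, _ = cc.shortest_path_efficiency(L)
        lam = shortest_path_enumeration(L)
        off = ~np.eye(n, dtype=bool)
        assert np.allclose(1.0 / spe[off], lam[off], rtol=1e-9)


def test_spe_predecessors_reconstruct_optimal_paths(rng):
    W = random_connected_graph(8, 0.3, rng)
    L = cc.weights_to_lengths(W, "wei")
    spe, pred = cc.shortest_path_efficiency(L)
    for i in range(8):
        for j in range(8):
            if i == j:
                continue
            path = reconstruct_path(pred, i, j)
            total = sum(L[u, v] for u, v in zip(path[:-1], path[1:]))
            assert total == pytest.approx(1.0 / spe[i, j], rel=1e-9)


# ---------------------------------------------------------------------------
# navigation

def test_navigation_complete_graph_single_hop(coords20):
    n = 20
    D = cc.euclidean_distance_matrix(coords20)
    L = cc.weights_to_lengths(complete_binary(n), "bin")
    ne, hops = cc.navigation_efficiency(L, D)
    off = ~np.eye(n, dtype=bool)
    assert np.all(ne[off] == 1.0)
    assert np.all(hops[off] == 1)


def test_navigation_never_beats_shortest_path(template20, coords20):
    D = cc.euclidean_distance_matrix(coords20)
    for scheme in ("bin", "wei", "dis"):
        W = template20 if scheme != "bin" else (template20 > 0).astype(float)
        L = cc.weights_to_lengths(template20, scheme, D)
        spe, _ = cc.shortest_path_efficiency(L)
        ne, _ = cc.navigation_efficiency(L, D)
        assert np.all(ne <= spe + 1e-12)


def test_navigation_matches_independent_simulator(rng):
    for _ in range(50):
        n = int(rng.integers(5, 12))
        xyz = rng.normal(scale=20, size=(n, 3))
        D = cc.euclidean_distance_matrix(xyz)
        W = random_connected_graph(n, 0.25, rng)
        L = cc.weights_to_lengths(W, "wei")
        ne, hops = cc.navigation_efficiency(L, D)
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                status, seq, total = greedy_navigation_simulator(L, D, i, j)
                if status == "reached":
                    assert ne[i, j] == pytest.approx(1.0 / total, rel=1e-9)
                    assert hops[i, j] == len(seq) - 1
                else:
                    assert ne[i, j] == 0.0 and hops[i, j] == -1


# ---------------------------------------------------------------------------
# diffusion

def test_diffusion_two_node_and_complete_graph_closed_forms():
    de, ctx = cc.diffusion_efficiency(np.array([[0.0, 1], [1, 0]]))
    assert ctx["H"][0, 1] == pytest.approx(1.0, abs=1e-12)
    assert de[0, 1] == pytest.approx(1.0, abs=1e-12)
    for n in (4, 6):
        de, ctx = cc.diffusion_efficiency(complete_binary(n))
        off = ~np.eye(n, dtype=bool)
        assert np.allclose(ctx["H"][off], n - 1, atol=1e-10)
        assert np.allclose(de[off], 1.0 / (n - 1), atol=1e-12)


def test_diffusion_stationary_distribution_proportional_to_strength(rng):
    W = random_connected_graph(6, 0.5, rng)
    _, ctx = cc.diffusion_efficiency(W)
    s = W.sum(axis=1)
    assert np.allclose(ctx["pi"], s / s.sum(), atol=1e-10)
    assert np.allclose(ctx["T"].sum(axis=1), 1.0, atol=1e-12)


def test_diffusion_matches_monte_carlo_hitting_times(rng):
    for g in range(2):
        n = 5
        W = random_connected_graph(n, 0.5, rng)
        _, ctx = cc.diffusion_efficiency(W)
        for (i, j) in [(0, n - 1), (n - 1, 1)]:
            est, se = mc_hitting_time(W, i, j, 200_000, rng)
            assert abs(ctx["H"][i, j] - est) < 3 * se + 1e-9


def test_diffusion_rejects_fragmented_graph():
    W = np.zeros((4, 4))
    W[0, 1] = W[1, 0] = W[2, 3] = W[3, 2] = 1
    with pytest.raises(ValueError, match="2 components"):
        cc.diffusion_efficiency(W)


# ---------------------------------------------------------------------------
# search information

def test_search_information_path_graph_values():
    W = binary_path_graph(3)
    L = cc.weights_to_lengths(W, "bin")
    si = cc.search_information(W, L)
    # T(0,1)=1, T(1,2)=1/2 -> log2(0.5) = -1; forced first step from node 0
    assert si[0, 2] == pytest.approx(-1.0, abs=1e-12)
    assert si[0, 1] == pytest.approx(0.0, abs=1e-12)
    assert si[1, 0] == pytest.approx(-1.0, abs=1e-12)
    assert cc.symmetrize(si)[0, 1] == pytest.approx(-0.5, abs=1e-12)
    # conventional negated form
    assert cc.search_information(W, L, negate=True)[0, 2] == pytest.approx(1.0)


def test_search_information_matches_walker_simulation(rng):
    W = random_connected_graph(6, 0.4, rng)
    L = cc.weights_to_lengths(W, "wei")
    si = cc.search_information(W, L)
    _, pred = cc.shortest_path_efficiency(L)
    for (i, j) in [(0, 5), (2, 4), (5, 1)]:
        path = reconstruct_path(pred, i, j)
        p_hat, se = mc_path_probability(W, path, 1_000_000, rng)
        assert abs(2.0 ** si[i, j] - p_hat) < 3 * se + 1e-9


def test_search_information_nonpositive_and_masked(rng):
    W = random_connected_graph(8, 0.3, rng)
    L = cc.weights_to_lengths(W, "wei")
    si = cc.search_information(W, L)
    off = ~np.eye(8, dtype=bool)
    assert np.all(si[off][np.isfinite(si[off])] <= 1e-12)


# ---------------------------------------------------------------------------
# communicability

def test_communicability_two_node_closed_form():
    cmy = cc.communicability(np.array([[0.0, 1], [1, 0]]), "bin")
    assert cmy[0, 1] == pytest.approx(np.sinh(1), abs=1e-12)
    assert cmy[0, 0] == pytest.approx(np.cosh(1), abs=1e-12)


def test_communicability_matches_truncated_series(rng):
    for _ in range(10):
        n = int(rng.integers(4, 9))
        W = random_connected_graph(n, 0.4, rng)
        s = W.sum(axis=1)
        Wn = W / np.sqrt(np.outer(s, s))
        assert np.allclose(cc.communicability(W, "wei"),
                           communicability_series(Wn), atol=1e-8)
        assert np.allclose(cc.communicability(W, "bin"),
                           communicability_series((W > 0).astype(float)),
                           atol=1e-8)


def test_communicability_rejects_isolated_node():
    W = np.zeros((3, 3))
    W[0, 1] = W[1, 0] = 1.0
    with pytest.raises(ValueError, match="isolated"):
        cc.communicability(W, "wei")


# ---------------------------------------------------------------------------
# symmetrization, battery, invariances

def test_symmetrize_mean_and_idempotence():
    C = np.array([[0.0, 0.4], [0.6, 0.0]])
    S = cc.symmetrize(C)
    assert S[0, 1] == S[1, 0] == pytest.approx(0.5)
    assert np.array_equal(cc.symmetrize(S), S)


def test_battery_is_complete_symmetric_and_deterministic(battery68, template68, coords68):
    assert len(battery68.matrices) == 15
    for (model, scheme), M in battery68.matrices.items():
        finite = np.isfinite(M)
        assert np.allclose(M[finite & finite.T], M.T[finite & finite.T])
        if model in ("SPE", "NE", "DE"):
            assert np.nanmin(M) >= 0
    again = cc.communication_battery(template68, coords68, density=0.20)
    for key in battery68.matrices:
        a, b = battery68[key], again[key]
        assert np.array_equal(np.nan_to_num(a, nan=-999), np.nan_to_num(b, nan=-999))


def test_battery_spe_dominates_ne_same_scheme(battery68):
    for scheme in cc.SCHEMES:
        assert np.all(battery68[("NE", scheme)] <= battery68[("SPE", scheme)] + 1e-12)


def test_scale_invariance_of_transition_but_not_lengths(rng):
    W = random_connected_graph(7, 0.4, rng)
    de1, _ = cc.diffusion_efficiency(W)
    de2, _ = cc.diffusion_efficiency(3.7 * W)
    assert np.allclose(de1, de2, atol=1e-10)
    L1 = cc.weights_to_lengths(W, "wei")
    L2 = cc.weights_to_lengths(3.7 * W, "wei")
    assert not np.allclose(L1[np.isfinite(L1)], L2[np.isfinite(L2)])


def test_permutation_equivariance(rng):
    n = 8
    W = random_connected_graph(n, 0.4, rng)
    xyz = rng.normal(scale=20, size=(n, 3))
    perm = rng.permutation(n)
    P = np.eye(n)[perm]
    Wp = P @ W @ P.T
    for compute in (
        lambda w, c: cc.communicability(w, "wei"),
        lambda w, c: cc.symmetrize(cc.diffusion_efficiency(w)[0]),
        lambda w, c: cc.symmetrize(cc.shortest_path_efficiency(
            cc.weights_to_lengths(w, "wei"))[0]),
        lambda w, c: cc.symmetrize(cc.navigation_efficiency(
            cc.weights_to_lengths(w, "wei"), cc.euclidean_distance_matrix(c))[0]),
    ):
        C = compute(W, xyz)
        Cp = compute(Wp, xyz[perm])
        assert np.allclose(P @ C @ P.T, Cp, atol=1e-9)
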