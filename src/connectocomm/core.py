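"""Structural-connectome construction: weight/length variants, thresholding,
group averaging and geometric auxiliaries.

A connectome is held as a dense symmetric nonnegative ``numpy`` array with
zero diagonal.  Three weight conventions are supported:

* ``wei`` — streamline counts (the raw tractography weights),
* ``bin`` — the 0/1 indicator of the weighted support,
* ``dis`` — 1/EuclideanDistance on exactly the weighted support.

Connection *lengths* (travel costs for path-based measures) place ``inf`` on
absent connections so that communication is restricted to the connectome.
"""

from __future__ import annotations

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import squareform, pdist

SCHEMES = ("bin", "wei", "dis")

_SYM_RTOL = 1e-10


def validate_weight_matrix(W: np.ndarray, *, name: str = "W") -> np.ndarray:
    """Validate a connectivity matrix: square, finite, nonnegative, symmetric
    (within 1e-10 relative tolerance) with zero diagonal.

    Returns the matrix as a float array.  Asymmetric input is rejected, not
    silently symmetrized.
    """
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError(f"{name} must be a square matrix, got shape {W.shape}")
    if not np.all(np.isfinite(W)):
        raise ValueError(f"{name} contains non-finite entries (NaN/inf forbidden)")
    if np.any(W < 0):
        raise ValueError(f"{name} contains negative entries")
    scale = max(np.abs(W).max(), 1.0)
    if np.abs(W - W.T).max() > _SYM_RTOL * scale:
        raise ValueError(f"{name} is not symmetric within tolerance")
    if np.any(np.diag(W) != 0):
        raise ValueError(f"{name} has nonzero diagonal entries")
    return W


def euclidean_distance_matrix(coords) -> np.ndarray:
    """Pairwise Euclidean distances (mm) between region centroids.

    Parameters
    ----------
    coords : pandas.DataFrame or (N, 3) array
        If a DataFrame, must have columns ``x, y, z`` and unique
        ``region_id`` values (index or column).
    """
    xyz, _ = _coords_to_array(coords)
    if xyz.shape[0] < 2:
        raise ValueError("need at least 2 regions")
    if not np.all(np.isfinite(xyz)):
        raise ValueError("centroids must be finite")
    return squareform(pdist(xyz))


def _coords_to_array(coords):
    """Extract (N,3) centroid array and hemisphere labels (or None)."""
    import pandas as pd

    if isinstance(coords, pd.DataFrame):
        if "region_id" in coords.columns:
            ids = coords["region_id"].to_numpy()
        else:
            ids = coords.index.to_numpy()
        if len(np.unique(ids)) != len(ids):
            raise ValueError("duplicate region_ids")
        order = np.argsort(ids)
        if not np.array_equal(np.sort(ids), np.arange(len(ids))):
            raise ValueError("region_ids must be contiguous 0..N-1")
        xyz = coords[["x", "y", "z"]].to_numpy(dtype=float)[order]
        hemi = (
            coords["hemisphere"].to_numpy()[order]
            if "hemisphere" in coords.columns
            else None
        )
        return xyz, hemi
    xyz = np.asarray(coords, dtype=float)
    if xyz.ndim != 2 or xyz.shape[1] != 3:
        raise ValueError("coords must be (N, 3)")
    return xyz, None


def build_weight_variants(streamlines: np.ndarray, D: np.ndarray):
    """Derive the binary and distance connectomes from a streamline-count one.

    ``W_bin(i,j) = 1`` where ``W_wei(i,j) > 0``; ``W_dis(i,j) = 1/D(i,j)`` on
    the same support.  All three outputs share an identical sparsity pattern.

    Returns ``(W_bin, W_wei, W_dis)``.
    """
    W = validate_weight_matrix(streamlines, name="W_wei")
    D = np.asarray(D, dtype=float)
    if D.shape != W.shape:
        raise ValueError("D must match W's shape")
    support = W > 0
    off = ~np.eye(W.shape[0], dtype=bool)
    if np.any((D == 0) & support & off):
        raise ValueError("zero distance between connected distinct regions")
    W_bin = support.astype(float)
    W_dis = np.zeros_like(W)
    W_dis[support] = 1.0 / D[support]
    return W_bin, W.copy(), W_dis


def weights_to_lengths(W: np.ndarray, scheme: str, D: np.ndarray | None = None) -> np.ndarray:
    """Map connection weights to connection lengths (travel costs).

    * ``bin``: length 1 on every existing connection.
    * ``dis``: length equals Euclidean distance on the support (requires D).
    * ``wei``: monotone log remap ``L = -log10(W / (max(W) + 1))``; the unity
      added to the denominator keeps the maximum weight from mapping to zero
      length, so all finite lengths are strictly positive.

    Absent connections (and the diagonal) get ``inf``: communication cannot
    leave the connectome.
    """
    W = validate_weight_matrix(W)
    support = W > 0
    if not support.any():
        raise ValueError("connectome has no edges")
    L = np.full(W.shape, np.inf)
    if scheme == "bin":
        L[support] = 1.0
    elif scheme == "dis":
        if D is None:
            raise ValueError("scheme 'dis' requires the distance matrix D")
        L[support] = np.asarray(D, dtype=float)[support]
    elif scheme == "wei":
        L[support] = -np.log10(W[support] / (W.max() + 1.0))
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    np.fill_diagonal(L, np.inf)
    if np.any(L[support & ~np.eye(len(W), dtype=bool)] <= 0):
        raise ValueError("derived lengths must be strictly positive")
    return L


def threshold_by_density(W: np.ndarray, density: float) -> np.ndarray:
    """Keep only the ``k = round(density * N(N-1)/2)`` strongest undirected
    connections (by streamline count); zero out the rest.

    Ties at the cutoff weight are broken deterministically in lexicographic
    (i, j) order.  Rounding is round-half-up.
    """
    W = validate_weight_matrix(W)
    if not 0 < density <= 1:
        raise ValueError("density must be in (0, 1]")
    n = W.shape[0]
    n_possible = n * (n - 1) // 2
    k = int(np.floor(density * n_possible + 0.5))
    if k == 0:
        raise ValueError("requested density retains zero edges")
    iu, ju = np.triu_indices(n, 1)
    w = W[iu, ju]
    # sort by weight desc, then (i, j) asc; lexsort's last key is primary
    order = np.lexsort((ju, iu, -w))
    keep = order[:k]
    keep = keep[w[keep] > 0]  # never "retain" absent edges
    out = np.zeros_like(W)
    out[iu[keep], ju[keep]] = w[keep]
    return out + out.T


def group_average(matrices) -> np.ndarray:
    """Entrywise arithmetic mean of per-subject connectivity matrices."""
    mats = list(matrices)
    if not mats:
        raise ValueError("empty subject list")
    shapes = {m.shape for m in mats}
    if len(shapes) != 1:
        raise ValueError("all matrices must share the same shape")
    return np.mean(np.stack([np.asarray(m, dtype=float) for m in mats]), axis=0)


def is_connected(W: np.ndarray) -> bool:
    """True iff the graph on W's support forms a single connected component."""
    n_comp, _ = _components(W)
    return n_comp == 1


def _components(W: np.ndarray):
    A = csr_matrix((np.asarray(W) > 0).astype(np.int8))
    return connected_components(A, directed=False)
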