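"""Correspondence between discriminatory and predictive edge signatures.

Three levels of comparison:

* single edges — intersection of two binary masks, tested against a
  degree-preserving rewiring null (double edge swap on the mask viewed as a
  simple undirected graph, so each node keeps its number of selected edges);
* network cells — percentage of selected edges per within/between-network
  cell, adjusted for the number of possible edges in the cell, and the
  correlation of two such matrices across cells;
* topography — per-node degree of selected edges, compared by Spearman
  correlation with a spherical spin permutation null that preserves the
  spatial autocorrelation of the maps.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .connectome import Parcellation, edge_node_pairs
from .fingerprint import EdgeMask, permutation_p

__all__ = [
    "OverlapResult",
    "NetworkMatrix",
    "SpinTestResult",
    "predictive_mask",
    "rewire_preserving_degree",
    "edge_overlap_test",
    "network_cell_proportions",
    "network_matrix_correlation",
    "node_degree",
    "spin_test",
]


@dataclass
class OverlapResult:
    observed: int
    null_mean: float
    null_sd: float
    p_value: float
    n_perm: int
    null_samples: np.ndarray = field(repr=False, default=None)


@dataclass
class NetworkMatrix:
    """Per-cell selected-edge percentages over network pairs.

    ``selected`` and ``total`` are symmetric K×K integer counts;
    ``cells[a, b] = 100 * selected / total`` with NaN where a cell has no
    possible edges (singleton-network diagonal).
    """

    labels: list[str]
    selected: np.ndarray
    total: np.ndarray

    @property
    def cells(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.total > 0, 100.0 * self.selected / self.total, np.nan)


@dataclass
class SpinTestResult:
    rho: float
    p_value: float
    n_perm: int
    null_rhos: np.ndarray = field(repr=False, default=None)


def _n_nodes_from_edges(E: int) -> int:
    n = int(round((1 + math.isqrt(1 + 8 * E)) / 2))
    if n * (n - 1) // 2 != E:
        raise ValueError(f"edge-vector length {E} is not N(N-1)/2 for integer N")
    return n


def _edge_index_of_pair(i: np.ndarray, j: np.ndarray, n: int) -> np.ndarray:
    """Row-major upper-triangle edge index of node pairs i < j."""
    return i * n - i * (i + 1) // 2 + (j - i - 1)


def predictive_mask(selection_frequency: np.ndarray, min_frac: float = 0.8) -> EdgeMask:
    """Edges selected in at least ``min_frac`` of the CV folds (inclusive)."""
    f = np.asarray(selection_frequency, dtype=float)
    if np.any((f < 0) | (f > 1)):
        raise ValueError("selection frequencies must lie in [0, 1]")
    return EdgeMask(bits=f >= min_frac, provenance=f"fold-frequency>={min_frac}")


def rewire_preserving_degree(
    mask: EdgeMask | np.ndarray,
    n_swap_factor: int = 10,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> EdgeMask:
    """Degree-preserving randomisation of a binary edge mask.

    The mask is viewed as a simple undirected graph on the parcellation's
    nodes and randomised by double edge swaps: ``n_swap_factor * |mask|``
    swap attempts, each replacing edges (a,b),(c,d) with (a,d),(c,b) when
    that creates no self-loop or duplicate edge.  The degree sequence is
    exactly preserved.
    """
    bits = mask.bits if isinstance(mask, EdgeMask) else np.asarray(mask, dtype=bool)
    E = bits.size
    n = _n_nodes_from_edges(E)
    m = int(bits.sum())
    if m < 2:
        warnings.warn("mask has fewer than 2 edges; returned unchanged", UserWarning)
        return EdgeMask(bits=bits.copy(), provenance="rewired (unchanged, <2 edges)")
    if rng is None:
        rng = np.random.default_rng(seed)
    ii, jj = edge_node_pairs(n)
    sel = np.flatnonzero(bits)
    edges = [(int(ii[k]), int(jj[k])) for k in sel]
    edge_set = set(edges)
    attempts = n_swap_factor * m
    pick = rng.integers(0, m, size=(attempts, 2))
    flip = rng.integers(0, 2, size=attempts)
    for t in range(attempts):
        e1, e2 = pick[t]
        if e1 == e2:
            continue
        a, b = edges[e1]
        c, d = edges[e2]
        if flip[t]:
            c, d = d, c
        # propose (a, d) and (c, b)
        if a == d or c == b:
            continue
        new1 = (a, d) if a < d else (d, a)
        new2 = (c, b) if c < b else (b, c)
        if new1 in edge_set or new2 in edge_set or new1 == new2:
            continue
        edge_set.discard((a, b))
        edge_set.discard((c, d) if c < d else (d, c))
        edge_set.add(new1)
        edge_set.add(new2)
        edges[e1] = new1
        edges[e2] = new2
    out = np.zeros(E, dtype=bool)
    if edge_set:
        pi = np.array([e[0] for e in edge_set])
        pj = np.array([e[1] for e in edge_set])
        out[_edge_index_of_pair(pi, pj, n)] = True
    return EdgeMask(bits=out, provenance="degree-preserving rewiring")


def edge_overlap_test(
    maskA: EdgeMask | np.ndarray,
    maskB: EdgeMask | np.ndarray,
    n_perm: int = 1000,
    seed: int | None = None,
    n_swap_factor: int = 10,
) -> OverlapResult:
    """Permutation test of the single-edge overlap between two masks.

    ``observed = |A ∩ B|``; the null rewires ``maskB`` (degree-preserving)
    ``n_perm`` times and intersects with the fixed ``maskA``;
    ``p = (#{null >= observed} + 1) / (n_perm + 1)``.
    """
    bitsA = maskA.bits if isinstance(maskA, EdgeMask) else np.asarray(maskA, dtype=bool)
    bitsB = maskB.bits if isinstance(maskB, EdgeMask) else np.asarray(maskB, dtype=bool)
    if bitsA.shape != bitsB.shape:
        raise ValueError("masks must share the edge indexing")
    observed = int(np.sum(bitsA & bitsB))
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # tiny masks rewire to themselves
        for b in range(n_perm):
            rw = rewire_preserving_degree(bitsB, n_swap_factor=n_swap_factor, rng=rng)
            null[b] = np.sum(bitsA & rw.bits)
    return OverlapResult(
        observed=observed,
        null_mean=float(null.mean()),
        null_sd=float(null.std(ddof=1)) if n_perm > 1 else 0.0,
        p_value=permutation_p(null, observed, mode="add_one"),
        n_perm=n_perm,
        null_samples=null,
    )


def network_cell_proportions(
    mask: EdgeMask | np.ndarray, parcellation: Parcellation
) -> NetworkMatrix:
    """Percentage of selected edges per network cell, adjusted for cell size.

    ``cells[a, b]`` is 100 times the number of selected edges with endpoints
    in networks {a, b} divided by the number of possible such edges.
    """
    bits = mask.bits if isinstance(mask, EdgeMask) else np.asarray(mask, dtype=bool)
    labels = parcellation.network_names
    K = len(labels)
    index = {lab: k for k, lab in enumerate(labels)}
    na, nb = parcellation.edge_networks()
    ka = np.array([index[str(x)] for x in na])
    kb = np.array([index[str(x)] for x in nb])
    lo, hi = np.minimum(ka, kb), np.maximum(ka, kb)
    total = np.zeros((K, K), dtype=int)
    selected = np.zeros((K, K), dtype=int)
    np.add.at(total, (lo, hi), 1)
    np.add.at(selected, (lo[bits], hi[bits]), 1)
    total = total + np.triu(total, 1).T
    selected = selected + np.triu(selected, 1).T
    return NetworkMatrix(labels=labels, selected=selected, total=total)


def network_matrix_correlation(
    matA: NetworkMatrix, matB: NetworkMatrix
) -> tuple[float, float, int]:
    """Pearson correlation of two network matrices across their defined cells.

    Cells are the K(K+1)/2 unique within/between pairs; cells undefined in
    either matrix are excluded pairwise.  Returns (r, two-sided p, df) with
    ``df = n_cells - 2``.
    """
    if matA.labels != matB.labels:
        raise ValueError("network matrices must share labels")
    K = len(matA.labels)
    iu = np.triu_indices(K)
    a = matA.cells[iu]
    b = matB.cells[iu]
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 3:
        raise ValueError("need at least 3 defined cells")
    if np.ptp(a[ok]) == 0 or np.ptp(b[ok]) == 0:
        raise ValueError("constant network matrix: correlation undefined")
    res = stats.pearsonr(a[ok], b[ok])
    return float(res.statistic), float(res.pvalue), int(ok.sum() - 2)


def node_degree(mask: EdgeMask | np.ndarray, parcellation: Parcellation) -> np.ndarray:
    """Per-node count of incident selected edges (handshake: sums to 2|mask|)."""
    bits = mask.bits if isinstance(mask, EdgeMask) else np.asarray(mask, dtype=bool)
    n = parcellation.n_nodes
    ii, jj = edge_node_pairs(n)
    deg = np.bincount(ii[bits], minlength=n) + np.bincount(jj[bits], minlength=n)
    return deg


def _uniform_rotation(rng: np.random.Generator) -> np.ndarray:
    a = rng.standard_normal((3, 3))
    q, r = np.linalg.qr(a)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def spin_test(
    mapA: np.ndarray,
    mapB: np.ndarray,
    parcellation: Parcellation,
    n_perm: int = 5000,
    seed: int | None = None,
) -> SpinTestResult:
    """Spin permutation test for the Spearman correlation of two node maps.

    Each permutation applies a uniform random 3D rotation to the (unit-
    sphere-projected) centroids and reassigns ``mapB``: every node takes the
    value of the node whose original centroid is nearest to its rotated
    position (duplicates permitted — the standard parcel-level variant).
    Two-sided: ``p = (#{|null rho| >= |observed rho|} + 1) / (n_perm + 1)``.
    """
    a = np.asarray(mapA, dtype=float)
    b = np.asarray(mapB, dtype=float)
    cent = np.asarray(parcellation.centroids, dtype=float)
    norms = np.linalg.norm(cent, axis=1)
    missing = np.flatnonzero(~np.isfinite(norms) | (norms == 0))
    if missing.size:
        raise ValueError(f"missing/degenerate centroids for nodes {missing.tolist()}")
    cent = cent / norms[:, None]
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        warnings.warn(
            "constant node map: spin-test correlation undefined", UserWarning
        )
        return SpinTestResult(
            rho=np.nan, p_value=np.nan, n_perm=n_perm, null_rhos=np.empty(0)
        )
    ra = stats.rankdata(a)
    observed = float(stats.spearmanr(a, b).statistic)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    ra_c = ra - ra.mean()
    for t in range(n_perm):
        rot = _uniform_rotation(rng)
        assignment = np.argmax((cent @ rot.T) @ cent.T, axis=1)
        rb = stats.rankdata(b[assignment])
        rb_c = rb - rb.mean()
        denom = np.sqrt(np.sum(ra_c**2) * np.sum(rb_c**2))
        null[t] = np.sum(ra_c * rb_c) / denom if denom > 0 else 0.0
    p = float((np.sum(np.abs(null) >= abs(observed)) + 1) / (n_perm + 1))
    return SpinTestResult(rho=observed, p_value=p, n_perm=n_perm, null_rhos=null)
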