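"""Functional-connectome containers and edge-vector construction.

A functional connectome is the symmetric matrix of Pearson correlations
between the nodal time courses of a brain parcellation.  Throughout the
package a connectome is analysed as the vectorized upper triangle of that
matrix, using a single fixed edge indexing: 0-based, row-major over pairs
(i, j) with i < j, i.e. the order produced by ``numpy.triu_indices(n, 1)``.
Edge ``k`` of every vector in a cohort therefore refers to the same node
pair for every subject and session.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Parcellation",
    "ConnectomeSet",
    "build_fc",
    "average_runs",
    "z_transform",
    "standardize_vectors",
    "vectorize_upper",
    "devectorize",
    "edge_node_pairs",
    "n_edges",
    "read_matrix",
    "read_timeseries",
]

#: clip bound applied to r before arctanh so that z stays finite
R_CLIP = 1.0 - 1e-7


def n_edges(n_nodes: int) -> int:
    """Number of upper-triangle edges of an ``n_nodes`` parcellation."""
    return n_nodes * (n_nodes - 1) // 2


def edge_node_pairs(n_nodes: int) -> tuple[np.ndarray, np.ndarray]:
    """Arrays (i, j) with i < j giving the node pair of each edge index."""
    return np.triu_indices(n_nodes, 1)


@dataclass
class Parcellation:
    """Node labels, resting-state-network assignment and centroids.

    Parameters
    ----------
    node_ids
        Ordered node labels; the node order is shared by every matrix and
        edge vector in the analysis.
    networks
        Per-node resting-state-network label (one label per node).
    centroids
        ``(n_nodes, 3)`` array of centroid coordinates.  Synthetic
        parcellations place these on the unit sphere; real atlas centroids
        are projected onto it before a spin test.
    """

    node_ids: list[str]
    networks: np.ndarray
    centroids: np.ndarray

    def __post_init__(self) -> None:
        self.networks = np.asarray(self.networks)
        self.centroids = np.asarray(self.centroids, dtype=float)
        if len(self.node_ids) != len(self.networks):
            raise ValueError("one network label per node required")
        if self.centroids.shape != (len(self.node_ids), 3):
            raise ValueError("centroids must be (n_nodes, 3)")

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def network_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for lab in self.networks:
            seen.setdefault(str(lab), None)
        return list(seen)

    def edge_networks(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-edge network labels of the two endpoints (edge-index order)."""
        ii, jj = edge_node_pairs(self.n_nodes)
        return self.networks[ii], self.networks[jj]

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(
            {
                "node_id": self.node_ids,
                "network": self.networks,
                "x": self.centroids[:, 0],
                "y": self.centroids[:, 1],
                "z": self.centroids[:, 2],
            }
        )
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "Parcellation":
        df = pd.read_csv(path, sep="\t", dtype={"node_id": str, "network": str})
        return cls(
            node_ids=list(df["node_id"]),
            networks=df["network"].to_numpy(),
            centroids=df[["x", "y", "z"]].to_numpy(float),
        )


@dataclass
class ConnectomeSet:
    """Per-subject, per-session edge vectors over a fixed edge indexing.

    ``data`` has shape ``(n_subjects, n_sessions, E)`` with
    ``E = n_nodes (n_nodes - 1) / 2``.  Both identification and prediction
    consume this object.
    """

    subjects: list[str]
    sessions: list[str]
    n_nodes: int
    data: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        expected = (len(self.subjects), len(self.sessions), n_edges(self.n_nodes))
        if self.data.shape != expected:
            raise ValueError(
                f"data shape {self.data.shape} != (subjects, sessions, E) {expected}"
            )

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_edges(self) -> int:
        return self.data.shape[2]

    def session(self, session) -> np.ndarray:
        """(n_subjects, E) matrix for one session (by id or position)."""
        idx = session if isinstance(session, int) else self.sessions.index(session)
        return self.data[:, idx, :]

    def session_mean(self) -> np.ndarray:
        """(n_subjects, E) mean over sessions — the standard prediction input."""
        return self.data.mean(axis=1)

    def to_tsv(self, path) -> None:
        """One row per subject-session: subject, session, e0 … e{E-1}."""
        rows = []
        for si, sub in enumerate(self.subjects):
            for ti, ses in enumerate(self.sessions):
                rows.append((sub, ses, *self.data[si, ti]))
        cols = ["subject", "session"] + [f"e{k}" for k in range(self.n_edges)]
        pd.DataFrame(rows, columns=cols).to_csv(
            path, sep="\t", index=False, float_format="%.17g"
        )

    @classmethod
    def from_tsv(cls, path, n_nodes: int) -> "ConnectomeSet":
        df = pd.read_csv(
            path, sep="\t", dtype={"subject": str, "session": str},
            float_precision="round_trip",
        )
        subjects = list(dict.fromkeys(df["subject"]))
        sessions = list(dict.fromkeys(df["session"]))
        E = n_edges(n_nodes)
        data = np.empty((len(subjects), len(sessions), E))
        vals = df[[f"e{k}" for k in range(E)]].to_numpy(float)
        for r, (sub, ses) in enumerate(zip(df["subject"], df["session"])):
            data[subjects.index(sub), sessions.index(ses)] = vals[r]
        return cls(subjects=subjects, sessions=sessions, n_nodes=n_nodes, data=data)


def build_fc(timeseries: np.ndarray) -> np.ndarray:
    """Pearson correlation matrix of a ``(T, N)`` nodal time-series array.

    Raises
    ------
    ValueError
        If fewer than 3 time points are given, or any node's time course is
        constant (its correlation is undefined); the error names the node.
    """
    ts = np.asarray(timeseries, dtype=float)
    if ts.ndim != 2 or ts.shape[0] < 3:
        raise ValueError("timeseries must be (T, N) with T >= 3")
    sd = ts.std(axis=0)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(f"constant time course for node(s) {bad.tolist()}")
    r = np.corrcoef(ts, rowvar=False)
    np.fill_diagonal(r, 1.0)
    return np.clip(r, -1.0, 1.0)


def average_runs(matrices: list[np.ndarray]) -> np.ndarray:
    """Element-wise mean of the per-run connectivity matrices of one session."""
    if not matrices:
        raise ValueError("need at least one matrix")
    mats = [np.asarray(m, dtype=float) for m in matrices]
    shape = mats[0].shape
    for m in mats[1:]:
        if m.shape != shape:
            raise ValueError(f"shape mismatch: {m.shape} vs {shape}")
    return np.mean(mats, axis=0)


def z_transform(matrix: np.ndarray) -> np.ndarray:
    """Fisher r-to-z (arctanh) of the off-diagonal entries.

    r is clipped to ±(1 − 1e−7) first so that perfectly correlated pairs map
    to a large finite z rather than infinity.  The diagonal is passed through
    as 0 (it is ignored downstream).
    """
    m = np.asarray(matrix, dtype=float)
    z = np.arctanh(np.clip(m, -R_CLIP, R_CLIP))
    if m.ndim == 2 and m.shape[0] == m.shape[1]:
        np.fill_diagonal(z, 0.0)
    return z


def vectorize_upper(matrix: np.ndarray) -> np.ndarray:
    """Row-major upper triangle (i < j) of a square symmetric matrix."""
    m = np.asarray(matrix)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("matrix must be square")
    ii, jj = np.triu_indices(m.shape[0], 1)
    return m[ii, jj].copy()


def devectorize(vector: np.ndarray, n_nodes: int) -> np.ndarray:
    """Inverse of :func:`vectorize_upper`; zero diagonal, symmetric output."""
    v = np.asarray(vector, dtype=float)
    E = n_edges(n_nodes)
    if v.shape != (E,):
        raise ValueError(f"vector length {v.shape} != N(N-1)/2 = {E}")
    m = np.zeros((n_nodes, n_nodes))
    ii, jj = np.triu_indices(n_nodes, 1)
    m[ii, jj] = v
    m[jj, ii] = v
    return m


def standardize_vectors(edge_vectors: np.ndarray) -> np.ndarray:
    """Per-vector standardization (subtract mean, divide SD across edges).

    The alternative reading of "z-scoring" a connectome.  Identification by
    Pearson correlation is invariant to this map, so the choice between it
    and the Fisher transform only matters for variability analyses.
    """
    x = np.asarray(edge_vectors, dtype=float)
    mu = x.mean(axis=-1, keepdims=True)
    sd = x.std(axis=-1, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("cannot standardize a constant edge vector")
    return (x - mu) / sd


def read_matrix(path, delimiter: str | None = None) -> np.ndarray:
    """Read a dense square connectivity matrix from a delimited text file.

    Whitespace/TSV by default; pass ``delimiter=','`` for CSV.
    """
    m = np.loadtxt(path, delimiter=delimiter)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"{path}: expected a square matrix, got {m.shape}")
    return m


def read_timeseries(path, delimiter: str = "\t") -> tuple[list[str], np.ndarray]:
    """Read a T x N nodal time-series file with a header row of node ids.

    Returns ``(node_ids, data)`` with ``data`` of shape (T, N), ready for
    :func:`build_fc`.
    """
    df = pd.read_csv(path, sep=delimiter)
    return [str(c) for c in df.columns], df.to_numpy(float)
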