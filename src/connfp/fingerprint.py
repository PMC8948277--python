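"""Connectome fingerprinting: identification, its permutation null, and
per-edge differential power.

Identification correlates each subject's edge vector from one session
(the "source") against every subject's vector from the other session (the
"database") and picks the argmax; a hit is scored when the picked database
subject is the source subject.  Differential power decomposes the same
Pearson statistic edge by edge: with per-vector centered, unit-norm vectors
x̃ (session 1) and ỹ (session 2), the edgewise product
``phi_i(j, k) = x̃[j, i] · ỹ[k, i]`` sums over edges to the correlation used
in identification, and an edge is discriminatory when its within-subject
product ``phi_i(j, j)`` exceeds the cross-subject products involving j.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "IdentificationResult",
    "DPVector",
    "EdgeMask",
    "identify",
    "identification_permutation_test",
    "differential_power",
    "threshold_percentile",
    "permutation_p",
    "format_p",
]


@dataclass
class IdentificationResult:
    hits_1to2: int
    hits_2to1: int
    n_subjects: int
    assignment_1to2: np.ndarray
    assignment_2to1: np.ndarray
    perm_accuracies: np.ndarray | None = None
    p_value: float | None = None

    @property
    def accuracy_1to2(self) -> float:
        return self.hits_1to2 / self.n_subjects

    @property
    def accuracy_2to1(self) -> float:
        return self.hits_2to1 / self.n_subjects

    @property
    def accuracy(self) -> float:
        """Mean accuracy over both identification directions."""
        return 0.5 * (self.accuracy_1to2 + self.accuracy_2to1)


@dataclass
class DPVector:
    """Per-edge differential power (nonnegative; high = discriminatory)."""

    values: np.ndarray
    n_subjects: int


@dataclass
class EdgeMask:
    """Sparse binary edge set with a provenance note (thresholding rule)."""

    bits: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=bool)

    @property
    def n_selected(self) -> int:
        return int(self.bits.sum())

    @property
    def indices(self) -> np.ndarray:
        return np.flatnonzero(self.bits)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# edge mask: {self.provenance}\n")
            for k in self.indices:
                fh.write(f"{k}\n")

    @classmethod
    def from_tsv(cls, path, n_edges: int) -> "EdgeMask":
        provenance = ""
        idx = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line.startswith("#"):
                    provenance = line.lstrip("# ").removeprefix("edge mask: ")
                elif line:
                    idx.append(int(line))
        bits = np.zeros(n_edges, dtype=bool)
        bits[idx] = True
        return cls(bits=bits, provenance=provenance)


def permutation_p(null: np.ndarray, observed: float, mode: str = "proportion") -> float:
    """Right-tailed permutation p under the two conventions used here.

    ``proportion`` (identification): strict exceedances over ``n_perm``.
    ``add_one`` (prediction / overlap): exceedances (ties included) over
    ``n_perm + 1``, which never returns exactly 0.
    """
    null = np.asarray(null, dtype=float)
    if mode == "proportion":
        return float(np.sum(null > observed) / null.size)
    if mode == "add_one":
        return float((np.sum(null >= observed) + 1) / (null.size + 1))
    raise ValueError(f"unknown p-value mode {mode!r}")


def format_p(p: float, n_perm: int) -> str:
    """Human-readable p; an empirical zero prints as '< 1/n_perm'."""
    if p == 0.0:
        return f"< {1 / n_perm:g}"
    return f"{p:g}"


def _check_vectors(x: np.ndarray, label: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = x.std(axis=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(f"constant edge vector for subject index {bad.tolist()} in {label}")
    return x


def _center_normalize(x: np.ndarray) -> np.ndarray:
    c = x - x.mean(axis=1, keepdims=True)
    return c / np.linalg.norm(c, axis=1, keepdims=True)


def _corr_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """rows of a vs rows of b; entry (j, k) = Pearson r(a_j, b_k)."""
    return _center_normalize(a) @ _center_normalize(b).T


def identify(db_source: np.ndarray, db_target: np.ndarray) -> IdentificationResult:
    """Cross-session identification in both directions.

    Parameters are (n_subjects, E) edge-vector matrices for the two sessions
    with identical subject ordering.  Ties in the argmax are broken toward
    the lowest subject index, with a warning.
    """
    x = _check_vectors(db_source, "session 1")
    y = _check_vectors(db_target, "session 2")
    if x.shape != y.shape:
        raise ValueError("sessions must contain the same subjects and edges")
    c = _corr_matrix(x, y)
    a12 = np.argmax(c, axis=1)  # session-1 source against session-2 database
    a21 = np.argmax(c.T, axis=1)
    for direction, (mat, am) in {"1->2": (c, a12), "2->1": (c.T, a21)}.items():
        n_tied = int(np.sum(np.sum(mat == mat.max(axis=1, keepdims=True), axis=1) > 1))
        if n_tied:
            warnings.warn(
                f"{n_tied} tied argmax correlation(s) in direction {direction}; "
                "lowest subject index picked",
                UserWarning,
                stacklevel=2,
            )
    n = x.shape[0]
    return IdentificationResult(
        hits_1to2=int(np.sum(a12 == np.arange(n))),
        hits_2to1=int(np.sum(a21 == np.arange(n))),
        n_subjects=n,
        assignment_1to2=a12,
        assignment_2to1=a21,
    )


def identification_permutation_test(
    db_source: np.ndarray,
    db_target: np.ndarray,
    n_perm: int = 1000,
    seed: int | None = None,
) -> IdentificationResult:
    """Permutation test of identification accuracy against chance.

    Each permutation randomises the identity labels of the database vectors
    and recomputes accuracy over both directions; p is the proportion of
    permutations whose accuracy strictly exceeds the observed accuracy.
    Under the null the expected accuracy is 1/n_subjects.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    res = identify(db_source, db_target)
    rng = np.random.default_rng(seed)
    n = res.n_subjects
    idx = np.arange(n)
    accs = np.empty(n_perm)
    for b in range(n_perm):
        lab12 = rng.permutation(n)
        lab21 = rng.permutation(n)
        hits = np.sum(lab12[res.assignment_1to2] == idx) + np.sum(
            lab21[res.assignment_2to1] == idx
        )
        accs[b] = hits / (2 * n)
    res.perm_accuracies = accs
    res.p_value = permutation_p(accs, res.accuracy, mode="proportion")
    return res


def differential_power(
    db_s1: np.ndarray, db_s2: np.ndarray, center: bool = True
) -> DPVector:
    """Differential power of every edge from the two-session cohort.

    For edge i and subject j, the empirical probability that a cross-subject
    edgewise product beats the within-subject one is

        P_i(j) = [#{k != j: phi_i(j,k) > phi_i(j,j)}
                  + #{k != j: phi_i(k,j) > phi_i(j,j)}] / (2 (S - 1)),

    clamped below at 1/(2(S-1)) so the log stays finite, and
    ``DP_i = sum_j -ln P_i(j)``.  Comparisons are strict: ties do not count
    as exceedance (an edge identical across everyone therefore clamps to the
    maximal DP — inspect masks for such degenerate edges).

    ``center=False`` skips the per-vector centering before unit-norm scaling
    (a sensitivity switch; with centering the edgewise products sum exactly
    to the identification correlation).
    """
    x = _check_vectors(db_s1, "session 1")
    y = _check_vectors(db_s2, "session 2")
    if center:
        x, y = _center_normalize(x), _center_normalize(y)
    else:
        x = x / np.linalg.norm(x, axis=1, keepdims=True)
        y = y / np.linalg.norm(y, axis=1, keepdims=True)
    if x.shape != y.shape:
        raise ValueError("sessions must contain the same subjects and edges")
    S, E = x.shape
    if S < 2:
        raise ValueError("differential power needs at least 2 subjects")
    within = x * y  # phi_i(j, j)
    counts = np.zeros((S, E))
    for j in range(S):
        phi_jk = x[j] * y  # (S, E): phi_i(j, k) over k
        phi_kj = x * y[j]  # (S, E): phi_i(k, j) over k
        exceed = (phi_jk > within[j]).astype(np.int64) + (phi_kj > within[j])
        exceed[j] = 0
        counts[j] = exceed.sum(axis=0)
    p = counts / (2 * (S - 1))
    p = np.maximum(p, 1.0 / (2 * (S - 1)))
    return DPVector(values=-np.log(p).sum(axis=0), n_subjects=S)


def threshold_percentile(values: np.ndarray, pct: float = 99) -> EdgeMask:
    """Binary mask of the edges at or above the ``pct``-th percentile.

    The mask keeps the top ``ceil((100 - pct)/100 * E)`` values (e.g. 358 of
    35,778 edges at the 99th percentile); with ties at the cutoff the mask
    may be slightly larger, since selection is by value.
    """
    v = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("values must be finite")
    if not 0.0 < pct < 100.0:
        raise ValueError("pct must be in (0, 100)")
    if np.all(v == v.flat[0]):
        raise ValueError("all values equal: percentile threshold is undefined")
    E = v.size
    k = math.ceil((100.0 - pct) * E / 100.0 - 1e-9)
    k = max(1, min(k, E))
    cutoff = np.partition(v, E - k)[E - k]
    return EdgeMask(bits=v >= cutoff, provenance=f"percentile>={pct}")
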